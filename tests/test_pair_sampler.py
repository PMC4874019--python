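"""The random independent sister-pair sampling algorithm."""
import numpy as np
import pytest

import ratepairs as rp
from ratepairs.pair_sampler import SamplerYieldError, find_partner, sample_pairs

from .conftest import make_traits
from .oracles import enumerate_reachable_pairsets, max_pairs_by_enumeration


def pair_key(pairset):
    return pairset.key()


class TestFindPartner:
    def test_cherry_meeting_threshold(self, cherry_tree, rng):
        traits = make_traits(A=(10, 0), B=(20, 0))
        pair = find_partner(cherry_tree, traits, "A", set(), 5.3, rng)
        assert pair is not None
        assert {pair.tip_a, pair.tip_b} == {"A", "B"}
        assert pair.bl_a == pytest.approx(0.1)
        assert pair.bl_b == pytest.approx(0.2)

    def test_cherry_below_threshold(self, cherry_tree, rng):
        traits = make_traits(A=(10, 0), B=(12, 0))
        assert find_partner(cherry_tree, traits, "A", set(), 5.3, rng) is None

    def test_blocked_sibling_prevents_pairing(self, three_tip_tree, rng):
        # C is outside A's sister clade; with B blocked, A has no partner
        traits = make_traits(A=(10, 0), B=(20, 0), C=(30, 0))
        pair = find_partner(three_tip_tree, traits, "A", {"B"}, 5.3, rng)
        assert pair is None

    def test_sister_clade_partner_not_always_cherry_mate(self, rng):
        # focal C's sister clade is (A,B); closest admissible is chosen
        tree = rp.PhyloTree.from_newick_string(
            "((A:0.1,B:0.5):0.2,C:0.4);"
        )
        traits = make_traits(A=(10, 0), B=(25, 0), C=(30, 0))
        pair = find_partner(tree, traits, "C", set(), 5.3, rng)
        # A: dist 0.1+0.2+0.4, dT=20 admissible; B: dist 0.5+0.2+0.4, dT=5 not
        assert pair is not None and {pair.tip_a, pair.tip_b} == {"C", "A"}
        assert pair.bl_a == pytest.approx(0.4)   # C to root
        assert pair.bl_b == pytest.approx(0.3)   # A to root

    def test_missing_traits_errors(self, cherry_tree, rng):
        traits = make_traits(A=(10, 0))
        with pytest.raises(KeyError):
            find_partner(cherry_tree, traits, "A", set(), 5.3, rng)

    def test_matches_enumeration_on_small_trees(self, rng):
        # admissible-partner rule against exhaustive dendropy-based search
        newick = "(((t1:1.0,t2:2.0):1.0,t3:0.5):1.0,(t4:1.0,t5:1.0):2.0);"
        temps = dict(t1=0.0, t2=10.0, t3=20.0, t4=5.0, t5=30.0)
        traits = make_traits(**{k: (v, 0) for k, v in temps.items()})
        tree = rp.PhyloTree.from_newick_string(newick)
        reachable = enumerate_reachable_pairsets(newick, temps, 5.3)
        observed = set()
        for seed in range(300):
            ps = sample_pairs(
                tree, traits,
                rp.SamplerConfig(temp_threshold=5.3, min_pairs_per_run=2,
                                 n_kept_runs=1, rng_seed=0),
                np.random.default_rng(seed),
            )
            observed.add(ps.key())
        assert observed == reachable


class TestSamplePairs:
    def test_two_tip_tree_always_one_pair(self, cherry_tree, rng):
        traits = make_traits(A=(0, 0), B=(30, 0))
        cfg = rp.SamplerConfig(min_pairs_per_run=2, n_kept_runs=1)
        for seed in range(10):
            ps = sample_pairs(cherry_tree, traits, cfg,
                              np.random.default_rng(seed))
            assert len(ps) == 1

    def test_balanced_four_tips_pairs_both_cherries(self, rng):
        tree = rp.PhyloTree.from_newick_string(
            "((A:1,B:1):1,(C:1,D:1):1);"
        )
        traits = make_traits(A=(0, 0), B=(10, 0), C=(20, 0), D=(30, 0))
        cfg = rp.SamplerConfig(temp_threshold=5.3, min_pairs_per_run=2,
                               n_kept_runs=1)
        expected = frozenset(
            {frozenset({"A", "B"}), frozenset({"C", "D"})}
        )
        for seed in range(50):
            ps = sample_pairs(tree, traits, cfg, np.random.default_rng(seed))
            assert ps.key() == expected

    def test_threshold_zero_pairs_every_cherry(self, balanced_ultrametric):
        traits = make_traits(
            **{t: (i, 0) for i, t in enumerate("ABCDEFGH")}
        )
        cfg = rp.SamplerConfig(temp_threshold=0.0, min_pairs_per_run=2,
                               n_kept_runs=1)
        cherries = frozenset(
            frozenset(p) for p in [("A", "B"), ("C", "D"),
                                   ("E", "F"), ("G", "H")]
        )
        for seed in range(30):
            ps = sample_pairs(balanced_ultrametric, traits, cfg,
                              np.random.default_rng(seed))
            assert ps.key() == cherries
            assert len(ps) == 4  # 2n tips -> n pairs

    def test_no_pairs_when_all_temperatures_close(self, balanced_ultrametric):
        traits = make_traits(
            **{t: (20 + 0.01 * i, 0) for i, t in enumerate("ABCDEFGH")}
        )
        cfg = rp.SamplerConfig(temp_threshold=5.3, min_pairs_per_run=2,
                               n_kept_runs=1)
        ps = sample_pairs(balanced_ultrametric, traits, cfg,
                          np.random.default_rng(0))
        assert len(ps) == 0

    def test_invariants_on_simulated_tree(self, small_dataset):
        tree, traits, _ = small_dataset
        cfg = rp.SamplerConfig(min_pairs_per_run=2, n_kept_runs=1)
        ps = sample_pairs(tree, traits, cfg, np.random.default_rng(1))
        assert len(ps) <= tree.n_tips // 2
        seen = set()
        clades = []
        for p in ps.pairs:
            assert p.tip_a != p.tip_b
            assert p.bl_a >= 0 and p.bl_b >= 0
            assert abs(p.temp_a - p.temp_b) >= cfg.temp_threshold
            for t in (p.tip_a, p.tip_b):
                assert t not in seen
                seen.add(t)
            clades.append(set(tree.labels[t] for t in tree.desc_tips(p.mrca)))
        for i in range(len(clades)):
            for j in range(i + 1, len(clades)):
                assert not (clades[i] & clades[j]), "clades overlap"

    def test_threshold_monotonicity_of_max_pair_count(self):
        # exact maxima from exhaustive enumeration must be non-increasing
        rng = np.random.default_rng(12)
        for _ in range(5):
            chrono = rp.synthetic_data.simulate_yule_tree(6, 1.0, rng)
            newick = chrono.to_newick()
            temps = {t: float(x) for t, x in
                     zip(chrono.tip_labels, rng.uniform(0, 30, 6))}
            maxima = [
                max_pairs_by_enumeration(newick, temps, thr)
                for thr in (0.0, 2.0, 5.3, 10.0)
            ]
            assert maxima == sorted(maxima, reverse=True)


class TestReplicates:
    def test_kept_runs_reach_min_pairs(self, small_dataset):
        tree, traits, _ = small_dataset
        cfg = rp.SamplerConfig(min_pairs_per_run=5, n_kept_runs=5, rng_seed=2)
        sets = rp.run_sampler_replicates(tree, traits, cfg)
        assert len(sets) == 5
        assert all(len(ps) >= 5 for ps in sets)

    def test_impossible_demand_raises_yield_error(self, small_dataset):
        tree, traits, _ = small_dataset
        cfg = rp.SamplerConfig(
            min_pairs_per_run=tree.n_tips // 2 + 1,
            n_kept_runs=2,
            max_attempted_runs=50,
            rng_seed=3,
        )
        with pytest.raises(SamplerYieldError, match="yield"):
            rp.run_sampler_replicates(tree, traits, cfg)

    def test_same_seed_reproduces_replicates(self, small_dataset):
        tree, traits, _ = small_dataset
        cfg = rp.SamplerConfig(min_pairs_per_run=5, n_kept_runs=4, rng_seed=7)
        a = rp.run_sampler_replicates(tree, traits, cfg)
        b = rp.run_sampler_replicates(tree, traits, cfg)
        assert [ps.pairs for ps in a] == [ps.pairs for ps in b]

    def test_pairset_hash_audits_duplicates(self, small_dataset):
        tree, traits, _ = small_dataset
        cfg = rp.SamplerConfig(min_pairs_per_run=5, n_kept_runs=3, rng_seed=7)
        sets = rp.run_sampler_replicates(tree, traits, cfg)
        hashes = [ps.content_hash() for ps in sets]
        assert all(isinstance(h, str) and len(h) == 16 for h in hashes)
        # identical pairings hash identically
        assert sets[0].content_hash() == rp.PairSet(
            pairs=list(sets[0].pairs)
        ).content_hash()
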
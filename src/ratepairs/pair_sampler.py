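"""Random sampling of phylogenetically independent sister-species pairs.

One algorithm run repeatedly draws an unblocked tip uniformly at random and
tries to pair it with an unblocked tip of its sister clade — the clade
subtended by the sibling(s) of the tip's parent node. Among sister-clade
tips whose temperature differs from the focal tip by at least the
configured threshold, the patristically closest one is taken (ties broken
uniformly at random). On success every tip descending from the pair's MRCA
is blocked. A focal tip whose parent clade already contains a previously
sampled pair's clade forms no pair (its MRCA would nest around the earlier
contrast), so the clades subtended by the accepted pairs' MRCAs are
pairwise disjoint — the Maddison-style independence guarantee. A
focal tip that finds no admissible partner is blocked for the remainder of
the run (it is eligible again in later runs). The run ends when no
unblocked tip remains.

The search never ascends beyond the sister clade: a focal tip whose close
relatives all fail the threshold yields no pair rather than a distant one.
"""
from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from typing import Callable, Iterable

import numpy as np
import pandas as pd

from .tree_io import PhyloTree, SpeciesPair

log = logging.getLogger(__name__)

__all__ = [
    "SamplerConfig",
    "PairSet",
    "SamplerYieldError",
    "find_partner",
    "sample_pairs",
    "run_sampler_replicates",
    "run_kept",
    "pairs_to_frame",
]


class SamplerYieldError(RuntimeError):
    """Raised when the attempt budget is exhausted before enough runs keep."""


@dataclass(frozen=True)
class SamplerConfig:
    """Study conditions for the pair-sampling replicates.

    temp_threshold
        Minimum |ΔT| in °C between the members of a pair (default 5.3;
        10 °C is the documented robustness alternative).
    min_pairs_per_run
        A run is kept only if it produced at least this many pairs.
    n_kept_runs
        Number of kept runs the replicate set must contain.
    max_attempted_runs
        Safety cap on total attempts; ``None`` derives a generous default.
    """

    temp_threshold: float = 5.3
    min_pairs_per_run: int = 50
    n_kept_runs: int = 1000
    max_attempted_runs: int | None = None
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.temp_threshold < 0:
            raise ValueError("temp_threshold must be >= 0")
        if self.min_pairs_per_run < 2:
            raise ValueError("min_pairs_per_run must be >= 2")
        if self.n_kept_runs < 1:
            raise ValueError("n_kept_runs must be >= 1")

    @property
    def attempt_cap(self) -> int:
        if self.max_attempted_runs is not None:
            return self.max_attempted_runs
        return max(200, 20 * self.n_kept_runs)


@dataclass
class PairSet:
    """The pairs from one algorithm run plus the tips their clades block."""

    pairs: list[SpeciesPair] = field(default_factory=list)
    used_tips: frozenset[str] = frozenset()

    def __len__(self) -> int:
        return len(self.pairs)

    def key(self) -> frozenset[frozenset[str]]:
        """Order-free identity of the sampled pairing."""
        return frozenset(frozenset((p.tip_a, p.tip_b)) for p in self.pairs)

    def content_hash(self) -> str:
        """Stable hash of the pairing, for auditing duplicate runs."""
        canon = sorted(tuple(sorted((p.tip_a, p.tip_b))) for p in self.pairs)
        return hashlib.sha1(repr(canon).encode()).hexdigest()[:16]


class _Prepared:
    """Tree-plus-traits working arrays shared by all runs of one analysis."""

    __slots__ = ("tree", "temp", "abslat", "tip_index")

    def __init__(self, tree: PhyloTree, traits: pd.DataFrame):
        self.tree = tree
        n = tree.n_nodes
        self.temp = np.full(n, np.nan)
        self.abslat = np.full(n, np.nan)
        self.tip_index = np.full(n, -1, dtype=np.int64)
        for k, node in enumerate(tree.tip_nodes):
            label = tree.labels[node]
            if label not in traits.index:
                raise KeyError(f"tip {label!r} has no trait row")
            row = traits.loc[label]
            self.temp[node] = float(row["temperature"])
            self.abslat[node] = float(row["abs_latitude"])
            self.tip_index[node] = k
        tree.depth  # warm caches shared across runs
        tree.desc_tips(tree.root)


def _find_partner_node(
    prep: _Prepared,
    blocked: np.ndarray,
    used: np.ndarray,
    focal: int,
    temp_threshold: float,
    rng: np.random.Generator,
) -> SpeciesPair | None:
    tree = prep.tree
    parent = int(tree.parent[focal])
    if parent < 0:  # single-tip tree
        return None
    cand = tree.desc_tips(parent)
    # any pair formed here has MRCA = parent; if that clade already
    # contains a sampled pair's clade the contrasts would nest, so the
    # focal tip cannot form an independent pair at all
    if used[cand].any():
        return None
    cand = cand[(cand != focal) & ~blocked[cand]]
    if cand.size == 0:
        return None
    dtemp = np.abs(prep.temp[cand] - prep.temp[focal])
    cand = cand[dtemp >= temp_threshold]
    if cand.size == 0:
        return None
    depth = tree.depth
    dist = depth[cand] - depth[parent]  # focal-side length is shared
    best = cand[dist == dist.min()]
    partner = int(best[0]) if best.size == 1 else int(rng.choice(best))
    return SpeciesPair(
        tip_a=tree.labels[focal],
        tip_b=tree.labels[partner],
        mrca=parent,
        bl_a=float(depth[focal] - depth[parent]),
        bl_b=float(depth[partner] - depth[parent]),
        temp_a=float(prep.temp[focal]),
        temp_b=float(prep.temp[partner]),
        abslat_a=float(prep.abslat[focal]),
        abslat_b=float(prep.abslat[partner]),
    )


def find_partner(
    tree: PhyloTree,
    traits: pd.DataFrame,
    focal_tip: str,
    blocked_tips: Iterable[str],
    temp_threshold: float,
    rng: np.random.Generator,
    used_tips: Iterable[str] = (),
) -> SpeciesPair | None:
    """Pair ``focal_tip`` with the closest admissible tip of its sister clade.

    Candidates are the unblocked tips of the clade subtended by the
    sibling(s) of the focal tip's parent; among those with
    ``|ΔT| >= temp_threshold`` the one at minimal patristic distance wins,
    ties broken uniformly at random. ``used_tips`` are tips belonging to
    previously sampled pairs' clades: if the focal tip's parent clade
    contains any of them the pair would nest inside — not be independent
    of — an earlier contrast, and the focal yields no pair. Returns
    ``None`` when no candidate qualifies.
    """
    prep = _Prepared(tree, traits)
    focal = tree.node_of(focal_tip)
    blocked = np.zeros(tree.n_nodes, dtype=bool)
    for lbl in blocked_tips:
        blocked[tree.node_of(lbl)] = True
    used = np.zeros(tree.n_nodes, dtype=bool)
    for lbl in used_tips:
        used[tree.node_of(lbl)] = True
        blocked[tree.node_of(lbl)] = True
    if blocked[focal]:
        raise ValueError(f"focal tip {focal_tip!r} is blocked")
    return _find_partner_node(prep, blocked, used, focal, temp_threshold, rng)


def _run_once(
    prep: _Prepared, temp_threshold: float, rng: np.random.Generator
) -> PairSet:
    tree = prep.tree
    tips = tree.tip_nodes
    unblocked = np.ones(tips.size, dtype=bool)
    blocked_nodes = np.zeros(tree.n_nodes, dtype=bool)
    used_nodes = np.zeros(tree.n_nodes, dtype=bool)
    pairs: list[SpeciesPair] = []
    used: set[str] = set()
    while True:
        open_tips = tips[unblocked]
        if open_tips.size == 0:
            break
        focal = int(rng.choice(open_tips))
        pair = _find_partner_node(
            prep, blocked_nodes, used_nodes, focal, temp_threshold, rng
        )
        if pair is None:
            blocked_nodes[focal] = True
            unblocked[prep.tip_index[focal]] = False
            continue
        pairs.append(pair)
        clade = tree.desc_tips(pair.mrca)
        blocked_nodes[clade] = True
        used_nodes[clade] = True
        unblocked[prep.tip_index[clade]] = False
        used.update(tree.labels[t] for t in clade)
    return PairSet(pairs=pairs, used_tips=frozenset(used))


def sample_pairs(
    tree: PhyloTree,
    traits: pd.DataFrame,
    config: SamplerConfig,
    rng: np.random.Generator,
) -> PairSet:
    """One algorithm run; see the module docstring for the loop."""
    if tree.n_tips < 2:
        raise ValueError("need at least 2 tips to sample pairs")
    prep = _Prepared(tree, traits)
    return _run_once(prep, config.temp_threshold, rng)


def run_kept(
    tree: PhyloTree,
    traits: pd.DataFrame,
    config: SamplerConfig,
    keep: Callable[[PairSet], object | None] | None = None,
):
    """Attempt runs until ``config.n_kept_runs`` pass the keep filter.

    ``keep`` maps a PairSet to a payload (kept) or ``None`` (rejected);
    by default a run keeps iff it reached ``min_pairs_per_run`` pairs.
    Returns the list of payloads. Deterministic in ``config.rng_seed``:
    attempt ``i`` always uses the ``i``-th spawned child stream.
    """
    if tree.n_tips < 2:
        raise ValueError("need at least 2 tips to sample pairs")
    prep = _Prepared(tree, traits)
    base = np.random.SeedSequence(config.rng_seed)
    if keep is None:
        keep = lambda ps: ps if len(ps) >= config.min_pairs_per_run else None
    kept: list[object] = []
    attempted = 0
    cap = config.attempt_cap
    while len(kept) < config.n_kept_runs:
        if attempted >= cap:
            rate = len(kept) / attempted if attempted else 0.0
            raise SamplerYieldError(
                f"kept {len(kept)}/{config.n_kept_runs} runs after "
                f"{attempted} attempts (yield {rate:.1%}); "
                "min_pairs_per_run may be unattainable on this input"
            )
        rng = np.random.default_rng(base.spawn(1)[0])
        attempted += 1
        payload = keep(_run_once(prep, config.temp_threshold, rng))
        if payload is not None:
            kept.append(payload)
    log.info("kept %d runs out of %d attempts", len(kept), attempted)
    return kept


def run_sampler_replicates(
    tree: PhyloTree, traits: pd.DataFrame, config: SamplerConfig
) -> list[PairSet]:
    """Replicate runs, keeping those with at least ``min_pairs_per_run``."""
    return run_kept(tree, traits, config)


def pairs_to_frame(pairsets: Iterable[PairSet]) -> pd.DataFrame:
    """Serialize pair sets to one row per pair, tagged by run_id."""
    rows = []
    for run_id, ps in enumerate(pairsets):
        for p in ps.pairs:
            rows.append(
                dict(
                    run_id=run_id,
                    tip_a=p.tip_a,
                    tip_b=p.tip_b,
                    bl_a=p.bl_a,
                    bl_b=p.bl_b,
                    temp_a=p.temp_a,
                    temp_b=p.temp_b,
                    abslat_a=p.abslat_a,
                    abslat_b=p.abslat_b,
                )
            )
    cols = [
        "run_id", "tip_a", "tip_b", "bl_a", "bl_b",
        "temp_a", "temp_b", "abslat_a", "abslat_b",
    ]
    return pd.DataFrame(rows, columns=cols)
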
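"""Synthetic trees and traits with a tunable temperature→rate coupling.

The generator composes four stages:

1. A Yule (pure-birth) chronogram grown from a crown of two lineages
   until ``n_tips`` lineages exist, plus one final exponential waiting
   period, so crown age has expectation (1/λ) Σ_{k=2..n} 1/k.
2. Brownian motion of mean annual temperature along the chronogram
   (child = parent + N(0, σ²·edge)), giving tips phylogenetic signal.
3. A monotone temperature→|latitude| map with Gaussian noise,
   |lat| = clamp((T_eq − T)/k + ε, 0, 90), hemisphere sign uniform —
   encoding the empirical anticorrelation between temperature and
   absolute latitude.
4. A branch-rate model: each edge evolves at
   r = r0·exp(β·(T̄ − T_ref)) with T̄ the mean of the parent and child
   temperatures, so its substitution length is r·duration, optionally
   multiplied by mean-1 lognormal noise. β = ln(2)/10 makes the rate
   double per 10 °C; β = 0 is the exact null (every branch r0·duration).

Temperature drives latitude, not vice versa, so any latitude-mode signal
in generated data is purely a consequence of the temperature coupling.
"""
from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .tree_io import PhyloTree, validate_traits

__all__ = [
    "SimConfig",
    "simulate_yule_tree",
    "simulate_bm_temperature",
    "temperature_to_latitude",
    "apply_rate_model",
    "generate_dataset",
]


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the generator (units in field comments).

    Defaults are sized to a mid-sized ectotherm clade: ~400 tips, tip
    temperatures spanning roughly 0–35 °C, and root-to-tip molecular
    depths around 0.3 substitutions/site.
    """

    n_tips: int = 400
    birth_rate: float = 1.0            # Yule speciation rate per unit time
    bm_sigma: float = 4.5              # temperature BM step SD, °C per sqrt(time)
    root_temperature: float = 18.0     # °C at the crown
    lat_equator_temp: float = 27.0     # T_eq: temperature mapping to |lat| = 0
    lat_gradient: float = 0.6          # k: °C lost per degree of latitude
    lat_noise_sd: float = 3.0          # degrees
    base_rate: float = 0.05            # r0: substitutions/site per unit time
    coupling: float = 0.0              # beta: per °C; exp(beta·ΔT) multiplier
    ref_temperature: float = 18.0      # T_ref for the rate model
    branch_noise: str = "lognormal"    # "none" | "lognormal" (mean-1)
    branch_noise_sd: float = 0.1       # σ_b of log branch noise
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tips < 2:
            raise ValueError("n_tips must be >= 2")
        if self.birth_rate <= 0 or self.base_rate <= 0:
            raise ValueError("birth_rate and base_rate must be > 0")
        if self.lat_gradient <= 0:
            raise ValueError("lat_gradient must be > 0")
        if self.branch_noise not in ("none", "lognormal"):
            raise ValueError("branch_noise must be 'none' or 'lognormal'")


def simulate_yule_tree(
    n_tips: int, birth_rate: float, rng: np.random.Generator
) -> PhyloTree:
    """Pure-birth ultrametric chronogram with ``n_tips`` tips.

    Grown from a crown of two lineages; while k lineages are alive the
    next event waits Exp(k·birth_rate). After reaching ``n_tips``
    lineages one more waiting period elapses before the present, so tips
    keep a positive terminal branch.
    """
    if n_tips < 2:
        raise ValueError("n_tips must be >= 2")
    lam = float(birth_rate)
    parent = [-1]
    start = [0.0]  # birth time of each node's subtending edge
    # active lineages: node ids whose edges are still growing
    active = [1, 2]
    parent += [0, 0]
    start += [0.0, 0.0]
    t = 0.0
    while len(active) < n_tips:
        k = len(active)
        t += rng.exponential(1.0 / (k * lam))
        i = int(rng.integers(k))
        node = active[i]
        # lineage `node` speciates at time t: it becomes an internal node
        left, right = len(parent), len(parent) + 1
        parent += [node, node]
        start += [t, t]
        active[i] = left
        active.append(right)
    t += rng.exponential(1.0 / (len(active) * lam))
    n_nodes = len(parent)
    lengths = np.zeros(n_nodes)
    labels: list[str | None] = [None] * n_nodes
    active_set = set(active)
    end = np.full(n_nodes, t)
    # an internal node's edge ends when its children are born
    for v in range(1, n_nodes):
        end[parent[v]] = start[v]
    for v in active:
        end[v] = t
    tip_no = 0
    for v in range(n_nodes):
        if v in active_set:
            tip_no += 1
            labels[v] = f"t{tip_no}"
        lengths[v] = 0.0 if v == 0 else end[v] - start[v]
    return PhyloTree(np.asarray(parent), lengths, labels)


def simulate_bm_temperature(
    tree: PhyloTree,
    root_temperature: float,
    bm_sigma: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Brownian temperatures for every node; child = parent + N(0, σ²·len)."""
    temps = np.empty(tree.n_nodes)
    steps = rng.normal(0.0, 1.0, size=tree.n_nodes)
    for v in tree.preorder():
        p = tree.parent[v]
        if p < 0:
            temps[v] = root_temperature
        else:
            temps[v] = temps[p] + bm_sigma * np.sqrt(tree.edge_length[v]) * steps[v]
    return temps


def temperature_to_latitude(
    tip_temperatures: np.ndarray,
    lat_equator_temp: float,
    lat_gradient: float,
    lat_noise_sd: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Signed latitudes from temperatures via a noisy linear gradient."""
    temps = np.asarray(tip_temperatures, dtype=float)
    abslat = (lat_equator_temp - temps) / lat_gradient
    if lat_noise_sd > 0:
        abslat = abslat + rng.normal(0.0, lat_noise_sd, size=temps.shape)
    abslat = np.clip(abslat, 0.0, 90.0)
    sign = np.where(rng.random(temps.shape) < 0.5, -1.0, 1.0)
    return sign * abslat


def apply_rate_model(
    tree: PhyloTree,
    node_temperatures: np.ndarray,
    base_rate: float,
    coupling: float,
    ref_temperature: float,
    branch_noise_sd: float | None,
    rng: np.random.Generator,
) -> PhyloTree:
    """Convert a chronogram into a substitutions-per-site tree.

    Edge rate is base_rate·exp(coupling·(T̄ − T_ref)) with T̄ the mean of
    parent and child temperatures; lognormal noise, if requested, is
    mean-1 parameterized (location −σ²/2) so it never biases the rate.
    """
    temps = np.asarray(node_temperatures, dtype=float)
    lengths = np.zeros(tree.n_nodes)
    nz = tree.parent >= 0
    par = tree.parent[nz]
    tbar = 0.5 * (temps[nz] + temps[par])
    rate = base_rate * np.exp(coupling * (tbar - ref_temperature))
    sub = rate * tree.edge_length[nz]
    if branch_noise_sd is not None and branch_noise_sd > 0:
        s = float(branch_noise_sd)
        noise = rng.lognormal(mean=-0.5 * s * s, sigma=s, size=sub.shape)
        sub = sub * noise
    lengths[nz] = sub
    return tree.with_edge_lengths(lengths)


def generate_dataset(
    config: SimConfig, out_dir: str | Path | None = None
) -> tuple[PhyloTree, pd.DataFrame, PhyloTree]:
    """Run the full generator.

    Returns (substitutions tree, trait table, chronogram). With
    ``out_dir`` set, writes ``tree.nwk`` (substitutions), ``traits.csv``
    and ``sim_config.json`` there.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.rng_seed))
    chrono = simulate_yule_tree(config.n_tips, config.birth_rate, rng)
    temps = simulate_bm_temperature(
        chrono, config.root_temperature, config.bm_sigma, rng
    )
    tip_temps = temps[chrono.tip_nodes]
    lats = temperature_to_latitude(
        tip_temps,
        config.lat_equator_temp,
        config.lat_gradient,
        config.lat_noise_sd,
        rng,
    )
    noise_sd = None if config.branch_noise == "none" else config.branch_noise_sd
    subs_tree = apply_rate_model(
        chrono,
        temps,
        config.base_rate,
        config.coupling,
        config.ref_temperature,
        noise_sd,
        rng,
    )
    traits = validate_traits(
        pd.DataFrame(
            dict(
                species_id=[chrono.labels[v] for v in chrono.tip_nodes],
                temperature=tip_temps,
                latitude=lats,
            )
        )
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        subs_tree.write_newick(out / "tree.nwk")
        traits.reset_index().to_csv(out / "traits.csv", index=False)
        (out / "sim_config.json").write_text(
            json.dumps(asdict(config), indent=2) + "\n"
        )
    return subs_tree, traits, chrono
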
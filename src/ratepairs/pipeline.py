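"""Orchestration: replicate sampling → contrasts → MA fits → summaries.

A single analysis draws ``n_kept_runs`` kept sampler runs and, for each,
fits a major-axis regression in one or both contrast modes. When both
modes are requested they run on the *same* kept pair sets, so the two
analyses are strictly paired (identical run_id → pairing hash).

The across-replicate "95% CI" reported in the summary is the empirical
2.5–97.5 percentile interval of the replicate slopes (linear-interpolation
percentile estimator), distinct from the per-replicate analytic slope CI
used for the significance calls.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import contrasts as _contrasts
from . import ma_regression as _ma
from . import pair_sampler as _sampler
from .pair_sampler import PairSet, SamplerConfig
from .tree_io import PhyloTree

log = logging.getLogger(__name__)

__all__ = [
    "AnalysisConfig",
    "ReplicateSummary",
    "run_analysis",
    "summarize_replicates",
    "richness_histogram",
    "plot_slope_distribution",
    "REFERENCE_SLOPES",
]

REFERENCE_SLOPES = {"temperature": 1.0, "abs_latitude": 0.0}


@dataclass(frozen=True)
class AnalysisConfig:
    """Sampler conditions plus regression settings for one analysis."""

    sampler: SamplerConfig = field(default_factory=SamplerConfig)
    modes: tuple[str, ...] = ("temperature",)
    alpha: float = 0.05
    reference_slopes: dict | None = None  # per-mode override of the defaults
    ci_method: str = "analytic"

    def __post_init__(self) -> None:
        for m in self.modes:
            if m not in _contrasts.MODES:
                raise ValueError(f"unknown mode {m!r}")

    def reference_for(self, mode: str) -> float:
        if self.reference_slopes and mode in self.reference_slopes:
            return float(self.reference_slopes[mode])
        return REFERENCE_SLOPES[mode]


@dataclass
class ReplicateSummary:
    """Per-replicate fits and their aggregates for one contrast mode."""

    mode: str
    reference_slope: float
    replicates: pd.DataFrame  # run_id, n_pairs, n_dropped, slope, ...
    mean_slope: float
    median_slope: float
    slope_p2_5: float
    slope_p97_5: float
    count_sig_above: int
    count_sig_below: int
    count_not_significant: int
    min_n_pairs: int
    max_n_pairs: int
    n_resampled: int

    def to_dict(self) -> dict:
        return dict(
            mode=self.mode,
            reference_slope=self.reference_slope,
            n_replicates=int(len(self.replicates)),
            mean_slope=self.mean_slope,
            median_slope=self.median_slope,
            slope_p2_5=self.slope_p2_5,
            slope_p97_5=self.slope_p97_5,
            count_sig_above=self.count_sig_above,
            count_sig_below=self.count_sig_below,
            count_not_significant=self.count_not_significant,
            min_n_pairs=self.min_n_pairs,
            max_n_pairs=self.max_n_pairs,
            n_resampled=self.n_resampled,
        )


def summarize_replicates(slopes, calls) -> dict:
    """Aggregate replicate slopes and significance calls.

    Percentiles use linear interpolation between order statistics
    (numpy's default), documented because the bounds at small replicate
    counts depend on the estimator.
    """
    slopes = np.asarray(list(slopes), dtype=float)
    calls = list(calls)
    if slopes.size == 0:
        raise ValueError("need at least one fit to summarize")
    lo, hi = np.percentile(slopes, [2.5, 97.5], method="linear")
    return dict(
        mean_slope=float(np.mean(slopes)),
        median_slope=float(np.median(slopes)),
        slope_p2_5=float(lo),
        slope_p97_5=float(hi),
        count_sig_above=int(sum(c == "sig_above" for c in calls)),
        count_sig_below=int(sum(c == "sig_below" for c in calls)),
        count_not_significant=int(sum(c == "not_significant" for c in calls)),
    )


def run_analysis(
    tree: PhyloTree,
    traits: pd.DataFrame,
    config: AnalysisConfig,
    out_dir: str | Path | None = None,
) -> dict[str, ReplicateSummary]:
    """Full replicate analysis; returns one summary per requested mode.

    A sampler run is kept when it reaches ``min_pairs_per_run`` pairs
    *and* yields a usable (≥3-row) contrast table in every requested
    mode; otherwise it is resampled (counted in ``n_resampled``).
    Deterministic given ``config.sampler.rng_seed``. With ``out_dir``
    set, writes ``pairs.csv``, per-mode ``replicates_<mode>.csv`` and
    ``summary.json``.
    """
    missing = set(tree.tip_labels) - set(traits.index)
    if missing:
        raise ValueError(
            f"{len(missing)} tree tips lack trait rows; join_traits first"
        )
    rng_boot = np.random.default_rng(
        np.random.SeedSequence(entropy=config.sampler.rng_seed, spawn_key=(2**20,))
    )
    n_resampled = 0

    def keep(ps: PairSet):
        nonlocal n_resampled
        if len(ps) < config.sampler.min_pairs_per_run:
            return None
        tables = {}
        for mode in config.modes:
            try:
                tables[mode] = _contrasts.build_contrasts(ps, mode)
            except _contrasts.ContrastError:
                n_resampled += 1
                log.info("run rejected: unusable %s contrast table", mode)
                return None
        return ps, tables

    kept = _sampler.run_kept(tree, traits, config.sampler, keep)
    pairsets = [ps for ps, _ in kept]
    summaries: dict[str, ReplicateSummary] = {}
    for mode in config.modes:
        ref = config.reference_for(mode)
        rows = []
        for run_id, (ps, tables) in enumerate(kept):
            table, dropped = tables[mode]
            fit = _ma.ma_fit(
                table["x"].to_numpy(),
                table["y"].to_numpy(),
                alpha=config.alpha,
                ci_method=config.ci_method,
                rng=rng_boot if config.ci_method == "bootstrap" else None,
            )
            rows.append(
                dict(
                    run_id=run_id,
                    n_pairs=len(ps),
                    n_used=fit.n,
                    n_dropped=dropped,
                    slope=fit.slope,
                    intercept=fit.intercept,
                    pearson_r=fit.pearson_r,
                    ci_low=fit.ci_low,
                    ci_high=fit.ci_high,
                    call=_ma.classify(fit, ref),
                    pairset_hash=ps.content_hash(),
                )
            )
        frame = pd.DataFrame(rows)
        agg = summarize_replicates(frame["slope"], frame["call"])
        summaries[mode] = ReplicateSummary(
            mode=mode,
            reference_slope=ref,
            replicates=frame,
            min_n_pairs=int(frame["n_pairs"].min()),
            max_n_pairs=int(frame["n_pairs"].max()),
            n_resampled=n_resampled,
            **agg,
        )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        _sampler.pairs_to_frame(pairsets).to_csv(out / "pairs.csv", index=False)
        payload = {}
        for mode, summ in summaries.items():
            summ.replicates.to_csv(out / f"replicates_{mode}.csv", index=False)
            payload[mode] = summ.to_dict()
        (out / "summary.json").write_text(json.dumps(payload, indent=2) + "\n")
    return summaries


def richness_histogram(
    traits: pd.DataFrame, variable: str = "temperature", bin_width: float = 1.0
) -> pd.DataFrame:
    """Species counts in fixed-width bins of temperature or signed latitude.

    Bin edges are aligned to multiples of ``bin_width`` (a species at
    exactly an edge falls in the upper bin). Counts always sum to the
    number of species.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    if variable not in ("temperature", "latitude"):
        raise ValueError("variable must be 'temperature' or 'latitude'")
    values = traits[variable].to_numpy(dtype=float)
    if values.size == 0:
        return pd.DataFrame(columns=["bin_mid", "count"])
    lo = np.floor(values.min() / bin_width) * bin_width
    hi = np.floor(values.max() / bin_width) * bin_width + bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    counts, _ = np.histogram(values, bins=edges)
    mids = (edges[:-1] + edges[1:]) / 2
    out = pd.DataFrame(dict(bin_mid=mids, count=counts))
    return out[out["count"] > 0].reset_index(drop=True)


def plot_slope_distribution(summary: ReplicateSummary, path: str | Path) -> None:
    """Histogram of replicate slopes with median and reference lines."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    slopes = summary.replicates["slope"]
    ax.hist(slopes, bins=40, color="0.7", edgecolor="0.3")
    ax.axvline(summary.median_slope, color="k", lw=2, label="median slope")
    ax.axvline(
        summary.reference_slope, color="k", ls="--", lw=1.5, label="reference"
    )
    ax.axvline(summary.slope_p2_5, color="0.4", ls=":", lw=1)
    ax.axvline(summary.slope_p97_5, color="0.4", ls=":", lw=1)
    ax.set_xlabel(f"MA slope ({summary.mode} mode)")
    ax.set_ylabel("replicates")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
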
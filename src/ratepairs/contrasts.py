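"""Turn sampled pairs into the two regression datasets.

Temperature mode: each pair contributes (x = cooler species' branch
length, y = warmer species' branch length). A temperature effect on the
substitution rate shows up as an MA slope above 1.

Absolute-latitude mode: each pair contributes
(x = |lat|_high − |lat|_low >= 0,
 y = (bl_high − bl_low) / mean(bl_high, bl_low)),
oriented by absolute latitude. The standardized branch-length difference
is scale-free and bounded in [−2, 2]. Under the metabolic-theory
prediction (faster evolution near the equator) the expected slope is
negative; the test is two-sided against 0. Note the orientation fixes the
sign of the slope: orienting by the *lower*-latitude member would flip it.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

import pandas as pd

from .tree_io import SpeciesPair

log = logging.getLogger(__name__)

__all__ = [
    "PairMember",
    "ContrastError",
    "orient_pair",
    "standardized_difference",
    "build_contrasts",
]

MODES = ("temperature", "abs_latitude")


class ContrastError(ValueError):
    """Raised when too few usable rows remain for a regression."""


@dataclass(frozen=True)
class PairMember:
    label: str
    bl: float
    temp: float
    abslat: float


def _members(pair: SpeciesPair) -> tuple[PairMember, PairMember]:
    return (
        PairMember(pair.tip_a, pair.bl_a, pair.temp_a, pair.abslat_a),
        PairMember(pair.tip_b, pair.bl_b, pair.temp_b, pair.abslat_b),
    )


def orient_pair(
    pair: SpeciesPair, by: str = "temperature"
) -> tuple[PairMember, PairMember] | None:
    """Order a pair as (high, low) by temperature or absolute latitude.

    Returns ``None`` (and logs a warning) on an exact tie in the
    orientation variable — the pair carries no usable contrast and is
    dropped rather than jittered.
    """
    if by not in MODES:
        raise ValueError(f"unknown orientation variable {by!r}")
    a, b = _members(pair)
    va, vb = (a.temp, b.temp) if by == "temperature" else (a.abslat, b.abslat)
    if va == vb:
        log.warning(
            "pair (%s, %s) tied on %s (%g); dropped", a.label, b.label, by, va
        )
        return None
    return (a, b) if va > vb else (b, a)


def standardized_difference(bl_hi: float, bl_lo: float) -> float:
    """(bl_hi − bl_lo) / mean(bl_hi, bl_lo); antisymmetric, in [−2, 2]."""
    if bl_hi + bl_lo == 0:
        raise ZeroDivisionError("both branch lengths are zero; 0/0 undefined")
    return (bl_hi - bl_lo) / ((bl_hi + bl_lo) / 2.0)


def build_contrasts(
    pairs, mode: str = "temperature", min_rows: int = 3
) -> tuple[pd.DataFrame, int]:
    """Build the regression table for one run; returns (table, n_dropped).

    ``pairs`` may be a PairSet or any iterable of SpeciesPair. Rows are
    dropped for orientation ties and (latitude mode) 0/0 branch lengths.
    Raises :class:`ContrastError` if fewer than ``min_rows`` rows remain.
    """
    if mode not in MODES:
        raise ValueError(f"unknown contrast mode {mode!r}")
    seq: Iterable[SpeciesPair] = getattr(pairs, "pairs", pairs)
    rows = []
    dropped = 0
    for p in seq:
        oriented = orient_pair(p, by=mode)
        if oriented is None:
            dropped += 1
            continue
        hi, lo = oriented
        if mode == "temperature":
            rows.append(
                dict(tip_hi=hi.label, tip_lo=lo.label, x=lo.bl, y=hi.bl)
            )
        else:
            try:
                y = standardized_difference(hi.bl, lo.bl)
            except ZeroDivisionError:
                log.warning(
                    "pair (%s, %s) has two zero branch lengths; dropped",
                    hi.label, lo.label,
                )
                dropped += 1
                continue
            rows.append(
                dict(
                    tip_hi=hi.label,
                    tip_lo=lo.label,
                    x=hi.abslat - lo.abslat,
                    y=y,
                )
            )
    table = pd.DataFrame(rows, columns=["tip_hi", "tip_lo", "x", "y"])
    table["mode"] = mode
    if len(table) < min_rows:
        raise ContrastError(
            f"only {len(table)} usable rows in {mode} mode "
            f"({dropped} dropped); need >= {min_rows}"
        )
    return table, dropped
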
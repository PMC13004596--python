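"""Quadrant classification of splicing events co-regulated by two perturbations.

An event is called significant within one contrast when its |dPSI| exceeds a
threshold (default 10 percentage points) and the minimum |dPSI| supported at
95% confidence (MVdPSI95) is strictly positive. An event is co-regulated by
the two contrasts when it clears the dPSI threshold in at least one of them
and has MVdPSI95 above the floor in both; it is then assigned to one of four
quadrants by the signs of its two dPSI values. Unchanged control events are
drawn from well-expressed transcripts whose splicing moved less than one
percentage point in both contrasts with a confidence floor of zero.

All cutoffs are strict inequalities except the control MV ceiling, which is
inclusive (the unchanged set is defined by MVdPSI95 = 0).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

QUADRANTS = ("A_up_B_up", "A_up_B_down", "A_down_B_up", "A_down_B_down")


@dataclass
class QuadrantResult:
    """Per-event quadrant assignments plus the four quadrant counts."""

    assignments: pd.DataFrame  # columns: event_id, dpsi_a, dpsi_b, quadrant
    counts: dict[str, int] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return int(sum(self.counts.values()))


def significant_events(
    table: pd.DataFrame, dpsi_min: float = 10.0, mv_min: float = 0.0
) -> pd.DataFrame:
    """Events with |dpsi| > dpsi_min and mv_dpsi95 > mv_min (both strict)."""
    if table.empty:
        raise ValueError("empty event table")
    mask = (table["dpsi"].abs() > dpsi_min) & (table["mv_dpsi95"] > mv_min)
    return table[mask].reset_index(drop=True)


def _merge_contrasts(table_a: pd.DataFrame, table_b: pd.DataFrame) -> pd.DataFrame:
    a = table_a.set_index("event_id")
    b = table_b.set_index("event_id")
    shared = a.index.intersection(b.index)
    dropped = len(a.index.symmetric_difference(b.index))
    if dropped:
        logger.info("ignored %d event(s) present in only one contrast", dropped)
    merged = pd.DataFrame(
        {
            "dpsi_a": a.loc[shared, "dpsi"],
            "mv_a": a.loc[shared, "mv_dpsi95"],
            "dpsi_b": b.loc[shared, "dpsi"],
            "mv_b": b.loc[shared, "mv_dpsi95"],
        }
    )
    for col in ("base_mean",):
        if col in a.columns and col in b.columns:
            merged["base_mean_a"] = a.loc[shared, col]
            merged["base_mean_b"] = b.loc[shared, col]
    return merged


def classify_coregulated(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    dpsi_min: float = 10.0,
    mv_min: float = 0.0,
) -> QuadrantResult:
    """Classify events co-regulated by both contrasts into sign quadrants.

    Co-regulated: (|dpsi_a| > dpsi_min or |dpsi_b| > dpsi_min) and both
    MVdPSI95 values strictly above mv_min. The quadrant is the pair of dPSI
    signs; events with a dPSI of exactly zero in either contrast cannot be
    sign-assigned and are dropped with a log message.
    """
    merged = _merge_contrasts(table_a, table_b)
    coreg = merged[
        ((merged["dpsi_a"].abs() > dpsi_min) | (merged["dpsi_b"].abs() > dpsi_min))
        & (merged["mv_a"] > mv_min)
        & (merged["mv_b"] > mv_min)
    ].copy()

    zero = (coreg["dpsi_a"] == 0) | (coreg["dpsi_b"] == 0)
    if zero.any():
        logger.info("dropped %d co-regulated event(s) with dpsi exactly 0", int(zero.sum()))
        coreg = coreg[~zero]

    def _quadrant(row: pd.Series) -> str:
        ua = "up" if row["dpsi_a"] > 0 else "down"
        ub = "up" if row["dpsi_b"] > 0 else "down"
        return f"A_{ua}_B_{ub}"

    coreg["quadrant"] = coreg.apply(_quadrant, axis=1) if len(coreg) else pd.Series(dtype=str)
    assignments = coreg.reset_index().rename(columns={"index": "event_id"})
    assignments = assignments.sort_values("event_id").reset_index(drop=True)
    counts = {q: int((assignments["quadrant"] == q).sum()) for q in QUADRANTS}
    return QuadrantResult(assignments=assignments, counts=counts)


def select_control_events(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    n: int = 1000,
    dpsi_max: float = 1.0,
    mv_max: float = 0.0,
    base_mean_min: float = 100.0,
    seed: int = 0,
    allow_fewer: bool = False,
) -> pd.DataFrame:
    """Sample unchanged, expressed control events.

    Eligible events satisfy, in both contrasts, |dpsi| < dpsi_max (strict)
    and mv_dpsi95 <= mv_max, and have base_mean > base_mean_min. A uniform
    sample of size ``n`` is drawn without replacement with the given seed.
    """
    merged = _merge_contrasts(table_a, table_b)
    if "base_mean_a" not in merged.columns:
        raise ValueError("base_mean column required in both tables for control selection")
    base_mean = merged[["base_mean_a", "base_mean_b"]].mean(axis=1)
    eligible = merged[
        (merged["dpsi_a"].abs() < dpsi_max)
        & (merged["dpsi_b"].abs() < dpsi_max)
        & (merged["mv_a"] <= mv_max)
        & (merged["mv_b"] <= mv_max)
        & (base_mean > base_mean_min)
    ]
    eligible = eligible.sort_index()  # row-order independent
    if len(eligible) < n:
        if not allow_fewer:
            raise ValueError(
                f"only {len(eligible)} eligible control events, need {n} "
                "(pass allow_fewer to take all)"
            )
        logger.info(
            "control shortfall: %d eligible < %d requested; returning all", len(eligible), n
        )
        chosen = eligible
    else:
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(eligible), size=n, replace=False)
        chosen = eligible.iloc[np.sort(idx)]
    return chosen.reset_index().rename(columns={"index": "event_id"})
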
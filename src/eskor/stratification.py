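"""Length-group x G+C-range stratification of ESKOR, and extreme fold-change G+C.

Genes between 5 kb and 230 kb are sorted into four length groups
(5-15, 15-30, 30-70, 70-230 kb, half-open) and genes with whole-gene G+C in
[45, 60) into three 5-point ranges.  Per stratum the ESKOR distribution is
summarized by n, median and quartiles (linear-interpolation quantiles), the
numbers behind a violin plot.  The same summary describes the G+C content of
the 1000 most up- and 1000 most down-regulated genes by RNA fold change.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

LENGTH_GROUPS: dict[str, tuple[int, int]] = {
    "group1": (5_000, 15_000),
    "group2": (15_000, 30_000),
    "group3": (30_000, 70_000),
    "group4": (70_000, 230_000),
}

GC_RANGES: dict[str, tuple[float, float]] = {
    "range1": (45.0, 50.0),
    "range2": (50.0, 55.0),
    "range3": (55.0, 60.0),
}

DEFAULT_K_EXPR = 1000


@dataclass(frozen=True)
class StratumSummary:
    """Distribution summary of one stratum (the numbers behind a violin)."""

    length_group: str | None
    gc_range: str | None
    n: int
    median: float
    q25: float
    q75: float
    values: np.ndarray


def assign_length_group(gene_length: int) -> str | None:
    """Half-open length-group label, or None outside [5 kb, 230 kb)."""
    for label, (lo, hi) in LENGTH_GROUPS.items():
        if lo <= gene_length < hi:
            return label
    return None


def assign_gc_range(gc: float) -> str | None:
    """Half-open G+C-range label, or None outside [45, 60)."""
    for label, (lo, hi) in GC_RANGES.items():
        if lo <= gc < hi:
            return label
    return None


def _summarize(values: np.ndarray, length_group=None, gc_range=None) -> StratumSummary:
    values = np.asarray(values, dtype=float)
    if len(values) == 0:
        return StratumSummary(length_group, gc_range, 0, np.nan, np.nan, np.nan, values)
    q25, med, q75 = np.percentile(values, [25, 50, 75])  # linear interpolation
    return StratumSummary(length_group, gc_range, len(values), med, q25, q75, values)


def summarize_strata(records: pd.DataFrame) -> list[StratumSummary]:
    """ESKOR summaries over the 4 x 3 length-group x G+C-range strata.

    Empty strata are reported with n = 0 and missing statistics.
    """
    length_labels = records["length"].map(assign_length_group)
    gc_labels = records["gc"].map(assign_gc_range)
    out = []
    for lg in LENGTH_GROUPS:
        for gr in GC_RANGES:
            values = records.loc[
                (length_labels == lg) & (gc_labels == gr), "eskor"
            ].to_numpy()
            out.append(_summarize(values, lg, gr))
    return out


def strata_table(summaries: list[StratumSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "length_group": s.length_group,
                "gc_range": s.gc_range,
                "n": s.n,
                "median": s.median,
                "q25": s.q25,
                "q75": s.q75,
            }
            for s in summaries
        ]
    )


def extreme_expression_gc(
    records: pd.DataFrame, k: int = DEFAULT_K_EXPR
) -> dict[str, StratumSummary]:
    """G+C summaries of the k most up- and k most down-regulated genes.

    Ranking is by ``rna_log2fc`` with ties broken by gene id; if fewer than
    2k genes are available, k shrinks to ``floor(n/2)`` with a warning.
    """
    usable = records.dropna(subset=["rna_log2fc", "gc"])
    n = len(usable)
    if n < 2 * k:
        k = n // 2
        logger.warning("fewer than 2k genes with fold change; k shrunk to %d", k)
    ordered = usable.sort_index().sort_values(
        "rna_log2fc", ascending=False, kind="mergesort"
    )
    up = ordered.iloc[:k]["gc"].to_numpy()
    down = ordered.iloc[n - k :]["gc"].to_numpy()
    return {
        "upregulated": _summarize(up),
        "downregulated": _summarize(down),
    }
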
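"""Per-gene occupancy quantification and the ESKOR statistic.

ESKOR (Effect of Supt4h Knockdown on Occupancy by RNA polymerase) is
``log2(FPKM_KD / FPKM_UNT)`` computed from RNAPII-S2 ChIP-seq fragment
counts, each condition normalized as fragments per kilobase of gene body per
million mapped fragments.  Zero means no occupancy difference; positive means
more occupancy after knockdown.  This module also fits the FPKM-vs-G+C
linear trendlines, ranks genes by ESKOR with a moving-average G+C overlay,
and computes RNA-level log2 fold changes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import FragmentSet, GeneModel

logger = logging.getLogger(__name__)

DEFAULT_MIN_LENGTH = 5000
DEFAULT_MIN_FPKM = 0.5
DEFAULT_SMOOTH_WINDOW = 100
DEFAULT_PSEUDOCOUNT = 0.01


@dataclass(frozen=True)
class TrendFit:
    """Ordinary least-squares fit of per-gene FPKM on whole-gene G+C percent."""

    slope: float
    intercept: float
    condition: str


def count_fragments(
    genes: dict[str, GeneModel], frags: FragmentSet
) -> dict[str, int]:
    """Assign each fragment to at most one gene by its midpoint.

    A fragment counts for a gene iff ``floor((start+end)/2)`` lies in
    ``[tx_start, tx_end)``.  When genes overlap, ties are broken by smallest
    ``tx_start`` then lexicographic gene id.  Genes on chromosomes absent
    from the fragment set get zero.
    """
    counts = {gene_id: 0 for gene_id in genes}
    by_chrom: dict[str, list[GeneModel]] = {}
    for gene in genes.values():
        by_chrom.setdefault(gene.chrom, []).append(gene)
    mids_by_chrom = frags.midpoints_by_chrom()
    for chrom, chrom_genes in by_chrom.items():
        mids = mids_by_chrom.get(chrom)
        if mids is None or len(mids) == 0:
            continue
        chrom_genes.sort(key=lambda g: (g.tx_start, g.gene_id))
        starts = np.array([g.tx_start for g in chrom_genes], dtype=np.int64)
        ends = np.array([g.tx_end for g in chrom_genes], dtype=np.int64)
        overlapping = bool(len(starts) > 1 and (ends[:-1] > starts[1:]).any())
        if not overlapping:
            idx = np.searchsorted(starts, mids, side="right") - 1
            valid = idx >= 0
            valid[valid] &= mids[valid] < ends[idx[valid]]
            hit = np.bincount(idx[valid], minlength=len(chrom_genes))
            for gene, c in zip(chrom_genes, hit):
                counts[gene.gene_id] += int(c)
        else:
            # overlapping annotation: scan candidates; genes are sorted by
            # (tx_start, gene_id) so the first container wins the tie-break
            cummax_end = np.maximum.accumulate(ends)
            for m in mids:
                j = int(np.searchsorted(starts, m, side="right")) - 1
                winner = None
                k = j
                while k >= 0 and cummax_end[k] > m:
                    if ends[k] > m:
                        winner = k
                    k -= 1
                if winner is not None:
                    counts[chrom_genes[winner].gene_id] += 1
    return counts


def fpkm(count: int, gene_length: int, total_mapped: int) -> float:
    """Fragments per kilobase of gene body per million mapped fragments."""
    if total_mapped <= 0:
        raise ValueError("total_mapped must be > 0")
    if gene_length <= 0:
        raise ValueError("gene_length must be > 0")
    return count / (gene_length / 1000.0) / (total_mapped / 1e6)


def eskor(fpkm_kd: float, fpkm_unt: float) -> float:
    """log2(FPKM_KD / FPKM_UNT); both inputs must be positive."""
    if fpkm_kd <= 0 or fpkm_unt <= 0:
        raise ValueError("ESKOR requires positive FPKM in both conditions")
    return float(np.log2(fpkm_kd / fpkm_unt))


def eskor_to_percent_shift(value: float) -> int:
    """Occupancy shift from baseline implied by an ESKOR value, as a rounded percent.

    ``(2**eskor - 1) * 100``: an ESKOR of -0.25 is a -16% shift, +0.24 is +18%.
    """
    if not np.isfinite(value):
        raise ValueError("ESKOR must be finite")
    return int(round((2.0**value - 1.0) * 100.0))


def filter_genes(
    records: pd.DataFrame,
    min_length: int = DEFAULT_MIN_LENGTH,
    min_fpkm: float = DEFAULT_MIN_FPKM,
    expressed: set[str] | None = None,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply the gene-inclusion filters and report per-stage counts.

    Retains genes with gene body length >= ``min_length``, ChIP FPKM strictly
    above ``min_fpkm`` in both conditions, and (when given) membership in the
    RNA-seq ``expressed`` set.
    """
    stages = {"input": len(records)}
    out = records[records["length"] >= min_length]
    stages["length"] = len(out)
    out = out[(out["fpkm_unt"] > min_fpkm) & (out["fpkm_kd"] > min_fpkm)]
    stages["fpkm"] = len(out)
    if expressed is not None:
        out = out[out.index.isin(expressed)]
    stages["expressed"] = len(out)
    logger.info("gene filters: %s", stages)
    return out, stages


def fit_trend(records: pd.DataFrame, condition: str) -> TrendFit:
    """OLS of per-gene FPKM (y) on whole-gene G+C percent (x) for one condition."""
    if len(records) < 3:
        raise ValueError("need >= 3 records to fit a trendline")
    x = records["gc"].to_numpy(dtype=float)
    y = records[f"fpkm_{condition.lower()}"].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("degenerate fit: all G+C values identical")
    res = stats.linregress(x, y)
    return TrendFit(slope=float(res.slope), intercept=float(res.intercept), condition=condition)


def slope_drop_percent(fit_unt: TrendFit, fit_kd: TrendFit) -> int:
    """Percent drop of the KD trendline slope relative to UNT, rounded."""
    if fit_unt.slope == 0:
        raise ValueError("untreated slope is zero; drop undefined")
    return int(round((fit_unt.slope - fit_kd.slope) / fit_unt.slope * 100.0))


def rank_and_smooth(
    records: pd.DataFrame, window: int = DEFAULT_SMOOTH_WINDOW
) -> tuple[pd.DataFrame, float]:
    """Rank genes by ESKOR (descending) and smooth G+C along the ranking.

    Adds ``eskor_rank`` (1 = highest ESKOR) and ``gc_moving_avg``, a centered
    moving average of G+C over ``window`` neighboring genes, shrunk
    symmetrically at the ends of the ranking.  Also returns the Pearson
    product-moment correlation between ESKOR and G+C (NaN with a warning if
    G+C is constant).
    """
    if len(records) < window:
        logger.warning(
            "only %d genes for a %d-gene smoothing window; window shrunk",
            len(records),
            window,
        )
    # stable sort: ESKOR descending, gene id ascending on ties
    out = records.sort_index().sort_values("eskor", ascending=False, kind="mergesort")
    out = out.copy()
    out["eskor_rank"] = np.arange(1, len(out) + 1)
    gc = out["gc"].to_numpy(dtype=float)
    n = len(gc)
    half = window // 2
    smoothed = np.empty(n)
    cum = np.concatenate([[0.0], np.cumsum(gc)])
    for i in range(n):
        h = min(i, n - 1 - i, half)
        smoothed[i] = (cum[i + h + 1] - cum[i - h]) / (2 * h + 1)
    out["gc_moving_avg"] = smoothed
    esk = out["eskor"].to_numpy(dtype=float)
    if np.ptp(gc) == 0 or np.ptp(esk) == 0:
        logger.warning("ESKOR-G+C correlation undefined (constant input)")
        r = float("nan")
    else:
        r = float(stats.pearsonr(esk, gc).statistic)
    return out, r


def rna_log2fc(
    expr: pd.DataFrame, pseudocount: float = DEFAULT_PSEUDOCOUNT
) -> pd.Series:
    """Per-id log2((FPKM_KD + pseudocount) / (FPKM_UNT + pseudocount))."""
    return pd.Series(
        np.log2(
            (expr["fpkm_kd"] + pseudocount) / (expr["fpkm_unt"] + pseudocount)
        ),
        index=expr.index,
        name="rna_log2fc",
    )


def build_occupancy_table(
    genes: dict[str, GeneModel],
    frags_unt: FragmentSet,
    frags_kd: FragmentSet,
    gc: pd.Series | pd.DataFrame,
    expression: pd.DataFrame | None = None,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> pd.DataFrame:
    """Assemble the unfiltered per-gene occupancy table.

    ``gc`` maps gene id to whole-gene G+C percent (genes missing from it are
    dropped).  ``expression``, if given, is indexed by the selected isoform's
    id or the gene id and contributes ``rna_log2fc``.
    """
    if isinstance(gc, pd.DataFrame):
        gc = gc["gc"]
    counts_unt = count_fragments(genes, frags_unt)
    counts_kd = count_fragments(genes, frags_kd)
    rows = []
    for gene_id, gene in genes.items():
        if gene_id not in gc.index:
            continue
        cu, ck = counts_unt[gene_id], counts_kd[gene_id]
        rows.append(
            {
                "gene_id": gene_id,
                "length": gene.gene_length,
                "gc": float(gc.loc[gene_id]),
                "count_unt": cu,
                "count_kd": ck,
                "fpkm_unt": fpkm(cu, gene.gene_length, frags_unt.total_mapped),
                "fpkm_kd": fpkm(ck, gene.gene_length, frags_kd.total_mapped),
            }
        )
    table = pd.DataFrame(rows).set_index("gene_id")
    if expression is not None:
        fc = rna_log2fc(expression, pseudocount)
        iso_of = {gid: g.isoform_id for gid, g in genes.items()}
        table["rna_log2fc"] = [
            float(fc.get(gid, fc.get(iso_of[gid], np.nan))) for gid in table.index
        ]
    return table


def add_eskor(records: pd.DataFrame) -> pd.DataFrame:
    """Add the ESKOR column; requires positive FPKM in both conditions."""
    out = records.copy()
    out["eskor"] = np.log2(out["fpkm_kd"] / out["fpkm_unt"])
    return out
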
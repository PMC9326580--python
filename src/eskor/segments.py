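"""Per-gene 500 bp segmentation and extreme-G+C segment comparison.

Each gene body is divided into consecutive 500 bp segments starting 1 kb 3'
of the TSS (in transcription direction).  The highest- and lowest-G+C
segments of each gene are selected and their fragment counts, normalized per
million mapped fragments, are binned at 25 bp.  Cohort-level means with SEM
and a two-sample equal-variance t-test compare conditions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .gc_profiles import gc_percent
from .io_formats import FragmentSet, GeneModel, fetch_sequence

logger = logging.getLogger(__name__)

DEFAULT_OFFSET = 1000
DEFAULT_SEGMENT = 500
DEFAULT_BIN = 25


class GeneTooShortError(ValueError):
    pass


@dataclass
class SegmentProfile:
    """One gene's extreme-G+C segment with 25 bp-binned normalized counts."""

    gene_id: str
    role: str  # "highest_gc" or "lowest_gc"
    interval: tuple[int, int]  # genomic half-open
    segment_gc: float
    binned_counts_unt: np.ndarray
    binned_counts_kd: np.ndarray
    degenerate: bool = False

    @property
    def total_unt(self) -> float:
        return float(self.binned_counts_unt.sum())

    @property
    def total_kd(self) -> float:
        return float(self.binned_counts_kd.sum())


def segment_gene(
    gene: GeneModel, offset: int = DEFAULT_OFFSET, seg: int = DEFAULT_SEGMENT
) -> list[tuple[int, int]]:
    """Non-overlapping ``seg`` bp genomic intervals from TSS+offset toward the TTS.

    Returned 5'->3' in transcription order; the trailing partial segment is
    dropped.  For minus-strand genes segments advance leftward from
    ``tx_end - offset``.
    """
    n_seg = (gene.gene_length - offset) // seg
    if n_seg < 1:
        raise GeneTooShortError(
            f"{gene.gene_id}: gene length {gene.gene_length} too short for "
            f"offset {offset} + segment {seg}"
        )
    if gene.strand == "+":
        base = gene.tx_start + offset
        return [(base + i * seg, base + (i + 1) * seg) for i in range(n_seg)]
    base = gene.tx_end - offset
    return [(base - (i + 1) * seg, base - i * seg) for i in range(n_seg)]


def pick_extreme_segments(
    gene: GeneModel, segments: list[tuple[int, int]], genome
) -> tuple[int, int, list[float], bool]:
    """Indices of the highest- and lowest-G+C segments (plus all segment G+C).

    Ties are broken by the 5'-most segment.  Returns
    ``(i_highest, i_lowest, gc_values, degenerate)`` where ``degenerate``
    flags an all-equal-G+C gene (both picks collapse to the 5'-most segment).
    Fewer than two segments is an error: the contrast needs both extremes.
    """
    if len(segments) < 2:
        raise GeneTooShortError(
            f"{gene.gene_id}: need >= 2 segments for an extreme-G+C contrast"
        )
    gc_values = [
        gc_percent(fetch_sequence(genome, gene.chrom, s, e)) for s, e in segments
    ]
    arr = np.asarray(gc_values)
    i_hi = int(np.argmax(arr))  # argmax returns the first (5'-most) maximum
    i_lo = int(np.argmin(arr))
    degenerate = bool(np.ptp(arr) == 0)
    return i_hi, i_lo, gc_values, degenerate


def binned_normalized_counts(
    gene: GeneModel,
    interval: tuple[int, int],
    frags: FragmentSet,
    bin_size: int = DEFAULT_BIN,
) -> np.ndarray:
    """Fragment midpoints per ``bin_size`` bp bin, per million mapped fragments.

    Bins are ordered 5'->3' along the transcription direction.
    """
    start, end = interval
    if (end - start) % bin_size != 0:
        raise ValueError("segment length must be divisible by bin size")
    n_bins = (end - start) // bin_size
    mids = frags.midpoints_by_chrom().get(gene.chrom)
    if mids is None:
        counts = np.zeros(n_bins)
    else:
        lo = np.searchsorted(mids, start, side="left")
        hi = np.searchsorted(mids, end, side="left")
        inside = mids[lo:hi]
        counts = np.bincount((inside - start) // bin_size, minlength=n_bins).astype(
            float
        )
    if gene.strand == "-":
        counts = counts[::-1]
    return counts / (frags.total_mapped / 1e6)


def segment_profiles(
    genes: dict[str, GeneModel],
    genome,
    frags_unt: FragmentSet,
    frags_kd: FragmentSet,
    offset: int = DEFAULT_OFFSET,
    seg: int = DEFAULT_SEGMENT,
    bin_size: int = DEFAULT_BIN,
) -> list[SegmentProfile]:
    """Highest- and lowest-G+C segment profiles for every eligible gene."""
    profiles: list[SegmentProfile] = []
    skipped = 0
    for gene_id, gene in genes.items():
        try:
            segs = segment_gene(gene, offset, seg)
            i_hi, i_lo, gc_values, degenerate = pick_extreme_segments(
                gene, segs, genome
            )
        except GeneTooShortError:
            skipped += 1
            continue
        for role, idx in (("highest_gc", i_hi), ("lowest_gc", i_lo)):
            profiles.append(
                SegmentProfile(
                    gene_id=gene_id,
                    role=role,
                    interval=segs[idx],
                    segment_gc=gc_values[idx],
                    binned_counts_unt=binned_normalized_counts(
                        gene, segs[idx], frags_unt, bin_size
                    ),
                    binned_counts_kd=binned_normalized_counts(
                        gene, segs[idx], frags_kd, bin_size
                    ),
                    degenerate=degenerate,
                )
            )
    if skipped:
        logger.warning("segment analysis: %d gene(s) too short, excluded", skipped)
    return profiles


def aggregate_cohort(
    profiles: list[SegmentProfile], role: str, condition: str
) -> tuple[float, float, int]:
    """Mean, SEM and n of per-gene segment totals for a role and condition.

    The per-gene total is the sum of the 20 bins (reads per million mapped);
    SEM is the sample standard deviation over sqrt(n).  Degenerate genes
    (all segments equal in G+C) are excluded from the contrast.
    """
    totals = segment_totals(profiles, role, condition)
    if len(totals) < 2:
        raise ValueError("need >= 2 genes for a cohort mean with SEM")
    mean = float(np.mean(totals))
    sem = float(np.std(totals, ddof=1) / np.sqrt(len(totals)))
    return mean, sem, len(totals)


def segment_totals(
    profiles: list[SegmentProfile], role: str, condition: str
) -> np.ndarray:
    key = {"UNT": "total_unt", "KD": "total_kd"}[condition.upper()]
    return np.array(
        [getattr(p, key) for p in profiles if p.role == role and not p.degenerate]
    )


def ttest_equal_var(x, y) -> tuple[float, float]:
    """Two-sample Student's t-test assuming equal variances, two tails.

    Pooled-variance t with ``len(x)+len(y)-2`` degrees of freedom.  With zero
    pooled variance the p-value is 1 if the means are equal, otherwise the
    comparison is undefined and an error is raised.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need >= 2 observations per sample")
    if np.var(x, ddof=1) == 0 and np.var(y, ddof=1) == 0:
        if np.mean(x) == np.mean(y):
            return 0.0, 1.0
        raise ValueError("zero pooled variance with unequal means: t undefined")
    res = stats.ttest_ind(x, y, equal_var=True)
    return float(res.statistic), float(res.pvalue)
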
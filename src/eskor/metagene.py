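"""Scaled metagene coverage profiles for extreme-ESKOR gene sets.

Each gene body is divided, independently of its length, into 100 bins; 1 kb
flanking regions on each side are binned at a fixed 25 bp (40 bins per
flank).  Bin values are fragment-midpoint densities: count per million
mapped fragments per kilobase of bin width, so body bins of unequal width
and the fixed-width flank bins are directly comparable.  Index 0 is always
the 5'-most upstream flank bin, regardless of strand.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .io_formats import FragmentSet, GeneModel

logger = logging.getLogger(__name__)

DEFAULT_K = 2000
DEFAULT_BODY_BINS = 100
DEFAULT_FLANK = 1000
DEFAULT_FLANK_BIN = 25


def select_extreme_eskor(
    records: pd.DataFrame, k: int = DEFAULT_K
) -> tuple[list[str], list[str]]:
    """Disjoint top-k and bottom-k gene ids by ESKOR.

    Boundary ties are broken by gene id.  If fewer than ``2k`` records are
    available, k is shrunk to ``floor(n/2)`` with a warning.
    """
    n = len(records)
    if n < 2 * k:
        k = n // 2
        logger.warning("fewer than 2k genes; k shrunk to %d", k)
    ordered = records.sort_index().sort_values(
        "eskor", ascending=False, kind="mergesort"
    )
    ids = list(ordered.index)
    return ids[:k], ids[n - k :][::-1]


def gene_profile(
    gene: GeneModel,
    frags: FragmentSet,
    body_bins: int = DEFAULT_BODY_BINS,
    flank: int = DEFAULT_FLANK,
    flank_bin: int = DEFAULT_FLANK_BIN,
    chrom_length: int | None = None,
) -> np.ndarray:
    """Normalized coverage vector: upstream flank + body + downstream flank.

    Body bin edges sit at ``TSS + round(j * L / body_bins)`` in transcription
    coordinates.  Flank bins outside the chromosome (when ``chrom_length`` is
    given) are flagged missing (NaN).  Genes shorter than ``body_bins`` bp
    cannot be profiled and raise :class:`ValueError`.
    """
    L = gene.gene_length
    if L < body_bins:
        raise ValueError(
            f"{gene.gene_id}: gene length {L} < {body_bins} body bins"
        )
    n_flank = flank // flank_bin
    mids = frags.midpoints_by_chrom().get(gene.chrom)
    if mids is None:
        mids = np.empty(0, dtype=np.int64)

    # restrict to the window [TSS - flank, TTS + flank] in genomic coordinates
    g_lo, g_hi = gene.tx_start - flank, gene.tx_end + flank
    window = mids[np.searchsorted(mids, g_lo) : np.searchsorted(mids, g_hi)]
    # transcription coordinate of each midpoint: 0 at the TSS base
    if gene.strand == "+":
        x = window - gene.tx_start
    else:
        x = (gene.tx_end - 1) - window

    body_edges = np.round(np.arange(body_bins + 1) * L / body_bins).astype(np.int64)
    widths_kb = np.diff(body_edges) / 1000.0

    per_million = frags.total_mapped / 1e6
    profile = np.empty(n_flank * 2 + body_bins)

    up = x[(x >= -flank) & (x < 0)]
    up_counts = np.bincount((up + flank) // flank_bin, minlength=n_flank)
    profile[:n_flank] = up_counts / per_million / (flank_bin / 1000.0)

    body = x[(x >= 0) & (x < L)]
    idx = np.searchsorted(body_edges, body, side="right") - 1
    idx = np.clip(idx, 0, body_bins - 1)
    body_counts = np.bincount(idx, minlength=body_bins)
    profile[n_flank : n_flank + body_bins] = (
        body_counts / per_million / widths_kb
    )

    down = x[(x >= L) & (x < L + flank)]
    down_counts = np.bincount((down - L) // flank_bin, minlength=n_flank)
    profile[n_flank + body_bins :] = down_counts / per_million / (flank_bin / 1000.0)

    if chrom_length is not None:
        # mask flank bins that extend beyond the chromosome
        for j in range(n_flank):
            if gene.strand == "+":
                up_start = gene.tx_start - flank + j * flank_bin
                down_end = gene.tx_end + (j + 1) * flank_bin
            else:
                up_start = gene.tx_end + flank - (j + 1) * flank_bin
                down_end = gene.tx_start - j * flank_bin
            if gene.strand == "+":
                if up_start < 0:
                    profile[j] = np.nan
                if down_end > chrom_length:
                    profile[n_flank + body_bins + j] = np.nan
            else:
                if up_start + flank_bin > chrom_length:
                    profile[j] = np.nan
                if down_end - flank_bin < 0:
                    profile[n_flank + body_bins + j] = np.nan
    return profile


def metagene_matrix(
    genes: list[GeneModel],
    frags: FragmentSet,
    body_bins: int = DEFAULT_BODY_BINS,
    flank: int = DEFAULT_FLANK,
    flank_bin: int = DEFAULT_FLANK_BIN,
    chrom_lengths: dict[str, int] | None = None,
) -> np.ndarray:
    """Stack per-gene profiles (rows) for a gene set and one condition."""
    rows = []
    excluded = 0
    for gene in genes:
        try:
            rows.append(
                gene_profile(
                    gene,
                    frags,
                    body_bins,
                    flank,
                    flank_bin,
                    chrom_lengths.get(gene.chrom) if chrom_lengths else None,
                )
            )
        except ValueError:
            excluded += 1
    if excluded:
        logger.warning("metagene: %d gene(s) shorter than %d bp excluded", excluded, body_bins)
    return np.vstack(rows) if rows else np.empty((0, 2 * (flank // flank_bin) + body_bins))


def aggregate_metagene(profiles: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Bin-wise mean across genes, skipping missing bins.

    Returns ``(mean_profile, n_per_bin)`` where ``n_per_bin`` counts the
    genes contributing to each bin.
    """
    if profiles.size == 0:
        raise ValueError("no profiles to aggregate")
    n_per_bin = np.sum(~np.isnan(profiles), axis=0)
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(profiles, axis=0)
    return mean, n_per_bin
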
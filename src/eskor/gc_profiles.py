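"""Windowed and whole-gene G+C content along genes in transcription orientation.

The gene body (exons and introns, TSS to TTS) is scanned with non-overlapping
100 bp windows ordered 5'->3'; for minus-strand genes windows advance leftward
from ``tx_end``.  Whole-gene G+C excludes the first 1 kb downstream of the
TSS, which for nearly all genes covers a G+C-rich promoter region.  Ambiguous
bases (N) are excluded from both numerator and denominator; a window that is
mostly N is reported as missing (NaN).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .io_formats import GeneModel, fetch_sequence, reverse_complement

logger = logging.getLogger(__name__)

DEFAULT_WINDOW = 100
DEFAULT_SKIP_5PRIME = 1000
DEFAULT_HEATMAP_SPAN = 10_000

_G, _C, _N = ord("G"), ord("C"), ord("N")


class GeneTooShortError(ValueError):
    """Gene body too short for the requested analysis region."""


def transcribed_sequence(gene: GeneModel, genome, span: int | None = None) -> str:
    """Gene-body sequence 5'->3' in transcription orientation.

    For minus-strand genes this is the reverse complement of the genomic
    span, so index 0 is always the TSS.  ``span`` optionally truncates to
    the first ``span`` bases downstream of the TSS.
    """
    if span is not None and span < gene.gene_length:
        if gene.strand == "+":
            seq = fetch_sequence(genome, gene.chrom, gene.tx_start, gene.tx_start + span)
        else:
            seq = fetch_sequence(genome, gene.chrom, gene.tx_end - span, gene.tx_end)
    else:
        seq = fetch_sequence(genome, gene.chrom, gene.tx_start, gene.tx_end)
    return reverse_complement(seq) if gene.strand == "-" else seq


def _codes(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def gc_percent(seq: str) -> float:
    """G+C percent of a sequence, N bases excluded from the denominator."""
    codes = _codes(seq)
    valid = int((codes != _N).sum())
    if valid == 0:
        return float("nan")
    gc = int(((codes == _G) | (codes == _C)).sum())
    return 100.0 * gc / valid


def window_gc(
    gene: GeneModel,
    genome,
    window: int = DEFAULT_WINDOW,
    step: int | None = None,
    span: int | None = None,
    max_n_fraction: float = 0.5,
) -> np.ndarray:
    """Per-window G+C percent tiling the gene body from the TSS toward the TTS.

    Windows advance in transcription direction with the given ``step``
    (default: non-overlapping, step == window).  The trailing partial window
    is dropped.  A window with at least ``max_n_fraction`` ambiguous bases is
    flagged missing (NaN).
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    step = window if step is None else step
    seq = transcribed_sequence(gene, genome, span=span)
    codes = _codes(seq)
    n = len(codes)
    if n < window:
        return np.empty(0, dtype=float)
    is_gc = ((codes == _G) | (codes == _C)).astype(np.int64)
    is_n = (codes == _N).astype(np.int64)
    cum_gc = np.concatenate([[0], np.cumsum(is_gc)])
    cum_n = np.concatenate([[0], np.cumsum(is_n)])
    offsets = np.arange(0, n - window + 1, step)
    gc = cum_gc[offsets + window] - cum_gc[offsets]
    nn = cum_n[offsets + window] - cum_n[offsets]
    valid = window - nn
    with np.errstate(invalid="ignore", divide="ignore"):
        values = 100.0 * gc / valid
    values[valid == 0] = np.nan
    values[nn >= max_n_fraction * window] = np.nan
    return values


def whole_gene_gc(
    gene: GeneModel, genome, skip_5prime: int = DEFAULT_SKIP_5PRIME
) -> float:
    """G+C percent of the gene body excluding the first ``skip_5prime`` bp after the TSS."""
    if gene.gene_length <= skip_5prime:
        raise GeneTooShortError(
            f"{gene.gene_id}: gene length {gene.gene_length} <= skip_5prime "
            f"{skip_5prime}"
        )
    seq = transcribed_sequence(gene, genome)
    return gc_percent(seq[skip_5prime:])


def dinucleotide_freq(
    gene: GeneModel,
    genome,
    skip_5prime: int = DEFAULT_SKIP_5PRIME,
    strand: str = "sense",
) -> dict[str, float]:
    """Mono- and dinucleotide percentages over the whole-gene G+C region.

    Computed 5'->3' on the sense (annotated) strand by default, or on the
    template strand with ``strand='template'``; the G+C total is identical
    either way.  Mononucleotide percentages are over unambiguous bases;
    CpG/GpC percent is dinucleotide count / (region length - 1) * 100.
    """
    if strand not in ("sense", "template"):
        raise ValueError("strand must be 'sense' or 'template'")
    if gene.gene_length <= skip_5prime:
        raise GeneTooShortError(
            f"{gene.gene_id}: gene length {gene.gene_length} <= skip_5prime "
            f"{skip_5prime}"
        )
    region = transcribed_sequence(gene, genome)[skip_5prime:]
    if strand == "template":
        region = reverse_complement(region)
    codes = _codes(region)
    valid = int((codes != _N).sum())
    out: dict[str, float] = {}
    for base in "ACGT":
        count = int((codes == ord(base)).sum())
        out[base] = 100.0 * count / valid if valid else float("nan")
    denom = len(region) - 1
    for dinuc, pattern in (("CpG", "CG"), ("GpC", "GC")):
        count = _fast_pair_count(codes, pattern)
        out[dinuc] = 100.0 * count / denom if denom > 0 else float("nan")
    return out


def _fast_pair_count(codes: np.ndarray, pattern: str) -> int:
    a, b = ord(pattern[0]), ord(pattern[1])
    return int(((codes[:-1] == a) & (codes[1:] == b)).sum())


def gc_table(
    genes: dict[str, GeneModel],
    genome,
    skip_5prime: int = DEFAULT_SKIP_5PRIME,
    with_dinucleotides: bool = False,
    strand: str = "sense",
) -> pd.DataFrame:
    """Per-gene whole-gene G+C (and optionally nucleotide frequencies).

    Genes shorter than the 5' exclusion zone are skipped with a warning.
    """
    rows = []
    skipped = []
    for gene_id, gene in genes.items():
        try:
            row = {"gene_id": gene_id, "gc": whole_gene_gc(gene, genome, skip_5prime)}
            if with_dinucleotides:
                row.update(dinucleotide_freq(gene, genome, skip_5prime, strand))
            rows.append(row)
        except GeneTooShortError:
            skipped.append(gene_id)
    if skipped:
        logger.warning(
            "%d gene(s) shorter than %d bp excluded from G+C table",
            len(skipped),
            skip_5prime,
        )
    return pd.DataFrame(rows).set_index("gene_id") if rows else pd.DataFrame(
        columns=["gc"]
    )


def heatmap_matrix(
    genes: list[GeneModel],
    genome,
    span: int = DEFAULT_HEATMAP_SPAN,
    window: int = DEFAULT_WINDOW,
) -> pd.DataFrame:
    """Windowed G+C over the first ``span`` bp of each gene, caller-ordered.

    Rows keep the input order (typically sorted by ESKOR); genes shorter than
    ``span`` are excluded.  Columns are the ``span // window`` windows from
    the TSS in transcription direction.
    """
    n_cols = span // window
    rows = {}
    excluded = 0
    for gene in genes:
        if gene.gene_length < span:
            excluded += 1
            continue
        rows[gene.gene_id] = window_gc(gene, genome, window=window, span=span)[:n_cols]
    if excluded:
        logger.info("heatmap_matrix: %d gene(s) shorter than %d bp excluded", excluded, span)
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=[f"win{i}" for i in range(n_cols)]
    )
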
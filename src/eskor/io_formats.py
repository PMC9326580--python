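"""Readers/writers for the external formats and the coordinate conventions.

All internal intervals are 0-based half-open ``[start, end)``; conversion to
and from 1-based or inclusive conventions happens only at parse/serialize
boundaries.  Gene models come from refFlat (UCSC genePred with a leading gene
symbol column), ChIP fragments from BED3+, expression tables from TSV, and
genome sequence from FASTA (via :mod:`pyfaidx`) or any mapping of chromosome
name to sequence string.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

EXPRESSION_COLUMNS = ("fpkm_unt", "fpkm_kd", "count_unt", "count_kd")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GeneModel:
    """One gene's selected isoform: span, strand and exons.

    ``tx_start``/``tx_end`` are 0-based half-open genomic coordinates.  The
    gene length is the TSS-to-TTS span including introns.  The TSS is
    ``tx_start`` for plus-strand genes and ``tx_end - 1`` for minus-strand
    genes; the TTS is the opposite end.
    """

    gene_id: str
    isoform_id: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    exons: tuple[tuple[int, int], ...] = field(default=())

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.tx_start < self.tx_end:
            raise ValueError(
                f"{self.isoform_id}: tx_start must be < tx_end "
                f"({self.tx_start} >= {self.tx_end})"
            )
        prev_end = self.tx_start
        for start, end in self.exons:
            if start < prev_end or end > self.tx_end or start >= end:
                raise ValueError(
                    f"{self.isoform_id}: exons must be sorted, non-overlapping "
                    f"and within the transcript span"
                )
            prev_end = end

    @property
    def gene_length(self) -> int:
        return self.tx_end - self.tx_start

    @property
    def tss(self) -> int:
        return self.tx_start if self.strand == "+" else self.tx_end - 1

    @property
    def tts(self) -> int:
        return self.tx_end - 1 if self.strand == "+" else self.tx_start


@dataclass
class FragmentSet:
    """A library of sequenced ChIP fragments for one condition.

    Fragments are stored as parallel arrays for speed; ``total_mapped`` is
    the library size used for per-million normalization and defaults to the
    number of records.
    """

    condition: str
    chroms: np.ndarray
    starts: np.ndarray
    ends: np.ndarray
    total_mapped: int

    def __post_init__(self) -> None:
        self.starts = np.asarray(self.starts, dtype=np.int64)
        self.ends = np.asarray(self.ends, dtype=np.int64)
        self.chroms = np.asarray(self.chroms, dtype=object)
        if len(self.starts) != len(self.ends) or len(self.starts) != len(self.chroms):
            raise ValueError("chroms, starts and ends must have equal length")
        bad = np.nonzero(self.starts >= self.ends)[0]
        if bad.size:
            i = int(bad[0])
            raise ValueError(
                f"fragment record {i + 1}: start >= end "
                f"({self.chroms[i]}:{self.starts[i]}-{self.ends[i]})"
            )
        if self.total_mapped < len(self.starts):
            raise ValueError("total_mapped must be >= number of fragments")
        self._midpoints: dict[str, np.ndarray] | None = None

    def __len__(self) -> int:
        return len(self.starts)

    @property
    def fragments(self) -> list[tuple[str, int, int]]:
        return [
            (str(c), int(s), int(e))
            for c, s, e in zip(self.chroms, self.starts, self.ends)
        ]

    def midpoints_by_chrom(self) -> dict[str, np.ndarray]:
        """Fragment midpoints ``floor((start+end)/2)``, sorted per chromosome."""
        if self._midpoints is None:
            mids = (self.starts + self.ends) // 2
            out: dict[str, np.ndarray] = {}
            order = np.argsort(self.chroms.astype(str), kind="stable")
            chroms = self.chroms[order]
            mids = mids[order]
            bounds = np.nonzero(chroms[1:] != chroms[:-1])[0] + 1
            for chunk_c, chunk_m in zip(
                np.split(chroms, bounds), np.split(mids, bounds)
            ):
                if len(chunk_c):
                    out[str(chunk_c[0])] = np.sort(chunk_m)
            self._midpoints = out
        return self._midpoints

    @classmethod
    def from_fragments(
        cls,
        condition: str,
        fragments: Iterable[tuple[str, int, int]],
        total_mapped: int | None = None,
    ) -> "FragmentSet":
        frags = list(fragments)
        chroms = np.array([f[0] for f in frags], dtype=object)
        starts = np.array([f[1] for f in frags], dtype=np.int64)
        ends = np.array([f[2] for f in frags], dtype=np.int64)
        return cls(
            condition,
            chroms,
            starts,
            ends,
            total_mapped if total_mapped is not None else len(frags),
        )


def pool_fragment_sets(sets: Sequence[FragmentSet]) -> FragmentSet:
    """Pool replicate libraries by concatenation; library sizes add."""
    if not sets:
        raise ValueError("no fragment sets to pool")
    return FragmentSet(
        sets[0].condition,
        np.concatenate([s.chroms for s in sets]),
        np.concatenate([s.starts for s in sets]),
        np.concatenate([s.ends for s in sets]),
        sum(s.total_mapped for s in sets),
    )


def _parse_exon_list(text: str) -> list[int]:
    return [int(x) for x in text.rstrip(",").split(",") if x != ""]


def read_refflat(path) -> list[GeneModel]:
    """Parse an 11-column refFlat file into one :class:`GeneModel` per line.

    txStart is taken as 0-based inclusive and txEnd as exclusive (the UCSC
    genePred convention).  Trailing commas in the exon lists are tolerated.
    Malformed lines raise :class:`ValueError` naming the line number.
    """
    models: list[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) == 1:
                fields = line.split()
            if len(fields) < 11:
                raise ValueError(
                    f"{path}: line {lineno}: expected 11 refFlat columns, "
                    f"got {len(fields)}"
                )
            gene, isoform, chrom, strand = fields[:4]
            if strand not in ("+", "-"):
                raise ValueError(
                    f"{path}: line {lineno}: strand must be '+' or '-', "
                    f"got {strand!r}"
                )
            try:
                tx_start, tx_end = int(fields[4]), int(fields[5])
                exon_count = int(fields[8])
                exon_starts = _parse_exon_list(fields[9])
                exon_ends = _parse_exon_list(fields[10])
            except ValueError as exc:
                raise ValueError(
                    f"{path}: line {lineno}: malformed numeric field ({exc})"
                ) from None
            if len(exon_starts) != exon_count or len(exon_ends) != exon_count:
                raise ValueError(
                    f"{path}: line {lineno}: exonCount={exon_count} does not "
                    f"match exon lists"
                )
            try:
                models.append(
                    GeneModel(
                        gene_id=gene,
                        isoform_id=isoform,
                        chrom=chrom,
                        strand=strand,
                        tx_start=tx_start,
                        tx_end=tx_end,
                        exons=tuple(zip(exon_starts, exon_ends)),
                    )
                )
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from None
    return models


def write_refflat(models: Iterable[GeneModel], path) -> None:
    with open(path, "w") as fh:
        for m in models:
            exon_starts = ",".join(str(s) for s, _ in m.exons) + ","
            exon_ends = ",".join(str(e) for _, e in m.exons) + ","
            fh.write(
                "\t".join(
                    [
                        m.gene_id,
                        m.isoform_id,
                        m.chrom,
                        m.strand,
                        str(m.tx_start),
                        str(m.tx_end),
                        str(m.tx_start),
                        str(m.tx_end),
                        str(len(m.exons)),
                        exon_starts,
                        exon_ends,
                    ]
                )
                + "\n"
            )


def select_most_abundant_isoform(
    models: Sequence[GeneModel], expr: pd.DataFrame
) -> dict[str, GeneModel]:
    """Pick, per gene, the isoform with the highest untreated RNA FPKM.

    ``expr`` must be indexed by isoform id and carry an ``fpkm_unt`` column.
    Ties are broken by longest gene length, then lexicographic isoform id.
    Genes with no isoform in the table are excluded with a warning.
    """
    selected: dict[str, GeneModel] = {}
    best: dict[str, tuple[float, int, str]] = {}
    skipped: set[str] = set()
    for m in models:
        if m.isoform_id not in expr.index:
            skipped.add(m.gene_id)
            continue
        fpkm = float(expr.at[m.isoform_id, "fpkm_unt"])
        # sort key: higher FPKM, then longer gene, then earlier isoform id
        key = (-fpkm, -m.gene_length, m.isoform_id)
        if m.gene_id not in best or key < best[m.gene_id]:
            best[m.gene_id] = key
            selected[m.gene_id] = m
    dropped = skipped - set(selected)
    if dropped:
        logger.warning(
            "%d gene(s) had no expressed isoform and were excluded: %s",
            len(dropped),
            ", ".join(sorted(dropped)[:10]),
        )
    return selected


def read_fragments(path, condition: str = "UNT", total_mapped: int | None = None) -> FragmentSet:
    """Read a BED3+ fragment file in file order.

    If ``total_mapped`` is omitted it defaults to the record count.  Records
    with ``start >= end`` raise :class:`ValueError` naming the record.
    """
    chroms: list[str] = []
    starts: list[int] = []
    ends: list[int] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) == 1:
                fields = line.split()
            if len(fields) < 3:
                raise ValueError(f"{path}: record {lineno}: expected >= 3 BED columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise ValueError(
                    f"{path}: record {lineno}: non-integer coordinates"
                ) from None
            if start >= end:
                raise ValueError(
                    f"{path}: record {lineno}: start >= end ({fields[0]}:{start}-{end})"
                )
            chroms.append(fields[0])
            starts.append(start)
            ends.append(end)
    return FragmentSet(
        condition,
        np.array(chroms, dtype=object),
        np.array(starts, dtype=np.int64),
        np.array(ends, dtype=np.int64),
        total_mapped if total_mapped is not None else len(starts),
    )


def write_fragments(frags: FragmentSet, path) -> None:
    with open(path, "w") as fh:
        for c, s, e in zip(frags.chroms, frags.starts, frags.ends):
            fh.write(f"{c}\t{s}\t{e}\n")


def read_expression_table(path) -> pd.DataFrame:
    """Read a TSV expression table indexed by id.

    Expected columns: ``fpkm_unt``, ``fpkm_kd``, ``count_unt``, ``count_kd``.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    missing = [c for c in EXPRESSION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing expression columns: {missing}")
    if not np.isfinite(df[["fpkm_unt", "fpkm_kd"]].to_numpy()).all():
        raise ValueError(f"{path}: FPKM values must be finite")
    if (df[["fpkm_unt", "fpkm_kd"]].to_numpy() < 0).any():
        raise ValueError(f"{path}: FPKM values must be non-negative")
    return df


def write_expression_table(expr: pd.DataFrame, path) -> None:
    expr.to_csv(path, sep="\t", index_label="id")


def open_genome(path):
    """Open an indexed FASTA as a genome source (lazily via pyfaidx)."""
    import pyfaidx

    return pyfaidx.Fasta(str(path))


def fetch_sequence(genome, chrom: str, start: int, end: int) -> str:
    """Fetch ``[start, end)`` upper-cased from a dict-of-strings or pyfaidx Fasta."""
    if start < 0 or end > chrom_length(genome, chrom):
        raise ValueError(
            f"span {chrom}:{start}-{end} outside chromosome bounds "
            f"(length {chrom_length(genome, chrom)})"
        )
    region = genome[chrom][start:end]
    seq = getattr(region, "seq", region)
    return str(seq).upper()


def chrom_length(genome, chrom: str) -> int:
    if chrom not in genome:
        raise KeyError(f"chromosome {chrom!r} not present in genome")
    return len(genome[chrom])


def write_fasta(genome: Mapping[str, str], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
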
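"""Readers and writers for the file formats the pipeline touches.

All genomic coordinates are held internally as 0-based half-open intervals
(BED arithmetic). GTF is the only 1-based inclusive surface: positions are
converted on read and on write, nowhere else.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from gffutils.feature import feature_from_line

VALID_STRANDS = {"+", "-", "."}
BIOTYPES = {"protein_coding", "known_lincrna", "novel", "unassigned"}
TRAIT_CATEGORIES = {"fat_deposition", "other"}

_NUC_RE = re.compile(r"^[ACGTN]+$")


class FormatError(ValueError):
    """Malformed record in an input file."""


class ConsistencyError(ValueError):
    """Cross-file identifier mismatch."""


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open interval on a named chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """Half-open overlap; touching intervals (end == start) do not overlap."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def gap(self, other: "GenomicInterval") -> int:
        """Distance in bp between two same-chromosome intervals; 0 if they overlap."""
        if self.chrom != other.chrom:
            raise ValueError("gap undefined across chromosomes")
        return max(0, max(self.start, other.start) - min(self.end, other.end))


@dataclass
class TranscriptModel:
    """A multi-exon transcript: span, exon chain, and a biotype label.

    The span is derived from the exons; ``length`` is the mature (summed-exon)
    length used by the structural filter and the characterization statistics.
    """

    transcript_id: str
    gene_id: str
    exons: list[GenomicInterval]
    biotype: str = "unassigned"

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"{self.transcript_id}: transcript needs >= 1 exon")
        if self.biotype not in BIOTYPES:
            raise ValueError(f"{self.transcript_id}: unknown biotype {self.biotype!r}")
        chroms = {e.chrom for e in self.exons}
        strands = {e.strand for e in self.exons}
        if len(chroms) > 1 or len(strands) > 1:
            raise ValueError(f"{self.transcript_id}: exons span chrom/strand")
        self.exons = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start < a.end:
                raise ValueError(f"{self.transcript_id}: overlapping exons")

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(
            self.exons[0].chrom,
            self.exons[0].start,
            self.exons[-1].end,
            self.exons[0].strand,
        )

    @property
    def length(self) -> int:
        return sum(e.length for e in self.exons)

    @property
    def n_exons(self) -> int:
        return len(self.exons)


@dataclass(frozen=True)
class SampleInfo:
    """One RNA-seq library: group label (fat/lean) and backfat-thickness EBV in mm."""

    sample_id: str
    group: str
    ebv: float

    def __post_init__(self) -> None:
        if self.group not in {"fat", "lean"}:
            raise ValueError(f"{self.sample_id}: group must be fat or lean")


@dataclass(frozen=True)
class QTLRecord:
    """A QTL interval with its trait name and coarse trait category."""

    qtl_id: str
    interval: GenomicInterval
    trait_name: str
    trait_category: str

    def __post_init__(self) -> None:
        if not self.trait_name:
            raise ValueError(f"{self.qtl_id}: empty trait_name")
        if self.trait_category not in TRAIT_CATEGORIES:
            raise ValueError(
                f"{self.qtl_id}: trait_category {self.trait_category!r} "
                f"not in {sorted(TRAIT_CATEGORIES)}"
            )


# ---------------------------------------------------------------------------
# GTF


def read_gtf(path: str | Path, kind: str = "assembly") -> list[TranscriptModel]:
    """Read an Ensembl-dialect GTF into TranscriptModels.

    Only ``exon`` features are used to build models; 1-based inclusive GTF
    coordinates become 0-based half-open. Biotype is taken from the
    ``gene_biotype`` (or ``transcript_biotype``) attribute when present,
    else ``unassigned``.
    """
    if kind not in {"reference", "assembly"}:
        raise ValueError("kind must be 'reference' or 'assembly'")
    exons: dict[str, list[GenomicInterval]] = {}
    meta: dict[str, tuple[str, str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            if line.rstrip("\n").count("\t") != 8:
                raise FormatError(f"{path}: parse error at line {lineno}: need 9 fields")
            try:
                feat = feature_from_line(line)
            except Exception as exc:  # gffutils raises assorted types
                raise FormatError(f"{path}: parse error at line {lineno}: {exc}") from exc
            if feat.featuretype != "exon":
                continue
            if feat.end < feat.start:
                raise FormatError(f"{path}: line {lineno}: exon end < start")
            attrs = feat.attributes
            try:
                tid = attrs["transcript_id"][0]
                gid = attrs["gene_id"][0]
            except KeyError as exc:
                raise FormatError(
                    f"{path}: line {lineno}: missing transcript_id/gene_id"
                ) from exc
            biotype = "unassigned"
            for key in ("gene_biotype", "transcript_biotype"):
                if key in attrs and attrs[key][0] in BIOTYPES:
                    biotype = attrs[key][0]
                    break
            strand = feat.strand if feat.strand in VALID_STRANDS else "."
            exons.setdefault(tid, []).append(
                GenomicInterval(feat.seqid, feat.start - 1, feat.end, strand)
            )
            meta[tid] = (gid, biotype)
    return [
        TranscriptModel(tid, meta[tid][0], ex, biotype=meta[tid][1])
        for tid, ex in exons.items()
    ]


def write_gtf(transcripts: Iterable[TranscriptModel], path: str | Path) -> None:
    """Write transcript + exon features, 1-based inclusive, Ensembl attributes."""
    with open(path, "w") as fh:
        fh.write("#!adipolinc GTF export\n")
        for t in transcripts:
            span = t.interval
            attrs = (
                f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}"; '
                f'gene_biotype "{t.biotype}";'
            )
            fh.write(
                f"{span.chrom}\tadipolinc\ttranscript\t{span.start + 1}\t{span.end}\t.\t"
                f"{span.strand}\t.\t{attrs}\n"
            )
            for e in t.exons:
                fh.write(
                    f"{e.chrom}\tadipolinc\texon\t{e.start + 1}\t{e.end}\t.\t"
                    f"{e.strand}\t.\t{attrs}\n"
                )


# ---------------------------------------------------------------------------
# QTL BED-like TSV


QTL_COLUMNS = ["chrom", "start", "end", "qtl_id", "trait_name", "trait_category"]


def read_qtl_bed(path: str | Path) -> list[QTLRecord]:
    """Read the 6-column BED-like QTL table (0-based half-open, unstranded)."""
    try:
        df = pd.read_csv(path, sep="\t", header=None, names=QTL_COLUMNS, dtype=str)
    except pd.errors.EmptyDataError:
        return []
    records = []
    for row in df.itertuples(index=False):
        if row.trait_category not in TRAIT_CATEGORIES:
            raise FormatError(
                f"{path}: QTL {row.qtl_id}: category {row.trait_category!r} "
                f"must be one of {sorted(TRAIT_CATEGORIES)}"
            )
        records.append(
            QTLRecord(
                qtl_id=row.qtl_id,
                interval=GenomicInterval(row.chrom, int(row.start), int(row.end)),
                trait_name=row.trait_name,
                trait_category=row.trait_category,
            )
        )
    return records


def write_qtl_bed(records: Iterable[QTLRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(
                f"{r.interval.chrom}\t{r.interval.start}\t{r.interval.end}\t"
                f"{r.qtl_id}\t{r.trait_name}\t{r.trait_category}\n"
            )


# ---------------------------------------------------------------------------
# FASTA / counts / samples


def read_fasta(path: str | Path) -> dict[str, str]:
    """FASTA -> {id: upper-cased sequence}; rejects non-ACGTN characters."""
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if not _NUC_RE.match(seq):
            raise FormatError(f"{path}: {rec.id}: non-ACGTN character in sequence")
        seqs[rec.id] = seq
    return seqs


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name in seqs:
            fh.write(f">{name}\n")
            s = seqs[name]
            for i in range(0, len(s), width):
                fh.write(s[i : i + width] + "\n")


def read_counts(path: str | Path) -> pd.DataFrame:
    """Gene-by-sample integer count matrix (TSV, first column gene_id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        raise FormatError(f"{path}: duplicated gene ids")
    if (df.values < 0).any():
        raise FormatError(f"{path}: negative count encountered")
    frac = df.values - df.values.astype(int)
    if (frac != 0).any():
        raise FormatError(f"{path}: non-integer count encountered")
    return df.astype(int)


def read_samples(path: str | Path) -> list[SampleInfo]:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "group": str})
    required = {"sample_id", "group", "ebv"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: needs columns {sorted(required)}")
    if df["sample_id"].duplicated().any():
        raise FormatError(f"{path}: duplicated sample ids")
    return [
        SampleInfo(r.sample_id, r.group, float(r.ebv)) for r in df.itertuples(index=False)
    ]


def check_counts_samples(counts: pd.DataFrame, samples: list[SampleInfo]) -> None:
    """Counts columns and sample metadata must name the same libraries."""
    cols = set(counts.columns)
    ids = {s.sample_id for s in samples}
    if cols != ids:
        missing = sorted(ids - cols)
        extra = sorted(cols - ids)
        raise ConsistencyError(
            f"counts/samples mismatch: missing from counts {missing}, "
            f"unknown columns {extra}"
        )
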
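"""Multi-stage lincRNA filter cascade with per-stage accounting.

Candidate intergenic transcripts are screened by structure (length >= 200 bp,
>= 2 exons), coding potential (a transparent two-term ORF score with the CPC
sign convention: negative means noncoding), protein homology evidence (any
hit with E-value below threshold discards the transcript), and expression
(FPKM > 0 in at least one sample). Survivors are labelled novel unless their
span overlaps a known lincRNA annotation.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio.Seq import Seq

from .io_formats import TranscriptModel, ConsistencyError
from .transcript_classify import SpanIndex, classify_transcripts

FRAMES = ("+1", "+2", "+3", "-1", "-2", "-3")

_NUC_RE = re.compile(r"^[ACGTN]*$")


@dataclass(frozen=True)
class OrfResult:
    """Longest complete ORF (ATG..in-frame stop, stop included) over 6 frames."""

    transcript_id: str
    longest_orf_nt: int
    orf_frame: str  # one of FRAMES or "none"
    orf_coverage: float


@dataclass(frozen=True)
class CodingPotentialResult:
    transcript_id: str
    score: float
    label: str  # coding | noncoding


@dataclass(frozen=True)
class HomologyEvidence:
    transcript_id: str
    source: str  # pfam | nr | uniref90
    evalue: float

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError(f"{self.transcript_id}: negative E-value")


@dataclass
class FilterReport:
    """Ordered per-stage survivor accounting for the identification cascade."""

    stages: list[str] = field(default_factory=list)
    n_in: dict[str, int] = field(default_factory=dict)
    n_out: dict[str, int] = field(default_factory=dict)
    survivors: dict[str, set[str]] = field(default_factory=dict)
    eliminated: dict[str, set[str]] = field(default_factory=dict)

    def record(self, stage: str, before: set[str], after: set[str]) -> None:
        self.stages.append(stage)
        self.n_in[stage] = len(before)
        self.n_out[stage] = len(after)
        self.survivors[stage] = set(after)
        self.eliminated[stage] = set(before) - set(after)

    def elimination_stage(self, transcript_id: str) -> str | None:
        for stage in self.stages:
            if transcript_id in self.eliminated[stage]:
                return stage
        return None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "stage": self.stages,
                "n_in": [self.n_in[s] for s in self.stages],
                "n_out": [self.n_out[s] for s in self.stages],
            }
        )


# ---------------------------------------------------------------------------
# Stage predicates


def filter_structure(
    transcripts: Iterable[TranscriptModel],
    min_length: int = 200,
    min_exons: int = 2,
) -> list[TranscriptModel]:
    """Keep transcripts with mature length >= min_length and >= min_exons exons."""
    return [t for t in transcripts if t.length >= min_length and t.n_exons >= min_exons]


def six_frame_translate(seq: str) -> dict[str, str]:
    """Translate all six frames; '*' marks stops, 'X' marks N-containing codons."""
    if not _NUC_RE.match(seq.upper()):
        raise ValueError("sequence contains non-ACGTN characters")
    seq = seq.upper()
    rc = str(Seq(seq).reverse_complement())
    out: dict[str, str] = {}
    for offset in range(3):
        for strand_seq, sign in ((seq, "+"), (rc, "-")):
            sub = strand_seq[offset:]
            sub = sub[: len(sub) - len(sub) % 3]
            out[f"{sign}{offset + 1}"] = str(Seq(sub).translate())
    return out


def find_longest_orf(transcript_id: str, seq: str) -> OrfResult:
    """Longest ATG-to-stop ORF over the six frames.

    Length counts nucleotides including the stop codon. Ties break by frame
    order (+1,+2,+3,-1,-2,-3) then by leftmost start within the frame, so the
    result is deterministic.
    """
    best_len = 0
    best_frame = "none"
    proteins = six_frame_translate(seq)
    for frame in FRAMES:
        prot = proteins[frame]
        open_at: int | None = None
        for i, aa in enumerate(prot):
            if aa == "M" and open_at is None:
                open_at = i
            elif aa == "*":
                if open_at is not None:
                    orf_nt = (i - open_at + 1) * 3
                    if orf_nt > best_len:
                        best_len = orf_nt
                        best_frame = frame
                open_at = None
    coverage = best_len / len(seq) if seq else 0.0
    return OrfResult(transcript_id, best_len, best_frame, coverage)


def coding_potential_score(
    orf: OrfResult, l0: float = 300.0, c0: float = 0.35
) -> CodingPotentialResult:
    """Two-term ORF score with the CPC sign convention (negative => noncoding).

    score = (longest_orf_nt / l0 - 1) + (orf_coverage - c0); a transcript
    whose longest ORF is short relative to l0 nt and covers little of the
    transcript scores negative.
    """
    score = (orf.longest_orf_nt / l0 - 1.0) + (orf.orf_coverage - c0)
    label = "noncoding" if score < 0 else "coding"
    return CodingPotentialResult(orf.transcript_id, score, label)


def filter_coding_potential(
    transcripts: Iterable[TranscriptModel],
    seqs: Mapping[str, str],
    l0: float = 300.0,
    c0: float = 0.35,
    external_scores: Mapping[str, float] | None = None,
) -> list[TranscriptModel]:
    """Keep predicted-noncoding transcripts (score < 0).

    ``external_scores`` overrides the built-in score per transcript when an
    externally computed coding-potential score is available.
    """
    out = []
    for t in transcripts:
        if external_scores is not None and t.transcript_id in external_scores:
            score = external_scores[t.transcript_id]
        else:
            if t.transcript_id not in seqs:
                raise ConsistencyError(f"no sequence for {t.transcript_id}")
            orf = find_longest_orf(t.transcript_id, seqs[t.transcript_id])
            score = coding_potential_score(orf, l0=l0, c0=c0).score
        if score < 0:
            out.append(t)
    return out


def filter_homology(
    transcripts: Iterable[TranscriptModel],
    evidence: Iterable[HomologyEvidence],
    threshold: float = 1e-5,
) -> list[TranscriptModel]:
    """Discard any transcript with at least one evidence row below threshold."""
    flagged = {e.transcript_id for e in evidence if e.evalue < threshold}
    return [t for t in transcripts if t.transcript_id not in flagged]


def filter_expression(
    transcripts: Iterable[TranscriptModel], fpkm: pd.DataFrame
) -> list[TranscriptModel]:
    """Keep transcripts with FPKM > 0 in at least one sample."""
    transcripts = list(transcripts)
    missing = [t.transcript_id for t in transcripts if t.transcript_id not in fpkm.index]
    if missing:
        raise ConsistencyError(f"transcripts missing from FPKM matrix: {missing[:5]}")
    keep = fpkm.max(axis=1) > 0
    return [t for t in transcripts if keep[t.transcript_id]]


# ---------------------------------------------------------------------------
# Cascade


def run_identification(
    assembly: Sequence[TranscriptModel],
    reference: Sequence[TranscriptModel],
    seqs: Mapping[str, str],
    evidence: Iterable[HomologyEvidence],
    fpkm: pd.DataFrame,
    min_length: int = 200,
    min_exons: int = 2,
    evalue: float = 1e-5,
    orf_l0: float = 300.0,
    orf_c0: float = 0.35,
    external_scores: Mapping[str, float] | None = None,
    known_reference: Sequence[TranscriptModel] | None = None,
) -> tuple[dict[str, str], FilterReport]:
    """Run the full cascade; returns {lincRNA transcript_id: novel|known} and a report.

    Stage order: intergenic classification -> structure -> coding potential ->
    homology -> expression. Survivors overlapping a known-lincRNA span are
    labelled known, all others novel; the known annotation defaults to the
    known_lincrna-biotype transcripts of ``reference`` but can be supplied
    separately (``known_reference``) when classification should run against a
    coding-only reference.
    """
    report = FilterReport()
    assembly = list(assembly)
    all_ids = {t.transcript_id for t in assembly}

    classified = classify_transcripts(assembly, reference)
    stage1 = [c.transcript for c in classified if c.class_label == "intergenic_u"]
    report.record("intergenic", all_ids, {t.transcript_id for t in stage1})

    stage2 = filter_structure(stage1, min_length=min_length, min_exons=min_exons)
    report.record(
        "structure",
        {t.transcript_id for t in stage1},
        {t.transcript_id for t in stage2},
    )

    stage3 = filter_coding_potential(
        stage2, seqs, l0=orf_l0, c0=orf_c0, external_scores=external_scores
    )
    report.record(
        "coding_potential",
        {t.transcript_id for t in stage2},
        {t.transcript_id for t in stage3},
    )

    stage4 = filter_homology(stage3, evidence, threshold=evalue)
    report.record(
        "homology",
        {t.transcript_id for t in stage3},
        {t.transcript_id for t in stage4},
    )

    stage5 = filter_expression(stage4, fpkm)
    report.record(
        "expression",
        {t.transcript_id for t in stage4},
        {t.transcript_id for t in stage5},
    )

    if known_reference is None:
        known_reference = [t for t in reference if t.biotype == "known_lincrna"]
    known_index = SpanIndex(known_reference)
    labels: dict[str, str] = {}
    for t in stage5:
        span = t.interval
        hit = known_index.overlaps(span.chrom, span.start, span.end)
        labels[t.transcript_id] = "known" if hit else "novel"
    return labels, report


def read_evidence(path) -> list[HomologyEvidence]:
    """TSV with columns transcript_id, source, evalue (header optional)."""
    rows: list[HomologyEvidence] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("transcript_id"):
                continue
            tid, source, evalue = line.split("\t")
            rows.append(HomologyEvidence(tid, source, float(evalue)))
    return rows


def write_evidence(evidence: Iterable[HomologyEvidence], path) -> None:
    with open(path, "w") as fh:
        fh.write("transcript_id\tsource\tevalue\n")
        for e in evidence:
            fh.write(f"{e.transcript_id}\t{e.source}\t{e.evalue:g}\n")
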
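"""Intergenic ('u'-class) transcript calling against a reference annotation.

A transcript is intergenic iff its genomic span overlaps no reference
transcript span on any strand — the gffcompare class-code 'u' semantics.
Overlap is span-level (introns count), strand-agnostic, half-open.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np
from intervaltree import IntervalTree

from .io_formats import TranscriptModel


@dataclass
class ClassifiedTranscript:
    transcript: TranscriptModel
    class_label: str  # intergenic_u | overlapping_reference
    nearest_reference_gap: float  # bp; math.inf if no reference span on the chrom


class SpanIndex:
    """Per-chromosome interval index over reference transcript spans."""

    def __init__(self, reference: Iterable[TranscriptModel]):
        self._trees: dict[str, IntervalTree] = {}
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        spans: dict[str, list[tuple[int, int]]] = {}
        for t in reference:
            s = t.interval
            spans.setdefault(s.chrom, []).append((s.start, s.end))
        for chrom, pairs in spans.items():
            self._trees[chrom] = IntervalTree.from_tuples(pairs)
            arr = np.asarray(pairs)
            self._starts[chrom] = arr[:, 0]
            self._ends[chrom] = arr[:, 1]

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        tree = self._trees.get(chrom)
        return bool(tree.overlap(start, end)) if tree is not None else False

    def nearest_gap(self, chrom: str, start: int, end: int) -> float:
        """Min bp distance to any reference span on ``chrom`` (0 if overlapping)."""
        if chrom not in self._starts:
            return math.inf
        gaps = np.maximum(
            0,
            np.maximum(self._starts[chrom] - end, start - self._ends[chrom]),
        )
        return float(gaps.min())


def build_span_index(reference: Iterable[TranscriptModel]) -> SpanIndex:
    return SpanIndex(reference)


def classify_transcripts(
    assembly: Iterable[TranscriptModel],
    reference: Iterable[TranscriptModel] | SpanIndex,
) -> list[ClassifiedTranscript]:
    index = reference if isinstance(reference, SpanIndex) else SpanIndex(reference)
    out = []
    for t in assembly:
        span = t.interval
        hit = index.overlaps(span.chrom, span.start, span.end)
        out.append(
            ClassifiedTranscript(
                transcript=t,
                class_label="overlapping_reference" if hit else "intergenic_u",
                nearest_reference_gap=index.nearest_gap(span.chrom, span.start, span.end),
            )
        )
    return out


def intergenic(classified: Iterable[ClassifiedTranscript]) -> list[TranscriptModel]:
    return [c.transcript for c in classified if c.class_label == "intergenic_u"]


def write_classification(classified: Iterable[ClassifiedTranscript], path) -> None:
    with open(path, "w") as fh:
        fh.write("transcript_id\tclass_label\tnearest_gap\n")
        for c in classified:
            gap = "inf" if math.isinf(c.nearest_reference_gap) else int(c.nearest_reference_gap)
            fh.write(f"{c.transcript.transcript_id}\t{c.class_label}\t{gap}\n")
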
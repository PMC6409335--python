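"""FPKM computation and transcript-class characterization statistics."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .io_formats import TranscriptModel


@dataclass
class ClassSummary:
    """Per-class averages: transcript length, pooled exon length, exon count, FPKM."""

    name: str
    n_transcripts: int
    mean_transcript_length: float  # bp; NaN when the class is empty
    mean_exon_length: float
    mean_exon_count: float
    mean_fpkm: float


def compute_fpkm(counts: pd.DataFrame, lengths: Mapping[str, int] | pd.Series) -> pd.DataFrame:
    """FPKM[i,j] = counts[i,j] * 1e9 / (length_i * librarySize_j).

    Library size is the column sum of the supplied count matrix, so FPKM is
    invariant to globally rescaling a sample's counts.
    """
    lengths = pd.Series(lengths).reindex(counts.index)
    if lengths.isna().any():
        missing = list(lengths.index[lengths.isna()])[:5]
        raise ValueError(f"lengths missing for ids: {missing}")
    if (lengths <= 0).any():
        raise ValueError("all transcript lengths must be positive")
    libsize = counts.sum(axis=0)
    zero = libsize.index[libsize == 0]
    if len(zero):
        raise ValueError(f"zero library size in sample(s): {list(zero)}")
    return counts * 1e9 / np.outer(lengths.values, libsize.values)


def characterize_classes(
    sets: Mapping[str, Iterable[TranscriptModel]],
    fpkm: pd.DataFrame | None = None,
    exon_length_per_transcript: bool = False,
) -> list[ClassSummary]:
    """Summarize named, disjoint transcript classes.

    Mean exon length pools all exons within a class by default; with
    ``exon_length_per_transcript`` it averages per-transcript means instead.
    Empty classes report NaN means rather than zero.
    """
    seen: set[str] = set()
    out: list[ClassSummary] = []
    for name, transcripts in sets.items():
        ts = list(transcripts)
        ids = {t.transcript_id for t in ts}
        if ids & seen:
            raise ValueError(f"class {name!r} overlaps a previous class")
        seen |= ids
        if not ts:
            out.append(ClassSummary(name, 0, np.nan, np.nan, np.nan, np.nan))
            continue
        lengths = [t.length for t in ts]
        exon_counts = [t.n_exons for t in ts]
        if exon_length_per_transcript:
            exon_len = float(np.mean([np.mean([e.length for e in t.exons]) for t in ts]))
        else:
            all_exons = [e.length for t in ts for e in t.exons]
            exon_len = float(np.mean(all_exons))
        if fpkm is not None:
            present = [i for i in ids if i in fpkm.index]
            mean_fpkm = float(fpkm.loc[present].values.mean()) if present else np.nan
        else:
            mean_fpkm = np.nan
        out.append(
            ClassSummary(
                name=name,
                n_transcripts=len(ts),
                mean_transcript_length=float(np.mean(lengths)),
                mean_exon_length=exon_len,
                mean_exon_count=float(np.mean(exon_counts)),
                mean_fpkm=mean_fpkm,
            )
        )
    return out


def summaries_to_frame(summaries: Iterable[ClassSummary]) -> pd.DataFrame:
    return pd.DataFrame([s.__dict__ for s in summaries]).set_index("name")
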
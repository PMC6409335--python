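"""QTL colocalization of differentially expressed lincRNA loci.

A lincRNA hits a QTL when their intervals share >= 1 bp (half-open
arithmetic, unstranded), the default intersect semantics of the standard
interval tools. Summaries count QTLs per lincRNA, lincRNAs per trait, QTLs
per chromosome, and the fat-deposition subset of each.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable

import pandas as pd

from .io_formats import QTLRecord
from .cis_targets import GeneLocus


@dataclass(frozen=True)
class QtlHit:
    lincrna_id: str
    qtl_id: str
    overlap_bp: int
    trait_name: str
    trait_category: str


@dataclass
class QtlSummary:
    n_hits: int
    qtls_per_lincrna: dict[str, int] = field(default_factory=dict)
    lincrnas_per_trait: dict[str, int] = field(default_factory=dict)
    qtls_per_chrom: dict[str, int] = field(default_factory=dict)
    fat_qtls_per_lincrna: dict[str, int] = field(default_factory=dict)
    n_fat_hits: int = 0


def map_to_qtls(
    lincrnas: Iterable[GeneLocus], qtls: Iterable[QTLRecord]
) -> list[QtlHit]:
    """One hit row per (lincRNA, QTL) pair with positive intersection."""
    qtls = list(qtls)
    by_chrom: dict[str, list[QTLRecord]] = {}
    for q in qtls:
        by_chrom.setdefault(q.interval.chrom, []).append(q)
    hits = []
    for locus in lincrnas:
        iv = locus.interval
        for q in by_chrom.get(iv.chrom, []):
            ov = min(iv.end, q.interval.end) - max(iv.start, q.interval.start)
            if ov > 0:
                hits.append(
                    QtlHit(
                        lincrna_id=locus.gene_id,
                        qtl_id=q.qtl_id,
                        overlap_bp=ov,
                        trait_name=q.trait_name,
                        trait_category=q.trait_category,
                    )
                )
    return hits


def summarize_hits(hits: Iterable[QtlHit], qtls: Iterable[QTLRecord] | None = None) -> QtlSummary:
    """Marginal counts over the hit list.

    ``qtls`` (optional) supplies chromosome locations so the per-chromosome
    count covers the hit QTLs; each QTL is counted once per chromosome even
    when hit by several lincRNAs.
    """
    hits = list(hits)
    per_linc = Counter(h.lincrna_id for h in hits)
    per_trait: dict[str, set[str]] = {}
    for h in hits:
        per_trait.setdefault(h.trait_name, set()).add(h.lincrna_id)
    fat_hits = [h for h in hits if h.trait_category == "fat_deposition"]
    fat_per_linc = Counter(h.lincrna_id for h in fat_hits)

    per_chrom: Counter = Counter()
    if qtls is not None:
        chrom_of = {q.qtl_id: q.interval.chrom for q in qtls}
        for qid in {h.qtl_id for h in hits}:
            per_chrom[chrom_of[qid]] += 1

    return QtlSummary(
        n_hits=len(hits),
        qtls_per_lincrna=dict(per_linc),
        lincrnas_per_trait={t: len(s) for t, s in per_trait.items()},
        qtls_per_chrom=dict(per_chrom),
        fat_qtls_per_lincrna=dict(fat_per_linc),
        n_fat_hits=len(fat_hits),
    )


def hits_to_frame(hits: Iterable[QtlHit]) -> pd.DataFrame:
    return pd.DataFrame([h.__dict__ for h in hits])
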
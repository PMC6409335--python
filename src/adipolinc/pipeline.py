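"""End-to-end orchestration: classify -> identify -> characterize -> DE -> targets -> QTL.

Every number in the run report is recomputable from the stage output files;
with a fixed configuration and seed the whole run is deterministic.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .io_formats import (
    GenomicInterval,
    TranscriptModel,
    check_counts_samples,
    read_counts,
    read_fasta,
    read_gtf,
    read_qtl_bed,
    read_samples,
    write_gtf,
)
from .transcript_classify import classify_transcripts, intergenic, write_classification
from .lincrna_id import read_evidence, run_identification
from .expression_stats import characterize_classes, compute_fpkm, summaries_to_frame
from .diffexpr import run_de
from .cis_targets import GeneLocus, build_network, edges_to_frame, find_neighbors, predict_targets
from .qtl_overlap import hits_to_frame, map_to_qtls, summarize_hits


@dataclass
class PipelineConfig:
    """All paths and numeric thresholds for a pipeline run."""

    reference_gtf: str
    assembly_gtf: str
    fasta: str
    counts: str
    samples: str
    qtl: str = ""
    evidence: str = ""
    outdir: str = "results"
    min_length: int = 200
    min_exons: int = 2
    evalue: float = 1e-5
    orf_l0: float = 300.0
    orf_c0: float = 0.35
    window_bp: int = 100_000
    alpha_de: float = 0.05
    alpha_ptg: float = 0.05
    seed: int = 1
    run_qtl: bool = True
    run_targets: bool = True

    def __post_init__(self) -> None:
        for name in ("min_length", "min_exons", "window_bp"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("alpha_de", "alpha_ptg"):
            if not 0 < getattr(self, name) < 1:
                raise ValueError(f"{name} must lie in (0, 1)")


def _gene_loci(transcripts: list[TranscriptModel], category: str) -> list[GeneLocus]:
    """Union span per gene over its transcripts."""
    spans: dict[str, GenomicInterval] = {}
    for t in transcripts:
        iv = t.interval
        prev = spans.get(t.gene_id)
        if prev is None:
            spans[t.gene_id] = iv
        else:
            spans[t.gene_id] = GenomicInterval(
                iv.chrom, min(prev.start, iv.start), max(prev.end, iv.end), prev.strand
            )
    return [GeneLocus(g, iv, category) for g, iv in spans.items()]


def run_all(config: PipelineConfig) -> dict:
    """Execute the full pipeline; returns the run report (also written as JSON)."""
    t0 = time.time()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "version": __version__,
        "config": dataclasses.asdict(config),
        "timings_s": {},
    }

    def _clock(stage: str, start: float) -> None:
        report["timings_s"][stage] = round(time.time() - start, 3)

    # --- inputs
    reference = read_gtf(config.reference_gtf, kind="reference")
    assembly = read_gtf(config.assembly_gtf, kind="assembly")
    seqs = read_fasta(config.fasta)
    counts = read_counts(config.counts)
    samples = read_samples(config.samples)
    check_counts_samples(counts, samples)
    evidence = read_evidence(config.evidence) if config.evidence else []

    # --- classification
    t = time.time()
    classified = classify_transcripts(assembly, reference)
    write_classification(classified, outdir / "classification.tsv")
    write_gtf(intergenic(classified), outdir / "intergenic.gtf")
    report["n_assembly"] = len(assembly)
    report["n_intergenic"] = len(intergenic(classified))
    _clock("classify", t)

    # --- transcript-level FPKM (transcript counts = its gene's counts)
    gene_of = {t_.transcript_id: t_.gene_id for t_ in assembly}
    covered = [tid for tid, g in gene_of.items() if g in counts.index]
    tx_counts = counts.loc[[gene_of[tid] for tid in covered]]
    tx_counts.index = covered
    tx_lengths = {t_.transcript_id: t_.length for t_ in assembly}
    tx_fpkm = compute_fpkm(tx_counts, {tid: tx_lengths[tid] for tid in covered})

    # --- identification cascade
    t = time.time()
    labels, filter_report = run_identification(
        assembly,
        reference,
        seqs,
        evidence,
        tx_fpkm,
        min_length=config.min_length,
        min_exons=config.min_exons,
        evalue=config.evalue,
        orf_l0=config.orf_l0,
        orf_c0=config.orf_c0,
    )
    filter_report.to_frame().to_csv(outdir / "filter_report.tsv", sep="\t", index=False)
    linc_transcripts = [t_ for t_ in assembly if t_.transcript_id in labels]
    write_gtf(linc_transcripts, outdir / "lincrnas.gtf")
    report["filter_report"] = {
        s: [filter_report.n_in[s], filter_report.n_out[s]] for s in filter_report.stages
    }
    report["n_lincrnas"] = len(labels)
    report["n_novel_lincrnas"] = sum(1 for v in labels.values() if v == "novel")
    report["n_known_lincrnas"] = sum(1 for v in labels.values() if v == "known")
    _clock("identify", t)

    # --- characterization
    t = time.time()
    classes = {
        "novel_lincrna": [t_ for t_ in linc_transcripts if labels[t_.transcript_id] == "novel"],
        "known_lincrna": [t_ for t_ in reference if t_.biotype == "known_lincrna"],
        "protein_coding": [t_ for t_ in reference if t_.biotype == "protein_coding"],
    }
    summaries = characterize_classes(classes, fpkm=tx_fpkm)
    summaries_to_frame(summaries).to_csv(outdir / "class_summaries.tsv", sep="\t")
    _clock("characterize", t)

    # --- differential expression (one engine, applied to all genes)
    t = time.time()
    de = run_de(counts, samples, alpha=config.alpha_de)
    de.to_csv(outdir / "de_results.tsv", sep="\t", index_label="gene_id")
    linc_genes = {t_.gene_id for t_ in linc_transcripts}
    coding_genes = {t_.gene_id for t_ in reference if t_.biotype == "protein_coding"}
    sig = de[de["direction"] != "ns"]
    del_genes = sorted(set(sig.index) & linc_genes)
    de_coding = sorted(set(sig.index) & coding_genes)
    report["n_de_lincrna_genes"] = len(del_genes)
    report["n_de_coding_genes"] = len(de_coding)
    report["de_lincrna_up"] = int(((sig["direction"] == "up_in_fat") & sig.index.isin(linc_genes)).sum())
    report["de_lincrna_down"] = int(((sig["direction"] == "down_in_fat") & sig.index.isin(linc_genes)).sum())
    report["de_coding_up"] = int(((sig["direction"] == "up_in_fat") & sig.index.isin(coding_genes)).sum())
    report["de_coding_down"] = int(((sig["direction"] == "down_in_fat") & sig.index.isin(coding_genes)).sum())
    _clock("de", t)

    del_loci = [
        l for l in _gene_loci(linc_transcripts, "lincrna") if l.gene_id in del_genes
    ]

    # --- target prediction on DEL genes
    if config.run_targets and del_genes:
        t = time.time()
        coding_tx = [t_ for t_ in reference if t_.biotype == "protein_coding"]
        coding_loci = _gene_loci(coding_tx, "coding")
        neighbors = find_neighbors(del_loci, coding_loci, window=config.window_bp)
        gene_lengths = (
            pd.Series(tx_lengths).groupby(pd.Series(gene_of)).max().to_dict()
        )
        gene_fpkm = compute_fpkm(
            counts, {g: gene_lengths.get(g, 1000) for g in counts.index}
        )
        coding_in_counts = sorted(coding_genes & set(counts.index))
        edges = predict_targets(
            gene_fpkm.loc[del_genes],
            gene_fpkm.loc[coding_in_counts],
            de_coding_ids=de_coding,
            alpha=config.alpha_ptg,
            neighbors=neighbors,
        )
        edges_to_frame(edges).to_csv(outdir / "target_edges.tsv", sep="\t", index=False)
        network = build_network(edges, restrict="deptg_only")
        pd.DataFrame(
            [
                {"lincrna_gene": u, "coding_gene": v, **d}
                for u, v, d in network.edges(data=True)
            ]
        ).to_csv(outdir / "network_edges.tsv", sep="\t", index=False)
        report["n_neighbor_pairs"] = len(neighbors)
        report["n_ptg_edges"] = sum(e.is_ptg for e in edges)
        report["n_deptg_edges"] = sum(e.is_deptg for e in edges)
        _clock("targets", t)
    else:
        report["targets"] = "skipped"

    # --- QTL colocalization of DELs
    if config.run_qtl and config.qtl:
        t = time.time()
        qtls = read_qtl_bed(config.qtl)
        hits = map_to_qtls(del_loci, qtls)
        hits_to_frame(hits).to_csv(outdir / "qtl_hits.tsv", sep="\t", index=False)
        summary = summarize_hits(hits, qtls)
        with open(outdir / "qtl_summary.json", "w") as fh:
            json.dump(dataclasses.asdict(summary), fh, indent=1, sort_keys=True)
        report["n_qtl_hits"] = summary.n_hits
        report["n_fat_qtl_hits"] = summary.n_fat_hits
        _clock("qtl", t)
    else:
        report["qtl"] = "skipped"

    report["timings_s"]["total"] = round(time.time() - t0, 3)
    # timings go to a sidecar so run_report.json is byte-identical across
    # repeat runs of the same config + seed
    timings = report.pop("timings_s")
    with open(outdir / "timings.json", "w") as fh:
        json.dump(timings, fh, indent=1, sort_keys=True)
    with open(outdir / "run_report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    report["timings_s"] = timings
    return report
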
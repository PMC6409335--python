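"""Seeded generator of a miniature two-group adipose RNA-seq study.

Emulates the structure of a 10-vs-10 fat/lean backfat design: a reference
annotation with protein-coding and known-lincRNA loci, an assembled
transcriptome carrying planted novel intergenic noncoding transcripts plus
decoys that each violate exactly one identification filter, NB-distributed
gene counts with planted fold changes and correlated lincRNA-coding pairs,
sample metadata with signed backfat EBVs, a QTL catalogue, and a homology
evidence table. Ground truth for every planted feature is returned and
written as JSON so each pipeline stage has an exact oracle.

One global seed governs all draws through named `numpy` SeedSequence
children (placement, sequences, counts, samples, qtl), so regenerating with
the same configuration is byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import (
    GenomicInterval,
    QTLRecord,
    SampleInfo,
    TranscriptModel,
    write_fasta,
    write_gtf,
    write_qtl_bed,
)
from .lincrna_id import HomologyEvidence, find_longest_orf, coding_potential_score, write_evidence

STOP_CODONS = ("TAA", "TAG", "TGA")
ALL_CODONS = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"]
NONSTOP_CODONS = [c for c in ALL_CODONS if c not in STOP_CODONS]

FAT_TRAITS = (
    "backfat_weight",
    "average_backfat_thickness",
    "shoulder_fat_thickness",
    "backfat_at_last_lumbar",
)
OTHER_TRAITS = (
    "loin_muscle_area",
    "days_to_100kg",
    "drip_loss",
    "feed_conversion_ratio",
)


class ConfigurationError(ValueError):
    """Infeasible simulation configuration."""


@dataclass
class SimulationConfig:
    """Study-design knobs for the synthetic generator (defaults = study conditions)."""

    seed: int = 1
    n_chroms: int = 5
    chrom_length: int = 10_000_000
    n_coding_genes: int = 200
    n_known_lincrnas: int = 30
    n_novel_intergenic: int = 30
    n_decoy_coding_intergenic: int = 10  # planted ORF >= 450 nt
    n_decoy_structural: int = 5  # alternating single-exon / <200 bp
    n_decoy_homology: int = 5  # noncoding but with E-value < 1e-5 evidence
    n_decoy_silent: int = 3  # zero counts in every sample
    n_samples_per_group: int = 10
    nb_dispersion: float = 0.05
    de_gene_fraction: float = 0.10  # of coding genes
    n_de_lincrnas: int = 5
    planted_log2fc: float = 2.0
    n_corr_pairs: int = 10  # lincRNA-coding pairs sharing a latent factor
    corr_latent_sd: float = 0.4  # sd of the shared lognormal factor (log scale)
    qtl_count: int = 60
    fat_qtl_fraction: float = 0.30
    coding_mean_range: tuple[float, float] = (50.0, 5000.0)
    linc_mean_range: tuple[float, float] = (5.0, 300.0)

    def __post_init__(self) -> None:
        for name in (
            "n_chroms",
            "chrom_length",
            "n_coding_genes",
            "n_known_lincrnas",
            "n_novel_intergenic",
            "n_decoy_coding_intergenic",
            "n_decoy_structural",
            "n_decoy_homology",
            "n_decoy_silent",
            "n_samples_per_group",
        ):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.nb_dispersion <= 0:
            raise ConfigurationError("nb_dispersion must be > 0")
        if not 0 <= self.de_gene_fraction <= 1:
            raise ConfigurationError("de_gene_fraction must lie in [0, 1]")


@dataclass
class GroundTruth:
    """Planted truth: the oracle every pipeline stage is tested against."""

    true_lincrna_ids: set[str] = field(default_factory=set)
    true_coding_intergenic_ids: set[str] = field(default_factory=set)
    decoy_stage: dict[str, str] = field(default_factory=dict)  # id -> defect stage
    true_de_gene_ids: dict[str, float] = field(default_factory=dict)  # gene -> log2fc
    true_de_lincrna_genes: set[str] = field(default_factory=set)
    true_neighbor_pairs: list[tuple[str, str, int]] = field(default_factory=list)
    true_corr_pairs: list[tuple[str, str]] = field(default_factory=list)
    true_qtl_hits: list[tuple[str, str]] = field(default_factory=list)
    gene_of_transcript: dict[str, str] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "true_lincrna_ids": sorted(self.true_lincrna_ids),
            "true_coding_intergenic_ids": sorted(self.true_coding_intergenic_ids),
            "decoy_stage": self.decoy_stage,
            "true_de_gene_ids": self.true_de_gene_ids,
            "true_de_lincrna_genes": sorted(self.true_de_lincrna_genes),
            "true_neighbor_pairs": self.true_neighbor_pairs,
            "true_corr_pairs": self.true_corr_pairs,
            "true_qtl_hits": self.true_qtl_hits,
            "gene_of_transcript": self.gene_of_transcript,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            true_lincrna_ids=set(d["true_lincrna_ids"]),
            true_coding_intergenic_ids=set(d["true_coding_intergenic_ids"]),
            decoy_stage=d["decoy_stage"],
            true_de_gene_ids={k: float(v) for k, v in d["true_de_gene_ids"].items()},
            true_de_lincrna_genes=set(d["true_de_lincrna_genes"]),
            true_neighbor_pairs=[tuple(x) for x in d["true_neighbor_pairs"]],
            true_corr_pairs=[tuple(x) for x in d["true_corr_pairs"]],
            true_qtl_hits=[tuple(x) for x in d["true_qtl_hits"]],
            gene_of_transcript=d["gene_of_transcript"],
        )


# ---------------------------------------------------------------------------
# sequence models


def _noncoding_sequence(rng: np.random.Generator, length: int, max_tries: int = 200) -> str:
    """Draw a sequence whose longest ORF is < 300 nt and CPC-style score < 0.

    Codon-sampled with stop codons over-weighted and ATG under-weighted;
    regenerated until the construction check passes.
    """
    weights = np.ones(64)
    for i, codon in enumerate(ALL_CODONS):
        if codon in STOP_CODONS:
            weights[i] = 4.0
        elif codon == "ATG":
            weights[i] = 0.2
    weights /= weights.sum()
    n_codons, rem = divmod(length, 3)
    for _ in range(max_tries):
        idx = rng.choice(64, size=n_codons, p=weights)
        seq = "".join(ALL_CODONS[i] for i in idx)
        seq += "".join(rng.choice(list("ACGT"), size=rem))
        orf = find_longest_orf("tmp", seq)
        if orf.longest_orf_nt < 300 and coding_potential_score(orf).score < 0:
            return seq
    raise RuntimeError(f"could not draw a noncoding sequence of length {length}")


def _coding_sequence(rng: np.random.Generator, length: int, orf_nt: int = 453) -> str:
    """Noncoding backbone with a planted complete ORF of ``orf_nt`` nt."""
    if length < orf_nt + 6:
        raise ValueError("transcript too short for the planted ORF")
    n_codons = orf_nt // 3 - 2
    body = "".join(
        NONSTOP_CODONS[i] for i in rng.integers(0, len(NONSTOP_CODONS), size=n_codons)
    )
    orf = "ATG" + body + "TAA"
    flank = length - orf_nt
    left = int(rng.integers(0, flank + 1))
    prefix = _noncoding_sequence(rng, left) if left else ""
    suffix = _noncoding_sequence(rng, flank - left) if flank - left else ""
    return prefix + orf + suffix


# ---------------------------------------------------------------------------
# gene placement


def _make_exons(
    rng: np.random.Generator,
    chrom: str,
    start: int,
    n_exons: int,
    exon_range: tuple[int, int],
    intron_range: tuple[int, int],
    strand: str,
) -> list[GenomicInterval]:
    exons = []
    pos = start
    for k in range(n_exons):
        elen = int(rng.integers(exon_range[0], exon_range[1] + 1))
        exons.append(GenomicInterval(chrom, pos, pos + elen, strand))
        pos += elen
        if k < n_exons - 1:
            pos += int(rng.integers(intron_range[0], intron_range[1] + 1))
    return exons


def _place_genes(config: SimulationConfig, rng: np.random.Generator):
    """Interleave all gene categories along the chromosomes with random gaps.

    Returns a list of (category, TranscriptModel). Sequential placement with
    strictly positive gaps guarantees every planted locus is intergenic with
    respect to everything else.
    """
    items: list[str] = (
        ["coding"] * config.n_coding_genes
        + ["known_linc"] * config.n_known_lincrnas
        + ["novel"] * config.n_novel_intergenic
        + ["decoy_orf"] * config.n_decoy_coding_intergenic
        + ["decoy_struct"] * config.n_decoy_structural
        + ["decoy_hom"] * config.n_decoy_homology
        + ["decoy_silent"] * config.n_decoy_silent
    )
    rng.shuffle(items)
    counters: dict[str, int] = {}
    cursors = {f"chr{c + 1}": 0 for c in range(config.n_chroms)}
    placed: list[tuple[str, TranscriptModel]] = []
    chrom_names = list(cursors)
    struct_flip = 0
    for slot, category in enumerate(items):
        chrom = chrom_names[slot % len(chrom_names)]
        gap = int(rng.integers(5_000, 80_000))
        start = cursors[chrom] + gap
        strand = "+" if rng.random() < 0.5 else "-"
        idx = counters.get(category, 0)
        counters[category] = idx + 1
        if category == "coding":
            n_ex = int(rng.integers(4, 10))
            exons = _make_exons(rng, chrom, start, n_ex, (120, 400), (200, 2000), strand)
            model = TranscriptModel(
                f"ref_cod_t{idx}", f"ref_cod_g{idx}", exons, biotype="protein_coding"
            )
        elif category == "known_linc":
            n_ex = int(rng.integers(2, 5))
            exons = _make_exons(rng, chrom, start, n_ex, (200, 600), (200, 1500), strand)
            model = TranscriptModel(
                f"ref_linc_t{idx}", f"ref_linc_g{idx}", exons, biotype="known_lincrna"
            )
        elif category in {"novel", "decoy_hom", "decoy_silent"}:
            prefix = {"novel": "novel", "decoy_hom": "decoy_hom", "decoy_silent": "decoy_silent"}[
                category
            ]
            n_ex = int(rng.integers(2, 5))
            exons = _make_exons(rng, chrom, start, n_ex, (150, 600), (200, 1500), strand)
            model = TranscriptModel(
                f"{prefix}_t{idx}", f"{prefix}_g{idx}", exons, biotype="unassigned"
            )
        elif category == "decoy_orf":
            n_ex = int(rng.integers(2, 4))
            exons = _make_exons(rng, chrom, start, n_ex, (300, 600), (200, 1500), strand)
            model = TranscriptModel(
                f"decoy_orf_t{idx}", f"decoy_orf_g{idx}", exons, biotype="unassigned"
            )
        elif category == "decoy_struct":
            if struct_flip % 2 == 0:  # single exon, long enough
                exons = [GenomicInterval(chrom, start, start + 1000, strand)]
            else:  # two exons, mature length < 200 bp
                exons = [
                    GenomicInterval(chrom, start, start + 90, strand),
                    GenomicInterval(chrom, start + 400, start + 490, strand),
                ]
            struct_flip += 1
            model = TranscriptModel(
                f"decoy_struct_t{idx}", f"decoy_struct_g{idx}", exons, biotype="unassigned"
            )
        else:  # pragma: no cover
            raise AssertionError(category)
        end = model.interval.end
        if end > config.chrom_length:
            raise ConfigurationError(
                f"cannot place {model.transcript_id} on {chrom}: exceeds chrom_length"
            )
        cursors[chrom] = end
        placed.append((category, model))
    return placed


# ---------------------------------------------------------------------------
# counts


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """NB draws with Var = mu + dispersion * mu^2 (numpy n/p parameterization)."""
    mean = np.asarray(mean, dtype=float)
    n = 1.0 / dispersion
    p = n / (n + mean)
    out = np.zeros(mean.shape, dtype=int)
    pos = mean > 0
    out[pos] = rng.negative_binomial(n, p[pos])
    return out


def make_samples(config: SimulationConfig, rng: np.random.Generator) -> list[SampleInfo]:
    """10 fat / 10 lean libraries; EBV uniform [3,8] mm fat, [-11,-6] mm lean."""
    samples = []
    for i in range(config.n_samples_per_group):
        samples.append(SampleInfo(f"fat_{i + 1}", "fat", float(np.round(rng.uniform(3, 8), 2))))
    for i in range(config.n_samples_per_group):
        samples.append(
            SampleInfo(f"lean_{i + 1}", "lean", float(np.round(rng.uniform(-11, -6), 2)))
        )
    return samples


def generate_null_counts(
    n_genes: int,
    config: SimulationConfig | None = None,
    zero_fraction: float = 0.02,
) -> pd.DataFrame:
    """Counts with identical NB means in both groups (type-I error harness).

    A small fraction of genes is all-zero to exercise the DE engine's
    excluded-gene accounting.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    config = config or SimulationConfig()
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(7)[0])
    n = config.n_samples_per_group
    cols = [f"fat_{i + 1}" for i in range(n)] + [f"lean_{i + 1}" for i in range(n)]
    means = np.exp(rng.uniform(np.log(5), np.log(5000), size=n_genes))
    n_zero = int(round(zero_fraction * n_genes))
    if n_zero:
        means[rng.choice(n_genes, size=n_zero, replace=False)] = 0.0
    mat = _nb_draw(
        rng, np.repeat(means[:, None], 2 * n, axis=1), config.nb_dispersion
    )
    return pd.DataFrame(mat, index=[f"g{i}" for i in range(n_genes)], columns=cols)


def generate_de_benchmark(
    n_genes: int = 2000,
    de_fraction: float = 0.10,
    de_mean: float = 500.0,
    log2fc: float = 2.0,
    config: SimulationConfig | None = None,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Null genes plus planted |log2FC| genes at a fixed mean (power harness).

    Returns (counts, {planted gene id: signed log2fc}).
    """
    config = config or SimulationConfig()
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(8)[0])
    n = config.n_samples_per_group
    cols = [f"fat_{i + 1}" for i in range(n)] + [f"lean_{i + 1}" for i in range(n)]
    means = np.exp(rng.uniform(np.log(5), np.log(5000), size=n_genes))
    n_de = int(round(de_fraction * n_genes))
    de_idx = rng.choice(n_genes, size=n_de, replace=False)
    truth: dict[str, float] = {}
    mu = np.repeat(means[:, None], 2 * n, axis=1)
    for j, gi in enumerate(de_idx):
        fc = log2fc if j % 2 == 0 else -log2fc
        truth[f"g{gi}"] = fc
        mu[gi, :n] = de_mean * 2 ** (fc / 2)
        mu[gi, n:] = de_mean * 2 ** (-fc / 2)
    mat = _nb_draw(rng, mu, config.nb_dispersion)
    return (
        pd.DataFrame(mat, index=[f"g{i}" for i in range(n_genes)], columns=cols),
        truth,
    )


# ---------------------------------------------------------------------------
# full study


def generate_study(
    config: SimulationConfig, outdir: str | Path
) -> tuple[GroundTruth, dict[str, Path]]:
    """Write the full miniature study to ``outdir`` and return its ground truth.

    Files: reference.gtf, assembly.gtf, transcripts.fa, counts.tsv,
    samples.tsv, qtl.tsv, evidence.tsv, ground_truth.json.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    streams = np.random.SeedSequence(config.seed).spawn(6)
    rng_place = np.random.default_rng(streams[0])
    rng_seq = np.random.default_rng(streams[1])
    rng_counts = np.random.default_rng(streams[2])
    rng_samples = np.random.default_rng(streams[3])
    rng_qtl = np.random.default_rng(streams[4])

    placed = _place_genes(config, rng_place)
    truth = GroundTruth()
    reference = [m for cat, m in placed if cat in {"coding", "known_linc"}]
    planted = [(cat, m) for cat, m in placed if cat not in {"coding", "known_linc"}]
    assembly = reference + [m for _, m in planted]
    for _, m in placed:
        truth.gene_of_transcript[m.transcript_id] = m.gene_id

    # --- sequences for planted transcripts
    seqs: dict[str, str] = {}
    evidence: list[HomologyEvidence] = []
    novel_counter = 0
    for cat, m in planted:
        tid = m.transcript_id
        if cat == "decoy_orf":
            seqs[tid] = _coding_sequence(rng_seq, m.length)
            truth.true_coding_intergenic_ids.add(tid)
            truth.decoy_stage[tid] = "coding_potential"
            evidence.append(HomologyEvidence(tid, "nr", float(rng_seq.uniform(1e-12, 1e-7))))
        else:
            seqs[tid] = _noncoding_sequence(rng_seq, m.length)
            if cat == "novel":
                truth.true_lincrna_ids.add(tid)
                # a third of true lincRNAs get harmless above-threshold evidence
                if novel_counter % 3 == 0:
                    evidence.append(
                        HomologyEvidence(tid, "uniref90", float(rng_seq.uniform(1e-3, 1e-1)))
                    )
                novel_counter += 1
            elif cat == "decoy_hom":
                truth.decoy_stage[tid] = "homology"
                evidence.append(
                    HomologyEvidence(tid, "pfam", float(rng_seq.uniform(1e-12, 1e-7)))
                )
            elif cat == "decoy_struct":
                truth.decoy_stage[tid] = "structure"
            elif cat == "decoy_silent":
                truth.decoy_stage[tid] = "expression"

    # --- samples
    samples = make_samples(config, rng_samples)
    n = config.n_samples_per_group
    sample_ids = [s.sample_id for s in samples]

    # --- counts
    gene_rows: list[tuple[str, str]] = []  # (gene_id, category)
    seen_genes = set()
    for cat, m in placed:
        if m.gene_id not in seen_genes:
            seen_genes.add(m.gene_id)
            gene_rows.append((m.gene_id, cat))

    base_mean: dict[str, float] = {}
    for gid, cat in gene_rows:
        lo, hi = (
            config.coding_mean_range if cat == "coding" else config.linc_mean_range
        )
        base_mean[gid] = float(np.exp(rng_counts.uniform(np.log(lo), np.log(hi))))

    # planted DE: coding genes and novel lincRNA genes, alternating sign
    coding_gids = [g for g, c in gene_rows if c == "coding"]
    novel_gids = [g for g, c in gene_rows if c == "novel"]
    n_de_coding = int(round(config.de_gene_fraction * len(coding_gids)))
    de_coding = list(rng_counts.choice(coding_gids, size=n_de_coding, replace=False))
    de_linc = list(
        rng_counts.choice(novel_gids, size=min(config.n_de_lincrnas, len(novel_gids)), replace=False)
    )
    for j, gid in enumerate(de_coding + de_linc):
        fc = config.planted_log2fc if j % 2 == 0 else -config.planted_log2fc
        truth.true_de_gene_ids[gid] = fc
    truth.true_de_lincrna_genes = set(de_linc)

    # planted correlated neighbor pairs (shared lognormal latent factor)
    loci: dict[str, GenomicInterval] = {}
    for cat, m in placed:
        iv = m.interval
        prev = loci.get(m.gene_id)
        if prev is None:
            loci[m.gene_id] = iv
        else:
            loci[m.gene_id] = GenomicInterval(
                iv.chrom, min(prev.start, iv.start), max(prev.end, iv.end), prev.strand
            )
    coding_set = set(coding_gids)
    neighbor_pairs = []
    for lg in novel_gids:
        for cg in coding_gids:
            if loci[lg].chrom == loci[cg].chrom:
                gap = loci[lg].gap(loci[cg])
                if gap < 100_000:
                    neighbor_pairs.append((lg, cg, gap))
    truth.true_neighbor_pairs = neighbor_pairs

    used_l: set[str] = set()
    used_c: set[str] = set()
    corr_pairs: list[tuple[str, str]] = []
    for lg, cg, _ in sorted(neighbor_pairs, key=lambda x: x[2]):
        if len(corr_pairs) >= config.n_corr_pairs:
            break
        if lg in used_l or cg in used_c:
            continue
        corr_pairs.append((lg, cg))
        used_l.add(lg)
        used_c.add(cg)
    truth.true_corr_pairs = corr_pairs

    depth = rng_counts.uniform(0.7, 1.4, size=2 * n)
    mu = np.zeros((len(gene_rows), 2 * n))
    gene_index = {gid: i for i, (gid, _) in enumerate(gene_rows)}
    for i, (gid, cat) in enumerate(gene_rows):
        m0 = base_mean[gid]
        fc = truth.true_de_gene_ids.get(gid, 0.0)
        mu[i, :n] = m0 * 2 ** (fc / 2)
        mu[i, n:] = m0 * 2 ** (-fc / 2)
    for lg, cg in corr_pairs:
        factor = np.exp(rng_counts.normal(0.0, config.corr_latent_sd, size=2 * n))
        mu[gene_index[lg]] *= factor
        mu[gene_index[cg]] *= factor
    mu *= depth[None, :]
    silent_idx = [i for i, (g, c) in enumerate(gene_rows) if c == "decoy_silent"]
    mu[silent_idx, :] = 0.0

    mat = _nb_draw(rng_counts, mu, config.nb_dispersion)
    # planted (non-silent) features must be expressed somewhere
    for i, (gid, cat) in enumerate(gene_rows):
        if cat != "decoy_silent" and mat[i].sum() == 0:
            mat[i] = _nb_draw(rng_counts, np.maximum(mu[i], 1.0), config.nb_dispersion)
            mat[i, 0] = max(mat[i, 0], 1)
    counts = pd.DataFrame(mat, index=[g for g, _ in gene_rows], columns=sample_ids)

    # --- QTLs
    qtls: list[QTLRecord] = []
    n_fat = int(round(config.fat_qtl_fraction * config.qtl_count))
    de_linc_loci = [loci[g] for g in sorted(truth.true_de_lincrna_genes)]
    for k in range(config.qtl_count):
        if k < n_fat and de_linc_loci:
            anchor = de_linc_loci[k % len(de_linc_loci)]
            start = max(0, anchor.start - int(rng_qtl.integers(10_000, 500_000)))
            end = min(
                config.chrom_length, anchor.end + int(rng_qtl.integers(10_000, 500_000))
            )
            chrom = anchor.chrom
            trait = FAT_TRAITS[k % len(FAT_TRAITS)]
            category = "fat_deposition"
        else:
            chrom = f"chr{int(rng_qtl.integers(1, config.n_chroms + 1))}"
            length = int(rng_qtl.integers(50_000, 2_000_000))
            start = int(rng_qtl.integers(0, max(1, config.chrom_length - length)))
            end = start + length
            trait = OTHER_TRAITS[k % len(OTHER_TRAITS)]
            category = "other"
        qtls.append(
            QTLRecord(f"qtl_{k}", GenomicInterval(chrom, start, end), trait, category)
        )
    for gid in sorted(truth.true_de_lincrna_genes):
        iv = loci[gid]
        for q in qtls:
            if iv.overlaps(q.interval):
                truth.true_qtl_hits.append((gid, q.qtl_id))

    # --- write files
    paths = {
        "reference_gtf": outdir / "reference.gtf",
        "assembly_gtf": outdir / "assembly.gtf",
        "fasta": outdir / "transcripts.fa",
        "counts": outdir / "counts.tsv",
        "samples": outdir / "samples.tsv",
        "qtl": outdir / "qtl.tsv",
        "evidence": outdir / "evidence.tsv",
        "ground_truth": outdir / "ground_truth.json",
    }
    write_gtf(reference, paths["reference_gtf"])
    write_gtf(assembly, paths["assembly_gtf"])
    write_fasta(seqs, paths["fasta"])
    counts.to_csv(paths["counts"], sep="\t", index_label="gene_id")
    pd.DataFrame([s.__dict__ for s in samples]).to_csv(
        paths["samples"], sep="\t", index=False
    )
    write_qtl_bed(qtls, paths["qtl"])
    write_evidence(evidence, paths["evidence"])
    truth.to_json(paths["ground_truth"])
    return truth, paths
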
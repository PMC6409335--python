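# Methods

## Coordinate conventions

All genomic arithmetic is 0-based half-open (BED convention); GTF is the
only 1-based inclusive surface and is converted at the read/write boundary.
Touching intervals (end == start) do not overlap and have gap 0. QTL
intervals are unstranded (`.`).

## Intergenic classification

A transcript is intergenic iff its genomic span overlaps no reference
transcript span, on any strand, at span level (introns included). This is
deliberately stricter than exon-level overlap: a transcript inside a
reference intron is *not* intergenic, which is the behaviour of the `u`
class code of gffcompare-style comparison. Whether the original class call
in this kind of screen is strand-aware is not recoverable from common
practice; strand-agnostic is chosen and stated. The nearest-reference gap
is reported per transcript (infinite when the chromosome has no reference
span).

Classification runs against the full reference annotation (coding plus
known lincRNA loci). When a caller classifies against a coding-only
reference instead, survivors that overlap a known lincRNA annotation are
labelled `known` rather than `novel` (`run_identification`'s
`known_reference` argument).

## Coding-potential score

External coding-potential classifiers are SVMs over alignment features and
need external databases. The built-in score is a transparent two-term
stand-in that keeps the sign convention (negative ⇒ noncoding):

    s = (L_orf / L0 − 1) + (L_orf / L_tx − C0),   L0 = 300 nt, C0 = 0.35

where `L_orf` is the longest complete ORF (ATG to in-frame stop, stop
included, over all six frames; ties broken by frame order then leftmost
start) and `L_tx` the transcript length. `L0` is the conventional 100-codon
boundary below which ORFs are considered non-informative; `C0` penalises
transcripts mostly covered by their ORF. Both are configurable, and an
externally computed score column overrides the stand-in per transcript.
ORFs are required to be complete (ATG and stop) because an open-ended ORF
makes the coverage term ill-defined.

## Homology and expression filters

Homology filtering consumes a precomputed evidence table
(transcript, source, E-value) rather than running HMMER/BLASTX; the rule is
the classical one — any hit with E-value < 1e-5 discards the transcript,
transcripts without evidence pass. The expression filter keeps transcripts
with FPKM > 0 in at least one sample. The four post-classification filters
are independent predicates, so the final survivor set does not depend on
their order (asserted in the tests); the per-stage counts of course do.

## FPKM

FPKM[i,j] = counts[i,j]·10⁹ / (length_i · librarySize_j) with library size
the column sum of the supplied matrix (mapped-read totals are not an input
of this package). This matches assembler-style FPKM up to a constant per
sample and makes the statistic invariant to global per-sample rescaling.
Class characterization pools all exons within a class for the mean exon
length; a per-transcript-mean alternative is available by flag. Mean
expression is the pooled mean over all transcript × sample FPKM cells.
Empty classes report NaN, not zero.

## Differential expression

The engine is a deliberately small negative-binomial Wald test rather than
a wrapper around an external tool:

- **Size factors** — median of ratios to per-gene geometric means over
  genes positive in all samples, rescaled to geometric mean 1; column-sum
  fallback (with warning) when no such gene exists.
- **Dispersion** — per-gene pooled method of moments on normalized counts,
  α̂ = (s² − μ̄)/μ̄². At 10-vs-10 these per-gene estimates are noisy and
  often fall at or below zero, which would make the Wald statistic
  anti-conservative; each gene's dispersion is therefore floored at the
  median of the positive per-gene estimates (a common-dispersion
  moderation in the spirit of the shared dispersions of the standard
  count-based DE tools), then at 10⁻⁸. The unmoderated engine remains
  available (`moderate_dispersion=False`) and is the one whose null
  p-values are checked for uniformity; the moderated default is slightly
  conservative and sits inside the 0.03–0.07 nominal-0.05 window across
  seeds.
- **Fold change and test** — log2fc = log2((μ_fat+0.5)/(μ_lean+0.5)) with
  a 0.5 pseudo-count to keep zero-mean genes finite; the standard error
  comes from the delta method with NB variance μ + α̂μ² and the group
  sample sizes; p is the two-sided normal tail of log2fc/se; BH step-up
  FDR at α = 0.05 (configurable). Genes with zero counts in all samples
  are excluded and tallied.

No dispersion shrinkage toward a fitted trend, Cook's outlier filtering or
independent filtering is attempted; the design target is calibration on
planted truth, not numerical equality with any external implementation
(whose median-of-ratios normalization is, however, used as an independent
cross-check in the tests).

## Target prediction and network

Neighbors are coding genes with gap < 100 kb of a DEL gene locus (union
span of its transcripts), strand ignored. Correlation uses plain Pearson r
on FPKM as given — the exact t-transform p at n samples reproduces printed
r/p pairs from published DEL–neighbor tables with no transformation, so
log2(FPKM+1) is offered only as an option. PTG calls use raw p < 0.05 (the
classical rule; BH adjustment available by flag). The co-expression
network is a bipartite graph of DELs and their DEPTGs exported as an edge
TSV (r, p, sign per edge).

All DEL × coding pairs are tested, with neighbor status carried as an edge
flag, so both the "neighbors only" and the "all pairs" reading of the PTG
universe are available downstream.

## QTL colocalization

A hit is ≥ 1 bp of intersection between a DEL gene locus and a QTL
interval (the default semantics of the standard interval tools); no
overlap-fraction threshold. The fat-deposition/other trait category is an
input column, not inferred from trait-name text, to avoid brittle keyword
matching. Summaries are pure marginal recounts of the hit list.

## Synthetic study generator

The generator emulates the structure of the motivating design — not any
real dataset: 5 chromosomes × 10 Mb carrying 200 protein-coding genes,
30 known lincRNA loci, 30 novel intergenic noncoding transcripts and four
decoy classes (10 with a planted complete ORF ≥ 450 nt, 5 structural
single-exon/<200 bp, 5 with sub-threshold homology evidence, 3 silent),
interleaved with 5–80 kb gaps so planted loci are intergenic by
construction. Counts for 10 fat + 10 lean libraries are negative-binomial
(dispersion 0.05) with means log-uniform in 50–5000 (coding) and 5–300
(lincRNA-like, enforcing the lower-expression ordering); 10 % of coding
genes and 5 lincRNA genes carry |log2FC| = 2 split symmetrically across
groups; 10 neighbor pairs share a lognormal latent factor (sd 0.4 on the
log scale, giving r ≈ 0.8) for target-prediction truth; per-sample depth
factors are uniform 0.7–1.4. EBVs are uniform [3, 8] mm (fat) and
[−11, −6] mm (lean), matching the sign structure of such designs. 60 QTLs
are drawn, 30 % fat-deposition and anchored on DE lincRNA loci. Noncoding
sequences are codon-sampled with stop codons over-weighted and ATG
under-weighted, then rejection-checked so the longest ORF is < 300 nt *and*
the coding-potential score is negative. One global seed drives named
SeedSequence streams (placement, sequences, counts, samples, QTLs), making
regeneration byte-identical.

What the generator does **not** emulate: read-level noise and mapping
artifacts, isoform complexity (one transcript per gene), annotation
incompleteness, batch or sex effects, and realistic linkage between QTLs
and expression. Passing tests therefore demonstrate the correctness and
calibration of the algorithms under the stated model, not performance on
real libraries; real-data headline counts depend on the real annotations
and databases and are out of scope by design.

## Problem sizes and numerical choices

The calibration harnesses use 2,000 genes at 10-vs-10 (null and planted
benchmarks), 1,000+ randomized fixtures per interval oracle and 100
random 1-kb sequences for the ORF oracle — sizes at which every check runs
in seconds while the binomial noise of the measured rates stays well
inside the asserted windows. Dispersion floor 10⁻⁸; SE floor 10⁻¹²;
correlation values clipped to [−1, 1] against rounding; |r| = 1 returns
p = 0 explicitly. Degenerate inputs (zero-variance vectors, zero library
sizes, groups with fewer than two samples, transcripts missing from
matrices) raise named errors rather than propagating NaN.
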
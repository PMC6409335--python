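import itertools

import numpy as np
import pandas as pd
import pytest

from adipolinc.io_formats import read_fasta, read_gtf
from adipolinc.lincrna_id import (
    FRAMES,
    HomologyEvidence,
    coding_potential_score,
    filter_coding_potential,
    filter_expression,
    filter_homology,
    filter_structure,
    find_longest_orf,
    read_evidence,
    run_identification,
    six_frame_translate,
)
from adipolinc.diffexpr import estimate_size_factors  # noqa: F401 (import check)
from conftest import make_transcript

# --- independent oracles -----------------------------------------------------

_BASES = "TCAG"
_AMINO = (
    "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
)
CODON_TABLE = {
    a + b + c: _AMINO[16 * i + 4 * j + k]
    for i, a in enumerate(_BASES)
    for j, b in enumerate(_BASES)
    for k, c in enumerate(_BASES)
}
_COMP = str.maketrans("ACGTN", "TGCAN")


def oracle_translate(seq: str, offset: int) -> str:
    out = []
    for i in range(offset, len(seq) - 2, 3):
        codon = seq[i : i + 3]
        out.append("X" if "N" in codon else CODON_TABLE[codon])
    return "".join(out)


def oracle_six_frames(seq: str) -> dict[str, str]:
    rc = seq.translate(_COMP)[::-1]
    frames = {}
    for off in range(3):
        frames[f"+{off + 1}"] = oracle_translate(seq, off)
        frames[f"-{off + 1}"] = oracle_translate(rc, off)
    return frames


def oracle_longest_orf(seq: str) -> tuple[int, str]:
    """Exhaustive scan over all (frame, start, stop) triples."""
    best, best_frame = 0, "none"
    frames = oracle_six_frames(seq)
    for frame in FRAMES:
        prot = frames[frame]
        for start in range(len(prot)):
            if prot[start] != "M":
                continue
            for stop in range(start + 1, len(prot)):
                if prot[stop] == "*":
                    nt = (stop - start + 1) * 3
                    if nt > best:
                        best, best_frame = nt, frame
                    break
    return best, best_frame


def random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


# --- stage predicates --------------------------------------------------------


class TestFilterStructure:
    @pytest.mark.parametrize(
        "length,n_exons,kept",
        [(200, 2, True), (199, 2, False), (5000, 1, False), (1000, 3, True)],
    )
    def test_boundaries(self, length, n_exons, kept):
        per = length // n_exons
        coords, pos = [], 0
        for i in range(n_exons):
            size = per if i < n_exons - 1 else length - per * (n_exons - 1)
            coords.append((pos, pos + size))
            pos += size + 500
        t = make_transcript("t", exon_coords=coords)
        assert t.length == length
        assert (filter_structure([t]) == [t]) is kept


class TestTranslation:
    def test_codon_basics(self):
        assert six_frame_translate("ATG")["+1"] == "M"
        assert six_frame_translate("ATGTTTTAA")["+1"] == "MF*"

    def test_n_codon_is_x_and_trailing_dropped(self):
        frames = six_frame_translate("ATGNNNT")
        assert frames["+1"] == "MX"  # trailing T dropped

    def test_rejects_bad_characters(self):
        with pytest.raises(ValueError):
            six_frame_translate("ATGU")

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_codon_table_oracle(self, seed):
        rng = np.random.default_rng(seed)
        seq = random_seq(rng, 120)
        assert six_frame_translate(seq) == oracle_six_frames(seq)


class TestLongestOrf:
    def test_single_orf(self):
        r = find_longest_orf("t", "ATGAAATAA")
        assert (r.longest_orf_nt, r.orf_frame) == (9, "+1")
        assert r.orf_coverage == 1.0

    def test_no_orf(self):
        r = find_longest_orf("t", "CCCCCCCCC")
        assert (r.longest_orf_nt, r.orf_frame) == (0, "none")

    def test_orf_on_reverse_strand(self):
        # reverse complement of ATGAAATAA is TTATTTCAT
        r = find_longest_orf("t", "TTATTTCAT")
        assert r.longest_orf_nt == 9
        assert r.orf_frame.startswith("-")

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(100 + seed)
        seq = random_seq(rng, 1000)
        r = find_longest_orf("t", seq)
        nt, frame = oracle_longest_orf(seq)
        assert r.longest_orf_nt == nt
        if nt > 0:
            assert r.orf_frame == frame


class TestCodingPotential:
    @pytest.mark.parametrize(
        "orf_nt,coverage,score,label",
        [
            (600, 0.60, 1.25, "coding"),
            (90, 0.10, -0.95, "noncoding"),
            (0, 0.0, -1.35, "noncoding"),
        ],
    )
    def test_score_formula(self, orf_nt, coverage, score, label):
        from adipolinc.lincrna_id import OrfResult

        res = coding_potential_score(OrfResult("t", orf_nt, "+1", coverage))
        assert res.score == pytest.approx(score)
        assert res.label == label

    def test_external_score_overrides(self):
        t = make_transcript("t1")
        # no sequence provided: would fail without the external override
        kept = filter_coding_potential([t], {}, external_scores={"t1": -2.0})
        assert kept == [t]
        kept = filter_coding_potential([t], {}, external_scores={"t1": 3.0})
        assert kept == []


class TestHomologyAndExpression:
    def test_homology_threshold(self):
        t1, t2 = make_transcript("t1"), make_transcript("t2")
        ev = [HomologyEvidence("t1", "pfam", 1e-6), HomologyEvidence("t2", "nr", 1e-4)]
        assert filter_homology([t1, t2], ev) == [t2]
        assert filter_homology([t1, t2], []) == [t1, t2]

    def test_negative_evalue_rejected(self):
        with pytest.raises(ValueError):
            HomologyEvidence("t", "nr", -1.0)

    def test_expression_any_nonzero_sample(self):
        t1, t2 = make_transcript("t1"), make_transcript("t2")
        fpkm = pd.DataFrame(
            {"s1": [0.0, 0.01], "s2": [0.0, 0.0]}, index=["t1", "t2"]
        )
        assert filter_expression([t1, t2], fpkm) == [t2]

    def test_missing_transcript_errors(self):
        from adipolinc.io_formats import ConsistencyError

        fpkm = pd.DataFrame({"s1": [1.0]}, index=["other"])
        with pytest.raises(ConsistencyError):
            filter_expression([make_transcript("t1")], fpkm)


# --- full cascade ------------------------------------------------------------


def _study_inputs(paths):
    import pandas as pd

    from adipolinc.expression_stats import compute_fpkm
    from adipolinc.io_formats import read_counts

    reference = read_gtf(paths["reference_gtf"], kind="reference")
    assembly = read_gtf(paths["assembly_gtf"])
    seqs = read_fasta(paths["fasta"])
    evidence = read_evidence(paths["evidence"])
    counts = read_counts(paths["counts"])
    gene_of = {t.transcript_id: t.gene_id for t in assembly}
    covered = [tid for tid, g in gene_of.items() if g in counts.index]
    tx_counts = counts.loc[[gene_of[t] for t in covered]]
    tx_counts.index = covered
    fpkm = compute_fpkm(tx_counts, {t.transcript_id: t.length for t in assembly})
    return assembly, reference, seqs, evidence, fpkm


class TestRunIdentification:
    def test_empty_assembly(self):
        labels, report = run_identification([], [], {}, [], pd.DataFrame())
        assert labels == {}
        assert all(report.n_in[s] == 0 for s in report.stages)

    def test_recovers_exactly_planted_lincrnas(self, study):
        truth, paths = study
        labels, report = run_identification(*_study_inputs(paths))
        assert set(labels) == truth.true_lincrna_ids
        assert set(labels.values()) == {"novel"}

    def test_each_decoy_eliminated_at_planted_stage(self, study):
        truth, paths = study
        _, report = run_identification(*_study_inputs(paths))
        for tid, stage in truth.decoy_stage.items():
            assert report.elimination_stage(tid) == stage, tid

    def test_cascade_counts_non_increasing(self, study):
        truth, paths = study
        _, report = run_identification(*_study_inputs(paths))
        outs = [report.n_out[s] for s in report.stages]
        ins = [report.n_in[s] for s in report.stages]
        assert all(o <= i for i, o in zip(ins, outs))
        assert ins[1:] == outs[:-1]
        for prev, nxt in zip(report.stages, report.stages[1:]):
            assert report.survivors[nxt] <= report.survivors[prev]

    def test_filter_order_does_not_change_final_set(self, study):
        """The four post-classification filters are independent predicates."""
        truth, paths = study
        assembly, reference, seqs, evidence, fpkm = _study_inputs(paths)
        from adipolinc.transcript_classify import classify_transcripts, intergenic

        base = intergenic(classify_transcripts(assembly, reference))
        filters = {
            "structure": lambda ts: filter_structure(ts),
            "cp": lambda ts: filter_coding_potential(ts, seqs),
            "hom": lambda ts: filter_homology(ts, evidence),
            "expr": lambda ts: filter_expression(ts, fpkm),
        }
        results = set()
        for order in itertools.permutations(filters):
            survivors = base
            for name in order:
                survivors = filters[name](survivors)
            results.add(frozenset(t.transcript_id for t in survivors))
        assert results == {frozenset(truth.true_lincrna_ids)}

    def test_known_label_when_reference_is_coding_only(self, study):
        """Classifying against a coding-only reference lets known lincRNAs
        through the cascade, where the overlap labeller marks them known."""
        truth, paths = study
        assembly, reference, seqs, evidence, fpkm = _study_inputs(paths)
        coding_only = [t for t in reference if t.biotype == "protein_coding"]
        known_ids = {t.transcript_id for t in reference if t.biotype == "known_lincrna"}
        known = [t for t in reference if t.biotype == "known_lincrna"]
        # known lincRNA transcripts lack FASTA entries; score them noncoding
        ext = {tid: -1.0 for tid in known_ids}
        labels, _ = run_identification(
            assembly,
            coding_only,
            seqs,
            evidence,
            fpkm,
            external_scores=ext,
            known_reference=known,
        )
        assert {t for t, lab in labels.items() if lab == "known"} == known_ids
        assert {t for t, lab in labels.items() if lab == "novel"} == truth.true_lincrna_ids
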
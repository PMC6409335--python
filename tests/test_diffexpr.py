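import numpy as np
import pandas as pd
import pytest
from scipy import stats

from adipolinc.diffexpr import (
    bh_adjust,
    call_de,
    estimate_size_factors,
    nb_wald_test,
    run_de,
)
from adipolinc.synthetic_data import (
    SimulationConfig,
    generate_de_benchmark,
    generate_null_counts,
)

GROUPS_4 = {"f1": "fat", "f2": "fat", "l1": "lean", "l2": "lean"}


def _groups(columns):
    return {c: ("fat" if c.startswith("fat") else "lean") for c in columns}


class TestSizeFactors:
    def test_exact_doubling_closed_form(self):
        # column 2 = 2 x column 1 -> median-of-ratios factors (1/sqrt2, sqrt2)
        col = np.array([10, 100, 1000, 50])
        counts = pd.DataFrame({"s1": col, "s2": 2 * col})
        sf = estimate_size_factors(counts)
        assert sf["s1"] == pytest.approx(1 / np.sqrt(2))
        assert sf["s2"] == pytest.approx(np.sqrt(2))

    def test_identical_columns_give_unit_factors(self):
        counts = pd.DataFrame({"a": [5, 8, 13], "b": [5, 8, 13]})
        assert np.allclose(estimate_size_factors(counts), 1.0)

    def test_scale_equivariance_before_recentering(self):
        rng = np.random.default_rng(2)
        counts = pd.DataFrame(
            rng.poisson(100, size=(200, 4)), columns=["a", "b", "c", "d"]
        ) + 1
        base = estimate_size_factors(counts)
        scaled = counts.copy()
        scaled["c"] = scaled["c"] * 3
        new = estimate_size_factors(scaled)
        # ratio to the other columns triples, up to the geometric recentering
        assert (new["c"] / new["a"]) / (base["c"] / base["a"]) == pytest.approx(3.0)

    def test_recovers_planted_depth_multipliers(self):
        rng = np.random.default_rng(10)
        depth = np.array([0.6, 1.0, 1.4, 2.0])
        means = np.exp(rng.uniform(np.log(20), np.log(2000), size=2000))
        mu = np.outer(means, depth)
        counts = pd.DataFrame(
            rng.poisson(mu), columns=["a", "b", "c", "d"]
        )
        sf = estimate_size_factors(counts)
        expected = depth / stats.gmean(depth)
        assert np.allclose(sf.values, expected, rtol=0.05)

    def test_fallback_warns_without_allpositive_gene(self):
        counts = pd.DataFrame({"a": [0, 10], "b": [10, 0]})
        with pytest.warns(UserWarning, match="column-sum"):
            sf = estimate_size_factors(counts)
        assert np.allclose(sf, 1.0)

    def test_matches_pydeseq2_median_of_ratios(self):
        """Independent route: DESeq2's median-of-ratios as implemented in
        pydeseq2, compared after normalizing both to geometric mean 1."""
        pydeseq2 = pytest.importorskip("pydeseq2")
        from pydeseq2.dds import DeseqDataSet

        rng = np.random.default_rng(77)
        depth = rng.uniform(0.5, 2.0, size=8)
        means = np.exp(rng.uniform(np.log(5), np.log(2000), size=300))
        counts = pd.DataFrame(
            rng.poisson(np.outer(means, depth)),
            index=[f"g{i}" for i in range(300)],
            columns=[f"s{i}" for i in range(8)],
        )
        mine = estimate_size_factors(counts)
        meta = pd.DataFrame({"condition": ["A"] * 4 + ["B"] * 4}, index=counts.columns)
        dds = DeseqDataSet(counts=counts.T, metadata=meta, design="~condition", quiet=True)
        dds.fit_size_factors()
        theirs = dds.obs["size_factors"].values
        theirs = theirs / stats.gmean(theirs)
        assert np.allclose(mine.values, theirs, rtol=1e-6)


class TestBhAdjust:
    def test_hand_computed_stepup(self):
        assert np.allclose(bh_adjust(np.array([0.01, 0.02, 0.03])), [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert bh_adjust(np.array([0.2]))[0] == pytest.approx(0.2)

    def test_monotone_in_sorted_order_and_capped(self):
        rng = np.random.default_rng(4)
        p = rng.uniform(size=200)
        adj = bh_adjust(p)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)
        assert adj.max() <= 1.0
        assert np.all(adj >= p)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust(np.array([0.5, 1.5]))


class TestNbWaldTest:
    def test_group_label_swap_negates_log2fc_preserves_p(self):
        counts = generate_null_counts(300, SimulationConfig(seed=3))
        groups = _groups(counts.columns)
        swapped = {c: ("lean" if g == "fat" else "fat") for c, g in groups.items()}
        sf = estimate_size_factors(counts)
        a = nb_wald_test(counts, sf, groups)
        b = nb_wald_test(counts, sf, swapped)
        assert np.allclose(a["log2fc"], -b["log2fc"])
        assert np.allclose(a["p"], b["p"])

    def test_all_zero_gene_excluded_and_tallied(self):
        counts = pd.DataFrame(
            {"f1": [10, 0], "f2": [12, 0], "l1": [9, 0], "l2": [11, 0]},
            index=["g1", "gz"],
        )
        res = nb_wald_test(counts, estimate_size_factors(counts), GROUPS_4)
        assert "gz" not in res.index
        assert res.attrs["n_excluded"] == 1

    def test_requires_two_samples_per_group(self):
        counts = pd.DataFrame({"f1": [10], "l1": [9], "l2": [11]}, index=["g1"])
        with pytest.raises(ValueError, match="2 samples"):
            nb_wald_test(counts, pd.Series(1.0, index=counts.columns), {"f1": "fat", "l1": "lean", "l2": "lean"})

    def test_null_p_uniform_ks(self):
        """The raw per-gene engine is approximately uniform under the null;
        the default moderated engine is slightly conservative (checked via
        the rejection-rate window below), so KS runs on the raw engine."""
        counts = generate_null_counts(2000, SimulationConfig(seed=1))
        res = nb_wald_test(
            counts,
            estimate_size_factors(counts),
            _groups(counts.columns),
            moderate_dispersion=False,
        )
        assert stats.kstest(res["p"], "uniform").pvalue > 0.01

    def test_null_rejection_rate_in_window(self):
        counts = generate_null_counts(2000, SimulationConfig(seed=1))
        res = nb_wald_test(counts, estimate_size_factors(counts), _groups(counts.columns))
        assert 0.03 <= (res["p"] < 0.05).mean() <= 0.07

    def test_planted_log2fc_recovered(self):
        """Planted |log2FC|=2 at mean 500, dispersion 0.05, 10v10: the
        delta-method sd is ~0.15, so ~91% of estimates land within +-0.25."""
        counts, truth = generate_de_benchmark(2000, config=SimulationConfig(seed=1))
        res = nb_wald_test(
            counts, estimate_size_factors(counts), _groups(counts.columns)
        )
        errors = np.array([abs(abs(res.loc[g, "log2fc"]) - 2.0) for g in truth])
        assert errors.mean() < 0.15
        assert np.mean(errors <= 0.25) >= 0.85


class TestCallDe:
    def test_direction_thresholds(self):
        res = pd.DataFrame(
            {
                "log2fc": [1.2, -0.8, 0.5],
                "p": [0.0005, 0.0006, 0.9],
                "base_mean": [10, 10, 10],
                "se": [0.1] * 3,
                "wald": [1.0] * 3,
            },
            index=["up", "down", "flat"],
        )
        out = call_de(res, alpha=0.05)
        assert out.loc["up", "direction"] == "up_in_fat"
        assert out.loc["down", "direction"] == "down_in_fat"
        assert out.loc["flat", "direction"] == "ns"
        assert (out["padj"] >= out["p"] - 1e-15).all()

    def test_sensitivity_and_fdr_on_planted_benchmark(self):
        counts, truth = generate_de_benchmark(2000, config=SimulationConfig(seed=1))
        de = run_de(counts, _groups(counts.columns))
        sig = set(de.index[de["direction"] != "ns"])
        sens = len(sig & set(truth)) / len(truth)
        fdr = len(sig - set(truth)) / max(1, len(sig))
        assert sens >= 0.8
        assert fdr <= 0.1
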
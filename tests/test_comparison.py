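"""BIC, JZS Bayes factors, frequentist tests and the cohort bias report."""

import numpy as np
import pytest
from scipy import stats

from optstop.comparison import (
    CAUCHY_SCALES,
    DEFAULT_CAUCHY_SCALE,
    best_fit_counts,
    bic,
    cohort_bias_report,
    compare_models,
    jzs_bayes_factor,
    paired_frequentist,
)

import pandas as pd


class TestBic:
    def test_formula(self):
        assert bic(100.0, k=2, n=66) == pytest.approx(200.0 + 2 * np.log(66))
        assert bic(0.0, k=2, n=1) == 0.0

    def test_monotone_in_nll(self):
        assert bic(10.0, 2, 50) < bic(11.0, 2, 50)

    def test_bic_differences_equal_twice_nll_differences(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            a, b, n = rng.uniform(0, 200), rng.uniform(0, 200), int(rng.integers(2, 100))
            assert bic(a, 2, n) - bic(b, 2, n) == pytest.approx(2 * (a - b))

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            bic(10.0, k=0, n=10)
        with pytest.raises(ValueError):
            bic(10.0, k=2, n=0)


class TestJzsBayesFactor:
    @pytest.mark.parametrize("scale", CAUCHY_SCALES)
    def test_null_favoured_at_zero_evidence(self, scale):
        bf10, bf01 = jzs_bayes_factor(t=0.0, n=30, scale=scale)
        assert bf10 < 1.0
        assert bf01 > 1.0

    def test_reciprocal_identity(self):
        for t in (0.0, 1.5, 4.0):
            bf10, bf01 = jzs_bayes_factor(t=t, n=40, scale=0.71)
            assert bf10 * bf01 == pytest.approx(1.0, rel=1e-9)

    def test_monotone_in_t(self):
        bfs = [jzs_bayes_factor(t=t, n=50)[0] for t in (0.0, 1.0, 2.0, 4.0, 6.0)]
        assert all(a < b for a, b in zip(bfs, bfs[1:]))

    def test_matches_independent_implementation(self):
        """Cross-check against pingouin's JZS Bayes factor."""
        pingouin = pytest.importorskip("pingouin")
        for t, n, r in ((2.0, 30, 0.707), (6.0, 50, 0.707), (1.0, 20, 0.5), (3.0, 40, 1.0)):
            ours, _ = jzs_bayes_factor(t=t, n=n, scale=r)
            theirs = float(pingouin.bayesfactor_ttest(t, n, paired=True, r=r))
            assert ours == pytest.approx(theirs, rel=1e-3)

    def test_matches_monte_carlo_oracle(self):
        """Quadrature agrees with 1e6-sample Monte-Carlo integration over g."""
        t, n, r = 6.0, 50, 0.707
        bf10, _ = jzs_bayes_factor(t=t, n=n, scale=r)
        rng = np.random.default_rng(17)
        g = stats.invgamma.rvs(0.5, scale=r**2 / 2.0, size=1_000_000, random_state=rng)
        nu = n - 1
        shrink = 1.0 + n * g
        alt = np.mean(shrink**-0.5 * (1.0 + t**2 / (shrink * nu)) ** (-(nu + 1) / 2))
        null = (1.0 + t**2 / nu) ** (-(nu + 1) / 2)
        assert bf10 == pytest.approx(alt / null, rel=0.02)

    def test_from_differences(self):
        rng = np.random.default_rng(3)
        diffs = rng.normal(0.8, 1.0, size=40)
        tval = diffs.mean() / (diffs.std(ddof=1) / np.sqrt(40))
        a, _ = jzs_bayes_factor(diffs)
        b, _ = jzs_bayes_factor(t=tval, n=40)
        assert a == pytest.approx(b, rel=1e-9)

    def test_degenerate_inputs(self):
        with pytest.raises(ZeroDivisionError):
            jzs_bayes_factor(np.ones(10))
        with pytest.raises(ValueError):
            jzs_bayes_factor(t=1.0, n=30, scale=-0.5)
        with pytest.raises(ValueError):
            jzs_bayes_factor()

    def test_default_scale_is_root_half(self):
        assert DEFAULT_CAUCHY_SCALE == pytest.approx(round(np.sqrt(2) / 2, 2))


class TestPairedFrequentist:
    def test_closed_form_example(self):
        res = paired_frequentist([1.0, 2.0, 3.0])
        assert res.t == pytest.approx(2 * np.sqrt(3))
        assert res.df == 2
        assert res.cohens_d == pytest.approx(2.0)

    def test_identical_independent_samples(self):
        res = paired_frequentist([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], paired=False)
        assert res.t == pytest.approx(0.0)
        assert res.p_adj == pytest.approx(1.0)

    def test_bonferroni_multiplication(self):
        rng = np.random.default_rng(5)
        x = rng.normal(0.5, 1.0, 30)
        raw = paired_frequentist(x, n_comparisons=1)
        adj = paired_frequentist(x, n_comparisons=15)
        assert adj.p_adj == pytest.approx(min(1.0, raw.p * 15))
        assert raw.p <= adj.p_adj <= 1.0
        # wider interval under the corrected alpha
        assert (adj.ci_high - adj.ci_low) > (raw.ci_high - raw.ci_low)

    def test_matches_scipy(self):
        rng = np.random.default_rng(6)
        x, y = rng.normal(5, 1, 25), rng.normal(4.5, 1, 25)
        res = paired_frequentist(x, y)
        ref = stats.ttest_rel(x, y)
        assert res.t == pytest.approx(ref.statistic)
        assert res.p == pytest.approx(ref.pvalue)

    def test_zero_variance_raises(self):
        with pytest.raises(ZeroDivisionError):
            paired_frequentist(np.zeros(5))


class TestBestFitCounts:
    def test_counts_and_conservation(self):
        table = pd.DataFrame(
            {"A": [1.0, 1.0, 5.0], "B": [2.0, 3.0, 2.0]},
            index=["p1", "p2", "p3"],
        )
        counts = best_fit_counts(table)
        assert counts["A"] == 2.0 and counts["B"] == 1.0
        assert counts.sum() == len(table)

    def test_tie_split_equally(self):
        table = pd.DataFrame({"A": [1.0], "B": [1.0], "C": [4.0]}, index=["p1"])
        with pytest.warns(UserWarning):
            counts = best_fit_counts(table)
        assert counts["A"] == counts["B"] == 0.5
        assert counts.sum() == pytest.approx(1.0)

    def test_missing_cells_rejected(self):
        table = pd.DataFrame({"A": [1.0, np.nan], "B": [2.0, 1.0]})
        with pytest.raises(ValueError):
            best_fit_counts(table)


class TestCompareModels:
    def test_pairwise_table_shape(self):
        rng = np.random.default_rng(9)
        rows = []
        for p in range(20):
            for model, shift in (("a", 0.0), ("b", 5.0), ("c", 20.0)):
                rows.append(
                    {
                        "participant_id": f"p{p}",
                        "model": model,
                        "bic": 100 + shift + rng.normal(0, 3),
                    }
                )
        fits = pd.DataFrame(rows)
        table = compare_models(fits)
        assert len(table) == 3
        assert {"bf10_r0.5", "bf10_r0.71", "bf10_r1.0"} <= set(table.columns)
        # the clearly separated pair carries overwhelming evidence
        row = table[(table.model1 == "a") & (table.model2 == "c")].iloc[0]
        assert row["bf10_r0.71"] > 1e3


class TestCohortBiasReport:
    def test_degenerate_zero_variance_flagged(self):
        samples = np.full(50, 6.0)
        report = cohort_bias_report(samples, samples)
        assert report.classification == "degenerate"
        assert report.bf10 == {}

    def test_equivalence_classification(self):
        rng = np.random.default_rng(2)
        ideal = rng.uniform(5, 8, size=60)
        noisy = ideal + rng.normal(0, 0.05, size=60)
        report = cohort_bias_report(noisy, ideal)
        assert report.classification == "equivalent"
        assert report.bf01[DEFAULT_CAUCHY_SCALE] > 3.0

    def test_undersampling_classification(self):
        rng = np.random.default_rng(3)
        ideal = rng.uniform(6, 8, size=40)
        under = ideal - rng.uniform(1.5, 2.5, size=40)
        report = cohort_bias_report(under, ideal)
        assert report.classification == "undersampling"
        assert report.mean_difference < 0

    def test_oversampling_classification(self):
        rng = np.random.default_rng(4)
        ideal = rng.uniform(4, 6, size=40)
        over = ideal + rng.uniform(1.0, 2.0, size=40)
        report = cohort_bias_report(over, ideal)
        assert report.classification == "oversampling"

    def test_design_mismatch(self):
        with pytest.raises(ValueError):
            cohort_bias_report(np.ones(10), np.ones(9))
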
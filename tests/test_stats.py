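"""Effect measures, propensity matching, logistic fits and ROC analysis."""

import itertools
import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from scipy.special import expit

from caphys.stats import (
    compare_means,
    fit_logistic,
    propensity_match,
    roc_analysis,
    two_by_two_effects,
)
from caphys.synthetic import CohortConfig, generate_cohort


class TestTwoByTwo:
    def test_published_mace_table(self):
        """21/129 vs 12/84 events: OR 1.17 (0.54-2.52), rates 16.28%/14.29%."""
        res = two_by_two_effects(21, 108, 12, 72)
        assert round(res.odds_ratio.point, 2) == 1.17
        assert round(res.odds_ratio.ci_low, 2) == 0.54
        assert round(res.odds_ratio.ci_high, 2) == 2.52
        assert res.rate1 * 100 == pytest.approx(16.28, abs=0.005)
        assert res.rate2 * 100 == pytest.approx(14.29, abs=0.005)

    def test_symmetric_table(self):
        res = two_by_two_effects(10, 10, 10, 10)
        assert res.odds_ratio.point == pytest.approx(1.0)
        assert res.risk_ratio.point == pytest.approx(1.0)

    def test_cross_product_equals_probability_definition(self):
        """OR/RR from the cell formulas match the empirical-probability
        definitions on every 2x2 table with margins <= 30."""
        for a, b, c, d in itertools.product(range(1, 31, 7), repeat=4):
            res = two_by_two_effects(a, b, c, d)
            p1, p2 = a / (a + b), c / (c + d)
            assert res.odds_ratio.point == pytest.approx(
                (p1 / (1 - p1)) / (p2 / (1 - p2))
            )
            assert res.risk_ratio.point == pytest.approx(p1 / p2)

    def test_zero_cell_continuity_correction(self):
        res = two_by_two_effects(0, 20, 5, 15)
        assert np.isfinite(res.odds_ratio.point)
        assert "continuity" in res.odds_ratio.notes

    def test_empty_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            two_by_two_effects(0, 0, 5, 15)

    def test_woolf_interval_coverage(self):
        """Empirical 95% coverage of the Woolf CI under a true OR of 1.5
        (n=200/group) lies in [0.92, 0.975] over 2000 simulated tables."""
        rng = np.random.default_rng(2024)
        true_or = 1.5
        p2 = 0.2
        p1 = true_or * p2 / (1 - p2) / (1 + true_or * p2 / (1 - p2))
        n = 200
        covered = 0
        sims = 2000
        for _ in range(sims):
            a = rng.binomial(n, p1)
            c = rng.binomial(n, p2)
            est = two_by_two_effects(a, n - a, c, n - c).odds_ratio
            if est.ci_low <= true_or <= est.ci_high:
                covered += 1
        assert 0.92 <= covered / sims <= 0.975


class TestCompareMeans:
    def test_published_caimr_difference(self):
        """36.49 (21.04, n=121) vs 34.23 (23.91, n=80): difference 2.26 with
        pooled-t 95% CI approximately (-4.05, 8.57)."""
        est = compare_means(36.49, 21.04, 121, 34.23, 23.91, 80)
        assert est.point == pytest.approx(2.26, abs=1e-12)
        assert est.ci_low == pytest.approx(-4.05, abs=0.01)
        assert est.ci_high == pytest.approx(8.57, abs=0.01)

    def test_identical_groups(self):
        est = compare_means(50.0, 10.0, 30, 50.0, 10.0, 30)
        assert est.point == 0.0
        assert est.ci_low == pytest.approx(-est.ci_high)

    def test_degenerate_n_rejected(self):
        with pytest.raises(ValueError):
            compare_means(1.0, 1.0, 1, 2.0, 1.0, 30)


class TestPropensityMatch:
    def test_balance_improves_on_confounded_cohort(self, default_cohort):
        m = propensity_match(default_cohort.table, seed=3)
        assert m.n_pairs > 0
        for cov in m.smd.index:
            assert abs(m.smd.loc[cov, "post"]) <= abs(m.smd.loc[cov, "pre"]), cov

    def test_one_to_one_no_reuse(self, default_cohort):
        m = propensity_match(default_cohort.table, seed=3)
        ids = np.concatenate([m.pairs["treated_id"], m.pairs["control_id"]])
        assert len(ids) == len(set(ids))
        assert m.n_pairs <= min(
            (default_cohort.table["dcb"] == 1).sum(),
            (default_cohort.table["dcb"] == 0).sum(),
        )

    def test_deterministic_under_seed(self, default_cohort):
        a = propensity_match(default_cohort.table, seed=7)
        b = propensity_match(default_cohort.table, seed=7)
        pd.testing.assert_frame_equal(a.pairs, b.pairs)

    def test_affine_invariance_of_pairing(self, default_cohort):
        """Recoding age to months changes nothing: matching is on the
        propensity logit."""
        base = propensity_match(default_cohort.table, seed=5)
        recoded = default_cohort.table.copy()
        recoded["age"] = recoded["age"] * 12.0
        alt = propensity_match(recoded, seed=5)
        pd.testing.assert_frame_equal(base.pairs, alt.pairs)

    def test_missing_column_reported(self, default_cohort):
        with pytest.raises(ValueError, match="nope"):
            propensity_match(default_cohort.table, covariates=["nope"])


class TestLogistic:
    def test_single_binary_predictor_equals_two_by_two(self):
        # build a table with known 2x2 counts
        a, b, c, d = 21, 108, 12, 72
        df = pd.DataFrame(
            {
                "y": [1] * a + [0] * b + [1] * c + [0] * d,
                "x": [1] * (a + b) + [0] * (c + d),
            }
        )
        logit_or = fit_logistic(df, "y", ["x"])["x"].point
        table_or = two_by_two_effects(a, b, c, d).odds_ratio.point
        assert logit_or == pytest.approx(table_or, abs=1e-6)

    def test_parameter_recovery_or_2(self):
        """A true OR of 2.0 per unit at n=5000 is estimated within
        [1.7, 2.3] in at least 95 of 100 seeds."""
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            x = rng.binomial(1, 0.4, 5000)
            p = expit(-1.5 + np.log(2.0) * x)
            y = rng.binomial(1, p)
            df = pd.DataFrame({"y": y, "x": x})
            est = fit_logistic(df, "y", ["x"])["x"].point
            if 1.7 <= est <= 2.3:
                hits += 1
        assert hits >= 95

    def test_joint_recovery_of_two_independent_effects(self):
        rng = np.random.default_rng(7)
        n = 20000
        x1 = rng.normal(size=n)
        x2 = rng.binomial(1, 0.3, n)
        p = expit(-2.0 + np.log(1.5) * x1 + np.log(2.5) * x2)
        df = pd.DataFrame({"y": rng.binomial(1, p), "x1": x1, "x2": x2})
        fit = fit_logistic(df, "y", ["x1", "x2"])
        assert fit["x1"].ci_low <= 1.5 <= fit["x1"].ci_high
        assert fit["x2"].ci_low <= 2.5 <= fit["x2"].ci_high

    def test_constant_predictor_dropped_with_warning(self):
        df = pd.DataFrame({"y": [0, 1] * 20, "x": np.r_[np.zeros(20), np.ones(20)],
                           "c": np.ones(40)})
        with pytest.warns(UserWarning, match="constant"):
            fit = fit_logistic(df, "y", ["x", "c"])
        assert "c" not in fit
        assert "x" in fit

    def test_non_binary_outcome_rejected(self):
        df = pd.DataFrame({"y": [0, 1, 2, 1], "x": [0.0, 1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="binary"):
            fit_logistic(df, "y", ["x"])


class TestRoc:
    def test_perfect_separation(self):
        scores = np.r_[np.zeros(50), np.ones(50)]
        labels = np.r_[np.zeros(50), np.ones(50)]
        roc = roc_analysis(scores, labels)
        assert roc.auc == pytest.approx(1.0)
        assert roc.youden_sensitivity == pytest.approx(1.0)
        assert roc.youden_specificity == pytest.approx(1.0)

    def test_auc_equals_rank_sum_statistic(self):
        """Trapezoid AUC equals the tie-corrected concordance U/(n1*n2)."""
        rng = np.random.default_rng(11)
        scores = np.round(rng.normal(size=400), 1)  # rounding forces ties
        labels = rng.binomial(1, 0.45, 400)
        roc = roc_analysis(scores, labels)
        u = sps.mannwhitneyu(scores[labels == 1], scores[labels == 0]).statistic
        auc_u = u / ((labels == 1).sum() * (labels == 0).sum())
        assert roc.auc == pytest.approx(auc_u, abs=1e-12)

    def test_null_auc_near_half(self):
        rng = np.random.default_rng(3)
        scores = rng.random(10000)
        labels = rng.binomial(1, 0.5, 10000)
        assert roc_analysis(scores, labels).auc == pytest.approx(0.5, abs=0.02)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="two classes"):
            roc_analysis(np.arange(10.0), np.ones(10))

    def test_roc_points_monotone(self, default_cohort):
        df = default_cohort.table
        roc = roc_analysis(df["stob_hours"].to_numpy(), df["mace"].to_numpy())
        assert np.all(np.diff(roc.sensitivity) >= 0)
        assert np.all(np.diff(roc.specificity) <= 0)
        assert 0.0 <= roc.auc <= 1.0
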
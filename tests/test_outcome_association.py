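import numpy as np
import pytest

from adherclust import (
    ClusterAssignment,
    OutcomeTable,
    chi_square_independence,
    cluster_risk_scores,
    fit_logistic,
    odds_ratios_vs_reference,
    reconstruct_event_counts,
    roc_curve,
)
from oracles import pairwise_auc, pearson_chi2

# published six-cluster mortality pattern: sizes and 2nd/3rd-year death rates
SIZES = (519, 309, 408, 441, 433, 850)
RATES = (0.033, 0.061, 0.034, 0.048, 0.020, 0.024)


@pytest.fixture(scope="module")
def mortality_table():
    events = tuple(reconstruct_event_counts(n, p) for n, p in zip(SIZES, RATES))
    return OutcomeTable(tuple(range(1, 7)), SIZES, events, reference=6)


class TestReconstructCounts:
    @pytest.mark.parametrize(
        "n,p,expected",
        [(309, 0.061, 19), (850, 0.024, 20), (433, 0.020, 9), (0, 0.5, 0)],
    )
    def test_rounds_half_away_from_zero(self, n, p, expected):
        assert reconstruct_event_counts(n, p) == expected

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            reconstruct_event_counts(-1, 0.5)
        with pytest.raises(ValueError):
            reconstruct_event_counts(10, 1.5)

    def test_total_reconstructed_deaths(self, mortality_table):
        assert sum(mortality_table.events) == 100


class TestOddsRatios:
    def test_poorest_cluster_versus_optimal(self, mortality_table):
        ors = odds_ratios_vs_reference(mortality_table)
        assert ors.or_[2] == pytest.approx(2.72, abs=0.005)
        assert ors.or_[5] == pytest.approx(0.88, abs=0.005)
        assert ors.or_[6] == 1.0

    def test_equal_rates_give_unit_or(self):
        table = OutcomeTable((1, 2), (100, 200), (10, 20), reference=2)
        assert odds_ratios_vs_reference(table).or_[1] == pytest.approx(1.0)

    def test_profile_ci_is_asymmetric_and_contains_or(self, mortality_table):
        ors = odds_ratios_vs_reference(mortality_table)
        for c in range(1, 6):
            assert ors.ci_low[c] < ors.or_[c] < ors.ci_high[c]
        # small event count -> visible asymmetry on the log scale
        up = np.log(ors.ci_high[5]) - np.log(ors.or_[5])
        down = np.log(ors.or_[5]) - np.log(ors.ci_low[5])
        assert up != pytest.approx(down, rel=1e-3)

    def test_wald_ci_is_log_symmetric(self, mortality_table):
        ors = odds_ratios_vs_reference(mortality_table, ci_method="wald")
        for c in range(1, 6):
            up = np.log(ors.ci_high[c]) - np.log(ors.or_[c])
            down = np.log(ors.or_[c]) - np.log(ors.ci_low[c])
            assert up == pytest.approx(down, rel=1e-9)

    def test_reversed_event_coding_reciprocates_ors(self, mortality_table):
        flipped = OutcomeTable(
            mortality_table.cluster_ids,
            mortality_table.n,
            tuple(n - e for n, e in zip(mortality_table.n, mortality_table.events)),
            reference=6,
        )
        a = odds_ratios_vs_reference(mortality_table)
        b = odds_ratios_vs_reference(flipped)
        for c in range(1, 6):
            assert b.or_[c] == pytest.approx(1.0 / a.or_[c])

    def test_zero_cell_comparison_flagged_not_raised(self):
        table = OutcomeTable((1, 2), (50, 100), (0, 10), reference=2)
        ors = odds_ratios_vs_reference(table)
        assert ors.or_[1] == 0.0
        assert np.isnan(ors.ci_low[1]) and 1 in ors.flagged

    def test_degenerate_reference_raises(self):
        table = OutcomeTable((1, 2), (50, 100), (5, 0), reference=2)
        with pytest.raises(ValueError):
            odds_ratios_vs_reference(table)


class TestChiSquare:
    def test_identical_rows_give_zero_statistic(self):
        stat, df, p = chi_square_independence([[10, 10], [10, 10]])
        assert stat == pytest.approx(0.0) and p == pytest.approx(1.0)
        assert df == 1

    def test_matches_direct_oe_summation(self, rng):
        for _ in range(20):
            table = rng.integers(1, 40, size=(3, 4))
            stat, df, _ = chi_square_independence(table)
            assert stat == pytest.approx(pearson_chi2(table), rel=1e-12)
            assert df == 6

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            chi_square_independence([[0, 0], [3, 4]])


class TestRiskScores:
    def test_members_get_their_cluster_rate(self):
        labels = ClusterAssignment(np.array([1, 1, 2, 2, 2]), 2)
        table = OutcomeTable((1, 2), (2, 3), (1, 0), reference=1)
        scores = cluster_risk_scores(table, labels)
        assert np.allclose(scores, [0.5, 0.5, 0.0, 0.0, 0.0])

    def test_scores_equal_indicator_logistic_fitted_probabilities(self, rng):
        labels_arr = np.concatenate([[1, 2, 3], rng.integers(1, 4, 117)])
        labels = ClusterAssignment(labels_arr, 3)
        y = rng.random(120) < 0.1 + 0.15 * (labels_arr == 2)
        y = y.astype(int)
        if y.sum() in (0, len(y)):
            pytest.skip("degenerate draw")
        table = OutcomeTable.from_assignment(labels, y, reference=1)
        scores = cluster_risk_scores(table, labels)
        indicators = np.column_stack([(labels_arr == c).astype(float) for c in (2, 3)])
        fit = fit_logistic(indicators, y)
        assert fit.converged
        assert np.allclose(fit.predict_proba(indicators), scores, atol=1e-6)


class TestLogisticFit:
    def test_intercept_only_is_logit_of_rate(self):
        y = np.array([1, 0, 0, 0, 1, 0, 0, 0, 0, 0])
        X = np.zeros((10, 1))
        fit = fit_logistic(X, y)
        assert fit.intercept == pytest.approx(np.log(0.2 / 0.8), abs=1e-6)

    def test_single_binary_predictor_slope_is_log_or(self):
        # 2x2 table: exposed 8/20 events, unexposed 3/30
        X = np.array([[1.0]] * 20 + [[0.0]] * 30)
        y = np.array([1] * 8 + [0] * 12 + [1] * 3 + [0] * 27)
        fit = fit_logistic(X, y)
        log_or = np.log((8 / 12) / (3 / 27))
        assert fit.coefficients[0] == pytest.approx(log_or, abs=1e-6)

    def test_duplicated_dataset_gives_identical_fit(self, rng):
        X = rng.random((40, 2))
        y = (rng.random(40) < 0.3).astype(int)
        fit1 = fit_logistic(X, y)
        fit2 = fit_logistic(np.vstack([X, X]), np.concatenate([y, y]))
        assert np.allclose(fit1.coefficients, fit2.coefficients, atol=1e-6)

    def test_complete_separation_flagged(self):
        X = np.array([[float(i)] for i in range(20)])
        y = (X.ravel() >= 10).astype(int)
        fit = fit_logistic(X, y)
        assert not fit.converged

    def test_one_class_outcomes_rejected(self):
        with pytest.raises(ValueError):
            fit_logistic(np.zeros((5, 1)), np.zeros(5))


class TestROC:
    def test_perfect_separation_gives_unit_auc(self):
        roc = roc_curve([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0])
        assert roc.auc == pytest.approx(1.0)

    def test_constant_scores_give_half(self):
        roc = roc_curve([0.5] * 10, [1, 0] * 5)
        assert roc.auc == pytest.approx(0.5)

    def test_curve_runs_corner_to_corner_monotonically(self, rng):
        scores = rng.random(50)
        y = (rng.random(50) < 0.4).astype(int)
        roc = roc_curve(scores, y)
        assert roc.fpr[0] == 0 and roc.tpr[0] == 0
        assert roc.fpr[-1] == 1 and roc.tpr[-1] == 1
        assert (np.diff(roc.fpr) >= 0).all() and (np.diff(roc.tpr) >= 0).all()

    def test_auc_matches_pair_counting_oracle(self, rng):
        for _ in range(25):
            n = int(rng.integers(8, 40))
            scores = rng.integers(0, 6, n).astype(float)  # ties guaranteed
            y = (rng.random(n) < 0.4).astype(int)
            if y.sum() in (0, n):
                continue
            roc = roc_curve(scores, y)
            assert roc.auc == pytest.approx(pairwise_auc(scores, y), abs=1e-12)

    def test_auc_invariant_under_monotone_transform(self, rng):
        scores = rng.random(60)
        y = (rng.random(60) < 0.3).astype(int)
        a = roc_curve(scores, y).auc
        b = roc_curve(np.exp(3 * scores) + 7, y).auc
        assert a == pytest.approx(b, abs=1e-12)

    def test_reversed_outcome_coding_complements_auc(self, rng):
        scores = rng.integers(0, 10, 80).astype(float)
        y = (rng.random(80) < 0.35).astype(int)
        a = roc_curve(scores, y).auc
        b = roc_curve(-scores, y).auc
        assert a + b == pytest.approx(1.0, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_curve([0.1, 0.2], [1, 1])
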
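import numpy as np
import pytest
from lifelines.statistics import logrank_test
from scipy import stats

from histoprog.errors import (
    DegenerateFeatureError,
    NoEventsError,
    ParameterError,
    UndefinedConcordanceError,
)
from histoprog.survival import (
    SurvivalRecord,
    concordance_index,
    cox_score_test,
    fit_elasticnet_cox,
    fit_univariate_cox,
    kaplan_meier,
    records_to_frame,
    screen_features,
)
from histoprog.synthetic_data import CohortSimSpec, simulate_cohort


def _os_frame(cohort):
    return records_to_frame(cohort.survival, endpoint="OS")


class TestSurvivalRecord:
    def test_field_validation(self):
        with pytest.raises(ParameterError):
            SurvivalRecord("a", -1.0, 1)
        with pytest.raises(ParameterError):
            SurvivalRecord("a", 1.0, 2)
        with pytest.raises(ParameterError):
            SurvivalRecord("a", 1.0, 1, endpoint="PFS")

    def test_duplicate_subjects_rejected_per_endpoint(self):
        recs = [SurvivalRecord("a", 1.0, 1), SurvivalRecord("a", 2.0, 0)]
        with pytest.raises(ParameterError):
            records_to_frame(recs, endpoint="OS")


class TestScoreTest:
    def test_two_subject_hand_evaluated_score(self):
        # Risk sets: {1,2} then {2}. U = (x1 - mean)/1 = (x1-x2)/2,
        # V = ((x1-x2)/2)^2, so chi2 = 1 and p = P(chi2_1 > 1).
        _, _, chi2, p = cox_score_test(
            np.array([[0.0], [1.0]]), np.array([1.0, 2.0]), np.array([1, 1])
        )
        assert chi2[0] == pytest.approx(1.0)
        assert p[0] == pytest.approx(stats.chi2.sf(1.0, 1))

    def test_matches_lifelines_logrank_for_binary_covariate(self):
        rng = np.random.default_rng(1)
        n = 80
        t = rng.exponential(1, n) + rng.uniform(0, 1e-9, n)  # no ties
        e = rng.integers(0, 2, n)
        e[:5] = 1
        g = rng.integers(0, 2, n).astype(float)
        _, _, _, p = cox_score_test(g[:, None], t, e)
        lr = logrank_test(t[g == 1], t[g == 0], e[g == 1], e[g == 0])
        assert p[0] == pytest.approx(lr.p_value, rel=1e-10)

    def test_null_pvalues_approximately_uniform(self):
        cohort = simulate_cohort(
            CohortSimSpec(
                n_tumor=200, n_normal=0, n_features=200, class_shift=0,
                n_clusters=1, survival_beta=np.zeros(200), censor_fraction=0.25, seed=8,
            )
        )
        fr = _os_frame(cohort)
        X = cohort.features.loc[fr.index].to_numpy()
        _, _, _, p = cox_score_test(X, fr["time"].to_numpy(), fr["event"].to_numpy())
        ks = stats.kstest(p, "uniform")
        assert ks.pvalue > 0.01

    def test_no_events_raises(self):
        with pytest.raises(NoEventsError):
            cox_score_test(np.ones((3, 1)), np.array([1.0, 2, 3]), np.zeros(3, int))


class TestUnivariateCox:
    def test_perfectly_concordant_feature(self):
        t = np.array([1.0, 2.0, 3.0, 4.0])
        e = np.ones(4, int)
        x = -stats.rankdata(t)
        res = fit_univariate_cox(x, t, e)
        assert res.coefficient > 0
        assert res.c_index == pytest.approx(1.0)
        assert res.hazard_ratio == pytest.approx(np.exp(res.coefficient))

    def test_simulation_recovers_true_coefficient(self):
        cohort = simulate_cohort(
            CohortSimSpec(
                n_tumor=300, n_normal=0, n_features=1, class_shift=0, n_clusters=1,
                survival_beta=np.array([1.0]), censor_fraction=0.25, seed=2,
            )
        )
        fr = _os_frame(cohort)
        x = cohort.features.loc[fr.index, "f0"].to_numpy()
        res = fit_univariate_cox(x, fr["time"].to_numpy(), fr["event"].to_numpy())
        assert abs(res.coefficient - 1.0) < 0.25
        assert res.logrank_p < 1e-3

    def test_constant_feature_rejected(self):
        with pytest.raises(DegenerateFeatureError):
            fit_univariate_cox(np.ones(10), np.arange(1.0, 11.0), np.ones(10, int))


class TestScreening:
    def test_reported_percentage_arithmetic(self):
        # 272 significant of 1408 features is reported as 19.3%.
        assert round(100 * 272 / 1408, 1) == 19.3

    def test_null_type_one_error_rate(self):
        cohort = simulate_cohort(
            CohortSimSpec(
                n_tumor=200, n_normal=0, n_features=500, class_shift=0, n_clusters=1,
                survival_beta=np.zeros(500), censor_fraction=0.25, seed=11,
            )
        )
        fr = _os_frame(cohort)
        sel, pct, _ = screen_features(
            cohort.features.loc[fr.index], fr["time"].to_numpy(), fr["event"].to_numpy()
        )
        assert 0.03 <= len(sel) / 500 <= 0.07
        assert pct == pytest.approx(100 * len(sel) / 500)

    def test_zero_threshold_selects_nothing(self, small_cohort):
        fr = _os_frame(small_cohort)
        X = small_cohort.tumor_features.loc[fr.index]
        sel, _, _ = screen_features(X, fr["time"].to_numpy(), fr["event"].to_numpy(), threshold=0.0)
        assert len(sel) == 0

    def test_constant_columns_excluded_with_warning(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((50, 4))
        X[:, 2] = 7.0
        t = rng.exponential(1, 50)
        e = np.ones(50, int)
        with pytest.warns(UserWarning, match="near-constant"):
            sel, _, p = screen_features(X, t, e)
        assert p[2] == 1.0 and 2 not in sel


class TestElasticNet:
    def test_huge_lambda_gives_null_model(self, small_cohort):
        fr = _os_frame(small_cohort)
        X = small_cohort.tumor_features.loc[fr.index]
        model = fit_elasticnet_cox(
            X, fr["time"].to_numpy(), fr["event"].to_numpy(), folds=5,
            lambda_override=1e6, seed=0,
        )
        assert (model.coefficients == 0).all()
        assert model.c_index == pytest.approx(0.5)

    def test_support_recovery_and_cindex(self):
        rng = np.random.default_rng(5)
        beta = np.zeros(50)
        true_idx = rng.choice(50, 5, replace=False)
        beta[true_idx] = 1.0
        cohort = simulate_cohort(
            CohortSimSpec(
                n_tumor=400, n_normal=0, n_features=50, class_shift=0, n_clusters=1,
                survival_beta=beta, censor_fraction=0.25, seed=5,
            )
        )
        fr = _os_frame(cohort)
        model = fit_elasticnet_cox(
            cohort.features.loc[fr.index], fr["time"].to_numpy(), fr["event"].to_numpy(),
            alpha=0.5, folds=10, seed=5,
        )
        assert model.alpha == 0.5
        recovered = np.flatnonzero(model.coefficients.to_numpy() != 0)
        assert len(set(recovered) & set(true_idx)) >= 4
        assert model.c_index >= 0.75
        assert model.logrank_p < 0.01

    def test_path_sparsity_nonincreasing_in_lambda(self, small_cohort):
        fr = _os_frame(small_cohort)
        X = small_cohort.tumor_features.loc[fr.index]
        from sksurv.linear_model import CoxnetSurvivalAnalysis
        from sksurv.util import Surv

        Z = (X - X.mean()) / X.std()
        fit = CoxnetSurvivalAnalysis(l1_ratio=0.5, n_alphas=50).fit(
            Z.to_numpy(), Surv.from_arrays(fr["event"].to_numpy(bool), fr["time"].to_numpy())
        )
        counts = (fit.coef_ != 0).sum(axis=0)  # alphas_ descend along the path
        assert all(a >= b for a, b in zip(counts[1:], counts[:-1]))

    def test_fewer_events_than_folds_rejected(self):
        t = np.arange(1.0, 9.0)
        e = np.array([1, 1, 0, 0, 0, 0, 0, 0])
        with pytest.raises(NoEventsError):
            fit_elasticnet_cox(np.random.default_rng(0).standard_normal((8, 3)), t, e, folds=10)


class TestConcordance:
    def test_perfectly_anti_ordered_risk(self):
        t = np.array([3.0, 2.0, 1.0])
        assert concordance_index(np.array([1.0, 2.0, 3.0]), t, np.ones(3, int)) == 1.0

    def test_three_subject_pair_enumeration(self):
        # pairs: (1,2) conc, (1,3) conc, (2,3) disc -> 2/3
        c = concordance_index(
            np.array([3.0, 1.0, 2.0]), np.array([1.0, 2.0, 3.0]), np.ones(3, int)
        )
        assert c == pytest.approx(2 / 3, abs=1e-9)

    def test_complement_under_negation(self):
        rng = np.random.default_rng(6)
        risk = rng.standard_normal(50)
        t = rng.exponential(1, 50)
        e = np.ones(50, int)
        assert concordance_index(risk, t, e) + concordance_index(-risk, t, e) == pytest.approx(1.0)

    def test_undefined_without_events(self):
        with pytest.raises(UndefinedConcordanceError):
            concordance_index(np.ones(3), np.arange(1.0, 4.0), np.zeros(3, int))


class TestKaplanMeier:
    def test_product_limit_by_hand(self):
        t = np.array([1.0, 2.0, 3.0, 4.0])
        e = np.array([1, 0, 0, 0])
        curves, _ = kaplan_meier(t, e, np.zeros(4, int))
        df = curves[0]
        at_one = df.loc[df["timeline"] == 1.0, "survival"].iloc[0]
        assert at_one == pytest.approx(0.75)

    def test_no_events_flat_curve(self):
        curves, _ = kaplan_meier(np.arange(1.0, 5.0), np.zeros(4, int), np.zeros(4, int))
        assert (curves[0]["survival"] == 1.0).all()

    def test_hazard_ratio_three_detected(self):
        rng = np.random.default_rng(7)
        t = np.concatenate([rng.exponential(1.0, 100), rng.exponential(3.0, 100)])
        e = np.ones(200, int)
        g = np.repeat([0, 1], 100)
        _, p = kaplan_meier(t, e, g)
        assert p < 0.01

    def test_single_group_returns_no_pvalue(self):
        _, p = kaplan_meier(np.arange(1.0, 5.0), np.ones(4, int), np.zeros(4, int))
        assert p is None


def test_generated_censoring_fraction_matches_spec(small_cohort):
    fr = _os_frame(small_cohort)
    assert abs((1 - fr["event"].mean()) - 0.25) <= 0.05
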
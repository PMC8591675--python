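import numpy as np
import pytest

from survpls.survival_core import SurvivalOutcome
from survpls.survival_metrics import (
    IAUC_METHODS,
    MetricCurve,
    brier_curve,
    event_time_grid,
    gonen_heller_c,
    gonen_heller_c_risk,
    harrell_c,
    iauc,
    integrate_curve,
    km_censoring,
    km_survival,
    r2_curve_integrated,
    r2_likelihood,
    schemper_henderson_curve,
    schmid_curve,
    survival_matrix_from_km,
    uno_c,
)


def step_predictions(outcome, grid):
    """Oracle predictions: Ŝ(t|i) steps from 1 to 0 at the subject's true time."""
    return (outcome.time[:, None] > np.asarray(grid)[None, :]).astype(float)


def make_censored(seed=0, n=80, link=1.0):
    rng = np.random.default_rng(seed)
    risk = rng.standard_normal(n)
    T = rng.exponential(np.exp(-link * risk))
    C = rng.exponential(1.5, n)
    return risk, SurvivalOutcome(np.minimum(T, C), (T <= C).astype(int))


class TestKMCensoring:
    def test_no_censoring_identically_one(self, toy_outcome):
        G = km_censoring(toy_outcome)
        assert G(0.5) == 1.0 and G(10.0) == 1.0

    def test_hand_example(self):
        outcome = SurvivalOutcome([1.0, 2.0, 3.0], [1, 0, 1])
        G = km_censoring(outcome)
        assert G(1.5) == pytest.approx(1.0)
        assert G(2.0) == pytest.approx(0.5)
        assert G(10.0) == pytest.approx(0.5)

    def test_nonincreasing(self):
        _, outcome = make_censored(1)
        G = km_censoring(outcome)
        grid = np.linspace(0, outcome.time.max(), 100)
        assert np.all(np.diff(G(grid)) <= 1e-12)

    def test_against_lifelines(self):
        from lifelines import KaplanMeierFitter

        _, outcome = make_censored(2)
        G = km_censoring(outcome)
        kmf = KaplanMeierFitter().fit(outcome.time, 1 - outcome.status)
        for t in np.quantile(outcome.time, [0.2, 0.5, 0.8]):
            assert G(t) == pytest.approx(
                float(kmf.survival_function_at_times(t).iloc[0]), abs=1e-10
            )


class TestBrierCurve:
    def test_perfect_oracle_zero(self, toy_outcome):
        grid = event_time_grid(toy_outcome)
        S = step_predictions(toy_outcome, grid)
        curve = brier_curve(S, toy_outcome)
        assert np.allclose(curve.values, 0.0)

    def test_two_subject_hand_value(self, two_subject_outcome):
        S = np.full((2, 1), 0.5)
        curve = brier_curve(S, two_subject_outcome, grid=np.array([1.5]))
        assert curve.values[0] == pytest.approx(0.25)

    def test_km_self_consistency(self):
        _, outcome = make_censored(3)
        grid = event_time_grid(outcome)
        S = survival_matrix_from_km(outcome, grid)
        c1 = brier_curve(S, outcome)
        c2 = brier_curve(survival_matrix_from_km(outcome, grid), outcome)
        assert np.allclose(c1.values, c2.values, atol=1e-12)

    def test_unweighted_in_unit_interval(self):
        rng = np.random.default_rng(4)
        _, outcome = make_censored(4)
        grid = event_time_grid(outcome)
        S = rng.random((outcome.n, grid.size))
        S = np.sort(S, axis=1)[:, ::-1]
        curve = brier_curve(S, outcome, weighted=False)
        assert np.all((curve.values >= 0) & (curve.values <= 1))

    def test_weighted_equals_unweighted_without_censoring(self, toy_outcome):
        grid = event_time_grid(toy_outcome)
        S = np.tile([0.8, 0.5, 0.2], (3, 1))
        w = brier_curve(S, toy_outcome, weighted=True)
        u = brier_curve(S, toy_outcome, weighted=False)
        assert np.allclose(w.values, u.values)


class TestSchmidCurve:
    def test_perfect_oracle_zero(self, toy_outcome):
        grid = event_time_grid(toy_outcome)
        S = step_predictions(toy_outcome, grid)
        assert np.allclose(schmid_curve(S, toy_outcome).values, 0.0)

    def test_two_subject_hand_value(self, two_subject_outcome):
        S = np.full((2, 1), 0.5)
        curve = schmid_curve(S, two_subject_outcome, grid=np.array([1.5]))
        assert curve.values[0] == pytest.approx(0.5)

    def test_dominates_brier_without_censoring(self):
        rng = np.random.default_rng(5)
        n = 30
        outcome = SurvivalOutcome(rng.exponential(1, n) + 0.01, np.ones(n))
        grid = event_time_grid(outcome)
        S = np.sort(rng.random((n, grid.size)), axis=1)[:, ::-1]
        ss = schmid_curve(S, outcome).values
        bs = brier_curve(S, outcome).values
        assert np.all(ss >= bs - 1e-12)


class TestSchemperHenderson:
    def test_perfect_oracle_zero(self, toy_outcome):
        grid = event_time_grid(toy_outcome)
        S = step_predictions(toy_outcome, grid)
        assert np.allclose(schemper_henderson_curve(S, toy_outcome).values, 0.0)

    def test_constant_half_no_censoring(self, toy_outcome):
        grid = event_time_grid(toy_outcome)
        S = np.full((3, grid.size), 0.5)
        assert np.allclose(schemper_henderson_curve(S, toy_outcome).values, 0.5)

    def test_two_subject_hand_spreadsheet(self, two_subject_outcome):
        # at t = 1.5: subject 1 died (term S = 0.3), subject 2 alive (1 - 0.6)
        S = np.array([[0.3], [0.6]])
        curve = schemper_henderson_curve(S, two_subject_outcome, grid=np.array([1.5]))
        assert curve.values[0] == pytest.approx((0.3 + 0.4) / 2)


class TestIntegrateCurve:
    def test_constant_curve(self):
        curve = MetricCurve(np.array([1.0, 2.0]), np.array([0.3, 0.3]), tmax=5.0)
        assert integrate_curve(curve) == pytest.approx(0.3)

    def test_two_point_hand_integration(self):
        # constant 0.2 on [0,1], linear 0.2->0.4 on [1,3], constant 0.4 on [3,4]
        curve = MetricCurve(np.array([1.0, 3.0]), np.array([0.2, 0.4]), tmax=4.0)
        expected = (0.2 * 1 + (0.2 + 0.4) / 2 * 2 + 0.4 * 1) / 4.0
        assert integrate_curve(curve) == pytest.approx(expected)

    def test_linearity(self):
        grid = np.array([0.5, 1.5, 2.5])
        vals = np.array([0.1, 0.4, 0.2])
        c1 = MetricCurve(grid, vals, tmax=3.0)
        c3 = MetricCurve(grid, 3 * vals, tmax=3.0)
        assert integrate_curve(c3) == pytest.approx(3 * integrate_curve(c1))


class TestR2Curves:
    def test_equal_curves_zero(self):
        grid = np.array([1.0, 2.0])
        c = MetricCurve(grid, np.array([0.2, 0.3]), tmax=2.0)
        assert r2_curve_integrated(c, c) == pytest.approx(0.0)

    def test_zero_curve_gives_one(self):
        grid = np.array([1.0, 2.0])
        c = MetricCurve(grid, np.zeros(2), tmax=2.0)
        null = MetricCurve(grid, np.array([0.2, 0.3]), tmax=2.0)
        assert r2_curve_integrated(c, null) == pytest.approx(1.0)

    def test_constant_ratio(self):
        grid = np.array([1.0, 2.0])
        c = MetricCurve(grid, np.full(2, 0.1), tmax=2.0)
        null = MetricCurve(grid, np.full(2, 0.2), tmax=2.0)
        assert r2_curve_integrated(c, null) == pytest.approx(0.5)

    def test_null_zero_curve_raises(self):
        grid = np.array([1.0])
        c = MetricCurve(grid, np.array([0.1]), tmax=1.0)
        null = MetricCurve(grid, np.array([0.0]), tmax=1.0)
        with pytest.raises(ValueError):
            r2_curve_integrated(c, null)

    def test_oracle_predictions_near_one_uncensored(self):
        rng = np.random.default_rng(6)
        n = 40
        outcome = SurvivalOutcome(rng.exponential(1, n) + 0.01, np.ones(n))
        grid = event_time_grid(outcome)
        S = step_predictions(outcome, grid)
        null = survival_matrix_from_km(outcome, grid)
        irss = r2_curve_integrated(schmid_curve(S, outcome), schmid_curve(null, outcome))
        ir2bs = r2_curve_integrated(brier_curve(S, outcome), brier_curve(null, outcome))
        assert irss > 0.99 and ir2bs > 0.99

    def test_km_predictions_give_zero(self):
        _, outcome = make_censored(7)
        grid = event_time_grid(outcome)
        null = survival_matrix_from_km(outcome, grid)
        assert r2_curve_integrated(
            schmid_curve(null, outcome), schmid_curve(null, outcome)
        ) == pytest.approx(0.0)


class TestR2Likelihood:
    def test_no_improvement_zero(self):
        assert r2_likelihood(-10.0, -10.0, n=20, kind="nagelkerke") == 0.0
        assert r2_likelihood(-10.0, -10.0, e=5, kind="oxs") == 0.0

    def test_oxs_equals_nagelkerke_when_all_events(self):
        assert r2_likelihood(-10, -8, n=20, kind="nagelkerke") == pytest.approx(
            r2_likelihood(-10, -8, e=20, kind="oxs")
        )

    def test_xo_zero_when_equal_j(self):
        assert r2_likelihood(0, 0, kind="xo", J0=3.0, Jbeta=3.0) == 0.0

    def test_zero_counts_raise(self):
        with pytest.raises(ValueError):
            r2_likelihood(-10, -8, n=0, kind="nagelkerke")
        with pytest.raises(ValueError):
            r2_likelihood(-10, -8, e=0, kind="oxs")


def harrell_oracle(risk, time, status, tie_value=0.0):
    """Pair-enumeration oracle for the concordance index."""
    num = den = 0.0
    n = len(time)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            if time[i] < time[j] and status[i] == 1:
                den += 1
                if risk[i] > risk[j]:
                    num += 1
                elif risk[i] == risk[j]:
                    num += tie_value
    return num / den


class TestHarrellC:
    def test_three_subject_enumeration(self):
        outcome = SurvivalOutcome([1.0, 2.0, 3.0], [1, 1, 0])
        assert harrell_c(np.array([3.0, 1.0, 2.0]), outcome) == pytest.approx(2 / 3)

    def test_perfect_separation(self):
        rng = np.random.default_rng(8)
        t = np.sort(rng.exponential(1, 20)) + 0.01
        outcome = SurvivalOutcome(t, np.ones(20))
        assert harrell_c(-t, outcome) == pytest.approx(1.0)

    def test_independent_risk_near_half(self):
        rng = np.random.default_rng(9)
        n = 2000
        outcome = SurvivalOutcome(rng.exponential(1, n) + 1e-9, np.ones(n))
        assert harrell_c(rng.standard_normal(n), outcome) == pytest.approx(0.5, abs=0.03)

    def test_matches_enumeration_oracle(self):
        risk, outcome = make_censored(10, n=40)
        assert harrell_c(risk, outcome) == pytest.approx(
            harrell_oracle(risk, outcome.time, outcome.status), abs=1e-12
        )

    def test_tie_flag(self):
        outcome = SurvivalOutcome([1.0, 2.0], [1, 1])
        risk = np.array([1.0, 1.0])
        assert harrell_c(risk, outcome) == 0.0
        assert harrell_c(risk, outcome, tie_value=0.5) == 0.5

    def test_no_usable_pairs_raises(self):
        outcome = SurvivalOutcome([1.0, 2.0], [0, 1])
        with pytest.raises(ValueError):
            harrell_c(np.array([1.0, 2.0]), outcome)


class TestGonenHeller:
    def test_zero_beta_gives_zero(self):
        rng = np.random.default_rng(11)
        assert gonen_heller_c(np.zeros(3), rng.standard_normal((10, 3))) == 0.0

    def test_two_subject_hand_value(self):
        # beta'(X2 - X1) = -1
        X = np.array([[1.0], [0.0]])
        assert gonen_heller_c(np.array([1.0]), X) == pytest.approx(1 / (1 + np.exp(-1)), abs=1e-10)
        assert gonen_heller_c(np.array([1.0]), X) == pytest.approx(0.7311, abs=1e-4)

    def test_translation_invariance(self):
        rng = np.random.default_rng(12)
        eta = rng.standard_normal(30)
        assert gonen_heller_c_risk(eta) == pytest.approx(gonen_heller_c_risk(eta + 17.3))

    def test_needs_two_subjects(self):
        with pytest.raises(ValueError):
            gonen_heller_c_risk(np.array([1.0]))


def survroc_oracle(risk, outcome):
    """Brute-force cumulative/dynamic integrated AUC with KM density weights,
    entirely independent of the package implementation (lifelines KM)."""
    from lifelines import KaplanMeierFitter

    kmf = KaplanMeierFitter().fit(outcome.time, outcome.status)
    aucs, weights = [], []
    for t in np.unique(outcome.time[outcome.status == 1]):
        cases = [i for i in range(outcome.n) if outcome.time[i] <= t and outcome.status[i] == 1]
        controls = [j for j in range(outcome.n) if outcome.time[j] > t]
        if not cases or not controls:
            continue
        num = 0.0
        for i in cases:
            for j in controls:
                if risk[i] > risk[j]:
                    num += 1.0
                elif risk[i] == risk[j]:
                    num += 0.5
        s_right = float(kmf.survival_function_at_times(t).iloc[0])
        s_left = float(kmf.survival_function_at_times(t - 1e-9).iloc[0])
        aucs.append(num / (len(cases) * len(controls)))
        weights.append(2.0 * (s_left - s_right) * s_right)
    w = np.asarray(weights)
    if w.sum() <= 0:
        w = np.ones(len(aucs))
    return float(np.asarray(aucs) @ w / w.sum())


class TestIAUC:
    def test_survroc_matches_brute_force_oracle(self):
        rng = np.random.default_rng(13)
        time = rng.exponential(1, 10) + 0.01
        status = np.array([1, 1, 0, 1, 1, 0, 1, 1, 1, 0])
        outcome = SurvivalOutcome(time, status)
        risk = rng.standard_normal(10)
        got = iauc(risk, outcome, outcome, method="survROC")
        assert got == pytest.approx(survroc_oracle(risk, outcome), abs=1e-8)

    @pytest.mark.parametrize("method", IAUC_METHODS)
    def test_independent_risk_near_half(self, method):
        rng = np.random.default_rng(14)
        n = 400
        T = rng.exponential(1, n)
        C = rng.exponential(1.5, n)
        outcome = SurvivalOutcome(np.minimum(T, C) + 1e-9, (T <= C).astype(int))
        val = iauc(rng.standard_normal(n), outcome, outcome, method=method)
        assert val == pytest.approx(0.5, abs=0.05)

    @pytest.mark.parametrize("method", IAUC_METHODS)
    def test_perfect_ranking_near_one(self, method):
        rng = np.random.default_rng(15)
        t = np.sort(rng.exponential(1, 60)) + 0.01
        outcome = SurvivalOutcome(t, np.ones(60))
        val = iauc(-t, outcome, outcome, method=method)
        assert val > 0.95

    @pytest.mark.parametrize("method", ["survROC", "HC", "Uno", "HZ"])
    def test_monotone_transform_invariance(self, method):
        risk, outcome = make_censored(16, n=50)
        v1 = iauc(risk, outcome, outcome, method=method)
        v2 = iauc(np.exp(2 * risk) + 3, outcome, outcome, method=method)
        assert v1 == pytest.approx(v2, abs=1e-10)

    @pytest.mark.parametrize("method", ["CD", "SH"])
    def test_affine_transform_invariance_model_based(self, method):
        # the model-based estimators refit a Cox on the score, which absorbs
        # affine maps exactly but not arbitrary monotone ones
        risk, outcome = make_censored(16, n=50)
        v1 = iauc(risk, outcome, outcome, method=method)
        v2 = iauc(2.5 * risk - 7.0, outcome, outcome, method=method)
        assert v1 == pytest.approx(v2, abs=1e-8)

    def test_too_few_events_raises(self):
        outcome = SurvivalOutcome([1.0, 2.0, 3.0], [1, 0, 0])
        with pytest.raises(ValueError):
            iauc(np.array([1.0, 2.0, 3.0]), outcome, outcome, method="survROC")

    def test_unknown_method_rejected(self, toy_outcome):
        with pytest.raises(ValueError):
            iauc(np.zeros(3), toy_outcome, toy_outcome, method="nope")


class TestUnoC:
    def test_no_censoring_equals_restricted_harrell(self):
        rng = np.random.default_rng(17)
        n = 30
        t = rng.exponential(1, n) + 0.01
        outcome = SurvivalOutcome(t, np.ones(n))
        risk = rng.standard_normal(n)
        tau = float(np.median(t))
        # restricted Harrell oracle: usable pairs with earlier time < tau
        num = den = 0.0
        for i in range(n):
            for j in range(n):
                if t[i] < t[j] and t[i] < tau:
                    den += 1
                    num += 1.0 if risk[i] > risk[j] else 0.0
        assert uno_c(risk, outcome, tau) == pytest.approx(num / den, abs=1e-10)

    def test_perfect_ranking(self):
        rng = np.random.default_rng(18)
        t = np.sort(rng.exponential(1, 25)) + 0.01
        outcome = SurvivalOutcome(t, np.ones(25))
        assert uno_c(-t, outcome) == pytest.approx(1.0)

    def test_random_risk_near_half(self):
        risk, outcome = make_censored(19, n=600, link=0.0)
        assert uno_c(risk, outcome) == pytest.approx(0.5, abs=0.05)

    def test_tau_beyond_data_rejected(self):
        _, outcome = make_censored(20)
        with pytest.raises(ValueError):
            uno_c(np.zeros(outcome.n), outcome, tau=outcome.time.max() * 2)
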
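import numpy as np
import pandas as pd
import pytest
from scipy.linalg import expm as scipy_expm

from msphase._linalg import expm_batch
from msphase.markov import (
    MarkovModelError,
    ProportionalIntensityModel,
    TransitionStructure,
    crude_init,
    fit,
    hazard_ratios,
    ms_structure,
    panel_loglik,
    predicted_probabilities_ci,
    expected_prevalence,
    transition_probability,
)
from msphase.simulate import simulate_panel_ctmc


def two_state(q=0.1):
    st = TransitionStructure(("alive", "dead"), (("alive", "dead"),), frozenset({"dead"}))
    return ProportionalIntensityModel(st, np.log([q]))


def random_generator_matrix(rng, n):
    A = rng.uniform(0.05, 1.0, (n, n))
    np.fill_diagonal(A, 0.0)
    np.fill_diagonal(A, -A.sum(axis=1))
    return A


class TestExpmBatch:
    def test_matches_scipy_to_1e12(self, rng):
        A = np.stack([random_generator_matrix(rng, 4) * rng.uniform(0.1, 5) for _ in range(100)])
        ref = np.stack([scipy_expm(a) for a in A])
        assert np.abs(expm_batch(A) - ref).max() < 1e-12

    def test_defective_matrix(self):
        A = np.array([[0.0, 1.0], [0.0, 0.0]])  # nilpotent: exp = I + A
        assert np.allclose(expm_batch(A), np.eye(2) + A, atol=1e-14)


class TestIntensityMatrix:
    def test_baseline_rates(self):
        st = ms_structure()
        logq = np.log([0.1, 0.2, 0.3, 0.4, 0.01, 0.02, 0.03])
        m = ProportionalIntensityModel(st, logq)
        Q = m.intensity_matrix({})
        assert Q[0, 1] == pytest.approx(0.1)
        assert Q[2, 1] == pytest.approx(0.4)
        assert np.abs(Q.sum(axis=1)).max() < 1e-12
        assert np.all(Q[3] == 0)  # absorbing row

    def test_per_transition_covariate_effect(self):
        """An age hazard ratio of 1.044 on RRMS->nrSPMS multiplies only that
        entry when age increases by one year."""
        st = ms_structure()
        spec = {("RRMS", "nrSPMS"): ["age"], ("nrSPMS", "rSPMS"): ["age"]}
        beta = {("RRMS", "nrSPMS"): np.array([np.log(1.044)]),
                ("nrSPMS", "rSPMS"): np.array([0.0])}
        m = ProportionalIntensityModel(st, np.full(7, -2.0), beta, spec)
        Q0, Q1 = m.intensity_matrix({"age": 40.0}), m.intensity_matrix({"age": 41.0})
        assert Q1[0, 1] / Q0[0, 1] == pytest.approx(1.044)
        assert Q1[1, 2] == pytest.approx(Q0[1, 2])

    def test_missing_covariate_named(self):
        st = ms_structure()
        m = ProportionalIntensityModel(
            st, np.zeros(7), {("RRMS", "nrSPMS"): np.array([0.1])},
            {("RRMS", "nrSPMS"): ["edss"]},
        )
        with pytest.raises(MarkovModelError, match="edss"):
            m.intensity_matrix({"age": 40.0})


class TestTransitionProbability:
    def test_identity_at_zero_duration(self):
        m = two_state()
        assert np.array_equal(transition_probability(m, {}, 3.0, 3.0), np.eye(2))

    def test_exponential_survival(self):
        P = transition_probability(two_state(0.1), {}, 0.0, 5.0)
        assert P[0, 0] == pytest.approx(np.exp(-0.5), abs=1e-12)

    def test_semigroup_property(self, rng):
        st = ms_structure()
        m = ProportionalIntensityModel(st, rng.normal(-2, 0.5, 7))
        one = transition_probability(m, {}, 0.0, 7.0)
        two = transition_probability(m, [(0.0, {}), (3.0, {})], 0.0, 7.0)
        assert np.abs(one - two).max() < 1e-12

    def test_path_gap_raises(self):
        m = two_state()
        with pytest.raises(MarkovModelError, match="cover"):
            transition_probability(m, [(2.0, {})], 0.0, 5.0)

    def test_rows_sum_to_one(self, rng):
        st = ms_structure()
        for _ in range(20):
            m = ProportionalIntensityModel(st, rng.normal(-1, 1, 7))
            P = transition_probability(m, {}, 0.0, float(rng.uniform(0.1, 20)))
            assert np.abs(P.sum(axis=1) - 1).max() < 1e-10


class TestPanelLoglik:
    def test_zero_intensity_same_state(self):
        m = two_state(1e-12)
        panel = pd.DataFrame(
            {"patient_id": ["a", "a"], "time": [0.0, 5.0], "state": [1, 1],
             "obs_type": ["panel", "panel"]}
        )
        assert panel_loglik(m, panel) == pytest.approx(0.0, abs=1e-10)

    def test_death_density_closed_form(self):
        q, t = 0.23, 4.2
        panel = pd.DataFrame(
            {"patient_id": ["a", "a"], "time": [0.0, t], "state": [1, 2],
             "obs_type": ["panel", "exact_death"]}
        )
        ll = panel_loglik(two_state(q), panel)
        assert ll == pytest.approx(np.log(q) - q * t, abs=1e-10)

    def test_impossible_transition_is_minus_inf(self):
        st = ms_structure()
        m = ProportionalIntensityModel(st, np.full(7, -2.0))
        panel = pd.DataFrame(
            {"patient_id": ["a", "a"], "time": [0.0, 1.0], "state": [2, 1],
             "obs_type": ["panel", "panel"]}
        )  # nrSPMS -> RRMS is structurally impossible
        with pytest.warns(UserWarning, match="zero-probability"):
            assert panel_loglik(m, panel) == -np.inf

    def test_state_relabelling_invariance(self, rng):
        """Permuting the transient state labels consistently leaves the
        likelihood unchanged."""
        st = TransitionStructure(("a", "b", "c"), (("a", "b"), ("b", "a"), ("b", "c")),
                                 frozenset({"c"}))
        logq = rng.normal(-1, 0.5, 3)
        m = ProportionalIntensityModel(st, logq)
        pan = simulate_panel_ctmc(m, lambda r, i: {}, 40, np.arange(0, 8.0), seed=5)
        # swap labels a<->b everywhere
        st2 = TransitionStructure(("b", "a", "c"), (("a", "b"), ("b", "a"), ("b", "c")),
                                  frozenset({"c"}))
        m2 = ProportionalIntensityModel(st2, logq)
        pan2 = pan.copy()
        pan2["state"] = pan["state"].map({1: 2, 2: 1, 3: 3})
        assert panel_loglik(m2, pan2) == pytest.approx(panel_loglik(m, pan), abs=1e-9)


class TestFit:
    def test_two_state_recovery(self):
        truth = two_state(0.2)
        pan = simulate_panel_ctmc(truth, lambda r, i: {}, 500, np.arange(0, 10.5, 1.0), seed=2)
        res = fit(crude_init(truth, pan), pan)
        assert res.converged
        assert abs(res.estimates[0] - np.log(0.2)) < 3 * res.se()[0]

    def test_covariate_hazard_ratio_recovery(self):
        st = TransitionStructure(("alive", "dead"), (("alive", "dead"),), frozenset({"dead"}))
        truth = ProportionalIntensityModel(
            st, np.log([0.1]), {("alive", "dead"): np.array([np.log(2.0)])},
            {("alive", "dead"): ["x"]},
        )
        pan = simulate_panel_ctmc(
            truth, lambda r, i: {"x": float(r.integers(0, 2))}, 1000,
            np.arange(0, 10.5, 1.0), seed=4,
        )
        res = fit(crude_init(truth, pan), pan)
        k = res.param_names.index("beta(alive->dead):x")
        assert abs(res.estimates[k] - np.log(2)) < 3 * res.se()[k]

    def test_centered_fit_matches_uncentered(self):
        """Centering covariates during optimization changes conditioning only:
        the reported parameters and standard errors agree with the uncentered
        fit."""
        st = TransitionStructure(("alive", "dead"), (("alive", "dead"),), frozenset({"dead"}))
        truth = ProportionalIntensityModel(
            st, np.log([0.15]), {("alive", "dead"): np.array([0.05])},
            {("alive", "dead"): ["age"]},
        )
        pan = simulate_panel_ctmc(
            truth, lambda r, i: {"age": float(r.normal(40, 5))}, 400,
            np.arange(0, 10.5, 1.0), seed=6,
        )
        init = crude_init(truth, pan)
        plain = fit(init, pan)
        centered = fit(init, pan, center=True)
        assert np.abs(plain.estimates - centered.estimates).max() < 1e-3
        assert np.abs(plain.se() - centered.se()).max() < 1e-3

    def test_refit_from_optimum_is_fixed_point(self):
        truth = two_state(0.2)
        pan = simulate_panel_ctmc(truth, lambda r, i: {}, 200, np.arange(0, 8.0), seed=9)
        res1 = fit(crude_init(truth, pan), pan)
        res2 = fit(res1.model, pan)
        assert np.abs(res2.estimates - res1.estimates).max() < 1e-5

    def test_nonfinite_init_raises(self):
        st = ms_structure()
        m = ProportionalIntensityModel(st, np.full(7, -2.0))
        panel = pd.DataFrame(
            {"patient_id": ["a", "a"], "time": [0.0, 1.0], "state": [2, 1],
             "obs_type": ["panel", "panel"]}
        )
        with pytest.warns(UserWarning):
            with pytest.raises(MarkovModelError, match="crude"):
                fit(m, panel)


class TestHazardRatios:
    def make_fit(self, beta, se):
        st = TransitionStructure(("alive", "dead"), (("alive", "dead"),), frozenset({"dead"}))
        m = ProportionalIntensityModel(
            st, np.log([0.1]), {("alive", "dead"): np.array([beta])}, {("alive", "dead"): ["x"]}
        )
        from msphase.markov import FitResult

        vcov = np.diag([0.01, se**2])
        return FitResult(m, m.pack(), vcov, -1.0, True, pd.DataFrame(), m.param_names)

    def test_zero_beta_unit_hr(self):
        hr = hazard_ratios(self.make_fit(0.0, 0.1))
        row = hr.iloc[0]
        assert row["hr"] == pytest.approx(1.0)
        assert row["lower"] < 1.0 < row["upper"]

    def test_ci_width_monotone_in_se(self):
        widths = [
            hazard_ratios(self.make_fit(0.1, se)).iloc[0][["lower", "upper"]].diff().iloc[-1]
            for se in (0.05, 0.1, 0.2)
        ]
        assert widths[0] < widths[1] < widths[2]

    def test_reference_format(self):
        from msphase.pipeline import fmt_ci

        hr = hazard_ratios(self.make_fit(np.log(1.0435), 0.00220))
        row = hr.iloc[0]
        assert fmt_ci(row["hr"], row["lower"], row["upper"]) == "1.044 (1.039–1.048)"


class TestPredictedProbabilities:
    def test_degenerate_vcov(self):
        truth = two_state(0.2)
        pan = simulate_panel_ctmc(truth, lambda r, i: {}, 100, np.arange(0, 6.0), seed=3)
        res = fit(crude_init(truth, pan), pan)
        res.vcov[:] = 0.0
        pred = predicted_probabilities_ci(res, {}, horizons=(5.0,), n_draws=20, seed=0)
        d = pred[5.0]
        assert np.abs(d["lower"] - d["point"]).max() < 1e-12
        assert np.abs(d["upper"] - d["point"]).max() < 1e-12

    def test_drawn_matrices_are_stochastic_and_reproducible(self):
        truth = two_state(0.2)
        pan = simulate_panel_ctmc(truth, lambda r, i: {}, 100, np.arange(0, 6.0), seed=3)
        res = fit(crude_init(truth, pan), pan)
        p1 = predicted_probabilities_ci(res, {}, horizons=(5.0,), n_draws=50, seed=11)
        p2 = predicted_probabilities_ci(res, {}, horizons=(5.0,), n_draws=50, seed=11)
        assert np.array_equal(p1[5.0]["lower"], p2[5.0]["lower"])
        assert np.abs(p1[5.0]["point"].sum(axis=1) - 1).max() < 1e-10
        assert np.all(p1[5.0]["lower"] <= p1[5.0]["point"] + 1e-12)
        assert np.all(p1[5.0]["upper"] >= p1[5.0]["point"] - 1e-12)


class TestExpectedPrevalence:
    def test_initial_grid_point_matches(self):
        truth = two_state(0.2)
        pan = simulate_panel_ctmc(truth, lambda r, i: {}, 100, np.arange(0, 6.0), seed=3)
        res = fit(crude_init(truth, pan), pan)
        prev = res and expected_prevalence(res, pan, [0.0])
        alive = prev[prev["state"] == "alive"].iloc[0]
        assert alive["observed"] == pytest.approx(1.0)
        assert alive["expected"] == pytest.approx(1.0)

    def test_zero_intensity_constant(self):
        m = two_state(1e-12)
        pan = simulate_panel_ctmc(m, lambda r, i: {}, 50, np.arange(0, 6.0), seed=3)
        from msphase.markov import FitResult

        res = FitResult(m, m.pack(), np.zeros((1, 1)), 0.0, True, pd.DataFrame(), m.param_names)
        prev = expected_prevalence(res, pan, [0.0, 2.0, 4.0])
        alive = prev[prev["state"] == "alive"]
        assert np.allclose(alive["expected"], 1.0, atol=1e-9)
        assert np.allclose(alive["observed"], 1.0)
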
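import numpy as np
import pandas as pd
import pytest

from msphase.survival import (
    SurvivalError,
    aalen_johansen,
    cox_ph,
    gee_poisson_arr,
    kaplan_meier,
    poisson_arr,
    schoenfeld_trend_test,
)


def random_survival_records(rng, n=80, competing=False):
    entry = np.zeros(n)
    exit_ = rng.exponential(5.0, n) + 0.01
    cens = rng.exponential(7.0, n) + 0.01
    ev = np.where(exit_ <= cens, "A", "censored").astype(object)
    if competing:
        is_b = rng.random(n) < 0.4
        ev = np.where((ev == "A") & is_b, "B", ev)
    t = np.minimum(exit_, cens)
    return pd.DataFrame({"entry": entry, "exit": t, "event": ev})


class TestAalenJohansen:
    def test_all_censored(self):
        rec = pd.DataFrame({"entry": [0, 0], "exit": [1, 2], "event": ["censored"] * 2})
        est = aalen_johansen(rec, ("A",))
        assert np.all(est.surv == 1.0) if est.times.size else True
        assert est.cif_at("A", 5.0) == 0.0
        assert est.surv_at(5.0) == 1.0

    def test_hand_enumerated_example(self):
        """Five subjects, risk sets 5/3/2 at the event times: CIF_A(4)=7/15,
        CIF_B(4)=4/15."""
        rec = pd.DataFrame(
            {"entry": [0] * 5, "exit": [1, 2, 3, 4, 5],
             "event": ["A", "censored", "B", "A", "censored"]}
        )
        est = aalen_johansen(rec)
        assert est.cif_at("A", 4) == pytest.approx(7 / 15, abs=1e-12)
        assert est.cif_at("B", 4) == pytest.approx(4 / 15, abs=1e-12)

    def test_single_type_is_km_complement(self, rng):
        rec = random_survival_records(rng)
        est = aalen_johansen(rec, ("A",))
        km = kaplan_meier(rec, "A")
        for t, s in zip(est.times, est.surv):
            assert 1.0 - est.cif_at("A", t) == pytest.approx(s, abs=1e-12)
            assert km.loc[t] == pytest.approx(s, abs=1e-10)

    def test_conservation(self, rng):
        rec = random_survival_records(rng, competing=True)
        est = aalen_johansen(rec)
        total = est.surv + sum(est.cif.values())
        assert np.abs(total - 1.0).max() < 1e-12

    def test_late_entry_shrinks_early_risk_set(self):
        rec = pd.DataFrame(
            {"entry": [0, 0, 3], "exit": [2, 5, 6], "event": ["A", "A", "A"]}
        )
        est = aalen_johansen(rec)
        assert est.at_risk[0] == 2  # the late entrant is not at risk at t=2
        assert est.cif_at("A", 2) == pytest.approx(0.5)

    def test_order_invariance(self, rng):
        rec = random_survival_records(rng, competing=True)
        shuffled = rec.sample(frac=1.0, random_state=1).reset_index(drop=True)
        a, b = aalen_johansen(rec), aalen_johansen(shuffled)
        assert np.array_equal(a.times, b.times)
        for k in a.cif:
            assert np.allclose(a.cif[k], b.cif[k], atol=1e-14)

    def test_empty_raises(self):
        with pytest.raises(SurvivalError):
            aalen_johansen(pd.DataFrame(columns=["entry", "exit", "event"]))


class TestKaplanMeier:
    def test_no_events(self):
        rec = pd.DataFrame({"entry": [0, 0], "exit": [1, 2], "event": ["censored"] * 2})
        s = kaplan_meier(rec, "A")
        assert np.all(s.to_numpy() == 1.0)

    def test_exhaustion(self):
        rec = pd.DataFrame({"entry": [0, 0], "exit": [1, 2], "event": ["A", "A"]})
        s = kaplan_meier(rec)
        assert s.loc[2] == 0.0


class TestCoxPH:
    def toy_records(self):
        return pd.DataFrame(
            {
                "entry": [0.0] * 6,
                "exit": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
                "event": ["m", "m", "censored", "m", "m", "censored"],
                "x": [1.0, 1.0, 0.0, 0.0, 1.0, 0.0],
            }
        )

    def grid_oracle(self, rec, grid):
        """Dense grid search of the Breslow log partial likelihood."""
        t = rec["exit"].to_numpy()
        d = (rec["event"] != "censored").to_numpy()
        x = rec["x"].to_numpy()
        best, best_ll = None, -np.inf
        for b in grid:
            ll = 0.0
            for i in np.flatnonzero(d):
                at_risk = t >= t[i]
                ll += b * x[i] - np.log(np.sum(np.exp(b * x[at_risk])))
            if ll > best_ll:
                best, best_ll = b, ll
        return best

    def test_coefficient_matches_grid_oracle(self):
        rec = self.toy_records()
        res = cox_ph(rec, ["x"])
        oracle = self.grid_oracle(rec, np.arange(-3, 3, 1e-4))
        assert res.table.loc[0, "coef"] == pytest.approx(oracle, abs=1e-4)

    def test_score_vanishes_at_optimum(self):
        res = cox_ph(self.toy_records(), ["x"])
        assert res.score_norm < 1e-6

    def test_constant_covariate_flagged(self):
        rec = self.toy_records().assign(z=1.0)
        with pytest.warns(UserWarning, match="constant"):
            res = cox_ph(rec, ["z"])
        assert res.table.loc[0, "coef"] == 0.0

    def test_time_rescaling_invariance(self):
        rec = self.toy_records()
        res1 = cox_ph(rec, ["x"])
        rec2 = rec.assign(exit=rec["exit"] * 2.0)
        res2 = cox_ph(rec2, ["x"])
        assert res2.table.loc[0, "coef"] == pytest.approx(res1.table.loc[0, "coef"], abs=1e-10)

    def test_hr_format(self):
        res = cox_ph(self.toy_records(), ["x"])
        txt = res.format_hr("x")
        assert "(" in txt and "–" in txt

    def test_schoenfeld_trend_runs(self, rng):
        rec = random_survival_records(rng).assign(x=rng.normal(size=80))
        out = schoenfeld_trend_test(rec, ["x"])
        assert set(out.columns) == {"term", "corr_with_time_rank", "p"}


class TestPoissonARR:
    def test_single_subject(self):
        res = poisson_arr([2], [2.0])
        assert res.arr == pytest.approx(1.0, abs=1e-8)

    def test_intercept_only_equals_crude_rate(self, rng):
        counts = rng.poisson(1.3, 40)
        expo = rng.uniform(0.5, 3.0, 40)
        res = poisson_arr(counts, expo)
        assert res.arr == pytest.approx(counts.sum() / expo.sum(), rel=1e-9)

    def test_robust_ci_wider_under_overdispersion(self, rng):
        # negative-binomial counts: variance >> mean, so the sandwich CI must
        # be wider than the model-based Poisson CI
        n = 400
        lam = rng.gamma(shape=0.5, scale=2.0, size=n)
        counts = rng.poisson(lam * 2.0)
        expo = np.full(n, 2.0)
        import statsmodels.api as sm

        X = np.ones((n, 1))
        model = sm.GLM(counts, X, family=sm.families.Poisson(), offset=np.log(expo))
        naive = model.fit()
        robust = model.fit(cov_type="HC0")
        assert robust.bse[0] > naive.bse[0]
        res = poisson_arr(counts, expo)
        assert res.table.loc[0, "se_log"] == pytest.approx(robust.bse[0], rel=1e-6)

    def test_zero_exposure_raises(self):
        with pytest.raises(SurvivalError):
            poisson_arr([1], [0.0])


class TestGEE:
    def make_onerow_data(self, rng, n=120):
        group = rng.choice(["RRMS", "nrSPMS"], n)
        sex = rng.choice(["female", "male"], n)
        age = rng.uniform(20, 60, n)
        expo = rng.uniform(0.5, 3.0, n)
        rate = 0.3 * np.exp(0.4 * (group == "nrSPMS") - 0.01 * (age - 40))
        counts = rng.poisson(rate * expo)
        return pd.DataFrame(
            {"patient_id": [f"p{i}" for i in range(n)], "age": age, "count": counts,
             "exposure": expo, "group": group, "sex": sex}
        )

    def test_degenerates_to_glm_with_independence(self, rng):
        """One row per patient + independence working correlation solves the
        same estimating equations as the Poisson GLM."""
        import statsmodels.api as sm

        df = self.make_onerow_data(rng)
        gee = gee_poisson_arr(df, cov_struct="independence", interaction=False, age_degree=1)
        glm = sm.GLM.from_formula(
            "count ~ C(group) + C(sex) + age", data=df,
            family=sm.families.Poisson(), offset=np.log(df["exposure"]),
        ).fit(tol=1e-12)
        gee_coefs = gee.table.set_index("term")["coef"]
        for term, value in glm.params.items():
            assert gee_coefs[term] == pytest.approx(value, abs=1e-8)

    def test_clustered_irr_recovery(self, rng):
        """Clustered counts with a true group IRR of 2 are recovered within
        three robust standard errors."""
        rows = []
        for i in range(150):
            group = "B" if i % 2 else "A"
            frailty = rng.gamma(4.0, 0.25)
            for a in range(30, 34):
                rate = 0.5 * (2.0 if group == "B" else 1.0) * frailty
                rows.append(
                    {"patient_id": f"p{i}", "age": a, "count": rng.poisson(rate),
                     "exposure": 1.0, "group": group, "sex": "female"}
                )
        df = pd.DataFrame(rows)
        res = gee_poisson_arr(df, cov_struct="exchangeable", interaction=False)
        row = res.table[res.table["term"].str.contains("group")].iloc[0]
        assert abs(row["coef"] - np.log(2)) < 3 * row["se"]

    def test_unbalanced_bins_fall_back(self, rng):
        df = self.make_onerow_data(rng)
        df2 = pd.concat([df, df.iloc[[0]].assign(age=df["age"].iloc[0] + 1)])
        with pytest.warns(UserWarning, match="exchangeable"):
            res = gee_poisson_arr(df2, interaction=False)
        assert res.cov_struct == "exchangeable"

    def test_patient_order_invariance(self, rng):
        df = self.make_onerow_data(rng)
        res1 = gee_poisson_arr(df, cov_struct="independence", interaction=False)
        res2 = gee_poisson_arr(
            df.sample(frac=1.0, random_state=7).reset_index(drop=True),
            cov_struct="independence", interaction=False,
        )
        a = res1.table.set_index("term")["coef"]
        b = res2.table.set_index("term")["coef"]
        for term in a.index:
            assert a[term] == pytest.approx(b[term], abs=1e-8)
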
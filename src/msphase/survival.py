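"""Non-Markov estimators: Aalen–Johansen cumulative incidence under competing
risks, Kaplan–Meier, Cox proportional hazards, Poisson annualized relapse
rates with robust variance, and GEE Poisson rate trajectories.

Event records are tidy DataFrames with columns ``entry`` and ``exit`` (years),
``event`` (an event-type label, or ``"censored"``), and any covariate columns.
The tie rule everywhere is events before censorings at equal times; Cox uses
the Breslow partial likelihood.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from lifelines import KaplanMeierFitter
from statsmodels.duration.hazard_regression import PHReg

Z95 = 1.959964
CENSORED = "censored"


class SurvivalError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Aalen–Johansen


@dataclass
class CIFEstimate:
    """Stepwise cumulative-incidence functions per competing event type.

    ``times`` is the increasing grid of event times; ``cif[k][j]`` the
    cumulative incidence of type k just after ``times[j]``; ``surv`` the
    overall (all-cause) survival; ``at_risk`` the risk-set size at each event
    time.  Conservation surv(t) + sum_k cif_k(t) = 1 holds exactly by
    construction.
    """

    times: np.ndarray
    cif: dict[str, np.ndarray]
    surv: np.ndarray
    at_risk: np.ndarray
    event_types: tuple[str, ...] = field(default=())

    def cif_at(self, event_type: str, t: float) -> float:
        i = np.searchsorted(self.times, t, side="right") - 1
        return 0.0 if i < 0 else float(self.cif[event_type][i])

    def surv_at(self, t: float) -> float:
        i = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if i < 0 else float(self.surv[i])

    def as_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"time": self.times, "surv": self.surv, "at_risk": self.at_risk})
        for k, v in self.cif.items():
            df[f"cif_{k}"] = v
        return df


def aalen_johansen(records: pd.DataFrame, event_types: tuple[str, ...] | None = None) -> CIFEstimate:
    """Aalen–Johansen estimator of cumulative incidence with late entry.

    At each event time t with risk set n(t) = #{entry < t <= exit}:
    ``cif_k += S(t-) d_k / n`` and ``S *= 1 - d/n``, where d is the all-type
    event count at t.  Subjects censored exactly at t remain in the risk set
    (events before censorings).
    """
    if len(records) == 0:
        raise SurvivalError("empty event records")
    entry = records["entry"].to_numpy(dtype=float) if "entry" in records else np.zeros(len(records))
    exit_ = records["exit"].to_numpy(dtype=float)
    ev = records["event"].astype(str).to_numpy()
    if np.any(entry >= exit_):
        raise SurvivalError("entry must precede exit for every record")
    if event_types is None:
        event_types = tuple(sorted(set(ev) - {CENSORED}))
    unknown = set(ev) - set(event_types) - {CENSORED}
    if unknown:
        raise SurvivalError(f"undeclared event type(s): {sorted(unknown)}")

    is_event = ev != CENSORED
    times = np.unique(exit_[is_event])
    S = 1.0
    surv = np.empty(times.size)
    at_risk = np.empty(times.size, dtype=int)
    cif = {k: np.empty(times.size) for k in event_types}
    cum = {k: 0.0 for k in event_types}
    for j, t in enumerate(times):
        n = int(np.sum((entry < t) & (exit_ >= t)))
        at_risk[j] = n
        d_total = 0
        for k in event_types:
            d_k = int(np.sum((exit_ == t) & (ev == k)))
            if n > 0 and d_k:
                cum[k] += S * d_k / n
            d_total += d_k
        if n > 0:
            S *= 1.0 - d_total / n
        surv[j] = S
        for k in event_types:
            cif[k][j] = cum[k]
    return CIFEstimate(times, cif, surv, at_risk, event_types)


def kaplan_meier(records: pd.DataFrame, event_type: str | None = None) -> pd.Series:
    """Product-limit survival curve (single event type), as a step series
    indexed by time.  Late entry is honoured via the ``entry`` column."""
    ev = records["event"].astype(str).to_numpy()
    types = sorted(set(ev) - {CENSORED})
    if event_type is None:
        if len(types) != 1:
            raise SurvivalError(f"kaplan_meier needs a single event type, found {types}")
        event_type = types[0]
    entry = records["entry"].to_numpy(dtype=float) if "entry" in records else None
    kmf = KaplanMeierFitter()
    kmf.fit(records["exit"], event_observed=(ev == event_type), entry=entry)
    s = kmf.survival_function_["KM_estimate"]
    s.index.name = "time"
    return s


# ---------------------------------------------------------------------------
# Cox proportional hazards


@dataclass
class CoxResult:
    table: pd.DataFrame  # term, coef, se, hr, lower, upper, p
    loglik: float
    score_norm: float
    warnings: list[str] = field(default_factory=list)

    def format_hr(self, term: str) -> str:
        row = self.table.set_index("term").loc[term]
        return f"{row['hr']:.3f} ({row['lower']:.3f}–{row['upper']:.3f})"


def cox_ph(records: pd.DataFrame, covariates: list[str]) -> CoxResult:
    """Multivariable Cox PH via the Breslow partial likelihood, with late
    entry.  Zero-variance covariates are reported with coefficient 0 and a
    warning (flat partial likelihood); suspicious separation (|coef| > 10) is
    flagged and capped."""
    ev = records["event"].astype(str).to_numpy()
    status = (ev != CENSORED).astype(int)
    if status.sum() == 0:
        raise SurvivalError("no events in the records")
    notes: list[str] = []
    X = records[covariates].to_numpy(dtype=float)
    keep = [i for i in range(len(covariates)) if np.ptp(X[:, i]) > 0]
    dropped = [covariates[i] for i in range(len(covariates)) if i not in keep]
    for name in dropped:
        notes.append(f"covariate {name} is constant: flat partial likelihood, coefficient set to 0")
        warnings.warn(notes[-1])
    entry = records["entry"].to_numpy(dtype=float) if "entry" in records else None
    model = PHReg(
        records["exit"].to_numpy(dtype=float),
        X[:, keep] if keep else np.zeros((len(records), 0)),
        status=status,
        entry=entry,
        ties="breslow",
    )
    if keep:
        res = model.fit(disp=False)
        params = np.asarray(res.params, dtype=float)
        se = np.asarray(res.bse, dtype=float)
        capped = np.abs(params) > 10
        if capped.any():
            notes.append("possible separation: coefficient(s) capped at |10|")
            warnings.warn(notes[-1])
            params = np.clip(params, -10, 10)
        score_norm = float(np.linalg.norm(model.score(np.asarray(res.params, dtype=float))))
        loglik = float(model.loglike(np.asarray(res.params, dtype=float)))
    else:
        params = np.empty(0)
        se = np.empty(0)
        score_norm = 0.0
        loglik = float("nan")
    rows = []
    j = 0
    for i, name in enumerate(covariates):
        if i in keep:
            b, s = params[j], se[j]
            j += 1
        else:
            b, s = 0.0, np.nan
        z = b / s if s and np.isfinite(s) and s > 0 else np.nan
        rows.append(
            {
                "term": name,
                "coef": b,
                "se": s,
                "hr": float(np.exp(b)),
                "lower": float(np.exp(b - Z95 * s)) if np.isfinite(s) else np.nan,
                "upper": float(np.exp(b + Z95 * s)) if np.isfinite(s) else np.nan,
                "p": float(2 * (1 - _ncdf(abs(z)))) if np.isfinite(z) else np.nan,
            }
        )
    return CoxResult(pd.DataFrame(rows), loglik, score_norm, notes)


def _ncdf(x: float) -> float:
    from scipy.stats import norm

    return float(norm.cdf(x))


def schoenfeld_trend_test(records: pd.DataFrame, covariates: list[str]) -> pd.DataFrame:
    """Proportional-hazards check: correlation of Schoenfeld residuals with
    event-time rank, per covariate.

    This is a standard residual-trend diagnostic, not the score-process
    simulation diagnostic; it answers the same question (does a covariate
    effect drift with time?) with a simple slope test.
    """
    fitres = cox_ph(records, covariates)
    beta = fitres.table.set_index("term")["coef"].to_numpy()
    X = records[covariates].to_numpy(dtype=float)
    exit_ = records["exit"].to_numpy(dtype=float)
    entry = records["entry"].to_numpy(dtype=float) if "entry" in records else np.zeros(len(records))
    ev = (records["event"].astype(str) != CENSORED).to_numpy()
    eta = np.exp(X @ beta)
    etimes = np.sort(np.unique(exit_[ev]))
    resid, ranks = [], []
    for rank, t in enumerate(etimes):
        at_risk = (entry < t) & (exit_ >= t)
        w = eta[at_risk]
        zbar = (X[at_risk].T @ w) / w.sum()
        for i in np.flatnonzero((exit_ == t) & ev):
            resid.append(X[i] - zbar)
            ranks.append(rank)
    R = np.asarray(resid)
    ranks = np.asarray(ranks, dtype=float)
    from scipy.stats import pearsonr

    rows = []
    for j, name in enumerate(covariates):
        if R.shape[0] > 2 and np.ptp(R[:, j]) > 0 and np.ptp(ranks) > 0:
            r, p = pearsonr(ranks, R[:, j])
        else:
            r, p = np.nan, np.nan
        rows.append({"term": name, "corr_with_time_rank": r, "p": p})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Poisson / GEE relapse rates


@dataclass
class RateResult:
    table: pd.DataFrame  # term, estimate (rate or ratio), lower, upper, se_log
    arr: float  # overall adjusted rate at the reference level
    model_result: object = None


def poisson_arr(
    counts, exposure_years, covariates: pd.DataFrame | None = None
) -> RateResult:
    """Annualized rate via Poisson regression with log-exposure offset and
    robust (HC0 sandwich) variance.

    Intercept-only: ARR = total events / total person-years exactly, with a
    robust CI.  With covariates, covariate rows are rate ratios.
    """
    y = np.asarray(counts, dtype=float)
    expo = np.asarray(exposure_years, dtype=float)
    if np.any(expo <= 0) or expo.sum() <= 0:
        raise SurvivalError("exposures must be positive")
    if y.sum() == 0:
        # boundary case: MLE rate is 0; exact Poisson 97.5% upper bound
        from scipy.stats import chi2

        upper = chi2.ppf(0.975, 2) / 2 / expo.sum()
        table = pd.DataFrame(
            [{"term": "intercept", "estimate": 0.0, "lower": 0.0,
              "upper": float(upper), "se_log": np.nan}]
        )
        return RateResult(table, arr=0.0)
    if covariates is None or covariates.shape[1] == 0:
        X = np.ones((y.size, 1))
        names = ["intercept"]
    else:
        X = sm.add_constant(covariates.to_numpy(dtype=float), has_constant="add")
        names = ["intercept"] + list(covariates.columns)
    res = sm.GLM(y, X, family=sm.families.Poisson(), offset=np.log(expo)).fit(
        cov_type="HC0", maxiter=200, tol=1e-12
    )
    b = np.asarray(res.params)
    se = np.asarray(res.bse)
    rows = []
    for i, name in enumerate(names):
        rows.append(
            {
                "term": name,
                "estimate": float(np.exp(b[i])),
                "lower": float(np.exp(b[i] - Z95 * se[i])),
                "upper": float(np.exp(b[i] + Z95 * se[i])),
                "se_log": float(se[i]),
            }
        )
    return RateResult(pd.DataFrame(rows), arr=float(np.exp(b[0])), model_result=res)


@dataclass
class GEEResult:
    table: pd.DataFrame
    cov_struct: str
    model_result: object = None
    warnings: list[str] = field(default_factory=list)

    def predict_arr(self, frame: pd.DataFrame) -> np.ndarray:
        """Marginal adjusted ARR for covariate rows (exposure = 1 year)."""
        return np.asarray(self.model_result.predict(frame, offset=np.zeros(len(frame))))


def gee_poisson_arr(
    data: pd.DataFrame,
    group_col: str = "group",
    age_col: str = "age",
    sex_col: str = "sex",
    count_col: str = "count",
    exposure_col: str = "exposure",
    cluster_col: str = "patient_id",
    age_degree: int = 1,
    interaction: bool = True,
    cov_struct: str = "unstructured",
) -> GEEResult:
    """Adjusted ARR trajectories via GEE Poisson with log link and
    log-exposure offset.

    One row per patient per age bin.  The mean model contains phenotype group,
    sex, a polynomial in age (degree ``age_degree``) and, optionally, the
    group-by-age interaction; clustering on patient with the requested
    working correlation (unstructured by default).  Unstructured correlation
    needs bins aligned across patients; with unbalanced bins it falls back to
    exchangeable with a logged warning.  Inference is by the robust sandwich
    covariance either way.
    """
    import statsmodels.genmod.cov_struct as cs

    df = data.copy()
    if np.any(df[exposure_col].to_numpy(dtype=float) <= 0):
        raise SurvivalError("exposures must be positive")
    notes: list[str] = []
    terms = [f"C({group_col})", f"C({sex_col})"]
    terms += [f"I({age_col}**{d})" if d > 1 else age_col for d in range(1, age_degree + 1)]
    if interaction:
        terms.append(f"C({group_col}):{age_col}")
    formula = f"{count_col} ~ " + " + ".join(terms)

    struct_name = cov_struct.lower()
    time = None
    if struct_name == "unstructured":
        bins = df.groupby(cluster_col)[age_col].apply(lambda s: tuple(sorted(s)))
        if bins.nunique() > 1:
            notes.append(
                "unstructured working correlation requires aligned age bins; "
                "falling back to exchangeable"
            )
            warnings.warn(notes[-1])
            struct_name = "exchangeable"
        else:
            base = min(b[0] for b in bins)
            time = (df[age_col] - base).to_numpy(dtype=int)
    struct = {
        "unstructured": cs.Unstructured,
        "exchangeable": cs.Exchangeable,
        "independence": cs.Independence,
    }[struct_name]()
    model = sm.GEE.from_formula(
        formula,
        groups=df[cluster_col],
        data=df,
        family=sm.families.Poisson(),
        offset=np.log(df[exposure_col].to_numpy(dtype=float)),
        cov_struct=struct,
        time=time,
    )
    res = model.fit(maxiter=200, ctol=1e-10)
    b = np.asarray(res.params)
    se = np.asarray(res.bse)
    table = pd.DataFrame(
        {
            "term": res.model.exog_names,
            "coef": b,
            "irr": np.exp(b),
            "lower": np.exp(b - Z95 * se),
            "upper": np.exp(b + Z95 * se),
            "se": se,
        }
    )
    return GEEResult(table, struct_name, res, notes)
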
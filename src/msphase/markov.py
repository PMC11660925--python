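"""Continuous-time multi-state Markov engine for panel-observed disease states.

States are observed only at visit times (panel data); transition times in
between are unobserved.  Transition intensities follow a log-linear
(proportional-intensity) model

    q_rs(z) = q0_rs * exp(beta_rs . z_rs)

with a transition-specific covariate subset z_rs taken piecewise-constant at
the left endpoint of each observation interval.  The likelihood of a panel
pair (t_i, s_i) -> (t_j, s_j) is the (s_i, s_j) entry of expm(Q(z_i) * (t_j -
t_i)); a death at an exactly known time contributes the density sum_s P[s_i,
s] * q_{s,Death} instead.  Times are in years; intensities and hazard ratios
are per-year.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from ._linalg import expm_batch

Z95 = 1.959964  # Wald 97.5% normal quantile


class MarkovModelError(ValueError):
    pass


# ---------------------------------------------------------------------------
# structure and model


@dataclass(frozen=True)
class TransitionStructure:
    """State labels, allowed directed transitions and absorbing states."""

    states: tuple[str, ...]
    allowed: tuple[tuple[str, str], ...]
    absorbing: frozenset[str]

    def __post_init__(self):
        idx = {s: i for i, s in enumerate(self.states)}
        for r, s in self.allowed:
            if r not in idx or s not in idx:
                raise MarkovModelError(f"transition {r}->{s} references unknown state")
            if r in self.absorbing:
                raise MarkovModelError(f"absorbing state {r} has outgoing transition")
            if r == s:
                raise MarkovModelError("self-transitions are implicit, not allowed pairs")

    @property
    def n_states(self) -> int:
        return len(self.states)

    def index(self, state: str) -> int:
        return self.states.index(state)

    def allowed_indices(self) -> list[tuple[int, int]]:
        return [(self.index(r), self.index(s)) for r, s in self.allowed]


def ms_structure() -> TransitionStructure:
    """The four-state MS phenotype structure: three transient states (RRMS,
    nrSPMS, rSPMS), death absorbing, RRMS never re-entered."""
    return TransitionStructure(
        states=("RRMS", "nrSPMS", "rSPMS", "Death"),
        allowed=(
            ("RRMS", "nrSPMS"),
            ("RRMS", "rSPMS"),
            ("nrSPMS", "rSPMS"),
            ("rSPMS", "nrSPMS"),
            ("RRMS", "Death"),
            ("nrSPMS", "Death"),
            ("rSPMS", "Death"),
        ),
        absorbing=frozenset({"Death"}),
    )


def ms_covariate_spec(reduced: bool = False) -> dict[tuple[str, str], list[str]]:
    """Per-transition covariate sets for the MS model.

    The RRMS exit transitions carry the full eight covariates; the
    SPMS-to-SPMS transitions carry sex, age, DMT exposures and EDSS only;
    death transitions carry age and sex.  ``reduced=True`` gives a lighter
    spec (sex, age, EDSS on RRMS exits; age between SPMS states) suitable for
    quick pipeline runs.
    """
    full = [
        "sex_female",
        "age",
        "hedmt_years",
        "medmt_years",
        "edss",
        "dx_year",
        "cum_relapses",
        "dx_duration",
    ]
    spms = ["sex_female", "age", "hedmt_years", "medmt_years", "edss"]
    death = ["age", "sex_female"]
    if reduced:
        full = ["sex_female", "age", "edss"]
        spms = ["age"]
    return {
        ("RRMS", "nrSPMS"): list(full),
        ("RRMS", "rSPMS"): list(full),
        ("nrSPMS", "rSPMS"): list(spms),
        ("rSPMS", "nrSPMS"): list(spms),
        ("RRMS", "Death"): list(death),
        ("nrSPMS", "Death"): list(death),
        ("rSPMS", "Death"): list(death),
    }


@dataclass
class ProportionalIntensityModel:
    """Transition structure plus baseline log-intensities and covariate effects.

    ``log_q0[k]`` is the log baseline intensity (log 1/year) of the k-th
    allowed transition; ``beta[(r, s)]`` the coefficient vector on that
    transition's covariate subset ``covariate_spec[(r, s)]``.
    """

    structure: TransitionStructure
    log_q0: np.ndarray
    beta: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)
    covariate_spec: dict[tuple[str, str], list[str]] = field(default_factory=dict)

    def __post_init__(self):
        self.log_q0 = np.asarray(self.log_q0, dtype=float)
        if self.log_q0.shape != (len(self.structure.allowed),):
            raise MarkovModelError(
                f"log_q0 must have one entry per allowed transition "
                f"({len(self.structure.allowed)}), got shape {self.log_q0.shape}"
            )
        for tr in self.structure.allowed:
            spec = self.covariate_spec.get(tr, [])
            b = np.asarray(self.beta.get(tr, np.zeros(len(spec))), dtype=float)
            if b.shape != (len(spec),):
                raise MarkovModelError(
                    f"beta for {tr} has length {b.size}, covariate_spec has {len(spec)}"
                )
            self.beta[tr] = b
            self.covariate_spec[tr] = list(spec)

    # -- parameter vector packing -------------------------------------------------
    @property
    def covariate_names(self) -> list[str]:
        names: list[str] = []
        for tr in self.structure.allowed:
            for c in self.covariate_spec[tr]:
                if c not in names:
                    names.append(c)
        return names

    @property
    def param_names(self) -> list[str]:
        names = [f"logq({r}->{s})" for r, s in self.structure.allowed]
        for r, s in self.structure.allowed:
            names += [f"beta({r}->{s}):{c}" for c in self.covariate_spec[(r, s)]]
        return names

    @property
    def n_params(self) -> int:
        return self.log_q0.size + sum(b.size for b in self.beta.values())

    def pack(self) -> np.ndarray:
        parts = [self.log_q0] + [self.beta[tr] for tr in self.structure.allowed]
        return np.concatenate(parts) if parts else np.empty(0)

    def unpack(self, theta: np.ndarray) -> "ProportionalIntensityModel":
        theta = np.asarray(theta, dtype=float)
        if theta.size != self.n_params:
            raise MarkovModelError(f"expected {self.n_params} parameters, got {theta.size}")
        k = self.log_q0.size
        log_q0 = theta[:k].copy()
        beta = {}
        for tr in self.structure.allowed:
            m = len(self.covariate_spec[tr])
            beta[tr] = theta[k : k + m].copy()
            k += m
        return ProportionalIntensityModel(self.structure, log_q0, beta, dict(self.covariate_spec))

    # -- intensity matrices -------------------------------------------------------
    def _q_batch(self, Z: np.ndarray, cov_names: Sequence[str]) -> np.ndarray:
        """Stack of intensity matrices for covariate rows Z (columns = cov_names)."""
        n, S = Z.shape[0], self.structure.n_states
        col = {c: i for i, c in enumerate(cov_names)}
        Q = np.zeros((n, S, S))
        for k, (tr, (i, j)) in enumerate(
            zip(self.structure.allowed, self.structure.allowed_indices())
        ):
            eta = np.full(n, self.log_q0[k])
            spec = self.covariate_spec[tr]
            if spec:
                idx = [col[c] for c in spec]
                eta = eta + Z[:, idx] @ self.beta[tr]
            Q[:, i, j] = np.exp(np.clip(eta, -700, 50))
        d = np.arange(S)
        Q[:, d, d] = -Q.sum(axis=2)
        return Q

    def intensity_matrix(self, z: Mapping[str, float]) -> np.ndarray:
        """The intensity matrix Q(z): off-diagonal rates per year, zero row sums,
        absorbing row identically zero."""
        names = self.covariate_names
        missing = [c for c in names if c not in z]
        if missing:
            raise MarkovModelError(f"missing covariate(s): {missing}")
        Z = np.array([[float(z[c]) for c in names]])
        return self._q_batch(Z, names)[0]


# ---------------------------------------------------------------------------
# covariate paths and transition probabilities


def _normalize_path(covariate_path, t0: float, t1: float) -> list[tuple[float, float, dict]]:
    """Turn a constant mapping or [(start, z), ...] list into closed segments
    covering [t0, t1]."""
    if isinstance(covariate_path, Mapping):
        return [(t0, t1, dict(covariate_path))]
    segs = sorted(covariate_path, key=lambda p: p[0])
    if not segs or segs[0][0] > t0:
        raise MarkovModelError(f"covariate path does not cover start time {t0}")
    out = []
    for k, (start, z) in enumerate(segs):
        stop = segs[k + 1][0] if k + 1 < len(segs) else t1
        a, b = max(start, t0), min(stop, t1)
        if a < b:
            out.append((a, b, dict(z)))
    if not out and t0 == t1:
        out = [(t0, t1, dict(segs[-1][1]))]
    covered = sum(b - a for a, b, _ in out)
    if abs(covered - (t1 - t0)) > 1e-9:
        raise MarkovModelError("gap in covariate path over the requested interval")
    return out


def transition_probability(
    model: ProportionalIntensityModel, covariate_path, t0: float, t1: float
) -> np.ndarray:
    """P(t0, t1): product of interval exponentials over the piecewise-constant
    covariate path; a stochastic matrix (identity when t1 == t0)."""
    if t1 < t0:
        raise MarkovModelError("t1 must be >= t0")
    S = model.structure.n_states
    P = np.eye(S)
    if t1 == t0:
        return P
    names = model.covariate_names
    for a, b, z in _normalize_path(covariate_path, t0, t1):
        Q = model.intensity_matrix({**{c: 0.0 for c in names}, **z})
        P = P @ expm_batch(Q * (b - a))
    return P


# ---------------------------------------------------------------------------
# panel design and likelihood


@dataclass
class _PanelDesign:
    Z: np.ndarray  # (n_intervals, n_cov) covariates at left endpoint
    dt: np.ndarray  # interval lengths, years
    from_idx: np.ndarray
    to_idx: np.ndarray
    is_death: np.ndarray  # exact-death observation at interval end
    cov_names: list[str]
    n_patients: int
    count_table: pd.DataFrame


def build_design(model: ProportionalIntensityModel, panel: pd.DataFrame) -> _PanelDesign:
    """Flatten a per-patient panel into interval arrays for the likelihood.

    ``panel`` columns: patient_id, time (years), state (1-based), obs_type
    ('panel' or 'exact_death'), plus one column per covariate the model uses.
    """
    names = model.covariate_names
    missing = [c for c in names if c not in panel.columns]
    if missing:
        raise MarkovModelError(f"panel is missing covariate column(s): {missing}")
    S = model.structure.n_states
    df = panel.sort_values(["patient_id", "time"], kind="stable")
    pid = df["patient_id"].to_numpy()
    t = df["time"].to_numpy(dtype=float)
    state = df["state"].to_numpy(dtype=int) - 1
    death = (df["obs_type"].to_numpy() == "exact_death")
    Zall = df[names].to_numpy(dtype=float) if names else np.zeros((len(df), 0))

    same = pid[1:] == pid[:-1]
    i0 = np.flatnonzero(same)
    dt = t[i0 + 1] - t[i0]
    if np.any(dt < 0):
        raise MarkovModelError("observation times not increasing within a patient")
    keep = dt > 0
    i0 = i0[keep]
    dt = dt[keep]
    design = _PanelDesign(
        Z=Zall[i0],
        dt=dt,
        from_idx=state[i0],
        to_idx=state[i0 + 1],
        is_death=death[i0 + 1],
        cov_names=names,
        n_patients=len(np.unique(pid)),
        count_table=pd.crosstab(
            pd.Series(state[i0], name="from"), pd.Series(state[i0 + 1], name="to")
        ),
    )
    if np.any(~np.isfinite(design.Z)):
        raise MarkovModelError("non-finite covariate values in panel")
    return design


def _interval_probs(model: ProportionalIntensityModel, d: _PanelDesign) -> np.ndarray:
    Q = model._q_batch(d.Z, d.cov_names)
    P = expm_batch(Q * d.dt[:, None, None])
    n = d.dt.size
    rows = np.arange(n)
    p = P[rows, d.from_idx, d.to_idx]
    if d.is_death.any():
        k = np.flatnonzero(d.is_death)
        # density: sum_s P[from, s] * q_{s, death}; absorbing rows of Q are zero
        p[k] = np.einsum("is,is->i", P[k, d.from_idx[k], :], Q[k, :, d.to_idx[k]])
    return p


def panel_loglik(model: ProportionalIntensityModel, panel: pd.DataFrame) -> float:
    """Log-likelihood of the panel; -inf (with a diagnostic warning) if any
    observed transition has zero probability under the model."""
    d = build_design(model, panel)
    p = _interval_probs(model, d)
    if np.any(p <= 0):
        bad = np.flatnonzero(p <= 0)[:5]
        warnings.warn(
            "zero-probability observed transition(s): "
            + ", ".join(
                f"{model.structure.states[d.from_idx[i]]}->"
                f"{model.structure.states[d.to_idx[i]]} over {d.dt[i]:.3g}y"
                for i in bad
            )
        )
        return -np.inf
    return float(np.log(p).sum())


# ---------------------------------------------------------------------------
# fitting


@dataclass
class FitResult:
    model: ProportionalIntensityModel
    estimates: np.ndarray
    vcov: np.ndarray
    loglik: float
    converged: bool
    n_transitions_observed: pd.DataFrame
    param_names: list[str]
    n_patients: int = 0
    n_intervals: int = 0

    def se(self) -> np.ndarray:
        return np.sqrt(np.clip(np.diag(self.vcov), 0, None))


def crude_init(
    model: ProportionalIntensityModel, panel: pd.DataFrame, floor: float = 1e-3
) -> ProportionalIntensityModel:
    """Initialize baseline log-intensities from crude rates (observed r->s
    jumps / person-years spent in r) with betas at zero."""
    d = build_design(model, panel)
    S = model.structure.n_states
    jumps = np.zeros((S, S))
    np.add.at(jumps, (d.from_idx, d.to_idx), 1.0)
    py = np.zeros(S)
    np.add.at(py, d.from_idx, d.dt)
    log_q0 = np.empty(len(model.structure.allowed))
    for k, (i, j) in enumerate(model.structure.allowed_indices()):
        rate = jumps[i, j] / py[i] if py[i] > 0 else floor
        log_q0[k] = np.log(max(rate, floor))
    return ProportionalIntensityModel(
        model.structure,
        log_q0,
        {tr: np.zeros(len(model.covariate_spec[tr])) for tr in model.structure.allowed},
        dict(model.covariate_spec),
    )


def _hessian(f, theta: np.ndarray, rel_step: float = 1e-4) -> np.ndarray:
    """Central-difference Hessian, step 1e-4 * max(1, |theta_i|) per axis."""
    p = theta.size
    h = rel_step * np.maximum(1.0, np.abs(theta))
    H = np.empty((p, p))
    for i in range(p):
        for j in range(i, p):
            ei = np.zeros(p)
            ej = np.zeros(p)
            ei[i] = h[i]
            ej[j] = h[j]
            if i == j:
                H[i, i] = (f(theta + ei) - 2 * f(theta) + f(theta - ei)) / h[i] ** 2
            else:
                H[i, j] = H[j, i] = (
                    f(theta + ei + ej) - f(theta + ei - ej) - f(theta - ei + ej) + f(theta - ei - ej)
                ) / (4 * h[i] * h[j])
    return 0.5 * (H + H.T)


def fit(
    model_init: ProportionalIntensityModel,
    panel: pd.DataFrame,
    maxiter: int = 500,
    gtol: float = 1e-6,
    compute_vcov: bool = True,
    center: bool = False,
    bounds_logq: tuple[float, float] = (-20.0, 5.0),
    bounds_beta: tuple[float, float] = (-10.0, 10.0),
) -> FitResult:
    """Maximize the panel likelihood by bounded quasi-Newton (L-BFGS-B).

    The covariance matrix is the inverse of the numerically differenced
    observed information at the optimum (central differences, symmetrized).
    ``center=True`` centers the covariate columns during optimization for
    conditioning and maps the estimates (and covariance) back to the
    uncentered scale, leaving reported hazard ratios unchanged.
    """
    d = build_design(model_init, panel)
    mu = d.Z.mean(axis=0) if (center and d.Z.size) else np.zeros(d.Z.shape[1])
    if center:
        d = _PanelDesign(d.Z - mu, d.dt, d.from_idx, d.to_idx, d.is_death,
                         d.cov_names, d.n_patients, d.count_table)
        # linear map from centered to uncentered parameters:
        # log_q0 = log_q0_c - beta . mu ; beta unchanged
        A = np.eye(model_init.n_params)
        col = {c: i for i, c in enumerate(d.cov_names)}
        pos = model_init.log_q0.size
        for k, tr in enumerate(model_init.structure.allowed):
            for c in model_init.covariate_spec[tr]:
                A[k, pos] = -mu[col[c]]
                pos += 1
        # initial parameters supplied on the uncentered scale
        theta_init_c = np.linalg.solve(A, model_init.pack())
        model_init = model_init.unpack(theta_init_c)
    # identifiability warning: every allowed transition should be observed
    observed = set(zip(d.from_idx, d.to_idx))
    for tr, (i, j) in zip(model_init.structure.allowed, model_init.structure.allowed_indices()):
        if (i, j) not in observed:
            warnings.warn(f"allowed transition {tr[0]}->{tr[1]} never observed in the panel")

    tiny = 1e-300

    def nll(theta: np.ndarray) -> float:
        m = model_init.unpack(theta)
        p = _interval_probs(m, d)
        return -float(np.log(np.maximum(p, tiny)).sum())

    theta0 = model_init.pack()
    if np.any(_interval_probs(model_init, d) <= 0) or not np.isfinite(nll(theta0)):
        raise MarkovModelError(
            "non-finite likelihood at the initial parameters; try crude_init()"
        )
    nq = model_init.log_q0.size
    bounds = [bounds_logq] * nq + [bounds_beta] * (theta0.size - nq)
    res = minimize(
        nll,
        theta0,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": maxiter, "gtol": gtol, "ftol": 1e-12},
    )
    theta = res.x
    if compute_vcov:
        H = _hessian(nll, theta)
        vcov = np.linalg.pinv(H)
        vcov = 0.5 * (vcov + vcov.T)
        # flat or barely-identified directions (e.g. an unobserved transition at
        # its bound) can leave the numeric information indefinite; project onto
        # the PSD cone so Wald machinery stays usable, and say so
        eigval, eigvec = np.linalg.eigh(vcov)
        if eigval.min() < 0:
            warnings.warn(
                "observed information not positive definite; covariance projected "
                "to the nearest positive semi-definite matrix"
            )
            vcov = (eigvec * np.clip(eigval, 0, None)) @ eigvec.T
            vcov = 0.5 * (vcov + vcov.T)
    else:
        vcov = np.full((theta.size, theta.size), np.nan)
    if center:
        theta = A @ theta
        vcov = A @ vcov @ A.T
    fitted = model_init.unpack(theta)
    ct = d.count_table.copy()
    ct.index = [model_init.structure.states[i] for i in ct.index]
    ct.columns = [model_init.structure.states[j] for j in ct.columns]
    return FitResult(
        model=fitted,
        estimates=theta,
        vcov=vcov,
        loglik=-res.fun,
        converged=bool(res.success),
        n_transitions_observed=ct,
        param_names=fitted.param_names,
        n_patients=d.n_patients,
        n_intervals=int(d.dt.size),
    )


def hazard_ratios(result: FitResult) -> pd.DataFrame:
    """Tidy per-transition hazard-ratio table: exp(beta) with 95% Wald CIs.

    Covariates a transition does not carry are absent from its rows (rendered
    as "not included" by the table formatter).
    """
    model = result.model
    se = result.se()
    rows = []
    k = model.log_q0.size
    for tr in model.structure.allowed:
        for c, b in zip(model.covariate_spec[tr], model.beta[tr]):
            s = se[k]
            rows.append(
                {
                    "transition": f"{tr[0]}->{tr[1]}",
                    "covariate": c,
                    "hr": float(np.exp(b)),
                    "lower": float(np.exp(b - Z95 * s)),
                    "upper": float(np.exp(b + Z95 * s)),
                    "log_hr": float(b),
                    "se_log_hr": float(s),
                }
            )
            k += 1
    return pd.DataFrame(rows)


def predicted_probabilities_ci(
    result: FitResult,
    z_profile,
    horizons: Sequence[float] = (5.0, 10.0, 15.0),
    n_draws: int = 100,
    seed: int | None = None,
    ridge: float = 0.0,
) -> dict[float, dict[str, np.ndarray]]:
    """Predicted transition-probability matrices at each horizon with
    percentile CIs from draws of the asymptotic sampling distribution.

    The point estimate maps the fitted parameters through
    :func:`transition_probability`; each of ``n_draws`` multivariate-normal
    draws (mean = estimates, covariance = vcov, on the log-intensity /
    coefficient scale) is mapped through the same function and the 2.5/97.5
    percentiles taken entrywise.
    """
    vcov = np.asarray(result.vcov, dtype=float)
    if ridge > 0:
        vcov = vcov + ridge * np.eye(vcov.shape[0])
    eig = np.linalg.eigvalsh(0.5 * (vcov + vcov.T))
    if eig.min() < -1e-8 * max(1.0, eig.max()):
        raise MarkovModelError(
            "vcov is not positive semi-definite; pass ridge > 0 to repair "
            "(off by default)"
        )
    rng = np.random.default_rng(seed)
    draws = rng.multivariate_normal(result.estimates, vcov, size=n_draws, method="svd")
    out: dict[float, dict[str, np.ndarray]] = {}
    for h in horizons:
        point = transition_probability(result.model, z_profile, 0.0, float(h))
        samples = np.stack(
            [
                transition_probability(result.model.unpack(th), z_profile, 0.0, float(h))
                for th in draws
            ]
        )
        out[float(h)] = {
            "point": point,
            "lower": np.percentile(samples, 2.5, axis=0),
            "upper": np.percentile(samples, 97.5, axis=0),
        }
    return out


def expected_prevalence(
    result: FitResult, panel: pd.DataFrame, grid: Sequence[float]
) -> pd.DataFrame:
    """Observed vs model-expected state-occupancy proportions over a time grid.

    Observed: each patient's state carried forward from the last observation
    at or before t, counted while the patient is under observation (death
    persists beyond the last record).  Expected: the average of model
    transition-probability rows from each patient's first observation, using
    that patient's piecewise-constant covariate path, over the same risk set.
    Both are normalized among contributing patients, so rows sum to one.
    """
    grid = np.asarray(sorted(grid), dtype=float)
    if grid.size == 0:
        raise MarkovModelError("empty prevalence grid")
    model = result.model
    S = model.structure.n_states
    names = model.covariate_names
    absorbing = {model.structure.index(s) for s in model.structure.absorbing}

    obs_counts = np.zeros((grid.size, S))
    exp_counts = np.zeros((grid.size, S))
    for _, g in panel.groupby("patient_id", sort=False):
        g = g.sort_values("time")
        t = g["time"].to_numpy(dtype=float)
        st = g["state"].to_numpy(dtype=int) - 1
        Z = g[names].to_numpy(dtype=float) if names else np.zeros((len(g), 0))
        path = [(t[i], dict(zip(names, Z[i]))) for i in range(len(g))]
        for gi, tau in enumerate(grid):
            if tau < t[0]:
                continue
            i = np.searchsorted(t, tau, side="right") - 1
            in_followup = tau <= t[-1] or st[i] in absorbing
            if not in_followup:
                continue
            obs_counts[gi, st[i]] += 1
            P = transition_probability(model, path, t[0], tau)
            exp_counts[gi] += P[st[0]]
    rows = []
    for gi, tau in enumerate(grid):
        n_obs = obs_counts[gi].sum()
        n_exp = exp_counts[gi].sum()
        for s in range(S):
            rows.append(
                {
                    "time": tau,
                    "state": model.structure.states[s],
                    "observed": obs_counts[gi, s] / n_obs if n_obs else np.nan,
                    "expected": exp_counts[gi, s] / n_exp if n_exp else np.nan,
                    "n": int(n_obs),
                }
            )
    return pd.DataFrame(rows)
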
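"""Synthetic registry cohorts and exact CTMC panel simulation.

Two deliberately different generators:

* :func:`simulate_cohort` — a mechanistic registry simulator emulating how a
  national MS registry accrues records: relapse point processes whose rate
  declines with age and differs by sex, phase and treatment; a latent SPMS
  onset hazard increasing with age and EDSS, with a diagnostic delay before
  the recorded SPMS diagnosis; monotone jump-process EDSS trajectories at
  jittered visit days; alternating treatment episodes of two efficacy
  classes; and competing death/emigration/administrative censoring.  Its
  trajectories intentionally violate the Markov assumption, as real
  registries do.
* :func:`simulate_panel_ctmc` — exact continuous-time Markov chain
  trajectories under a given proportional-intensity model, recorded only at
  scheduled observation days (panel censoring) with death recorded exactly.
  Because the data-generating process equals the inferential model, this mode
  gives sharp parameter-recovery tests.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .markov import ProportionalIntensityModel
from .registry import (
    DAYS_PER_YEAR,
    Cohort,
    EDSSObservation,
    PatientRecord,
    RelapseEvent,
    TreatmentEpisode,
)

_HIGH_POOL = ("natalizumab", "fingolimod", "ocrelizumab", "rituximab")
_MODERATE_POOL = ("interferon beta-1a", "glatiramer acetate", "teriflunomide", "dimethyl fumarate")


@dataclass
class CohortParams:
    """Parameters of the mechanistic registry simulator (rates per year).

    Defaults are the registry-like preset: ~70% female, age at onset 34.1 +/- 9.2
    years, a relapse rate declining with age and boosted in the two years
    before RRMS diagnosis (diagnosis is triggered by activity), an SPMS onset
    hazard increasing with age and EDSS followed by an exponential diagnostic
    delay (mean 2 years), and an administrative horizon of ~22.7 years of
    calendar time.
    """

    n_patients: int = 500
    seed: int = 0
    sex_p_female: float = 0.70
    age_at_onset: tuple[float, float] = (34.1, 9.2)  # mean, sd (years), truncated at 18
    relapse_base_rate: float = 0.45  # events/year at the reference age
    relapse_age_loghr: float = -0.02  # per year of age
    relapse_sex_loghr: float = 0.15  # female vs male
    relapse_treatment_loghr: Mapping[str, float] = field(
        default_factory=lambda: {"high": -1.2, "moderate": -0.5}
    )
    relapse_ref_age: float = 34.0
    prediag_boost: float = 4.0  # multiplier in the 2 years before RRMS diagnosis
    post_spms_relapse_factor: float = 0.25  # residual relapse rate after latent SPMS onset
    spms_base_hazard: float = 0.02  # /year at reference age/EDSS
    spms_age_loghr: float = 0.04
    spms_edss_loghr: float = 0.25
    spms_ref_age: float = 40.0
    spms_ref_edss: float = 2.0
    diag_delay_mean_years: float = 2.0
    edss_visit_interval: tuple[float, float] = (365.0, 90.0)  # mean, jitter (days)
    edss_drift: float = 0.15  # expected EDSS points/year before latent SPMS onset
    edss_spms_drift: float = 0.45  # after latent SPMS onset
    relapse_edss_p: float = 0.3  # probability a relapse leaves a +0.5 step
    death_base_hazard: float = 0.02  # /year at the reference age
    death_age_loghr: float = 0.09
    death_ref_age: float = 65.0
    emigration_rate: float = 0.003
    admin_horizon: int = 8280  # epoch day of administrative censoring (~2022-09)
    onset_window_days: int = 4018  # onsets uniform over [0, onset_window_days]

    def validate(self) -> None:
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")
        if not (0 <= self.sex_p_female <= 1):
            raise ValueError("sex_p_female must be a probability")
        for name in (
            "relapse_base_rate",
            "spms_base_hazard",
            "death_base_hazard",
            "emigration_rate",
            "prediag_boost",
            "post_spms_relapse_factor",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.admin_horizon <= 0:
            raise ValueError("admin_horizon must be positive")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["relapse_treatment_loghr"] = dict(self.relapse_treatment_loghr)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "CohortParams":
        kwargs = dict(d)
        for key in ("age_at_onset", "edss_visit_interval"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)


def _exp_or_inf(rng: np.random.Generator, rate: float) -> float:
    return rng.exponential(1.0 / rate) if rate > 0 else np.inf


def simulate_cohort(params: CohortParams) -> Cohort:
    """Generate a registry cohort; byte-identical tables for identical seeds.

    Patients are simulated chronologically over inter-visit segments, with
    hazards held constant within a segment at their segment-start values and
    the relapse process thinned against a per-patient dominating rate so that
    arbitrary log-linear modifiers stay exact.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    patients: list[PatientRecord] = []
    relapses: list[RelapseEvent] = []
    edss_rows: list[EDSSObservation] = []
    treatments: list[TreatmentEpisode] = []
    latent_onsets: dict[str, float | None] = {}

    tx_loghr = dict(params.relapse_treatment_loghr)
    for i in range(params.n_patients):
        pid = f"P{i:05d}"
        sex = "female" if rng.random() < params.sex_p_female else "male"
        female = 1.0 if sex == "female" else 0.0
        mu, sd = params.age_at_onset
        age0 = mu + sd * rng.standard_normal()
        while age0 < 18.0:
            age0 = mu + sd * rng.standard_normal()
        onset = int(rng.integers(0, params.onset_window_days + 1))
        delay_y = float(rng.lognormal(0.0, 1.5))
        dx = onset + max(30, int(round(delay_y * DAYS_PER_YEAR)))
        dx = min(dx, params.admin_horizon - 365)
        horizon = params.admin_horizon

        def age_at(day: float) -> float:
            return age0 + (day - onset) / DAYS_PER_YEAR

        # treatment episodes from diagnosis to the horizon (clipped later)
        eps: list[tuple[str, int, int]] = []
        t = dx + rng.exponential(0.5) * DAYS_PER_YEAR
        while t < horizon:
            drug = (
                str(rng.choice(_HIGH_POOL))
                if rng.random() < 0.3
                else str(rng.choice(_MODERATE_POOL))
            )
            dur = max(30.0, rng.exponential(3.0) * DAYS_PER_YEAR)
            start, stop = int(t), int(min(t + dur, horizon))
            if stop > start:
                eps.append((drug, start, stop))
            t = stop + rng.exponential(1.5) * DAYS_PER_YEAR
        ep_objs = [TreatmentEpisode(pid, d, a, b) for d, a, b in eps]

        def tx_modifier(day: float) -> float:
            m = 0.0
            for ep in ep_objs:
                if ep.start_day <= day < ep.stop_day and ep.efficacy_class in tx_loghr:
                    m += tx_loghr[ep.efficacy_class]
            return m

        def relapse_rate(day: float, latent_spms: float | None) -> float:
            r = params.relapse_base_rate * np.exp(
                params.relapse_age_loghr * (age_at(day) - params.relapse_ref_age)
                + params.relapse_sex_loghr * female
                + tx_modifier(day)
            )
            if dx - 730 <= day < dx:
                r *= params.prediag_boost
            if latent_spms is not None and day >= latent_spms:
                r *= params.post_spms_relapse_factor
            return r

        # dominating rate for thinning (age effect maximized at whichever end)
        age_span = (age0, age_at(horizon))
        dom = params.relapse_base_rate * np.exp(
            max(params.relapse_age_loghr * (a - params.relapse_ref_age) for a in age_span)
            + max(0.0, params.relapse_sex_loghr) * female
            + sum(max(0.0, v) for v in tx_loghr.values())
        )
        dom *= max(1.0, params.prediag_boost) * max(1.0, params.post_spms_relapse_factor)

        # pre-diagnosis relapses (thinning over [onset, dx))
        my_relapses: list[int] = []
        if dom > 0:
            t = float(onset)
            while True:
                t += rng.exponential(1.0 / dom) * DAYS_PER_YEAR
                if t >= dx:
                    break
                if rng.random() < relapse_rate(t, None) / dom:
                    my_relapses.append(int(t))

        # visit days
        vmean, vjit = params.edss_visit_interval
        visits = [dx]
        t = float(dx)
        while True:
            t += max(30.0, vmean + vjit * rng.standard_normal())
            if t > horizon:
                break
            visits.append(int(t))

        # chronological walk over inter-visit segments
        edss = max(0.0, round((1.5 + rng.standard_normal()) * 2) / 2)
        edss_vals = [edss]
        latent_spms: float | None = None
        death_day: float | None = None
        emig_day: float | None = None
        for k in range(len(visits) - 1):
            a, b = float(visits[k]), float(visits[k + 1])
            dt_y = (b - a) / DAYS_PER_YEAR
            # competing terminal events, hazards frozen at segment start
            td = _exp_or_inf(
                rng,
                params.death_base_hazard
                * np.exp(params.death_age_loghr * (age_at(a) - params.death_ref_age)),
            )
            te = _exp_or_inf(rng, params.emigration_rate)
            if latent_spms is None:
                ts = _exp_or_inf(
                    rng,
                    params.spms_base_hazard
                    * np.exp(
                        params.spms_age_loghr * (age_at(a) - params.spms_ref_age)
                        + params.spms_edss_loghr * (edss - params.spms_ref_edss)
                    ),
                )
                if ts < dt_y:
                    latent_spms = a + ts * DAYS_PER_YEAR
            seg_end = b
            if td < dt_y or te < dt_y:
                if td <= te:
                    death_day = a + td * DAYS_PER_YEAR
                    seg_end = death_day
                else:
                    emig_day = a + te * DAYS_PER_YEAR
                    seg_end = emig_day
            # relapses in [a, seg_end)
            n_seg_relapses = 0
            if dom > 0:
                t = a
                while True:
                    t += rng.exponential(1.0 / dom) * DAYS_PER_YEAR
                    if t >= seg_end:
                        break
                    if rng.random() < relapse_rate(t, latent_spms) / dom:
                        my_relapses.append(int(t))
                        n_seg_relapses += 1
            if death_day is not None or emig_day is not None:
                break
            drift = params.edss_spms_drift if latent_spms is not None else params.edss_drift
            steps = rng.poisson(max(0.0, drift) * dt_y / 0.5)
            steps += rng.binomial(n_seg_relapses, params.relapse_edss_p)
            edss = min(10.0, edss + 0.5 * steps)
            edss_vals.append(edss)

        if death_day is not None:
            end_day, end_reason = int(death_day), "death"
        elif emig_day is not None:
            end_day, end_reason = int(emig_day), "emigration"
        else:
            end_day, end_reason = horizon, "admin_censor"
        end_day = max(end_day, dx + 1)

        spms_dx: int | None = None
        if latent_spms is not None:
            cand = latent_spms + rng.exponential(params.diag_delay_mean_years) * DAYS_PER_YEAR
            if cand <= end_day:
                spms_dx = max(int(cand), dx)

        patients.append(
            PatientRecord(pid, sex, onset, dx, spms_dx, end_day, end_reason, round(age0, 2))
        )
        latent_onsets[pid] = None if latent_spms is None else float(latent_spms)
        for day in sorted(set(my_relapses)):
            if day <= end_day:
                relapses.append(RelapseEvent(pid, day))
        for day, val in zip(visits, edss_vals):
            if day <= end_day:
                edss_rows.append(EDSSObservation(pid, day, val))
        for ep in ep_objs:
            if ep.start_day < end_day:
                treatments.append(
                    TreatmentEpisode(pid, ep.drug_name, ep.start_day, min(ep.stop_day, end_day))
                )

    cohort = Cohort(patients, relapses, edss_rows, treatments)
    cohort.report["latent_spms_onset_day"] = latent_onsets
    cohort.report["params"] = params.to_dict()
    return cohort


# ---------------------------------------------------------------------------
# exact CTMC panel simulation


def simulate_panel_ctmc(
    model: ProportionalIntensityModel,
    covariate_process: Callable[[np.random.Generator, int], Mapping[str, float] | list],
    n: int,
    schedule: Sequence[float] | Callable[[np.random.Generator, int], Sequence[float]],
    seed: int | None = None,
    initial_state: int = 1,
) -> pd.DataFrame:
    """Exact CTMC trajectories recorded at panel observation times.

    ``covariate_process(rng, i)`` returns patient i's covariates: either a
    constant mapping or a list of ``(start_time, mapping)`` segments.  The
    chain is simulated segment-by-segment with competing exponential clocks
    under the segment's intensity matrix; the state is recorded only at the
    schedule times, except entry into an absorbing state, which is recorded
    exactly (``obs_type='exact_death'``).  States are 1-based as in the panel
    format.
    """
    structure = model.structure
    S = structure.n_states
    absorbing = {structure.index(s) for s in structure.absorbing}
    if (initial_state - 1) in absorbing:
        raise ValueError("initial state must be transient")
    rng = np.random.default_rng(seed)
    names = model.covariate_names
    rows = []
    for i in range(n):
        times = np.asarray(schedule(rng, i) if callable(schedule) else schedule, dtype=float)
        times = np.sort(times)
        horizon = float(times[-1])
        cov = covariate_process(rng, i)
        segs = (
            [(0.0, horizon, dict(cov))]
            if isinstance(cov, Mapping)
            else [
                (float(s), float(cov[k + 1][0]) if k + 1 < len(cov) else horizon, dict(z))
                for k, (s, z) in enumerate(cov)
            ]
        )
        state = initial_state - 1
        t = 0.0
        absorb_time: float | None = None
        jumps: list[tuple[float, int]] = [(0.0, state)]
        for a, b, z in segs:
            if absorb_time is not None or a >= horizon:
                break
            zfull = {**{c: 0.0 for c in names}, **z}
            Q = model.intensity_matrix(zfull)
            t = max(t, a)
            while t < min(b, horizon):
                rate = -Q[state, state]
                if rate <= 0:
                    t = b
                    break
                w = rng.exponential(1.0 / rate)
                if t + w >= min(b, horizon):
                    t = b
                    break
                t = t + w
                probs = np.clip(Q[state], 0, None)
                probs[state] = 0.0
                state = int(rng.choice(S, p=probs / probs.sum()))
                jumps.append((t, state))
                if state in absorbing:
                    absorb_time = t
                    break

        jump_t = np.array([jt for jt, _ in jumps])
        jump_s = np.array([js for _, js in jumps])

        def state_at(tau: float) -> int:
            return int(jump_s[np.searchsorted(jump_t, tau, side="right") - 1])

        def z_at(tau: float) -> dict:
            for a, b, z in segs:
                if a <= tau < b or (tau >= b and b == horizon):
                    return {**{c: 0.0 for c in names}, **z}
            return {**{c: 0.0 for c in names}, **segs[-1][2]}

        for tau in times:
            if absorb_time is not None and tau >= absorb_time:
                break
            rows.append(
                {
                    "patient_id": f"S{i:05d}",
                    "time": float(tau),
                    "state": state_at(tau) + 1,
                    "obs_type": "panel",
                    **z_at(tau),
                }
            )
        if absorb_time is not None and absorb_time <= horizon:
            rows.append(
                {
                    "patient_id": f"S{i:05d}",
                    "time": float(absorb_time),
                    "state": int(jump_s[-1]) + 1,
                    "obs_type": "exact_death",
                    **z_at(absorb_time),
                }
            )
    return pd.DataFrame(rows)
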
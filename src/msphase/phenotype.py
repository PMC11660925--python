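"""Daily phenotype-state classification and panel construction.

A patient diagnosed with relapsing-remitting MS (RRMS) may later receive a
physician diagnosis of secondary progressive MS (SPMS).  From that day on the
phenotype is split operationally by recent relapse activity: relapsing SPMS
(rSPMS) if at least one relapse occurred in the retrospective 2-year window,
non-relapsing SPMS (nrSPMS) otherwise.  The window is half-open,
``(t - 730, t]``: a relapse on the assessed day itself makes the day rSPMS,
and an isolated relapse at day r keeps the patient rSPMS through day r + 729.
Relapses recorded before the SPMS diagnosis count toward the window, so a
patient can enter the SPMS phase already in the rSPMS state.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .registry import (
    DAYS_PER_YEAR,
    Cohort,
    EDSSObservation,
    PatientRecord,
    TreatmentEpisode,
    cumulative_exposure,
    day_to_year,
)

#: Retrospective relapse window defining rSPMS vs nrSPMS: 2 years, in days.
WINDOW_DAYS = 730

RRMS, NRSPMS, RSPMS, DEATH = "RRMS", "nrSPMS", "rSPMS", "Death"
STATE_CODES = {RRMS: 1, NRSPMS: 2, RSPMS: 3, DEATH: 4}

COVARIATE_NAMES = [
    "sex_female",
    "age",
    "hedmt_years",
    "medmt_years",
    "edss",
    "dx_year",
    "cum_relapses",
    "dx_duration",
]


class FollowUpError(ValueError):
    """Assessment day outside the patient's follow-up period."""


@dataclass
class StateTimeline:
    """Ordered partition of ``[rrms_dx_day, end_day]`` into phenotype intervals.

    ``intervals`` is a list of ``(state, start_day, end_day)`` with inclusive
    endpoints; ``death_day`` is set when follow-up ended in death.
    """

    patient_id: str
    intervals: list[tuple[str, int, int]]
    death_day: int | None = None

    def state_on(self, t: int) -> str:
        for state, a, b in self.intervals:
            if a <= t <= b:
                return state
        raise FollowUpError(f"day {t} outside follow-up of patient {self.patient_id}")


def state_at(patient: PatientRecord, relapse_days: Sequence[int], t: int,
             window_days: int = WINDOW_DAYS) -> str:
    """Phenotype state of ``patient`` on follow-up day ``t``.

    RRMS before any SPMS diagnosis; afterwards rSPMS iff at least one relapse
    falls in the half-open window ``(t - window_days, t]``, else nrSPMS.
    """
    if not (patient.rrms_dx_day <= t <= patient.end_day):
        raise FollowUpError(
            f"day {t} outside follow-up [{patient.rrms_dx_day}, {patient.end_day}] "
            f"of patient {patient.patient_id}"
        )
    if patient.spms_dx_day is None or t < patient.spms_dx_day:
        return RRMS
    days = sorted(relapse_days)
    # any relapse r with t - window_days < r <= t
    i = bisect_right(days, t)
    if i > 0 and days[i - 1] > t - window_days:
        return RSPMS
    return NRSPMS


def classify_timeline(patient: PatientRecord, relapse_days: Sequence[int],
                      window_days: int = WINDOW_DAYS) -> StateTimeline:
    """Partition the whole follow-up into maximal same-state intervals.

    Runs in O(#relapses): the rSPMS days form the union over relapses r of
    ``[max(r, spms_dx), r + window - 1]`` clipped to follow-up; the complement
    of that union within the SPMS phase is nrSPMS.
    """
    dx, end, spms = patient.rrms_dx_day, patient.end_day, patient.spms_dx_day
    intervals: list[tuple[str, int, int]] = []
    if spms is None:
        intervals.append((RRMS, dx, end))
    else:
        if spms > dx:
            intervals.append((RRMS, dx, spms - 1))
        # merge rSPMS cover intervals
        covers: list[list[int]] = []
        for r in sorted(relapse_days):
            a, b = max(r, spms), min(r + window_days - 1, end)
            if b < spms or a > end:
                continue
            if covers and a <= covers[-1][1] + 1:
                covers[-1][1] = max(covers[-1][1], b)
            else:
                covers.append([a, b])
        cursor = spms
        for a, b in covers:
            if a > cursor:
                intervals.append((NRSPMS, cursor, a - 1))
            intervals.append((RSPMS, a, b))
            cursor = b + 1
        if cursor <= end:
            intervals.append((NRSPMS, cursor, end))
    death_day = patient.end_day if patient.end_reason == "death" else None
    return StateTimeline(patient.patient_id, intervals, death_day)


def transition_pattern(timeline: StateTimeline, sep: str = "→") -> str:
    """SPMS-phase interval labels joined in time order, e.g. ``rSPMS→nrSPMS→rSPMS``."""
    labels = [s for s, _, _ in timeline.intervals if s in (NRSPMS, RSPMS)]
    if not labels:
        raise ValueError(f"patient {timeline.patient_id}: no SPMS phase")
    return sep.join(labels)


def pattern_frequencies(timelines: Sequence[StateTimeline]) -> pd.Series:
    """Counts of SPMS transition patterns over a cohort (SPMS patients only)."""
    pats = []
    for tl in timelines:
        try:
            pats.append(transition_pattern(tl))
        except ValueError:
            continue
    return pd.Series(pats, dtype=object).value_counts()


@dataclass
class PanelObservation:
    patient_id: str
    obs_day: int
    state: int  # 1=RRMS, 2=nrSPMS, 3=rSPMS, 4=Death
    obs_type: str  # "panel" | "exact_death"
    covariates: dict[str, float] = field(default_factory=dict)


def default_schedule(patient: PatientRecord, edss: Sequence[EDSSObservation]) -> list[int]:
    """Default panel schedule: EDSS visit days plus the SPMS diagnosis day.

    Visits are when the registry actually observes the patient, which is the
    natural panel-data observation set; the SPMS diagnosis day is added so the
    first day of the SPMS phase is always observed.
    """
    days = {e.obs_day for e in edss if patient.rrms_dx_day <= e.obs_day <= patient.end_day}
    days.add(patient.rrms_dx_day)
    if patient.spms_dx_day is not None:
        days.add(patient.spms_dx_day)
    return sorted(days)


def _edss_at(edss: Sequence[EDSSObservation], t: int) -> float | None:
    """EDSS carried forward from the last visit at or before t; if none, the
    first subsequent visit within 365 days; else None."""
    days = [e.obs_day for e in edss]
    i = bisect_right(days, t)
    if i > 0:
        return edss[i - 1].edss
    j = bisect_left(days, t)
    if j < len(edss) and edss[j].obs_day - t <= 365:
        return edss[j].edss
    return None


def build_panel(
    patient: PatientRecord,
    relapse_days: Sequence[int],
    edss: Sequence[EDSSObservation],
    episodes: Sequence[TreatmentEpisode],
    schedule: Sequence[int] | None = None,
    window_days: int = WINDOW_DAYS,
) -> tuple[list[PanelObservation], bool]:
    """One panel observation per schedule day, plus an exact death record.

    Returns ``(observations, edss_missing_flag)``; the flag marks patients
    with a schedule day for which no EDSS could be imputed (last value carried
    forward, with a 365-day look-ahead fallback before the first visit) —
    such patients are excluded from the Markov fit by the pipeline.

    Covariates evaluated at each day t: sex indicator, age in years (anchored
    at age at onset), cumulative high-/moderate-efficacy DMT years, EDSS,
    calendar year of RRMS diagnosis, cumulative relapses since RRMS diagnosis
    (pre-diagnosis relapses count toward the rSPMS window but not here), and
    disease duration at RRMS diagnosis in years.
    """
    if schedule is None:
        schedule = default_schedule(patient, edss)
    schedule = sorted({int(d) for d in schedule})
    if not schedule:
        raise ValueError(f"patient {patient.patient_id}: empty panel schedule")
    if schedule[0] < patient.rrms_dx_day or schedule[-1] > patient.end_day:
        raise FollowUpError(
            f"patient {patient.patient_id}: schedule days outside follow-up"
        )
    timeline = classify_timeline(patient, relapse_days, window_days)
    edss = sorted(edss, key=lambda e: e.obs_day)
    post_dx = sorted(d for d in relapse_days if d > patient.rrms_dx_day)

    dx_year = day_to_year(patient.rrms_dx_day)
    dx_duration = (patient.rrms_dx_day - patient.onset_day) / DAYS_PER_YEAR
    sex_female = 1.0 if patient.sex == "female" else 0.0
    flagged = False

    obs: list[PanelObservation] = []
    if patient.end_reason == "death":
        schedule = [d for d in schedule if d < patient.end_day]
    for t in schedule:
        score = _edss_at(edss, t)
        if score is None:
            flagged = True
            score = float("nan")
        cov = {
            "sex_female": sex_female,
            "age": patient.age_at_onset + (t - patient.onset_day) / DAYS_PER_YEAR,
            "hedmt_years": cumulative_exposure(episodes, t, "high"),
            "medmt_years": cumulative_exposure(episodes, t, "moderate"),
            "edss": score,
            "dx_year": dx_year,
            "cum_relapses": float(bisect_right(post_dx, t)),
            "dx_duration": dx_duration,
        }
        obs.append(
            PanelObservation(patient.patient_id, t, STATE_CODES[timeline.state_on(t)], "panel", cov)
        )
    if patient.end_reason == "death":
        t = patient.end_day
        last_cov = obs[-1].covariates if obs else None
        if last_cov is None:
            raise ValueError(
                f"patient {patient.patient_id}: death with no prior panel observation"
            )
        cov = dict(last_cov)
        cov["age"] = patient.age_at_onset + (t - patient.onset_day) / DAYS_PER_YEAR
        obs.append(PanelObservation(patient.patient_id, t, STATE_CODES[DEATH], "exact_death", cov))
    return obs, flagged


def cohort_panel(cohort: Cohort, window_days: int = WINDOW_DAYS) -> pd.DataFrame:
    """Build the full panel DataFrame for a cohort (one row per observation).

    Columns: patient_id, obs_day, time (years since RRMS diagnosis), state,
    obs_type, the eight covariates, and ``edss_flagged`` marking patients with
    unimputable EDSS.  Patients with fewer than two observations contribute
    nothing to a Markov fit but are kept for bookkeeping.
    """
    rows = []
    for p in cohort.patients:
        observations, flagged = build_panel(
            p,
            cohort.relapses_of(p.patient_id),
            cohort.edss_of(p.patient_id),
            cohort.treatments_of(p.patient_id),
            window_days=window_days,
        )
        for o in observations:
            row = {
                "patient_id": o.patient_id,
                "obs_day": o.obs_day,
                "time": (o.obs_day - p.rrms_dx_day) / DAYS_PER_YEAR,
                "state": o.state,
                "obs_type": o.obs_type,
                "edss_flagged": flagged,
            }
            row.update(o.covariates)
            rows.append(row)
    df = pd.DataFrame(rows)
    return df.sort_values(["patient_id", "obs_day"], kind="stable").reset_index(drop=True)


def timelines_frame(timelines: Sequence[StateTimeline]) -> pd.DataFrame:
    """Tidy (patient_id, state, start_day, end_day) table of all intervals."""
    rows = [
        {"patient_id": tl.patient_id, "state": s, "start_day": a, "end_day": b}
        for tl in timelines
        for s, a, b in tl.intervals
    ]
    return pd.DataFrame(rows)
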
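"""Registry domain types, delimited-file I/O, validation and DMT classification.

The registry layout mirrors how national MS registries record patients: one row
per patient (demographic anchors and follow-up span), one row per relapse, one
row per EDSS score, one row per treatment episode.  All dates are integer day
offsets from a fixed epoch (2000-01-01); durations are in days and converted to
years by dividing by 365.25.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

EPOCH = _dt.date(2000, 1, 1)
DAYS_PER_YEAR = 365.25

END_REASONS = ("death", "emigration", "discontinuation", "admin_censor")
SEXES = ("female", "male")

#: Drugs counted toward the cumulative high-efficacy DMT exposure covariate.
HIGH_EFFICACY_DMTS = frozenset(
    {
        "alemtuzumab",
        "cladribine",
        "daclizumab",
        "fingolimod",
        "natalizumab",
        "ocrelizumab",
        "ofatumumab",
        "ozanimod",
        "rituximab",
        "siponimod",
    }
)

#: Moderate-efficacy DMTs (interferon family matched by substring, see classify_dmt).
MODERATE_EFFICACY_DMTS = frozenset(
    {
        "dimethyl fumarate",
        "diroximel fumarate",
        "glatiramer acetate",
        "teriflunomide",
    }
)

_INTERFERON_SUBSTRINGS = ("interferon", "peginterferon")


class RegistryError(ValueError):
    """Raised when a registry table violates the schema or a record invariant."""


def to_day(date: str | _dt.date) -> int:
    """Convert an ISO ``yyyy-mm-dd`` date (or a date object) to an epoch day offset."""
    if isinstance(date, str):
        date = _dt.date.fromisoformat(date)
    return (date - EPOCH).days


def day_to_year(day: float) -> float:
    """Calendar year (continuous) corresponding to an epoch day offset."""
    return EPOCH.year + day / DAYS_PER_YEAR


def classify_dmt(drug_name: str) -> str:
    """Classify a drug name as ``high``, ``moderate`` or ``unclassified`` efficacy.

    Matching is case- and whitespace-insensitive; interferon variants
    (beta-1a, beta-1b, pegylated) all count as moderate.  Unknown entries are
    ``unclassified`` and contribute to neither cumulative-exposure covariate.
    """
    name = " ".join(str(drug_name).lower().split())
    if name in HIGH_EFFICACY_DMTS:
        return "high"
    if name in MODERATE_EFFICACY_DMTS:
        return "moderate"
    if any(s in name for s in _INTERFERON_SUBSTRINGS):
        return "moderate"
    return "unclassified"


@dataclass(frozen=True)
class PatientRecord:
    patient_id: str
    sex: str
    onset_day: int
    rrms_dx_day: int
    spms_dx_day: int | None
    end_day: int
    end_reason: str
    age_at_onset: float = 34.1  # years; birth anchor = onset_day - age_at_onset

    def validate(self) -> None:
        pid = self.patient_id
        if self.sex not in SEXES:
            raise RegistryError(f"patient {pid}: sex {self.sex!r} not in {SEXES}")
        if self.end_reason not in END_REASONS:
            raise RegistryError(
                f"patient {pid}: end_reason {self.end_reason!r} not in {END_REASONS}"
            )
        if not (self.onset_day <= self.rrms_dx_day <= self.end_day):
            raise RegistryError(
                f"patient {pid}: require onset_day <= rrms_dx_day <= end_day, "
                f"got {self.onset_day}, {self.rrms_dx_day}, {self.end_day}"
            )
        if self.spms_dx_day is not None and not (
            self.rrms_dx_day <= self.spms_dx_day <= self.end_day
        ):
            raise RegistryError(
                f"patient {pid}: spms_dx_day {self.spms_dx_day} outside "
                f"[{self.rrms_dx_day}, {self.end_day}]"
            )
        if not self.age_at_onset > 0:
            raise RegistryError(f"patient {pid}: age_at_onset must be positive")


@dataclass(frozen=True)
class RelapseEvent:
    patient_id: str
    relapse_day: int


@dataclass(frozen=True)
class EDSSObservation:
    patient_id: str
    obs_day: int
    edss: float

    def validate(self) -> None:
        if not (0 <= self.edss <= 10) or round(self.edss * 2) != self.edss * 2:
            raise RegistryError(
                f"patient {self.patient_id}: EDSS {self.edss} not on the 0–10 half-point grid"
            )


@dataclass(frozen=True)
class TreatmentEpisode:
    patient_id: str
    drug_name: str
    start_day: int
    stop_day: int | None  # open episode; clipped at end_day on load
    efficacy_class: str = field(default="", compare=False)

    def __post_init__(self):
        if not self.efficacy_class:
            object.__setattr__(self, "efficacy_class", classify_dmt(self.drug_name))

    def validate(self) -> None:
        if self.stop_day is not None and not self.start_day < self.stop_day:
            raise RegistryError(
                f"patient {self.patient_id}: treatment episode start_day "
                f"{self.start_day} not before stop_day {self.stop_day}"
            )


@dataclass
class Cohort:
    """A validated registry cohort: typed records grouped per table.

    ``report`` records rows repaired or dropped during loading (deduplicated
    relapses, clipped open treatment episodes, merged overlapping episodes).
    """

    patients: list[PatientRecord]
    relapses: list[RelapseEvent]
    edss: list[EDSSObservation]
    treatments: list[TreatmentEpisode]
    report: dict = field(default_factory=dict)

    def patient(self, patient_id: str) -> PatientRecord:
        for p in self.patients:
            if p.patient_id == patient_id:
                return p
        raise KeyError(patient_id)

    def relapses_of(self, patient_id: str) -> list[int]:
        return sorted(r.relapse_day for r in self.relapses if r.patient_id == patient_id)

    def edss_of(self, patient_id: str) -> list[EDSSObservation]:
        return sorted(
            (e for e in self.edss if e.patient_id == patient_id), key=lambda e: e.obs_day
        )

    def treatments_of(self, patient_id: str) -> list[TreatmentEpisode]:
        return sorted(
            (t for t in self.treatments if t.patient_id == patient_id),
            key=lambda t: t.start_day,
        )


_REQUIRED_COLUMNS = {
    "patients": ["patient_id", "sex", "onset_day", "rrms_dx_day", "spms_dx_day", "end_day", "end_reason"],
    "relapses": ["patient_id", "relapse_day"],
    "edss": ["patient_id", "obs_day", "edss"],
    "treatments": ["patient_id", "drug_name", "start_day", "stop_day"],
}


def _read_table(path: str | Path, name: str) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"patient_id": str}, keep_default_na=False, na_values=[""])
    missing = [c for c in _REQUIRED_COLUMNS[name] if c not in df.columns]
    if missing:
        raise RegistryError(f"{name} table {path}: missing required column(s) {missing}")
    return df


def _merge_episodes(episodes: list[TreatmentEpisode]) -> tuple[list[TreatmentEpisode], int]:
    """Merge overlapping/abutting episodes of one patient within an efficacy class."""
    merged: list[TreatmentEpisode] = []
    n_merged = 0
    by_class: dict[tuple[str, str], list[TreatmentEpisode]] = {}
    for ep in episodes:
        by_class.setdefault((ep.patient_id, ep.efficacy_class), []).append(ep)
    for eps in by_class.values():
        eps.sort(key=lambda e: e.start_day)
        cur = eps[0]
        for nxt in eps[1:]:
            if nxt.start_day <= cur.stop_day:  # overlap or abutment
                n_merged += 1
                cur = replace(cur, stop_day=max(cur.stop_day, nxt.stop_day))
            else:
                merged.append(cur)
                cur = nxt
        merged.append(cur)
    merged.sort(key=lambda e: (e.patient_id, e.start_day, e.drug_name))
    return merged, n_merged


def load_registry(
    patients_path: str | Path,
    relapses_path: str | Path,
    edss_path: str | Path,
    treatments_path: str | Path,
) -> Cohort:
    """Load and validate the four registry tables into a :class:`Cohort`.

    Hard failures (naming the offending column or patient) on schema or
    invariant violations; repairable issues — duplicate relapse days, open
    treatment episodes, within-class episode overlaps — are fixed and counted
    in ``cohort.report``.
    """
    pdf = _read_table(patients_path, "patients")
    rdf = _read_table(relapses_path, "relapses")
    edf = _read_table(edss_path, "edss")
    tdf = _read_table(treatments_path, "treatments")

    report: dict = {"relapses_deduplicated": 0, "episodes_clipped": 0, "episodes_merged": 0,
                    "age_at_onset_defaulted": 0}

    patients: list[PatientRecord] = []
    for row in pdf.itertuples(index=False):
        age = getattr(row, "age_at_onset", None)
        if age is None or pd.isna(age):
            age = 34.1
            report["age_at_onset_defaulted"] += 1
        spms = None if pd.isna(row.spms_dx_day) else int(row.spms_dx_day)
        rec = PatientRecord(
            patient_id=str(row.patient_id),
            sex=str(row.sex),
            onset_day=int(row.onset_day),
            rrms_dx_day=int(row.rrms_dx_day),
            spms_dx_day=spms,
            end_day=int(row.end_day),
            end_reason=str(row.end_reason),
            age_at_onset=float(age),
        )
        rec.validate()
        patients.append(rec)
    end_by_id = {p.patient_id: p.end_day for p in patients}
    if len(end_by_id) != len(patients):
        raise RegistryError("patients table contains duplicate patient_id values")

    relapses: list[RelapseEvent] = []
    seen: set[tuple[str, int]] = set()
    for row in rdf.itertuples(index=False):
        pid, day = str(row.patient_id), int(row.relapse_day)
        if pid not in end_by_id:
            raise RegistryError(f"relapse row references unknown patient {pid}")
        if day > end_by_id[pid]:
            raise RegistryError(
                f"patient {pid}: relapse_day {day} after end of follow-up {end_by_id[pid]}"
            )
        if (pid, day) in seen:
            report["relapses_deduplicated"] += 1
            continue
        seen.add((pid, day))
        relapses.append(RelapseEvent(pid, day))

    edss: list[EDSSObservation] = []
    for row in edf.itertuples(index=False):
        pid = str(row.patient_id)
        if pid not in end_by_id:
            raise RegistryError(f"edss row references unknown patient {pid}")
        obs = EDSSObservation(pid, int(row.obs_day), float(row.edss))
        obs.validate()
        edss.append(obs)

    treatments: list[TreatmentEpisode] = []
    for row in tdf.itertuples(index=False):
        pid = str(row.patient_id)
        if pid not in end_by_id:
            raise RegistryError(f"treatment row references unknown patient {pid}")
        stop = None if pd.isna(row.stop_day) else int(row.stop_day)
        if stop is None:
            stop = end_by_id[pid]
            report["episodes_clipped"] += 1
        ep = TreatmentEpisode(pid, str(row.drug_name), int(row.start_day), stop)
        ep.validate()
        treatments.append(ep)
    treatments, n_merged = _merge_episodes(treatments) if treatments else ([], 0)
    report["episodes_merged"] = n_merged

    relapses.sort(key=lambda r: (r.patient_id, r.relapse_day))
    edss.sort(key=lambda e: (e.patient_id, e.obs_day))
    return Cohort(patients, relapses, edss, treatments, report)


def write_registry(cohort: Cohort, out_dir: str | Path) -> dict[str, Path]:
    """Write the four registry CSVs; returns the path of each table."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "patients": out / "patients.csv",
        "relapses": out / "relapses.csv",
        "edss": out / "edss.csv",
        "treatments": out / "treatments.csv",
    }
    pd.DataFrame(
        [
            {
                "patient_id": p.patient_id,
                "sex": p.sex,
                "onset_day": p.onset_day,
                "rrms_dx_day": p.rrms_dx_day,
                "spms_dx_day": "" if p.spms_dx_day is None else p.spms_dx_day,
                "end_day": p.end_day,
                "end_reason": p.end_reason,
                "age_at_onset": p.age_at_onset,
            }
            for p in cohort.patients
        ]
    ).to_csv(paths["patients"], index=False)
    pd.DataFrame(
        [{"patient_id": r.patient_id, "relapse_day": r.relapse_day} for r in cohort.relapses]
    ).to_csv(paths["relapses"], index=False)
    pd.DataFrame(
        [{"patient_id": e.patient_id, "obs_day": e.obs_day, "edss": e.edss} for e in cohort.edss]
    ).to_csv(paths["edss"], index=False)
    pd.DataFrame(
        [
            {
                "patient_id": t.patient_id,
                "drug_name": t.drug_name,
                "start_day": t.start_day,
                "stop_day": "" if t.stop_day is None else t.stop_day,
            }
            for t in cohort.treatments
        ]
    ).to_csv(paths["treatments"], index=False)
    return paths


def cumulative_exposure(
    episodes: Iterable[TreatmentEpisode], t: float, efficacy_class: str
) -> float:
    """Cumulative years spent on DMTs of ``efficacy_class`` up to (and including) day t.

    Piecewise linear and non-decreasing in t; disjoint episodes contribute
    additively.  Episode days are half-open ``[start_day, stop_day)`` so that
    abutting episodes merge seamlessly.
    """
    total_days = 0.0
    for ep in episodes:
        if ep.efficacy_class != efficacy_class:
            continue
        stop = ep.stop_day if ep.stop_day is not None else t
        total_days += max(0.0, min(stop, t) - ep.start_day)
    return total_days / DAYS_PER_YEAR
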
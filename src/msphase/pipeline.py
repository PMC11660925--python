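"""End-to-end orchestration: simulate/load -> classify -> descriptives ->
competing-risks incidence -> Cox milestones -> relapse rates -> multi-state
Markov fit -> predictions and goodness of fit, with a manifest for
reproducibility.

Every stage logs attrition counts (patients in/out, rows, transitions
observed), and all artifacts are plain CSV/JSON so that two runs with the
same configuration and seed produce byte-identical tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .markov import (
    ProportionalIntensityModel,
    crude_init,
    expected_prevalence,
    fit,
    hazard_ratios,
    ms_covariate_spec,
    ms_structure,
    predicted_probabilities_ci,
)
from .phenotype import (
    WINDOW_DAYS,
    classify_timeline,
    cohort_panel,
    pattern_frequencies,
    timelines_frame,
)
from .registry import DAYS_PER_YEAR, Cohort, load_registry, write_registry
from .simulate import CohortParams, simulate_cohort
from .survival import aalen_johansen, cox_ph, gee_poisson_arr, poisson_arr

log = logging.getLogger("msphase.pipeline")

EN_DASH = "–"


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    Either ``input_dir`` (a directory holding the four registry CSVs) or
    ``sim_params`` (mechanistic simulation) must be given.  ``covariates``
    selects the per-transition Markov covariate sets: "full" is the complete
    eight-covariate specification, "reduced" a lighter set for quick runs.
    """

    input_dir: str | None = None
    sim_params: CohortParams | None = None
    window_days: int = WINDOW_DAYS
    horizons: tuple[float, ...] = (5.0, 10.0, 15.0)
    n_draws: int = 100
    seed: int = 0
    out_dir: str = "msphase_out"
    covariates: str = "full"  # "full" | "reduced"
    markov_maxiter: int = 500
    milestones: tuple[float, ...] = (3.0, 4.0, 6.0)
    prevalence_grid: tuple[float, ...] = (0.0, 2.5, 5.0, 7.5, 10.0, 12.5, 15.0)

    def semantic_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d.pop("out_dir")
        if self.sim_params is not None:
            d["sim_params"] = self.sim_params.to_dict()
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.semantic_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "sim_params" in raw and raw["sim_params"] is not None:
            raw["sim_params"] = CohortParams.from_dict(raw["sim_params"])
        for key in ("horizons", "milestones", "prevalence_grid"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


# ---------------------------------------------------------------------------
# analysis-dataset builders


def spms_group_at_dx(cohort: Cohort) -> pd.Series:
    """Per patient: RRMS (never diagnosed SPMS), or the subtype at SPMS diagnosis."""
    out = {}
    for p in cohort.patients:
        if p.spms_dx_day is None:
            out[p.patient_id] = "RRMS"
        else:
            tl = classify_timeline(p, cohort.relapses_of(p.patient_id))
            out[p.patient_id] = tl.state_on(p.spms_dx_day)
    return pd.Series(out, name="group")


def first_spms_records(cohort: Cohort, groups: pd.Series) -> pd.DataFrame:
    """Time from RRMS diagnosis to SPMS diagnosis (split by subtype at
    diagnosis) with death competing; for the initial-cohort incidence curves."""
    rows = []
    for p in cohort.patients:
        t_end = (p.end_day - p.rrms_dx_day) / DAYS_PER_YEAR
        if p.spms_dx_day is not None:
            t = (p.spms_dx_day - p.rrms_dx_day) / DAYS_PER_YEAR
            event = groups[p.patient_id]
        elif p.end_reason == "death":
            t, event = t_end, "death"
        else:
            t, event = t_end, "censored"
        rows.append({"patient_id": p.patient_id, "entry": 0.0, "exit": max(t, 1e-3), "event": event})
    return pd.DataFrame(rows)


def subtype_switch_records(cohort: Cohort, initial: str) -> pd.DataFrame:
    """From SPMS diagnosis, time to the first opposite SPMS subtype interval
    for patients whose subtype at diagnosis was ``initial``; death competes."""
    other = "rSPMS" if initial == "nrSPMS" else "nrSPMS"
    rows = []
    for p in cohort.patients:
        if p.spms_dx_day is None:
            continue
        tl = classify_timeline(p, cohort.relapses_of(p.patient_id))
        if tl.state_on(p.spms_dx_day) != initial:
            continue
        switch = next(
            (a for s, a, b in tl.intervals if s == other and a > p.spms_dx_day), None
        )
        if switch is not None:
            t, event = (switch - p.spms_dx_day) / DAYS_PER_YEAR, other
        elif p.end_reason == "death":
            t, event = (p.end_day - p.spms_dx_day) / DAYS_PER_YEAR, "death"
        else:
            t, event = (p.end_day - p.spms_dx_day) / DAYS_PER_YEAR, "censored"
        rows.append({"patient_id": p.patient_id, "entry": 0.0, "exit": max(t, 1e-3), "event": event})
    return pd.DataFrame(rows)


def milestone_records(cohort: Cohort, groups: pd.Series, threshold: float) -> pd.DataFrame:
    """Time from MS onset to the first EDSS >= threshold, censored at SPMS
    diagnosis or end of follow-up; SPMS patients only, with the subtype at
    diagnosis as the exposure of interest (unconfirmed first crossing)."""
    rows = []
    for p in cohort.patients:
        if p.spms_dx_day is None:
            continue
        censor_day = min(p.spms_dx_day, p.end_day)
        hit = next(
            (e.obs_day for e in cohort.edss_of(p.patient_id)
             if e.edss >= threshold and e.obs_day <= censor_day),
            None,
        )
        if hit is not None:
            t, event = (hit - p.onset_day) / DAYS_PER_YEAR, "milestone"
        else:
            t, event = (censor_day - p.onset_day) / DAYS_PER_YEAR, "censored"
        rows.append(
            {
                "patient_id": p.patient_id,
                "entry": 0.0,
                "exit": max(t, 1e-3),
                "event": event,
                "rspms": 1.0 if groups[p.patient_id] == "rSPMS" else 0.0,
                "age_at_onset": p.age_at_onset,
                "sex_female": 1.0 if p.sex == "female" else 0.0,
            }
        )
    return pd.DataFrame(rows)


def relapse_age_bins(cohort: Cohort, groups: pd.Series, window_days: int = WINDOW_DAYS) -> pd.DataFrame:
    """One row per patient per year of age during the relapsing-remitting
    phase: relapse count and exposure years.

    The relapsing-remitting phase runs from MS onset to the end of follow-up
    for patients who remain RRMS, and to ``window_days`` before the SPMS
    diagnosis for SPMS patients, so the relapses that define the SPMS
    subtypes are excluded.
    """
    rows = []
    for p in cohort.patients:
        phase_end = (
            p.end_day if p.spms_dx_day is None else min(p.spms_dx_day - window_days, p.end_day)
        )
        if phase_end <= p.onset_day:
            continue
        relapses = [d for d in cohort.relapses_of(p.patient_id) if p.onset_day <= d < phase_end]
        age_start = p.age_at_onset
        age_end = p.age_at_onset + (phase_end - p.onset_day) / DAYS_PER_YEAR
        for a in range(int(np.floor(age_start)), int(np.ceil(age_end))):
            lo, hi = max(age_start, a), min(age_end, a + 1)
            if hi <= lo:
                continue
            d_lo = p.onset_day + (lo - age_start) * DAYS_PER_YEAR
            d_hi = p.onset_day + (hi - age_start) * DAYS_PER_YEAR
            rows.append(
                {
                    "patient_id": p.patient_id,
                    "age": a,
                    "count": sum(d_lo <= d < d_hi for d in relapses),
                    "exposure": hi - lo,
                    "group": groups[p.patient_id],
                    "sex": p.sex,
                }
            )
    return pd.DataFrame(rows)


def prediagnosis_relapse_counts(cohort: Cohort, window_days: int = WINDOW_DAYS) -> pd.DataFrame:
    """Relapse count and exposure over the 2 years before RRMS diagnosis
    (clipped at onset for shorter histories), for the pre-diagnosis ARR."""
    rows = []
    for p in cohort.patients:
        lo = max(p.onset_day, p.rrms_dx_day - window_days)
        expo = (p.rrms_dx_day - lo) / DAYS_PER_YEAR
        if expo <= 0:
            expo = 1.0 / DAYS_PER_YEAR
        n = sum(lo <= d < p.rrms_dx_day for d in cohort.relapses_of(p.patient_id))
        rows.append({"patient_id": p.patient_id, "count": n, "exposure": expo})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# table formatting


def fmt_ci(est: float, lower: float, upper: float, decimals: int = 3) -> str:
    """The field's "est (lower–upper)" cell format, e.g. ``1.044 (1.035–1.053)``."""
    return f"{est:.{decimals}f} ({lower:.{decimals}f}{EN_DASH}{upper:.{decimals}f})"


def fmt_pct(est: float, lower: float, upper: float) -> str:
    """Percentage cells with one decimal, e.g. ``94.6 (94.1–95.0)``."""
    return f"{100 * est:.1f} ({100 * lower:.1f}{EN_DASH}{100 * upper:.1f})"


NOT_INCLUDED = "not included"


def hazard_ratio_table(hr: pd.DataFrame, transitions: Sequence[str], covariates: Sequence[str]) -> pd.DataFrame:
    """Per-transition HR columns with "not included" for absent covariates."""
    out = pd.DataFrame(index=list(covariates), columns=list(transitions), data=NOT_INCLUDED)
    out.index.name = "covariate"
    for _, row in hr.iterrows():
        if row["covariate"] in out.index and row["transition"] in out.columns:
            out.loc[row["covariate"], row["transition"]] = fmt_ci(
                row["hr"], row["lower"], row["upper"]
            )
    return out


def transition_probability_table(
    pred: Mapping[float, Mapping[str, np.ndarray]], states: Sequence[str]
) -> pd.DataFrame:
    """Horizon-stacked matrix of "94.6 (94.1–95.0)"-style percentage cells for
    the transient states."""
    transient = [s for s in states if s != "Death"]
    rows = []
    for h, d in pred.items():
        for i, r in enumerate(states):
            if r not in transient:
                continue
            row = {"horizon_years": h, "from": r}
            for j, s in enumerate(states):
                if s not in transient:
                    continue
                row[s] = fmt_pct(d["point"][i, j], d["lower"][i, j], d["upper"][i, j])
            rows.append(row)
    return pd.DataFrame(rows)


def make_tables(results: Mapping) -> dict[str, pd.DataFrame]:
    """Format fitted results into publication-shaped tables."""
    out: dict[str, pd.DataFrame] = {}
    if "hazard_ratios" in results:
        hr = results["hazard_ratios"]
        out["hazard_ratio_table"] = hazard_ratio_table(
            hr,
            transitions=sorted(hr["transition"].unique()),
            covariates=list(dict.fromkeys(hr["covariate"])),
        )
    if "predicted_probabilities" in results:
        out["transition_probability_table"] = transition_probability_table(
            results["predicted_probabilities"], ms_structure().states
        )
    return out


# ---------------------------------------------------------------------------
# the pipeline


def _descriptive_table(cohort: Cohort, groups: pd.Series) -> pd.DataFrame:
    pre = prediagnosis_relapse_counts(cohort).set_index("patient_id")
    rows = []
    for gname in ("RRMS", "nrSPMS", "rSPMS"):
        ids = [p.patient_id for p in cohort.patients if groups[p.patient_id] == gname]
        if not ids:
            continue
        ps = [cohort.patient(i) for i in ids]
        fu = [(p.end_day - p.rrms_dx_day) / DAYS_PER_YEAR for p in ps]
        sub = pre.loc[ids]
        arr = poisson_arr(sub["count"], sub["exposure"])
        rows.append(
            {
                "group": gname,
                "n": len(ps),
                "pct_female": 100 * np.mean([p.sex == "female" for p in ps]),
                "age_at_onset_mean": np.mean([p.age_at_onset for p in ps]),
                "age_at_onset_sd": np.std([p.age_at_onset for p in ps], ddof=1) if len(ps) > 1 else 0.0,
                "followup_median_years": float(np.median(fu)),
                "arr_prediag": arr.arr,
                "arr_prediag_ci": fmt_ci(
                    arr.arr, arr.table.loc[0, "lower"], arr.table.loc[0, "upper"], 2
                ),
            }
        )
    return pd.DataFrame(rows)


def run_all(config: RunConfig) -> dict:
    """Execute the full analysis sequence; returns the results dict and writes
    every artifact (plus MANIFEST.json) under ``config.out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {}
    notices: list[str] = []

    # -- stage: data
    if config.sim_params is not None:
        params = dataclasses.replace(config.sim_params, seed=config.seed)
        cohort = simulate_cohort(params)
        write_registry(cohort, out / "registry")
        truth = {
            "latent_spms_onset_day": cohort.report.get("latent_spms_onset_day", {}),
            "params": params.to_dict(),
        }
        (out / "registry" / "truth.json").write_text(json.dumps(truth, indent=1, sort_keys=True))
    elif config.input_dir is not None:
        d = Path(config.input_dir)
        cohort = load_registry(
            d / "patients.csv", d / "relapses.csv", d / "edss.csv", d / "treatments.csv"
        )
    else:
        raise ValueError("RunConfig needs input_dir or sim_params")
    log.info("stage=data patients=%d relapses=%d", len(cohort.patients), len(cohort.relapses))
    results["cohort"] = cohort

    # -- stage: classification
    timelines = [
        classify_timeline(p, cohort.relapses_of(p.patient_id), config.window_days)
        for p in cohort.patients
    ]
    groups = spms_group_at_dx(cohort)
    tl_frame = timelines_frame(timelines)
    tl_frame.to_csv(out / "timelines.csv", index=False)
    patterns = pattern_frequencies(timelines)
    patterns.rename_axis("pattern").rename("n").to_csv(out / "patterns.csv")
    results["timelines"] = timelines
    results["groups"] = groups
    results["patterns"] = patterns
    n_spms = int((groups != "RRMS").sum())
    log.info("stage=classify spms=%d nrspms=%d rspms=%d", n_spms,
             int((groups == "nrSPMS").sum()), int((groups == "rSPMS").sum()))

    # -- stage: descriptives
    desc = _descriptive_table(cohort, groups)
    desc.to_csv(out / "descriptive.csv", index=False)
    results["descriptive"] = desc

    # -- stage: competing-risks cumulative incidence
    rec0 = first_spms_records(cohort, groups)
    results["cif_initial"] = aalen_johansen(rec0, ("nrSPMS", "rSPMS", "death"))
    results["cif_initial"].as_frame().to_csv(out / "cif_initial.csv", index=False)
    if n_spms > 0:
        for initial, key in (("nrSPMS", "cif_from_nrspms"), ("rSPMS", "cif_from_rspms")):
            rec = subtype_switch_records(cohort, initial)
            if len(rec) and (rec["event"] != "censored").any():
                other = "rSPMS" if initial == "nrSPMS" else "nrSPMS"
                results[key] = aalen_johansen(rec, (other, "death"))
                results[key].as_frame().to_csv(out / f"{key}.csv", index=False)

    # -- stage: Cox milestones
    if n_spms > 0:
        cox_rows = []
        for thr in config.milestones:
            rec = milestone_records(cohort, groups, thr)
            if (rec["event"] == "milestone").sum() >= 5 and rec["rspms"].nunique() > 1:
                res = cox_ph(rec, ["rspms", "age_at_onset", "sex_female"])
                for _, r in res.table.iterrows():
                    cox_rows.append({"milestone": thr, **r.to_dict()})
        results["cox_milestones"] = pd.DataFrame(cox_rows)
        results["cox_milestones"].to_csv(out / "cox_milestones.csv", index=False)

    # -- stage: relapse rates
    bins = relapse_age_bins(cohort, groups, config.window_days)
    if len(bins):
        if bins["count"].sum() > 0 and bins["group"].nunique() > 1:
            gee = gee_poisson_arr(bins)
            results["gee_arr"] = gee
            gee.table.to_csv(out / "gee_arr.csv", index=False)
        by_group = []
        for gname, sub in bins.groupby("group"):
            arr = poisson_arr(sub["count"], sub["exposure"])
            by_group.append(
                {"group": gname, "arr": arr.arr,
                 "arr_ci": fmt_ci(arr.arr, arr.table.loc[0, "lower"], arr.table.loc[0, "upper"])}
            )
        results["arr_by_group"] = pd.DataFrame(by_group)
        results["arr_by_group"].to_csv(out / "arr_by_group.csv", index=False)

    # -- stage: multi-state Markov model
    if n_spms == 0:
        notices.append("no SPMS diagnoses in the cohort: Markov fit skipped")
        log.warning(notices[-1])
    else:
        panel = cohort_panel(cohort, config.window_days)
        flagged = panel.loc[panel["edss_flagged"], "patient_id"].unique()
        if flagged.size:
            log.warning("excluding %d patient(s) with unimputable EDSS", flagged.size)
        panel = panel[~panel["edss_flagged"]].drop(columns="edss_flagged")
        panel.to_csv(out / "panel.csv", index=False)
        structure = ms_structure()
        spec = ms_covariate_spec(reduced=(config.covariates == "reduced"))
        proto = ProportionalIntensityModel(
            structure, np.full(len(structure.allowed), -3.0), covariate_spec=spec
        )
        init = crude_init(proto, panel)
        result = fit(init, panel, maxiter=config.markov_maxiter)
        results["markov_fit"] = result
        (out / "markov_fit.json").write_text(
            json.dumps(
                {
                    "param_names": result.param_names,
                    "estimates": result.estimates.tolist(),
                    "vcov": result.vcov.tolist(),
                    "loglik": result.loglik,
                    "converged": result.converged,
                    "n_patients": result.n_patients,
                    "n_intervals": result.n_intervals,
                },
                indent=1,
            )
        )
        log.info("stage=markov patients=%d intervals=%d loglik=%.2f converged=%s",
                 result.n_patients, result.n_intervals, result.loglik, result.converged)

        hr = hazard_ratios(result)
        hr.to_csv(out / "hazard_ratios.csv", index=False)
        results["hazard_ratios"] = hr

        first = panel.sort_values(["patient_id", "time"]).groupby("patient_id").first()
        profile = {c: float(first[c].mean()) for c in result.model.covariate_names}
        pred = predicted_probabilities_ci(
            result, profile, config.horizons, n_draws=config.n_draws, seed=config.seed
        )
        results["predicted_probabilities"] = pred

        prev = expected_prevalence(result, panel, config.prevalence_grid)
        prev.to_csv(out / "prevalence.csv", index=False)
        results["prevalence"] = prev

    tables = make_tables(results)
    for name, tbl in tables.items():
        tbl.to_csv(out / f"{name}.csv")
    results.update(tables)
    results["notices"] = notices

    manifest = {
        "config": config.semantic_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "msphase_version": __version__,
        "notices": notices,
        "artifacts": sorted(p.name for p in out.iterdir() if p.is_file()),
    }
    (out / "MANIFEST.json").write_text(json.dumps(manifest, indent=1, sort_keys=True, default=str))
    results["manifest"] = manifest
    return results
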
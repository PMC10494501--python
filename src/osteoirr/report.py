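"""Pipeline driver and output surfaces.

``run_pipeline`` takes a study configuration and a claims directory and
emits the study's output tables: flow-diagram counts, baseline
characteristics, treatment-exposure summary, incidence tables, IRR tables
with log-transformed columns for forest plots, and a machine-readable run
log.  Reruns on identical inputs are byte-identical.
"""

from __future__ import annotations

import json
import logging
import os
import sys
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import cohorts, episodes, fractures, irr_stats, persontime
from .dates import DAYS_PER_YEAR, to_day

log = logging.getLogger("osteoirr")

DEFAULT_STRATA = ("age_class", "fracture_history_class",
                  "prior_osteoporosis_medication", "corticosteroid_class",
                  "dementia", "nervous_system_disorder")


@dataclass
class StudyConfig:
    """Everything one analysis run needs.

    Dates are ISO strings; ``inclusion_window`` bounds index dates and
    ``study_end`` is the last day of the study period (the ITT censoring
    horizon).  ``modes`` selects the analysis modes to run and ``strata``
    the covariates for subgroup runs.
    """

    claims_dir: str = "."
    output_dir: str = "results"
    inclusion_window: tuple = ("2014-01-01", "2016-12-31")
    study_end: str = "2018-12-31"
    drug_specs: tuple = episodes.DEFAULT_DRUGS
    code_map: fractures.FractureCodeMap = field(
        default_factory=fractures.FractureCodeMap)
    modes: tuple = ("as_treated", "itt", "virtual_exposure")
    strata: tuple = ()
    eligibility: cohorts.EligibilityParams = field(
        default_factory=cohorts.EligibilityParams)
    irr_method: str = "exact"

    def validate(self):
        if to_day(self.study_end) < to_day(self.inclusion_window[1]):
            raise ValueError("study_end must not precede the inclusion "
                             "window end")

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        kwargs = dict(d)
        if "inclusion_window" in kwargs:
            kwargs["inclusion_window"] = tuple(kwargs["inclusion_window"])
        if "code_map" in kwargs and isinstance(kwargs["code_map"], dict):
            kwargs["code_map"] = fractures.FractureCodeMap(
                prefixes=kwargs["code_map"])
        if "drug_specs" in kwargs and isinstance(kwargs["drug_specs"], list):
            kwargs["drug_specs"] = tuple(
                episodes.DrugSpec(**s) for s in kwargs["drug_specs"])
        for k in ("modes", "strata"):
            if k in kwargs:
                kwargs[k] = tuple(kwargs[k])
        return cls(**kwargs)


def _stage(name, fn, timings):
    t0 = time.perf_counter()
    try:
        out = fn()
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc
    dt = time.perf_counter() - t0
    timings.append({"stage": name, "seconds": round(dt, 3)})
    log.info("stage %-18s %7.2fs", name, dt)
    return out


def characteristics_table(covariates: pd.DataFrame,
                          assignment: pd.DataFrame) -> pd.DataFrame:
    """Baseline-characteristics summary per cohort (age, covariate %)."""
    if covariates.empty:
        return pd.DataFrame()
    rows = []
    for cohort, grp in covariates.groupby("cohort_drug", sort=True):
        row = {"cohort": cohort, "n": len(grp),
               "age_mean": round(grp["age"].mean(), 2),
               "age_sd": round(grp["age"].std(ddof=1), 2)
               if len(grp) > 1 else 0.0}
        for col in ("fracture_history_any", "prior_osteoporosis_medication",
                    "dementia", "nervous_system_disorder", "vitd_calcium",
                    "bone_densitometry"):
            row[f"{col}_pct"] = round(100.0 * grp[col].mean(), 2)
        row["comorbidity_score_mean"] = round(
            grp["comorbidity_score"].mean(), 3)
        rows.append(row)
    return pd.DataFrame(rows)


def exposure_table(assignment: pd.DataFrame, persons: pd.DataFrame,
                   dispensings: pd.DataFrame,
                   specs=episodes.DEFAULT_DRUGS) -> pd.DataFrame:
    """Treatment-exposure summary per cohort.

    Median/IQR exposure duration in months, end-of-exposure reasons, and
    median/IQR post-discontinuation duration among discontinuers.
    """
    if assignment.empty:
        return pd.DataFrame()
    month = DAYS_PER_YEAR / 12.0
    pers = persons.set_index("person_id")
    rows = []
    for cohort, grp in assignment.groupby("cohort_drug", sort=True):
        dur = (grp["end"] - grp["index_date"]) / month
        row = {"cohort": cohort, "n": len(grp),
               "exposure_months_median": round(float(dur.median()), 2),
               "exposure_months_q1": round(float(dur.quantile(0.25)), 2),
               "exposure_months_q3": round(float(dur.quantile(0.75)), 2)}
        reasons = grp["end_reason"].value_counts()
        for reason in (episodes.END_DEATH, episodes.END_FOLLOWUP,
                       episodes.END_DISCONTINUATION, episodes.END_SWITCH):
            row[f"end_{reason}_n"] = int(reasons.get(reason, 0))
            row[f"end_{reason}_pct"] = round(
                100.0 * reasons.get(reason, 0) / len(grp), 2)
        disc = grp[grp["end_reason"] == episodes.END_DISCONTINUATION].copy()
        if len(disc):
            disc["reinit"] = persontime.reinitiation_dates(
                disc, dispensings, specs)
            death_excl = disc["person_id"].map(
                lambda p: float(pers.loc[p, "death_date"]) + 1
                if pd.notna(pers.loc[p, "death_date"]) else np.inf)
            obs_excl = disc["person_id"].map(
                lambda p: float(pers.loc[p, "data_end"]) + 1)
            end = np.fmin(np.fmin(disc["reinit"].fillna(np.inf),
                                  death_excl), obs_excl)
            pdm = (end - disc["end"].astype(float)) / month
            row["postdisc_months_median"] = round(float(pdm.median()), 2)
            row["postdisc_months_q1"] = round(float(pdm.quantile(0.25)), 2)
            row["postdisc_months_q3"] = round(float(pdm.quantile(0.75)), 2)
        rows.append(row)
    return pd.DataFrame(rows)


def forest_data(irr_table: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Plot-ready forest records: log IRR and log bounds, labelled and
    ordered by cohort, site group, then comparison.  Undefined rows are
    omitted; their count is returned alongside."""
    if irr_table.empty:
        return irr_table.copy(), 0
    defined = irr_table[irr_table["defined"] &
                        np.isfinite(irr_table["log_irr"])]
    omitted = len(irr_table) - len(defined)
    out = defined.sort_values(["cohort", "site_group", "comparison"],
                              kind="stable", ignore_index=True).copy()
    out["label"] = (out["cohort"] + " | " + out["site_group"] + " | " +
                    out["comparison"])
    cols = ["label", "cohort", "site_group", "mode", "stratum",
            "comparison", "irr", "ci_low", "ci_high", "log_irr",
            "log_ci_low", "log_ci_high"]
    return out[cols], omitted


def run_pipeline(config: StudyConfig, write: bool = True,
                 with_covariates: bool = True) -> dict:
    """Run the full own-control analysis and write the output bundle.

    Returns a dict bundle with the flow counts, assignment, covariates,
    cell counts, incidence and IRR tables, forest data, and stage timings.
    ``with_covariates=False`` skips covariate extraction (and hence the
    characteristics table and stratified runs) for lean simulation
    replicates.
    """
    config.validate()
    timings: list[dict] = []
    specs = config.drug_specs
    window = (to_day(config.inclusion_window[0]),
              to_day(config.inclusion_window[1]))
    study_end = to_day(config.study_end)

    persons, dispensings, stays = _stage(
        "read_claims", lambda: episodes.read_claims(config.claims_dir),
        timings)
    index_events = _stage(
        "index_dates", lambda: episodes.find_index_dates(
            dispensings, specs, (window[0], window[1] + 1)), timings)
    eps = _stage(
        "episodes", lambda: episodes.detect_switch(
            episodes.build_episodes(persons, dispensings, index_events,
                                    specs)), timings)
    episode_flags, person_results, flow = _stage(
        "eligibility", lambda: cohorts.apply_eligibility(
            persons, eps, stays, dispensings, specs, config.eligibility),
        timings)
    assignment = _stage(
        "assign_cohorts", lambda: cohorts.assign_cohorts(
            episode_flags, specs, window), timings)
    events = _stage(
        "fractures", lambda: fractures.find_fracture_events(
            stays, config.code_map), timings)
    if with_covariates:
        covariates = _stage(
            "covariates", lambda: cohorts.extract_covariates(
                stays, dispensings, assignment, persons, specs,
                code_map=config.code_map), timings)
    else:
        if config.strata:
            raise ValueError("stratified runs require covariates")
        covariates = pd.DataFrame(columns=["person_id", "cohort_drug",
                                           "age", "age_class"])

    def build_cells():
        parts = []
        for mode in config.modes:
            parts.append(persontime.accumulate(
                assignment, events, persons, mode, specs,
                study_end=study_end))
        parts.append(persontime.accumulate_post_disc(
            assignment, events, persons, dispensings, specs))
        for var in config.strata:
            for value in sorted(covariates[var].astype(str).unique()):
                sub = persontime.select_stratum(
                    assignment, covariates,
                    var, _parse_stratum_value(covariates[var], value))
                parts.append(persontime.accumulate(
                    sub, events, persons, "as_treated", specs,
                    study_end=study_end, stratum=f"{var}={value}"))
        return pd.concat(parts, ignore_index=True) if parts \
            else pd.DataFrame()

    cells = _stage("persontime", build_cells, timings)
    incidence = _stage("rates", lambda: irr_stats.rates_table(cells),
                       timings)
    irr_table = _stage("irr", lambda: irr_stats.run_all(
        cells, method=config.irr_method), timings)
    forest, omitted = forest_data(irr_table)

    flow["cohort_sizes"] = (assignment.groupby("cohort_drug").size()
                            .to_dict())
    bundle = {
        "flow": flow,
        "persons": persons, "dispensings": dispensings, "stays": stays,
        "episode_flags": episode_flags,
        "assignment": assignment,
        "covariates": covariates,
        "events": events,
        "cells": cells,
        "incidence": incidence,
        "irr": irr_table,
        "forest": forest,
        "forest_omitted": omitted,
        "characteristics": characteristics_table(covariates, assignment),
        "exposure": exposure_table(assignment, persons, dispensings, specs),
        "timings": timings,
    }
    if write:
        _write_bundle(bundle, config)
    return bundle


def _parse_stratum_value(col: pd.Series, value: str):
    # stratified runs iterate string renderings; map back to dtype
    if col.dtype == bool:
        return value == "True"
    return value


def _write_bundle(bundle: dict, config: StudyConfig):
    out = config.output_dir
    os.makedirs(out, exist_ok=True)
    for name in ("assignment", "covariates", "cells", "incidence", "irr",
                 "forest", "characteristics", "exposure"):
        bundle[name].to_csv(os.path.join(out, f"{name}.csv"), index=False,
                            float_format="%.10g")
    summary = {
        "flow": bundle["flow"],
        "forest_omitted": bundle["forest_omitted"],
        "n_events_independent": int(bundle["events"]["independent"].sum())
        if len(bundle["events"]) else 0,
        "timings": bundle["timings"],
    }
    with open(os.path.join(out, "summary.json"), "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=str)
    log.info("wrote output bundle to %s", out)
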
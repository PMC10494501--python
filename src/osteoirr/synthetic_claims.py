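"""Synthetic claims generator with known ground truth.

Emulates the statistical structure the own-control analysis assumes: women
aged >= 55 initiate one osteoporosis medication at an index date inside an
inclusion window, refill it with small jitter until a planned
discontinuation, and experience hospitalized fractures from a
piecewise-constant Poisson process whose hazard changes at two timeline
breakpoints — the end of the 3-month baseline period and the
discontinuation date:

    rate(t) = h0                      for index <= t < index + 91
    rate(t) = h0 * on_treatment_irr   for index + 91 <= t < discontinuation
    rate(t) = h0 * post_disc_irr      for discontinuation <= t < end of data

so the true on-treatment and post-discontinuation incidence rate ratios are
known by construction.  Each true event produces one hospital stay admitted
on the event date carrying a site-appropriate ICD-10-style diagnosis code,
mostly in principal position with a configurable fraction in associated
position.

Site groups overlap downstream (a wrist fracture is also a
non-hip/nonvertebral fracture), so the generator drives each group with a
disjoint carrier site: hip -> hip, vertebral -> vertebral, wrist_forearm ->
wrist/forearm, and nonhip_nonvertebral -> pelvis.  The observed
non-hip/nonvertebral group therefore aggregates the wrist and pelvis
processes; its true rate is the sum of the two configured rates.

Mortality is modelled as an exponential time to death starting after the
6-month treatment-qualification point, so that eligibility is controlled by
``exclusion_fractions`` alone.  Hazards depend only on period and drug, not
on comorbidity.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .dates import DAYS_PER_YEAR, days_to_iso_series, to_day
from .episodes import DEFAULT_DRUGS, DrugSpec, specs_by_name

GROUP_CARRIER_SITE = {
    "hip": "hip",
    "vertebral": "vertebral",
    "wrist_forearm": "wrist_forearm",
    "nonhip_nonvertebral": "pelvis",
}

SITE_CODE = {
    "hip": "S720",
    "vertebral": "S220",
    "wrist_forearm": "S525",
    "pelvis": "S325",
}

#: Baseline (months 0-3) fracture hazards in events per 1000 person-years,
#: by site group and drug.  Magnitudes mirror what treated post-menopausal
#: cohorts show in national claims data: teriparatide initiators carry a far
#: higher vertebral risk than raloxifene initiators.  The
#: nonhip_nonvertebral entry is the non-wrist remainder of that group
#: (carried by pelvis fractures).
DEFAULT_BASELINE_HAZARDS: dict[str, dict[str, float]] = {
    "vertebral": {"denosumab": 8.78, "oral_bisphosphonate": 4.99,
                  "zoledronic_acid": 19.22, "raloxifene": 1.74,
                  "teriparatide": 34.75},
    "hip": {"denosumab": 8.72, "oral_bisphosphonate": 3.37,
            "zoledronic_acid": 10.52, "raloxifene": 0.70,
            "teriparatide": 8.65},
    "wrist_forearm": {"denosumab": 8.24, "oral_bisphosphonate": 6.37,
                      "zoledronic_acid": 7.20, "raloxifene": 4.87,
                      "teriparatide": 8.11},
    "nonhip_nonvertebral": {"denosumab": 13.84, "oral_bisphosphonate": 5.76,
                            "zoledronic_acid": 14.65, "raloxifene": 2.09,
                            "teriparatide": 8.12},
}

#: True on-treatment rate multipliers (vs the baseline period), by site
#: group and drug: antiresorptives and teriparatide reduce vertebral risk,
#: effects elsewhere are weaker or absent.
DEFAULT_ON_TREATMENT_IRR: dict[str, dict[str, float]] = {
    "vertebral": {"denosumab": 0.55, "oral_bisphosphonate": 0.56,
                  "zoledronic_acid": 0.36, "raloxifene": 0.55,
                  "teriparatide": 0.34},
    "hip": {"denosumab": 0.75, "oral_bisphosphonate": 1.65,
            "zoledronic_acid": 0.90, "raloxifene": 1.20,
            "teriparatide": 1.10},
    "wrist_forearm": {"denosumab": 0.82, "oral_bisphosphonate": 0.96,
                      "zoledronic_acid": 1.05, "raloxifene": 0.95,
                      "teriparatide": 1.18},
    "nonhip_nonvertebral": {"denosumab": 0.82, "oral_bisphosphonate": 1.10,
                            "zoledronic_acid": 0.97, "raloxifene": 1.28,
                            "teriparatide": 1.55},
}

#: True post-discontinuation multipliers (vs baseline): denosumab cessation
#: rebounds above its on-treatment level, zoledronic acid retains much of
#: its effect.
DEFAULT_POST_DISC_IRR: dict[str, dict[str, float]] = {
    "vertebral": {"denosumab": 1.10, "oral_bisphosphonate": 1.00,
                  "zoledronic_acid": 0.50, "raloxifene": 1.00,
                  "teriparatide": 0.70},
    "hip": {"denosumab": 1.40, "oral_bisphosphonate": 1.00,
            "zoledronic_acid": 0.90, "raloxifene": 1.00,
            "teriparatide": 1.10},
    "wrist_forearm": {"denosumab": 1.00, "oral_bisphosphonate": 1.00,
                      "zoledronic_acid": 1.00, "raloxifene": 1.00,
                      "teriparatide": 1.00},
    "nonhip_nonvertebral": {"denosumab": 1.10, "oral_bisphosphonate": 1.00,
                            "zoledronic_acid": 1.00, "raloxifene": 1.00,
                            "teriparatide": 1.00},
}

#: Median treatment duration in days (log-normal), per drug; medians sit
#: between 12 and 17 months as observed for these products.
DEFAULT_DISCONTINUATION = {
    "denosumab": {"median_days": 360.0, "sigma": 0.8},
    "oral_bisphosphonate": {"median_days": 455.0, "sigma": 0.8},
    "zoledronic_acid": {"median_days": 365.0, "sigma": 0.8},
    "raloxifene": {"median_days": 495.0, "sigma": 0.8},
    "teriparatide": {"median_days": 520.0, "sigma": 0.3},
}


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic dataset.

    Hazard maps accept either a single float per site group (applied to all
    drugs) or a ``{drug: value}`` dict.  ``exclusion_fractions`` plant
    women who fail eligibility: a cancer diagnosis in the pre-index year,
    an index age below 55, a second study drug dispensed on the index date,
    or a planned treatment duration under 6 months.  With all fractions at
    zero every generated woman passes eligibility.
    """

    n_women_per_drug: int | dict = 1000
    age_mean: float = 72.0
    age_sd: float = 9.0
    inclusion_window: tuple = ("2014-01-01", "2016-12-31")
    study_end: str = "2018-12-31"
    data_start: str = "2010-01-01"
    baseline_hazards: dict = field(
        default_factory=lambda: {g: dict(v) for g, v in
                                 DEFAULT_BASELINE_HAZARDS.items()})
    on_treatment_irr: dict = field(
        default_factory=lambda: {g: dict(v) for g, v in
                                 DEFAULT_ON_TREATMENT_IRR.items()})
    post_disc_irr: dict = field(
        default_factory=lambda: {g: dict(v) for g, v in
                                 DEFAULT_POST_DISC_IRR.items()})
    discontinuation_time_distribution: dict = field(
        default_factory=lambda: {d: dict(v) for d, v in
                                 DEFAULT_DISCONTINUATION.items()})
    refill_jitter_mean: float = 2.0
    refill_jitter_sd: float = 5.0
    death_rate: float = 10.0
    exclusion_fractions: dict = field(
        default_factory=lambda: {"cancer_or_paget": 0.02, "age_lt_55": 0.02,
                                 "multi_drug_index": 0.01,
                                 "treated_lt_6m": 0.25})
    associated_position_fraction: float = 0.2
    seed: int = 0

    def validate(self, drugs):
        if to_day(self.inclusion_window[0]) > to_day(self.inclusion_window[1]):
            raise ValueError("inclusion window is empty")
        for name, mapping in (("baseline_hazards", self.baseline_hazards),):
            for g, v in mapping.items():
                vals = v.values() if isinstance(v, dict) else [v]
                if any(x < 0 for x in vals):
                    raise ValueError(f"{name}[{g}] must be >= 0")
        for name, mapping in (("on_treatment_irr", self.on_treatment_irr),
                              ("post_disc_irr", self.post_disc_irr)):
            for g, v in mapping.items():
                vals = v.values() if isinstance(v, dict) else [v]
                if any(x <= 0 for x in vals):
                    raise ValueError(f"{name}[{g}] must be > 0")
        if self.death_rate < 0:
            raise ValueError("death_rate must be >= 0")

    def n_for(self, drug: str) -> int:
        if isinstance(self.n_women_per_drug, dict):
            return int(self.n_women_per_drug.get(drug, 0))
        return int(self.n_women_per_drug)

    def rate_of(self, mapping: dict, group: str, drug: str,
                default: float = 1.0) -> float:
        v = mapping.get(group, default)
        if isinstance(v, dict):
            return float(v.get(drug, default))
        return float(v)


@dataclass
class SyntheticDataset:
    """Claims tables plus ground truth, all dates as integer epoch days."""

    persons: pd.DataFrame
    dispensings: pd.DataFrame
    stays: pd.DataFrame
    ground_truth: pd.DataFrame
    ground_truth_events: pd.DataFrame
    config: SimulationConfig


QUALIFICATION_DAYS = 183  # 6-month treatment requirement
GRACE = 30


def _truncated_normal(rng, mean, sd, low, size):
    out = rng.normal(mean, sd, size)
    bad = out < low
    while bad.any():
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = out < low
    return out


def _simulate_refills(rng, index_day, planned_duration, coverage, stop_excl,
                      jitter_mean, jitter_sd):
    """Refill dates and the chained coverage end for one woman.

    Refills recur while the planned coverage end is short of the planned
    duration; jitter is clipped below the 30-day grace so the realized
    discontinuation equals the planned one.  Dispensing stops at death or
    end of data (``stop_excl``).
    """
    dates = [int(index_day)]
    cov_end = int(index_day) + coverage
    while cov_end - int(index_day) < planned_duration:
        jitter = int(round(np.clip(rng.normal(jitter_mean, jitter_sd),
                                   -min(7, coverage - 1), GRACE - 2)))
        nxt = cov_end + jitter
        if nxt >= stop_excl:
            break
        dates.append(nxt)
        cov_end = max(nxt, cov_end) + coverage
    return dates, cov_end


def generate_dataset(config: SimulationConfig,
                     drugs: tuple[DrugSpec, ...] = DEFAULT_DRUGS
                     ) -> SyntheticDataset:
    """Generate persons, dispensings, stays, and ground truth.

    Deterministic given ``config.seed``.  Event processes are
    piecewise-constant Poisson on ``[index, index+91)``,
    ``[index+91, discontinuation)`` and ``[discontinuation, data_end)``.
    """
    config.validate(drugs)
    rng = np.random.default_rng(config.seed)
    spec_map = specs_by_name(drugs)

    win_lo = to_day(config.inclusion_window[0])
    win_hi = to_day(config.inclusion_window[1])
    data_start = to_day(config.data_start)
    data_end = to_day(config.study_end)          # last observed day
    data_end_excl = data_end + 1

    persons_rows, disp_rows, stay_rows = [], [], []
    gt_rows, gt_event_rows = [], []
    stay_counter = 0
    pid_counter = 0
    frac = config.exclusion_fractions

    for drug in sorted(spec_map):
        spec = spec_map[drug]
        n = config.n_for(drug)
        if n == 0:
            continue
        ages = _truncated_normal(rng, config.age_mean, config.age_sd, 55.0, n)
        young = rng.random(n) < frac.get("age_lt_55", 0.0)
        ages[young] = rng.uniform(45.0, 54.9, int(young.sum()))
        index_days = rng.integers(win_lo, win_hi + 1, n)
        cancer = rng.random(n) < frac.get("cancer_or_paget", 0.0)
        multi = rng.random(n) < frac.get("multi_drug_index", 0.0)
        short = rng.random(n) < frac.get("treated_lt_6m", 0.0)

        dist = config.discontinuation_time_distribution.get(
            drug, {"median_days": 365.0, "sigma": 0.8})
        mu = np.log(dist["median_days"])
        durations = np.exp(rng.normal(mu, dist["sigma"], n))
        durations = np.maximum(durations, QUALIFICATION_DAYS)
        cov = spec.coverage_days_per_unit
        # a planted short stayer gets at most qualification-1 days of plan;
        # unreachable for coverage >= 183 d (one delivery already qualifies)
        short_durations = rng.integers(min(cov, QUALIFICATION_DAYS - 1),
                                       QUALIFICATION_DAYS, n)
        durations = np.where(short, short_durations, durations)

        # death only after the qualification point (see module docstring)
        death_offsets = (QUALIFICATION_DAYS +
                         rng.exponential(1000.0 / max(config.death_rate, 1e-12)
                                         * DAYS_PER_YEAR, n)
                         if config.death_rate > 0 else np.full(n, np.inf))

        for i in range(n):
            pid_counter += 1
            pid = f"W{pid_counter:07d}"
            idx = int(index_days[i])
            birth = idx - int(round(ages[i] * DAYS_PER_YEAR))
            death_day = idx + int(round(death_offsets[i])) \
                if np.isfinite(death_offsets[i]) else None
            if death_day is not None and death_day >= data_end_excl:
                death_day = None
            stop_excl = min(data_end_excl,
                            death_day + 1 if death_day is not None
                            else data_end_excl)

            refills, cov_end = _simulate_refills(
                rng, idx, float(durations[i]), cov, stop_excl,
                config.refill_jitter_mean, config.refill_jitter_sd)
            for d in refills:
                disp_rows.append((pid, d, spec.codes[0], 1))
            if multi[i]:
                other = next(s for nm, s in sorted(spec_map.items())
                             if nm != drug)
                disp_rows.append((pid, idx, other.codes[0], 1))

            # piecewise-constant event process per carrier site
            b1 = idx + 91
            b2 = cov_end            # true discontinuation (exclusive)
            end = stop_excl
            for group, site in GROUP_CARRIER_SITE.items():
                h0 = config.rate_of(config.baseline_hazards, group, drug,
                                    default=0.0)
                if h0 <= 0:
                    continue
                on = config.rate_of(config.on_treatment_irr, group, drug)
                post = config.rate_of(config.post_disc_irr, group, drug)
                per_day = h0 / 1000.0 / DAYS_PER_YEAR
                segs = (
                    (idx, min(b1, b2, end), per_day),
                    (b1, min(b2, end), per_day * on),
                    (b2, end, per_day * post),
                )
                for s0, s1, rate in segs:
                    length = s1 - s0
                    if length <= 0:
                        continue
                    k = rng.poisson(rate * length)
                    if k == 0:
                        continue
                    days = np.sort(rng.integers(s0, s1, k))
                    for d in days:
                        gt_event_rows.append((pid, group, site, int(d)))
                        stay_counter += 1
                        pos = ("associated" if rng.random() <
                               config.associated_position_fraction
                               else "principal")
                        stay_rows.append(
                            (pid, f"H{stay_counter:08d}", int(d), int(d) + 3,
                             SITE_CODE[site], pos, "diagnosis"))
            if cancer[i]:
                stay_counter += 1
                cdate = idx - int(rng.integers(1, 365))
                stay_rows.append((pid, f"H{stay_counter:08d}", cdate,
                                  cdate + 5, "C509", "principal",
                                  "diagnosis"))

            persons_rows.append((pid, "F", birth, death_day, data_start,
                                 data_end))
            gt_rows.append((pid, drug, idx, cov_end - 1,
                            int(durations[i]), death_day,
                            bool(cancer[i]), bool(young[i]),
                            bool(multi[i]), bool(short[i])))

    persons = pd.DataFrame(persons_rows, columns=[
        "person_id", "sex", "birth_date", "death_date", "data_start",
        "data_end"])
    persons["death_date"] = persons["death_date"].astype("Int64")
    dispensings = pd.DataFrame(disp_rows, columns=[
        "person_id", "dispense_date", "drug_code", "units"]).sort_values(
        ["person_id", "dispense_date", "drug_code"], kind="stable",
        ignore_index=True)
    stays = pd.DataFrame(stay_rows, columns=[
        "person_id", "stay_id", "admission_date", "discharge_date", "code",
        "position", "code_type"]).sort_values(
        ["person_id", "admission_date", "stay_id"], kind="stable",
        ignore_index=True)
    ground_truth = pd.DataFrame(gt_rows, columns=[
        "person_id", "drug", "index_date", "disc_date", "planned_duration",
        "death_date", "planted_cancer", "planted_age_lt_55",
        "planted_multi_drug", "planted_short_treatment"])
    ground_truth["death_date"] = ground_truth["death_date"].astype("Int64")
    ground_truth_events = pd.DataFrame(gt_event_rows, columns=[
        "person_id", "site_group", "site", "event_date"]).sort_values(
        ["person_id", "event_date", "site"], kind="stable",
        ignore_index=True)
    return SyntheticDataset(persons, dispensings, stays, ground_truth,
                            ground_truth_events, config)


# ---------------------------------------------------------------------------
# I/O


def write_claims(dataset: SyntheticDataset, directory) -> dict:
    """Write the claims tables and ground truth as CSV with ISO dates.

    Returns a dict of the file paths written.  Output is byte-identical for
    identical datasets.
    """
    os.makedirs(directory, exist_ok=True)
    paths = {}

    persons = dataset.persons.copy()
    for c in ("birth_date", "death_date", "data_start", "data_end"):
        persons[c] = days_to_iso_series(persons[c])
    paths["persons"] = os.path.join(directory, "persons.csv")
    persons.to_csv(paths["persons"], index=False)

    disp = dataset.dispensings.copy()
    disp["dispense_date"] = days_to_iso_series(disp["dispense_date"])
    paths["dispensings"] = os.path.join(directory, "dispensings.csv")
    disp.to_csv(paths["dispensings"], index=False)

    stays = dataset.stays.copy()
    for c in ("admission_date", "discharge_date"):
        stays[c] = days_to_iso_series(stays[c])
    paths["stays"] = os.path.join(directory, "stays.csv")
    stays.to_csv(paths["stays"], index=False)

    gt = dataset.ground_truth.copy()
    for c in ("index_date", "disc_date", "death_date"):
        gt[c] = days_to_iso_series(gt[c])
    paths["ground_truth"] = os.path.join(directory, "ground_truth.csv")
    gt.to_csv(paths["ground_truth"], index=False)

    gte = dataset.ground_truth_events.copy()
    gte["event_date"] = days_to_iso_series(gte["event_date"])
    paths["ground_truth_events"] = os.path.join(directory,
                                                "ground_truth_events.csv")
    gte.to_csv(paths["ground_truth_events"], index=False)
    return paths
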
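"""Eligibility, flow-diagram counts, and hierarchical cohort assignment.

A woman is eligible when at least one of her treatment episodes satisfies
every criterion: female sex, age >= 55 at index, a 3-year look-back and a
2-year follow-up window in the data, at least 6 months of treatment, no
cancer/Paget diagnosis in the pre-index year, and no second study drug
dispensed on the index date.  Exclusion reasons are not mutually exclusive.
Death within the 2-year follow-up does not disqualify — follow-up is
measured on the observation window, and death censors person-time
downstream.

Calendar criteria are fixed day counts: 6 months = 183 days, 1 year = 365,
2 years = 730, 3 years = 1095.

Eligible women are assigned to exactly one cohort by drug hierarchy (most
recently marketed first: denosumab, zoledronic acid, teriparatide, oral
bisphosphonates, raloxifene); the chosen episode's index date becomes the
woman's index date.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dates import DAYS_PER_YEAR
from .episodes import DEFAULT_DRUGS, specs_by_name
from . import fractures

REASONS = ("male", "age_lt_55", "lookback_lt_3y", "followup_lt_2y",
           "treated_lt_6m", "cancer_or_paget", "multi_drug_index")

MONTHS6_DAYS = 183
YEAR_DAYS = 365
YEARS2_DAYS = 730
YEARS3_DAYS = 1095

#: Diagnosis-code prefixes excluding a woman when found in the pre-index
#: year: any malignant neoplasm (C) or Paget's disease of bone (M88).
DEFAULT_EXCLUSION_CODES = ("C", "M88")


@dataclass
class EligibilityParams:
    exclusion_code_prefixes: tuple = DEFAULT_EXCLUSION_CODES
    min_treatment_days: int = MONTHS6_DAYS
    lookback_days: int = YEARS3_DAYS
    followup_days: int = YEARS2_DAYS
    min_age: float = 55.0


def _age_at(index_day, birth_day) -> float:
    return (index_day - birth_day) / DAYS_PER_YEAR


def apply_eligibility(persons: pd.DataFrame, episodes: pd.DataFrame,
                      stays: pd.DataFrame, dispensings: pd.DataFrame,
                      specs=DEFAULT_DRUGS,
                      params: EligibilityParams | None = None):
    """Evaluate eligibility per episode and per woman.

    Returns ``(episode_flags, person_results, flow_counts)``:
    ``episode_flags`` is ``episodes`` with one boolean column per criterion
    and an ``episode_eligible`` column; ``person_results`` has one row per
    woman with her ``eligible`` flag and the union of exclusion reasons over
    her episodes (empty when eligible); ``flow_counts`` is a dict with the
    total, per-reason, and eligible counts.
    """
    params = params or EligibilityParams()
    ep = episodes.merge(persons, on="person_id", how="left")

    ep["male"] = ep["sex"] != "F"
    age = (ep["index_date"] - ep["birth_date"]) / DAYS_PER_YEAR
    ep["age_lt_55"] = age < params.min_age
    ep["lookback_lt_3y"] = (ep["index_date"] - ep["data_start"]
                            ) < params.lookback_days
    # follow-up on the observation window, death allowed
    ep["followup_lt_2y"] = (ep["data_end"] + 1 - ep["index_date"]
                            ) < params.followup_days
    ep["treated_lt_6m"] = (ep["end"] - ep["index_date"]
                           ) < params.min_treatment_days

    # cancer / Paget: any configured code admitted in the pre-index year
    prefixes = tuple(params.exclusion_code_prefixes)
    flagged = set()
    if len(stays):
        sub = stays[stays["code"].str.startswith(prefixes)]
        if len(sub):
            by_person = sub.groupby("person_id")["admission_date"].apply(
                lambda s: s.to_numpy())
            for i, row in ep.iterrows():
                dates = by_person.get(row["person_id"])
                if dates is None:
                    continue
                lo = row["index_date"] - YEAR_DAYS
                if ((dates >= lo) & (dates < row["index_date"])).any():
                    flagged.add(i)
    ep["cancer_or_paget"] = ep.index.isin(flagged)

    # >1 distinct study drug dispensed on the index date
    from .episodes import code_to_drug
    drug_of_code = code_to_drug(specs)
    d = dispensings[dispensings["drug_code"].isin(drug_of_code)].copy()
    d["drug_name"] = d["drug_code"].map(drug_of_code)
    on_date = (d.groupby(["person_id", "dispense_date"])["drug_name"]
                .nunique().rename("n_drugs_on_date"))
    ep = ep.merge(on_date, left_on=["person_id", "index_date"],
                  right_index=True, how="left")
    ep["multi_drug_index"] = ep["n_drugs_on_date"].fillna(0) > 1

    ep["episode_eligible"] = ~ep[list(REASONS)].any(axis=1)

    person_rows = []
    for pid, grp in ep.groupby("person_id", sort=True):
        eligible = bool(grp["episode_eligible"].any())
        if eligible:
            reasons = frozenset()
        else:
            reasons = frozenset(r for r in REASONS if grp[r].any())
        person_rows.append((pid, eligible, reasons))
    person_results = pd.DataFrame(person_rows,
                                  columns=["person_id", "eligible",
                                           "exclusion_reasons"])

    flow = {"total": len(person_results),
            "eligible": int(person_results["eligible"].sum())}
    for r in REASONS:
        flow[f"excluded_{r}"] = int(
            person_results["exclusion_reasons"].map(lambda s: r in s).sum())
    flow["excluded_any"] = flow["total"] - flow["eligible"]
    return ep, person_results, flow


def assign_cohorts(episode_flags: pd.DataFrame, specs=DEFAULT_DRUGS,
                   inclusion_window: tuple[int, int] | None = None
                   ) -> pd.DataFrame:
    """Assign each eligible woman to one cohort by drug hierarchy.

    Among a woman's eligible episodes whose index date lies in the inclusion
    window, the episode of the drug with minimal ``hierarchy_rank`` wins and
    its index date becomes the woman's index date.  Returns one row per
    assigned woman with the chosen episode's columns.
    """
    spec_map = specs_by_name(specs)
    el = episode_flags[episode_flags["episode_eligible"]].copy()
    if inclusion_window is not None:
        el = el[(el["index_date"] >= inclusion_window[0]) &
                (el["index_date"] <= inclusion_window[1])]
    if el.empty:
        return pd.DataFrame(columns=["person_id", "cohort_drug",
                                     "index_date", "end", "end_reason",
                                     "dispensing_count"])
    el["rank"] = el["drug_name"].map(lambda d: spec_map[d].hierarchy_rank)
    el = el.sort_values(["person_id", "rank", "index_date"], kind="stable")
    chosen = el.groupby("person_id", as_index=False).first()
    chosen = chosen.rename(columns={"drug_name": "cohort_drug"})
    return chosen[["person_id", "cohort_drug", "index_date", "end",
                   "end_reason", "dispensing_count"]].reset_index(drop=True)


# ---------------------------------------------------------------------------
# Covariates (descriptive flags and stratification variables)

AGE_CLASSES = (("55-64", 55, 65), ("65-74", 65, 75), ("75-79", 75, 80),
               (">=80", 80, np.inf))

#: Simplified comorbidity score: configurable weights over diagnosis-code
#: prefixes found in the 3-year look-back.  A deliberate simplification of
#: claims-adapted Charlson-style indices.
DEFAULT_COMORBIDITY_WEIGHTS = {
    "diabetes": (("E10", "E11", "E12", "E13", "E14"), 1),
    "cardiovascular": (("I",), 1),
    "rheumatoid_arthritis": (("M05", "M06"), 1),
    "inflammatory_bowel": (("K50", "K51"), 1),
    "lupus": (("M32",), 1),
    "endocrine": (("E0", "E2", "E3"), 1),
    "nervous_system": (("G",), 1),
}

DEFAULT_CODE_CONFIG = {
    "corticosteroid_codes": ("PREDNISONE", "PREDNISOLONE",
                             "METHYLPREDNISOLONE", "CORTICOSTEROID"),
    "vitd_calcium_codes": ("COLECALCIFEROL", "CALCIUM", "VITD"),
    "dementia_prefixes": ("F00", "F01", "F02", "F03", "G30"),
    "nervous_prefixes": ("G",),
    "densitometry_codes": ("DENSITOMETRY", "PAQK"),
    "comorbidity_weights": DEFAULT_COMORBIDITY_WEIGHTS,
}


def age_class(age: float) -> str:
    for label, lo, hi in AGE_CLASSES:
        if lo <= age < hi:
            return label
    return "<55"


def extract_covariates(stays: pd.DataFrame, dispensings: pd.DataFrame,
                       assignment: pd.DataFrame, persons: pd.DataFrame,
                       specs=DEFAULT_DRUGS,
                       code_config: dict | None = None,
                       code_map: fractures.FractureCodeMap | None = None
                       ) -> pd.DataFrame:
    """Descriptive covariates and stratification flags per assigned woman.

    Flags are documented in the look-back windows: fracture history (any /
    hip / vertebral / non-hip-nonvertebral, with the 90-day independence
    rule) and comorbidities over 3 years; prior osteoporosis medication,
    corticosteroid deliveries (``<=3`` vs ``>3``), and vitamin D / calcium
    over 1 year.  The comorbidity score is the weighted sum of configured
    condition flags.
    """
    cfg = dict(DEFAULT_CODE_CONFIG)
    if code_config:
        cfg.update(code_config)
    from .episodes import code_to_drug
    drug_of_code = code_to_drug(specs)
    code_map = code_map or fractures.FractureCodeMap()
    weights = cfg["comorbidity_weights"]

    if assignment.empty:
        return pd.DataFrame(columns=["person_id", "cohort_drug", "age",
                                     "age_class"])
    births = persons.set_index("person_id")["birth_date"]

    # one pass over stays / dispensings: per-person numpy arrays
    raw_events = fractures.identify_raw_events(stays, code_map)
    ev_by = {pid: (g["event_date"].to_numpy(np.int64),
                   g["site"].to_numpy())
             for pid, g in raw_events.groupby("person_id")} \
        if len(raw_events) else {}
    stay_by = {pid: (g["admission_date"].to_numpy(np.int64),
                     g["code"].astype(str).to_numpy(),
                     g["code_type"].astype(str).to_numpy())
               for pid, g in stays.groupby("person_id")} \
        if len(stays) else {}
    disp_by = {pid: (g["dispense_date"].to_numpy(np.int64),
                     g["drug_code"].astype(str).to_numpy())
               for pid, g in dispensings.groupby("person_id")} \
        if len(dispensings) else {}

    cortico = tuple(cfg["corticosteroid_codes"])
    vitd_codes = tuple(cfg["vitd_calcium_codes"])
    dementia = tuple(cfg["dementia_prefixes"])
    nervous = tuple(cfg["nervous_prefixes"])
    densito_codes = tuple(cfg["densitometry_codes"])

    rows = []
    for pid, cohort, idx in zip(assignment["person_id"],
                                assignment["cohort_drug"],
                                assignment["index_date"]):
        idx = int(idx)
        age = _age_at(idx, int(births.loc[pid]))
        row = {"person_id": pid, "cohort_drug": cohort, "age": age,
               "age_class": age_class(age)}

        # fracture history: independence rule applied to look-back events
        dates, sites = ev_by.get(pid, (np.empty(0, np.int64),
                                       np.empty(0, object)))
        in_look = (dates >= idx - YEARS3_DAYS) & (dates < idx)
        dates, sites = dates[in_look], sites[in_look]
        flags = fractures.dedup_flags(dates, sites) if len(dates) \
            else np.empty(0, bool)
        indep_sites = sites[flags]
        n_any = int(flags.sum())
        row["fracture_history_any"] = n_any > 0
        row["fracture_history_class"] = ("0" if n_any == 0 else
                                         "1" if n_any == 1 else ">=2")
        for grp_name in ("hip", "vertebral", "nonhip_nonvertebral"):
            row[f"fracture_history_{grp_name}"] = any(
                grp_name in fractures.assign_groups(s) for s in indep_sites)

        # comorbidity flags and score over the 3-year look-back
        adm, codes, ctypes = stay_by.get(
            pid, (np.empty(0, np.int64), np.empty(0, object),
                  np.empty(0, object)))
        m3 = (adm >= idx - YEARS3_DAYS) & (adm < idx)
        codes3 = codes[m3]
        score = 0
        for cond, (prefixes, w) in weights.items():
            flag = any(c.startswith(prefixes) for c in codes3)
            row[f"comorbidity_{cond}"] = flag
            score += w * int(flag)
        row["comorbidity_score"] = score
        row["dementia"] = any(c.startswith(dementia) for c in codes3)
        row["nervous_system_disorder"] = any(c.startswith(nervous)
                                             for c in codes3)
        row["bone_densitometry"] = any(
            c.startswith(densito_codes)
            for c, t in zip(codes3, ctypes[m3]) if t == "procedure")

        # dispensing-based flags over the 1-year look-back
        ddates, dcodes = disp_by.get(pid, (np.empty(0, np.int64),
                                           np.empty(0, object)))
        m1 = (ddates >= idx - YEAR_DAYS) & (ddates < idx)
        codes1 = dcodes[m1]
        n_cortico = sum(c.startswith(cortico) for c in codes1)
        row["corticosteroid_deliveries"] = int(n_cortico)
        row["corticosteroid_class"] = "<=3" if n_cortico <= 3 else ">3"
        row["prior_osteoporosis_medication"] = any(c in drug_of_code
                                                   for c in codes1)
        row["vitd_calcium"] = any(c.startswith(vitd_codes) for c in codes1)
        rows.append(row)
    return pd.DataFrame(rows)
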
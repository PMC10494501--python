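"""Person-time and event counts per (cohort, site group, window, mode).

Analysis windows are fixed day offsets from the index date, half-open:

    baseline  [0, 91)      — months 0-3, the own-control reference
    m3_12     [91, 365)    — months 3-12
    m3_18     [91, 548)    — months 3-18
    m3_24     [91, 730)    — months 3-24

plus a post-discontinuation window anchored at the discontinuation date.
The three analysis modes differ only in the censoring rule:

    as_treated        min(episode end, death, end of data)
    itt               min(death, study end)
    virtual_exposure  min(episode end + drug carry-over, death, end of data)

A woman contributes person-days to every window she overlaps; baseline
events do not truncate later windows (incidence counting, not
time-to-first-event).  Only independent fracture events are counted.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .dates import DAYS_PER_YEAR
from .episodes import (DEFAULT_DRUGS, END_DISCONTINUATION, code_to_drug,
                       specs_by_name)
from .fractures import GROUPS, events_by_group

WINDOWS = {
    "baseline": (0, 91),
    "m3_12": (91, 365),
    "m3_18": (91, 548),
    "m3_24": (91, 730),
}

RISK_WINDOWS = ("m3_12", "m3_18", "m3_24")

MODES = ("as_treated", "itt", "virtual_exposure")

POST_DISC = "post_disc"


def censor_dates(assignment: pd.DataFrame, persons: pd.DataFrame,
                 mode: str, specs=DEFAULT_DRUGS,
                 study_end: int | None = None) -> pd.Series:
    """Exclusive censoring day per assigned woman under one analysis mode.

    ``assignment`` rows carry the chosen episode (``index_date``, ``end``,
    ``cohort_drug``); ``study_end`` is the last day of the study period
    (required for ``itt``).
    """
    spec_map = specs_by_name(specs)
    df = assignment.merge(persons, on="person_id", how="left")
    death_excl = (df["death_date"] + 1).astype("Float64")
    obs_end_excl = (df["data_end"] + 1).astype("Float64")

    if mode == "as_treated":
        censor = df["end"].astype("Float64")
    elif mode == "itt":
        if study_end is None:
            raise ValueError("itt mode requires a study_end date")
        censor = pd.Series(float(study_end + 1), index=df.index,
                           dtype="Float64")
    elif mode == "virtual_exposure":
        ext = df["cohort_drug"].map(
            lambda d: spec_map[d].virtual_extension_days)
        censor = (df["end"] + ext).astype("Float64")
    else:
        raise ValueError(f"unknown analysis mode: {mode!r}")

    out = censor.copy()
    out = np.fmin(out, death_excl.fillna(np.inf))
    out = np.fmin(out, obs_end_excl)
    # merge reset the row index; restore the caller's for safe assignment
    return pd.Series(np.asarray(out, dtype=float),
                     index=assignment.index, name="censor")


def accumulate(assignment: pd.DataFrame, events: pd.DataFrame,
               persons: pd.DataFrame, mode: str, specs=DEFAULT_DRUGS,
               study_end: int | None = None,
               stratum: str = "all") -> pd.DataFrame:
    """Aggregate person-days and independent events per cell.

    Returns one row per (cohort, site_group, window, mode, stratum) over
    the four index-anchored windows with columns ``events`` and
    ``person_days``.  Window person-time for a woman is the overlap of the
    window with ``[index, censor)``; an event is counted when its date lies
    in that same intersection.
    """
    rows = []
    if assignment.empty:
        return pd.DataFrame(columns=["cohort", "site_group", "window",
                                     "mode", "stratum", "events",
                                     "person_days"])
    a = assignment.copy()
    a["censor"] = censor_dates(a, persons, mode, specs, study_end)
    idx = a["index_date"].to_numpy(dtype=float)
    cen = a["censor"].to_numpy(dtype=float)

    indep = events[events["independent"]] if len(events) else events
    grouped = events_by_group(indep) if len(indep) else None
    if grouped is not None and len(grouped):
        ev = grouped.merge(a[["person_id", "cohort_drug", "index_date",
                              "censor"]], on="person_id", how="inner")
    else:
        ev = None

    for window, (s, e) in WINDOWS.items():
        lo = idx + s
        hi = np.minimum(cen, idx + e)
        pdays = np.maximum(0.0, hi - lo)
        pt = pd.DataFrame({"cohort": a["cohort_drug"], "pd": pdays})
        pt_sum = pt.groupby("cohort")["pd"].sum()
        for group in GROUPS:
            if ev is not None:
                m = ((ev["site_group"] == group) &
                     (ev["event_date"] >= ev["index_date"] + s) &
                     (ev["event_date"] < np.minimum(
                         ev["censor"], ev["index_date"] + e)))
                ev_sum = ev[m].groupby("cohort_drug").size()
            else:
                ev_sum = pd.Series(dtype=int)
            for cohort, p in pt_sum.items():
                rows.append({"cohort": cohort, "site_group": group,
                             "window": window, "mode": mode,
                             "stratum": stratum,
                             "events": int(ev_sum.get(cohort, 0)),
                             "person_days": float(p)})
    out = pd.DataFrame(rows)
    bad = (out["person_days"] == 0) & (out["events"] > 0)
    if bad.any():  # cannot happen: events require in-interval dates
        raise AssertionError("events counted in a zero person-time cell")
    return out


def reinitiation_dates(assignment: pd.DataFrame,
                       dispensings: pd.DataFrame,
                       specs=DEFAULT_DRUGS) -> pd.Series:
    """First dispensing of any study drug after the discontinuation date.

    Indexed like ``assignment``; NaN when the woman never reinitiates.
    The discontinuation date here is the episode's exclusive end, so a
    same-day redelivery on the last covered day does not count.
    """
    drug_of_code = code_to_drug(specs)
    d = dispensings[dispensings["drug_code"].isin(drug_of_code)]
    by_person = {pid: grp["dispense_date"].to_numpy(dtype=np.int64)
                 for pid, grp in d.groupby("person_id")}
    out = []
    for _, row in assignment.iterrows():
        dates = by_person.get(row["person_id"])
        if dates is None:
            out.append(np.nan)
            continue
        later = dates[dates >= row["end"]]
        out.append(float(later.min()) if later.size else np.nan)
    return pd.Series(out, index=assignment.index, name="reinit")


def accumulate_post_disc(assignment: pd.DataFrame, events: pd.DataFrame,
                         persons: pd.DataFrame, dispensings: pd.DataFrame,
                         specs=DEFAULT_DRUGS,
                         stratum: str = "all") -> pd.DataFrame:
    """Post-discontinuation window cells for women who discontinued.

    The window runs from the discontinuation (the day after the last
    covered day, keeping intervals half-open and disjoint from the
    on-treatment time) until reinitiation of any study drug, death, or end
    of data.  Women whose episode ended for another reason are skipped.
    """
    disc = assignment[assignment["end_reason"] == END_DISCONTINUATION].copy()
    if disc.empty:
        return pd.DataFrame(columns=["cohort", "site_group", "window",
                                     "mode", "stratum", "events",
                                     "person_days"])
    pers = persons.set_index("person_id")
    disc["reinit"] = reinitiation_dates(disc, dispensings, specs)
    death_excl = disc["person_id"].map(
        lambda p: float(pers.loc[p, "death_date"]) + 1
        if pd.notna(pers.loc[p, "death_date"]) else np.inf)
    obs_excl = disc["person_id"].map(
        lambda p: float(pers.loc[p, "data_end"]) + 1)
    disc["pd_start"] = disc["end"].astype(float)
    disc["pd_end"] = np.fmin(np.fmin(disc["reinit"].fillna(np.inf),
                                     death_excl), obs_excl)
    disc["pdays"] = np.maximum(0.0, disc["pd_end"] - disc["pd_start"])

    indep = events[events["independent"]] if len(events) else events
    grouped = events_by_group(indep) if len(indep) else None
    rows = []
    pt_sum = disc.groupby("cohort_drug")["pdays"].sum()
    for group in GROUPS:
        if grouped is not None and len(grouped):
            ev = grouped[grouped["site_group"] == group].merge(
                disc[["person_id", "cohort_drug", "pd_start", "pd_end"]],
                on="person_id", how="inner")
            m = ((ev["event_date"] >= ev["pd_start"]) &
                 (ev["event_date"] < ev["pd_end"]))
            ev_sum = ev[m].groupby("cohort_drug").size()
        else:
            ev_sum = pd.Series(dtype=int)
        for cohort, p in pt_sum.items():
            rows.append({"cohort": cohort, "site_group": group,
                         "window": POST_DISC, "mode": "as_treated",
                         "stratum": stratum,
                         "events": int(ev_sum.get(cohort, 0)),
                         "person_days": float(p)})
    return pd.DataFrame(rows)


def select_stratum(assignment: pd.DataFrame, covariates: pd.DataFrame,
                   variable: str, value) -> pd.DataFrame:
    """Restrict an assignment table to one stratum of a covariate."""
    keep = covariates.loc[covariates[variable] == value, "person_id"]
    return assignment[assignment["person_id"].isin(set(keep))].copy()


def posthoc_early_discontinuers(episode_flags: pd.DataFrame,
                                events: pd.DataFrame,
                                persons: pd.DataFrame,
                                dispensings: pd.DataFrame,
                                specs=DEFAULT_DRUGS,
                                drug: str = "oral_bisphosphonate",
                                qualification_days: int = 183
                                ) -> pd.DataFrame:
    """Cells for women who discontinued ``drug`` within 6 months of index.

    These women fail the minimum-treatment criterion and sit outside the
    main cohorts; their fracture incidence is compared between the baseline
    period ``[0, 91)`` and the months 3-6 period ``[91, 183)``, with
    person-time censored at reinitiation, death, or end of data (the women
    are off treatment for most of the comparison window, so treatment
    discontinuation itself does not censor).
    """
    sel = episode_flags[
        (episode_flags["drug_name"] == drug) &
        (episode_flags["end_reason"] == END_DISCONTINUATION) &
        ((episode_flags["end"] - episode_flags["index_date"])
         < qualification_days) &
        ~episode_flags[["male", "age_lt_55", "lookback_lt_3y",
                        "followup_lt_2y", "cancer_or_paget",
                        "multi_drug_index"]].any(axis=1)].copy()
    cols = ["cohort", "site_group", "window", "mode", "stratum", "events",
            "person_days"]
    if sel.empty:
        return pd.DataFrame(columns=cols)
    sel = sel.rename(columns={"drug_name": "cohort_drug"})
    sel["reinit"] = reinitiation_dates(sel, dispensings, specs)
    pers = persons.set_index("person_id")
    death_excl = sel["person_id"].map(
        lambda p: float(pers.loc[p, "death_date"]) + 1
        if pd.notna(pers.loc[p, "death_date"]) else np.inf)
    obs_excl = sel["person_id"].map(
        lambda p: float(pers.loc[p, "data_end"]) + 1)
    sel["censor"] = np.fmin(np.fmin(sel["reinit"].fillna(np.inf),
                                    death_excl), obs_excl)

    indep = events[events["independent"]] if len(events) else events
    grouped = events_by_group(indep) if len(indep) else None
    rows = []
    for window, (s, e) in (("baseline", (0, 91)), ("m3_6", (91, 183))):
        lo = sel["index_date"] + s
        hi = np.fmin(sel["censor"], sel["index_date"] + e)
        pdays = float(np.maximum(0.0, hi - lo).sum())
        for group in GROUPS:
            n_ev = 0
            if grouped is not None and len(grouped):
                ev = grouped[grouped["site_group"] == group].merge(
                    sel[["person_id", "index_date", "censor"]],
                    on="person_id", how="inner")
                m = ((ev["event_date"] >= ev["index_date"] + s) &
                     (ev["event_date"] < np.fmin(ev["censor"],
                                                 ev["index_date"] + e)))
                n_ev = int(m.sum())
            rows.append({"cohort": f"{drug}_early_disc", "site_group": group,
                         "window": window, "mode": "posthoc",
                         "stratum": "all", "events": n_ev,
                         "person_days": pdays})
    return pd.DataFrame(rows, columns=cols)


def person_years(person_days) -> float:
    return float(person_days) / DAYS_PER_YEAR
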
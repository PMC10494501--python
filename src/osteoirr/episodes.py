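"""Treatment-episode construction from dispensing claims.

A treatment episode is a continuous coverage interval for one (woman, drug)
pair.  It starts at an index date — the first delivery with no dispensing of
the same drug (same *class* for oral bisphosphonates) in the preceding
365 days — and chains deliveries while each refill arrives no later than
30 days (the grace period) after the end of the period covered by the
previous deliveries.  Coverage stockpiles: an early refill starts counting
from the end of the current coverage, not from its dispense date.

Episodes end for one of four reasons: ``discontinuation`` (no refill within
the grace period; the episode's last day is the last day covered by the last
delivery), ``switch`` (another study drug is initiated before
discontinuation), ``death``, or ``end_of_followup``.

Internally every interval is half-open ``[start, end)``; the printed
discontinuation date is ``end - 1``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dates import series_to_days

GRACE_DAYS = 30
WASHOUT_DAYS = 365

END_DISCONTINUATION = "discontinuation"
END_SWITCH = "switch"
END_DEATH = "death"
END_FOLLOWUP = "end_of_followup"


@dataclass(frozen=True)
class DrugSpec:
    """Per-drug configuration.

    ``hierarchy_rank`` orders cohort assignment (1 = assigned first, the most
    recently marketed product).  ``virtual_extension_days`` is the carry-over
    added to the exposed period in the virtual-exposure sensitivity analysis:
    365 days for bisphosphonates (including zoledronic acid), 30 days
    otherwise.  ``washout_class`` groups drugs that share the new-user
    washout; the three oral bisphosphonates share one class, every other
    product is its own class.
    """

    name: str
    codes: tuple[str, ...]
    drug_class: str
    coverage_days_per_unit: int
    hierarchy_rank: int
    virtual_extension_days: int

    def __post_init__(self):
        if self.coverage_days_per_unit < 1:
            raise ValueError("coverage_days_per_unit must be >= 1")
        if self.virtual_extension_days < 0:
            raise ValueError("virtual_extension_days must be >= 0")


#: Default study drugs.  Coverage per unit is an assumption of the pipeline
#: (days supplied is not carried in dispensing claims): one unit of an oral
#: bisphosphonate or raloxifene covers a 30-day pack-month, denosumab is
#: injected twice yearly, zoledronic acid once yearly, and a teriparatide
#: pen covers 28 days.
DEFAULT_DRUGS: tuple[DrugSpec, ...] = (
    DrugSpec("denosumab", ("DENOSUMAB",), "denosumab", 182, 1, 30),
    DrugSpec("zoledronic_acid", ("ZOLEDRONIC",), "zoledronic_acid", 365, 2, 365),
    DrugSpec("teriparatide", ("TERIPARATIDE",), "teriparatide", 28, 3, 30),
    DrugSpec("oral_bisphosphonate",
             ("ALENDRONATE", "RISEDRONATE", "IBANDRONATE"),
             "oral_bisphosphonate", 30, 4, 365),
    DrugSpec("raloxifene", ("RALOXIFENE",), "raloxifene", 30, 5, 30),
)


def specs_by_name(specs=DEFAULT_DRUGS) -> dict[str, DrugSpec]:
    out = {s.name: s for s in specs}
    ranks = [s.hierarchy_rank for s in specs]
    if len(set(ranks)) != len(ranks):
        raise ValueError("hierarchy ranks must be unique across drug specs")
    return out


def code_to_drug(specs=DEFAULT_DRUGS) -> dict[str, str]:
    return {c: s.name for s in specs for c in s.codes}


# ---------------------------------------------------------------------------
# Claims readers


def _require_columns(df: pd.DataFrame, cols, fname: str):
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{fname}: missing column(s) {missing}")


def read_persons(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"person_id": str}, keep_default_na=False)
    _require_columns(df, ["person_id", "sex", "birth_date", "death_date",
                          "data_start", "data_end"], "persons")
    for col in ("birth_date", "death_date", "data_start", "data_end"):
        df[col] = series_to_days(df[col], context=f"persons.{col}")
    if (df["data_start"] >= df["data_end"]).any():
        raise ValueError("persons: data_start must precede data_end")
    return df


def read_dispensings(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"person_id": str, "drug_code": str},
                     keep_default_na=False)
    _require_columns(df, ["person_id", "dispense_date", "drug_code", "units"],
                     "dispensings")
    df["dispense_date"] = series_to_days(df["dispense_date"],
                                         context="dispensings.dispense_date")
    df["units"] = pd.to_numeric(df["units"]).astype(int)
    if (df["units"] < 1).any():
        raise ValueError("dispensings: units must be >= 1")
    return df.sort_values(["person_id", "dispense_date"], kind="stable",
                          ignore_index=True)


def read_stays(path) -> pd.DataFrame:
    """Read hospital stays, one row per (stay, code)."""
    df = pd.read_csv(path, dtype={"person_id": str, "stay_id": str,
                                  "code": str, "position": str,
                                  "code_type": str}, keep_default_na=False)
    _require_columns(df, ["person_id", "stay_id", "admission_date",
                          "discharge_date", "code", "position", "code_type"],
                     "stays")
    for col in ("admission_date", "discharge_date"):
        df[col] = series_to_days(df[col], context=f"stays.{col}")
    if len(df) and (df["admission_date"] > df["discharge_date"]).any():
        raise ValueError("stays: admission_date must not exceed discharge_date")
    return df.sort_values(["person_id", "admission_date"], kind="stable",
                          ignore_index=True)


def read_claims(directory):
    """Load the three claims tables from ``directory``.

    Returns ``(persons, dispensings, stays)`` as typed DataFrames with all
    date columns converted to integer epoch days.
    """
    import os
    persons = read_persons(os.path.join(directory, "persons.csv"))
    dispensings = read_dispensings(os.path.join(directory, "dispensings.csv"))
    stays = read_stays(os.path.join(directory, "stays.csv"))
    return persons, dispensings, stays


# ---------------------------------------------------------------------------
# Index dates (new-user rule)


def find_index_dates(dispensings: pd.DataFrame, specs=DEFAULT_DRUGS,
                     inclusion_window: tuple[int, int] | None = None
                     ) -> pd.DataFrame:
    """Find candidate index events: the first in-window delivery of each drug
    with no dispensing of the same drug (same class for oral bisphosphonates)
    in the preceding 365 days.

    ``inclusion_window`` is a half-open ``(start_day, end_day_exclusive)``
    pair; ``None`` means no calendar restriction.  Returns a DataFrame with
    columns ``person_id, drug_name, index_date``.
    """
    spec_map = specs_by_name(specs)
    drug_of_code = code_to_drug(specs)
    df = dispensings[dispensings["drug_code"].isin(drug_of_code)].copy()
    if df.empty:
        return pd.DataFrame(columns=["person_id", "drug_name", "index_date"])
    df["drug_name"] = df["drug_code"].map(drug_of_code)
    df["washout_key"] = df["drug_name"].map(
        lambda n: spec_map[n].drug_class)
    df = df.sort_values(["person_id", "washout_key", "dispense_date"],
                        kind="stable", ignore_index=True)

    # fast path: the first in-window delivery of each (person, class) whose
    # nearest prior same-class dispensing (if any) is > 365 days back
    keys = ["person_id", "washout_key"]
    df["prev_date"] = df.groupby(keys)["dispense_date"].shift(1)
    if inclusion_window is not None:
        in_win = (df["dispense_date"] >= inclusion_window[0]) & \
                 (df["dispense_date"] < inclusion_window[1])
    else:
        in_win = pd.Series(True, index=df.index)
    first = df[in_win].groupby(keys, as_index=False).first()
    clean = first["prev_date"].isna() | (
        first["dispense_date"] - first["prev_date"] > WASHOUT_DAYS)

    rows = [(r["person_id"], r["drug_name"], int(r["dispense_date"]))
            for _, r in first[clean].iterrows()]

    # slow path: the first in-window delivery carries a recent prior; scan
    # later in-window deliveries for one that re-satisfies the washout
    retry = first.loc[~clean, keys]
    if len(retry):
        sub = df.merge(retry, on=keys)
        for (pid, key), grp in sub.groupby(keys, sort=True):
            dates = grp["dispense_date"].to_numpy(dtype=np.int64)
            for j, d in enumerate(dates):
                if inclusion_window is not None and not (
                        inclusion_window[0] <= d < inclusion_window[1]):
                    continue
                prior = dates[(dates < d) & (dates >= d - WASHOUT_DAYS)]
                if prior.size == 0:
                    rows.append((pid, grp["drug_name"].iloc[j], int(d)))
                    break
    out = pd.DataFrame(rows, columns=["person_id", "drug_name",
                                      "index_date"])
    return out.sort_values(["person_id", "drug_name"], kind="stable",
                           ignore_index=True)


# ---------------------------------------------------------------------------
# Episode chaining


def build_episode(dispensings_for_drug: pd.DataFrame, spec: DrugSpec,
                  person: pd.Series, index_date: int,
                  grace_days: int = GRACE_DAYS) -> dict:
    """Chain deliveries of one drug for one woman into a treatment episode.

    ``dispensings_for_drug`` holds the woman's dispensings of this drug (any
    date; rows before ``index_date`` are ignored).  Coverage of a delivery is
    ``[start, start + units * coverage_days)`` with
    ``start = max(dispense_date, previous coverage end)``.  The episode
    extends while the next delivery arrives within ``grace_days`` after the
    current coverage end, then ends by discontinuation — or earlier, by death
    or end of observation.

    Returns a dict episode record with half-open ``end`` (exclusive).
    """
    dates = dispensings_for_drug.loc[
        dispensings_for_drug["dispense_date"] >= index_date,
        "dispense_date"].to_numpy(dtype=np.int64)
    units = dispensings_for_drug.loc[
        dispensings_for_drug["dispense_date"] >= index_date,
        "units"].to_numpy(dtype=np.int64)
    if dates.size == 0:
        raise ValueError("no dispensings at or after the index date")
    order = np.argsort(dates, kind="stable")
    dates, units = dates[order], units[order]
    if dates[0] != index_date:
        raise ValueError("dispensings must begin at the index event")

    cov_end = int(index_date)
    n_disp = 0
    for d, u in zip(dates, units):
        if n_disp and d > cov_end + grace_days:
            break
        start = max(int(d), cov_end)
        cov_end = start + int(u) * spec.coverage_days_per_unit
        n_disp += 1

    end = cov_end
    reason = END_DISCONTINUATION
    death = person.get("death_date")
    obs_end_excl = int(person["data_end"]) + 1
    if pd.notna(death) and int(death) + 1 < end:
        end, reason = int(death) + 1, END_DEATH
    if obs_end_excl < end:
        end, reason = obs_end_excl, END_FOLLOWUP
    return {
        "person_id": person["person_id"],
        "drug_name": spec.name,
        "index_date": int(index_date),
        "end": int(end),
        "end_reason": reason,
        "dispensing_count": int(n_disp),
    }


def build_episodes(persons: pd.DataFrame, dispensings: pd.DataFrame,
                   index_events: pd.DataFrame, specs=DEFAULT_DRUGS,
                   grace_days: int = GRACE_DAYS) -> pd.DataFrame:
    """Build one episode per candidate index event (vectorised single pass).

    Equivalent to calling :func:`build_episode` per (person, drug) but runs
    in one sweep over the sorted dispensing table.
    """
    spec_map = specs_by_name(specs)
    drug_of_code = code_to_drug(specs)
    disp = dispensings[dispensings["drug_code"].isin(drug_of_code)].copy()
    disp["drug_name"] = disp["drug_code"].map(drug_of_code)
    disp = disp.sort_values(["person_id", "drug_name", "dispense_date"],
                            kind="stable")

    idx = index_events.set_index(["person_id", "drug_name"])["index_date"]
    pers = persons.set_index("person_id")

    records: list[dict] = []
    for (pid, drug), grp in disp.groupby(["person_id", "drug_name"],
                                         sort=True):
        try:
            index_date = int(idx.loc[(pid, drug)])
        except KeyError:
            continue
        spec = spec_map[drug]
        dates = grp["dispense_date"].to_numpy(dtype=np.int64)
        units = grp["units"].to_numpy(dtype=np.int64)
        mask = dates >= index_date
        dates, units = dates[mask], units[mask]
        cov_end = index_date
        n_disp = 0
        for d, u in zip(dates, units):
            if n_disp and d > cov_end + grace_days:
                break
            start = max(int(d), cov_end)
            cov_end = start + int(u) * spec.coverage_days_per_unit
            n_disp += 1
        end, reason = cov_end, END_DISCONTINUATION
        p = pers.loc[pid]
        death = p["death_date"]
        if pd.notna(death) and int(death) + 1 < end:
            end, reason = int(death) + 1, END_DEATH
        obs_end_excl = int(p["data_end"]) + 1
        if obs_end_excl < end:
            end, reason = obs_end_excl, END_FOLLOWUP
        records.append({"person_id": pid, "drug_name": drug,
                        "index_date": index_date, "end": int(end),
                        "end_reason": reason, "dispensing_count": n_disp})
    cols = ["person_id", "drug_name", "index_date", "end", "end_reason",
            "dispensing_count"]
    return pd.DataFrame(records, columns=cols)


def detect_switch(episodes: pd.DataFrame) -> pd.DataFrame:
    """Censor episodes at initiation of a different study drug.

    If another drug's index date falls strictly inside an episode's
    ``[index, end)`` interval, the episode ends the day before that
    initiation (``end`` = the new drug's first delivery day, exclusive) with
    reason ``switch``.  Episodes ending by death keep their death end when it
    precedes the switch.
    """
    if episodes.empty:
        return episodes.copy()
    out = episodes.copy()
    for pid, grp in episodes.groupby("person_id", sort=False):
        if len(grp) < 2:
            continue
        for i, row in grp.iterrows():
            others = grp.loc[grp["drug_name"] != row["drug_name"],
                             "index_date"]
            starts = others[(others > row["index_date"]) &
                            (others < row["end"])]
            if len(starts):
                out.loc[i, "end"] = int(starts.min())
                out.loc[i, "end_reason"] = END_SWITCH
    return out
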
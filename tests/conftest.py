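"""Shared fixtures and brute-force oracles.

The oracles re-derive episode coverage and window person-time by explicit
day-by-day simulation, independently of the interval arithmetic used by the
package, so equivalence tests are meaningful.
"""

import numpy as np
import pandas as pd
import pytest

import osteoirr as o
from osteoirr.dates import to_day


@pytest.fixture(scope="session")
def small_config():
    return o.SimulationConfig(n_women_per_drug=200, seed=42)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return o.generate_dataset(small_config)


@pytest.fixture(scope="session")
def claims_dir(small_dataset, tmp_path_factory):
    d = tmp_path_factory.mktemp("claims")
    o.write_claims(small_dataset, str(d))
    return str(d)


@pytest.fixture(scope="session")
def pipeline_bundle(claims_dir, tmp_path_factory):
    out = tmp_path_factory.mktemp("results")
    cfg = o.StudyConfig(claims_dir=claims_dir, output_dir=str(out))
    return o.run_pipeline(cfg)


def make_persons(n=1, birth="1950-01-01", start="2010-01-01",
                 end="2018-12-31", death=None, sex="F"):
    """Tiny persons table with integer-day columns, ids P1..Pn."""
    rows = []
    for i in range(n):
        rows.append({
            "person_id": f"P{i + 1}",
            "sex": sex,
            "birth_date": to_day(birth),
            "death_date": to_day(death) if death else pd.NA,
            "data_start": to_day(start),
            "data_end": to_day(end),
        })
    df = pd.DataFrame(rows)
    df["death_date"] = df["death_date"].astype("Int64")
    return df


def make_dispensings(records):
    """records: iterable of (person_id, iso_date, drug_code[, units])."""
    rows = []
    for rec in records:
        pid, date, code = rec[:3]
        units = rec[3] if len(rec) > 3 else 1
        rows.append({"person_id": pid, "dispense_date": to_day(date),
                     "drug_code": code, "units": units})
    df = pd.DataFrame(rows, columns=["person_id", "dispense_date",
                                     "drug_code", "units"])
    return df.sort_values(["person_id", "dispense_date"],
                          ignore_index=True)


def make_stays(records):
    """records: iterable of (person_id, iso_date, code[, position])."""
    rows = []
    for i, rec in enumerate(records):
        pid, date, code = rec[:3]
        pos = rec[3] if len(rec) > 3 else "principal"
        rows.append({"person_id": pid, "stay_id": f"H{i + 1}",
                     "admission_date": to_day(date),
                     "discharge_date": to_day(date) + 3, "code": code,
                     "position": pos, "code_type": "diagnosis"})
    cols = ["person_id", "stay_id", "admission_date", "discharge_date",
            "code", "position", "code_type"]
    return pd.DataFrame(rows, columns=cols)


EMPTY_STAYS = make_stays([])


def brute_force_coverage_end(deliveries, coverage_days, index_day,
                             grace_days=30):
    """Day-by-day pill-supply simulation of one woman's episode.

    ``deliveries`` maps day -> units.  Each delivered unit adds
    ``coverage_days`` days of supply; one unit-day is consumed per covered
    day; an uncovered streak longer than the grace period discontinues the
    episode and later deliveries are ignored.  Returns the exclusive
    coverage end (last covered day + 1).
    """
    horizon = (max(deliveries) +
               sum(deliveries.values()) * coverage_days + grace_days + 2)
    supply = 0
    last_covered = None
    gap = 0
    for day in range(index_day, horizon):
        if day in deliveries:
            supply += deliveries[day] * coverage_days
        if supply > 0:
            supply -= 1
            last_covered = day
            gap = 0
        else:
            gap += 1
            if gap > grace_days:
                break
    assert last_covered is not None
    return last_covered + 1


def brute_force_person_days(index_day, censor_day, windows):
    """Day-count loop over one woman's timeline, per window."""
    out = {}
    for label, (s, e) in windows.items():
        n = 0
        for day in range(index_day, int(censor_day)):
            if s <= day - index_day < e:
                n += 1
        out[label] = n
    return out


def count_events_in_window(event_days, index_day, censor_day, s, e):
    return sum(1 for d in event_days
               if s <= d - index_day < e and d < censor_day)
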
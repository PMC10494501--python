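"""Window person-time, censoring modes, strata, post hoc analysis."""

import numpy as np
import pandas as pd
import pytest

import osteoirr as o
from osteoirr import persontime
from osteoirr.dates import to_day

from conftest import (EMPTY_STAYS, brute_force_person_days,
                      count_events_in_window, make_dispensings,
                      make_persons)

IDX = to_day("2014-06-01")
STUDY_END = to_day("2018-12-31")


def assignment_df(rows):
    return pd.DataFrame(rows, columns=["person_id", "cohort_drug",
                                       "index_date", "end", "end_reason",
                                       "dispensing_count"])


def events_df(records):
    df = pd.DataFrame(records, columns=["person_id", "event_date", "site"])
    df["independent"] = True
    return df


NO_EVENTS = events_df([])


class TestCensorDates:
    def test_as_treated_stops_at_discontinuation(self):
        a = assignment_df([("P1", "denosumab", IDX, IDX + 300,
                            "discontinuation", 2)])
        c = o.censor_dates(a, make_persons(), "as_treated")
        assert c.iloc[0] == IDX + 300

    def test_virtual_exposure_extends_oral_bp_by_365(self):
        a = assignment_df([("P1", "oral_bisphosphonate", IDX, IDX + 300,
                            "discontinuation", 10)])
        c = o.censor_dates(a, make_persons(), "virtual_exposure")
        assert c.iloc[0] == IDX + 300 + 365

    def test_virtual_exposure_extends_denosumab_by_30(self):
        a = assignment_df([("P1", "denosumab", IDX, IDX + 300,
                            "discontinuation", 2)])
        c = o.censor_dates(a, make_persons(), "virtual_exposure")
        assert c.iloc[0] == IDX + 300 + 30

    def test_itt_runs_to_study_end(self):
        a = assignment_df([("P1", "denosumab", IDX, IDX + 300,
                            "discontinuation", 2)])
        c = o.censor_dates(a, make_persons(), "itt", study_end=STUDY_END)
        assert c.iloc[0] == STUDY_END + 1

    def test_itt_death_before_study_end(self):
        persons = make_persons(death="2015-10-14")  # day 500 after index
        a = assignment_df([("P1", "denosumab", IDX, IDX + 300,
                            "discontinuation", 2)])
        c = o.censor_dates(a, persons, "itt", study_end=STUDY_END)
        assert c.iloc[0] == to_day("2015-10-14") + 1

    def test_death_caps_virtual_extension(self):
        persons = make_persons(death="2014-12-01")
        a = assignment_df([("P1", "oral_bisphosphonate", IDX,
                            to_day("2014-12-01") + 1, "death", 6)])
        c = o.censor_dates(a, persons, "virtual_exposure")
        assert c.iloc[0] == to_day("2014-12-01") + 1

    def test_unknown_mode_rejected(self):
        a = assignment_df([("P1", "denosumab", IDX, IDX + 300,
                            "discontinuation", 2)])
        with pytest.raises(ValueError):
            o.censor_dates(a, make_persons(), "per_protocol")


class TestAccumulate:
    def test_full_windows_person_days(self):
        a = assignment_df([("P1", "denosumab", IDX, IDX + 800,
                            "discontinuation", 5)])
        cells = o.accumulate(a, NO_EVENTS, make_persons(), "as_treated")
        by_win = cells[cells["site_group"] == "hip"].set_index("window")
        assert by_win.loc["baseline", "person_days"] == 91
        assert by_win.loc["m3_12", "person_days"] == 274
        assert by_win.loc["m3_18", "person_days"] == 457
        assert by_win.loc["m3_24", "person_days"] == 639
        assert (cells["events"] == 0).all()

    def test_discontinuation_day_200_truncates_m3_12(self):
        a = assignment_df([("P1", "denosumab", IDX, IDX + 200,
                            "discontinuation", 2)])
        cells = o.accumulate(a, NO_EVENTS, make_persons(), "as_treated")
        by_win = cells[cells["site_group"] == "hip"].set_index("window")
        assert by_win.loc["m3_12", "person_days"] == 109
        assert by_win.loc["baseline", "person_days"] == 91

    def test_baseline_event_counted_only_in_baseline(self):
        a = assignment_df([("P1", "denosumab", IDX, IDX + 800,
                            "discontinuation", 5)])
        ev = events_df([("P1", IDX + 50, "hip")])
        cells = o.accumulate(a, ev, make_persons(), "as_treated")
        hip = cells[cells["site_group"] == "hip"].set_index("window")
        assert hip.loc["baseline", "events"] == 1
        assert hip.loc["m3_12", "events"] == 0
        assert hip.loc["m3_24", "events"] == 0

    def test_event_after_censor_not_counted(self):
        a = assignment_df([("P1", "denosumab", IDX, IDX + 200,
                            "discontinuation", 2)])
        ev = events_df([("P1", IDX + 250, "hip")])
        cells = o.accumulate(a, ev, make_persons(), "as_treated")
        assert (cells["events"] == 0).all()

    def test_non_independent_events_not_counted(self):
        a = assignment_df([("P1", "denosumab", IDX, IDX + 800,
                            "discontinuation", 5)])
        ev = events_df([("P1", IDX + 100, "hip"), ("P1", IDX + 120, "hip")])
        ev.loc[1, "independent"] = False
        cells = o.accumulate(a, ev, make_persons(), "as_treated")
        hip = cells[cells["site_group"] == "hip"].set_index("window")
        assert hip.loc["m3_12", "events"] == 1

    def test_wrist_event_counted_in_both_groups(self):
        a = assignment_df([("P1", "denosumab", IDX, IDX + 800,
                            "discontinuation", 5)])
        ev = events_df([("P1", IDX + 100, "wrist_forearm")])
        cells = o.accumulate(a, ev, make_persons(), "as_treated")
        m = cells[cells["window"] == "m3_12"].set_index("site_group")
        assert m.loc["wrist_forearm", "events"] == 1
        assert m.loc["nonhip_nonvertebral", "events"] == 1
        assert m.loc["hip", "events"] == 0

    def test_mode_person_time_ordering(self, pipeline_bundle):
        """ITT >= virtual exposure >= as-treated person-time, cell-wise."""
        cells = pipeline_bundle["cells"]
        keys = ["cohort", "site_group", "window", "stratum"]
        sub = cells[cells["window"] != "post_disc"]
        wide = sub.pivot_table(index=keys, columns="mode",
                               values="person_days")
        assert (wide["itt"] >= wide["virtual_exposure"] - 1e-9).all()
        assert (wide["virtual_exposure"] >= wide["as_treated"] - 1e-9).all()

    def test_window_nesting_monotone(self, pipeline_bundle):
        cells = pipeline_bundle["cells"]
        keys = ["cohort", "site_group", "mode", "stratum"]
        wide_pd = cells.pivot_table(index=keys, columns="window",
                                    values="person_days")
        wide_ev = cells.pivot_table(index=keys, columns="window",
                                    values="events")
        for a, b in (("m3_12", "m3_18"), ("m3_18", "m3_24")):
            assert (wide_pd[a] <= wide_pd[b] + 1e-9).all()
            assert (wide_ev[a] <= wide_ev[b]).all()

    def test_person_time_conservation(self, pipeline_bundle):
        """baseline + m3_24 person-days never exceed censor - index."""
        b = pipeline_bundle
        a = b["assignment"].copy()
        a["censor"] = o.censor_dates(a, b["persons"], "as_treated")
        total = float((a["censor"] - a["index_date"]).sum())
        cells = b["cells"]
        at = cells[(cells["mode"] == "as_treated") &
                   (cells["stratum"] == "all") &
                   (cells["site_group"] == "hip")]
        spent = at[at["window"].isin(["baseline", "m3_24"])][
            "person_days"].sum()
        assert spent <= total + 1e-9


class TestPostDisc:
    def test_window_runs_to_reinitiation(self):
        a = assignment_df([("P1", "denosumab", IDX, IDX + 364,
                            "discontinuation", 2)])
        disp = make_dispensings([("P1", "2014-06-01", "DENOSUMAB"),
                                 ("P1", "2016-06-01", "RALOXIFENE")])
        cells = o.accumulate_post_disc(a, NO_EVENTS, make_persons(), disp)
        hip = cells[cells["site_group"] == "hip"].iloc[0]
        reinit = to_day("2016-06-01")
        assert hip["person_days"] == reinit - (IDX + 364)

    def test_window_runs_to_data_end_without_reinitiation(self):
        a = assignment_df([("P1", "denosumab", IDX, IDX + 364,
                            "discontinuation", 2)])
        cells = o.accumulate_post_disc(a, NO_EVENTS, make_persons(),
                                       make_dispensings([]))
        hip = cells[cells["site_group"] == "hip"].iloc[0]
        assert hip["person_days"] == (to_day("2018-12-31") + 1
                                      - (IDX + 364))

    def test_non_discontinuers_skipped(self):
        a = assignment_df([("P1", "denosumab", IDX, IDX + 364, "switch",
                            2)])
        cells = o.accumulate_post_disc(a, NO_EVENTS, make_persons(),
                                       make_dispensings([]))
        assert cells.empty

    def test_post_disc_event_counted(self):
        a = assignment_df([("P1", "denosumab", IDX, IDX + 364,
                            "discontinuation", 2)])
        ev = events_df([("P1", IDX + 500, "vertebral")])
        cells = o.accumulate_post_disc(a, ev, make_persons(),
                                       make_dispensings([]))
        vert = cells[cells["site_group"] == "vertebral"].iloc[0]
        assert vert["events"] == 1


class TestStrata:
    def test_single_stratum_equals_total(self, pipeline_bundle):
        b = pipeline_bundle
        cov = b["covariates"].copy()
        cov["const"] = "x"
        sub = o.select_stratum(b["assignment"], cov, "const", "x")
        total = o.accumulate(b["assignment"], b["events"], b["persons"],
                             "as_treated")
        strat = o.accumulate(sub, b["events"], b["persons"], "as_treated")
        pd.testing.assert_frame_equal(total, strat)

    def test_partition_additivity(self, pipeline_bundle):
        """Cells of a random 2-way partition sum to the pooled cells."""
        b = pipeline_bundle
        cov = b["covariates"].copy()
        rng = np.random.default_rng(5)
        cov["half"] = rng.integers(0, 2, len(cov))
        parts = []
        for v in (0, 1):
            sub = o.select_stratum(b["assignment"], cov, "half", v)
            parts.append(o.accumulate(sub, b["events"], b["persons"],
                                      "as_treated"))
        total = o.accumulate(b["assignment"], b["events"], b["persons"],
                             "as_treated")
        keys = ["cohort", "site_group", "window"]
        summed = (pd.concat(parts).groupby(keys)[["events", "person_days"]]
                  .sum())
        pooled = total.groupby(keys)[["events", "person_days"]].sum()
        pd.testing.assert_frame_equal(pooled, summed)


class TestPosthoc:
    def _flags(self, eps, persons, disp):
        flags, _, _ = o.apply_eligibility(persons, eps, EMPTY_STAYS, disp)
        return flags

    def test_no_early_discontinuers_empty_table(self):
        persons = make_persons()
        eps = pd.DataFrame([("P1", "oral_bisphosphonate", IDX, IDX + 400,
                             "discontinuation", 13)],
                           columns=["person_id", "drug_name", "index_date",
                                    "end", "end_reason",
                                    "dispensing_count"])
        flags = self._flags(eps, persons, make_dispensings([]))
        cells = o.posthoc_early_discontinuers(flags, NO_EVENTS, persons,
                                              make_dispensings([]))
        assert cells.empty

    def test_early_discontinuer_windows(self):
        persons = make_persons()
        eps = pd.DataFrame([("P1", "oral_bisphosphonate", IDX, IDX + 120,
                             "discontinuation", 4)],
                           columns=["person_id", "drug_name", "index_date",
                                    "end", "end_reason",
                                    "dispensing_count"])
        flags = self._flags(eps, persons, make_dispensings([]))
        cells = o.posthoc_early_discontinuers(flags, NO_EVENTS, persons,
                                              make_dispensings([]))
        hip = cells[cells["site_group"] == "hip"].set_index("window")
        assert hip.loc["baseline", "person_days"] == 91
        assert hip.loc["m3_6", "person_days"] == 92

    def test_planted_excess_rate_recovered(self, tmp_path):
        """A planted uniform 1.5x vertebral hazard after month 3 (on and
        off treatment alike, so the months-3-6 window has a clean true
        IRR) is recovered inside the exact interval for early oral-BP
        discontinuers."""
        true_irr = 1.5
        cfg = o.SimulationConfig(
            n_women_per_drug={"oral_bisphosphonate": 6000}, seed=77,
            baseline_hazards={"vertebral": 40.0},
            on_treatment_irr={"vertebral": true_irr},
            post_disc_irr={"vertebral": true_irr},
            exclusion_fractions={"cancer_or_paget": 0.0, "age_lt_55": 0.0,
                                 "multi_drug_index": 0.0,
                                 "treated_lt_6m": 0.8})
        ds = o.generate_dataset(cfg)
        o.write_claims(ds, str(tmp_path))
        bundle = o.run_pipeline(o.StudyConfig(claims_dir=str(tmp_path)),
                                write=False, with_covariates=False)
        cells = o.posthoc_early_discontinuers(
            bundle["episode_flags"], bundle["events"], bundle["persons"],
            bundle["dispensings"])
        irr = o.run_all(cells)
        row = irr[(irr["site_group"] == "vertebral") &
                  (irr["comparison"] == "m3_6_vs_baseline")].iloc[0]
        assert row["irr"] > 1.0
        assert row["ci_low"] <= true_irr <= row["ci_high"]


class TestBruteForceOracle:
    def test_accumulate_matches_day_by_day(self, pipeline_bundle):
        """Vectorised person-time equals an explicit day loop for a sample
        of women across all windows."""
        b = pipeline_bundle
        a = b["assignment"].copy()
        a["censor"] = o.censor_dates(a, b["persons"], "as_treated")
        ev = b["events"]
        ev = ev[ev["independent"]]
        sample = a.head(60)
        totals = {(w, g): 0.0 for w in persontime.WINDOWS
                  for g in ("hip", "vertebral")}
        counts = {(w, g): 0 for w in persontime.WINDOWS
                  for g in ("hip", "vertebral")}
        for _, row in sample.iterrows():
            pdays = brute_force_person_days(int(row["index_date"]),
                                            row["censor"],
                                            persontime.WINDOWS)
            her = ev[ev["person_id"] == row["person_id"]]
            for w, (s, e) in persontime.WINDOWS.items():
                for g in ("hip", "vertebral"):
                    totals[(w, g)] += pdays[w]
                    days = her.loc[her["site"] == g, "event_date"]
                    counts[(w, g)] += count_events_in_window(
                        days.tolist(), int(row["index_date"]),
                        row["censor"], s, e)
        cells = o.accumulate(sample, ev, b["persons"], "as_treated")
        agg = cells.groupby(["window", "site_group"])[
            ["events", "person_days"]].sum()
        for (w, g), t in totals.items():
            assert agg.loc[(w, g), "person_days"] == t
            assert agg.loc[(w, g), "events"] == counts[(w, g)]
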
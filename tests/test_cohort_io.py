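"""Cohort data model: seroconversion dating, eligibility, endpoints, I/O."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cd4slope import (
    CohortError,
    apply_eligibility,
    build_endpoint,
    build_pre_cart_baseline,
    derive_seroconversion,
    read_cohort,
    write_cohort,
)
from cd4slope.cohort_io import DAYS_PER_YEAR, ERA_PRE_CART

from conftest import make_cohort, make_patient


class TestDeriveSeroconversion:
    def test_midpoint_of_one_year_window(self):
        mid = derive_seroconversion("2000-01-01", "2001-01-01")
        assert mid == pd.Timestamp("2000-07-02")  # 366/2 days into a leap year

    def test_degenerate_window(self):
        t0 = pd.Timestamp("1999-05-05")
        assert derive_seroconversion(t0, t0) == t0

    def test_median_cohort_window(self):
        # a 0.82-year test window dates seroconversion 0.41 years in
        t0 = pd.Timestamp("2000-01-01")
        fp = t0 + pd.Timedelta(days=round(0.82 * DAYS_PER_YEAR))
        mid = derive_seroconversion(t0, fp)
        assert abs((mid - t0).days - 0.41 * DAYS_PER_YEAR) <= 1

    def test_reversed_dates_rejected(self):
        with pytest.raises(CohortError, match="precedes"):
            derive_seroconversion("2001-01-01", "2000-01-01")

    def test_wide_window_rejected(self):
        with pytest.raises(CohortError, match="too wide"):
            derive_seroconversion("2000-01-01", "2003-06-01")

    @given(st.integers(min_value=0, max_value=1095), st.integers(0, 10000))
    @settings(max_examples=50, deadline=None)
    def test_midpoint_lies_inside_window(self, width_days, start_offset):
        ln = pd.Timestamp("1990-01-01") + pd.Timedelta(days=start_offset)
        fp = ln + pd.Timedelta(days=width_days)
        mid = derive_seroconversion(ln, fp)
        assert ln <= mid <= fp


def _eligibility_cohort():
    patients = [
        # eligible: CD4 and VL 30 d before cART, earlier CD4 200 d before
        make_patient("ok", cart="2001-01-01", log10_vl=None),
        # a single CD4 right before cART
        make_patient("one_cd4", cart="2001-01-01", log10_vl=None),
        # two CD4s but none within the 91-day window (VL present at cART)
        make_patient("stale_cd4", cart="2001-01-01", log10_vl=4.2),
        # windowed CD4 but no VL anywhere
        make_patient("no_vl", cart="2001-01-01", log10_vl=None),
        # neither CD4 nor VL in the window
        make_patient("neither", cart="2001-01-01", log10_vl=None),
        # windowed CD4 with the earlier count only 40 d before it
        make_patient("short_gap", cart="2001-01-01", log10_vl=4.0),
        # no cART date: dropped before accounting
        make_patient("untreated", cart=None, log10_vl=None),
    ]
    meas = [
        ("ok", "2000-12-02", 250, 4.4),
        ("ok", "2000-06-15", 400),
        ("one_cd4", "2000-12-22", 300, 4.4),
        ("stale_cd4", "2000-09-23", 310),  # 100 d before cART
        ("stale_cd4", "2000-03-01", 420),
        ("no_vl", "2000-12-10", 280),
        ("no_vl", "2000-05-10", 390),
        ("neither", "2000-08-01", 350),
        ("neither", "2000-02-01", 430),
        ("short_gap", "2000-12-22", 260),
        ("short_gap", "2000-11-12", 300),
        ("untreated", "2000-12-01", 500),
    ]
    return make_cohort(patients, meas)


class TestEligibility:
    def test_reasons_partition_and_eligibility(self):
        cohort = _eligibility_cohort()
        eligible, report = apply_eligibility(cohort)
        assert sorted(eligible.patients["patient_id"]) == ["ok"]
        assert report.n_input == 6  # untreated dropped before accounting
        assert report.exclusions == {
            "fewer_than_two_cd4": 1,
            "missing_cd4_window": 1,
            "missing_vl_window": 1,
            "missing_both": 1,
            "interval_below_3mo": 1,
        }
        assert report.n_input == report.n_eligible + sum(
            report.exclusions.values()
        )

    def test_baseline_cd4_is_latest_in_window(self):
        cohort = _eligibility_cohort()
        eligible, _ = apply_eligibility(cohort)
        assert eligible.patients["baseline_cd4"].iloc[0] == 250.0

    def test_widening_window_is_monotone(self, default_cohort):
        cohort, _ = default_cohort
        narrow, _ = apply_eligibility(cohort, window_days=91)
        wide, _ = apply_eligibility(cohort, window_days=182)
        assert set(narrow.patients["patient_id"]) <= set(
            wide.patients["patient_id"]
        )

    def test_empty_cohort(self):
        cohort = make_cohort([], [])
        eligible, report = apply_eligibility(cohort)
        assert eligible.n_patients == 0
        assert report.n_input == 0 and report.n_eligible == 0


class TestEndpoint:
    def test_death_event(self):
        cohort = make_cohort(
            [make_patient("A", cart="2001-01-01", death="2003-01-01",
                          last_visit="2003-01-01")],
            [],
        )
        ep = build_endpoint(cohort, "aids_or_death")
        assert ep["event"].iloc[0]
        assert ep["time"].iloc[0] == pytest.approx(2.0, abs=0.01)

    def test_censored_at_last_visit(self):
        lv = pd.Timestamp("2001-01-01") + pd.Timedelta(days=round(3.2 * DAYS_PER_YEAR))
        cohort = make_cohort(
            [make_patient("A", cart="2001-01-01", last_visit=lv)], []
        )
        ep = build_endpoint(cohort)
        assert not ep["event"].iloc[0]
        assert ep["time"].iloc[0] == pytest.approx(3.2, abs=0.01)

    def test_first_event_wins(self):
        cohort = make_cohort(
            [make_patient("A", cart="2001-01-01", aids="2002-01-01",
                          death="2003-01-01", last_visit="2003-01-01")],
            [],
        )
        ep = build_endpoint(cohort, "aids_or_death")
        assert ep["time"].iloc[0] == pytest.approx(1.0, abs=0.01)
        # death endpoint ignores the AIDS event
        ep_d = build_endpoint(cohort, "death")
        assert ep_d["time"].iloc[0] == pytest.approx(2.0, abs=0.01)

    def test_event_before_cart_invalid(self):
        cohort = make_cohort(
            [make_patient("A", cart="2001-01-01", death="2000-06-01",
                          last_visit="2000-06-01")],
            [],
        )
        with pytest.raises(CohortError, match="before cART"):
            build_endpoint(cohort)


class TestPreCartBaseline:
    def _cohort(self, **kw):
        patients = [
            make_patient("A", cart=None, last_negative="1988-01-01",
                         first_positive="1989-01-01", last_visit="1996-06-01",
                         **kw),
        ]
        meas = [
            ("A", "1991-06-01", 500),
            ("A", "1993-03-01", 420),
            ("A", "1993-09-01", 400),
        ]
        return make_cohort(patients, meas, era=ERA_PRE_CART)

    def test_baseline_is_last_1993_count(self):
        built = build_pre_cart_baseline(self._cohort())
        assert built.patients["baseline_date"].iloc[0] == pd.Timestamp("1993-09-01")
        assert built.patients["baseline_cd4"].iloc[0] == 400.0

    def test_event_after_censor_date_is_censored(self):
        built = build_pre_cart_baseline(self._cohort(death="1996-02-01"))
        row = built.patients.iloc[0]
        assert not row["pc_event"]
        expected = (pd.Timestamp("1995-12-31") - pd.Timestamp("1993-09-01")).days
        assert row["pc_time"] == pytest.approx(expected / DAYS_PER_YEAR)

    def test_prior_aids_excluded(self):
        built = build_pre_cart_baseline(self._cohort(aids="1993-01-01"))
        assert built.n_patients == 0

    def test_no_baseline_year_count_excluded(self):
        cohort = make_cohort(
            [make_patient("B", cart=None, last_negative="1988-01-01",
                          first_positive="1989-01-01", last_visit="1996-01-01")],
            [("B", "1991-01-01", 500), ("B", "1992-01-01", 450)],
            era=ERA_PRE_CART,
        )
        assert build_pre_cart_baseline(cohort).n_patients == 0

    def test_exclude_any_art(self):
        # therapy from 1992: dropped entirely under the sensitivity rule
        cohort = self._cohort()
        cohort.patients.loc[0, "cart_date"] = pd.Timestamp("1992-05-01")
        assert build_pre_cart_baseline(cohort, exclude_any_art=True).n_patients == 0
        # therapy from 1994: retained but censored at therapy start
        cohort.patients.loc[0, "cart_date"] = pd.Timestamp("1994-07-01")
        built = build_pre_cart_baseline(cohort, exclude_any_art=True)
        expected = (pd.Timestamp("1994-07-01") - pd.Timestamp("1993-09-01")).days
        assert built.patients["pc_time"].iloc[0] == pytest.approx(
            expected / DAYS_PER_YEAR
        )


class TestRoundTrip:
    def test_write_read_identity(self, tmp_path, default_cohort):
        cohort, _ = default_cohort
        write_cohort(cohort, tmp_path)
        back = read_cohort(tmp_path / "patients.csv", tmp_path / "measurements.csv")
        write_cohort(back, tmp_path / "again")
        a = (tmp_path / "patients.csv").read_text()
        b = (tmp_path / "again" / "patients.csv").read_text()
        assert a == b
        a = (tmp_path / "measurements.csv").read_text()
        b = (tmp_path / "again" / "measurements.csv").read_text()
        assert a == b

    def test_negative_cd4_rejected(self, tmp_path, default_cohort):
        cohort, _ = default_cohort
        write_cohort(cohort, tmp_path)
        meas = pd.read_csv(tmp_path / "measurements.csv")
        meas.loc[3, "cd4"] = -5
        meas.to_csv(tmp_path / "measurements.csv", index=False)
        with pytest.raises(CohortError, match="row 3"):
            read_cohort(tmp_path / "patients.csv", tmp_path / "measurements.csv")

    def test_empty_measurements_ok(self, tmp_path, default_cohort):
        cohort, _ = default_cohort
        write_cohort(cohort, tmp_path)
        (tmp_path / "measurements.csv").write_text("patient_id,date,cd4,log10_vl\n")
        back = read_cohort(tmp_path / "patients.csv", tmp_path / "measurements.csv")
        assert len(back.measurements) == 0

    def test_unknown_column_warns(self, tmp_path, default_cohort):
        cohort, _ = default_cohort
        write_cohort(cohort, tmp_path)
        meas = pd.read_csv(tmp_path / "measurements.csv")
        meas["extra"] = 1
        meas.to_csv(tmp_path / "measurements.csv", index=False)
        with pytest.warns(UserWarning, match="unknown columns"):
            read_cohort(tmp_path / "patients.csv", tmp_path / "measurements.csv")

    def test_missing_mandatory_column_fails(self, tmp_path, default_cohort):
        cohort, _ = default_cohort
        write_cohort(cohort, tmp_path)
        meas = pd.read_csv(tmp_path / "measurements.csv").drop(columns=["cd4"])
        meas.to_csv(tmp_path / "measurements.csv", index=False)
        with pytest.raises(CohortError, match="missing mandatory"):
            read_cohort(tmp_path / "patients.csv", tmp_path / "measurements.csv")
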
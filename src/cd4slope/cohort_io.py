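"""Cohort data model, CSV readers/writers, and epidemiological derivations.

A cohort couples a patient table (one row per seroconverter: test dates,
covariates, treatment and outcome dates) with a long measurement table
(CD4 counts, optionally viral loads, at calendar dates).  Time for all
longitudinal modelling is measured in years since the estimated
seroconversion date; the seroconversion date is the midpoint of the
last-negative / first-positive HIV test window when not supplied.

Two study eras are supported:

``cart``
    Patients initiating combination antiretroviral therapy (cART); the
    analysis baseline is the cART initiation date and eligibility requires
    baseline CD4 and viral-load values within a window before initiation.
``pre_cart``
    The 1989–1995 era before cART; the analysis baseline is the patient's
    last CD4 measurement in a baseline calendar year (1993 by default) and
    follow-up is administratively censored at the end of 1995.  In this era
    the ``cart_date`` column records the start of *any* antiretroviral
    therapy (mono/dual), which only the sensitivity analysis consumes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

DAYS_PER_YEAR = 365.25
#: widest admissible seroconversion test window, years
MAX_TEST_INTERVAL_YEARS = 3.0

ERA_CART = "cart"
ERA_PRE_CART = "pre_cart"

EXCLUSION_REASONS = (
    "fewer_than_two_cd4",
    "missing_cd4_window",
    "missing_vl_window",
    "missing_both",
    "interval_below_3mo",
)

PATIENT_DATE_COLUMNS = (
    "last_negative_date",
    "first_positive_date",
    "seroconversion_date",
    "cart_date",
    "aids_date",
    "death_date",
    "last_visit_date",
)

PATIENT_REQUIRED_COLUMNS = (
    "patient_id",
    "sex",
    "age_at_baseline",
    "transmission_group",
    "prior_aids",
    "last_negative_date",
    "first_positive_date",
    "last_visit_date",
)

PATIENT_OPTIONAL_COLUMNS = (
    "seroconversion_date",
    "cart_date",
    "log10_vl_at_cart",
    "aids_date",
    "death_date",
)

MEASUREMENT_REQUIRED_COLUMNS = ("patient_id", "date", "cd4")
MEASUREMENT_OPTIONAL_COLUMNS = ("log10_vl",)


class CohortError(ValueError):
    """Invalid cohort input (bad dates, schema violations, bad records)."""


def derive_seroconversion(last_negative, first_positive) -> pd.Timestamp:
    """Midpoint seroconversion date from the HIV test window.

    Parameters
    ----------
    last_negative, first_positive
        Calendar dates (anything ``pd.Timestamp`` accepts) of the last
        documented negative and first positive HIV antibody test.

    Returns
    -------
    pandas.Timestamp
        The midpoint of ``[last_negative, first_positive]``.

    Raises
    ------
    CohortError
        If the dates are reversed or the window exceeds 3 years.
    """
    ln = pd.Timestamp(last_negative)
    fp = pd.Timestamp(first_positive)
    if pd.isna(ln) or pd.isna(fp):
        raise CohortError("seroconversion window dates must both be present")
    if fp < ln:
        raise CohortError(
            f"first positive test ({fp.date()}) precedes last negative ({ln.date()})"
        )
    if (fp - ln).days > MAX_TEST_INTERVAL_YEARS * DAYS_PER_YEAR:
        raise CohortError(
            f"test interval {(fp - ln).days} d exceeds "
            f"{MAX_TEST_INTERVAL_YEARS:g} y; seroconversion window too wide"
        )
    return ln + (fp - ln) / 2


@dataclass
class EligibilityReport:
    """Patient-flow accounting for the cART-era eligibility filter."""

    n_input: int
    n_eligible: int
    exclusions: dict[str, int]

    def __post_init__(self) -> None:
        for reason in EXCLUSION_REASONS:
            self.exclusions.setdefault(reason, 0)
        if self.n_input != self.n_eligible + sum(self.exclusions.values()):
            raise CohortError("eligibility report counts do not sum to n_input")

    def to_frame(self) -> pd.DataFrame:
        rows = [("eligible", self.n_eligible)]
        rows += [(r, self.exclusions[r]) for r in EXCLUSION_REASONS]
        return pd.DataFrame(rows, columns=["reason", "count"])

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass
class Cohort:
    """Patients plus their longitudinal measurements.

    ``patients`` carries one row per patient (see module docstring for the
    column schema); ``measurements`` is long-format with columns
    ``patient_id, date, cd4, log10_vl`` and a derived ``time`` column in
    years since the patient's seroconversion date.
    """

    patients: pd.DataFrame
    measurements: pd.DataFrame
    era: str = ERA_CART

    def __post_init__(self) -> None:
        if self.era not in (ERA_CART, ERA_PRE_CART):
            raise CohortError(f"unknown era {self.era!r}")
        ids = set(self.patients["patient_id"])
        stray = set(self.measurements["patient_id"]) - ids
        if stray:
            raise CohortError(
                f"measurements reference unknown patient ids: {sorted(stray)[:5]}"
            )
        self.measurements = self.measurements.sort_values(
            ["patient_id", "date"], kind="mergesort"
        ).reset_index(drop=True)
        if "time" not in self.measurements.columns:
            self.measurements = _attach_times(self.patients, self.measurements)

    @property
    def n_patients(self) -> int:
        return len(self.patients)

    def subset(self, patient_ids) -> "Cohort":
        keep = self.patients["patient_id"].isin(set(patient_ids))
        meas = self.measurements[
            self.measurements["patient_id"].isin(set(patient_ids))
        ]
        return Cohort(
            self.patients[keep].reset_index(drop=True),
            meas.reset_index(drop=True),
            era=self.era,
        )

    def measurements_of(self, patient_id) -> pd.DataFrame:
        return self.measurements[self.measurements["patient_id"] == patient_id]


def _attach_times(patients: pd.DataFrame, measurements: pd.DataFrame) -> pd.DataFrame:
    m = measurements.copy()
    if len(m) == 0:
        m["time"] = pd.Series(dtype=float)
        return m
    sero = patients.set_index("patient_id")["seroconversion_date"]
    m["time"] = (
        m["date"] - m["patient_id"].map(sero)
    ).dt.days / DAYS_PER_YEAR
    return m


def _parse_dates(df: pd.DataFrame, columns, label: str) -> pd.DataFrame:
    df = df.copy()
    for col in columns:
        if col not in df.columns:
            continue
        raw = df[col]
        parsed = pd.to_datetime(raw, errors="coerce", format="mixed")
        bad = parsed.isna() & raw.notna() & (raw.astype(str).str.strip() != "")
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise CohortError(
                f"{label}: unparseable date {raw.iloc[row]!r} in column "
                f"{col!r} at row {row}"
            )
        df[col] = parsed
    return df


def read_cohort(patient_path, measurement_path, era: str = ERA_CART) -> Cohort:
    """Read a cohort from ``patients.csv`` and ``measurements.csv``.

    Unknown columns raise a warning and are dropped; missing mandatory
    columns, unparseable dates and negative CD4 counts are hard errors that
    name the offending row.  Measurements are returned sorted by
    ``(patient_id, date)`` and seroconversion dates are derived by the
    midpoint rule where absent.
    """
    patients = pd.read_csv(patient_path, float_precision="round_trip")
    _check_columns(
        patients, PATIENT_REQUIRED_COLUMNS, PATIENT_OPTIONAL_COLUMNS, "patients"
    )
    patients = _parse_dates(patients, PATIENT_DATE_COLUMNS, "patients")
    for col in PATIENT_OPTIONAL_COLUMNS:
        if col not in patients.columns:
            patients[col] = pd.NaT if col.endswith("_date") else np.nan
    patients["prior_aids"] = patients["prior_aids"].astype(bool)

    rev = patients["first_positive_date"] < patients["last_negative_date"]
    if rev.any():
        raise CohortError(
            f"patients: reversed test dates at row {int(np.flatnonzero(rev)[0])}"
        )
    wide = (
        patients["first_positive_date"] - patients["last_negative_date"]
    ).dt.days > MAX_TEST_INTERVAL_YEARS * DAYS_PER_YEAR
    if wide.any():
        raise CohortError(
            f"patients: test interval exceeds {MAX_TEST_INTERVAL_YEARS:g} y "
            f"at row {int(np.flatnonzero(wide)[0])}"
        )
    need_sero = patients["seroconversion_date"].isna()
    if need_sero.any():
        mid = (
            patients["last_negative_date"]
            + (patients["first_positive_date"] - patients["last_negative_date"]) / 2
        )
        patients.loc[need_sero, "seroconversion_date"] = mid[need_sero]

    measurements = pd.read_csv(measurement_path, float_precision="round_trip")
    if len(measurements) == 0:
        measurements = pd.DataFrame(
            columns=list(MEASUREMENT_REQUIRED_COLUMNS) + ["log10_vl"]
        )
    _check_columns(
        measurements,
        MEASUREMENT_REQUIRED_COLUMNS,
        MEASUREMENT_OPTIONAL_COLUMNS,
        "measurements",
    )
    measurements = _parse_dates(measurements, ("date",), "measurements")
    if "log10_vl" not in measurements.columns:
        measurements["log10_vl"] = np.nan
    cd4 = pd.to_numeric(measurements["cd4"], errors="coerce")
    bad = cd4.isna() | (cd4 < 0) | ~np.isfinite(cd4)
    if len(measurements) and bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise CohortError(
            f"measurements: invalid cd4 value "
            f"{measurements['cd4'].iloc[row]!r} at row {row}"
        )
    measurements["cd4"] = cd4.astype(float)
    measurements["date"] = pd.to_datetime(measurements["date"])
    return Cohort(patients, measurements, era=era)


def _check_columns(df, required, optional, label):
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise CohortError(f"{label}: missing mandatory columns {missing}")
    unknown = [c for c in df.columns if c not in required and c not in optional]
    if unknown:
        warnings.warn(
            f"{label}: ignoring unknown columns {unknown}", stacklevel=3
        )
        df.drop(columns=unknown, inplace=True)


def write_cohort(cohort: Cohort, directory) -> None:
    """Write ``patients.csv`` and ``measurements.csv`` under ``directory``."""
    import pathlib

    directory = pathlib.Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    patients = cohort.patients.copy()
    for col in PATIENT_DATE_COLUMNS:
        if col in patients.columns:
            patients[col] = patients[col].dt.strftime("%Y-%m-%d")
    cols = [
        c
        for c in list(PATIENT_REQUIRED_COLUMNS) + list(PATIENT_OPTIONAL_COLUMNS)
        if c in patients.columns
    ]
    # keep the schema order: ids/covariates first, then dates
    order = [
        "patient_id", "sex", "age_at_baseline", "transmission_group",
        "prior_aids", "last_negative_date", "first_positive_date",
        "seroconversion_date", "cart_date", "log10_vl_at_cart",
        "aids_date", "death_date", "last_visit_date",
    ]
    patients[[c for c in order if c in cols]].to_csv(
        directory / "patients.csv", index=False
    )
    meas = cohort.measurements.copy()
    meas["date"] = meas["date"].dt.strftime("%Y-%m-%d")
    meas[["patient_id", "date", "cd4", "log10_vl"]].to_csv(
        directory / "measurements.csv", index=False
    )


# ---------------------------------------------------------------------------
# Eligibility (cART era)
# ---------------------------------------------------------------------------

def apply_eligibility(
    cohort: Cohort, window_days: int = 91, min_gap_days: int = 91
) -> tuple[Cohort, EligibilityReport]:
    """Apply the cART-era inclusion criteria.

    A patient is eligible when they have (a) a CD4 count in the window
    ``[cart - window_days, cart]``, (b) a viral load in the same window
    (either a windowed measurement or the ``log10_vl_at_cart`` field), and
    (c) at least one CD4 count at least ``min_gap_days`` before the
    windowed CD4.  Patients without a cART date are dropped before any
    accounting.  Exclusion reasons are assigned in a fixed order so each
    excluded patient is counted exactly once.

    Returns the eligible sub-cohort — whose patient table gains
    ``baseline_cd4`` and ``baseline_cd4_date`` columns — and an
    :class:`EligibilityReport`.
    """
    if cohort.era != ERA_CART:
        raise CohortError("eligibility filter applies to the cART era only")
    patients = cohort.patients[cohort.patients["cart_date"].notna()]
    exclusions = {r: 0 for r in EXCLUSION_REASONS}
    eligible_ids: list = []
    baseline_cd4: dict = {}
    baseline_date: dict = {}
    window = pd.Timedelta(days=window_days)
    min_gap = pd.Timedelta(days=min_gap_days)

    groups = dict(iter(cohort.measurements.groupby("patient_id")))
    for row in patients.itertuples(index=False):
        cart = row.cart_date
        meas = groups.get(row.patient_id)
        if meas is not None:
            meas = meas[meas["date"] <= cart]
        n_cd4 = 0 if meas is None else int(meas["cd4"].notna().sum())
        if n_cd4 < 2:
            exclusions["fewer_than_two_cd4"] += 1
            continue
        in_window = meas[meas["date"] >= cart - window]
        cd4_window = in_window[in_window["cd4"].notna()]
        has_cd4 = len(cd4_window) > 0
        has_vl = bool(np.isfinite(getattr(row, "log10_vl_at_cart", np.nan))) or bool(
            in_window["log10_vl"].notna().any()
        )
        if not has_cd4 and not has_vl:
            exclusions["missing_both"] += 1
            continue
        if not has_cd4:
            exclusions["missing_cd4_window"] += 1
            continue
        if not has_vl:
            exclusions["missing_vl_window"] += 1
            continue
        # baseline CD4: closest to cART; all candidates are <= cart, so the
        # closest is the latest, which also resolves the later-date tie-break
        anchor = cd4_window.iloc[-1]
        earlier = meas[(meas["date"] <= anchor["date"] - min_gap) & meas["cd4"].notna()]
        if len(earlier) == 0:
            exclusions["interval_below_3mo"] += 1
            continue
        eligible_ids.append(row.patient_id)
        baseline_cd4[row.patient_id] = float(anchor["cd4"])
        baseline_date[row.patient_id] = anchor["date"]

    out = cohort.subset(eligible_ids)
    out.patients["baseline_cd4"] = out.patients["patient_id"].map(baseline_cd4)
    out.patients["baseline_cd4_date"] = out.patients["patient_id"].map(baseline_date)
    report = EligibilityReport(
        n_input=len(patients), n_eligible=len(eligible_ids), exclusions=exclusions
    )
    return out, report


# ---------------------------------------------------------------------------
# Endpoints
# ---------------------------------------------------------------------------

ENDPOINT_AIDS_OR_DEATH = "aids_or_death"
ENDPOINT_DEATH = "death"


def build_endpoint(cohort: Cohort, endpoint: str = ENDPOINT_AIDS_OR_DEATH) -> pd.DataFrame:
    """Time-to-event table from cART initiation.

    Returns a frame with columns ``patient_id, time, event`` where ``time``
    is years from cART initiation to the first qualifying event (new AIDS
    event or death for ``aids_or_death``; death only for ``death``) or to
    censoring at the last clinic visit.  All times must be strictly
    positive; an event on or before cART initiation is an invalid record.
    """
    if endpoint not in (ENDPOINT_AIDS_OR_DEATH, ENDPOINT_DEATH):
        raise CohortError(f"unknown endpoint {endpoint!r}")
    rows = []
    for row in cohort.patients.itertuples(index=False):
        cart = row.cart_date
        if pd.isna(cart):
            raise CohortError(f"patient {row.patient_id}: no cART date")
        candidates = [row.death_time if hasattr(row, "death_time") else row.death_date]
        event_dates = [row.death_date]
        if endpoint == ENDPOINT_AIDS_OR_DEATH:
            event_dates.append(row.aids_date)
        event_dates = [d for d in event_dates if pd.notna(d)]
        event_date = min(event_dates) if event_dates else pd.NaT
        censor_date = row.last_visit_date
        if pd.notna(event_date) and event_date <= censor_date:
            end, event = event_date, True
        else:
            end, event = censor_date, False
        t = (end - cart).days / DAYS_PER_YEAR
        if t <= 0:
            raise CohortError(
                f"patient {row.patient_id}: endpoint at or before cART initiation"
            )
        rows.append((row.patient_id, t, event))
    return pd.DataFrame(rows, columns=["patient_id", "time", "event"])


def build_pre_cart_baseline(
    cohort: Cohort,
    baseline_year: int = 1993,
    slope_window: tuple[int, int] = (1989, 1993),
    censor_date="1995-12-31",
    exclude_any_art: bool = False,
) -> Cohort:
    """Construct the pre-cART-era analysis cohort.

    The analysis baseline is each patient's last CD4 measurement date in
    ``baseline_year``.  Patients are retained when they have such a
    measurement, at least one earlier CD4 in the slope window, and no AIDS
    event on or before baseline.  The returned cohort keeps only
    measurements in the slope window up to baseline and its patient table
    gains ``baseline_date``, ``baseline_cd4``, ``pc_time`` (years) and
    ``pc_event`` columns; events after ``censor_date`` are censored there.

    With ``exclude_any_art``, patients on any antiretroviral therapy by
    ``baseline_year`` (recorded in ``cart_date``) are dropped and follow-up
    is censored at therapy start when therapy began after baseline.
    """
    if cohort.era != ERA_PRE_CART:
        raise CohortError("pre-cART baseline applies to pre_cart-era cohorts")
    censor = pd.Timestamp(censor_date)
    lo = pd.Timestamp(f"{slope_window[0]}-01-01")
    year_start = pd.Timestamp(f"{baseline_year}-01-01")
    year_end = pd.Timestamp(f"{baseline_year}-12-31")
    groups = dict(iter(cohort.measurements.groupby("patient_id")))

    keep_rows = []
    for row in cohort.patients.itertuples(index=False):
        meas = groups.get(row.patient_id)
        if meas is None:
            continue
        meas = meas[meas["cd4"].notna()]
        in_year = meas[(meas["date"] >= year_start) & (meas["date"] <= year_end)]
        if len(in_year) == 0:
            continue
        base = in_year.iloc[-1]
        prior = meas[(meas["date"] >= lo) & (meas["date"] < base["date"])]
        if len(prior) == 0:
            continue
        if pd.notna(row.aids_date) and row.aids_date <= base["date"]:
            continue
        if bool(row.prior_aids):
            continue
        art = row.cart_date  # any ART start in this era
        if exclude_any_art and pd.notna(art) and art <= year_end:
            continue
        end_candidates = [censor, row.last_visit_date]
        if exclude_any_art and pd.notna(art):
            end_candidates.append(art)
        censor_at = min(d for d in end_candidates if pd.notna(d))
        event_dates = [d for d in (row.aids_date, row.death_date) if pd.notna(d)]
        event_date = min(event_dates) if event_dates else pd.NaT
        if pd.notna(event_date) and event_date <= censor_at:
            end, event = event_date, True
        else:
            end, event = censor_at, False
        t = (end - base["date"]).days / DAYS_PER_YEAR
        if t <= 0:
            continue
        keep_rows.append(
            (row.patient_id, base["date"], float(base["cd4"]), t, event)
        )

    extra = pd.DataFrame(
        keep_rows,
        columns=["patient_id", "baseline_date", "baseline_cd4", "pc_time", "pc_event"],
    )
    out = cohort.subset(extra["patient_id"])
    if len(extra) == 0:
        for col in extra.columns[1:]:
            out.patients[col] = extra[col]
        return out
    out.patients = out.patients.merge(extra, on="patient_id", how="left")
    # restrict measurements to the slope-estimation window up to baseline
    base_dates = extra.set_index("patient_id")["baseline_date"]
    m = out.measurements
    mask = (m["date"] >= lo) & (m["date"] <= m["patient_id"].map(base_dates))
    out.measurements = m[mask].reset_index(drop=True)
    return out
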
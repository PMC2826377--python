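import numpy as np
import pandas as pd
import pytest

from cd4slope import apply_eligibility
from cd4slope.cohort_io import Cohort
from cd4slope.synthetic_cohort import SimulationConfig, simulate_cohort


def make_patient(
    pid="A",
    cart="2001-01-01",
    last_negative="1997-01-01",
    first_positive="1998-01-01",
    sex="male",
    age=35.0,
    transmission="msm",
    prior_aids=False,
    log10_vl=4.5,
    aids=None,
    death=None,
    last_visit="2005-01-01",
):
    return {
        "patient_id": pid,
        "sex": sex,
        "age_at_baseline": age,
        "transmission_group": transmission,
        "prior_aids": prior_aids,
        "last_negative_date": pd.Timestamp(last_negative),
        "first_positive_date": pd.Timestamp(first_positive),
        "seroconversion_date": pd.Timestamp(last_negative)
        + (pd.Timestamp(first_positive) - pd.Timestamp(last_negative)) / 2,
        "cart_date": pd.Timestamp(cart) if cart else pd.NaT,
        "log10_vl_at_cart": log10_vl if log10_vl is not None else np.nan,
        "aids_date": pd.Timestamp(aids) if aids else pd.NaT,
        "death_date": pd.Timestamp(death) if death else pd.NaT,
        "last_visit_date": pd.Timestamp(last_visit),
    }


def make_cohort(patient_rows, measurement_rows, era="cart"):
    """measurement_rows: (patient_id, date, cd4) or (pid, date, cd4, vl)."""
    patients = pd.DataFrame(patient_rows)
    if len(patients) == 0:
        patients = pd.DataFrame(columns=list(make_patient().keys()))
    rows = []
    for r in measurement_rows:
        pid, date, cd4 = r[:3]
        vl = r[3] if len(r) > 3 else np.nan
        rows.append((pid, pd.Timestamp(date), float(cd4), vl))
    meas = pd.DataFrame(rows, columns=["patient_id", "date", "cd4", "log10_vl"])
    if len(meas) == 0:
        meas = pd.DataFrame(columns=["patient_id", "date", "cd4", "log10_vl"])
        meas["date"] = pd.to_datetime(meas["date"])
    return Cohort(patients, meas, era=era)


def measurements_frame(times, cd4, pid="A"):
    """Minimal per-patient measurement frame in time-since-sero units."""
    return pd.DataFrame(
        {
            "patient_id": pid,
            "time": np.asarray(times, dtype=float),
            "cd4": np.asarray(cd4, dtype=float),
        }
    )


def lmm_frame(rng, n_patients, beta0, beta1, sd_b0, sd_b1, sd_eps,
              n_visits=6, t_max=4.0):
    """Long frame drawn exactly from the random-intercept/slope model."""
    rows = []
    for i in range(n_patients):
        b0 = rng.normal(0, sd_b0)
        b1 = rng.normal(0, sd_b1)
        t = np.sort(rng.uniform(0, t_max, size=n_visits))
        y = beta0 + b0 + (beta1 + b1) * t + rng.normal(0, sd_eps, size=n_visits)
        for tt, yy in zip(t, y):
            rows.append((f"P{i:04d}", tt, yy))
    return pd.DataFrame(rows, columns=["patient_id", "time", "cd4"])


@pytest.fixture(scope="session")
def default_cohort():
    """A mid-sized cohort under the default (linear-trajectory) conditions."""
    cohort, truth = simulate_cohort(SimulationConfig(n_patients=400, seed=1))
    return cohort, truth


@pytest.fixture(scope="session")
def default_eligible(default_cohort):
    cohort, truth = default_cohort
    eligible, report = apply_eligibility(cohort)
    return eligible, report, truth
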
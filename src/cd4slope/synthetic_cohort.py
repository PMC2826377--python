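"""Synthetic seroconverter cohorts with the structure the analysis assumes.

Each simulated patient gets a seroconversion test window (last negative /
first positive, at most 3 years apart) with the true infection date at a
uniform point inside it, an irregular CD4 visit schedule, a latent CD4
trajectory from either a linear random-intercept/random-slope model or an
integrated Ornstein–Uhlenbeck process, independent measurement error,
CD4-threshold-driven (informative) cART initiation, and a post-cART
AIDS/death time from a proportional-hazards model on covariates frozen at
initiation.  Ground truth (random effects and realised slopes) is returned
separately and never consumed by the estimation stages.

Randomness is drawn from one stream per patient, keyed by
``(seed, patient index)``, so enlarging a cohort never perturbs
previously generated patients.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .cohort_io import Cohort, DAYS_PER_YEAR, ERA_CART, ERA_PRE_CART
from .longitudinal_models import iou_kernel

#: log-hazard coefficients of the post-baseline outcome model; covariates
#: are centred at typical values so ``baseline_hazard`` is close to the
#: marginal event rate per person-year.
DEFAULT_OUTCOME = {
    "cd4_per100": -0.35,
    "log10_vl": 0.35,
    "age_per10": 0.30,
    "prior_aids": 0.80,
    "slope_per10": 0.0,
}

_OUTCOME_CENTER = {"cd4_per100": 3.0, "log10_vl": 4.5, "age_per10": 3.6,
                   "prior_aids": 0.0, "slope_per10": -6.0}

TRANSMISSION_GROUPS = ("heterosexual", "msm", "idu", "other")
TRANSMISSION_PROBS = (0.26, 0.59, 0.09, 0.06)


@dataclass
class SimulationConfig:
    """Knobs of the cohort generator; defaults mimic a seroconverter cohort
    of the cART era (CD4 ~600 cells/µl at infection declining ~60/year,
    roughly twice-yearly monitoring, treatment triggered below 350)."""

    n_patients: int = 1000
    seed: int = 0
    era: str = ERA_CART
    trajectory: str = "linear"  # or "iou"
    beta0: float = 600.0  # mean CD4 at seroconversion, cells/µl
    beta1: float = -60.0  # population slope, cells/µl per year
    sd_b0: float = 150.0
    sd_b1: float = 25.0  # random-slope SD (linear trajectory)
    alpha: float = 10.0  # OU velocity mean-reversion, 1/years (iou)
    tau: float = 60.0  # stationary OU velocity SD, cells/µl per year (iou)
    sd_eps: float = 100.0  # measurement-error SD, cells/µl
    visit_interval_mean: float = 0.5  # years
    visit_schedule: str = "exponential"  # or "fixed"
    followup_max: float = 10.0  # years of pre-treatment visiting
    cart_threshold: float = 350.0
    cart_prob_per_visit: float = 0.75
    #: what the initiation decision sees: the noisy assay value ("observed",
    #: a missing-at-random mechanism the plain mixed model handles) or the
    #: patient's latent CD4 ("latent", the not-at-random regime the joint
    #: model is built to correct)
    cart_trigger: str = "observed"
    outcome: dict = field(default_factory=lambda: dict(DEFAULT_OUTCOME))
    baseline_hazard: float = 0.025  # events per person-year
    admin_censor: float = 5.0  # years of post-baseline follow-up
    test_window_max: float = 3.0  # widest seroconversion window, years
    sero_year_range: tuple = ()  # default depends on era
    vl_mean: float = 4.6
    vl_sd: float = 0.7
    vl_slope_coef: float = 0.0  # log10 VL shift per (slope_true/10)
    p_vl_missing: float = 0.05
    p_cd4_window_missing: float = 0.01
    p_prior_aids: float = 0.08
    p_female: float = 0.20
    age_mean: float = 33.0
    age_sd: float = 8.0
    p_death_given_event: float = 0.40

    def __post_init__(self) -> None:
        if self.n_patients < 0:
            raise ValueError("n_patients must be non-negative")
        for name in ("sd_b0", "sd_b1", "sd_eps", "tau", "vl_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.trajectory not in ("linear", "iou"):
            raise ValueError("trajectory must be 'linear' or 'iou'")
        if self.trajectory == "iou" and self.alpha <= 0:
            raise ValueError("alpha must be positive for the IOU trajectory")
        if not 0.0 <= self.cart_prob_per_visit <= 1.0:
            raise ValueError("cart_prob_per_visit must be in [0, 1]")
        if self.baseline_hazard < 0 or self.visit_interval_mean <= 0:
            raise ValueError("rates must be positive")
        if not 0 < self.test_window_max <= 3.0:
            raise ValueError("test_window_max must be in (0, 3] years")
        if self.era not in (ERA_CART, ERA_PRE_CART):
            raise ValueError(f"unknown era {self.era!r}")
        if self.cart_trigger not in ("observed", "latent"):
            raise ValueError("cart_trigger must be 'observed' or 'latent'")
        if not self.sero_year_range:
            self.sero_year_range = (
                (1996.5, 2004.0) if self.era == ERA_CART else (1986.0, 1991.5)
            )
        unknown = set(self.outcome) - set(DEFAULT_OUTCOME)
        if unknown:
            raise ValueError(f"unknown outcome coefficients: {sorted(unknown)}")
        full = dict(DEFAULT_OUTCOME)
        full.update(self.outcome)
        self.outcome = full

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        if "sero_year_range" in d:
            d["sero_year_range"] = tuple(d["sero_year_range"])
        return cls(**d)


def draw_trajectory_linear(times, b0: float, b1: float, config: SimulationConfig):
    """Latent CD4 at ``times``: ``beta0 + b0 + (beta1 + b1) t``."""
    t = np.asarray(times, dtype=float)
    return config.beta0 + b0 + (config.beta1 + b1) * t


def draw_trajectory_iou(
    times, b0: float, config: SimulationConfig, rng: np.random.Generator
):
    """Latent CD4 from the IOU model, sampled exactly.

    One joint multivariate-normal draw of the integrated process using the
    stationary-start IOU kernel (no Euler discretisation); ``W(0) = 0`` so
    the value at time zero is ``beta0 + b0`` exactly.
    """
    t = np.asarray(times, dtype=float)
    if np.any(np.diff(t) < 0) or np.any(t < 0):
        raise ValueError("times must be sorted and non-negative")
    sigma2 = 2.0 * config.alpha * config.tau**2
    W = np.zeros_like(t)
    pos = t > 0  # W(0) = 0 exactly; keep the kernel non-singular
    if pos.any():
        tp = t[pos]
        K = iou_kernel(tp[:, None], tp[None, :], config.alpha, sigma2)
        W[pos] = _mvn_draw(K, rng)
    return config.beta0 + b0 + config.beta1 * t + W


def _mvn_draw(K: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    z = rng.standard_normal(K.shape[0])
    jitter = 0.0
    for _ in range(4):
        try:
            L = np.linalg.cholesky(K + jitter * np.eye(K.shape[0]))
            return L @ z
        except np.linalg.LinAlgError:
            scale = max(np.mean(np.diag(K)), 1e-12)
            jitter = scale * 1e-10 if jitter == 0.0 else jitter * 100.0
    raise np.linalg.LinAlgError("IOU kernel not positive definite after jitter")


def _patient_rng(seed: int, index: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(index,))
    )


def _year_to_date(year_float: float) -> pd.Timestamp:
    base = pd.Timestamp("1970-01-01")
    return base + pd.Timedelta(days=round((year_float - 1970.0) * DAYS_PER_YEAR))


def simulate_cohort(config: SimulationConfig) -> tuple[Cohort, pd.DataFrame]:
    """Simulate a cohort and its ground truth.

    Returns ``(cohort, truth)`` where ``truth`` has one row per patient:
    ``patient_id, b0, b1, slope_true, sero_offset_years`` (``b1`` is NaN
    for the IOU trajectory; ``slope_true`` is the realised average slope
    over the observed pre-treatment period; ``sero_offset_years`` is the
    signed error of the midpoint seroconversion estimate).  Measurement
    dates are quantised to whole days and the latent trajectory is
    evaluated at the quantised times, so noise-free configurations are
    exactly linear in the recorded times.
    """
    patients = []
    meas_rows = []
    truth_rows = []
    pre_cart = config.era == ERA_PRE_CART
    censor_cal = pd.Timestamp("1995-12-31")

    for i in range(config.n_patients):
        rng = _patient_rng(config.seed, i)
        pid = f"P{i:05d}"

        # --- seroconversion window ---------------------------------------
        w = rng.uniform(0.0, config.test_window_max)
        w = max(w, 1.0 / DAYS_PER_YEAR)  # window width strictly positive
        v = rng.uniform()
        y0, y1 = config.sero_year_range
        sero_true_cal = _year_to_date(rng.uniform(y0, y1))
        last_negative = sero_true_cal - pd.Timedelta(days=round(v * w * DAYS_PER_YEAR))
        first_positive = last_negative + pd.Timedelta(days=round(w * DAYS_PER_YEAR))
        sero_est = last_negative + (first_positive - last_negative) / 2

        sex = "female" if rng.uniform() < config.p_female else "male"
        age = float(np.clip(rng.normal(config.age_mean, config.age_sd), 16, 75))
        tg = TRANSMISSION_GROUPS[
            rng.choice(len(TRANSMISSION_GROUPS), p=TRANSMISSION_PROBS)
        ]
        prior_aids = bool(rng.uniform() < config.p_prior_aids)

        # --- visit schedule (days since true seroconversion) -------------
        # monitoring begins at diagnosis (the first positive test), so all
        # measurement times are non-negative relative to the midpoint estimate
        times = []
        t = (first_positive - sero_true_cal).days / DAYS_PER_YEAR
        while True:
            gap = (
                config.visit_interval_mean
                if config.visit_schedule == "fixed"
                else rng.exponential(config.visit_interval_mean)
            )
            t += gap
            if t > config.followup_max:
                break
            times.append(t)
        t_days = np.unique(np.maximum(np.round(np.asarray(times) * DAYS_PER_YEAR), 1))
        times = t_days / DAYS_PER_YEAR
        if pre_cart:
            # visits stop at the administrative end of the era
            dates_all = sero_true_cal + pd.to_timedelta(t_days, unit="D")
            keep = dates_all <= censor_cal
            times, t_days = times[keep], t_days[keep]

        # --- latent trajectory and observations --------------------------
        b0 = rng.normal(0.0, config.sd_b0)
        if config.trajectory == "linear":
            b1 = rng.normal(0.0, config.sd_b1)
            latent = draw_trajectory_linear(times, b0, b1, config)
        else:
            b1 = np.nan
            latent = draw_trajectory_iou(times, b0, config, rng)
        eps = rng.normal(0.0, config.sd_eps, size=len(times))
        observed = np.maximum(latent + eps, 0.0)

        # --- informative cART initiation ----------------------------------
        cart_idx = None
        if not pre_cart and config.cart_prob_per_visit > 0:
            fires = rng.uniform(size=len(times)) < config.cart_prob_per_visit
            trigger_value = (
                observed if config.cart_trigger == "observed" else latent
            )
            below = trigger_value < config.cart_threshold
            hits = np.flatnonzero(below & fires)
            if len(hits):
                cart_idx = int(hits[0])
        if cart_idx is not None:
            keep = slice(0, cart_idx + 1)
        else:
            keep = slice(0, len(times))
        times_kept = times[keep]
        observed_kept = observed[keep]
        latent_kept = latent[keep]
        t_days_kept = t_days[keep]

        if len(times_kept) == 0:
            slope_true = config.beta1 if config.trajectory == "iou" else config.beta1 + b1
        elif config.trajectory == "linear":
            slope_true = config.beta1 + b1
        else:
            # realised average slope over the observed period:
            # (X(t_last) - X(0)) / t_last = beta1 + W(t_last) / t_last
            t_last = times_kept[-1]
            if t_last > 0:
                slope_true = (latent_kept[-1] - (config.beta0 + b0)) / t_last
            else:
                slope_true = config.beta1

        dates = sero_true_cal + pd.to_timedelta(t_days_kept, unit="D")

        # drop the treatment-window CD4 occasionally (exclusion-path fuel)
        drop_window_cd4 = (
            cart_idx is not None
            and rng.uniform() < config.p_cd4_window_missing
            and len(times_kept) > 1
        )

        cart_date = pd.NaT
        log10_vl = np.nan
        aids_date = pd.NaT
        death_date = pd.NaT
        if cart_idx is not None:
            cart_date = dates[-1]
            if rng.uniform() >= config.p_vl_missing:
                log10_vl = rng.normal(
                    config.vl_mean + config.vl_slope_coef * (slope_true / 10.0),
                    config.vl_sd,
                )
            cd4_at_base = observed_kept[-1]
            lp = _linear_predictor(
                config.outcome,
                cd4=cd4_at_base,
                log10_vl=log10_vl if np.isfinite(log10_vl) else config.vl_mean,
                age=age + times_kept[-1],
                prior_aids=prior_aids,
                slope=slope_true,
            )
            rate = config.baseline_hazard * np.exp(lp)
            t_event = rng.exponential(1.0 / rate) if rate > 0 else np.inf
            if t_event < config.admin_censor:
                event_date = cart_date + pd.Timedelta(
                    days=max(round(t_event * DAYS_PER_YEAR), 1)
                )
                if rng.uniform() < config.p_death_given_event:
                    death_date = event_date
                else:
                    aids_date = event_date
                last_visit = event_date
            else:
                last_visit = cart_date + pd.Timedelta(
                    days=round(config.admin_censor * DAYS_PER_YEAR)
                )
        elif pre_cart and len(times_kept):
            # outcome clock starts at the last 1993 visit, mirroring the
            # supplementary-era baseline definition
            base_idx = _last_index_in_year(dates, 1993)
            last_visit = dates[-1]
            if base_idx is not None:
                base_date = dates[base_idx]
                lp = _linear_predictor(
                    config.outcome,
                    cd4=observed_kept[base_idx],
                    log10_vl=config.vl_mean,  # VL not used in this era
                    age=age + times_kept[base_idx],
                    prior_aids=prior_aids,
                    slope=slope_true,
                    use_vl=False,
                )
                rate = config.baseline_hazard * np.exp(lp)
                t_event = rng.exponential(1.0 / rate) if rate > 0 else np.inf
                if t_event < config.admin_censor:
                    event_date = base_date + pd.Timedelta(
                        days=max(round(t_event * DAYS_PER_YEAR), 1)
                    )
                    if rng.uniform() < config.p_death_given_event:
                        death_date = event_date
                    else:
                        aids_date = event_date
                    last_visit = max(last_visit, event_date)
                else:
                    last_visit = max(
                        last_visit,
                        base_date
                        + pd.Timedelta(
                            days=round(config.admin_censor * DAYS_PER_YEAR)
                        ),
                    )
        else:
            last_visit = (
                dates[-1] if len(dates) else sero_true_cal + pd.Timedelta(days=30)
            )

        if drop_window_cd4:
            dates_out = dates[:-1]
            obs_out = observed_kept[:-1]
        else:
            dates_out = dates
            obs_out = observed_kept
        for d, cd4 in zip(dates_out, obs_out):
            meas_rows.append((pid, d, float(cd4), np.nan))

        patients.append(
            {
                "patient_id": pid,
                "sex": sex,
                "age_at_baseline": round(
                    age
                    + (
                        times_kept[-1]
                        if cart_idx is not None and len(times_kept)
                        else 0.0
                    ),
                    2,
                ),
                "transmission_group": tg,
                "prior_aids": prior_aids,
                "last_negative_date": last_negative,
                "first_positive_date": first_positive,
                "seroconversion_date": sero_est,
                "cart_date": cart_date,
                "log10_vl_at_cart": (
                    round(log10_vl, 3) if np.isfinite(log10_vl) else np.nan
                ),
                "aids_date": aids_date,
                "death_date": death_date,
                "last_visit_date": last_visit,
            }
        )
        truth_rows.append(
            {
                "patient_id": pid,
                "b0": b0,
                "b1": b1,
                "slope_true": slope_true,
                "sero_offset_years": (sero_est - sero_true_cal).days / DAYS_PER_YEAR,
            }
        )

    patients = pd.DataFrame(patients)
    measurements = pd.DataFrame(
        meas_rows, columns=["patient_id", "date", "cd4", "log10_vl"]
    )
    if len(measurements) == 0:
        measurements = pd.DataFrame(
            columns=["patient_id", "date", "cd4", "log10_vl"]
        )
    measurements["date"] = pd.to_datetime(measurements["date"])
    cohort = Cohort(patients, measurements, era=config.era)
    truth = pd.DataFrame(truth_rows)
    return cohort, truth


def _last_index_in_year(dates, year: int):
    years = pd.DatetimeIndex(dates).year
    idx = np.flatnonzero(years == year)
    return int(idx[-1]) if len(idx) else None


#: representative CD4 of each baseline category; the hazard acts through
#: the category, so stratified adjustment on the same category absorbs the
#: baseline-CD4 signal completely and a zero slope coefficient really does
#: mean "no signal beyond the adjustment covariates"
_CD4_STRATUM_MIDPOINTS = np.array([50.0, 150.0, 275.0, 450.0])


def _cd4_stratum_value(cd4: float) -> float:
    idx = int(np.searchsorted([100.0, 200.0, 350.0], cd4, side="right"))
    return float(_CD4_STRATUM_MIDPOINTS[idx])


def _linear_predictor(
    coefs: dict,
    cd4: float,
    log10_vl: float,
    age: float,
    prior_aids: bool,
    slope: float,
    use_vl: bool = True,
) -> float:
    x = {
        "cd4_per100": _cd4_stratum_value(cd4) / 100.0,
        "log10_vl": log10_vl if use_vl else _OUTCOME_CENTER["log10_vl"],
        "age_per10": age / 10.0,
        "prior_aids": float(prior_aids),
        "slope_per10": slope / 10.0,
    }
    return sum(
        coefs[k] * (x[k] - _OUTCOME_CENTER[k]) for k in coefs
    )


def write_truth(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, index=False)
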
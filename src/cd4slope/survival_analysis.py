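"""Outcome models: stratified Cox regression, discrimination, event rates.

The prognostic question is whether the pre-treatment CD4 slope adds to the
established baseline predictors (CD4 stratum, log10 viral load, age, prior
AIDS, injection-drug-use transmission) for AIDS/death after cART
initiation.  Cox models stratify on the CD4 category × IDU cross, handle
ties by Efron's method, and report the hazard ratio per +10 cells/µl/year
higher (less steeply declining) slope with Wald confidence limits.
Discrimination uses a Harrell-type concordance over pairs comparable
within a 5-year horizon, scored by the predicted 5-year event probability
(Breslow baseline per stratum).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter

CD4_STRATA = ("<100", "100-<200", "200-<350", ">=350")


def cd4_stratum(cd4) -> np.ndarray:
    """Baseline CD4 category: <100, 100–<200, 200–<350, >=350 cells/µl."""
    cd4 = np.asarray(cd4, dtype=float)
    bins = np.array([100.0, 200.0, 350.0])
    return np.asarray(CD4_STRATA, dtype=object)[np.searchsorted(bins, cd4, side="right")]


@dataclass
class EventRate:
    n_events: int
    person_years: float
    rate_per_100py: float
    ci: tuple[float, float]


def event_rate(n_events: int, person_years: float) -> EventRate:
    """Events per 100 person-years with a normal-approximation Poisson CI.

    ``CI = 100 (n ± 1.96 sqrt(n)) / person_years``, floored at zero.
    """
    if person_years <= 0:
        raise ValueError("person_years must be positive")
    rate = 100.0 * n_events / person_years
    half = 1.96 * np.sqrt(n_events)
    lo = max(100.0 * (n_events - half) / person_years, 0.0)
    hi = 100.0 * (n_events + half) / person_years
    return EventRate(int(n_events), float(person_years), float(rate), (float(lo), float(hi)))


@dataclass
class CoxFit:
    """Summary of a (possibly stratified) proportional-hazards fit."""

    coefficients: pd.DataFrame  # index covariate; columns coef, se, p, hr, hr_lo, hr_hi
    hr_slope_per10: float
    hr_ci: tuple[float, float]
    p_slope: float
    n: int
    n_events: int
    n_strata: int
    loglik: float
    flagged: bool = False
    model_: object = field(default=None, repr=False)


def _flagged_fit(df, duration_col, event_col, covariates) -> CoxFit:
    coef = pd.DataFrame(
        np.nan,
        index=covariates,
        columns=["coef", "se", "p", "hr", "hr_lo", "hr_hi"],
    )
    return CoxFit(
        coefficients=coef,
        hr_slope_per10=np.nan,
        hr_ci=(np.nan, np.nan),
        p_slope=np.nan,
        n=len(df),
        n_events=int(df[event_col].sum()),
        n_strata=0,
        loglik=np.nan,
        flagged=True,
    )


def cox_fit_stratified(
    records: pd.DataFrame,
    covariates: list[str],
    strata: tuple[str, ...] | None = ("cd4_stratum", "idu"),
    duration_col: str = "time",
    event_col: str = "event",
) -> CoxFit:
    """Stratified Cox model of the records.

    ``slope`` in ``covariates`` is rescaled to ``slope_per10`` (per +10
    cells/µl per year) before fitting, so its hazard ratio is directly the
    quantity of interest.  Ties are handled by Efron's method (the
    lifelines default).  Degenerate inputs (a constant covariate, or
    apparent separation) yield a flagged fit rather than an exception.
    """
    df = records.copy()
    covs = list(covariates)
    if "slope" in covs:
        df["slope_per10"] = df["slope"] / 10.0
        covs[covs.index("slope")] = "slope_per10"
    use_cols = covs + [duration_col, event_col] + list(strata or ())
    df = df[use_cols].dropna()
    if len(df) == 0 or df[event_col].sum() == 0:
        return _flagged_fit(df, duration_col, event_col, covs)
    for c in covs:
        if df[c].nunique() <= 1:
            return _flagged_fit(df, duration_col, event_col, covs)

    cph = CoxPHFitter()
    flagged = False
    try:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            cph.fit(
                df,
                duration_col=duration_col,
                event_col=event_col,
                strata=list(strata) if strata else None,
            )
        flagged = any("convergence" in str(w.message).lower() for w in caught)
    except Exception:
        return _flagged_fit(df, duration_col, event_col, covs)

    summ = cph.summary
    coef = pd.DataFrame(
        {
            "coef": summ["coef"],
            "se": summ["se(coef)"],
            "p": summ["p"],
            "hr": np.exp(summ["coef"]),
            "hr_lo": np.exp(summ["coef"] - 1.96 * summ["se(coef)"]),
            "hr_hi": np.exp(summ["coef"] + 1.96 * summ["se(coef)"]),
        }
    )
    if "slope_per10" in coef.index:
        row = coef.loc["slope_per10"]
        hr, lo, hi, p = row["hr"], row["hr_lo"], row["hr_hi"], row["p"]
    else:
        hr = lo = hi = p = np.nan
    n_strata = (
        int(df.groupby(list(strata)).ngroups) if strata else 1
    )
    return CoxFit(
        coefficients=coef,
        hr_slope_per10=float(hr),
        hr_ci=(float(lo), float(hi)),
        p_slope=float(p),
        n=len(df),
        n_events=int(df[event_col].sum()),
        n_strata=n_strata,
        loglik=float(cph.log_likelihood_),
        flagged=flagged,
        model_=cph,
    )


@dataclass
class ConcordanceResult:
    c: float
    horizon: float
    n_comparable_pairs: int


def concordance_5y(
    durations, events, risk_scores, horizon: float = 5.0
) -> ConcordanceResult:
    """Harrell-type c index over pairs comparable within a horizon.

    A pair ``(i, j)`` is comparable when ``t_i < t_j``, ``t_i <= horizon``
    and subject ``i`` had the event; the pair is concordant when the
    earlier failure carries the higher risk score, and score ties count
    one half.
    """
    t = np.asarray(durations, dtype=float)
    d = np.asarray(events, dtype=bool)
    s = np.asarray(risk_scores, dtype=float)
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    comparable = (t[:, None] < t[None, :]) & (t[:, None] <= horizon) & d[:, None]
    n_pairs = int(comparable.sum())
    if n_pairs == 0:
        raise ValueError("no comparable pairs within the horizon")
    better = s[:, None] > s[None, :]
    tied = s[:, None] == s[None, :]
    conc = float((comparable & better).sum()) + 0.5 * float((comparable & tied).sum())
    return ConcordanceResult(conc / n_pairs, float(horizon), n_pairs)


def risk_scores_5y(fit: CoxFit, records: pd.DataFrame, horizon: float = 5.0) -> np.ndarray:
    """Predicted event probability by ``horizon`` years for each record.

    ``1 - exp(-H0_s(horizon) * exp(lp))`` with ``H0_s`` the Breslow
    baseline cumulative hazard of the subject's stratum (lifelines centres
    the linear predictor and the baseline consistently).  A subject whose
    stratum was absent from the fitting data is an error.
    """
    if fit.model_ is None:
        raise ValueError("fit carries no underlying model (flagged fit?)")
    cph: CoxPHFitter = fit.model_
    df = records.copy()
    if "slope_per10" in cph.summary.index.tolist() and "slope_per10" not in df:
        df["slope_per10"] = df["slope"] / 10.0
    bch = cph.baseline_cumulative_hazard_
    strata = cph.strata
    if strata:
        key = list(strata)
        H0 = {}
        for col in bch.columns:
            grid = bch[col]
            idx = grid.index.searchsorted(horizon, side="right") - 1
            H0[col] = float(grid.iloc[idx]) if idx >= 0 else 0.0
        tuples = list(df[key].itertuples(index=False, name=None))
        tuples = [t if len(t) > 1 else t[0] for t in tuples]
        missing = [t for t in tuples if t not in H0]
        if missing:
            raise ValueError(f"stratum {missing[0]!r} absent from the fitted model")
        H = np.array([H0[t] for t in tuples])
    else:
        grid = bch.iloc[:, 0]
        idx = grid.index.searchsorted(horizon, side="right") - 1
        H = np.full(len(df), float(grid.iloc[idx]) if idx >= 0 else 0.0)
    lp = cph.predict_log_partial_hazard(df).to_numpy(dtype=float)
    return 1.0 - np.exp(-H * np.exp(lp))


def quartile_event_table(records: pd.DataFrame, slope_col: str = "slope"):
    """Event counts cross-classified by empirical slope quartiles.

    Cut points are the 25/50/75 percentiles over all analysed patients;
    values exactly at a cut point go to the lower quartile.  Returns
    ``(counts, cuts)`` with ``counts.sum() == n_events``.
    """
    s = records[slope_col].to_numpy(dtype=float)
    if len(np.unique(s)) < 4:
        raise ValueError("need at least 4 distinct slope values")
    cuts = np.percentile(s, [25, 50, 75])
    q = np.searchsorted(cuts, s, side="left")
    ev = records["event"].to_numpy(dtype=bool)
    counts = np.array([int(ev[q == k].sum()) for k in range(4)])
    return counts, cuts


def rapid_decline_binary_cox(
    records: pd.DataFrame,
    threshold: float = 100.0,
    covariates: list[str] | None = None,
    strata: tuple[str, ...] | None = ("cd4_stratum", "idu"),
    **kwargs,
) -> CoxFit:
    """Cox fit with the slope dichotomised at a rapid-decline threshold.

    ``rapid`` is a decline steeper than ``threshold`` cells/µl per year
    (slope < -threshold), entered in place of the continuous slope.
    """
    df = records.copy()
    df["rapid"] = (df["slope"] < -threshold).astype(float)
    covs = ["rapid"] + [c for c in (covariates or []) if c != "slope"]
    return cox_fit_stratified(df, covs, strata=strata, **kwargs)


def make_survival_records(
    cohort,
    endpoint_df: pd.DataFrame,
    slopes: pd.DataFrame,
    include_vl: bool = True,
) -> pd.DataFrame:
    """Assemble the per-patient survival analysis frame.

    Joins the endpoint table with slope estimates and baseline covariates;
    requires the patient table to carry ``baseline_cd4`` (attached by the
    eligibility filter or the pre-cART baseline construction).
    """
    p = cohort.patients.set_index("patient_id")
    df = endpoint_df.merge(
        slopes[["patient_id", "slope"]], on="patient_id", how="inner"
    )
    df["cd4_stratum"] = cd4_stratum(p.loc[df["patient_id"], "baseline_cd4"].to_numpy())
    df["idu"] = (
        p.loc[df["patient_id"], "transmission_group"].to_numpy() == "idu"
    ).astype(float)
    df["age"] = p.loc[df["patient_id"], "age_at_baseline"].to_numpy(dtype=float)
    df["prior_aids"] = p.loc[df["patient_id"], "prior_aids"].to_numpy().astype(float)
    df["baseline_cd4"] = p.loc[df["patient_id"], "baseline_cd4"].to_numpy(dtype=float)
    if include_vl:
        df["log10_vl"] = p.loc[df["patient_id"], "log10_vl_at_cart"].to_numpy(
            dtype=float
        )
    return df
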
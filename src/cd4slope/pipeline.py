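"""End-to-end orchestration of the slope-prognosis analysis.

``run_main_analysis`` walks the cART-era stages — eligibility, slope
estimation by every method, longitudinal model fits and comparison, and
stratified Cox outcome models with discrimination — and writes a
human-readable table bundle plus a machine-readable JSON bundle.
``run_pre_cart_analysis`` is the 1989–1995 supplementary variant and
``run_sensitivity_suite`` reruns the adjusted outcome model across the
alternative slope estimators.
"""

from __future__ import annotations

import hashlib
import json
import logging
import pathlib
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import cohort_io as cio
from . import slope_estimators as se
from . import longitudinal_models as lm
from . import survival_analysis as sa

log = logging.getLogger("cd4slope")

__version__ = "0.1.0"

ADJUSTED_COVARIATES = ["slope", "log10_vl", "age", "prior_aids"]
STRATA = ("cd4_stratum", "idu")


@dataclass
class AnalysisConfig:
    """Configuration of one pipeline run."""

    era: str = cio.ERA_CART
    endpoints: tuple = (cio.ENDPOINT_AIDS_OR_DEATH, cio.ENDPOINT_DEATH)
    subgroups: tuple = ("all", "cd4_gt_350")
    slope_method: str = "blup"
    slope_filter: str = "none"
    scale: str = "raw"
    binary_threshold: float = 100.0
    horizon: float = 5.0
    include_iou: bool = True
    include_joint: bool = False
    seed: int = 0

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        for k in ("endpoints", "subgroups"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


def _fingerprint_frame(df: pd.DataFrame) -> str:
    h = hashlib.sha256()
    h.update(df.to_csv(index=False).encode())
    return h.hexdigest()[:16]


def build_manifest(config: AnalysisConfig, cohort: cio.Cohort, counts: dict) -> dict:
    cfg = asdict(config)
    cfg["endpoints"] = list(config.endpoints)
    cfg["subgroups"] = list(config.subgroups)
    return {
        "software_version": __version__,
        "config": cfg,
        "seed": config.seed,
        "input_fingerprints": {
            "patients": _fingerprint_frame(
                cohort.patients.astype(str).sort_index(axis=1)
            ),
            "measurements": _fingerprint_frame(cohort.measurements.astype(str)),
        },
        "stage_counts": counts,
    }


def _subgroup(records: pd.DataFrame, name: str) -> pd.DataFrame:
    if name == "all":
        return records
    if name == "cd4_gt_350":
        return records[records["baseline_cd4"] > 350.0]
    raise ValueError(f"unknown subgroup {name!r}")


def _outcome_block(records: pd.DataFrame, include_vl: bool, horizon: float) -> dict:
    """Table-2-style summary for one endpoint × subgroup cell."""
    n = len(records)
    n_events = int(records["event"].sum())
    py = float(records["time"].sum())
    if n == 0 or py <= 0:
        return {"n": n, "n_events": n_events, "person_years": py,
                "error": "no follow-up in this cell"}
    rate = sa.event_rate(n_events, py)

    unadj = sa.cox_fit_stratified(records, ["slope"], strata=None)
    try:
        c_slope = sa.concordance_5y(
            records["time"], records["event"], -records["slope"], horizon=horizon
        ).c
    except ValueError:
        c_slope = np.nan

    covs = [c for c in ADJUSTED_COVARIATES if include_vl or c != "log10_vl"]
    adj = sa.cox_fit_stratified(records, covs, strata=STRATA)
    covs_wo = [c for c in covs if c != "slope"]
    adj_wo = sa.cox_fit_stratified(records, covs_wo, strata=STRATA)

    def c_of(fit, recs):
        if fit.flagged or fit.model_ is None or len(recs) == 0:
            return np.nan
        try:
            scores = sa.risk_scores_5y(fit, recs, horizon=horizon)
            return sa.concordance_5y(
                recs["time"], recs["event"], scores, horizon=horizon
            ).c
        except ValueError:
            return np.nan

    used = records.dropna(
        subset=[c for c in covs + ["time", "event"]]
    )
    c_with = c_of(adj, used)
    c_without = c_of(adj_wo, used)

    return {
        "n": n,
        "n_events": n_events,
        "pct_events": 100.0 * n_events / n if n else np.nan,
        "person_years": py,
        "event_rate_per_100py": rate.rate_per_100py,
        "event_rate_ci": list(rate.ci),
        "unadjusted_hr_per10": unadj.hr_slope_per10,
        "unadjusted_hr_ci": list(unadj.hr_ci),
        "unadjusted_p": unadj.p_slope,
        "c_slope_alone": c_slope,
        "adjusted_hr_per10": adj.hr_slope_per10,
        "adjusted_hr_ci": list(adj.hr_ci),
        "adjusted_p": adj.p_slope,
        "c_without_slope": c_without,
        "c_with_slope": c_with,
    }


def run_main_analysis(cohort: cio.Cohort, config: AnalysisConfig, out_dir=None) -> dict:
    """cART-era pipeline: eligibility → slopes → model fits → outcome models.

    Returns (and optionally writes) a result bundle with the eligibility
    report, slope summaries per method, the LMM/IOU comparison, the
    quartile event table and a Table-2 analogue per endpoint × subgroup.
    """
    counts: dict = {"input_patients": cohort.n_patients}
    eligible, report = cio.apply_eligibility(cohort)
    counts["eligible"] = report.n_eligible
    log.info("eligibility: %d of %d retained", report.n_eligible, report.n_input)

    slope_frames = {}
    lmm_fit_raw = lm.fit_lmm(eligible, scale=config.scale)
    for method in ("two_point", "ols", "blup"):
        kwargs = {"fit": lmm_fit_raw} if method == "blup" else {}
        slope_frames[method] = se.estimate_slopes(eligible, method, **kwargs)
    if config.include_joint:
        slope_frames["joint"] = se.estimate_slopes(eligible, "joint")
    summaries = {
        m: asdict_summary(se.summarize_slopes(f, config.binary_threshold))
        for m, f in slope_frames.items()
    }
    counts["slopes"] = {m: len(f) for m, f in slope_frames.items()}

    comparison = None
    if config.include_iou:
        lmm_sqrt = lm.fit_lmm(eligible, scale="sqrt")
        iou_sqrt = lm.fit_iou(eligible, scale="sqrt")
        comp = lm.compare_models(lmm_sqrt, iou_sqrt)
        comparison = {
            "aic_lmm": comp.aic_lmm,
            "aic_iou": comp.aic_iou,
            "delta_aic": comp.delta_aic,
            "preferred": comp.preferred,
            "alpha_hat": iou_sqrt.alpha,
        }

    slopes = slope_frames[config.slope_method]
    tables: dict = {}
    quartiles = None
    binary = None
    for endpoint in config.endpoints:
        ep = cio.build_endpoint(eligible, endpoint)
        records = sa.make_survival_records(eligible, ep, slopes)
        if endpoint == cio.ENDPOINT_AIDS_OR_DEATH and quartiles is None:
            counts_q, cuts_q = sa.quartile_event_table(records)
            quartiles = {"counts": counts_q.tolist(), "cuts": cuts_q.tolist()}
            bfit = sa.rapid_decline_binary_cox(
                records, threshold=config.binary_threshold,
                covariates=ADJUSTED_COVARIATES, strata=STRATA,
            )
            binary = {
                "threshold": config.binary_threshold,
                "hr_rapid": (
                    float(np.exp(bfit.coefficients.loc["rapid", "coef"]))
                    if not bfit.flagged else None
                ),
                "p": float(bfit.coefficients.loc["rapid", "p"])
                if not bfit.flagged else None,
                "flagged": bfit.flagged,
            }
        for sub in config.subgroups:
            recs = _subgroup(records, sub)
            tables[f"{endpoint}/{sub}"] = _outcome_block(
                recs, include_vl=True, horizon=config.horizon
            )
            counts[f"records_{endpoint}_{sub}"] = len(recs)

    bundle = {
        "eligibility": {
            "n_input": report.n_input,
            "n_eligible": report.n_eligible,
            "exclusions": report.exclusions,
        },
        "slope_summaries": summaries,
        "model_comparison": comparison,
        "quartile_events": quartiles,
        "binary_slope": binary,
        "outcome_tables": tables,
        "manifest": build_manifest(config, cohort, counts),
    }
    if out_dir is not None:
        write_bundle(bundle, out_dir, report=report)
    return bundle


def asdict_summary(s: se.SlopeSummary) -> dict:
    return {
        "method": s.method,
        "median": s.median,
        "iqr": list(s.iqr),
        "prop_rapid": s.prop_rapid,
        "threshold": s.threshold,
        "n": s.n,
    }


def run_pre_cart_analysis(
    cohort: cio.Cohort, config: AnalysisConfig, out_dir=None
) -> dict:
    """Supplementary 1989–1995 pipeline (no viral-load adjustment).

    Runs the main variant and the sensitivity variant that drops patients
    on any antiretroviral therapy by the baseline year.
    """
    bundles = {}
    for sens, label in ((False, "main"), (True, "no_art_sensitivity")):
        built = cio.build_pre_cart_baseline(cohort, exclude_any_art=sens)
        if built.n_patients < 10:
            bundles[label] = {"error": "too few patients after baseline rule"}
            continue
        lmm_fit = lm.fit_lmm(built, scale=config.scale)
        slopes = se.slopes_blup(built, fit=lmm_fit)
        ep = built.patients[["patient_id", "pc_time", "pc_event"]].rename(
            columns={"pc_time": "time", "pc_event": "event"}
        )
        records = sa.make_survival_records(built, ep, slopes, include_vl=False)
        tables = {}
        for sub in config.subgroups:
            recs = _subgroup(records, sub)
            if len(recs) == 0 or recs["event"].sum() == 0:
                tables[sub] = {"error": "no events"}
                continue
            n_events = int(recs["event"].sum())
            py = float(recs["time"].sum())
            rate = sa.event_rate(n_events, py)
            unadj = sa.cox_fit_stratified(recs, ["slope"], strata=None)
            adj = sa.cox_fit_stratified(
                recs, ["slope", "age"], strata=STRATA
            )
            tables[sub] = {
                "n": len(recs),
                "n_events": n_events,
                "pct_events": 100.0 * n_events / len(recs),
                "event_rate_per_100py": rate.rate_per_100py,
                "event_rate_ci": list(rate.ci),
                "unadjusted_hr_per10": unadj.hr_slope_per10,
                "unadjusted_hr_ci": list(unadj.hr_ci),
                "adjusted_hr_per10": adj.hr_slope_per10,
                "adjusted_hr_ci": list(adj.hr_ci),
                "adjusted_p": adj.p_slope,
            }
        bundles[label] = {
            "n_patients": built.n_patients,
            "median_slope": float(slopes["slope"].median()),
            "tables": tables,
        }
    bundle = {
        "pre_cart": bundles,
        "manifest": build_manifest(config, cohort, {"input": cohort.n_patients}),
    }
    if out_dir is not None:
        write_bundle(bundle, out_dir)
    return bundle


SENSITIVITY_VARIANTS = (
    ("blup", "drop_first_6mo"),
    ("blup", "last_2y_window"),
    ("blup", "seroconversion_1996_plus"),
    ("ols", "none"),
    ("joint", "none"),
)


def run_sensitivity_suite(cohort: cio.Cohort, config: AnalysisConfig) -> pd.DataFrame:
    """Adjusted slope effect across the alternative slope estimators.

    One row per variant with the adjusted hazard ratio per +10 cells/µl/yr
    and its p-value; a failing variant is recorded and the suite
    continues.
    """
    eligible, _ = cio.apply_eligibility(cohort)
    ep = cio.build_endpoint(eligible, cio.ENDPOINT_AIDS_OR_DEATH)
    rows = []
    for method, filt in SENSITIVITY_VARIANTS:
        label = f"{method}/{filt}"
        try:
            if method == "blup":
                slopes = se.slopes_blup(eligible, slope_filter=filt)
            else:
                slopes = se.estimate_slopes(eligible, method)
            records = sa.make_survival_records(eligible, ep, slopes)
            adj = sa.cox_fit_stratified(records, ADJUSTED_COVARIATES, strata=STRATA)
            rows.append(
                (label, method, filt, adj.hr_slope_per10, adj.hr_ci[0],
                 adj.hr_ci[1], adj.p_slope, adj.n, False, "")
            )
        except Exception as exc:  # variant-specific failure, suite continues
            rows.append(
                (label, method, filt, np.nan, np.nan, np.nan, np.nan, 0, True,
                 str(exc))
            )
    return pd.DataFrame(
        rows,
        columns=[
            "variant", "method", "filter", "adjusted_hr_per10", "hr_lo",
            "hr_hi", "p", "n", "failed", "error",
        ],
    )


def write_bundle(bundle: dict, out_dir, report: cio.EligibilityReport | None = None):
    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "manifest.json").write_text(
        json.dumps(bundle.get("manifest", {}), indent=2, sort_keys=True)
    )
    (out / "results.json").write_text(
        json.dumps(_jsonable(bundle), indent=2, sort_keys=True)
    )
    if report is not None:
        report.write_tsv(out / "eligibility.tsv")
    tables = bundle.get("outcome_tables")
    if tables:
        frames = []
        for key, block in tables.items():
            row = {"cell": key}
            row.update(block)
            frames.append(row)
        pd.DataFrame(frames).to_csv(out / "outcome_tables.tsv", sep="\t", index=False)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj
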
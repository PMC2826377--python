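"""Longitudinal CD4 trajectory models and their maximum-likelihood fits.

Three marginal models for pre-treatment CD4 trajectories are implemented,
all Gaussian and all fitted by (restricted) maximum likelihood on either
raw or square-root-transformed counts:

* a linear mixed model (LMM) with patient-specific random intercept and
  random slope in time since seroconversion — the working model behind
  BLUP slope estimation;
* an integrated Ornstein–Uhlenbeck (IOU) model with a random intercept, a
  fixed population slope, an integrated OU velocity process and
  measurement error.  Its stability parameter ``alpha`` is the
  mean-reversion rate of the velocity: ``alpha -> 0`` recovers the
  constant-patient-slope LMM (with slope variance ``sigma2/(2*alpha)``),
  while ``alpha -> inf`` with ``sigma2/alpha**2`` fixed gives Brownian
  fluctuation around the population slope;
* a joint model coupling the LMM with a proportional-hazards model for
  time to cART initiation whose linear predictor loads on the shared
  random effects — the initiation process acting as a missing-data
  mechanism for informatively truncated CD4 series.

All covariance matrices are built per patient and the likelihood is the sum
of per-patient multivariate-normal log-densities; fixed effects are profiled
out by generalised least squares.  Optimisation is quasi-Newton on
log/atanh-transformed parameters with central-difference gradients and
multiple deterministic starts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .cohort_io import Cohort

LOG2PI = np.log(2.0 * np.pi)


# ---------------------------------------------------------------------------
# IOU kernel
# ---------------------------------------------------------------------------

def iou_kernel(s, t, alpha: float, sigma2: float):
    """Covariance of the integrated OU process at times ``s`` and ``t``.

    ``Cov(W(s), W(t)) = sigma2/(2 alpha^3) * (2 alpha min(s,t) + e^{-alpha s}
    + e^{-alpha t} - 1 - e^{-alpha |s-t|})`` for an OU velocity started in
    its stationary distribution (stationary velocity variance
    ``sigma2/(2 alpha)``).  Vanishes whenever ``s`` or ``t`` is zero.
    Broadcasts over array arguments.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    s = np.asarray(s, dtype=float)
    t = np.asarray(t, dtype=float)
    m = np.minimum(s, t)
    # expm1 keeps each term O(alpha) so the alpha -> 0 cancellation is benign
    bracket = (
        2.0 * alpha * m
        + np.expm1(-alpha * s)
        + np.expm1(-alpha * t)
        - np.expm1(-alpha * np.abs(s - t))
    )
    return sigma2 / (2.0 * alpha**3) * bracket


def slope_autocorrelation(alpha: float, lag: float) -> float:
    """Correlation of the instantaneous CD4 slope with itself ``lag`` years on.

    The OU velocity is stationary with autocorrelation ``exp(-alpha * lag)``;
    large ``alpha`` means a patient's current rate of decline says nothing
    about their rate of decline a few months later.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    if lag < 0:
        raise ValueError("lag must be non-negative")
    return float(np.exp(-alpha * lag))


# ---------------------------------------------------------------------------
# Packed per-patient data
# ---------------------------------------------------------------------------

class _Packed:
    """Measurements grouped by visit count for batched linear algebra."""

    def __init__(self, measurements: pd.DataFrame, scale: str = "raw"):
        if scale not in ("raw", "sqrt"):
            raise ValueError("scale must be 'raw' or 'sqrt'")
        m = measurements.dropna(subset=["cd4"])
        value = np.sqrt(m["cd4"]) if scale == "sqrt" else m["cd4"]
        m = pd.DataFrame(
            {"patient_id": m["patient_id"], "time": m["time"], "y": value}
        ).sort_values(["patient_id", "time"], kind="mergesort")
        self.scale = scale
        self.groups: list[tuple[np.ndarray, np.ndarray, np.ndarray]] = []
        by_k: dict[int, list] = {}
        for pid, g in m.groupby("patient_id", sort=True):
            k = len(g)
            if k == 0:
                continue
            by_k.setdefault(k, []).append(
                (pid, g["time"].to_numpy(), g["y"].to_numpy())
            )
        for k in sorted(by_k):
            entries = by_k[k]
            ids = np.array([e[0] for e in entries], dtype=object)
            times = np.stack([e[1] for e in entries])
            ys = np.stack([e[2] for e in entries])
            self.groups.append((ids, times, ys))
        self.n_obs = int(sum(t.size for _, t, _ in self.groups))
        self.n_patients = int(sum(len(i) for i, _, _ in self.groups))
        total = float(sum(y.sum() for _, _, y in self.groups))
        self.fingerprint = (self.n_obs, round(total, 6), scale)

    def patient_ids(self) -> np.ndarray:
        return np.concatenate([ids for ids, _, _ in self.groups])


def _as_measurements(data) -> pd.DataFrame:
    if isinstance(data, Cohort):
        return data.measurements
    return data


def _ridge(V: np.ndarray) -> np.ndarray:
    # relative ridge: keeps near-singular covariances (sd_eps -> 0 with a
    # rank-deficient random-effects part) from producing spurious likelihood
    # divergences, while being negligible for well-conditioned matrices
    k = V.shape[-1]
    diag_mean = np.mean(np.diagonal(V, axis1=-2, axis2=-1), axis=-1)
    return V + (1e-8 * diag_mean + 1e-30)[..., None, None] * np.eye(k)


def _lmm_cov(times: np.ndarray, sd_b0, sd_b1, corr, sd_eps) -> np.ndarray:
    ti = times[..., :, None]
    tj = times[..., None, :]
    V = (
        sd_b0**2
        + corr * sd_b0 * sd_b1 * (ti + tj)
        + sd_b1**2 * ti * tj
    )
    k = times.shape[-1]
    return _ridge(V + (sd_eps**2) * np.eye(k))


def _iou_cov(times: np.ndarray, sd_b0, alpha, sigma2, sd_eps) -> np.ndarray:
    ti = times[..., :, None]
    tj = times[..., None, :]
    V = sd_b0**2 + iou_kernel(ti, tj, alpha, sigma2)
    k = times.shape[-1]
    return _ridge(V + (sd_eps**2) * np.eye(k))


def _profile_loglik(packed: _Packed, cov_fn, reml: bool = False):
    """Gaussian log-likelihood with fixed effects (1, t) profiled by GLS.

    Returns ``(loglik, beta)`` or ``(-inf, None)`` when any per-patient
    covariance is not positive definite (after one jitter retry).
    """
    A = np.zeros((2, 2))
    c = np.zeros(2)
    q = 0.0
    logdet = 0.0
    pieces = []
    for ids, times, ys in packed.groups:
        V = cov_fn(times)
        sign, ld = np.linalg.slogdet(V)
        if np.any(sign <= 0):
            V = V + 1e-8 * np.mean(np.diagonal(V, axis1=-2, axis2=-1)) * np.eye(
                V.shape[-1]
            )
            sign, ld = np.linalg.slogdet(V)
            if np.any(sign <= 0):
                return -np.inf, None
        X = np.stack([np.ones_like(times), times], axis=-1)  # (m, k, 2)
        rhs = np.concatenate([ys[..., None], X], axis=-1)  # (m, k, 3)
        try:
            sol = np.linalg.solve(V, rhs)
        except np.linalg.LinAlgError:
            return -np.inf, None
        logdet += float(ld.sum())
        q += float(np.einsum("mk,mk->", ys, sol[..., 0]))
        c += np.einsum("mkp,mk->p", X, sol[..., 0])
        A += np.einsum("mkp,mkq->pq", X, sol[..., 1:])
        pieces.append((times, ys, V))
    try:
        beta = np.linalg.solve(A, c)
    except np.linalg.LinAlgError:
        return -np.inf, None
    quad = q - beta @ c
    ll = -0.5 * (packed.n_obs * LOG2PI + logdet + quad)
    if reml:
        sign, ldA = np.linalg.slogdet(A)
        if sign <= 0:
            return -np.inf, None
        ll += -0.5 * ldA + LOG2PI  # + (p/2) log 2 pi with p = 2
    return float(ll), beta


def _loglik_fixed_beta(packed: _Packed, cov_fn, beta0: float, beta1: float):
    """Gaussian log-likelihood at fixed mean ``beta0 + beta1 t``."""
    ll = 0.0
    for ids, times, ys in packed.groups:
        V = cov_fn(times)
        sign, ld = np.linalg.slogdet(V)
        if np.any(sign <= 0):
            V = V + 1e-8 * np.mean(np.diagonal(V, axis1=-2, axis2=-1)) * np.eye(
                V.shape[-1]
            )
            sign, ld = np.linalg.slogdet(V)
            if np.any(sign <= 0):
                return -np.inf
        r = ys - beta0 - beta1 * times
        sol = np.linalg.solve(V, r[..., None])[..., 0]
        quad = float(np.einsum("mk,mk->", r, sol))
        ll += -0.5 * (times.size * LOG2PI + float(ld.sum()) + quad)
    return float(ll)


def _central_diff_grad(f, x, rel_step=1e-5):
    g = np.empty_like(x)
    for i in range(len(x)):
        h = rel_step * max(1.0, abs(x[i]))
        xp, xm = x.copy(), x.copy()
        xp[i] += h
        xm[i] -= h
        g[i] = (f(xp) - f(xm)) / (2 * h)
    return g


def _minimize_multistart(objective, starts, bounds=None):
    best = None
    for x0 in starts:
        res = optimize.minimize(
            objective,
            np.asarray(x0, dtype=float),
            jac=lambda x: _central_diff_grad(objective, x),
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": 400},
        )
        if best is None or res.fun < best.fun:
            best = res
    if best is not None and best.fun >= 1e11:
        # gradient path failed everywhere; derivative-free rescue
        for x0 in starts:
            res = optimize.minimize(
                objective,
                np.asarray(x0, dtype=float),
                method="Nelder-Mead",
                options={"maxiter": 2000, "xatol": 1e-6, "fatol": 1e-8},
            )
            if res.fun < best.fun:
                best = res
    return best


# ---------------------------------------------------------------------------
# Fit result containers
# ---------------------------------------------------------------------------

@dataclass
class LMMFit:
    """Random-intercept/random-slope linear mixed model fit."""

    beta0: float
    beta1: float
    sd_b0: float
    sd_b1: float
    corr_b0b1: float
    sd_eps: float
    loglik: float
    n_params: int
    scale: str
    reml: bool
    converged: bool
    independent_re: bool
    blups: pd.DataFrame
    fingerprint: tuple
    n_patients: int
    n_obs: int

    @property
    def aic(self) -> float:
        return 2 * self.n_params - 2 * self.loglik


@dataclass
class IOUFit:
    """Integrated-OU trajectory model fit."""

    beta0: float
    beta1: float
    sd_b0: float
    alpha: float
    sigma2: float
    sd_eps: float
    loglik: float
    n_params: int
    scale: str
    converged: bool
    fingerprint: tuple
    n_patients: int
    n_obs: int
    alpha_ci: tuple | None = None

    @property
    def aic(self) -> float:
        return 2 * self.n_params - 2 * self.loglik


@dataclass
class JointFit:
    """Joint longitudinal / time-to-initiation model fit."""

    beta0: float
    beta1: float
    sd_b0: float
    sd_b1: float
    corr_b0b1: float
    sd_eps: float
    gamma_b0: float
    gamma_b1: float
    baseline_hazards: np.ndarray
    baseline_cuts: np.ndarray
    calendar_coef: float | None
    loglik: float
    n_params: int
    scale: str
    converged: bool
    quadrature_points: int
    blups: pd.DataFrame
    fingerprint: tuple
    n_patients: int
    #: parameter vector at the optimum and the (negated) objective used to
    #: find it, retained for diagnostics (e.g. local-maximum checks)
    phi_: np.ndarray = field(default=None, repr=False)
    objective_: object = field(default=None, repr=False)

    @property
    def aic(self) -> float:
        return 2 * self.n_params - 2 * self.loglik


@dataclass
class ModelComparison:
    aic_lmm: float
    aic_iou: float
    delta_aic: float
    preferred: str


# ---------------------------------------------------------------------------
# Linear mixed model
# ---------------------------------------------------------------------------

def fit_lmm(
    data,
    scale: str = "raw",
    reml: bool = False,
    independent_re: bool = False,
    n_starts: int = 3,
) -> LMMFit:
    """ML (or REML) fit of the random-intercept/random-slope model.

    ``data`` is a :class:`~cd4slope.cohort_io.Cohort` or a measurement frame
    with ``patient_id, time, cd4`` columns.  BLUPs of the per-patient random
    effects are computed from the fitted variance components by the
    conditional-mean formula ``G Z' V^{-1} (y - X beta)``.  If the fitted
    intercept–slope correlation hits the boundary the model is refitted with
    independent random effects and flagged via ``independent_re``.
    """
    packed = _Packed(_as_measurements(data), scale)
    if packed.n_patients < 2:
        raise ValueError("need at least two patients with measurements")

    sd0, sd1, sde, b1_guess = _lmm_start_heuristics(packed)

    def unpack(theta):
        if independent_re:
            lsd0, lsd1, lsde = theta
            rho = 0.0
        else:
            lsd0, lsd1, z, lsde = theta
            rho = np.tanh(z)
        return np.exp(lsd0), np.exp(lsd1), rho, np.exp(lsde)

    def objective(theta):
        s0, s1, rho, se = unpack(theta)
        ll, _ = _profile_loglik(
            packed, lambda t: _lmm_cov(t, s0, s1, rho, se), reml=reml
        )
        return -ll if np.isfinite(ll) else 1e12

    base = (
        [np.log(sd0), np.log(sd1), np.log(sde)]
        if independent_re
        else [np.log(sd0), np.log(sd1), 0.0, np.log(sde)]
    )
    factors = [1.0, 0.3, 3.0][:n_starts]
    starts = []
    for f in factors:
        s = list(base)
        s[1] = base[1] + np.log(f)
        starts.append(s)
    sd_bound = (-15.0, 15.0)
    bounds = (
        [sd_bound] * 3
        if independent_re
        else [sd_bound, sd_bound, (-6.0, 6.0), sd_bound]
    )
    res = _minimize_multistart(objective, starts, bounds=bounds)
    s0, s1, rho, se = unpack(res.x)
    ll, beta = _profile_loglik(
        packed, lambda t: _lmm_cov(t, s0, s1, rho, se), reml=reml
    )
    if not independent_re and abs(rho) > 0.999:
        fit = fit_lmm(
            data, scale=scale, reml=reml, independent_re=True, n_starts=n_starts
        )
        return fit
    blups = lmm_blups(packed, beta[0], beta[1], s0, s1, rho, se)
    return LMMFit(
        beta0=float(beta[0]),
        beta1=float(beta[1]),
        sd_b0=float(s0),
        sd_b1=float(s1),
        corr_b0b1=float(rho),
        sd_eps=float(se),
        loglik=float(ll),
        n_params=5 + (0 if independent_re else 1),
        scale=scale,
        reml=reml,
        converged=bool(res.success),
        independent_re=independent_re,
        blups=blups,
        fingerprint=packed.fingerprint,
        n_patients=packed.n_patients,
        n_obs=packed.n_obs,
    )


def _lmm_start_heuristics(packed: _Packed):
    """Moment-style starting values from pooled OLS residuals."""
    times = np.concatenate([t.ravel() for _, t, _ in packed.groups])
    ys = np.concatenate([y.ravel() for _, _, y in packed.groups])
    X = np.stack([np.ones_like(times), times], axis=1)
    beta, *_ = np.linalg.lstsq(X, ys, rcond=None)
    resid = ys - X @ beta
    s = float(np.std(resid)) or 1.0
    sd0 = 0.7 * s
    sde = 0.6 * s
    sd1 = max(0.3 * abs(beta[1]), 0.05 * s, 1e-3)
    return sd0, sd1, sde, beta[1]


def lmm_blups(
    data,
    beta0: float,
    beta1: float,
    sd_b0: float,
    sd_b1: float,
    corr: float,
    sd_eps: float,
    scale: str = "raw",
) -> pd.DataFrame:
    """Conditional means of the random effects given the data.

    Returns a frame with columns ``patient_id, b0, b1, n_points,
    fitted_mean`` — ``fitted_mean`` is the average fitted trajectory value
    over the patient's own visit times (used for delta-method back-mapping
    of sqrt-scale slopes).
    """
    packed = data if isinstance(data, _Packed) else _Packed(
        _as_measurements(data), scale
    )
    G = np.array(
        [
            [sd_b0**2, corr * sd_b0 * sd_b1],
            [corr * sd_b0 * sd_b1, sd_b1**2],
        ]
    )
    out_ids, out_b, out_n, out_fit = [], [], [], []
    for ids, times, ys in packed.groups:
        V = _lmm_cov(times, sd_b0, sd_b1, corr, sd_eps)
        r = ys - beta0 - beta1 * times
        sol = np.linalg.solve(V, r[..., None])[..., 0]  # (m, k)
        Z = np.stack([np.ones_like(times), times], axis=-1)  # (m, k, 2)
        b = np.einsum("pq,mkq,mk->mp", G, Z, sol)  # (m, 2)
        fitted = (
            beta0
            + b[:, 0:1]
            + (beta1 + b[:, 1:2]) * times
        ).mean(axis=1)
        out_ids.append(ids)
        out_b.append(b)
        out_n.append(np.full(len(ids), times.shape[1]))
        out_fit.append(fitted)
    b = np.concatenate(out_b)
    return (
        pd.DataFrame(
            {
                "patient_id": np.concatenate(out_ids),
                "b0": b[:, 0],
                "b1": b[:, 1],
                "n_points": np.concatenate(out_n).astype(int),
                "fitted_mean": np.concatenate(out_fit),
            }
        )
        .sort_values("patient_id", kind="mergesort")
        .reset_index(drop=True)
    )


# ---------------------------------------------------------------------------
# IOU model
# ---------------------------------------------------------------------------

def loglik_iou(
    data,
    beta0: float,
    beta1: float,
    sd_b0: float,
    alpha: float,
    sigma2: float,
    sd_eps: float,
    scale: str = "raw",
) -> float:
    """IOU-model log-likelihood at fully specified parameters."""
    packed = data if isinstance(data, _Packed) else _Packed(
        _as_measurements(data), scale
    )
    return _loglik_fixed_beta(
        packed,
        lambda t: _iou_cov(t, sd_b0, alpha, sigma2, sd_eps),
        beta0,
        beta1,
    )


def fit_iou(
    data,
    scale: str = "sqrt",
    n_starts: int = 3,
    starts=None,
    alpha_bounds: tuple[float, float] = (1e-6, 1e6),
) -> IOUFit:
    """Maximum-likelihood fit of the integrated-OU trajectory model.

    Optimises ``(log sd_b0, log alpha, log sigma2, log sd_eps)`` by
    quasi-Newton with the fixed effects profiled out; ``n_starts``
    deterministic starting points spread over small/moderate/large
    ``alpha`` regimes, best log-likelihood kept.
    """
    packed = _Packed(_as_measurements(data), scale)
    if packed.n_patients < 2:
        raise ValueError("need at least two patients with measurements")
    sd0, sd1, sde, _ = _lmm_start_heuristics(packed)
    la, ua = np.log(alpha_bounds[0]), np.log(alpha_bounds[1])

    def objective(theta):
        lsd0, lalpha, lsig2, lsde = theta
        ll, _ = _profile_loglik(
            packed,
            lambda t: _iou_cov(
                t, np.exp(lsd0), np.exp(lalpha), np.exp(lsig2), np.exp(lsde)
            ),
        )
        return -ll if np.isfinite(ll) else 1e12

    if starts is None:
        tau = max(sd1, 1e-3)  # stationary velocity SD guess
        starts = []
        for a in [0.5, 5.0, 50.0][:max(n_starts, 1)]:
            starts.append(
                [np.log(sd0), np.log(a), np.log(2 * a * tau**2), np.log(sde)]
            )
    bounds = [(-15.0, 15.0), (la, ua), (-30.0, 30.0), (-15.0, 15.0)]
    res = _minimize_multistart(objective, starts, bounds=bounds)
    if res is None or not np.isfinite(res.fun):
        raise RuntimeError("IOU fit failed to converge from all starts")
    lsd0, lalpha, lsig2, lsde = res.x
    ll, beta = _profile_loglik(
        packed,
        lambda t: _iou_cov(
            t, np.exp(lsd0), np.exp(lalpha), np.exp(lsig2), np.exp(lsde)
        ),
    )
    return IOUFit(
        beta0=float(beta[0]),
        beta1=float(beta[1]),
        sd_b0=float(np.exp(lsd0)),
        alpha=float(np.exp(lalpha)),
        sigma2=float(np.exp(lsig2)),
        sd_eps=float(np.exp(lsde)),
        loglik=float(ll),
        n_params=6,
        scale=scale,
        converged=bool(res.success),
        fingerprint=packed.fingerprint,
        n_patients=packed.n_patients,
        n_obs=packed.n_obs,
    )


def profile_ci_alpha(
    fit: IOUFit,
    data,
    level: float = 0.95,
    alpha_max: float = 1e6,
    alpha_min: float = 1e-6,
) -> tuple[float, float]:
    """Profile-likelihood confidence interval for the IOU stability ``alpha``.

    All ``alpha`` with ``2 (loglik_max - profile(alpha)) <= chi2_1(level)``
    are in the interval.  If the criterion still holds at ``alpha_max`` the
    upper limit is reported as ``inf`` (the data cannot distinguish very
    large mean-reversion rates — the Brownian-limit plateau); if it holds at
    ``alpha_min`` the lower limit is 0.
    """
    if level <= 0:
        return (fit.alpha, fit.alpha)
    packed = _Packed(_as_measurements(data), fit.scale)
    if packed.fingerprint != fit.fingerprint:
        raise ValueError("profile data do not match the fitted data")
    crit = stats.chi2.ppf(level, 1)
    x_hat = np.log([fit.sd_b0, fit.sigma2, fit.sd_eps])
    kappa_hat = fit.sigma2 / fit.alpha**2  # Brownian-limit diffusion scale
    tau2_hat = fit.sigma2 / (2.0 * fit.alpha)  # small-alpha slope variance

    def profile_ll(log_alpha):
        a = np.exp(log_alpha)

        def objective(theta):
            lsd0, lsig2, lsde = theta
            ll, _ = _profile_loglik(
                packed,
                lambda t: _iou_cov(
                    t, np.exp(lsd0), a, np.exp(lsig2), np.exp(lsde)
                ),
            )
            return -ll if np.isfinite(ll) else 1e12

        # sigma2 must track alpha along the profile: offer the raw MLE plus
        # starts matched to the Brownian (kappa a^2) and random-slope
        # (2 a tau^2) invariants so distant alpha values still optimise
        starts = [
            x_hat,
            np.log([fit.sd_b0, max(kappa_hat * a**2, 1e-12), fit.sd_eps]),
            np.log([fit.sd_b0, max(2.0 * a * tau2_hat, 1e-12), fit.sd_eps]),
        ]
        res = _minimize_multistart(
            objective, starts, bounds=[(-15.0, 15.0), (-30.0, 30.0), (-15.0, 15.0)]
        )
        return -res.fun

    ll_max = fit.loglik

    def g(log_alpha):
        return 2.0 * (ll_max - profile_ll(log_alpha)) - crit

    la_hat = np.log(fit.alpha)

    def bracket_root(direction, la_bound):
        """Walk from the MLE towards la_bound until g changes sign."""
        step = direction * np.log(10.0)
        lo = la_hat
        g_lo = min(g(lo), -1e-8 * crit)  # numerically clamp at the MLE
        la = la_hat
        while True:
            la = la + step
            if (direction > 0 and la >= la_bound) or (
                direction < 0 and la <= la_bound
            ):
                la = la_bound
            g_hi = g(la)
            if g_hi > 0:
                return optimize.brentq(g, lo, la, xtol=1e-3) if direction > 0 else \
                    optimize.brentq(g, la, lo, xtol=1e-3)
            if la == la_bound:
                return None
            lo, g_lo = la, g_hi

    root_up = bracket_root(+1, np.log(alpha_max))
    upper = np.inf if root_up is None else float(np.exp(root_up))
    root_dn = bracket_root(-1, np.log(alpha_min))
    lower = 0.0 if root_dn is None else float(np.exp(root_dn))
    return (lower, upper)


# ---------------------------------------------------------------------------
# Joint longitudinal / time-to-initiation model
# ---------------------------------------------------------------------------

def _initiation_table(cohort: Cohort) -> pd.DataFrame:
    """Per-patient time to cART initiation (years since seroconversion)."""
    from .cohort_io import DAYS_PER_YEAR

    last_time = cohort.measurements.groupby("patient_id")["time"].max()
    rows = []
    for row in cohort.patients.itertuples(index=False):
        pid = row.patient_id
        if pid not in last_time.index:
            continue
        if pd.notna(row.cart_date):
            t = (row.cart_date - row.seroconversion_date).days / DAYS_PER_YEAR
            initiated = True
        else:
            t = float(last_time.loc[pid])
            initiated = False
        rows.append((pid, max(t, 1e-6), initiated))
    return pd.DataFrame(rows, columns=["patient_id", "t_init", "initiated"])


def _piecewise_cumhaz(t, cuts, hazards):
    """Cumulative hazard of a piecewise-constant baseline at times ``t``."""
    t = np.atleast_1d(np.asarray(t, dtype=float))
    edges = np.concatenate([[0.0], cuts, [np.inf]])
    H = np.zeros_like(t)
    for k in range(len(hazards)):
        lo, hi = edges[k], edges[k + 1]
        H += hazards[k] * np.clip(t - lo, 0.0, hi - lo)
    return H


def fit_joint(
    cohort: Cohort,
    quadrature_points: int = 9,
    calendar_covariate: str | None = None,
    scale: str = "raw",
    n_baseline_pieces: int = 4,
    _check_doubling: bool = True,
) -> JointFit:
    """ML fit of the joint longitudinal / time-to-cART model.

    The longitudinal sub-model is the random-intercept/random-slope LMM;
    the initiation hazard is piecewise-constant in time since
    seroconversion (pieces cut at quartiles of observed initiation times)
    times ``exp(gamma_b0 * b0 + gamma_b1 * b1 [+ delta * calendar])``.
    The shared random effects are integrated out with pseudo-adaptive
    Gauss–Hermite quadrature centred on each patient's Gaussian posterior
    given the longitudinal data alone.  Quadrature resolution is verified
    by a doubling check on the final log-likelihood.

    Returns corrected BLUPs: posterior means of ``(b0, b1)`` given both the
    measurements and the initiation time.
    """
    packed = _Packed(cohort.measurements, scale)
    init = _initiation_table(cohort)
    init = init.set_index("patient_id")
    # quartile cuts of observed initiation times
    evt = init.loc[init["initiated"], "t_init"].to_numpy()
    if len(evt) < n_baseline_pieces:
        raise ValueError("too few initiation events for the baseline pieces")
    qs = np.linspace(0, 100, n_baseline_pieces + 1)[1:-1]
    cuts = np.percentile(evt, qs)

    calendar = None
    if calendar_covariate is not None:
        cal = cohort.patients.set_index("patient_id")[calendar_covariate]
        calendar = cal.astype(float)

    # flatten per-group survival data aligned with packed order
    pid_order = packed.patient_ids()
    t_init = init.loc[pid_order, "t_init"].to_numpy(dtype=float)
    d_init = init.loc[pid_order, "initiated"].to_numpy(dtype=bool)
    cal_vec = (
        calendar.loc[pid_order].to_numpy(dtype=float)
        if calendar is not None
        else np.zeros(len(pid_order))
    )
    piece_idx = np.searchsorted(cuts, t_init, side="right")

    nodes, weights = np.polynomial.hermite.hermgauss(quadrature_points)
    # 2-D tensor grid for a standard normal: b = m + L (sqrt(2) u)
    U = np.sqrt(2.0) * np.stack(
        np.meshgrid(nodes, nodes, indexing="ij"), axis=-1
    ).reshape(-1, 2)
    W = np.outer(weights, weights).reshape(-1) / np.pi

    lmm0 = fit_lmm(cohort.measurements, scale=scale)
    # internal rescaling: express the fixed effects and the association in
    # units of the random-effect SDs so the optimiser sees O(1) parameters
    B0S = max(lmm0.sd_b0, 1e-3)
    B1S = max(lmm0.sd_b1, 1e-3)

    def loglik(phi, q_U=U, q_W=W, return_blups=False):
        beta0 = phi[0] * B0S
        beta1 = phi[1] * B1S
        lsd0, lsd1, z, lsde = phi[2:6]
        g0, g1 = phi[6] / B0S, phi[7] / B1S
        log_lams = phi[8 : 8 + n_baseline_pieces]
        delta = phi[8 + n_baseline_pieces] if calendar is not None else 0.0
        s0, s1, rho, se = np.exp(lsd0), np.exp(lsd1), np.tanh(z), np.exp(lsde)
        G = np.array([[s0**2, rho * s0 * s1], [rho * s0 * s1, s1**2]])
        try:
            Ginv = np.linalg.inv(G)
        except np.linalg.LinAlgError:
            return 1e12
        lams = np.exp(log_lams)

        ll = 0.0
        blup_rows = []
        offset = 0
        for ids, times, ys in packed.groups:
            m_g, k = times.shape
            V = _lmm_cov(times, s0, s1, rho, se)
            sign, ld = np.linalg.slogdet(V)
            if np.any(sign <= 0):
                return 1e12
            r = ys - beta0 - beta1 * times
            sol = np.linalg.solve(V, r[..., None])[..., 0]
            quad = np.einsum("mk,mk->m", r, sol)
            ll_long = -0.5 * (k * LOG2PI + ld + quad)  # (m,)
            # Gaussian posterior of b given y
            Z = np.stack([np.ones_like(times), times], axis=-1)  # (m,k,2)
            ZtZ = np.einsum("mkp,mkq->mpq", Z, Z)
            P = Ginv[None, :, :] + ZtZ / se**2
            C = np.linalg.inv(P)
            mpost = np.einsum(
                "mpq,mq->mp", C, np.einsum("mkp,mk->mp", Z, r) / se**2
            )
            L = np.linalg.cholesky(C)
            b_nodes = mpost[:, None, :] + np.einsum(
                "mpq,nq->mnp", L, q_U
            )  # (m, n_nodes, 2)

            sl = slice(offset, offset + m_g)
            eta = (
                g0 * b_nodes[..., 0]
                + g1 * b_nodes[..., 1]
                + delta * cal_vec[sl][:, None]
            )
            eta = np.clip(eta, -500.0, 500.0)  # keep exp() finite
            Lam0 = _piecewise_cumhaz(t_init[sl], cuts, lams)[:, None]
            log_f = -np.exp(eta) * Lam0
            log_f = log_f + np.where(
                d_init[sl][:, None],
                np.log(lams[piece_idx[sl]])[:, None] + eta,
                0.0,
            )
            # log-sum-exp over quadrature nodes
            mmax = log_f.max(axis=1, keepdims=True)
            wexp = np.exp(log_f - mmax) * q_W[None, :]
            surv_int = wexp.sum(axis=1)
            ll += float(np.sum(ll_long + mmax[:, 0] + np.log(surv_int)))
            if return_blups:
                wnorm = wexp / surv_int[:, None]
                b_mean = np.einsum("mn,mnp->mp", wnorm, b_nodes)
                for i, pid in enumerate(ids):
                    blup_rows.append((pid, b_mean[i, 0], b_mean[i, 1], k))
            offset += m_g
        if return_blups:
            return ll, pd.DataFrame(
                blup_rows, columns=["patient_id", "b0", "b1", "n_points"]
            )
        return -ll

    # starting point: marginal LMM + null piecewise-exponential hazard
    exposure = np.array(
        [
            np.sum(
                np.clip(
                    t_init
                    - np.concatenate([[0.0], cuts])[k],
                    0.0,
                    np.concatenate([cuts, [np.inf]])[k]
                    - np.concatenate([[0.0], cuts])[k],
                )
            )
            for k in range(n_baseline_pieces)
        ]
    )
    events_per_piece = np.array(
        [np.sum(d_init & (piece_idx == k)) for k in range(n_baseline_pieces)]
    )
    lam0 = np.log(np.maximum(events_per_piece, 0.5) / np.maximum(exposure, 1e-6))
    phi0 = [
        lmm0.beta0 / B0S,
        lmm0.beta1 / B1S,
        np.log(max(lmm0.sd_b0, 1e-3)),
        np.log(max(lmm0.sd_b1, 1e-3)),
        np.arctanh(np.clip(lmm0.corr_b0b1, -0.99, 0.99)),
        np.log(max(lmm0.sd_eps, 1e-3)),
        0.0,
        0.0,
        *lam0,
    ]
    if calendar is not None:
        phi0.append(0.0)
    phi0 = np.asarray(phi0, dtype=float)

    res = optimize.minimize(
        loglik,
        phi0,
        jac=lambda x: _central_diff_grad(loglik, x),
        method="L-BFGS-B",
        options={"maxiter": 500},
    )
    phi = res.x
    ll = -res.fun

    if _check_doubling:
        n2, w2 = np.polynomial.hermite.hermgauss(2 * quadrature_points)
        U2 = np.sqrt(2.0) * np.stack(
            np.meshgrid(n2, n2, indexing="ij"), axis=-1
        ).reshape(-1, 2)
        W2 = np.outer(w2, w2).reshape(-1) / np.pi
        ll2 = -loglik(phi, q_U=U2, q_W=W2)
        if abs(ll2 - ll) > 0.1:
            refit = fit_joint(
                cohort,
                quadrature_points=2 * quadrature_points,
                calendar_covariate=calendar_covariate,
                scale=scale,
                n_baseline_pieces=n_baseline_pieces,
                _check_doubling=False,
            )
            return refit

    ll_final, blups = loglik(phi, return_blups=True)
    lsd0, lsd1, z, lsde = phi[2:6]
    n_params = 8 + n_baseline_pieces + (1 if calendar is not None else 0)
    return JointFit(
        beta0=float(phi[0] * B0S),
        beta1=float(phi[1] * B1S),
        sd_b0=float(np.exp(lsd0)),
        sd_b1=float(np.exp(lsd1)),
        corr_b0b1=float(np.tanh(z)),
        sd_eps=float(np.exp(lsde)),
        gamma_b0=float(phi[6] / B0S),
        gamma_b1=float(phi[7] / B1S),
        baseline_hazards=np.exp(phi[8 : 8 + n_baseline_pieces]),
        baseline_cuts=cuts,
        calendar_coef=(
            float(phi[8 + n_baseline_pieces]) if calendar is not None else None
        ),
        loglik=float(ll_final),
        n_params=n_params,
        scale=scale,
        converged=bool(res.success),
        quadrature_points=quadrature_points,
        blups=blups,
        fingerprint=packed.fingerprint,
        n_patients=packed.n_patients,
        phi_=phi,
        objective_=loglik,
    )


# ---------------------------------------------------------------------------
# Model comparison
# ---------------------------------------------------------------------------

def compare_models(lmm_fit: LMMFit, iou_fit: IOUFit) -> ModelComparison:
    """AIC comparison of the LMM and IOU fits on the same data.

    The two models are non-nested in general and ``alpha`` sits on a
    boundary under the LMM, so AIC rather than a likelihood-ratio test is
    used.  Both fits must carry the same data fingerprint (same
    observations, same scale).
    """
    if lmm_fit.fingerprint != iou_fit.fingerprint:
        raise ValueError("fits were computed on different data or scales")
    if lmm_fit.reml:
        raise ValueError("AIC comparison requires ML (reml=False) fits")
    aic_l, aic_i = lmm_fit.aic, iou_fit.aic
    return ModelComparison(
        aic_lmm=float(aic_l),
        aic_iou=float(aic_i),
        delta_aic=float(aic_l - aic_i),
        preferred="iou" if aic_i < aic_l else "lmm",
    )
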
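"""Statistical layer: single-predictor GLMs with AIC ranking, per-phase linear
fits, and a penalized-spline smoother with a bootstrap confidence band.

The binomial (logit) and gaussian (identity) families are fit by iteratively
reweighted least squares with a two-column design (intercept, slope).  The
binomial log-likelihood includes the combinatorial constant, so absolute AIC
values are comparable to other likelihood-based software; within-response
rankings are unaffected by that constant either way.  Station-level binomial
responses are supplied as (successes, trials), retaining trial counts for
correct likelihood weighting rather than fitting the bare frequency.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import make_smoothing_spline
from scipy.special import expit, gammaln

MAX_ITER = 100
TOL = 1e-8
VARIANCE_FLOOR = 1e-12


@dataclass
class GlmFit:
    family: str                      # binomial-logit | gaussian-identity
    coefficients: np.ndarray         # (intercept[, slope])
    standard_errors: np.ndarray
    log_likelihood: float
    aic: float
    p_value_slope: float             # Wald test on the slope; nan if intercept-only
    n: int
    converged: bool
    n_iterations: int = 0

    @property
    def intercept(self) -> float:
        return float(self.coefficients[0])

    @property
    def slope(self) -> float:
        return float(self.coefficients[1]) if len(self.coefficients) > 1 else float("nan")


def _design(x: np.ndarray | None, n: int) -> np.ndarray:
    if x is None:
        return np.ones((n, 1))
    x = np.asarray(x, dtype=float)
    return np.column_stack([np.ones(len(x)), x])


def fit_glm(x: np.ndarray | None, y: np.ndarray, family: str = "binomial",
            trials: np.ndarray | None = None) -> GlmFit:
    """Maximum-likelihood GLM fit by IRLS.

    binomial: ``y`` are success counts and ``trials`` the trial counts per
    observation.  gaussian: ``y`` is the response; ``trials`` ignored.
    ``x=None`` fits an intercept-only model.  Convergence: max coefficient
    change < 1e-8 or 100 iterations; a non-converged or separated fit is
    returned with ``converged=False``.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < 3:
        raise ValueError("need at least 3 observations")
    X = _design(x, n)
    p = X.shape[1]

    if family.startswith("binomial"):
        if trials is None:
            raise ValueError("binomial fits need trial counts")
        m = np.asarray(trials, dtype=float)
        if np.any(m <= 0):
            raise ValueError("trials must be positive")
        succ = y
        if np.any(succ > m) or np.any(succ < 0):
            raise ValueError("successes outside [0, trials]")
        beta = np.zeros(p)
        converged = False
        it = 0
        singular = False
        for it in range(1, MAX_ITER + 1):
            eta = X @ beta
            mu = expit(eta)
            mu = np.clip(mu, 1e-10, 1 - 1e-10)
            w = m * mu * (1 - mu)
            z = eta + (succ - m * mu) / w
            XtW = X.T * w
            try:
                beta_new = np.linalg.solve(XtW @ X, XtW @ z)
            except np.linalg.LinAlgError:
                singular = True
                break
            if np.max(np.abs(beta_new - beta)) < TOL:
                beta = beta_new
                converged = True
                break
            beta = beta_new
        eta = X @ beta
        if np.any(np.abs(eta) > 30):  # quasi-separation: probabilities at 0/1
            converged = False
        if singular:
            converged = False
        mu = np.clip(expit(eta), 1e-12, 1 - 1e-12)
        logl = float(np.sum(gammaln(m + 1) - gammaln(succ + 1) - gammaln(m - succ + 1)
                            + succ * np.log(mu) + (m - succ) * np.log(1 - mu)))
        w = m * mu * (1 - mu)
        cov = np.linalg.pinv((X.T * w) @ X)
        se = np.sqrt(np.diag(cov))
        k = p
        if p > 1 and se[1] > 0:
            z_stat = beta[1] / se[1]
            p_slope = float(2 * stats.norm.sf(abs(z_stat)))
        else:
            p_slope = float("nan")
        return GlmFit("binomial-logit", beta, se, logl, -2 * logl + 2 * k,
                      p_slope, n, converged, it)

    if family.startswith("gaussian"):
        # identity link, closed-form weighted least squares = one IRLS step
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        rss = float(resid @ resid)
        sigma2_mle = max(rss / n, VARIANCE_FLOOR)
        logl = float(-0.5 * n * (np.log(2 * np.pi * sigma2_mle) + 1.0))
        k = p + 1  # + the variance parameter
        dof = n - p
        sigma2_unb = max(rss / dof, VARIANCE_FLOOR) if dof > 0 else VARIANCE_FLOOR
        cov = sigma2_unb * np.linalg.pinv(X.T @ X)
        se = np.sqrt(np.diag(cov))
        if p > 1 and se[1] > 0:
            t_stat = beta[1] / se[1]
            p_slope = float(2 * stats.t.sf(abs(t_stat), dof))
        else:
            p_slope = float("nan")
        return GlmFit("gaussian-identity", beta, se, logl, -2 * logl + 2 * k,
                      p_slope, n, True, 1)

    raise ValueError(f"unknown family {family!r}")


def rank_predictors(fits: Mapping[str, GlmFit], response: str = "",
                    alpha: float = 0.05) -> pd.DataFrame:
    """AIC-rank single-predictor fits within one response column.

    Non-converged fits are excluded from ranking and reported in the frame
    with a missing rank.  Rank 1 = lowest AIC; ranks are only meaningful
    within a response, never across responses.
    """
    usable = {name: f for name, f in fits.items() if f.converged}
    if len(usable) < 2:
        raise ValueError(f"need >= 2 converged fits to rank (response {response!r})")
    order = sorted(usable, key=lambda name: usable[name].aic)
    ranks = {name: r + 1 for r, name in enumerate(order)}
    rows = []
    for name, f in fits.items():
        rows.append({
            "response": response, "predictor": name,
            "slope": f.slope, "slope_se": float(f.standard_errors[-1]),
            "log_likelihood": f.log_likelihood, "aic": f.aic,
            "p_value": f.p_value_slope,
            "significant": bool(f.p_value_slope <= alpha) if np.isfinite(f.p_value_slope) else False,
            "converged": f.converged,
            "aic_rank": ranks.get(name, np.nan),
            "n": f.n,
        })
    return pd.DataFrame(rows).sort_values("aic_rank").reset_index(drop=True)


@dataclass
class PhaseFit:
    phase: str
    slope: float
    intercept: float
    slope_ci_low: float
    slope_ci_high: float
    n: int


def fit_line_by_phase(x: np.ndarray, y: np.ndarray, phases: np.ndarray,
                      min_points: int = 3) -> tuple[pd.DataFrame, list[str]]:
    """Separate OLS lines per phase with t-based 95% CIs on the slope.

    Phases with fewer than ``min_points`` cruises are skipped and reported.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    phases = np.asarray(phases)
    rows, skipped = [], []
    for phase in pd.unique(phases):
        mask = phases == phase
        if mask.sum() < min_points:
            skipped.append(str(phase))
            continue
        fit = fit_glm(x[mask], y[mask], family="gaussian")
        dof = mask.sum() - 2
        tcrit = stats.t.ppf(0.975, dof) if dof > 0 else np.inf
        se = float(fit.standard_errors[1])
        rows.append({"phase": phase, "slope": fit.slope, "intercept": fit.intercept,
                     "slope_ci_low": fit.slope - tcrit * se,
                     "slope_ci_high": fit.slope + tcrit * se,
                     "p_value": fit.p_value_slope, "n": int(mask.sum())})
    return pd.DataFrame(rows), skipped


@dataclass
class SplineFit:
    grid: np.ndarray
    fitted: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    predict: Callable[[np.ndarray], np.ndarray] = field(repr=False, default=None)
    linear_fallback: bool = False


def _collapse_duplicates(x: np.ndarray, y: np.ndarray):
    """Smoothing splines need strictly increasing x: average replicate y."""
    order = np.argsort(x)
    x, y = x[order], y[order]
    ux, inverse, counts = np.unique(x, return_inverse=True, return_counts=True)
    uy = np.bincount(inverse, weights=y) / counts
    return ux, uy, counts.astype(float)


def spline_smooth(x: np.ndarray, y: np.ndarray, n_boot: int = 500,
                  seed: int = 0, grid: np.ndarray | None = None) -> SplineFit:
    """Cubic smoothing spline (GCV-chosen penalty) with a bootstrap 95% band.

    The pointwise band comes from ``n_boot`` case-resampling refits evaluated
    on the grid; fewer than 4 unique x values fall back to a straight line
    with a warning.  Deterministic for a fixed seed.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 10:
        raise ValueError("need at least 10 points for a smoother")
    if grid is None:
        grid = np.linspace(x.min(), x.max(), 100)

    def _fit(xs: np.ndarray, ys: np.ndarray, warn: bool = False):
        ux, uy, w = _collapse_duplicates(xs, ys)
        if len(ux) < 4:
            if warn:
                warnings.warn("fewer than 4 unique x values: falling back to a "
                              "linear fit", stacklevel=3)
            coef = np.polyfit(xs, ys, 1)
            return (lambda g: np.polyval(coef, g)), True
        spline = make_smoothing_spline(ux, uy, w=w)
        return spline, False

    predictor, fallback = _fit(x, y, warn=True)
    fitted = np.asarray(predictor(grid), dtype=float)

    rng = np.random.default_rng(seed)
    boots = np.empty((n_boot, len(grid)))
    idx_all = np.arange(len(x))
    for b in range(n_boot):
        idx = rng.choice(idx_all, size=len(x), replace=True)
        pred_b, _ = _fit(x[idx], y[idx])
        boots[b] = pred_b(grid)
    lower = np.percentile(boots, 2.5, axis=0)
    upper = np.percentile(boots, 97.5, axis=0)
    return SplineFit(grid=grid, fitted=fitted, lower=lower, upper=upper,
                     predict=predictor, linear_fallback=fallback)
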
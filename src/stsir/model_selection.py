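"""Goodness-of-fit battery for fitted space-time models.

All criteria are computed from the per-draw, per-cell Poisson log-likelihoods
stored in a :class:`~stsir.st_models.PosteriorFit`; nothing here refits a
model.

* DIC = D-bar + p_D with p_D = D-bar - D(posterior-mean linear predictor).
* WAIC = -2 * (sum_cells log mean_draws lik  -  sum_cells var_draws loglik).
* CPO_cell = harmonic mean over draws of the cell likelihood; Sum log CPO is
  the leave-one-out predictive score (higher is better).  The harmonic-mean
  estimator can be unstable; cells whose estimated relative Monte Carlo error
  is large are flagged rather than silently smoothed.
* PIT uses the mid-distribution correction for discrete counts,
  ``mean F(y) - 0.5 * mean f(y)``: the plain PIT is non-uniform for counts
  even under the true model.
* Uniformity of the PIT values is tested with the Anderson-Darling statistic
  against a fully specified Uniform(0,1), with the Marsaglia-Marsaglia
  evaluation of the null distribution.
* R^2 defaults to the squared Pearson correlation between the crude and the
  posterior-mean smoothed SIR over all cells (a deviance-based pseudo-R^2 is
  available as an alternative).

Lower DIC/WAIC, higher Sum log CPO and R^2, and uniform PIT indicate the
better-fitting model.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import poisson as _poisson

from .st_models import PosteriorFit
from .standardization import SIRMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "FitDiagnostics",
    "dic",
    "waic",
    "cpo",
    "pit",
    "anderson_darling_uniform",
    "r_squared",
    "evaluate",
    "compare_models",
]


@dataclass(frozen=True)
class FitDiagnostics:
    """All criteria for one fitted model."""

    model: str
    dic: float
    p_dic: float
    waic: float
    p_waic: float
    sum_log_cpo: float
    ad_statistic: float
    ad_p: float
    r2: float


def _check(fit: PosteriorFit, force: bool):
    if not fit.converged and not force:
        raise RuntimeError(
            f"fit of {fit.model.label} flagged as not converged; pass force=True"
        )


def dic(fit: PosteriorFit, force: bool = False) -> tuple:
    """Deviance information criterion and its effective parameter count.

    The plug-in deviance is evaluated at the posterior mean of the linear
    predictor (mean of log theta), the natural scale for a log-linear model.
    """
    _check(fit, force)
    dev_draws = -2.0 * fit.loglik_draws.sum(axis=1)
    dbar = float(dev_draws.mean())
    eta_bar = np.log(fit.theta_draws).mean(axis=0)
    lam_hat = fit.expected * np.exp(eta_bar)
    d_hat = float(-2.0 * _poisson.logpmf(fit.observed, lam_hat).sum())
    p_d = dbar - d_hat
    return dbar + p_d, p_d


def waic(fit: PosteriorFit, force: bool = False) -> tuple:
    """Watanabe-Akaike information criterion (variance-based penalty)."""
    _check(fit, force)
    ll = fit.loglik_draws
    S = ll.shape[0]
    lppd = float(np.sum(logsumexp(ll, axis=0) - math.log(S)))
    p_w = float(np.sum(ll.var(axis=0, ddof=1 if S > 1 else 0)))
    return -2.0 * (lppd - p_w), p_w


def cpo(fit: PosteriorFit, force: bool = False, rel_se_limit: float = 0.25) -> tuple:
    """Per-cell conditional predictive ordinates and their summed log.

    Returns ``(cpo_values, sum_log_cpo, flagged)`` where ``flagged`` marks
    cells whose harmonic-mean estimate is unreliable (a zero-likelihood draw,
    or an estimated relative Monte Carlo error above ``rel_se_limit``);
    flagged cells are excluded from the sum with a warning.
    """
    _check(fit, force)
    ll = fit.loglik_draws
    S = ll.shape[0]
    neg = -ll
    log_cpo = math.log(S) - logsumexp(neg, axis=0)
    cpo_vals = np.exp(log_cpo)

    # relative MC standard error of the harmonic-mean estimator
    with np.errstate(over="ignore"):
        w = np.exp(neg - neg.max(axis=0, keepdims=True))
    wbar = w.mean(axis=0)
    wvar = w.var(axis=0, ddof=1 if S > 1 else 0)
    rel_se = np.sqrt(wvar / S) / np.where(wbar > 0, wbar, 1.0)
    flagged = ~np.isfinite(log_cpo) | (rel_se > rel_se_limit)
    if flagged.any():
        logger.warning("CPO unstable in %d/%d cells; excluded from the sum",
                       int(flagged.sum()), flagged.size)
    total = float(log_cpo[~flagged].sum())
    return cpo_vals, total, flagged


def pit(fit: PosteriorFit, force: bool = False) -> np.ndarray:
    """Mid-corrected probability integral transform per cell.

    ``PIT = mean_draws F(y; lam) - 0.5 * mean_draws f(y; lam)`` with F and f
    the Poisson CDF/PMF at lam = E * theta.  Uniform on [0,1] when the model
    is predictively calibrated.
    """
    _check(fit, force)
    lam = fit.expected.ravel()[None, :] * fit.theta_draws.reshape(fit.n_draws, -1)
    y = fit.observed.ravel()[None, :]
    F = _poisson.cdf(y, lam).mean(axis=0)
    f = _poisson.pmf(y, lam).mean(axis=0)
    return np.clip(F - 0.5 * f, 0.0, 1.0)


def _ad_cdf_asymptotic(z: float) -> float:
    """Marsaglia's adinf: asymptotic null CDF of the A^2 statistic."""
    if z <= 0:
        return 0.0
    if z < 2.0:
        return (math.exp(-1.2337141 / z) / math.sqrt(z)
                * (2.00012 + (0.247105 - (0.0649821 - (0.0347962
                   - (0.011672 - 0.00168691 * z) * z) * z) * z) * z))
    return math.exp(-math.exp(1.0776 - (2.30695 - (0.43424 - (0.082433
                    - (0.008056 - 0.0003146 * z) * z) * z) * z) * z))


def _ad_errfix(n: int, x: float) -> float:
    """Marsaglia's finite-n correction to the asymptotic AD CDF."""
    if x > 0.8:
        return (-130.2137 + (745.2337 - (1705.091 - (1950.646
                - (1116.360 - 255.7844 * x) * x) * x) * x) * x) / n
    c = 0.01265 + 0.1757 / n
    if x < c:
        t = x / c
        t = math.sqrt(t) * (1.0 - t) * (49.0 * t - 102.0)
        return t * (0.0037 / n ** 2 + 0.00078 / n + 0.00006) / n
    t = (x - c) / (0.8 - c)
    t = (-0.00022633 + (6.54034 - (14.6538 - (14.458 - (8.259
         - 1.91864 * t) * t) * t) * t) * t)
    return t * (0.04213 + 0.01365 / n) / n


def anderson_darling_uniform(values) -> tuple:
    """Anderson-Darling test of Uniform(0,1) (fully specified null).

    ``A^2 = -n - (1/n) sum_k (2k-1) [ln U_(k) + ln(1 - U_(n+1-k))]``; the
    p-value uses the Marsaglia-Marsaglia evaluation of the exact-null CDF.
    Requires at least 5 values.
    """
    u = np.sort(np.asarray(values, dtype=float))
    n = u.size
    if n < 5:
        raise ValueError("Anderson-Darling uniformity test needs at least 5 values")
    if np.any(u < 0) or np.any(u > 1):
        raise ValueError("values outside [0, 1]")
    eps = 1e-12
    u = np.clip(u, eps, 1 - eps)
    k = np.arange(1, n + 1)
    a2 = -n - np.mean((2 * k - 1) * (np.log(u) + np.log(1 - u[::-1])))
    cdf = _ad_cdf_asymptotic(float(a2))
    cdf = min(max(cdf + _ad_errfix(n, cdf), 0.0), 1.0)
    return float(a2), float(1.0 - cdf)


def r_squared(fit: PosteriorFit, crude: SIRMatrix, method: str = "pearson_sir",
              force: bool = False) -> float:
    """Variance in the crude SIR explained by the smoothed surface.

    ``pearson_sir`` (default): squared Pearson correlation between crude and
    posterior-mean smoothed SIR across cells.  ``deviance``: 1 minus the
    ratio of the plug-in model deviance to the intercept-only deviance.
    """
    _check(fit, force)
    if method == "pearson_sir":
        x = np.asarray(crude.sir, dtype=float).ravel()
        y = fit.theta_mean.ravel()
        ok = np.isfinite(x) & np.isfinite(y)
        x, y = x[ok], y[ok]
        if x.size < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
            return 0.0
        return float(np.corrcoef(x, y)[0, 1] ** 2)
    if method == "deviance":
        y = fit.observed.ravel().astype(float)
        lam_model = (fit.expected * fit.theta_mean).ravel()
        lam_null = fit.expected.ravel() * (y.sum() / fit.expected.sum())
        def dev(lam):
            with np.errstate(divide="ignore", invalid="ignore"):
                t = np.where(y > 0, y * np.log(np.where(y > 0, y, 1.0) / lam), 0.0)
            return 2.0 * np.sum(t - (y - lam))
        d0 = dev(lam_null)
        return float(1.0 - dev(lam_model) / d0) if d0 > 0 else 0.0
    raise ValueError(f"unknown R^2 method {method!r}")


def evaluate(fit: PosteriorFit, crude: SIRMatrix, force: bool = False) -> FitDiagnostics:
    """Compute the full criterion battery for one fit."""
    d, p_d = dic(fit, force)
    w, p_w = waic(fit, force)
    _, slc, _ = cpo(fit, force)
    pvec = pit(fit, force)
    a2, ad_p = anderson_darling_uniform(pvec)
    r2 = r_squared(fit, crude, force=force)
    return FitDiagnostics(fit.model.label, d, p_d, w, p_w, slc, a2, ad_p, r2)


def compare_models(fits: list, crude: SIRMatrix, force: bool = False) -> pd.DataFrame:
    """One row per model with the criterion battery and best-model flags.

    Each criterion gets its own best flag (lowest DIC, lowest WAIC, highest
    Sum log CPO, highest R^2); ``best_overall`` follows WAIC.
    """
    rows = [evaluate(f, crude, force) for f in fits]
    df = pd.DataFrame([r.__dict__ for r in rows])
    df["best_dic"] = df["dic"] == df["dic"].min()
    df["best_waic"] = df["waic"] == df["waic"].min()
    df["best_cpo"] = df["sum_log_cpo"] == df["sum_log_cpo"].max()
    df["best_r2"] = df["r2"] == df["r2"].max()
    df["best_overall"] = df["best_waic"]
    return df
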
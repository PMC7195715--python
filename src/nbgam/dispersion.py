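"""Three-stage empirical-Bayes dispersion estimation.

Stage 1 estimates a per-gene dispersion by maximising the Cox–Reid
adjusted NB profile likelihood at the fitted means.  Stage 2 fits the
parametric mean–dispersion trend ``alpha_tr(mean) = a1/mean + a0`` across
genes by an iterated gamma-family regression with ratio-based outlier
exclusion.  Stage 3 shrinks each gene's dispersion toward its trend value
under a log-normal prior whose width is the across-gene spread of
log dispersion residuals in excess of the estimation-noise component
``trigamma((m - p)/2)``; genes far above the trend escape shrinkage.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
from scipy import optimize, special

from ._likelihood import nb_loglik, nb_weights

logger = logging.getLogger(__name__)

ALPHA_MIN = 1e-8
PRIOR_VAR_FLOOR = 0.25
OUTLIER_SD_MULT = 2.0
TREND_RATIO_BOUNDS = (1e-4, 15.0)


def alpha_bounds(m: int) -> tuple[float, float]:
    return ALPHA_MIN, float(max(10, m))


def _cr_loglik(log_alpha: float, y, mu, X, S_pen=None) -> float:
    """Cox–Reid adjusted profile log-likelihood at fixed fitted means.

    For penalized mean models the determinant uses the penalized Hessian
    ``X'WX + sum lambda_t S_t``: heavily penalized directions are then
    alpha-insensitive, so the adjustment reflects the smooth's effective
    (not raw) degrees of freedom.  With no penalty this is the classic
    Cox-Reid correction.
    """
    alpha = np.exp(log_alpha)
    ll = nb_loglik(y, mu, alpha)
    w = nb_weights(mu, alpha)
    A = X.T @ (X * w[:, None])
    if S_pen is not None:
        A = A + S_pen
    sign, logdet = np.linalg.slogdet(A)
    if sign <= 0:
        return -np.inf
    return ll - 0.5 * logdet


def _maximize_log_alpha(obj, m: int, xatol: float = 1e-6) -> float:
    lo, hi = np.log(ALPHA_MIN), np.log(alpha_bounds(m)[1])
    res = optimize.minimize_scalar(
        lambda la: -obj(la), bounds=(lo, hi), method="bounded",
        options={"xatol": xatol},
    )
    best = res.x
    # bounded Brent can stall short of a boundary optimum; check the ends
    for end in (lo, hi):
        if obj(end) > obj(best):
            best = end
    return float(best)


def genewise_dispersion(
    y, mu_hat, X, edf_proxy: int | None = None, S_pen=None
) -> float:
    """Cox–Reid adjusted per-gene dispersion MLE on [1e-8, max(10, m)]."""
    y = np.asarray(y, float)
    m = len(y)
    la = _maximize_log_alpha(lambda la: _cr_loglik(la, y, mu_hat, X, S_pen), m)
    return float(np.exp(la))


def fit_dispersion_trend(
    alpha_gw: np.ndarray,
    base_mean: np.ndarray,
    min_genes: int = 50,
    max_iter: int = 10,
    tol: float = 1e-6,
):
    """Fit alpha_tr(mean) = a1/mean + a0 by iterated gamma-family regression.

    Genes whose gene-wise estimate sits at the lower optimisation bound are
    excluded; within the loop, genes with ratio alpha_gw/trend outside
    [1e-4, 15] are dropped and the weighted fit repeated.  Coefficients are
    kept non-negative by a non-negative least squares inner solve.  Falls
    back to a flat trend (mean dispersion) if too few genes are usable or
    the iteration fails.
    """
    alpha_gw = np.asarray(alpha_gw, float)
    base_mean = np.asarray(base_mean, float)
    usable = (alpha_gw > 10 * ALPHA_MIN) & (base_mean > 0)
    if usable.sum() < min_genes:
        warnings.warn(
            "too few genes for trend fitting; using a flat mean-dispersion trend"
        )
        a0_flat = float(np.mean(alpha_gw[alpha_gw > 10 * ALPHA_MIN]) if usable.any()
                        else np.mean(alpha_gw))
        return a0_flat, 0.0
    a = np.array([np.mean(alpha_gw[usable]), 0.0])  # (a0, a1)
    Xd = np.column_stack([np.ones(usable.sum()), 1.0 / base_mean[usable]])
    yv = alpha_gw[usable]
    fitted = np.full_like(yv, a[0])
    for _ in range(max_iter):
        ratio = yv / np.clip(fitted, 1e-12, None)
        keep = (ratio >= TREND_RATIO_BOUNDS[0]) & (ratio <= TREND_RATIO_BOUNDS[1])
        if keep.sum() < min_genes:
            break
        w = 1.0 / np.clip(fitted[keep], 1e-12, None) ** 2  # gamma-family weights
        sw = np.sqrt(w)
        a_new, _ = optimize.nnls(Xd[keep] * sw[:, None], yv[keep] * sw)
        if not np.all(np.isfinite(a_new)):
            break
        fitted = Xd @ a_new
        if np.max(np.abs(a_new - a)) < tol:
            a = a_new
            break
        a = a_new
    a0, a1 = float(max(a[0], ALPHA_MIN)), float(max(a[1], 0.0))
    return a0, a1


def trend_values(base_mean: np.ndarray, a0: float, a1: float) -> np.ndarray:
    return a1 / np.clip(np.asarray(base_mean, float), 1e-12, None) + a0


def prior_variance(
    alpha_gw: np.ndarray,
    alpha_trend: np.ndarray,
    m: int,
    p: int,
) -> float:
    """Width of the log-normal dispersion prior.

    The robust (MAD-based) variance of log residuals about the trend mixes
    true biological spread with sampling noise; the chi-square sampling
    component ``trigamma((m - p)/2)`` is subtracted, and the result floored
    at 0.25.
    """
    if m <= p:
        raise ValueError("sample size must exceed the mean-model degrees of freedom")
    alpha_gw = np.asarray(alpha_gw, float)
    mask = (alpha_gw > 10 * ALPHA_MIN) & (alpha_gw < 0.99 * alpha_bounds(m)[1])
    lr = np.log(alpha_gw[mask]) - np.log(np.asarray(alpha_trend, float)[mask])
    if lr.size == 0:
        return PRIOR_VAR_FLOOR
    mad = np.median(np.abs(lr - np.median(lr)))
    s2_lr = (1.4826 * mad) ** 2
    return float(max(s2_lr - special.polygamma(1, (m - p) / 2.0), PRIOR_VAR_FLOOR))


def map_dispersion(
    y,
    mu_hat,
    X,
    alpha_trend_i: float,
    sigma2_lp: float,
    alpha_gw_i: float,
    S_pen=None,
):
    """Log-normal MAP dispersion with outlier escape.

    Returns ``(alpha_map, outlier)``; a gene whose gene-wise estimate lies
    more than 2 prior SDs above its trend keeps the gene-wise value.
    """
    y = np.asarray(y, float)
    m = len(y)
    log_tr = np.log(alpha_trend_i)
    if np.log(alpha_gw_i) > log_tr + OUTLIER_SD_MULT * np.sqrt(sigma2_lp):
        return float(alpha_gw_i), True

    def post(la):
        return _cr_loglik(la, y, mu_hat, X, S_pen) - (la - log_tr) ** 2 / (2.0 * sigma2_lp)

    la = _maximize_log_alpha(post, m)
    return float(np.exp(la)), False


def dispersion_mse(estimates, truth, stratum=None) -> float:
    """Mean squared error of dispersion estimates over a gene stratum."""
    estimates = np.asarray(estimates, float)
    truth = np.asarray(truth, float)
    if stratum is not None:
        estimates = estimates[stratum]
        truth = truth[stratum]
    if estimates.size == 0:
        raise ValueError("empty stratum")
    return float(np.mean((estimates - truth) ** 2))
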
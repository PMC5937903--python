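"""Random-intercept linear mixed model by profile REML.

The model for one (protein, carotenoid) pair is

    y_rk = b0 + b1 * x_rk + B_r + e_rk,
    B_r ~ N(0, sigma_B^2),   e_rk ~ N(0, sigma_e^2),

where y is log2 carotenoid concentration, x is log2 relative protein
abundance, and r indexes the multiplexed experiment (plex) the sample was
measured in.  The plex random intercept absorbs shared batch shifts in the
carotenoid response across the samples of one plex.

Estimation profiles the REML log-likelihood down to a single variance
ratio lambda = sigma_B^2 / sigma_e^2.  Writing V* = I + lambda * Z Z' for
the scaled marginal covariance (Z the plex indicator matrix), the GLS
estimates and the REML residual variance have closed forms at fixed
lambda, and the profiled criterion

    l(lambda) = -1/2 [ (n-p)(log 2*pi + 1) + (n-p) log sigma_e^2(lambda)
                       + log|V*| + log|X' V*^-1 X| ]

is maximized over log(lambda) by a coarse log-spaced grid followed by
golden-section refinement.  Because V*^-1 is block diagonal with
rank-one corrections, every evaluation needs only per-plex sufficient
statistics (counts and sums), making a single fit O(#plexes) after one
O(n) aggregation pass.

A boundary estimate lambda=0 (no plex variance) is accepted and reduces
the fit exactly to ordinary least squares on the pooled data.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import (
    InsufficientDataError,
    InsufficientGroupsError,
    NoSlopeVarianceError,
)

_LOG2PI = math.log(2.0 * math.pi)
_INVPHI = (math.sqrt(5.0) - 1.0) / 2.0


@dataclass
class LMEFit:
    """One fitted random-intercept model.

    Attributes
    ----------
    b0, b1_raw
        Fixed-effect intercept (log2 μmol/L) and slope (log2 μmol/L per
        log2-unit abundance).
    se_b1
        Wald standard error of ``b1_raw`` at the REML variance estimates.
    sigma_B2, sigma_e2
        Plex random-intercept variance and residual variance.
    lambda_hat
        REML-maximizing variance ratio sigma_B2 / sigma_e2 (0 at the
        boundary).
    blups
        Map plex label → shrinkage predictor (BLUP) of the plex deviation.
    reml_loglik
        Profiled REML log-likelihood at the optimum.
    boundary
        True when the variance ratio was estimated at 0.
    """

    b0: float
    b1_raw: float
    se_b1: float
    sigma_B2: float
    sigma_e2: float
    lambda_hat: float
    blups: dict
    n_obs: int
    n_groups: int
    reml_loglik: float
    converged: bool
    boundary: bool = False


class _Profile:
    """Profiled REML criterion from per-group sufficient statistics."""

    def __init__(self, y: np.ndarray, x: np.ndarray, codes: np.ndarray, n_groups: int):
        self.n = y.size
        self.ng = np.bincount(codes, minlength=n_groups).astype(float)
        self.Sx = np.bincount(codes, weights=x, minlength=n_groups)
        self.Sy = np.bincount(codes, weights=y, minlength=n_groups)
        self.Sxx = float(x @ x)
        self.Sxy = float(x @ y)
        self.Syy = float(y @ y)
        self.Sx_tot = float(x.sum())
        self.Sy_tot = float(y.sum())

    def components(self, lam):
        """GLS pieces at variance ratio(s) lam (scalar or 1-D array)."""
        lam = np.asarray(lam, dtype=float)
        scalar = lam.ndim == 0
        lam2 = np.atleast_1d(lam)[:, None]          # (L, 1)
        c = lam2 / (1.0 + self.ng[None, :] * lam2)  # (L, G)
        A00 = self.n - (c * self.ng**2).sum(axis=1)
        A01 = self.Sx_tot - (c * self.ng * self.Sx).sum(axis=1)
        A11 = self.Sxx - (c * self.Sx**2).sum(axis=1)
        t0 = self.Sy_tot - (c * self.ng * self.Sy).sum(axis=1)
        t1 = self.Sxy - (c * self.Sx * self.Sy).sum(axis=1)
        yy = self.Syy - (c * self.Sy**2).sum(axis=1)
        det = A00 * A11 - A01**2
        b1 = (A00 * t1 - A01 * t0) / det
        b0 = (t0 - A01 * b1) / A00
        rss = yy - b0 * t0 - b1 * t1
        logdetV = np.log1p(self.ng[None, :] * lam2).sum(axis=1)
        out = (b0, b1, rss, det, A00, A11, A01, logdetV)
        if scalar:
            out = tuple(np.asarray(v).item() for v in out)
        return out

    def loglik(self, lam):
        """Profiled REML log-likelihood at lam (vectorized)."""
        b0, b1, rss, det, *_rest, logdetV = self.components(lam)
        nmp = self.n - 2
        sigma2 = np.maximum(np.asarray(rss, dtype=float) / nmp, 1e-300)
        return -0.5 * (
            nmp * (_LOG2PI + 1.0)
            + nmp * np.log(sigma2)
            + logdetV
            + np.log(det)
        )


def fit_random_intercept(
    y,
    x,
    groups,
    *,
    min_obs: int = 10,
    lam_lo: float = 1e-8,
    lam_hi: float = 1e6,
    grid_points: int = 57,
    tol: float = 1e-10,
) -> LMEFit:
    """Fit the random-intercept model for one protein:carotenoid pair.

    Parameters
    ----------
    y, x, groups
        Aligned 1-D sequences of log2 concentration, log2 abundance and
        plex labels; complete cases only (no NaN).
    min_obs
        Minimum number of observations below which the pair is skipped
        (raises :class:`InsufficientDataError`).
    lam_lo, lam_hi, grid_points
        Log-spaced search grid for the variance ratio; the bracketing
        interval around the grid maximum is refined by golden section.

    Raises
    ------
    NoSlopeVarianceError
        If x is constant.
    InsufficientGroupsError
        If fewer than two distinct plexes are present.
    InsufficientDataError
        If fewer than ``min_obs`` observations are available.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    groups = np.asarray(groups)
    if not (y.shape == x.shape == groups.shape) or y.ndim != 1:
        raise ValueError("y, x and groups must be aligned 1-D sequences")
    if np.isnan(y).any() or np.isnan(x).any():
        raise ValueError("complete cases only: NaN found in y or x")
    n = y.size
    if n < min_obs:
        raise InsufficientDataError(f"{n} observations < floor {min_obs}")
    labels, codes = np.unique(groups, return_inverse=True)
    n_groups = labels.size
    if n_groups < 2:
        raise InsufficientGroupsError("need >= 2 plexes to separate variance")
    if np.ptp(x) == 0:
        raise NoSlopeVarianceError("constant abundance: slope not estimable")

    prof = _Profile(y, x, codes, n_groups)

    # Perfect-fit guard: with an exactly linear y the residual variance is 0
    # and the likelihood is unbounded; report the OLS line with variances at
    # their lower boundary.
    b0_ols, b1_ols, rss_ols, det_ols, A00_ols, *_ = prof.components(0.0)
    scale = max(prof.Syy, 1.0)
    if rss_ols <= 1e-12 * scale:
        sigma2 = max(rss_ols / (n - 2), 0.0)
        se = math.sqrt(max(sigma2 * A00_ols / det_ols, 0.0))
        return LMEFit(
            b0=b0_ols, b1_raw=b1_ols, se_b1=se,
            sigma_B2=0.0, sigma_e2=max(sigma2, 5e-324),
            lambda_hat=0.0,
            blups={lab: 0.0 for lab in labels},
            n_obs=n, n_groups=n_groups,
            reml_loglik=float(prof.loglik(0.0)),
            converged=True, boundary=True,
        )

    loglam = np.linspace(math.log(lam_lo), math.log(lam_hi), grid_points)
    ll_grid = prof.loglik(np.exp(loglam))
    i = int(np.argmax(ll_grid))
    a = loglam[max(i - 1, 0)]
    b = loglam[min(i + 1, grid_points - 1)]

    # golden-section maximization of the profiled criterion on [a, b]
    f = lambda t: float(prof.loglik(math.exp(t)))
    h = b - a
    c, d = b - _INVPHI * h, a + _INVPHI * h
    fc, fd = f(c), f(d)
    for _ in range(200):
        if h < 1e-9:
            break
        if fc >= fd:
            b, d, fd = d, c, fc
            h = b - a
            c = b - _INVPHI * h
            fc = f(c)
        else:
            a, c, fc = c, d, fd
            h = b - a
            d = a + _INVPHI * h
            fd = f(d)
    t_hat = c if fc >= fd else d
    lam_hat = math.exp(t_hat)
    ll_hat = max(fc, fd)

    # boundary check: accept lambda = 0 when it is at least as likely
    ll0 = float(prof.loglik(0.0))
    boundary = False
    if ll0 >= ll_hat - tol:
        lam_hat, ll_hat, boundary = 0.0, ll0, True

    b0, b1, rss, det, A00, *_rest = prof.components(lam_hat)
    sigma_e2 = max(rss / (n - 2), 5e-324)
    sigma_B2 = lam_hat * sigma_e2
    se_b1 = math.sqrt(sigma_e2 * A00 / det)
    # shrinkage predictors: B_r = lam/(1 + n_r lam) * sum of fixed-part residuals
    c_r = lam_hat / (1.0 + prof.ng * lam_hat)
    resid_sum = prof.Sy - b0 * prof.ng - b1 * prof.Sx
    blups = dict(zip(labels.tolist(), (c_r * resid_sum).tolist()))
    return LMEFit(
        b0=float(b0), b1_raw=float(b1), se_b1=float(se_b1),
        sigma_B2=float(sigma_B2), sigma_e2=float(sigma_e2),
        lambda_hat=float(lam_hat), blups=blups,
        n_obs=n, n_groups=n_groups,
        reml_loglik=float(ll_hat), converged=True, boundary=boundary,
    )


def wald_p(fit: LMEFit) -> float:
    """Two-sided normal-reference Wald p-value for the slope being zero."""
    if fit.se_b1 == 0.0:
        if fit.b1_raw == 0.0:
            return 1.0
        warnings.warn(
            "degenerate inference: zero standard error with nonzero slope",
            RuntimeWarning,
            stacklevel=2,
        )
        return 0.0
    z = abs(fit.b1_raw / fit.se_b1)
    return float(2.0 * stats.norm.sf(z))


def percent_change(b1_raw):
    """Percent change in concentration per 2-fold increase in abundance.

    On the log2–log2 scale a slope b maps a doubling of protein abundance
    to a factor 2**b in concentration, i.e. (2**b - 1) * 100 percent.
    """
    return (np.exp2(b1_raw) - 1.0) * 100.0


def association_stats(fit: LMEFit, y, x, groups) -> tuple[float, float]:
    """Model-based correlation (r) and R² for one fitted pair.

    Fitted values include the plex BLUPs: yhat = b0 + b1*x + B_r.  The
    magnitude of r is the Pearson correlation of observed y with yhat;
    its sign is taken from the slope (the correlation with fitted values
    is non-negative by construction).  Returns (nan, nan) when yhat is
    constant.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    b = np.array([fit.blups.get(g, 0.0) for g in np.asarray(groups)])
    yhat = fit.b0 + fit.b1_raw * x + b
    if np.ptp(yhat) == 0 or np.ptp(y) == 0:
        warnings.warn("undefined correlation: constant fitted values",
                      RuntimeWarning, stacklevel=2)
        return (float("nan"), float("nan"))
    rho = float(np.corrcoef(y, yhat)[0, 1])
    sign = 1.0 if fit.b1_raw > 0 else (-1.0 if fit.b1_raw < 0 else 0.0)
    r = sign * abs(rho)
    return (r, r * r)
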
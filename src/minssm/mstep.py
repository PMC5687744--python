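"""M step: closed-form updates of (mu, Sigma, sigma_R^2, sigma_Q^2).

Given the smoothed sufficient statistics and the regularized transition
matrix A-hat, each update maximizes the expected complete-data log-likelihood
over its own coordinate:

    mu-hat      = x_1^T
    Sigma-hat   = (xx')_1^T - x_1^T (x_1^T)'
    sigma_R^2   = trace( sum_t E[(y_t - x_t)(y_t - x_t)' | Y] ) / (T p)
    sigma_Q^2   = trace( s_self - A S10' - S10 A' + A S11 A' ) / ((T-1) p)

The noise updates use the full expected quadratic forms, i.e. the exact
maximizers of the expected likelihood for *any* fixed A (the simplified
two-term expressions sometimes quoted for these updates are valid only when
A is the unpenalized MLE, which the regularized A-hat is not). The matrix
expressions are symmetrized and projected onto the scalar-diagonal family by
trace-averaging, matching the model restriction Q = sigma_Q^2 I,
R = sigma_R^2 I.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .kalman import SufficientStatistics
from .ssm import ObservationSeries

__all__ = ["MStepUpdate", "mstep_update", "expected_loglik"]

_LOG2PI = np.log(2.0 * np.pi)


@dataclass
class MStepUpdate:
    mu_hat: np.ndarray
    Sigma_hat: np.ndarray
    sigma_R2_hat: float
    sigma_Q2_hat: float


def _measurement_sse(ss: SufficientStatistics, Y: np.ndarray) -> float:
    """trace of sum_t E[(y_t - x_t)(y_t - x_t)' | Y]."""
    X = ss.smooth_mean
    tr_V = np.trace(ss.smooth_cov, axis1=1, axis2=2).sum()
    return float(np.sum((Y - X) ** 2) + tr_V)


def _transition_sse(ss: SufficientStatistics, A: np.ndarray) -> float:
    """trace of sum_t E[(x_t - A x_{t-1})(x_t - A x_{t-1})' | Y]."""
    M = ss.s_self - A @ ss.S10.T - ss.S10 @ A.T + A @ ss.S11 @ A.T
    M = 0.5 * (M + M.T)
    return float(np.trace(M))


def mstep_update(
    ss: SufficientStatistics, A_hat: np.ndarray, Y: ObservationSeries, cfg
) -> MStepUpdate:
    """Closed-form maximizers of the expected likelihood given A_hat.

    Variances are floored at ``cfg.var_floor``; a negative trace before
    flooring signals model misfit and triggers a warning. Which components
    the caller actually applies is governed by the config estimate flags.
    """
    Ym = Y.Y
    T, p = Ym.shape
    if ss.p != p or A_hat.shape != (p, p):
        raise ValueError("inconsistent shapes in M step")
    floor = cfg.var_floor

    mu_hat = ss.smooth_mean[0].copy()
    Sigma_hat = 0.5 * (ss.smooth_cov[0] + ss.smooth_cov[0].T)

    sse_R = _measurement_sse(ss, Ym)
    sse_Q = _transition_sse(ss, A_hat)
    if sse_R < -1e-10 or sse_Q < -1e-10:
        warnings.warn("negative expected sum of squares floored (model misfit?)")
    sigma_R2 = max(sse_R / (T * p), floor)
    sigma_Q2 = max(sse_Q / ((T - 1) * p), floor)
    return MStepUpdate(mu_hat, Sigma_hat, sigma_R2, sigma_Q2)


def expected_loglik(
    ss: SufficientStatistics,
    A: np.ndarray,
    mu: np.ndarray,
    Sigma: np.ndarray,
    sigma_R2: float,
    sigma_Q2: float,
    Y: ObservationSeries,
) -> float:
    """Expected complete-data log-likelihood G(theta) under the smoothing law.

    Used by the M step's tests (the closed-form updates must be its argmax)
    and available as a diagnostic.
    """
    Ym = Y.Y
    T, p = Ym.shape
    meas = -0.5 * _measurement_sse(ss, Ym) / sigma_R2 - 0.5 * T * p * np.log(sigma_R2)
    trans = -0.5 * _transition_sse(ss, A) / sigma_Q2 - 0.5 * (T - 1) * p * np.log(
        sigma_Q2
    )
    d = ss.smooth_mean[0] - mu
    S1 = ss.smooth_cov[0] + np.outer(d, d)
    sign, logdet = np.linalg.slogdet(Sigma)
    if sign <= 0:
        raise ValueError("Sigma must be positive definite")
    init = -0.5 * np.trace(np.linalg.solve(Sigma, S1)) - 0.5 * logdet
    return float(meas + trans + init - T * p * _LOG2PI)
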
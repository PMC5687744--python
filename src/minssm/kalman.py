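"""E step: Kalman filtering, smoothing and the sufficient statistics.

The filter/smoother here is specialized to the identity observation matrix
and scalar-diagonal noise covariances of the interaction-network model. The
initial state is x_1 ~ N(mu, Sigma), matching the complete-data likelihood
and the M-step update mu-hat = x_1^T, so the innovations log-likelihood
returned by the filter is exactly the marginal likelihood of the data under
the same model whose expected complete-data likelihood the M step maximizes.

Sufficient statistics produced by the smoother:

    S11    = sum_{t=1}^{T-1} E(x_t x_t' | Y)        ("Gram" of lagged states)
    S10    = sum_{t=2}^{T}   E(x_t x_{t-1}' | Y)    (lag-one cross-moments)
    s_self = sum_{t=2}^{T}   E(x_t x_t' | Y)

where E(x_t x_s' | Y) = V_{t,s}^T + x_t^T (x_s^T)'.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ssm import ObservationSeries, SSMParameters

__all__ = [
    "FilterResult",
    "SufficientStatistics",
    "kalman_filter",
    "kalman_smoother",
    "recursive_spd_inverse",
]

_LOG2PI = np.log(2.0 * np.pi)


@dataclass
class FilterResult:
    """Forward-pass quantities: predictions, filtered moments, gains."""

    pred_mean: np.ndarray  # (T, p)   x_t^{t-1}
    pred_cov: np.ndarray  # (T, p, p) V_t^{t-1}
    filt_mean: np.ndarray  # (T, p)   x_t^t
    filt_cov: np.ndarray  # (T, p, p) V_t^t
    gain: np.ndarray  # (T, p, p) K_t
    loglik: float  # innovations log-likelihood


@dataclass
class SufficientStatistics:
    """Smoothed moments and their sums feeding the R and M steps."""

    smooth_mean: np.ndarray  # (T, p)     x_t^T
    smooth_cov: np.ndarray  # (T, p, p)   V_t^T
    lag1_cov: np.ndarray  # (T-1, p, p)   V_{t,t-1}^T for t = 2..T
    S11: np.ndarray  # (p, p)
    S10: np.ndarray  # (p, p)
    s_self: np.ndarray  # (p, p)

    @property
    def T(self) -> int:
        return self.smooth_mean.shape[0]

    @property
    def p(self) -> int:
        return self.smooth_mean.shape[1]


def _sym(M: np.ndarray) -> np.ndarray:
    return 0.5 * (M + M.swapaxes(-1, -2))


def plugin_statistics(X: np.ndarray) -> SufficientStatistics:
    """Zero-variance plug-in statistics from a point estimate of the states."""
    X = np.asarray(X, dtype=float)
    T, p = X.shape
    return SufficientStatistics(
        smooth_mean=X.copy(),
        smooth_cov=np.zeros((T, p, p)),
        lag1_cov=np.zeros((T - 1, p, p)),
        S11=X[:-1].T @ X[:-1],
        S10=X[1:].T @ X[:-1],
        s_self=X[1:].T @ X[1:],
    )


def recursive_spd_inverse(B: np.ndarray, delta: np.ndarray, D: np.ndarray) -> np.ndarray:
    """Compute (B' Delta B + D^{-1})^{-1} by n rank-one updates.

    Blockwise-inversion recursion: with b_i the i-th row of B and D_0 = D,

        D_{i+1} = D_i - D_i b_{i+1} b_{i+1}' D_i / (1/delta_{i+1} + b_{i+1}' D_i b_{i+1})

    and the result is D_n. No explicit matrix inversion is performed, which
    is the point for high-dimensional filtering.
    """
    B = np.atleast_2d(np.asarray(B, dtype=float))
    delta = np.atleast_1d(np.asarray(delta, dtype=float))
    Di = np.array(D, dtype=float, copy=True)
    n = B.shape[0]
    for i in range(n):
        if delta[i] == 0.0:
            continue
        b = B[i]
        Db = Di @ b
        denom = 1.0 / delta[i] + b @ Db
        if denom == 0.0 or not np.isfinite(denom):
            raise np.linalg.LinAlgError(f"zero denominator at recursion step {i}")
        Di -= np.outer(Db, Db) / denom
    return Di


def _pred_cov_inverse_recursive(
    A: np.ndarray, sigma_Q: float, filt_cov_prev: np.ndarray
) -> np.ndarray:
    """(V_t^{t-1})^{-1} without inverting V, via the blockwise recursion.

    (V_t^{t-1})^{-1} = Q^{-1} - Q^{-1} A [A' Q^{-1} A + (V_{t-1}^{t-1})^{-1}]^{-1} A' Q^{-1}
    with the bracket evaluated by ``recursive_spd_inverse``.
    """
    p = A.shape[0]
    inner = recursive_spd_inverse(A, np.full(p, 1.0 / sigma_Q), filt_cov_prev)
    QiA = A / sigma_Q  # Q^{-1} A with Q = sigma_Q * I
    return np.eye(p) / sigma_Q - QiA @ inner @ QiA.T


def kalman_filter(
    params: SSMParameters, Y: ObservationSeries, inversion: str = "direct"
) -> FilterResult:
    """Forward recursions (prediction and filtering) with C = I.

    x_t^{t-1} = A x_{t-1}^{t-1},  V_t^{t-1} = A V_{t-1}^{t-1} A' + Q,
    K_t = V_t^{t-1} (V_t^{t-1} + R)^{-1},
    x_t^t = x_t^{t-1} + K_t (y_t - x_t^{t-1}),  V_t^t = V_t^{t-1} - K_t V_t^{t-1};
    at t = 1 the prediction is the prior of the initial state, x_1^0 = mu and
    V_1^0 = Sigma. ``loglik`` accumulates sum_t log N(y_t; x_t^{t-1},
    V_t^{t-1} + R).

    With ``inversion="recursive"`` the filtered covariance is computed through
    the inverse-free rank-one recursion instead of a dense solve.
    """
    Ym = Y.Y
    T, p = Ym.shape
    if params.p != p:
        raise ValueError("parameter dimension does not match data")
    if not np.all(np.isfinite(Ym)):
        raise ValueError("non-finite observations")
    A, sq, sr = params.A, params.sigma_Q, params.sigma_R
    eye = np.eye(p)

    pred_mean = np.empty((T, p))
    pred_cov = np.empty((T, p, p))
    filt_mean = np.empty((T, p))
    filt_cov = np.empty((T, p, p))
    gain = np.empty((T, p, p))
    loglik = 0.0

    for t in range(T):
        if t == 0:
            xp = params.mu
            Vp = 0.5 * (params.Sigma + params.Sigma.T)
        else:
            xp = A @ filt_mean[t - 1]
            Vp = _sym(A @ filt_cov[t - 1] @ A.T) + sq * eye
        innov_cov = Vp + sr * eye
        sign, logdet = np.linalg.slogdet(innov_cov)
        if sign <= 0:
            raise np.linalg.LinAlgError(
                f"singular innovation covariance at time index {t}"
            )
        innov = Ym[t] - xp
        solved = np.linalg.solve(innov_cov, innov)
        loglik += -0.5 * (p * _LOG2PI + logdet + innov @ solved)

        if inversion == "recursive" and sr > 0:
            if t == 0:
                # Sigma may be singular at init; bracket form needs V_p SPD.
                Vf = _sym(
                    recursive_spd_inverse(eye, np.full(p, 1.0 / sr), Vp)
                    if np.linalg.matrix_rank(Vp) == p
                    else Vp - Vp @ np.linalg.solve(innov_cov, Vp)
                )
            else:
                Vf = _sym(recursive_spd_inverse(eye, np.full(p, 1.0 / sr), Vp))
            K = Vf / sr  # K_t = V_t^t R^{-1} for C = I
        else:
            K = np.linalg.solve(innov_cov.T, Vp.T).T  # V_p (V_p + R)^{-1}
            Vf = _sym(Vp - K @ Vp)
        pred_mean[t], pred_cov[t] = xp, Vp
        gain[t] = K
        filt_mean[t] = xp + K @ innov
        filt_cov[t] = Vf

    return FilterResult(pred_mean, pred_cov, filt_mean, filt_cov, gain, float(loglik))


def kalman_smoother(
    params: SSMParameters, fr: FilterResult, inversion: str = "direct"
) -> SufficientStatistics:
    """Backward (Rauch-Tung-Striebel) recursions and lag-one covariances.

    J_{t-1} = V_{t-1}^{t-1} A' (V_t^{t-1})^{-1}
    x_{t-1}^T = x_{t-1}^{t-1} + J_{t-1} (x_t^T - A x_{t-1}^{t-1})
    V_{t-1}^T = V_{t-1}^{t-1} + J_{t-1} (V_t^T - V_t^{t-1}) J_{t-1}'
    with the lag-one recursion started at V_{T,T-1}^T = (I - K_T) A V_{T-1}^{T-1}.
    """
    T, p = fr.filt_mean.shape
    if T < 2:
        raise ValueError("smoother requires T >= 2")
    A = params.A
    eye = np.eye(p)

    smooth_mean = np.empty((T, p))
    smooth_cov = np.empty((T, p, p))
    lag1_cov = np.empty((T - 1, p, p))
    smooth_mean[-1] = fr.filt_mean[-1]
    smooth_cov[-1] = fr.filt_cov[-1]

    J = np.empty((T - 1, p, p))  # J[t] is the gain used to smooth time t
    for t in range(T - 2, -1, -1):
        Vp_next = fr.pred_cov[t + 1]
        if inversion == "recursive":
            Vp_inv = _pred_cov_inverse_recursive(A, params.sigma_Q, fr.filt_cov[t])
            Jt = fr.filt_cov[t] @ A.T @ Vp_inv
        else:
            Jt = np.linalg.solve(Vp_next.T, (fr.filt_cov[t] @ A.T).T).T
        J[t] = Jt
        smooth_mean[t] = fr.filt_mean[t] + Jt @ (
            smooth_mean[t + 1] - A @ fr.filt_mean[t]
        )
        smooth_cov[t] = _sym(
            fr.filt_cov[t] + Jt @ (smooth_cov[t + 1] - Vp_next) @ Jt.T
        )

    # lag1_cov[k] = V_{t,t-1}^T with t = k + 2 (1-based), i.e. Cov(x_{k+1}, x_k).
    lag1_cov[-1] = (eye - fr.gain[-1]) @ A @ fr.filt_cov[-2]
    for t in range(T - 2, 0, -1):
        # V_{t,t-1}^T = V_t^t J_{t-1}' + J_t (V_{t+1,t}^T - A V_t^t) J_{t-1}'
        lag1_cov[t - 1] = (
            fr.filt_cov[t] @ J[t - 1].T
            + J[t] @ (lag1_cov[t] - A @ fr.filt_cov[t]) @ J[t - 1].T
        )

    Exx = smooth_cov + smooth_mean[:, :, None] * smooth_mean[:, None, :]
    Exx_lag = lag1_cov + smooth_mean[1:, :, None] * smooth_mean[:-1, None, :]
    return SufficientStatistics(
        smooth_mean=smooth_mean,
        smooth_cov=smooth_cov,
        lag1_cov=lag1_cov,
        S11=_sym(Exx[:-1].sum(axis=0)),
        S10=Exx_lag.sum(axis=0),
        s_self=_sym(Exx[1:].sum(axis=0)),
    )
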
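"""Independent oracles used by the test suite.

Each oracle recomputes a quantity by a route that shares no code with the
implementation it checks: dense joint-Gaussian conditioning for the Kalman
recursions, generic Gaussian log-pdfs for the likelihoods, KKT / sign-pattern
enumeration for the adaptive-LASSO path, fixed-point covariance iteration for
the simulator, and power iteration for the spectral radius.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.stats import multivariate_normal


def gaussian_logpdf(x, mean, cov):
    return float(multivariate_normal.logpdf(x, mean=mean, cov=cov))


def joint_gaussian_moments(params, T):
    """Exact joint distribution of (x_{1:T}, y_{1:T}) for the linear SSM.

    x_1 ~ N(mu, Sigma), x_t = A x_{t-1} + w_t, y_t = x_t + v_t. Returns
    (mean_x, P) for the stacked states and (mean_y, S, Cxy) for the stacked
    observations, with P the Tp x Tp state covariance.
    """
    A, sq, sr = params.A, params.sigma_Q, params.sigma_R
    p = A.shape[0]
    mean_x = np.empty((T, p))
    mean_x[0] = params.mu
    for t in range(1, T):
        mean_x[t] = A @ mean_x[t - 1]
    P = np.zeros((T, T, p, p))
    P[0, 0] = params.Sigma
    for t in range(1, T):
        P[t, t] = A @ P[t - 1, t - 1] @ A.T + sq * np.eye(p)
        for s in range(t):
            P[s, t] = P[s, t - 1] @ A.T
            P[t, s] = P[s, t].T
    Pbig = P.transpose(0, 2, 1, 3).reshape(T * p, T * p)
    mean = mean_x.reshape(-1)
    S = Pbig + sr * np.eye(T * p)  # Cov(vec Y)
    return mean, Pbig, mean, S


def conditional_state_moments(params, Y):
    """E(x_{1:T} | y_{1:T}) and Cov by direct conditioning of the joint Gaussian."""
    T, p = Y.shape
    mean_x, Pbig, mean_y, S = joint_gaussian_moments(params, T)
    resid = Y.reshape(-1) - mean_y
    K = Pbig @ np.linalg.inv(S)
    post_mean = (mean_x + K @ resid).reshape(T, p)
    post_cov = Pbig - K @ Pbig  # (Tp, Tp)
    return post_mean, post_cov


def filtered_mean_oracle(params, Y, t):
    """E(x_t | y_1..y_t) by conditioning the sub-joint on the first t observations."""
    T, p = Y.shape
    mean_x, Pbig, mean_y, S = joint_gaussian_moments(params, T)
    xi = slice(t * p, (t + 1) * p)  # block of x_{t+1} in 0-based t
    yi = slice(0, (t + 1) * p)
    Cxy = Pbig[xi, yi]
    Syy = S[yi, yi]
    resid = Y[: t + 1].reshape(-1) - mean_y[yi]
    return mean_x[xi] + Cxy @ np.linalg.solve(Syy, resid)


def observed_loglik_oracle(params, Y):
    """log N(vec Y; mean, P + sigma_R^2 I): the exact marginal likelihood."""
    T, p = Y.shape
    _, _, mean_y, S = joint_gaussian_moments(params, T)
    return gaussian_logpdf(Y.reshape(-1), mean_y, S)


def complete_loglik_oracle(params, X, Y):
    """Sum of generic multivariate-normal log-densities for the complete data."""
    T, p = Y.shape
    total = gaussian_logpdf(X[0], params.mu, params.Sigma)
    for t in range(1, T):
        total += gaussian_logpdf(X[t], params.A @ X[t - 1], params.sigma_Q * np.eye(p))
    for t in range(T):
        total += gaussian_logpdf(Y[t], X[t], params.sigma_R * np.eye(p))
    return total


def power_iteration_radius(A, n_burn=500):
    """Spectral radius via power iteration with a two-step recurrence fit.

    After burn-in the iterate lies in the dominant (at most two-dimensional)
    invariant subspace, where x_{k+2} = a x_{k+1} + b x_k with z^2 = a z + b
    solved by the dominant eigenvalue(s); the radius is the largest root
    modulus. Handles real and complex-conjugate dominant pairs alike.
    """
    rng = np.random.default_rng(0)
    v = rng.standard_normal(A.shape[0])
    v /= np.linalg.norm(v)
    for _ in range(n_burn):
        w = A @ v
        nw = np.linalg.norm(w)
        if nw == 0:
            return 0.0
        v = w / nw
    x0 = v
    x1 = A @ x0
    x2 = A @ x1
    coef, *_ = np.linalg.lstsq(np.column_stack([x1, x0]), x2, rcond=None)
    a, b = coef
    roots = np.roots([1.0, -a, -b])
    return float(np.abs(roots).max())


def stationary_covariance(A, sigma_Q, n_iter=10000, tol=1e-12):
    """Fixed point of V <- A V A' + Q."""
    p = A.shape[0]
    V = np.zeros((p, p))
    for _ in range(n_iter):
        V_new = A @ V @ A.T + sigma_Q * np.eye(p)
        if np.max(np.abs(V_new - V)) < tol:
            return V_new
        V = V_new
    return V


def adaptive_lasso_kkt_ok(G, c, w, lam, a, tol=1e-6):
    """Check the subgradient conditions of min yy - 2a'c + a'Ga + lam*sum w|a|."""
    grad = 2.0 * (G @ a - c)
    for j in range(len(a)):
        if not np.isfinite(w[j]):
            if a[j] != 0:
                return False
            continue
        if a[j] != 0:
            if abs(grad[j] + lam * w[j] * np.sign(a[j])) > tol * max(1.0, lam * w[j]):
                return False
        else:
            if abs(grad[j]) > lam * w[j] + tol * max(1.0, lam * w[j]):
                return False
    return True


def adaptive_lasso_enumerate(G, c, w, lam):
    """Global minimizer of the weighted L1 quadratic by sign-pattern enumeration.

    For every sign pattern s in {-1, 0, +1}^p, solve the stationarity system
    on the active set, verify sign feasibility and the zero-coordinate
    subgradient bound, and return the verified solution. Exponential in p;
    intended for p <= 4.
    """
    p = G.shape[0]
    finite = np.isfinite(w)
    for signs in itertools.product((-1, 0, 1), repeat=p):
        s = np.array(signs, dtype=float)
        if np.any(~finite & (s != 0)):
            continue
        active = np.flatnonzero(s != 0)
        a = np.zeros(p)
        if active.size:
            rhs = c[active] - 0.5 * lam * w[active] * s[active]
            try:
                a_act = np.linalg.solve(G[np.ix_(active, active)], rhs)
            except np.linalg.LinAlgError:
                continue
            if np.any(np.sign(a_act) != s[active]):
                continue
            a[active] = a_act
        grad = 2.0 * (G @ a - c)
        inactive = np.flatnonzero(s == 0)
        ok = True
        for j in inactive:
            if finite[j] and abs(grad[j]) > lam * w[j] + 1e-9:
                ok = False
                break
        if ok:
            return a
    raise RuntimeError("no KKT point found (should not happen for PSD G)")
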
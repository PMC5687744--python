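"""R step: adaptive-LASSO estimation of the sparse transition matrix.

Because the latent states are never observed, the VAR regression of x_t on
x_{t-1} is replaced by a *pseudo-regression* built from expected sufficient
statistics: the Gram matrix E(Z*'Z*) = S11, the cross-moments E(Z*'X_i) from
S10, and the response energies from the diagonal of s_self. The expected
residual sum of squares of any candidate row a is then the exact quadratic

    E || X_i - Z* a ||^2 = yy_i - 2 a'c_i + a' G a ,

so the full LARS/LASSO path, the RSS at every breakpoint, and the eBIC score
can all be computed from p x p objects alone. Per-coefficient adaptive
weights w_ij = |ref_ij|^{-1} come from the unpenalized MLE when T - 1 > p and
from a zero-consistent marginal estimator otherwise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln
from sklearn.linear_model import lars_path_gram as _sk_lars_path_gram

from .kalman import SufficientStatistics

__all__ = [
    "PseudoRegression",
    "AdaptiveWeights",
    "LassoPath",
    "EBICSelection",
    "MatrixVariantCapacityError",
    "build_pseudo_regression",
    "mle_A",
    "marginal_A",
    "adaptive_weights",
    "lars_path_gram",
    "ebic_select",
    "rstep_row",
    "rstep_matrix",
]

_DIAG_TINY = 1e-12
_RSS_FLOOR = 1e-12


class MatrixVariantCapacityError(RuntimeError):
    """Raised when the matrix-based R step is asked to exceed its size guard.

    The vectorized problem manipulates p^2-sized objects; beyond the guard the
    row-based variant should be used instead.
    """


@dataclass
class PseudoRegression:
    """Moments defining the pseudo-regression X_i = Z* a_i + e_i for all rows."""

    G: np.ndarray  # (p, p)  E(Z*'Z*) = S11
    c: np.ndarray  # (p, p)  row i = E(Z*'X_i) = i-th row of S10
    yy: np.ndarray  # (p,)   yy_i = E(X_i'X_i) = diag(s_self)
    n_eff: int  # T - 1


@dataclass
class AdaptiveWeights:
    """Entrywise penalty weights w_ij = |ref_ij|^{-1}; +inf freezes an entry."""

    W: np.ndarray
    mode: str  # {"mle", "marginal"}


@dataclass
class LassoPath:
    """Piecewise-linear adaptive-LASSO path for one row of A.

    ``breakpoints`` are penalty values on the scale of the objective
    E||X_i - Z* a||^2 + lambda * sum_j w_j |a_j|, in decreasing order;
    ``coefs[k]`` is the coefficient vector (original, unweighted scale) at
    breakpoint k; ``rss[k]`` the expected residual sum of squares there.
    """

    breakpoints: np.ndarray  # (n_bp,) decreasing
    coefs: np.ndarray  # (n_bp, p)
    rss: np.ndarray  # (n_bp,)

    @property
    def active_sets(self) -> list[np.ndarray]:
        return [np.flatnonzero(c) for c in self.coefs]

    def coefs_at(self, lam: float) -> np.ndarray:
        """Coefficients at an arbitrary penalty by piecewise-linear interpolation."""
        bp = self.breakpoints
        if lam >= bp[0]:
            return np.zeros_like(self.coefs[0])
        if lam <= bp[-1]:
            return self.coefs[-1].copy()
        # np.interp needs ascending x
        x = bp[::-1]
        return np.array(
            [np.interp(lam, x, self.coefs[::-1, j]) for j in range(self.coefs.shape[1])]
        )


@dataclass
class EBICSelection:
    gamma: float
    chosen_index: int
    scores: np.ndarray
    chosen_coefs: np.ndarray


def build_pseudo_regression(ss: SufficientStatistics) -> PseudoRegression:
    """Assemble (G, c, yy, n_eff) from the smoothed sufficient statistics."""
    if not np.allclose(ss.S11, ss.S11.T, atol=1e-8 * (1.0 + np.abs(ss.S11).max())):
        raise RuntimeError("S11 is asymmetric beyond tolerance")
    return PseudoRegression(
        G=0.5 * (ss.S11 + ss.S11.T),
        c=ss.S10.copy(),
        yy=np.diag(ss.s_self).copy(),
        n_eff=ss.T - 1,
    )


def mle_A(ss: SufficientStatistics) -> np.ndarray:
    """Unpenalized maximizer A-hat = S10 S11^{-1} of the expected likelihood."""
    return np.linalg.solve(ss.S11.T, ss.S10.T).T


def marginal_A(ss: SufficientStatistics) -> np.ndarray:
    """Entrywise marginal estimator: column j of S10 scaled by 1/[S11]_jj.

    Zero-consistent under mild conditions, hence usable for adaptive weights
    in the 'large p, small n' regime where the MLE does not exist.
    """
    d = np.diag(ss.S11)
    bad = np.flatnonzero(d <= 0)
    if bad.size:
        raise ValueError(f"nonpositive diagonal of S11 at predictor index {bad[0]}")
    return ss.S10 / d[None, :]


def adaptive_weights(ref: np.ndarray, mode: str = "mle") -> AdaptiveWeights:
    """w_ij = 1/|ref_ij|; exact zeros of the reference map to +inf."""
    ref = np.asarray(ref, dtype=float)
    if not np.all(np.isfinite(ref)):
        raise ValueError("reference estimator must be finite")
    with np.errstate(divide="ignore"):
        W = 1.0 / np.abs(ref)
    return AdaptiveWeights(W=W, mode=mode)


def lars_path_gram(
    G: np.ndarray,
    c_i: np.ndarray,
    yy_i: float,
    w_i: np.ndarray,
    n_eff: int,
) -> LassoPath:
    """Full adaptive-LASSO path for one row, from moments alone.

    Reparameterizes b_j = a_j * w_j so the weighted problem becomes a plain
    LASSO on the rescaled moments, runs LARS with the LASSO modification in
    Gram form, then maps coefficients back. Predictors with infinite weight
    (or numerically zero energy) never enter the candidate set.
    """
    G = np.asarray(G, dtype=float)
    c_i = np.asarray(c_i, dtype=float)
    w_i = np.asarray(w_i, dtype=float)
    p = G.shape[0]
    live = np.isfinite(w_i) & (w_i > 0) & (np.diag(G) > _DIAG_TINY)
    if np.any(np.diag(G) < -_DIAG_TINY):
        raise ValueError("Gram matrix has negative diagonal: not PSD")

    if not np.any(live):
        return LassoPath(
            breakpoints=np.array([0.0]),
            coefs=np.zeros((1, p)),
            rss=np.array([max(float(yy_i), 0.0)]),
        )

    idx = np.flatnonzero(live)
    w = w_i[idx]
    Gs = G[np.ix_(idx, idx)] / np.outer(w, w)
    cs = c_i[idx] / w
    alphas, _, coefs_b = _sk_lars_path_gram(
        Xy=cs.copy(), Gram=Gs.copy(), n_samples=n_eff, method="lasso"
    )
    n_bp = alphas.shape[0]
    coefs = np.zeros((n_bp, p))
    coefs[:, idx] = (coefs_b / w[:, None]).T  # back to the unweighted scale
    # RSS via the quadratic form in the weighted coordinates (identical value)
    B = coefs_b.T  # (n_bp, n_live)
    rss = yy_i - 2.0 * B @ cs + np.einsum("kj,jl,kl->k", B, Gs, B)
    return LassoPath(
        breakpoints=2.0 * n_eff * alphas,  # objective-scale penalty
        coefs=coefs,
        rss=np.maximum(rss, 0.0),
    )


def ebic_select(
    path: LassoPath, n_eff: int, p_total: int, gamma: float
) -> EBICSelection:
    """Select a breakpoint by the extended BIC.

    eBIC(k) = n * log(RSS/n) + k * log(n) + 2 * gamma * log C(p_total, k),
    the Gaussian-RSS form; gamma = 0 recovers the ordinary BIC and gamma = 1
    is the most conservative member. Ties go to the smaller model.
    """
    if not 0.0 <= gamma <= 1.0:
        raise ValueError("gamma must lie in [0, 1]")
    if path.breakpoints.size == 0:
        raise ValueError("empty path")
    rss = np.asarray(path.rss, dtype=float)
    if np.any(rss < -1e-8):
        warnings.warn("negative RSS clamped; numerical noise in the moments")
    rss = np.maximum(rss, _RSS_FLOOR)
    k = np.array([np.count_nonzero(c) for c in path.coefs])
    log_binom = (
        gammaln(p_total + 1) - gammaln(k + 1) - gammaln(p_total - k + 1)
    )
    scores = n_eff * np.log(rss / n_eff) + k * np.log(n_eff) + 2.0 * gamma * log_binom
    best = np.min(scores)
    candidates = np.flatnonzero(scores <= best + 1e-10)
    chosen = int(candidates[np.argmin(k[candidates])])
    return EBICSelection(
        gamma=gamma,
        chosen_index=chosen,
        scores=scores,
        chosen_coefs=path.coefs[chosen].copy(),
    )


def _reference_weights(ss: SufficientStatistics, weight_mode: str) -> AdaptiveWeights:
    n_eff, p = ss.T - 1, ss.p
    mode = weight_mode
    if mode == "auto":
        mode = "mle" if n_eff > p else "marginal"
    if mode == "mle":
        try:
            ref = mle_A(ss)
        except np.linalg.LinAlgError:
            mode = "marginal"
            ref = marginal_A(ss)
    elif mode == "marginal":
        ref = marginal_A(ss)
    else:
        raise ValueError(f"unknown weight mode {weight_mode!r}")
    return adaptive_weights(ref, mode=mode)


def _row_paths(ss: SufficientStatistics, weight_mode: str) -> list[LassoPath]:
    pr = build_pseudo_regression(ss)
    W = _reference_weights(ss, weight_mode).W
    return [
        lars_path_gram(pr.G, pr.c[i], pr.yy[i], W[i], pr.n_eff)
        for i in range(ss.p)
    ]


def rstep_row(ss: SufficientStatistics, cfg) -> np.ndarray:
    """Row-based R step: independent adaptive-LASSO + per-row eBIC.

    Each row of A is its own pseudo-regression (rows are independent under
    the diagonal system noise), so only p x p objects are ever materialized
    and each row gets its own penalty.
    """
    p, n_eff = ss.p, ss.T - 1
    A_hat = np.zeros((p, p))
    paths = _row_paths(ss, cfg.weight_mode)
    for i, path in enumerate(paths):
        try:
            sel = ebic_select(path, n_eff, p, cfg.gamma)
        except Exception as exc:  # attach the row for diagnosis
            raise RuntimeError(f"R step failed at row {i}: {exc}") from exc
        A_hat[i] = sel.chosen_coefs
    return A_hat


def rstep_matrix(ss: SufficientStatistics, cfg) -> np.ndarray:
    """Matrix-based R step: one global penalty on the vectorized problem.

    The p^2 x p^2 Gram of the vectorized design Z = Z* (x) I is block-diagonal
    with identical blocks G under diagonal Q, so the joint problem separates
    into the p row problems *sharing one penalty*. The global path is the
    union of the per-row breakpoints; eBIC is evaluated with n = (T-1) * p
    and model space size p^2.
    """
    p, n_eff = ss.p, ss.T - 1
    if p > cfg.matrix_p_max:
        raise MatrixVariantCapacityError(
            f"matrix-based R step limited to p <= {cfg.matrix_p_max} (got p = {p}); "
            "the p^2-sized vectorized problem does not fit in memory at this "
            "dimension -- use the row-based variant (rstep_variant='row')"
        )
    paths = _row_paths(ss, cfg.weight_mode)
    lams = np.unique(np.concatenate([pa.breakpoints for pa in paths]))[::-1]
    if lams.size > 300:  # cap the candidate grid; endpoints always kept
        keep = np.unique(np.linspace(0, lams.size - 1, 300).astype(int))
        lams = lams[keep]

    pr = build_pseudo_regression(ss)
    n_total = n_eff * p
    best_score, best_coefs, best_k = np.inf, None, None
    for lam in lams:
        rss_tot, k_tot = 0.0, 0
        coef_rows = np.empty((p, p))
        for i, path in enumerate(paths):
            a = path.coefs_at(lam)
            coef_rows[i] = a
            k_tot += int(np.count_nonzero(a))
            rss_tot += pr.yy[i] - 2.0 * a @ pr.c[i] + a @ pr.G @ a
        rss_tot = max(rss_tot, _RSS_FLOOR)
        log_binom = (
            gammaln(p * p + 1) - gammaln(k_tot + 1) - gammaln(p * p - k_tot + 1)
        )
        score = (
            n_total * np.log(rss_tot / n_total)
            + k_tot * np.log(n_total)
            + 2.0 * cfg.gamma * log_binom
        )
        if score < best_score - 1e-10 or (
            score <= best_score + 1e-10 and best_k is not None and k_tot < best_k
        ):
            best_score, best_coefs, best_k = score, coef_rows.copy(), k_tot
    return best_coefs
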
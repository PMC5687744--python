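"""scikit-learn style estimator wrapping the ERM fitting procedure.

``ERMNetwork`` is the public face of the package: ``fit`` runs the
Expectation-Regularization-Maximization iteration on a (T, p) time series,
``predict`` produces one-step-ahead forecasts from filtered states, and
``score`` returns the mean per-taxon coefficient of determination. It
follows the scikit-learn estimator contract (get_params/set_params, fitted
attributes with trailing underscores, validation in fit) and composes with
sklearn utilities such as ``clone``.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .erm import ERMConfig, fit_erm
from .kalman import kalman_filter
from .ssm import ObservationSeries

__all__ = ["ERMNetwork"]


class ERMNetwork(BaseEstimator):
    """Sparse dynamic interaction network via a regularized state-space model.

    Parameters mirror :class:`minssm.erm.ERMConfig`; see there for the noise
    identifiability policy and defaults.

    Attributes
    ----------
    A_ : (p, p) ndarray
        Estimated sparse transition matrix (the interaction network).
    sigma_Q2_, sigma_R2_ : float
        Final system / measurement noise variances.
    mu_, Sigma_ : initial-state parameters actually used.
    loglik_trace_ : list of float
        Innovations log-likelihood after each E step.
    n_iter_ : int
    converged_ : bool
    """

    def __init__(
        self,
        *,
        tol: float = 1e-4,
        max_iter: int = 100,
        gamma: float = 0.5,
        weight_mode: str = "auto",
        estimate_Q: bool = True,
        estimate_R: bool = False,
        estimate_mu: bool = False,
        sigma_Q_init: float = 1.0,
        sigma_R_fixed: float = 0.1,
        rstep_variant: str = "row",
        matrix_p_max: int = 60,
        var_floor: float = 1e-8,
        smoother: str = "spline",
        inversion: str = "direct",
        random_state: int = 0,
    ):
        self.tol = tol
        self.max_iter = max_iter
        self.gamma = gamma
        self.weight_mode = weight_mode
        self.estimate_Q = estimate_Q
        self.estimate_R = estimate_R
        self.estimate_mu = estimate_mu
        self.sigma_Q_init = sigma_Q_init
        self.sigma_R_fixed = sigma_R_fixed
        self.rstep_variant = rstep_variant
        self.matrix_p_max = matrix_p_max
        self.var_floor = var_floor
        self.smoother = smoother
        self.inversion = inversion
        self.random_state = random_state

    def _config(self) -> ERMConfig:
        return ERMConfig(
            tol=self.tol,
            max_iter=self.max_iter,
            gamma=self.gamma,
            weight_mode=self.weight_mode,
            estimate_Q=self.estimate_Q,
            estimate_R=self.estimate_R,
            estimate_mu=self.estimate_mu,
            sigma_Q_init=self.sigma_Q_init,
            sigma_R_fixed=self.sigma_R_fixed,
            rstep_variant=self.rstep_variant,
            matrix_p_max=self.matrix_p_max,
            var_floor=self.var_floor,
            smoother=self.smoother,
            seed=self.random_state,
            inversion=self.inversion,
        )

    def fit(self, X, y=None):
        """Fit the network to a (T, p) series (rows = time points)."""
        series = X if isinstance(X, ObservationSeries) else ObservationSeries(
            np.asarray(X, dtype=float)
        )
        res = fit_erm(series, self._config())
        self.A_ = res.A_hat
        self.params_ = res.params
        self.sigma_Q2_ = res.params.sigma_Q
        self.sigma_R2_ = res.params.sigma_R
        self.mu_ = res.params.mu
        self.Sigma_ = res.params.Sigma
        self.loglik_trace_ = res.loglik_trace
        self.n_iter_ = res.n_iter
        self.converged_ = res.converged
        self.suffstats_ = res.suffstats
        self.n_features_in_ = series.p
        return self

    def predict(self, X):
        """One-step-ahead forecasts y-hat_t = A x_{t-1}^{t-1} for t = 2..T.

        Uses filtered (causal) states from a filter pass at the fitted
        parameters; returns a (T-1, p) array aligned with rows 2..T of X.
        """
        from .pipeline import one_step_predict  # local import: avoids cycle

        if not hasattr(self, "A_"):
            raise RuntimeError("estimator is not fitted")
        series = X if isinstance(X, ObservationSeries) else ObservationSeries(
            np.asarray(X, dtype=float)
        )
        return one_step_predict(self, series).y_pred

    def score(self, X, y=None) -> float:
        """Mean per-taxon one-step-ahead coefficient of determination."""
        from .pipeline import one_step_predict

        series = X if isinstance(X, ObservationSeries) else ObservationSeries(
            np.asarray(X, dtype=float)
        )
        return float(np.mean(one_step_predict(self, series).r2))

    def filter(self, X):
        """Kalman filter pass at the fitted parameters (diagnostics)."""
        series = X if isinstance(X, ObservationSeries) else ObservationSeries(
            np.asarray(X, dtype=float)
        )
        return kalman_filter(self.params_, series, inversion=self.inversion)
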
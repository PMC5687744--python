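"""Linear state-space model for dynamic microbial interaction networks.

The model couples a first-order vector autoregression on latent abundances
with an identity observation map:

    x_t = A x_{t-1} + w_t,   w_t ~ N(0, sigma_Q^2 I),   t = 2..T
    y_t = x_t + v_t,         v_t ~ N(0, sigma_R^2 I),   t = 1..T
    x_1 ~ N(mu, Sigma)

Entry ``a_ij`` of the transition matrix ``A`` is the directed dynamic effect
of taxon *j* on taxon *i*; the sparse support of ``A`` is the interaction
network. Observation dimension equals state dimension because sequencing
yields a (noisy) reading of every taxon, so the observation matrix is the
identity and both noise covariances are taken scalar-diagonal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SSMParameters",
    "ObservationSeries",
    "StateTrajectory",
    "simulate_ssm",
    "complete_data_loglik",
    "spectral_radius",
]

_LOG2PI = np.log(2.0 * np.pi)


@dataclass
class SSMParameters:
    """Full parameter set theta = (A, sigma_Q^2, sigma_R^2, mu, Sigma).

    Parameters
    ----------
    A : (p, p) ndarray
        State transition / interaction matrix.
    sigma_Q : float
        System noise variance sigma_Q^2 > 0; Q = sigma_Q^2 * I.
    sigma_R : float
        Measurement noise variance sigma_R^2 >= 0; R = sigma_R^2 * I.
    mu : (p,) ndarray
        Initial state mean (of x_1).
    Sigma : (p, p) ndarray
        Initial state covariance, symmetric PSD.
    """

    A: np.ndarray
    sigma_Q: float
    sigma_R: float
    mu: np.ndarray
    Sigma: np.ndarray

    def __post_init__(self) -> None:
        self.A = np.atleast_2d(np.asarray(self.A, dtype=float))
        self.mu = np.atleast_1d(np.asarray(self.mu, dtype=float))
        self.Sigma = np.atleast_2d(np.asarray(self.Sigma, dtype=float))
        self.sigma_Q = float(self.sigma_Q)
        self.sigma_R = float(self.sigma_R)
        p = self.A.shape[0]
        if self.A.shape != (p, p):
            raise ValueError("A must be square")
        if self.mu.shape != (p,):
            raise ValueError(f"mu must have length {p}, got {self.mu.shape}")
        if self.Sigma.shape != (p, p):
            raise ValueError("Sigma must be p x p")
        if self.sigma_Q <= 0:
            raise ValueError("sigma_Q (system noise variance) must be > 0")
        if self.sigma_R < 0:
            raise ValueError("sigma_R (measurement noise variance) must be >= 0")
        if not np.allclose(self.Sigma, self.Sigma.T, atol=1e-10):
            raise ValueError("Sigma must be symmetric")
        eigs = np.linalg.eigvalsh(0.5 * (self.Sigma + self.Sigma.T))
        if eigs.min() < -1e-10:
            raise ValueError("Sigma must be positive semi-definite")

    @property
    def p(self) -> int:
        return self.A.shape[0]


@dataclass
class ObservationSeries:
    """Observed abundances: row t of ``Y`` is y_t, columns are taxa."""

    Y: np.ndarray
    names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.Y = np.atleast_2d(np.asarray(self.Y, dtype=float))
        if self.Y.shape[0] < 2:
            raise ValueError("need at least T = 2 time points")
        if not np.all(np.isfinite(self.Y)):
            raise ValueError("observations must be finite with no missing entries")
        if not self.names:
            self.names = [f"OTU{i + 1}" for i in range(self.Y.shape[1])]
        if len(self.names) != self.Y.shape[1]:
            raise ValueError("names length must match number of columns")

    @property
    def T(self) -> int:
        return self.Y.shape[0]

    @property
    def p(self) -> int:
        return self.Y.shape[1]


@dataclass
class StateTrajectory:
    """Latent state path: row t of ``X`` is x_t."""

    X: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))


def simulate_ssm(
    params: SSMParameters, T: int, seed: int | np.random.Generator
) -> tuple[StateTrajectory, ObservationSeries]:
    """Draw one trajectory and its noisy observations from the model.

    x_1 ~ N(mu, Sigma); x_t = A x_{t-1} + w_t for t = 2..T;
    y_t = x_t + v_t. Bit-reproducible for a fixed seed.
    """
    if T < 2:
        raise ValueError("T must be >= 2")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p = params.p
    # Sigma is PSD by the parameter invariant; use eigh-based square root so
    # rank-deficient (e.g. zero) Sigma is allowed.
    eigval, eigvec = np.linalg.eigh(0.5 * (params.Sigma + params.Sigma.T))
    eigval = np.clip(eigval, 0.0, None)
    sqrt_Sigma = eigvec * np.sqrt(eigval) @ eigvec.T

    X = np.empty((T, p))
    X[0] = params.mu + sqrt_Sigma @ rng.standard_normal(p)
    sd_q = np.sqrt(params.sigma_Q)
    for t in range(1, T):
        X[t] = params.A @ X[t - 1] + sd_q * rng.standard_normal(p)
    Y = X + np.sqrt(params.sigma_R) * rng.standard_normal((T, p))
    return StateTrajectory(X), ObservationSeries(Y)


def complete_data_loglik(
    params: SSMParameters, X: StateTrajectory, Y: ObservationSeries
) -> float:
    """Joint log-likelihood of states and observations.

    Sum of the measurement term (T Gaussians with covariance sigma_R^2 I),
    the transition term (T-1 Gaussians with covariance sigma_Q^2 I) and the
    initial-state term N(x_1; mu, Sigma), with normalizing constant
    -T*p*log(2*pi) (the exact normalizer for the 2T p-dimensional Gaussians).
    """
    Xm, Ym = X.X, Y.Y
    T, p = Ym.shape
    if Xm.shape != Ym.shape:
        raise ValueError("state and observation shapes differ")
    if params.sigma_R <= 0 or params.sigma_Q <= 0:
        raise ValueError("complete-data likelihood requires sigma_R > 0 and sigma_Q > 0")
    sign, logdet_Sigma = np.linalg.slogdet(params.Sigma)
    if sign <= 0:
        raise ValueError("Sigma must be nonsingular")

    meas = -0.5 * np.sum((Ym - Xm) ** 2) / params.sigma_R - 0.5 * T * p * np.log(
        params.sigma_R
    )
    resid = Xm[1:] - Xm[:-1] @ params.A.T
    trans = -0.5 * np.sum(resid**2) / params.sigma_Q - 0.5 * (T - 1) * p * np.log(
        params.sigma_Q
    )
    d0 = Xm[0] - params.mu
    init = -0.5 * d0 @ np.linalg.solve(params.Sigma, d0) - 0.5 * logdet_Sigma
    return float(meas + trans + init - T * p * _LOG2PI)


def spectral_radius(A: np.ndarray) -> float:
    """Maximum modulus of the eigenvalues of a square matrix."""
    A = np.atleast_2d(np.asarray(A, dtype=float))
    if A.shape[0] != A.shape[1]:
        raise ValueError("matrix must be square")
    return float(np.abs(np.linalg.eigvals(A)).max())
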
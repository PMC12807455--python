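"""Stationary autoregressive (AR) processes.

The building block of the dynamic scale-mixture framework: zero-mean,
stationary AR(k) Gaussian processes

    x_t = sum_i phi_i x_{t-i} + xi_t,      xi_t ~ N(0, sigma^2),

their stationary autocovariances and Toeplitz covariance matrices, exact
simulation (the first k values are drawn from the stationary joint, not
burned in), and exact maximum-likelihood estimation under the stationary
Gaussian likelihood.  The exact likelihood of N independent length-T series
depends on the data only through the second-moment matrix C = sum_n x_n x_n^T,
so estimation from raw segments and from expected sufficient statistics (the
M-step of the stochastic-approximation EM) share a single routine.

Stationarity is enforced throughout by optimizing over partial
autocorrelations in (-1, 1), mapped to AR coefficients by the Levinson-Durbin
recursion; every iterate is stationary by construction.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, optimize

__all__ = [
    "ARParams",
    "StationaryCov",
    "yule_walker_autocov",
    "stationary_cov",
    "simulate_ar",
    "ar_exact_mle",
    "ar_mle_from_suffstat",
    "pacf_to_ar",
    "ar_to_pacf",
    "ar_loglik_from_suffstat",
]


def _companion_stationary(phi: np.ndarray) -> bool:
    """True iff all companion-matrix eigenvalues lie strictly inside the unit circle."""
    k = len(phi)
    if k == 0 or not np.any(phi):
        return True
    comp = np.zeros((k, k))
    comp[0, :] = phi
    if k > 1:
        comp[1:, :-1] = np.eye(k - 1)
    return bool(np.max(np.abs(np.linalg.eigvals(comp))) < 1.0)


@dataclass(frozen=True)
class ARParams:
    """Parameters of a stationary AR(k) process.

    Attributes
    ----------
    order : int
        Model order k (>= 1; use phi = 0 for white noise of a given order).
    phi : ndarray, shape (k,)
        Regression coefficients (phi_1 .. phi_k).
    noise_var : float
        Variance sigma^2 > 0 of the driving Gaussian noise xi_t.
    """

    order: int
    phi: np.ndarray
    noise_var: float

    def __post_init__(self):
        phi = np.atleast_1d(np.asarray(self.phi, dtype=float))
        if self.order < 1 or phi.shape != (self.order,):
            raise ValueError(f"phi must have shape ({self.order},), got {phi.shape}")
        if not np.all(np.isfinite(phi)):
            raise ValueError("non-finite AR coefficients")
        if not self.noise_var > 0:
            raise ValueError(f"noise_var must be positive, got {self.noise_var}")
        if not _companion_stationary(phi):
            raise ValueError(f"non-stationary AR coefficients: {phi}")
        object.__setattr__(self, "phi", phi)

    @property
    def stationary_var(self) -> float:
        """Stationary (lag-0) variance gamma_0."""
        return float(yule_walker_autocov(self, 0)[0])

    def autocorr(self, max_lag: int) -> np.ndarray:
        g = yule_walker_autocov(self, max_lag)
        return g / g[0]

    def to_json(self) -> str:
        return json.dumps(
            {"order": self.order, "phi": self.phi.tolist(), "noise_var": self.noise_var}
        )

    @classmethod
    def from_json(cls, s: str) -> "ARParams":
        d = json.loads(s)
        return cls(order=d["order"], phi=np.asarray(d["phi"]), noise_var=d["noise_var"])


@dataclass(frozen=True)
class StationaryCov:
    """Stationary autocovariances and the induced symmetric Toeplitz covariance."""

    autocov: np.ndarray
    cov_matrix: np.ndarray = field(repr=False)


def yule_walker_autocov(ar: ARParams, max_lag: int) -> np.ndarray:
    """Autocovariances gamma_0 .. gamma_{max_lag} of a stationary AR(k) process.

    Solves the (k+1)-equation Yule-Walker system

        gamma_0 = sum_i phi_i gamma_i + sigma^2
        gamma_h = sum_i phi_i gamma_{|h-i|},   h = 1..k,

    then extends beyond lag k by the AR recursion.
    """
    if max_lag < 0:
        raise ValueError("max_lag must be >= 0")
    k, phi, s2 = ar.order, ar.phi, ar.noise_var
    # linear system A @ gamma[0:k+1] = rhs
    A = np.zeros((k + 1, k + 1))
    rhs = np.zeros(k + 1)
    rhs[0] = s2
    for h in range(k + 1):
        A[h, h] += 1.0
        for i in range(1, k + 1):
            A[h, abs(h - i)] -= phi[i - 1]
    g = np.linalg.solve(A, rhs)
    if max_lag <= k:
        return g[: max_lag + 1]
    out = np.empty(max_lag + 1)
    out[: k + 1] = g
    for h in range(k + 1, max_lag + 1):
        out[h] = np.dot(phi, out[h - k : h][::-1])
    return out


def stationary_cov(ar: ARParams, T: int) -> StationaryCov:
    """T x T stationary covariance matrix (symmetric Toeplitz, SPD)."""
    if T < 1:
        raise ValueError("T must be >= 1")
    g = yule_walker_autocov(ar, T - 1)
    return StationaryCov(autocov=g, cov_matrix=linalg.toeplitz(g))


def simulate_ar(
    ar: ARParams, T: int, n: int, seed=None, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Simulate n independent stationary series of length T (rows).

    The first min(k, T) values of each series are drawn exactly from the
    stationary joint Gaussian; the remainder follow the AR recursion.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    k = ar.order
    m = min(k, T)
    g = yule_walker_autocov(ar, max(m - 1, 0))
    L = np.linalg.cholesky(linalg.toeplitz(g[:m]) + 0.0)
    x = np.empty((n, T))
    x[:, :m] = rng.standard_normal((n, m)) @ L.T
    if T > m:
        noise = rng.normal(scale=np.sqrt(ar.noise_var), size=(n, T - m))
        phi = ar.phi
        for t in range(m, T):
            x[:, t] = x[:, t - k : t] @ phi[::-1] + noise[:, t - m]
    return x


# ---------------------------------------------------------------------------
# partial-autocorrelation parameterization (Levinson-Durbin)

def pacf_to_ar(pacf: np.ndarray) -> np.ndarray:
    """Map partial autocorrelations in (-1,1) to stationary AR coefficients."""
    pacf = np.asarray(pacf, dtype=float)
    a = np.zeros(0)
    for m, r in enumerate(pacf, start=1):
        a_new = np.empty(m)
        a_new[m - 1] = r
        if m > 1:
            a_new[: m - 1] = a - r * a[::-1]
        a = a_new
    return a


def ar_to_pacf(phi: np.ndarray) -> np.ndarray:
    """Inverse of :func:`pacf_to_ar` (step-down recursion)."""
    a = np.asarray(phi, dtype=float).copy()
    k = len(a)
    pacf = np.empty(k)
    for m in range(k, 0, -1):
        r = a[m - 1]
        pacf[m - 1] = r
        if m > 1:
            denom = 1.0 - r * r
            if denom <= 0:
                raise ValueError("non-stationary coefficients (|pacf| >= 1)")
            a = (a[: m - 1] + r * a[: m - 1][::-1]) / denom
    return pacf


# ---------------------------------------------------------------------------
# exact stationary Gaussian likelihood and MLE

def _unit_cov(phi: np.ndarray, T: int) -> np.ndarray:
    """Stationary covariance for unit driving-noise variance."""
    ar = ARParams(order=len(phi), phi=phi, noise_var=1.0)
    return stationary_cov(ar, T).cov_matrix


def ar_loglik_from_suffstat(C: np.ndarray, N: float, params: ARParams) -> float:
    """Exact stationary Gaussian log-likelihood -1/2 tr(C Sigma^-1) - N/2 log det Sigma
    - NT/2 log 2pi, where Sigma is the stationary covariance of ``params``."""
    T = C.shape[0]
    R = _unit_cov(params.phi, T) * params.noise_var
    cho = linalg.cho_factor(R, lower=True)
    logdet = 2.0 * np.sum(np.log(np.diag(cho[0])))
    quad = float(np.trace(linalg.cho_solve(cho, C)))
    return -0.5 * quad - 0.5 * N * logdet - 0.5 * N * T * np.log(2 * np.pi)


def ar_exact_loglik(data: np.ndarray, params: ARParams) -> float:
    """Exact stationary log-likelihood of an n x T data matrix."""
    data = np.atleast_2d(np.asarray(data, dtype=float))
    return ar_loglik_from_suffstat(data.T @ data, data.shape[0], params)


def _negloglik_profiled(u: np.ndarray, C: np.ndarray, N: float, T: int):
    """Profile negative log-likelihood over pacf = tanh(u); sigma^2 profiled out."""
    phi = pacf_to_ar(np.tanh(u))
    R = _unit_cov(phi, T)
    try:
        cho = linalg.cho_factor(R, lower=True)
    except linalg.LinAlgError:
        return 1e12, None
    logdetR = 2.0 * np.sum(np.log(np.diag(cho[0])))
    quad = float(np.trace(linalg.cho_solve(cho, C)))
    s2 = quad / (N * T)
    if not np.isfinite(s2) or s2 <= 0:
        return 1e12, None
    nll = 0.5 * N * T * np.log(s2) + 0.5 * N * logdetR + 0.5 * N * T
    return nll, s2


def ar_mle_from_suffstat(
    C: np.ndarray,
    N: float,
    k: int,
    x0: ARParams | None = None,
    tol: float = 1e-8,
    maxiter: int = 500,
) -> ARParams:
    """Maximize the expected stationary complete-data log-likelihood
    -1/2 tr(C Sigma^-1) - N/2 log det Sigma over stationary AR(k) parameters.

    Parameters
    ----------
    C : (T, T) symmetric positive-(semi)definite second-moment matrix.
    N : number of series contributing to C.
    k : AR order, must satisfy k < T/2.
    x0 : optional warm start.
    """
    C = np.asarray(C, dtype=float)
    T = C.shape[0]
    if C.shape != (T, T):
        raise ValueError("C must be square")
    if not np.allclose(C, C.T, atol=1e-8 * max(1.0, np.abs(C).max())):
        raise ValueError("C must be symmetric")
    if not 2 * k < T:
        raise ValueError(f"order k={k} must satisfy k < T/2 with T={T}")
    if np.trace(C) <= 0:
        raise ValueError("C must have positive trace")
    # reject clearly indefinite C
    w = np.linalg.eigvalsh((C + C.T) / 2.0)
    if w[0] < -1e-8 * max(w[-1], 1.0):
        raise ValueError("C is indefinite")

    if x0 is not None:
        u0 = np.arctanh(np.clip(ar_to_pacf(x0.phi), -0.999999, 0.999999))
    else:
        u0 = np.zeros(k)

    def fun(u):
        return _negloglik_profiled(u, C, N, T)[0]

    res = optimize.minimize(
        fun,
        u0,
        method="L-BFGS-B",
        options={"maxiter": maxiter, "ftol": tol, "gtol": 1e-10},
    )
    if not res.success and np.max(np.abs(res.jac)) > 1e-3 * max(1.0, abs(res.fun)):
        warnings.warn(f"AR MLE optimizer did not converge cleanly: {res.message}")
    nll, s2 = _negloglik_profiled(res.x, C, N, T)
    phi = pacf_to_ar(np.tanh(res.x))
    return ARParams(order=k, phi=phi, noise_var=float(s2))


def ar_exact_mle(data: np.ndarray, k: int, x0: ARParams | None = None) -> ARParams:
    """Exact maximum-likelihood AR(k) fit of n independent length-T series.

    The initial k values of every series are modeled by the stationary joint
    distribution (not conditioned out), making the problem nonlinear; it is
    solved numerically over the partial-autocorrelation parameterization.
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    n, T = data.shape
    if n < 1:
        raise ValueError("need at least one series")
    if not 2 * k < T:
        raise ValueError(f"order k={k} must satisfy k < T/2 with T={T}")
    return ar_mle_from_suffstat(data.T @ data, n, k, x0=x0)
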
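"""Time-independent Gaussian scale-mixture (GSM) with log-normal scale.

The observed variable is X = Y * S with Y ~ N(0, sigma_Y^2) and
S = exp(Z), Z ~ N(0, sigma_Z^2) (the "scale generator").  In two dimensions
the components X_1 = Y_1 S and X_2 = Y_2 S share a single scale, which makes
them uncorrelated but not independent: their magnitudes are positively
correlated whenever S has nonzero variance.  Closed-form moments:

    var(X)      = sigma_Y^2 exp(2 sigma_Z^2)
    kurtosis(X) = 3 exp(4 sigma_Z^2)

The marginal density has no closed form; it is evaluated by Gauss-Hermite
quadrature over z, which is also how the E-step of the EM fitter computes
posterior expectations of the scalar latent z.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

__all__ = [
    "GSMParams",
    "gsm_moments",
    "gsm_logdensity",
    "sample_gsm",
    "magnitude_correlation",
    "fit_gsm_static",
    "posterior_mean_z",
    "aic",
]

_GH_NODES = 64


def _gh(sigma_z: float, n: int = _GH_NODES):
    """Gauss-Hermite nodes/log-weights for integrating against N(0, sigma_z^2)."""
    t, w = np.polynomial.hermite.hermgauss(n)
    z = np.sqrt(2.0) * sigma_z * t
    logw = np.log(w) - 0.5 * np.log(np.pi)
    return z, logw


@dataclass(frozen=True)
class GSMParams:
    """Parameters of a (1-D or 2-D shared-scale) log-normal GSM.

    sigma_y1, sigma_y2 : standard deviations of the underlying Gaussian
        components (sigma_y2 is None for the 1-D model).
    sigma_z : standard deviation of the Gaussian scale generator Z (>= 0;
        zero recovers a pure Gaussian).
    """

    sigma_y1: float
    sigma_z: float
    sigma_y2: float | None = None
    converged: bool = True

    def __post_init__(self):
        if not self.sigma_y1 > 0:
            raise ValueError("sigma_y1 must be positive")
        if self.sigma_y2 is not None and not self.sigma_y2 > 0:
            raise ValueError("sigma_y2 must be positive")
        if self.sigma_z < 0:
            raise ValueError("sigma_z must be non-negative")

    @property
    def ndim(self) -> int:
        return 1 if self.sigma_y2 is None else 2

    def to_json(self) -> str:
        sy = [self.sigma_y1] if self.sigma_y2 is None else [self.sigma_y1, self.sigma_y2]
        return json.dumps({"sigma_y": sy, "sigma_z": self.sigma_z})

    @classmethod
    def from_json(cls, s: str) -> "GSMParams":
        d = json.loads(s)
        sy = d["sigma_y"]
        return cls(
            sigma_y1=sy[0],
            sigma_y2=sy[1] if len(sy) > 1 else None,
            sigma_z=d["sigma_z"],
        )


def gsm_moments(params: GSMParams):
    """Per-component (variance, kurtosis).

    Returns scalars for a 1-D model, arrays of length 2 for the shared-scale
    2-D model.  Kurtosis 3 exp(4 sigma_Z^2) is shared by both components.
    """
    kurt = 3.0 * np.exp(4.0 * params.sigma_z**2)
    scale = np.exp(2.0 * params.sigma_z**2)
    if params.ndim == 1:
        return params.sigma_y1**2 * scale, kurt
    var = np.array([params.sigma_y1**2, params.sigma_y2**2]) * scale
    return var, np.array([kurt, kurt])


def gsm_logdensity(x, params: GSMParams) -> np.ndarray:
    """Marginal log-density of a single component, by quadrature over z.

    At sigma_z = 0 this is exactly the N(0, sigma_y1^2) log-density.
    """
    x = np.asarray(x, dtype=float)
    sy = params.sigma_y1
    if params.sigma_z == 0.0:
        return -0.5 * np.log(2 * np.pi * sy**2) - 0.5 * (x / sy) ** 2
    z, logw = _gh(params.sigma_z)
    # log N(x; 0, e^{2z} sy^2) at each node
    var = np.exp(2.0 * z)[None, :] * sy**2
    ll = -0.5 * np.log(2 * np.pi * var) - 0.5 * (x.reshape(-1, 1) ** 2) / var
    out = logsumexp(ll + logw[None, :], axis=1)
    if not np.all(np.isfinite(out)):
        bad = x.reshape(-1)[~np.isfinite(out)]
        raise FloatingPointError(f"non-finite GSM log-density at x={bad[:5]}")
    return out.reshape(x.shape)


def sample_gsm(params: GSMParams, n: int, seed=None, rng=None) -> np.ndarray:
    """Draw n samples; columns are components sharing one scale draw per row."""
    if rng is None:
        rng = np.random.default_rng(seed)
    s = np.exp(rng.normal(scale=params.sigma_z, size=n)) if params.sigma_z > 0 else np.ones(n)
    if params.ndim == 1:
        return (rng.normal(scale=params.sigma_y1, size=n) * s)[:, None]
    y = rng.standard_normal((n, 2)) * np.array([params.sigma_y1, params.sigma_y2])
    return y * s[:, None]


def magnitude_correlation(x1, x2) -> float:
    """Pearson correlation of |x1| and |x2| — the scalar signature of a shared scale."""
    a, b = np.abs(np.asarray(x1, float)), np.abs(np.asarray(x2, float))
    if a.shape != b.shape or a.size < 2:
        raise ValueError("inputs must have equal length >= 2")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero-variance input")
    return float(np.corrcoef(a, b)[0, 1])


def aic(loglik: float, n_params: int) -> float:
    """Akaike information criterion, 2 n_params - 2 loglik."""
    return 2.0 * n_params - 2.0 * loglik


def _loglik_2d(x: np.ndarray, sy: np.ndarray, sz: float) -> float:
    """Observed-data log-likelihood of the shared-scale model (quadrature)."""
    z, logw = _gh(max(sz, 1e-12))
    e2z = np.exp(2.0 * z)  # (J,)
    q = (x**2 / sy**2).sum(axis=1)  # (n,)
    d = x.shape[1]
    ll = (
        -0.5 * q[:, None] / e2z[None, :]
        - d * z[None, :]
        - 0.5 * d * np.log(2 * np.pi)
        - np.log(sy).sum()
    )
    return float(logsumexp(ll + logw[None, :], axis=1).sum())


def fit_gsm_static(
    x: np.ndarray, max_iter: int = 1000, tol: float = 1e-8
) -> GSMParams:
    """EM fit of the shared-scale GSM to an (n, 2) or (n, 1) sample.

    The E-step evaluates posterior expectations of the scalar latent z by
    Gauss-Hermite quadrature; the observed-data log-likelihood is
    non-decreasing across iterations.  Returns ``converged=False`` on the
    result if the relative log-likelihood change never fell below ``tol``.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    n, d = x.shape
    if d not in (1, 2):
        raise ValueError("x must have one or two columns")
    # moment-matched start: kappa = 3 exp(4 sz^2) on pooled standardized data
    pooled = (x / x.std(axis=0)).ravel()
    kurt = np.mean(pooled**4) / np.mean(pooled**2) ** 2
    sz = float(np.clip(np.sqrt(max(np.log(kurt / 3.0), 1e-6) / 4.0), 0.01, 1.5))
    sy = x.std(axis=0) * np.exp(-(sz**2))
    prev = -np.inf
    converged = False
    for _ in range(max_iter):
        z, logw = _gh(max(sz, 1e-12))
        e2z = np.exp(2.0 * z)
        q = (x**2 / sy**2).sum(axis=1)
        logpost = (
            -0.5 * q[:, None] / e2z[None, :] - d * z[None, :] + logw[None, :]
        )
        ll = float(logsumexp(logpost, axis=1).sum()) - 0.5 * d * n * np.log(
            2 * np.pi
        ) - n * float(np.log(sy).sum())
        w = np.exp(logpost - logsumexp(logpost, axis=1, keepdims=True))
        e_inv2 = w @ np.exp(-2.0 * z)  # E[e^{-2z} | x_i]
        e_z2 = w @ z**2
        sy = np.sqrt((e_inv2[:, None] * x**2).mean(axis=0))
        sz = float(np.sqrt(max(e_z2.mean(), 0.0)))
        if np.abs(ll - prev) < tol * (1.0 + np.abs(ll)):
            converged = True
            break
        prev = ll
    if not converged:
        warnings.warn("GSM EM did not converge within max_iter")
    return GSMParams(
        sigma_y1=float(sy[0]),
        sigma_y2=float(sy[1]) if d == 2 else None,
        sigma_z=sz,
        converged=converged,
    )


def posterior_mean_z(x: np.ndarray, params: GSMParams) -> np.ndarray:
    """Posterior mean E[z | x] of the scalar log-scale for each row of x."""
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    d = x.shape[1]
    sy = np.array([params.sigma_y1] if d == 1 else [params.sigma_y1, params.sigma_y2])
    z, logw = _gh(max(params.sigma_z, 1e-12))
    q = (x**2 / sy**2).sum(axis=1)
    logpost = -0.5 * q[:, None] * np.exp(-2.0 * z)[None, :] - d * z[None, :] + logw[None, :]
    w = np.exp(logpost - logsumexp(logpost, axis=1, keepdims=True))
    return w @ z
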
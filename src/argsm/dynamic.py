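"""The dynamic Gaussian scale-mixture (ARGSM) model.

Two velocity components along a point trajectory are modeled as independent
stationary AR(k) Gaussian processes Y_1, Y_2 multiplied element-wise by a
shared positive scale process S = exp(Z), where the scale generator Z is
itself a stationary AR(k) Gaussian process:

    X_{1,t} = Y_{1,t} S_t,   X_{2,t} = Y_{2,t} S_t,   S_t = exp(Z_t).

Conditional on z the observations are Gaussian with covariance
D_s Sigma_Y D_s (D_s diagonal in s), so the complete-data likelihood
factorizes into three stationary AR Gaussian terms.  The marginal
likelihood integrates over the T-dimensional latent z and is intractable;
fitting uses stochastic-approximation EM (SAEM): one Gibbs sweep per
trajectory per iteration samples the latent log-scale from its exact site
conditionals (rejection sampling with a Gaussian envelope), running
averages of the second-moment matrices C_{Y1}, C_{Y2}, C_Z under the
step-size schedule eta_t replace the intractable E-step, and each M-step is
the exact stationary AR maximum-likelihood update from those sufficient
statistics.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from .ar import (
    ARParams,
    ar_exact_mle,
    ar_mle_from_suffstat,
    simulate_ar,
    stationary_cov,
    yule_walker_autocov,
)
from . import gsm as _gsm
from ._gibbs import gibbs_sweep_kernel

__all__ = [
    "ARGSMParams",
    "TrajectoryEnsemble",
    "LatentState",
    "SuffStats",
    "FitDiagnostics",
    "VariantFit",
    "simulate_argsm",
    "gibbs_sweep",
    "saem_fit",
    "fit_variant",
    "normalize_scale",
    "model_precisions",
    "constant_z_loglik",
]


@dataclass(frozen=True)
class ARGSMParams:
    """Full ARGSM parameter set: AR(k) parameters for Y1, Y2 and the scale
    generator Z.  All three processes share one order k."""

    y1: ARParams
    y2: ARParams
    z: ARParams

    def __post_init__(self):
        if not (self.y1.order == self.y2.order == self.z.order):
            raise ValueError("Y1, Y2 and Z must share one AR order")

    @property
    def order(self) -> int:
        return self.y1.order

    def to_json(self, **metadata) -> str:
        d = {
            "y1": json.loads(self.y1.to_json()),
            "y2": json.loads(self.y2.to_json()),
            "z": json.loads(self.z.to_json()),
        }
        if metadata:
            d["metadata"] = metadata
        return json.dumps(d, indent=1)

    @classmethod
    def from_json(cls, s: str) -> "ARGSMParams":
        d = json.loads(s)
        return cls(
            y1=ARParams.from_json(json.dumps(d["y1"])),
            y2=ARParams.from_json(json.dumps(d["y2"])),
            z=ARParams.from_json(json.dumps(d["z"])),
        )


@dataclass
class TrajectoryEnsemble:
    """N trajectories of T velocity frames with two spatial components.

    velocities : (N, T, 2) array, pixels/frame; [..., 0] is horizontal (u),
        [..., 1] vertical (v).
    trajectory_ids : length-N identifiers.
    frame_rate : acquisition rate in Hz (default 60).
    """

    velocities: np.ndarray
    trajectory_ids: np.ndarray | None = None
    frame_rate: float = 60.0

    def __post_init__(self):
        v = np.asarray(self.velocities, dtype=float)
        if v.ndim != 3 or v.shape[2] != 2 or v.shape[0] < 1 or v.shape[1] < 2:
            raise ValueError(f"velocities must be (N>=1, T>=2, 2), got {v.shape}")
        if not np.all(np.isfinite(v)):
            raise ValueError("velocities contain non-finite values")
        self.velocities = v
        if self.trajectory_ids is None:
            self.trajectory_ids = np.arange(v.shape[0])
        else:
            self.trajectory_ids = np.asarray(self.trajectory_ids)
            if len(self.trajectory_ids) != v.shape[0]:
                raise ValueError("trajectory_ids length mismatch")

    @property
    def n_traj(self) -> int:
        return self.velocities.shape[0]

    @property
    def n_frames(self) -> int:
        return self.velocities.shape[1]

    @property
    def u(self) -> np.ndarray:
        return self.velocities[:, :, 0]

    @property
    def v(self) -> np.ndarray:
        return self.velocities[:, :, 1]


@dataclass
class LatentState:
    """Latent log-scale estimates and the normalized velocities they imply."""

    z_hat: np.ndarray  # (N, T)
    s_hat: np.ndarray = None  # exp(z_hat)
    y_hat: np.ndarray = None  # (N, T, 2), velocities / s_hat

    @classmethod
    def from_z(cls, z_hat: np.ndarray, velocities: np.ndarray) -> "LatentState":
        s = np.exp(z_hat)
        return cls(z_hat=z_hat, s_hat=s, y_hat=velocities / s[:, :, None])


@dataclass
class SuffStats:
    """Stochastic-approximation accumulators for the three C matrices."""

    c_y1: np.ndarray
    c_y2: np.ndarray
    c_z: np.ndarray
    iteration: int
    alpha: int
    beta: float
    eta_history: list = field(default_factory=list)

    @staticmethod
    def eta(t: int, alpha: int, beta: float) -> float:
        return 1.0 if t <= alpha else float(t - alpha) ** (-beta)


@dataclass
class FitDiagnostics:
    """Per-iteration traces and sampler statistics from a SAEM run."""

    sd_z_trace: np.ndarray = None
    noise_var_traces: dict = None
    accept_rate: np.ndarray = None
    mh_fallback_rate: np.ndarray = None
    converged: bool = True
    notes: list = field(default_factory=list)


@dataclass
class VariantFit:
    """Result of fitting one model variant to an ensemble."""

    variant: str
    params: object
    latent: LatentState
    loglik: float | None = None
    n_params: int | None = None
    diagnostics: FitDiagnostics | None = None


# ---------------------------------------------------------------------------
# simulation

def simulate_argsm(params: ARGSMParams, N: int, T: int, seed=None):
    """Draw N trajectories of length T; returns (ensemble, ground-truth latent)."""
    rng = np.random.default_rng(seed)
    y1 = simulate_ar(params.y1, T, N, rng=rng)
    y2 = simulate_ar(params.y2, T, N, rng=rng)
    z = simulate_ar(params.z, T, N, rng=rng)
    s = np.exp(z)
    vel = np.stack([y1 * s, y2 * s], axis=2)
    ens = TrajectoryEnsemble(velocities=vel)
    return ens, LatentState.from_z(z, vel)


# ---------------------------------------------------------------------------
# posterior sampling

def model_precisions(params: ARGSMParams, T: int):
    """Precision matrices of the three stationary AR priors, zeroed outside
    the order-k band (an AR(k) process is Markov of order k, so its exact
    stationary precision is banded)."""
    k = params.order
    mats = []
    band = np.abs(np.subtract.outer(np.arange(T), np.arange(T))) <= k
    for p in (params.y1, params.y2, params.z):
        J = np.linalg.inv(stationary_cov(p, T).cov_matrix)
        J = np.where(band, J, 0.0)
        mats.append(np.ascontiguousarray((J + J.T) / 2.0))
    return mats


def gibbs_sweep(x1, x2, z, params: ARGSMParams, rng, max_rej: int = 100):
    """One Gibbs sweep over the sites of a single trajectory's log-scale.

    Each z_t is updated once, in ascending order, from its full conditional
    via rejection sampling (Gaussian envelope) with an independence-MH
    fallback after ``max_rej`` failed proposals.  Returns the updated z and
    a dict of sampler statistics.
    """
    x1 = np.atleast_2d(np.asarray(x1, float))
    x2 = np.atleast_2d(np.asarray(x2, float))
    z = np.atleast_2d(np.asarray(z, float)).copy()
    if not np.all(np.isfinite(z)):
        raise ValueError("current z must be finite")
    T = z.shape[1]
    J1, J2, Jz = model_precisions(params, T)
    y1 = x1 * np.exp(-z)
    y2 = x2 * np.exp(-z)
    if isinstance(rng, np.random.Generator):
        seed = int(rng.integers(2**31))
    else:
        seed = int(rng)
    n_prop, n_acc, n_mh = gibbs_sweep_kernel(
        x1, x2, y1, y2, z, J1, J2, Jz, params.order, max_rej, seed
    )
    stats = {
        "proposals": n_prop,
        "accepted_sites": n_acc,
        "sites": z.size,
        "mh_fallbacks": n_mh,
        "proposal_acceptance": n_acc / max(n_prop, 1),
    }
    return np.squeeze(z), stats


# ---------------------------------------------------------------------------
# SAEM fitting

def _init_params(ensemble: TrajectoryEnsemble, k: int) -> ARGSMParams:
    """AR fits to the raw velocities; scale generator uncorrelated with small
    variance sigma_Z^2 = 0.05^2 (gamma_{Y1,0} + gamma_{Y2,0}) / 2."""
    py1 = ar_exact_mle(ensemble.u, k)
    py2 = ar_exact_mle(ensemble.v, k)
    g0 = (py1.stationary_var + py2.stationary_var) / 2.0
    pz = ARParams(order=k, phi=np.zeros(k), noise_var=0.05**2 * g0)
    return ARGSMParams(y1=py1, y2=py2, z=pz)


def saem_fit(
    ensemble: TrajectoryEnsemble,
    k: int,
    alpha: int = 2500,
    beta: float = 1.0,
    iterations: int | None = None,
    seed=None,
    max_rej: int = 100,
    init: ARGSMParams | None = None,
):
    """Stochastic-approximation EM fit of the full ARGSM model.

    Each iteration runs one Gibbs sweep per trajectory (the chain persists
    across iterations), forms the sample second-moment matrices
    C_Z = sum_n z_n z_n^T and C_{Y_i} = sum_n (x_{i,n} ⊘ s_n)(...)^T, blends
    them into running averages with step eta_t (1 for t <= alpha,
    (t-alpha)^-beta after), and refits all three AR processes by exact MLE
    from the averaged statistics.  The posterior-mean log-scale is
    accumulated with the same schedule.

    Returns (ARGSMParams, LatentState, FitDiagnostics).
    """
    if iterations is None:
        iterations = 2 * alpha
    if iterations <= alpha:
        raise ValueError("iterations must exceed alpha")
    N, T = ensemble.n_traj, ensemble.n_frames
    if not 2 * k < T:
        raise ValueError(f"order k={k} must satisfy k < T/2 with T={T}")

    x1 = np.ascontiguousarray(ensemble.u)
    x2 = np.ascontiguousarray(ensemble.v)
    params = init if init is not None else _init_params(ensemble, k)
    z = np.zeros((N, T))
    y1 = x1.copy()
    y2 = x2.copy()

    sweep_seeds = np.random.SeedSequence(seed).generate_state(iterations)
    c_y1 = c_y2 = c_z = None
    zbar = np.zeros((N, T))
    sd_z = np.empty(iterations)
    nv = {"y1": np.empty(iterations), "y2": np.empty(iterations), "z": np.empty(iterations)}
    acc = np.empty(iterations)
    mh = np.empty(iterations)
    notes = []
    converged = True

    J1, J2, Jz = model_precisions(params, T)
    for t in range(1, iterations + 1):
        n_prop, n_acc, n_mh = gibbs_sweep_kernel(
            x1, x2, y1, y2, z, J1, J2, Jz, k, max_rej, int(sweep_seeds[t - 1] % 2**31)
        )
        acc[t - 1] = n_acc / max(n_prop, 1)
        mh[t - 1] = n_mh / (N * T)

        chat_z = z.T @ z
        chat_y1 = y1.T @ y1
        chat_y2 = y2.T @ y2
        eta = SuffStats.eta(t, alpha, beta)
        if c_z is None:
            c_z, c_y1, c_y2 = chat_z, chat_y1, chat_y2
            zbar = z.copy()
        else:
            c_z += eta * (chat_z - c_z)
            c_y1 += eta * (chat_y1 - c_y1)
            c_y2 += eta * (chat_y2 - c_y2)
            zbar += eta * (z - zbar)
        if not (np.all(np.isfinite(c_z)) and np.all(np.isfinite(c_y1))):
            raise FloatingPointError(f"SAEM diverged at iteration {t}: non-finite C")

        try:
            py1 = ar_mle_from_suffstat(c_y1, N, k, x0=params.y1)
            py2 = ar_mle_from_suffstat(c_y2, N, k, x0=params.y2)
            pz = ar_mle_from_suffstat(c_z, N, k, x0=params.z)
            params = ARGSMParams(y1=py1, y2=py2, z=pz)
            J1, J2, Jz = model_precisions(params, T)
        except (ValueError, np.linalg.LinAlgError) as e:  # keep previous params
            notes.append(f"M-step failure at iteration {t}: {e}")
            converged = False

        sd_z[t - 1] = np.sqrt(params.z.stationary_var)
        nv["y1"][t - 1] = params.y1.noise_var
        nv["y2"][t - 1] = params.y2.noise_var
        nv["z"][t - 1] = params.z.noise_var

    latent = LatentState.from_z(zbar, ensemble.velocities)
    diag = FitDiagnostics(
        sd_z_trace=sd_z,
        noise_var_traces=nv,
        accept_rate=acc,
        mh_fallback_rate=mh,
        converged=converged,
        notes=notes,
    )
    return params, latent, diag


# ---------------------------------------------------------------------------
# restricted variants

def _traj_quadforms(ensemble: TrajectoryEnsemble, py1: ARParams, py2: ARParams):
    """Per-trajectory quadratic forms x^T Sigma^-1 x and log-dets for both
    velocity components under their stationary AR covariances."""
    from scipy import linalg as sla

    T = ensemble.n_frames
    out_q = []
    out_ld = []
    for p, x in ((py1, ensemble.u), (py2, ensemble.v)):
        S = stationary_cov(p, T).cov_matrix
        cho = sla.cho_factor(S, lower=True)
        ld = 2.0 * np.sum(np.log(np.diag(cho[0])))
        sol = sla.cho_solve(cho, x.T)
        out_q.append(np.einsum("tn,tn->n", x.T, sol))
        out_ld.append(ld)
    return out_q[0], out_q[1], out_ld[0], out_ld[1]


def constant_z_loglik(
    ensemble: TrajectoryEnsemble, py1: ARParams, py2: ARParams, sigma_z0: float
) -> float:
    """Marginal log-likelihood of the constant-scale variant (one scalar z
    per trajectory), by Gauss-Hermite quadrature over z."""
    from scipy.special import logsumexp

    T = ensemble.n_frames
    q1, q2, ld1, ld2 = _traj_quadforms(ensemble, py1, py2)
    zn, logw = _gsm._gh(max(sigma_z0, 1e-12))
    e = np.exp(-2.0 * zn)
    ll = (
        -0.5 * (q1 + q2)[:, None] * e[None, :]
        - 2.0 * T * zn[None, :]
        + logw[None, :]
    )
    const = -0.5 * (ld1 + ld2) - T * np.log(2 * np.pi)
    return float(logsumexp(ll, axis=1).sum() + ensemble.n_traj * const)


def _fit_constant_z(
    ensemble: TrajectoryEnsemble, k: int, max_iter: int = 200, tol: float = 1e-8
):
    """EM for the constant-scale variant: latent scalar z_n per trajectory,
    E-step by 1-D Gauss-Hermite quadrature, M-step the exact AR MLE from
    scale-corrected sufficient statistics."""
    from scipy.special import logsumexp

    N, T = ensemble.n_traj, ensemble.n_frames
    x1, x2 = ensemble.u, ensemble.v
    py1 = ar_exact_mle(x1, k)
    py2 = ar_exact_mle(x2, k)
    sz = 0.2
    prev = -np.inf
    ll = -np.inf
    converged = False
    ez = np.zeros(N)
    for _ in range(max_iter):
        q1, q2, ld1, ld2 = _traj_quadforms(ensemble, py1, py2)
        zn, logw = _gsm._gh(max(sz, 1e-12))
        e2 = np.exp(-2.0 * zn)
        lp = -0.5 * (q1 + q2)[:, None] * e2[None, :] - 2.0 * T * zn[None, :] + logw[None, :]
        ll = float(logsumexp(lp, axis=1).sum()) + N * (-0.5 * (ld1 + ld2) - T * np.log(2 * np.pi))
        w = np.exp(lp - logsumexp(lp, axis=1, keepdims=True))
        e_inv2 = w @ e2
        e_z2 = w @ zn**2
        ez = w @ zn
        c1 = (x1 * e_inv2[:, None]).T @ x1
        c2 = (x2 * e_inv2[:, None]).T @ x2
        py1 = ar_mle_from_suffstat(c1, N, k, x0=py1)
        py2 = ar_mle_from_suffstat(c2, N, k, x0=py2)
        sz = float(np.sqrt(max(e_z2.mean(), 1e-12)))
        if np.abs(ll - prev) < tol * (1.0 + np.abs(ll)):
            converged = True
            break
        prev = ll
    z_hat = np.repeat(ez[:, None], T, axis=1)
    latent = LatentState.from_z(z_hat, ensemble.velocities)
    return VariantFit(
        variant="constant_z",
        params={"y1": py1, "y2": py2, "sigma_z0": sz},
        latent=latent,
        loglik=ll,
        n_params=2 * (k + 1) + 1,
        diagnostics=FitDiagnostics(converged=converged),
    )


def fit_variant(ensemble: TrajectoryEnsemble, variant: str, k: int | None = None, **kwargs):
    """Fit one of the model variants used for comparison.

    variant:
        ``"full"``       — the dynamic ARGSM model (delegates to saem_fit).
        ``"ar_only"``    — pure Gaussian AR velocities, scale fixed at 1.
        ``"constant_z"`` — one scalar log-scale per trajectory.
        ``"static"``     — time-independent shared-scale GSM per time point.
    """
    N, T = ensemble.n_traj, ensemble.n_frames
    if variant == "full":
        params, latent, diag = saem_fit(ensemble, k=k, **kwargs)
        return VariantFit(
            variant="full",
            params=params,
            latent=latent,
            loglik=None,
            n_params=3 * (k + 1),
            diagnostics=diag,
        )
    if variant == "ar_only":
        py1 = ar_exact_mle(ensemble.u, k)
        py2 = ar_exact_mle(ensemble.v, k)
        from .ar import ar_exact_loglik

        ll = ar_exact_loglik(ensemble.u, py1) + ar_exact_loglik(ensemble.v, py2)
        latent = LatentState.from_z(np.zeros((N, T)), ensemble.velocities)
        return VariantFit(
            variant="ar_only",
            params={"y1": py1, "y2": py2},
            latent=latent,
            loglik=ll,
            n_params=2 * (k + 1),
        )
    if variant == "constant_z":
        return _fit_constant_z(ensemble, k, **kwargs)
    if variant == "static":
        pooled = ensemble.velocities.reshape(-1, 2)
        gp = _gsm.fit_gsm_static(pooled, **kwargs)
        z_hat = _gsm.posterior_mean_z(pooled, gp).reshape(N, T)
        ll = _gsm._loglik_2d(pooled, np.array([gp.sigma_y1, gp.sigma_y2]), gp.sigma_z)
        latent = LatentState.from_z(z_hat, ensemble.velocities)
        return VariantFit(
            variant="static", params=gp, latent=latent, loglik=ll, n_params=3
        )
    raise ValueError(f"unknown variant {variant!r}")


def normalize_scale(ensemble: TrajectoryEnsemble, latent: LatentState) -> TrajectoryEnsemble:
    """Divide each velocity sample by the estimated scale: y = x ⊘ exp(z_hat)."""
    if latent.z_hat.shape != ensemble.velocities.shape[:2]:
        raise ValueError("latent/ensemble shape mismatch")
    return TrajectoryEnsemble(
        velocities=ensemble.velocities / np.exp(latent.z_hat)[:, :, None],
        trajectory_ids=ensemble.trajectory_ids,
        frame_rate=ensemble.frame_rate,
    )
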
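"""Numba kernel for the Gibbs/rejection sweep over the latent log-scale.

Each site z_t is updated once per sweep from its full conditional

    p(z_t | z_-t, x_1, x_2) ∝ N(z_t; mu_t, tau_t^2) · exp(-2 z_t + g(z_t)),
    g(z) = -a/2 · e^{-2z} - b · e^{-z},

where (mu_t, tau_t^2) come from the banded AR precision of the scale prior,
a >= 0 collects the diagonal likelihood curvature of both velocity
components and b the off-diagonal coupling to the other normalized
velocities.  The log-linear -2 z_t factor is absorbed exactly into the
Gaussian proposal (mean shifted by -2 tau^2); the residual g is bounded
above by g_max = b^2/(2a) for b < 0 (else 0), giving a valid rejection
envelope.  After ``max_rej`` failed proposals one independence
Metropolis-Hastings step with the same proposal keeps the exact posterior
invariant.
"""

import numpy as np
from numba import njit


@njit(cache=True)
def gibbs_sweep_kernel(x1, x2, y1, y2, z, J1, J2, Jz, kb, max_rej, seed):
    """One in-place Gibbs sweep over all trajectories and sites.

    x1, x2, y1, y2, z : (N, T) arrays; y_i = x_i * exp(-z) is kept in sync.
    J1, J2, Jz : (T, T) precision matrices, banded with bandwidth kb.
    Returns (proposals, accepted_sites, mh_fallbacks).
    """
    np.random.seed(seed)
    N, T = z.shape
    n_prop = 0
    n_acc = 0
    n_mh = 0
    for n in range(N):
        for t in range(T):
            lo = max(0, t - kb)
            hi = min(T, t + kb + 1)
            p = Jz[t, t]
            tau2 = 1.0 / p
            s = 0.0
            s1 = 0.0
            s2 = 0.0
            for j in range(lo, hi):
                s += Jz[t, j] * z[n, j]
                s1 += J1[t, j] * y1[n, j]
                s2 += J2[t, j] * y2[n, j]
            s -= p * z[n, t]
            s1 -= J1[t, t] * y1[n, t]
            s2 -= J2[t, t] * y2[n, t]
            mu = -s * tau2
            mt = mu - 2.0 * tau2
            a = J1[t, t] * x1[n, t] ** 2 + J2[t, t] * x2[n, t] ** 2
            b = x1[n, t] * s1 + x2[n, t] * s2
            if a > 0.0 and b < 0.0:
                gmax = b * b / (2.0 * a)
            else:
                gmax = 0.0
            sd = np.sqrt(tau2)
            accepted = False
            znew = z[n, t]
            for _ in range(max_rej):
                n_prop += 1
                zp = mt + sd * np.random.standard_normal()
                u = np.exp(-zp)
                g = -0.5 * a * u * u - b * u
                if np.log(np.random.random()) < g - gmax:
                    znew = zp
                    accepted = True
                    break
            if not accepted:
                n_mh += 1
                n_prop += 1
                zp = mt + sd * np.random.standard_normal()
                u = np.exp(-zp)
                uc = np.exp(-z[n, t])
                g = -0.5 * a * u * u - b * u
                gc = -0.5 * a * uc * uc - b * uc
                if np.log(np.random.random()) < g - gc:
                    znew = zp
                    accepted = True
            if accepted:
                n_acc += 1
                z[n, t] = znew
                es = np.exp(znew)
                y1[n, t] = x1[n, t] / es
                y2[n, t] = x2[n, t] / es
    return n_prop, n_acc, n_mh
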
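"""Shared fixtures.

The parameter-recovery experiment (simulate a known heavy-tailed ARGSM
ensemble, fit it with SAEM, fit the restricted variants) is the most
expensive piece of the suite, so it runs once per session and is shared by
the recovery, normalization, and diagnostics tests.
"""

import numpy as np
import pytest

from argsm.ar import ARParams
from argsm.dynamic import ARGSMParams, fit_variant, saem_fit, simulate_argsm


def recovery_truth() -> ARGSMParams:
    """Ground truth for the recovery experiment: AR velocities with lag-1
    coefficient 0.9 and unit stationary variance, scale generator with lag-1
    coefficient 0.85 and stationary sd 0.5 (pooled kurtosis 3e ≈ 8.15)."""
    return ARGSMParams(
        y1=ARParams(2, np.array([0.9, 0.0]), 0.19),
        y2=ARParams(2, np.array([0.9, 0.0]), 0.19),
        z=ARParams(2, np.array([0.85, 0.0]), 0.25 * (1 - 0.85**2)),
    )


@pytest.fixture(scope="session")
def saem_experiment():
    """Simulate N=2048 x T=64 trajectories from the recovery truth and fit
    the full dynamic model (k=2, alpha=250, 500 iterations)."""
    truth = recovery_truth()
    ensemble, latent_truth = simulate_argsm(truth, N=2048, T=64, seed=11)
    params, latent, diag = saem_fit(
        ensemble, k=2, alpha=250, iterations=500, seed=7
    )
    return {
        "truth": truth,
        "ensemble": ensemble,
        "latent_truth": latent_truth,
        "params": params,
        "latent": latent,
        "diagnostics": diag,
    }


@pytest.fixture(scope="session")
def variant_fits(saem_experiment):
    """Time-independent and constant-scale fits of the same ensemble."""
    ens = saem_experiment["ensemble"]
    return {
        "static": fit_variant(ens, "static", k=2),
        "constant_z": fit_variant(ens, "constant_z", k=2),
        "ar_only": fit_variant(ens, "ar_only", k=2),
    }
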
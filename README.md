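# argsm — dynamic Gaussian scale-mixture modeling of natural motion

Velocities of individual points tracked through natural movies — animals,
wind-blown plants, flowing water — are strongly temporally correlated,
heavy-tailed, and nonlinearly dependent across the horizontal and vertical
components: the two components are uncorrelated, yet the spread of one grows
with the magnitude of the other (the "bow-tie" signature of a shared latent
scale). This package implements the generative model behind those
observations and everything needed to fit and interrogate it, for
researchers in natural scene statistics, visual neuroscience, and tracking.

## The model

A two-dimensional **Gaussian scale-mixture (GSM)** with log-normal scale:

    X₁ = Y₁·S,   X₂ = Y₂·S,   S = exp(Z),
    Y₁ ⊥ Y₂ ⊥ Z all zero-mean Gaussian,

so that var(Xᵢ) = σ²_{Yᵢ}·exp(2σ²_Z) and kurtosis κ = 3·exp(4σ²_Z) — Gaussian
(κ = 3) exactly when σ_Z = 0. Its dynamic extension (the **ARGSM** model)
promotes each variable to a stationary AR(k) Gaussian process:

    X_{i,t} = Y_{i,t} · exp(Z_t),

two independent AR velocity processes sharing one exponentiated AR
log-scale process. The package provides:

* **`argsm.ar`** — stationary AR(k) processes: Yule–Walker autocovariances,
  exact simulation, and exact maximum likelihood under the *stationary*
  Gaussian likelihood (initial segment not conditioned away), from raw data
  or from expected sufficient statistics.
* **`argsm.gsm`** — the static GSM: moments, density by quadrature,
  sampling, magnitude correlation, EM fitting.
* **`argsm.dynamic`** — ARGSM simulation, Gibbs/rejection sampling of the
  latent log-scale posterior, stochastic-approximation EM (SAEM) fitting,
  restricted variants (Gaussian AR only, constant scale per trajectory,
  time-independent GSM), and scale normalization.
* **`argsm.analytics`** — coding-efficiency curves for an additive white
  Gaussian noise channel carrying a GSM signal (capacity, mutual
  information by numerical entropy integration, E = I/C), one-step
  prediction formulas (R²_Y, R²_{X|Z}) and multi-step forecasting with
  scale-aware predictive variance, correlation times, lagged magnitude
  correlations, pooled kurtosis, and AIC comparison across variants.
* **`argsm.trajio`** — trajectory file I/O (CSV/HDF5), preprocessing
  (ensemble mean removal, decorrelating rotation, speed filtering), and
  category presets for synthetic ensembles; plus an `argsm` command-line
  interface (`simulate`, `preprocess`, `fit`, `normalize`, `analyze`,
  `efficiency`).

## Worked example

Simulate a heavy-tailed ensemble with known parameters, fit the full dynamic
model, and normalize away the scale:

```python
import numpy as np
from argsm import (
    ARParams, ARGSMParams, simulate_argsm, saem_fit, normalize_scale,
    pooled_kurtosis, prediction_r2, correlation_time,
)

truth = ARGSMParams(
    y1=ARParams(order=2, phi=[0.9, 0.0], noise_var=0.19),   # unit stationary sd
    y2=ARParams(order=2, phi=[0.9, 0.0], noise_var=0.19),
    z=ARParams(order=2, phi=[0.85, 0.0], noise_var=0.0694), # stationary sd 0.5
)
ensemble, _ = simulate_argsm(truth, N=2048, T=64, seed=0)
print(f"raw pooled kurtosis:        {pooled_kurtosis(ensemble):.2f}")

params, latent, diag = saem_fit(ensemble, k=2, alpha=250, iterations=500, seed=1)
print(f"fitted scale-generator sd:  {np.sqrt(params.z.stationary_var):.3f}   (truth 0.500)")

normalized = normalize_scale(ensemble, latent)
print(f"normalized pooled kurtosis: {pooled_kurtosis(normalized):.2f}   (Gaussian: 3)")

t_vel, _ = correlation_time(params.y1.autocorr(40), dt=1 / 60)
print(f"velocity correlation time:  {t_vel * 1000:.0f} ms to 0.5")

report = prediction_r2(params)
print(f"one-step R2_Y:              {report.r2_y:.3f}")
print(f"one-step R2_X|Z:            {report.r2_x_given_z:.3f}")
```

Output (about a minute on one CPU):

```
raw pooled kurtosis:        7.77
fitted scale-generator sd:  0.500   (truth 0.500)
normalized pooled kurtosis: 3.56   (Gaussian: 3)
velocity correlation time:  110 ms to 0.5
one-step R2_Y:              0.810
one-step R2_X|Z:            0.747
```

The raw velocities are far from Gaussian (kurtosis 7.8 vs 3); SAEM recovers
the scale process (stationary sd 0.500 vs truth 0.500); dividing by the
estimated scale brings the pooled kurtosis back near 3 (this statistic is
dominated by the most extreme trajectories, so it scatters by a few tenths
around 3 across seeds); the fitted velocity process halves its
autocorrelation in about 110 ms at 60 Hz; and one step ahead, 81% of the
underlying Gaussian velocity variance is predictable — dropping only to 75%
for the observed heavy-tailed velocities when the scale history is known.

The same workflow from the shell:

```sh
argsm simulate --preset animal --n 512 --t 64 --seed 0 --out raw.csv
argsm preprocess --input raw.csv --out clean.csv
argsm fit --input clean.csv --order 8 --alpha 500 --seed 0 --variant full --out model.json
argsm normalize --input clean.csv --model model.json --out normalized.csv
argsm analyze --input clean.csv --model model.json --report report.json
argsm efficiency --sigma-z 0.5 --grid -4:6:0.05 --out efficiency.csv
```

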
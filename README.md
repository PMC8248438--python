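# frapkit

Simulation and fast parameter estimation for FRAP (fluorescence recovery
after photobleaching) experiments.

FRAP is a workhorse microscopy technique for measuring diffusion in
liquids, gels, and cells: a high-power laser bleaches the fluorophores in a
region Ω, and the diffusion coefficient is inferred from how quickly
fluorescence recovers there. `frapkit` is for experimentalists and method
developers who analyse confocal FRAP time-lapse data — in particular in
batch, where conventional fitting becomes the bottleneck.

The package provides:

* **A spectral forward model.** Free 2-D diffusion ∂c/∂t = D∇²c on a
  periodic padded pixel lattice, solved exactly per Fourier mode
  (ĉ(ξ,η,t+Δt) = e^{−(ξ²+η²)DΔt} ĉ(ξ,η,t)); bleaching as spatial masking
  (α inside Ω per bleach frame, area-coverage smoothed edges). The
  observable is the recovery curve F(t) = Σ_{x,y} m(x,y) c(x,y,t), the
  ROI-weighted mean over 10 prebleach + 100 postbleach frames.
* **Two interchangeable estimators** of θ = (log₁₀D, c₀, α):
  1. *Least squares*: box-constrained multistart trust-region fits of
     θ̂ = argmin‖F_exp − F(·;θ)‖², the conventional approach;
  2. *Amortized neural regression*: an MLP (8×128 ELU reference
     architecture) trained on simulated curves with an inverse-noise
     (ζ ∝ 1/a) weighted MSE, which afterwards estimates parameters in a
     single forward pass — orders of magnitude faster per curve.
  Either way, the pixel noise variance `a` is recovered from curve-fit
  residuals via â = RSS/(n−3)/Σm².
* **A synthetic-data generator** (log-uniform D over [10⁻¹², 10⁻⁹] m²/s,
  uniform c₀ ∈ [0.5, 1] and α ∈ [0.45, 0.95], log-uniform
  a ∈ [10⁻⁴, 10⁻²]) with image-level or equivalent curve-level noise.
* **Evaluation harnesses**: weighted-MSE benchmarks, MAPE comparison grids
  over (D, α, a), estimator-agreement correlations, timing reports.
* **An experimental-data path**: 16-bit multi-page TIFF stacks →
  rescaling → Gaussian-filtered background subtraction → recovery curve.

## Worked example

Simulate a noisy recovery curve at known parameters and fit it back:

```python
import numpy as np
from frapkit import (default_protocol, SampleParams, d_star_from_si, d_star_to_si,
                     model_recovery_curve, make_roi_weights, curve_noise_sigma2,
                     fit_multistart, FitConfig, estimate_noise_variance)

proto = default_protocol(128)          # reduced desk grid, standard 30 um disk
truth = SampleParams(d_star=d_star_from_si(5e-11, proto.pixel_size_um),
                     c0=0.75, alpha=0.70, a=1e-3)

clean = model_recovery_curve(proto, truth.d_star, truth.c0, truth.alpha)
m = make_roi_weights(proto)
rng = np.random.default_rng(7)
noisy = clean + rng.normal(0, np.sqrt(curve_noise_sigma2(m, truth.a)), clean.shape)

fit = fit_multistart(noisy, proto, FitConfig(n_starts=10), seed=7)
a_hat = estimate_noise_variance(fit, noisy, m)
print(f"D_hat   = {d_star_to_si(fit.d_star, proto.pixel_size_um):.3e} m^2/s")
print(f"c0_hat  = {fit.c0:.4f}")
print(f"alpha   = {fit.alpha:.4f}")
print(f"a_hat   = {a_hat:.2e}")
```

Output:

```
D_hat   = 4.952e-11 m^2/s  (truth 5.000e-11)
c0_hat  = 0.7501              (truth 0.7500)
alpha   = 0.7013              (truth 0.7000)
a_hat   = 7.56e-04            (truth 1.00e-03)
```

The fitted diffusion coefficient lands within 1% of the truth at this
noise level; c₀ and α are recovered to three decimals. (`a_hat` is a
107-degrees-of-freedom residual-variance estimate, so ±25% scatter around
the true 10⁻³ is expected for a single curve.)

The same workflow from the shell:

```bash
frapkit --seed 7 simulate --d-si 5e-11 --c0 0.75 --alpha 0.7 --out-csv curve.csv
frapkit fit-lsq --curves curve.csv --n-side 128 --n-starts 10
frapkit generate --n 4096 --fast --out train.h5       # training data
frapkit train --train-data train.h5 --val-data val.h5 --target d_star --out dstar.npz
frapkit predict --network dstar.npz ... --curves curves.csv
frapkit benchmark --n 256                              # weighted-MSE benchmark
frapkit grid --replicates 64 --plot mape.png           # MAPE comparison grid
frapkit preprocess --stack stack.tif --out curve.csv   # experimental TIFF
```

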
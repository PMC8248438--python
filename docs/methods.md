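# Methods

## The estimation problem

A FRAP (fluorescence recovery after photobleaching) experiment bleaches the
fluorophores inside a region Ω of the field of view with a short high-power
laser pulse and then images the return of fluorescence as unbleached
molecules diffuse back in. The observable analysed here is the *recovery
curve* F(t): the mean intensity inside the bleach region over the
n_pre = 10 prebleach and n_post = 100 postbleach frames, a 110-point vector
under the standard acquisition protocol. Three parameters are estimated
from it:

* `d_star` = log10 D, the diffusion coefficient in pixels²/s (the internal
  unit; `d_star_from_si`/`d_star_to_si` convert to m²/s for a given pixel
  size). Working on the log scale keeps the three-decade prior
  well-conditioned.
* `c0`, the equilibrium prebleach intensity (dimensionless, proportional to
  fluorophore concentration).
* `alpha`, the multiplicative intensity reduction per bleach frame —
  the *relative* decrease, not an amount of bleaching.

The pixel noise variance `a` is not fitted jointly: it is recovered
afterwards from the curve-fit residuals (see below).

## Forward model

The concentration field c(x, y, t) lives on a periodic
(N + 2M) × (N + 2M) pixel lattice (field of view N, padding M = N/2; the
padding pushes the periodic images far enough away over the ~30 s
experiment). Free diffusion ∂c/∂t = D∇²c is solved spectrally: each FFT
mode decays exactly as exp(−(ξ² + η²) D Δt) per frame interval, with
angular wavenumbers ξ_k = 2πk/L on the pixel lattice and D in pixels²/s.
This is exact in time for any step, so one multiply per frame advances the
field. Bleaching is a spatial-domain multiplication by a mask that is
`alpha` inside Ω and 1 outside.

Numerical and protocol conventions (all double precision):

* **Edge smoothing.** Mask and ROI weights use the per-pixel area-coverage
  fraction of Ω, computed by 16×16 supersampling. Deep-interior pixels are
  exactly `alpha` (mask) and equal-weighted (ROI); edge pixels interpolate.
  The ROI weight matrix m(x, y) is coverage normalized to Σm = 1, so
  Σ m·frame is the within-region mean.
* **Clock.** All frames sit on a uniform Δt grid. Each of the n_bleach = 4
  bleach frames is an instantaneous mask multiplication followed by Δt of
  diffusion; the first postbleach frame is therefore observed one Δt after
  the last bleach event — the idealized immediately-post-bleach profile is
  never imaged. Bleach frames are simulated but excluded from the curve
  (10 + 100 = 110 points).
* **Coordinates.** Pixel centers at integer coordinates, origin at the
  field-of-view corner; the bleach region defaults to the field-of-view
  center ((N−1)/2, (N−1)/2), which preserves the four-fold symmetry of a
  centered disk on the sampled lattice.
* **Fast curve evaluation.** The mean-ROI value is an inner product, so by
  Parseval it is evaluated directly from the spectrum; after the last
  bleach event the spectrum decays mode-wise, making the whole postbleach
  curve a sum of exponentials over distinct wavenumber magnitudes.
  `model_recovery_curve` exploits this and agrees with the frame-by-frame
  simulation to ~1e-13 while being ~30× faster — this is what makes
  iterative least squares affordable. `simulate_recovery_curve` remains the
  literal frame-simulation composition.

Deliberately out of scope: immobile fractions, bleaching during imaging,
finite bleach/imaging resolution, reaction–diffusion (binding) kinetics,
3-D diffusion, non-periodic boundaries, intensity-proportional noise.

## Noise model and synthetic data

Image noise is i.i.d. zero-mean Gaussian with constant pixel variance `a`
added to every recorded frame (the intensity-proportional term of the
general affine noise model is assumed zero, the common CLSM working
assumption when bleaching is moderate). Because curve extraction is linear
in the pixels, the induced curve noise is Gaussian with variance a·Σm²;
for the standard 30 µm disk at 0.7598 µm/px, Σm² ≈ 1/1224 (the disk
averages ~1224 pixels).

`generate_dataset` draws (D, c0, alpha, a) from the priors — D log-uniform
over [1e-12, 1e-9] m²/s, c0 uniform [0.5, 1], alpha uniform [0.45, 0.95],
a log-uniform [1e-4, 1e-2] — and produces noisy curves either by the
image-level path (simulate frames, add pixel noise, extract; the default
and the literal acquisition emulation) or by the *fast path* (add curve
noise of variance a·Σm² to the noise-free curve). The two are
distributionally equivalent (tested by Monte-Carlo variance match and a
two-sample KS test) and the fast path is an order of magnitude cheaper, so
benchmarks use it. When a benchmark simulates on a reduced grid, the noise
scale a·Σm² is always taken from the full 256-px reference geometry, so
results remain comparable across grid sizes (the benchmark MSEs are
noise-dominated). Each sample also carries a loss weight ζ ∝ 1/a,
normalized to Σζ = 1 per dataset — estimator variance scales roughly
linearly with `a`, so inverse-noise weighting stops high-noise samples from
dominating training.

Reproducibility: one master seed per dataset with a counter-based substream
per sample index, so enlarging a dataset appends samples without perturbing
existing ones, and train/validation/test sets with different master seeds
are independent.

What the generator does *not* emulate: detector quantization (available
separately via `quantize_sequence`, and shown to add <1% error at
realistic noise), Poisson photon statistics, static background shading
(handled by the preprocessing path instead), sample drift, heterogeneous or
anisotropic diffusion. Tests passing on these data show correctness of the
estimation machinery under the stated model, not robustness to real-world
model violations.

## Least-squares estimation

`fit_multistart` minimizes ‖F_exp − F(·; θ)‖² over θ = (d_star, c0, alpha)
with scipy's trust-region-reflective bounded least squares
(finite-difference Jacobian, ftol = xtol = 1e-8), using all 110 pre- and
postbleach points. Box bounds default to the prior ranges with a small
margin on d_star. The first start is a cheap moment-style heuristic (c0
from the prebleach mean, alpha from the first-postbleach dip, D from the
classic half-recovery-time approximation τ½ ≈ 0.22 r²/D); the remaining
starts are uniform draws, with nested seed streams so the best rss is
non-increasing in the number of starts. Defaults: 10 starts for general
use (30 is advisable for experimental data); the packaged benchmarks use
the heuristic plus one random start (MSE benchmark) or the heuristic alone
(MAPE grid), which empirically converges to the global optimum on these
smooth single-basin problems and keeps the harnesses inside desk-scale CPU
budgets.

The pixel noise variance is estimated afterwards as
â = RSS/(n − 3)/Σm², inverting the curve-noise propagation; a fit is
flagged non-identifiable when the curve's dynamic range is below 3
estimated curve-noise standard deviations (a flat curve constrains D not
at all).

## Neural estimation

The amortized estimator is a fully connected network mapping the raw
110-point curve (no input standardization — its effect is negligible here)
to parameters. Reference architecture: 8 hidden layers × 128 ELU units
(γ = 1), linear output, Glorot-uniform weights, zero biases — 130,179
parameters for the joint 3-output net, 129,921 per single-output net,
389,763 for three merged blocks. Training is plain SGD with momentum 0.99
on the ζ-weighted MSE: the joint loss carries a 1/3 factor (so it is the
mean of the three per-parameter losses); batch gradients are scaled by
n/batch so dataset-normalized ζ need no per-batch renormalization. The
schedule is a linear warmup followed by a stepped decay
(log10 η dropping by 0.25 per step); the checkpoint with the lowest
validation loss is returned, and non-finite losses abort with a
diagnostic. Networks serialize to a flat-array container with a JSON
manifest. `merge_parameter_networks` assembles single-output blocks (or a
joint net serving only one column) into a bundle whose predictions equal
the components' exactly; the packaged final estimator follows the hybrid
pattern — d_star from the joint network, c0 and alpha from separate blocks.

Full-scale training (2^20 samples, ~48,000 epochs over days of CPU) is out
of desk scope by design. The desk-scale reference conditions used in the
test suite are: 8192 training / 1024 validation / 2048 test samples
(fast path, 64-px protocol), a 4×64 single- or 3-output network, batch
256, warmup 1e-4→1e-2 over 30 epochs, decay every 150 epochs, 1500 epochs
(c0 and alpha converge in ~200–250). Under these conditions the d_star
network reaches a weighted validation MSE ~3 orders of magnitude below the
constant-mean predictor, and the inverse-noise weighting measurably beats
uniform weighting on the low-noise (a ≤ 1e-3.5) test stratum — the effect
only emerges once training approaches the noise-limited regime, which is
why the desk schedule is as long as it is. Desk-scale networks do *not*
reach least-squares accuracy (the full-scale result); they trail it by
roughly an order of magnitude in weighted MSE, which is the expected
behaviour at ~1/128 of the data and ~1/30 of the epochs.

## Evaluation harnesses

* `benchmark_lsq`: draw n parameter vectors from the priors, simulate
  noisy curves, fit each, and report per-parameter weighted MSEs
  (Σζ e², ζ ∝ 1/a normalized) plus their joint mean/3. Failed fits are
  excluded and counted, never imputed.
* `mape_grid`: replicate noisy curves on a (D, alpha, a) grid with
  c0 = 0.75 and report the mean absolute percentage error per cell for
  each estimator — for D on the linear SI scale, not log. The default desk
  grid is 3×3×3 spanning the extremes D ∈ {1e-11.5, 1e-10.5, 1e-9.5} m²/s,
  alpha ∈ {0.5, 0.7, 0.9}, a ∈ {1e-4, 1e-3, 1e-2}. Estimator agreement is
  summarized by the Pearson correlation of per-cell MAPE vectors, computed
  on log MAPE by default (damps the large-error cells; the linear-scale
  value is available too).
* `timing_report` measures preprocess / curve-extraction / estimation wall
  clock per estimator, descriptively only — absolute timings are
  hardware-bound and never asserted against published figures beyond the
  structural fact that one forward pass beats iterated simulation fitting.

Desk problem sizes (reduced simulation grid 128 + 2·64 with the standard
30 µm disk, n = 256 benchmark draws, 64 replicates per grid cell) were
chosen so the full acceptance recomputation completes in minutes on one
CPU while keeping the weighted-MSE sampling error well inside the
comparison tolerances; they are the package's defaults, not protocol
constants.

## Experimental-stack preprocessing

16-bit CLSM stacks (prebleach frames then postbleach; bleach frames
unrecorded) are divided by 2¹⁶ − 1 into [0, 1] (an explicit choice — only
"rescale to [0, 1]" is conventional; rescaling by the observed maximum is
available), then background-corrected by subtracting the Gaussian-filtered
(σ = 5 px, truncation 4σ, reflective boundaries — the boundary mode and
truncation are package choices and configurable) mean prebleach frame and
adding the scalar prebleach mean back, preserving absolute intensity.
The identical curve then feeds either estimator. The pipeline is
deterministic: same stack and settings, bit-identical curve.

## Known limitations

* The desk-scale neural estimator is approximation-limited at low noise;
  its MAPE flattens near a few percent where least squares reaches 0.05%.
  Full-scale training removes this gap but is a multi-day computation.
* The forward model's periodic padding makes very fast diffusion
  (d_star near the upper prior edge) weakly sensitive to grid size; since
  fitting uses the same model, estimates remain self-consistent.
* MAPE grids at modest replicate counts have a noticeably noisy maximum
  statistic; the packaged defaults (64 replicates) keep the worst-cell
  estimates stable to ~±13%.
* The preprocessing path assumes static shading; time-varying backgrounds
  and drift are not modelled.
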
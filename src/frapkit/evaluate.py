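"""Benchmarks comparing the least-squares and neural estimators.

Two harnesses mirror the standard way FRAP estimators are assessed:

* :func:`benchmark_lsq` — draw parameters from the priors, simulate noisy
  curves, fit each, and report the 1/a-weighted MSE per parameter (the
  quantity that bounds what a regression network can hope to reach).
* :func:`mape_grid` — mean absolute percentage error of D (linear SI
  scale), c0 and alpha on a fixed (D, alpha, a) grid with c0 = 0.75,
  replicated noise realizations per cell, for any set of estimators.

Desk-scale note: simulations may run on a reduced grid, but curve-level
noise is always scaled by the ROI geometry of the full 256-pixel reference
protocol (MSE is noise-dominated, so this keeps reduced-grid results
comparable to full-scale ones).
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .datagen import ParameterPrior, curve_noise_sigma2, sample_parameters
from .forward import (
    ExperimentProtocol,
    RecoveryCurve,
    d_star_from_si,
    default_protocol,
    make_roi_weights,
    model_recovery_curve,
)
from .lsq import FitConfig, fit_multistart

__all__ = [
    "BenchmarkReport",
    "MapeGrid",
    "mape",
    "benchmark_lsq",
    "mape_grid",
    "reconstruct_curve",
    "timing_report",
    "lsq_estimator",
    "reference_sum_m2",
]

#: Estimator: (curves (n, L), protocol, seed) -> (n, 3) of (d_star, c0, alpha)
Estimator = Callable[[np.ndarray, ExperimentProtocol, int], np.ndarray]


def mape(estimates: np.ndarray, truth: float) -> float:
    """Mean absolute percentage error, in percent, against a scalar truth."""
    if truth == 0:
        raise ValueError("truth must be non-zero for a percentage error")
    estimates = np.asarray(estimates, dtype=float)
    return float(np.mean(np.abs((estimates - truth) / truth)) * 100.0)


def reference_sum_m2(protocol: ExperimentProtocol) -> float:
    """sum(m^2) of the ROI on the full 256-pixel reference grid sharing the
    protocol's bleach geometry — the curve-noise scale per unit a."""
    ref = default_protocol(256)
    ref = ExperimentProtocol(
        n_side=ref.n_side, padding=ref.padding,
        pixel_size_um=protocol.pixel_size_um, dt=protocol.dt,
        n_prebleach=protocol.n_prebleach, n_bleach=protocol.n_bleach,
        n_postbleach=protocol.n_postbleach,
        bleach_region=protocol.bleach_region)
    m = make_roi_weights(ref)
    return float(np.sum(m**2))


@dataclass
class BenchmarkReport:
    """Weighted-MSE benchmark of one estimator over prior draws."""

    estimator: str
    n: int
    seed: int
    mse_d_star: float
    mse_c0: float
    mse_alpha: float
    n_failed: int = 0
    runtime_s: float = 0.0

    @property
    def mse_joint(self) -> float:
        return (self.mse_d_star + self.mse_c0 + self.mse_alpha) / 3.0

    def as_dict(self) -> dict:
        return {"estimator": self.estimator, "n": self.n, "seed": self.seed,
                "mse_joint": self.mse_joint, "mse_d_star": self.mse_d_star,
                "mse_c0": self.mse_c0, "mse_alpha": self.mse_alpha,
                "n_failed": self.n_failed, "runtime_s": self.runtime_s}


def lsq_estimator(fit_config: FitConfig | None = None) -> Estimator:
    """Wrap the multistart least-squares fit as a batch estimator."""
    cfg = fit_config or FitConfig(n_starts=2)

    def run(curves: np.ndarray, protocol: ExperimentProtocol,
            seed: int) -> np.ndarray:
        out = np.full((len(curves), 3), np.nan)
        for i, c in enumerate(np.atleast_2d(curves)):
            try:
                out[i] = fit_multistart(c, protocol, cfg, seed=seed + i).theta_hat
            except RuntimeError:
                pass  # row stays NaN; callers count and exclude failures
        return out

    return run


def benchmark_lsq(protocol: ExperimentProtocol, prior: ParameterPrior,
                  n: int, seed: int,
                  fit_config: FitConfig | None = None,
                  curve_sigma2_per_a: float | None = None) -> BenchmarkReport:
    """Prior draws -> noisy curves -> LSQ fits -> 1/a-weighted MSEs.

    Noise is injected at curve level with variance ``a * sum(m^2)`` of the
    full reference ROI geometry (see module docstring); failed fits are
    excluded from the MSE and counted.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    t0 = time.perf_counter()
    s2a = (reference_sum_m2(protocol) if curve_sigma2_per_a is None
           else curve_sigma2_per_a)
    params = sample_parameters(prior, n, seed, protocol.pixel_size_um)
    cfg = fit_config or FitConfig(n_starts=2)
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(1,)))

    theta_true = np.array([(p.d_star, p.c0, p.alpha) for p in params])
    a = np.array([p.a for p in params])
    theta_hat = np.full((n, 3), np.nan)
    for i, p in enumerate(params):
        clean = model_recovery_curve(protocol, p.d_star, p.c0, p.alpha)
        noisy = clean + rng.normal(0.0, np.sqrt(p.a * s2a), clean.shape)
        try:
            theta_hat[i] = fit_multistart(noisy, protocol, cfg,
                                          seed=seed + i).theta_hat
        except RuntimeError:
            pass

    ok = np.all(np.isfinite(theta_hat), axis=1)
    w = (1.0 / a[ok])
    w /= w.sum()
    err2 = (theta_hat[ok] - theta_true[ok]) ** 2
    mses = w @ err2
    return BenchmarkReport(
        estimator="lsq", n=n, seed=seed,
        mse_d_star=float(mses[0]), mse_c0=float(mses[1]),
        mse_alpha=float(mses[2]), n_failed=int(n - ok.sum()),
        runtime_s=time.perf_counter() - t0)


@dataclass
class GridSpec:
    """Axes of the comparison grid (SI D values; c0 fixed)."""

    d_si: tuple[float, ...] = (10**-11.5, 10**-10.5, 10**-9.5)
    alpha: tuple[float, ...] = (0.5, 0.7, 0.9)
    a: tuple[float, ...] = (1e-4, 1e-3, 1e-2)
    c0: float = 0.75


@dataclass
class MapeGrid:
    """Per-cell MAPE for each estimator over a (D, alpha, a) grid."""

    spec: GridSpec
    replicates: int
    seed: int
    # estimator name -> array (nD, nalpha, na) per parameter
    mape_d: dict[str, np.ndarray] = field(default_factory=dict)
    mape_c0: dict[str, np.ndarray] = field(default_factory=dict)
    mape_alpha: dict[str, np.ndarray] = field(default_factory=dict)

    def correlation(self, est_a: str, est_b: str, param: str = "d",
                    log: bool = True) -> float:
        """Pearson correlation of two estimators' MAPE vectors over the grid
        (on log-MAPE by default, which damps the large-error cells)."""
        grids = {"d": self.mape_d, "c0": self.mape_c0,
                 "alpha": self.mape_alpha}[param]
        va, vb = grids[est_a].ravel(), grids[est_b].ravel()
        if log:
            va, vb = np.log(np.maximum(va, 1e-12)), np.log(np.maximum(vb, 1e-12))
        return float(np.corrcoef(va, vb)[0, 1])


def mape_grid(protocol: ExperimentProtocol, grid: GridSpec, replicates: int,
              estimators: dict[str, Estimator], seed: int,
              curve_sigma2_per_a: float | None = None) -> MapeGrid:
    """Replicate noisy curves per grid cell, run every estimator on the same
    curves, and record the MAPE of D (linear SI scale), c0 and alpha."""
    if not estimators:
        raise ValueError("at least one estimator is required")
    s2a = (reference_sum_m2(protocol) if curve_sigma2_per_a is None
           else curve_sigma2_per_a)
    shape = (len(grid.d_si), len(grid.alpha), len(grid.a))
    out = MapeGrid(spec=grid, replicates=replicates, seed=seed)
    for name in estimators:
        out.mape_d[name] = np.zeros(shape)
        out.mape_c0[name] = np.zeros(shape)
        out.mape_alpha[name] = np.zeros(shape)

    px = protocol.pixel_size_um
    cell = 0
    for i, d_si in enumerate(grid.d_si):
        d_star = d_star_from_si(d_si, px)
        for j, alpha in enumerate(grid.alpha):
            clean = model_recovery_curve(protocol, d_star, grid.c0, alpha)
            for k, a in enumerate(grid.a):
                rng = np.random.default_rng(
                    np.random.SeedSequence(seed, spawn_key=(cell,)))
                curves = clean + rng.normal(
                    0.0, np.sqrt(a * s2a), (replicates, len(clean)))
                for name, est in estimators.items():
                    theta = est(curves, protocol, seed + 7919 * cell)
                    ok = np.all(np.isfinite(theta), axis=1)
                    d_hat_si = np.array(
                        [10.0**t * (px * 1e-6) ** 2 for t in theta[ok, 0]])
                    out.mape_d[name][i, j, k] = mape(d_hat_si, d_si)
                    out.mape_c0[name][i, j, k] = mape(theta[ok, 1], grid.c0)
                    out.mape_alpha[name][i, j, k] = mape(theta[ok, 2], alpha)
                cell += 1
    return out


def reconstruct_curve(theta: np.ndarray, protocol: ExperimentProtocol
                      ) -> RecoveryCurve:
    """Model recovery curve at an estimated theta (for residual-based noise
    estimation and fit overlays)."""
    d_star, c0, alpha = np.asarray(theta, dtype=float)
    values = model_recovery_curve(protocol, d_star, c0, alpha)
    times = np.concatenate([
        np.arange(protocol.n_prebleach) * protocol.dt,
        (protocol.n_prebleach + protocol.n_bleach
         + np.arange(protocol.n_postbleach)) * protocol.dt,
    ])
    return RecoveryCurve(values=values, times=times, noise_flag=False)


def timing_report(protocol: ExperimentProtocol, n: int,
                  estimators: dict[str, Estimator], seed: int = 0) -> list[dict]:
    """Mean wall-clock of preprocessing, curve extraction and estimation
    over n simulated stacks, per estimator.  Purely descriptive (hardware
    dependent); never compared against published figures."""
    from .datagen import add_image_noise
    from .experiment import background_subtract
    from .forward import extract_recovery_curve, simulate_sequence

    if n == 0:
        return []
    prior = ParameterPrior()
    params = sample_parameters(prior, n, seed, protocol.pixel_size_um)
    m = make_roi_weights(protocol)
    rows = []
    pre_t = np.zeros(n)
    ext_t = np.zeros(n)
    est_t = {name: np.zeros(n) for name in estimators}
    rng = np.random.default_rng(seed)
    for i, p in enumerate(params):
        seq = add_image_noise(simulate_sequence(protocol, p), p.a, rng)
        t0 = time.perf_counter()
        seq = background_subtract(seq, protocol)
        pre_t[i] = time.perf_counter() - t0
        t0 = time.perf_counter()
        curve = extract_recovery_curve(seq, m, noise_flag=True)
        ext_t[i] = time.perf_counter() - t0
        for name, est in estimators.items():
            t0 = time.perf_counter()
            est(curve.values[None, :], protocol, seed + i)
            est_t[name][i] = time.perf_counter() - t0
    for name in estimators:
        rows.append({
            "estimator": name,
            "preprocess_s": float(pre_t.mean()),
            "extraction_s": float(ext_t.mean()),
            "estimation_s": float(est_t[name].mean()),
            "total_s": float(pre_t.mean() + ext_t.mean() + est_t[name].mean()),
            "n": n,
        })
    return rows
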
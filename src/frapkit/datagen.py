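"""Noise injection, parameter priors and synthetic dataset generation.

Image noise is i.i.d. zero-mean Gaussian with constant pixel variance ``a``
(no intensity-proportional component), added to every recorded frame.
Training/validation/test sets are drawn from independent priors over
(D, c0, alpha, a); per-sample loss weights ``zeta ~ 1/a`` compensate for the
roughly linear scaling of estimator variance with the data noise, so that
low-noise samples are not drowned out during training.

Reproducibility: each dataset has one master seed and a counter-based
substream per sample index, so enlarging ``n`` never perturbs the samples
already generated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .forward import (
    ExperimentProtocol,
    ImageSequence,
    RecoveryCurve,
    SampleParams,
    d_star_from_si,
    extract_recovery_curve,
    make_roi_weights,
    model_recovery_curve,
    simulate_sequence,
)

__all__ = [
    "ParameterPrior",
    "TrainingDataset",
    "sample_parameters",
    "add_image_noise",
    "curve_noise_sigma2",
    "generate_dataset",
    "save_dataset_hdf5",
    "load_dataset_hdf5",
    "save_dataset_csv",
]


@dataclass(frozen=True)
class ParameterPrior:
    """Sampling distributions of the generating parameters.

    D and a are log-uniform (each spans orders of magnitude and small and
    large values matter equally); c0 and alpha are uniform.
    """

    d_si_range: tuple[float, float] = (1e-12, 1e-9)   # m^2/s, log-uniform
    c0_range: tuple[float, float] = (0.5, 1.0)        # uniform
    alpha_range: tuple[float, float] = (0.45, 0.95)   # uniform
    a_range: tuple[float, float] = (1e-4, 1e-2)       # log-uniform

    def __post_init__(self) -> None:
        for name, (lo, hi) in [("d_si_range", self.d_si_range),
                               ("c0_range", self.c0_range),
                               ("alpha_range", self.alpha_range),
                               ("a_range", self.a_range)]:
            if not (lo <= hi):
                raise ValueError(f"{name}: lower bound exceeds upper bound")
        if self.d_si_range[0] <= 0 or self.a_range[0] < 0:
            raise ValueError("log-uniform ranges require positive bounds")

    def d_star_range(self, pixel_size_um: float) -> tuple[float, float]:
        return (d_star_from_si(self.d_si_range[0], pixel_size_um),
                d_star_from_si(self.d_si_range[1], pixel_size_um))


@dataclass
class TrainingDataset:
    """Aligned curves, targets (d_star, c0, alpha), noise variances and
    normalized 1/a loss weights."""

    inputs: np.ndarray        # (n, curve_length)
    targets: np.ndarray       # (n, 3)
    noise_vars: np.ndarray    # (n,)
    weights: np.ndarray       # (n,), sums to 1
    seed: int
    protocol: ExperimentProtocol
    prior: ParameterPrior = field(default_factory=ParameterPrior)

    def __len__(self) -> int:
        return len(self.inputs)


def _substream(seed: int, index: int) -> np.random.Generator:
    """Counter-based per-sample stream: stable under changes of n."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(index,)))


def sample_parameters(prior: ParameterPrior, n: int, seed: int,
                      pixel_size_um: float = 0.7598) -> list[SampleParams]:
    """Draw n parameter vectors from the prior (reproducible given seed)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    out = []
    log_d = np.log10(prior.d_si_range)
    log_a = np.log10(np.maximum(prior.a_range, 1e-300))
    for i in range(n):
        rng = _substream(seed, i)
        u = rng.random(4)
        d_si = 10.0 ** (log_d[0] + u[0] * (log_d[1] - log_d[0]))
        c0 = prior.c0_range[0] + u[1] * (prior.c0_range[1] - prior.c0_range[0])
        alpha = (prior.alpha_range[0]
                 + u[2] * (prior.alpha_range[1] - prior.alpha_range[0]))
        if prior.a_range[0] == 0 and prior.a_range[1] == 0:
            a = 0.0
        else:
            a = 10.0 ** (log_a[0] + u[3] * (log_a[1] - log_a[0]))
        out.append(SampleParams(d_star=d_star_from_si(d_si, pixel_size_um),
                                c0=c0, alpha=alpha, a=a))
    return out


def add_image_noise(seq: ImageSequence, a: float,
                    rng: np.random.Generator) -> ImageSequence:
    """Add i.i.d. N(0, a) noise to every pixel of every recorded frame."""
    if a < 0:
        raise ValueError("noise variance a must be non-negative")
    if a == 0:
        return ImageSequence(prebleach=seq.prebleach.copy(),
                             postbleach=seq.postbleach.copy(),
                             bleach=None if seq.bleach is None else seq.bleach.copy(),
                             dt=seq.dt, n_bleach_gap=seq.n_bleach_gap)
    sd = np.sqrt(a)
    return ImageSequence(
        prebleach=seq.prebleach + rng.normal(0.0, sd, seq.prebleach.shape),
        postbleach=seq.postbleach + rng.normal(0.0, sd, seq.postbleach.shape),
        bleach=(None if seq.bleach is None
                else seq.bleach + rng.normal(0.0, sd, seq.bleach.shape)),
        dt=seq.dt, n_bleach_gap=seq.n_bleach_gap,
    )


def curve_noise_sigma2(m: np.ndarray, a: float) -> float:
    """Variance of the mean-ROI curve value induced by pixel noise of
    variance a: Var(sum m*eps) = a * sum(m^2)."""
    return float(a * np.sum(np.asarray(m) ** 2))


def generate_dataset(protocol: ExperimentProtocol, prior: ParameterPrior,
                     n: int, seed: int, fast_path: bool = False,
                     curve_sigma2_per_a: float | None = None) -> TrainingDataset:
    """Generate n (noisy curve, parameter) pairs.

    Default path is image-level: simulate the frame sequence, add pixel
    noise, extract the ROI curve.  The fast path adds Gaussian noise of the
    propagated variance ``a * sum(m^2)`` directly to the noise-free curve —
    statistically equivalent (the extraction is linear in the pixels) and an
    order of magnitude cheaper.  ``curve_sigma2_per_a`` overrides sum(m^2)
    on the fast path, e.g. to match the ROI geometry of a larger reference
    grid when simulating on a reduced one.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    params = sample_parameters(prior, n, seed, protocol.pixel_size_um)
    m = make_roi_weights(protocol)
    sum_m2 = float(np.sum(m**2)) if curve_sigma2_per_a is None else curve_sigma2_per_a

    inputs = np.empty((n, protocol.curve_length))
    targets = np.empty((n, 3))
    noise_vars = np.empty(n)
    for i, p in enumerate(params):
        rng = _substream(seed, i)
        rng.random(4)  # skip the draws consumed by the parameter sample
        if fast_path:
            clean = model_recovery_curve(protocol, p.d_star, p.c0, p.alpha)
            sd = np.sqrt(p.a * sum_m2)
            inputs[i] = clean + rng.normal(0.0, sd, clean.shape)
        else:
            seq = simulate_sequence(protocol, p)
            noisy = add_image_noise(seq, p.a, rng)
            inputs[i] = extract_recovery_curve(noisy, m, noise_flag=True).values
        targets[i] = (p.d_star, p.c0, p.alpha)
        noise_vars[i] = p.a

    with np.errstate(divide="ignore"):
        w = 1.0 / noise_vars
    if not np.all(np.isfinite(w)):
        w = np.ones(n)  # zero-noise datasets: uniform weights
    weights = w / w.sum()
    return TrainingDataset(inputs=inputs, targets=targets,
                           noise_vars=noise_vars, weights=weights,
                           seed=seed, protocol=protocol, prior=prior)


def dataset_curve(ds: TrainingDataset, i: int) -> RecoveryCurve:
    """Row i of a dataset as a RecoveryCurve (times from the protocol)."""
    p = ds.protocol
    times = np.concatenate([
        np.arange(p.n_prebleach) * p.dt,
        (p.n_prebleach + p.n_bleach + np.arange(p.n_postbleach)) * p.dt,
    ])
    return RecoveryCurve(values=ds.inputs[i].copy(), times=times, noise_flag=True)


# ---------------------------------------------------------------------------
# storage
# ---------------------------------------------------------------------------

def save_dataset_hdf5(path: str, ds: TrainingDataset) -> None:
    import h5py

    with h5py.File(path, "w") as fh:
        fh.create_dataset("inputs", data=ds.inputs)
        fh.create_dataset("targets", data=ds.targets)
        fh.create_dataset("noise_vars", data=ds.noise_vars)
        fh.create_dataset("weights", data=ds.weights)
        prov = fh.create_group("provenance")
        prov.attrs["seed"] = ds.seed
        for k in ("n_side", "padding", "pixel_size_um", "dt",
                  "n_prebleach", "n_bleach", "n_postbleach"):
            prov.attrs[k] = getattr(ds.protocol, k)
        reg = ds.protocol.bleach_region
        prov.attrs["region_shape"] = reg.shape
        if reg.radius is not None:
            prov.attrs["region_radius"] = reg.radius
        if reg.half_size is not None:
            prov.attrs["region_half_size"] = reg.half_size
        if reg.center is not None:
            prov.attrs["region_center"] = reg.center
        for k, v in [("d_si_range", ds.prior.d_si_range),
                     ("c0_range", ds.prior.c0_range),
                     ("alpha_range", ds.prior.alpha_range),
                     ("a_range", ds.prior.a_range)]:
            prov.attrs[k] = v


def load_dataset_hdf5(path: str) -> TrainingDataset:
    import h5py

    from .forward import BleachRegion

    with h5py.File(path, "r") as fh:
        prov = fh["provenance"].attrs
        region = BleachRegion(
            shape=str(prov["region_shape"]),
            radius=float(prov["region_radius"]) if "region_radius" in prov else None,
            half_size=(tuple(prov["region_half_size"])
                       if "region_half_size" in prov else None),
            center=tuple(prov["region_center"]) if "region_center" in prov else None,
        )
        protocol = ExperimentProtocol(
            n_side=int(prov["n_side"]), padding=int(prov["padding"]),
            pixel_size_um=float(prov["pixel_size_um"]), dt=float(prov["dt"]),
            n_prebleach=int(prov["n_prebleach"]), n_bleach=int(prov["n_bleach"]),
            n_postbleach=int(prov["n_postbleach"]), bleach_region=region,
        )
        prior = ParameterPrior(
            d_si_range=tuple(prov["d_si_range"]),
            c0_range=tuple(prov["c0_range"]),
            alpha_range=tuple(prov["alpha_range"]),
            a_range=tuple(prov["a_range"]),
        )
        return TrainingDataset(
            inputs=fh["inputs"][...], targets=fh["targets"][...],
            noise_vars=fh["noise_vars"][...], weights=fh["weights"][...],
            seed=int(prov["seed"]), protocol=protocol, prior=prior,
        )


def save_dataset_csv(path: str, ds: TrainingDataset) -> None:
    """One row per sample: curve values, then d_star, c0, alpha, a."""
    import pandas as pd

    ncol = ds.inputs.shape[1]
    df = pd.DataFrame(ds.inputs, columns=[f"f{j}" for j in range(ncol)])
    df[["d_star", "c0", "alpha"]] = ds.targets
    df["a"] = ds.noise_vars
    df.to_csv(path, index=False)
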
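"""Experimental CLSM stack handling: reading, rescaling, background
subtraction and recovery-curve extraction.

Confocal FRAP acquisitions arrive as 16-bit multi-page TIFF stacks
(prebleach frames first, then postbleach; bleach frames are normally not
recorded).  Preprocessing: rescale the integer codes to [0, 1], subtract a
Gaussian-blurred (sigma = 5 px) average prebleach frame from every frame to
remove static shading, add the scalar prebleach mean back, then extract the
mean-ROI recovery curve.  The identical curve feeds either estimator.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import gaussian_filter

from .forward import (
    ExperimentProtocol,
    ImageSequence,
    RecoveryCurve,
    extract_recovery_curve,
    make_roi_weights,
)

__all__ = [
    "read_stack_tiff",
    "rescale_to_unit",
    "background_subtract",
    "preprocess_to_curve",
    "quantize_sequence",
]

BACKGROUND_SIGMA_PX = 5.0


def read_stack_tiff(path: str, protocol: ExperimentProtocol) -> ImageSequence:
    """Read a multi-page TIFF as (prebleach, postbleach) per the protocol's
    frame counts.  Bleach frames are assumed absent from the recording."""
    import tifffile

    frames = tifffile.imread(path)
    frames = np.atleast_3d(frames)
    if frames.ndim == 2:
        frames = frames[None]
    expected = protocol.n_prebleach + protocol.n_postbleach
    if len(frames) != expected:
        raise ValueError(
            f"stack has {len(frames)} frames, protocol expects {expected} "
            "(prebleach + postbleach; bleach frames not recorded)")
    if frames.shape[1:] != (protocol.n_side, protocol.n_side):
        raise ValueError("frame size does not match the protocol")
    return ImageSequence(
        prebleach=frames[:protocol.n_prebleach].astype(float),
        postbleach=frames[protocol.n_prebleach:].astype(float),
        bleach=None, dt=protocol.dt, n_bleach_gap=protocol.n_bleach)


def rescale_to_unit(seq: ImageSequence, bit_depth: int = 16,
                    by_max: bool = False) -> ImageSequence:
    """Divide integer intensities by 2**bit_depth - 1 (or by the actual
    maximum code value with ``by_max=True``), mapping into [0, 1]."""
    if by_max:
        divisor = max(float(seq.prebleach.max()), float(seq.postbleach.max()), 1.0)
    else:
        divisor = float(2**bit_depth - 1)
    hi = max(float(seq.prebleach.max()), float(seq.postbleach.max()))
    if hi > divisor:
        import warnings

        warnings.warn(
            f"intensities exceed the {bit_depth}-bit code range; "
            "pass by_max=True to rescale by the observed maximum",
            stacklevel=2)
    return ImageSequence(prebleach=seq.prebleach / divisor,
                         postbleach=seq.postbleach / divisor,
                         bleach=None if seq.bleach is None else seq.bleach / divisor,
                         dt=seq.dt, n_bleach_gap=seq.n_bleach_gap)


def background_subtract(seq: ImageSequence, protocol: ExperimentProtocol,
                        sigma: float = BACKGROUND_SIGMA_PX) -> ImageSequence:
    """Remove static shading: subtract the Gaussian-filtered mean prebleach
    frame from every frame, then add the scalar mean prebleach intensity
    back (so absolute intensity levels are preserved).

    Filter: truncation 4 sigma, reflective boundaries.
    """
    if len(seq.prebleach) < 1:
        raise ValueError("background subtraction requires >= 1 prebleach frame")
    mean_pre = seq.prebleach.mean(axis=0)
    background = gaussian_filter(mean_pre, sigma=sigma, mode="reflect",
                                 truncate=4.0)
    level = float(mean_pre.mean())
    corr = background - level   # subtracting this centers frames on `level`
    return ImageSequence(
        prebleach=seq.prebleach - corr,
        postbleach=seq.postbleach - corr,
        bleach=None if seq.bleach is None else seq.bleach - corr,
        dt=seq.dt, n_bleach_gap=seq.n_bleach_gap)


def preprocess_to_curve(seq: ImageSequence, protocol: ExperimentProtocol,
                        rescale: bool = True,
                        bit_depth: int = 16) -> RecoveryCurve:
    """Full experimental pipeline: rescale -> background subtract -> ROI
    extraction.  Deterministic: same stack and settings, bit-identical curve."""
    if rescale:
        seq = rescale_to_unit(seq, bit_depth=bit_depth)
    seq = background_subtract(seq, protocol)
    m = make_roi_weights(protocol)
    return extract_recovery_curve(seq, m, noise_flag=True)


def quantize_sequence(seq: ImageSequence, bit_depth: int = 16) -> ImageSequence:
    """Quantize a unit-range sequence to integer codes, emulating detector
    digitization (used to build synthetic experimental fixtures)."""
    scale = float(2**bit_depth - 1)

    def q(frames: np.ndarray) -> np.ndarray:
        return np.clip(np.rint(frames * scale), 0, scale)

    return ImageSequence(prebleach=q(seq.prebleach),
                         postbleach=q(seq.postbleach),
                         bleach=None if seq.bleach is None else q(seq.bleach),
                         dt=seq.dt, n_bleach_gap=seq.n_bleach_gap)
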
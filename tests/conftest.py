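"""Shared fixtures.

Protocols come in two desk sizes: a 64-px field of view with a 10-px bleach
disk for cheap unit tests, and a 128-px field of view with the standard
30 um bleach disk for benchmark-style tests.  Expensive artifacts (datasets,
trained networks) are session-scoped and reused; the training conditions are
frozen here so every dependent test sees the same estimator.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from frapkit import (
    BleachRegion,
    EstimatorBundle,
    ExperimentProtocol,
    ParameterPrior,
    default_protocol,
    generate_dataset,
)
from frapkit.nn import MLPSpec, TrainConfig, build_network, train

#: desk-scale SGD schedule for the d_star task (the hardest target): long
#: enough for the stepped decay to reach the noise-limited regime at n=8192
DESK_TRAIN_CONFIG = TrainConfig(
    batch_size=256, momentum=0.99, lr_start=1e-4, lr_peak=1e-2,
    warmup_epochs=30, epochs_per_step=150, epochs=1500, seed=0,
    joint_loss=False)

DESK_SPEC = MLPSpec(input_dim=110, hidden_layers=4, hidden_width=64,
                    output_dim=1)


@pytest.fixture(scope="session")
def proto64() -> ExperimentProtocol:
    """Tiny protocol: 64-px FOV, 10-px bleach disk, standard frame counts."""
    return ExperimentProtocol(
        n_side=64, padding=32,
        bleach_region=BleachRegion(shape="circle", radius=10.0))


@pytest.fixture(scope="session")
def proto128() -> ExperimentProtocol:
    """Reduced-grid protocol sharing the standard 30 um bleach geometry."""
    return default_protocol(128)


@pytest.fixture(scope="session")
def prior() -> ParameterPrior:
    return ParameterPrior()


@pytest.fixture(scope="session")
def desk_datasets(proto64, prior):
    """Fast-path train/val/test datasets at desk scale (seeded, distinct)."""
    train_ds = generate_dataset(proto64, prior, 8192, seed=101, fast_path=True)
    val_ds = generate_dataset(proto64, prior, 1024, seed=202, fast_path=True)
    test_ds = generate_dataset(proto64, prior, 2048, seed=303, fast_path=True)
    return train_ds, val_ds, test_ds


@pytest.fixture(scope="session")
def trained_d_star_net(desk_datasets):
    """Desk-scale single-output d_star regression net + training history."""
    train_ds, val_ds, _ = desk_datasets
    net = build_network(DESK_SPEC, seed=0)
    best, hist = train(net, train_ds, val_ds, DESK_TRAIN_CONFIG,
                       target_cols=[0])
    return best, hist


@pytest.fixture(scope="session")
def trained_joint_net(desk_datasets):
    """Desk-scale joint (3-output) network trained with the 1/3-weighted
    joint loss."""
    train_ds, val_ds, _ = desk_datasets
    spec = dataclasses.replace(DESK_SPEC, output_dim=3)
    cfg = dataclasses.replace(DESK_TRAIN_CONFIG, joint_loss=True)
    net = build_network(spec, seed=0)
    best, hist = train(net, train_ds, val_ds, cfg)
    return best, hist


@pytest.fixture(scope="session")
def trained_bundle(desk_datasets, trained_joint_net) -> EstimatorBundle:
    """The final hybrid estimator: d_star column served by the joint network,
    c0 and alpha by separate single-output blocks (c0 and alpha converge in
    far fewer epochs than d_star)."""
    train_ds, val_ds, _ = desk_datasets
    joint, _ = trained_joint_net
    blocks = [joint]
    for col, epochs, seed in [(1, 200, 1), (2, 250, 2)]:
        cfg = dataclasses.replace(DESK_TRAIN_CONFIG, epochs=epochs, seed=seed)
        net = build_network(DESK_SPEC, seed=seed)
        best, _ = train(net, train_ds, val_ds, cfg, target_cols=[col])
        blocks.append(best)
    return EstimatorBundle(
        blocks=blocks, block_outputs=[[0], [1], [2]],
        provenance=["joint/d_star", "separate/c0", "separate/alpha"])


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20260920)
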
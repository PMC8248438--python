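"""Amortized neural-network regression from recovery curves to parameters.

A fully connected network maps the 110-point recovery curve directly to
(d_star, c0, alpha) — either one joint 3-output network or three
single-output networks merged into a block-parallel bundle.  Training
minimizes the 1/a-weighted mean squared error with plain SGD + momentum
(warmup then stepped learning-rate decay); the checkpoint with the lowest
validation loss is kept.  Once trained, estimation is a single deterministic
forward pass, orders of magnitude faster than iterative least squares.

The implementation is self-contained numpy: dense layers with ELU
activations, Glorot-uniform weight init, zero bias init, and reverse-mode
gradients written out by hand (the model class is small enough that a
framework would be mostly ceremony).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MLPSpec",
    "TrainConfig",
    "MLP",
    "EstimatorBundle",
    "TrainingDivergedError",
    "elu",
    "build_network",
    "count_parameters",
    "weighted_mse_loss",
    "train",
    "merge_parameter_networks",
    "predict",
    "save_network",
    "load_network",
]


def elu(x: np.ndarray, gamma: float = 1.0) -> np.ndarray:
    """Exponential linear unit: x for x > 0, gamma*(exp(x) - 1) otherwise."""
    x = np.asarray(x, dtype=float)
    return np.where(x > 0, x, gamma * np.expm1(np.minimum(x, 0.0)))


def _elu_grad(x: np.ndarray, gamma: float = 1.0) -> np.ndarray:
    return np.where(x > 0, 1.0, gamma * np.exp(np.minimum(x, 0.0)))


@dataclass(frozen=True)
class MLPSpec:
    """Architecture of one fully connected block.

    The reference architecture is 110 inputs, 8 hidden layers of 128 ELU
    units, and a linear output layer (3 outputs joint, 1 per-parameter).
    """

    input_dim: int = 110
    hidden_layers: int = 8
    hidden_width: int = 128
    output_dim: int = 3
    gamma: float = 1.0  # ELU scale

    def __post_init__(self) -> None:
        if min(self.input_dim, self.hidden_width, self.output_dim) < 1:
            raise ValueError("all dimensions must be >= 1")
        if self.hidden_layers < 0:
            raise ValueError("hidden_layers must be >= 0")

    def layer_dims(self) -> list[tuple[int, int]]:
        dims = [self.input_dim] + [self.hidden_width] * self.hidden_layers \
            + [self.output_dim]
        return list(zip(dims[:-1], dims[1:]))


@dataclass(frozen=True)
class TrainConfig:
    """SGD schedule. Reference settings: batch 1024, momentum 0.99, linear
    warmup 1e-3 -> 1e-1 over 50 epochs, then stepped decay
    log10(lr) = -1, -1.25, -1.5, ... with 8000 epochs per step.  Desk-scale
    runs shrink epochs/epochs_per_step (and often the peak rate)."""

    batch_size: int = 1024
    momentum: float = 0.99
    lr_start: float = 1e-3
    lr_peak: float = 1e-1
    warmup_epochs: int = 50
    epochs_per_step: int = 8000
    decay_per_step: float = 0.25   # log10 decrement of lr per step
    epochs: int = 2000
    seed: int = 0
    joint_loss: bool = True        # include the 1/3 factor (3-target nets)

    def learning_rate(self, epoch: int) -> float:
        if epoch < self.warmup_epochs:
            frac = epoch / max(self.warmup_epochs - 1, 1)
            return self.lr_start + frac * (self.lr_peak - self.lr_start)
        step = (epoch - self.warmup_epochs) // self.epochs_per_step
        return self.lr_peak * 10.0 ** (-self.decay_per_step * step)


class TrainingDivergedError(RuntimeError):
    def __init__(self, epoch: int, loss: float, lr: float):
        super().__init__(
            f"training loss became non-finite at epoch {epoch} "
            f"(loss={loss}, learning rate={lr}); lower the peak learning rate")
        self.epoch = epoch
        self.loss = loss
        self.lr = lr


class MLP:
    """Fully connected chain h_l = W_l g(h_{l-1}) + b_l with ELU hidden
    activations and identity output."""

    def __init__(self, spec: MLPSpec, weights: list[np.ndarray],
                 biases: list[np.ndarray]):
        self.spec = spec
        self.weights = weights
        self.biases = biases

    def forward(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        if x.shape[1] != self.spec.input_dim:
            raise ValueError(
                f"input dim {x.shape[1]} != network input {self.spec.input_dim}")
        h = x
        last = len(self.weights) - 1
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            h = h @ w + b
            if i < last:
                h = elu(h, self.spec.gamma)
        return h

    __call__ = forward

    def forward_with_cache(self, x: np.ndarray):
        """Forward pass keeping pre-activations for backprop."""
        acts = [x]          # post-activation inputs to each layer
        pre = []            # pre-activation h of each layer
        h = x
        last = len(self.weights) - 1
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            z = h @ w + b
            pre.append(z)
            h = elu(z, self.spec.gamma) if i < last else z
            if i < last:
                acts.append(h)
        return h, acts, pre

    def gradients(self, x: np.ndarray, grad_out: np.ndarray,
                  acts: list[np.ndarray], pre: list[np.ndarray]):
        """Backprop dLoss/d(weights, biases) given dLoss/d(output)."""
        gw = [None] * len(self.weights)
        gb = [None] * len(self.biases)
        delta = grad_out
        for i in range(len(self.weights) - 1, -1, -1):
            gw[i] = acts[i].T @ delta
            gb[i] = delta.sum(axis=0)
            if i > 0:
                delta = (delta @ self.weights[i].T) * _elu_grad(pre[i - 1],
                                                                self.spec.gamma)
        return gw, gb

    def copy(self) -> "MLP":
        return MLP(self.spec, [w.copy() for w in self.weights],
                   [b.copy() for b in self.biases])


def build_network(spec: MLPSpec, seed: int = 0) -> MLP:
    """Glorot-uniform weights (limit sqrt(6/(fan_in+fan_out))), zero biases."""
    rng = np.random.default_rng(seed)
    weights, biases = [], []
    for fan_in, fan_out in spec.layer_dims():
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        weights.append(rng.uniform(-limit, limit, size=(fan_in, fan_out)))
        biases.append(np.zeros(fan_out))
    return MLP(spec, weights, biases)


def count_parameters(net: "MLP | EstimatorBundle") -> int:
    """Exact number of trainable scalars (weights + biases)."""
    if isinstance(net, EstimatorBundle):
        return sum(count_parameters(b) for b in net.blocks)
    return int(sum(w.size for w in net.weights) + sum(b.size for b in net.biases))


def weighted_mse_loss(pred: np.ndarray, target: np.ndarray, zeta: np.ndarray,
                      joint: bool | None = None) -> float:
    """Weighted MSE: sum_i zeta_i ||y_i - yhat_i||^2, divided by the number
    of target components when ``joint`` (so the joint loss is the mean of
    the per-parameter losses).  ``zeta`` is expected to be normalized over
    the dataset it came from (uniform weights 1/n recover the plain MSE).
    """
    pred = np.atleast_2d(pred)
    target = np.atleast_2d(target)
    if pred.shape != target.shape or len(zeta) != len(pred):
        raise ValueError("pred, target and zeta shapes are inconsistent")
    if joint is None:
        joint = pred.shape[1] > 1
    sq = ((pred - target) ** 2).sum(axis=1)
    loss = float(np.asarray(zeta) @ sq)
    return loss / pred.shape[1] if joint else loss


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    learning_rate: list[float] = field(default_factory=list)

    @property
    def best_epoch(self) -> int:
        return int(np.argmin(self.val_loss))

    @property
    def best_val_loss(self) -> float:
        return float(np.min(self.val_loss))


def _dataset_arrays(ds, target_cols):
    x = ds.inputs
    y = ds.targets[:, target_cols] if target_cols is not None else ds.targets
    return x, np.atleast_2d(y.T).T, ds.weights


def train(net: MLP, train_ds, val_ds, config: TrainConfig,
          target_cols: list[int] | None = None,
          verbose: bool = False) -> tuple[MLP, TrainHistory]:
    """SGD-with-momentum training; returns (best network, history).

    ``target_cols`` selects target columns for single-parameter networks
    (e.g. ``[0]`` for a d_star-only net).  Batch gradients are scaled by
    n_dataset / batch_size so that dataset-level weights ``zeta`` (which sum
    to one per dataset) need no per-batch renormalization.
    """
    x, y, zeta = _dataset_arrays(train_ds, target_cols)
    xv, yv, zv = _dataset_arrays(val_ds, target_cols)
    if y.shape[1] != net.spec.output_dim:
        raise ValueError("target columns do not match the network output dim")
    if config.batch_size > len(x):
        raise ValueError("batch_size exceeds the training-set size")

    n = len(x)
    k = y.shape[1]
    joint = config.joint_loss and k > 1
    denom = k if joint else 1
    rng = np.random.default_rng(config.seed)
    vel_w = [np.zeros_like(w) for w in net.weights]
    vel_b = [np.zeros_like(b) for b in net.biases]
    hist = TrainHistory()
    best_net = net.copy()
    best_val = np.inf

    for epoch in range(config.epochs):
        lr = config.learning_rate(epoch)
        order = rng.permutation(n)
        ep_loss = 0.0
        for lo in range(0, n - config.batch_size + 1, config.batch_size):
            idx = order[lo:lo + config.batch_size]
            xb, yb, zb = x[idx], y[idx], zeta[idx]
            out, acts, pre = net.forward_with_cache(xb)
            err = out - yb
            with np.errstate(over="ignore", invalid="ignore"):
                batch_loss = float(zb @ (err**2).sum(axis=1)) / denom
            # scale so the expected batch loss equals the dataset loss
            scale = n / config.batch_size
            ep_loss += batch_loss * scale / (n // config.batch_size)
            if not np.isfinite(batch_loss):
                raise TrainingDivergedError(epoch, batch_loss, lr)
            grad_out = (2.0 * scale / denom) * zb[:, None] * err
            gw, gb = net.gradients(xb, grad_out, acts, pre)
            for i in range(len(net.weights)):
                vel_w[i] = config.momentum * vel_w[i] - lr * gw[i]
                vel_b[i] = config.momentum * vel_b[i] - lr * gb[i]
                net.weights[i] += vel_w[i]
                net.biases[i] += vel_b[i]

        val_loss = weighted_mse_loss(net.forward(xv), yv, zv, joint=joint)
        if not np.isfinite(val_loss):
            raise TrainingDivergedError(epoch, val_loss, lr)
        hist.train_loss.append(ep_loss)
        hist.val_loss.append(float(val_loss))
        hist.learning_rate.append(lr)
        if val_loss < best_val:
            best_val = float(val_loss)
            best_net = net.copy()
        if verbose and (epoch % 50 == 0 or epoch == config.epochs - 1):
            print(f"epoch {epoch:5d} lr {lr:.4g} train {ep_loss:.4g} "
                  f"val {val_loss:.4g}")
    return best_net, hist


# ---------------------------------------------------------------------------
# bundles
# ---------------------------------------------------------------------------

PARAM_NAMES = ("d_star", "c0", "alpha")


@dataclass
class EstimatorBundle:
    """One or three fully connected blocks exposed as a single estimator
    whose output is always (d_star, c0, alpha).

    ``provenance`` records where each output column came from (e.g. the
    d_star column of a joint network merged with separate c0/alpha nets).
    """

    blocks: list[MLP]
    block_outputs: list[list[int]]       # target columns served per block
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        served = sorted(c for cols in self.block_outputs for c in cols)
        if served != [0, 1, 2]:
            raise ValueError("bundle must serve exactly (d_star, c0, alpha)")
        dims = {b.spec.input_dim for b in self.blocks}
        if len(dims) != 1:
            raise ValueError("all blocks must share the input dimension")
        if not self.provenance:
            self.provenance = ["" for _ in self.blocks]

    @property
    def input_dim(self) -> int:
        return self.blocks[0].spec.input_dim

    def predict(self, curves: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(curves, dtype=float))
        out = np.empty((len(x), 3))
        for net, cols in zip(self.blocks, self.block_outputs):
            block_out = net.forward(x)
            for j, col in enumerate(cols):
                out[:, col] = block_out[:, j]
        return out


def merge_parameter_networks(nets: list[MLP],
                             provenance: list[str] | None = None,
                             columns: list[list[int]] | None = None,
                             ) -> EstimatorBundle:
    """Merge single-parameter networks (one per target, in d_star/c0/alpha
    order) into one block-parallel estimator.  Predictions equal the
    component networks' exactly.  ``columns`` overrides the per-block output
    assignment, supporting hybrids such as a 3-output joint network serving
    only its d_star column alongside separate c0 and alpha blocks."""
    if columns is None:
        if len(nets) != 3 or any(n.spec.output_dim != 1 for n in nets):
            raise ValueError("default merge expects three single-output nets")
        columns = [[0], [1], [2]]
    return EstimatorBundle(blocks=list(nets), block_outputs=columns,
                           provenance=provenance or [])


def predict(bundle: "EstimatorBundle | MLP", curves: np.ndarray) -> np.ndarray:
    """Parameter estimates (n, 3) for an array of curves (n, input_dim)."""
    if isinstance(bundle, MLP):
        out = bundle.forward(curves)
        if out.shape[1] != 3:
            raise ValueError("a bare MLP must have 3 outputs; use a bundle")
        return out
    return bundle.predict(curves)


# ---------------------------------------------------------------------------
# serialization: flat weight arrays + JSON manifest
# ---------------------------------------------------------------------------

def save_network(path: str, net: MLP) -> None:
    manifest = {
        "spec": {"input_dim": net.spec.input_dim,
                 "hidden_layers": net.spec.hidden_layers,
                 "hidden_width": net.spec.hidden_width,
                 "output_dim": net.spec.output_dim,
                 "gamma": net.spec.gamma},
        "layer_shapes": [list(w.shape) for w in net.weights],
    }
    arrays = {f"w{i}": w for i, w in enumerate(net.weights)}
    arrays.update({f"b{i}": b for i, b in enumerate(net.biases)})
    np.savez(path if path.endswith(".npz") else path + ".npz",
             manifest=json.dumps(manifest), **arrays)


def load_network(path: str) -> MLP:
    data = np.load(path if path.endswith(".npz") else path + ".npz",
                   allow_pickle=False)
    manifest = json.loads(str(data["manifest"]))
    spec = MLPSpec(**manifest["spec"])
    n_layers = len(manifest["layer_shapes"])
    weights = [data[f"w{i}"] for i in range(n_layers)]
    biases = [data[f"b{i}"] for i in range(n_layers)]
    return MLP(spec, weights, biases)
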
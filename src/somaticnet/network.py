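"""Variant-classification networks: architecture, training, inference.

Two backbones map a pileup image to a somatic-mutation probability:

* ``plain_conv`` (SNV default): 10 convolutional blocks, each
  convolution -> ReLU -> batch normalization, with two average-pooling
  layers between blocks, then global average pooling and three dense layers
  (256, 128, 64) into a single sigmoid output. Filter counts grow linearly
  (32, 64, ..., 320 at scale 1.0), which puts the trainable parameter count
  at ~3.4 million; the ``scale`` knob multiplies all filter counts for
  desk-scale variants.
* ``inception_style`` (indel default): blocks of parallel 1x1 / 3x3 / 5x5
  convolution branches (each conv -> BN -> ReLU) concatenated along
  channels — a scaled-down inception backbone suited to the wider indel
  images — with the same pooling/dense head.

Training uses the Adam optimizer (initial learning rate 1e-4) with
mini-batches of 32 and binary cross-entropy, early-stopping on validation
loss. One master seed fans out to weight init, shuffling and batching, so
runs are bit-reproducible on a fixed BLAS.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from .nn import (
    Adam,
    AvgPool,
    BatchNorm,
    Conv2D,
    Dense,
    GlobalAvgPool,
    InceptionBlock,
    ReLU,
    Sequential,
    bce_loss,
    sigmoid,
)

SNV_INPUT_SHAPE = (100, 70, 5)
INDEL_INPUT_SHAPE = (140, 150, 5)


@dataclass
class NetSpec:
    """Architecture description; ``scale`` multiplies filter counts only."""

    input_shape: tuple[int, int, int] = SNV_INPUT_SHAPE
    conv_blocks: int = 10
    pool_positions: tuple[int, ...] = (1, 6)   # pool after these blocks (1-based)
    pool_sizes: tuple[int, ...] = (4, 2)
    dense_units: tuple[int, ...] = (256, 128, 64)
    scale: float = 1.0
    arch_style: str = "plain_conv"  # plain_conv | inception_style
    base_filters: int = 32

    def __post_init__(self) -> None:
        if self.conv_blocks < 1:
            raise ValueError("conv_blocks must be >= 1")
        if not self.dense_units:
            raise ValueError("dense_units must be nonempty")
        if len(self.pool_positions) != len(self.pool_sizes):
            raise ValueError("pool_positions and pool_sizes must align")

    def filters(self, block: int) -> int:
        """Filter count of 1-based ``block`` after scaling (min 4)."""
        return max(4, int(round(self.base_filters * block * self.scale)))


@dataclass
class TrainConfig:
    optimizer: str = "adam"
    learning_rate: float = 1e-4
    batch_size: int = 32
    epochs: int = 10
    validation_fraction: float = 0.15
    early_stopping_patience: int = 3
    min_epochs: int = 6  # no early stop during the initial warmup plateau
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


def build_model(spec: NetSpec, seed: int = 0) -> Sequential:
    """Materialize a network; forward on any encoding returns a probability
    via :func:`predict`."""
    rng = np.random.default_rng(seed)
    pools = dict(zip(spec.pool_positions, spec.pool_sizes))
    layers = []
    if 0 in pools:  # position 0 = downsample the input itself
        layers.append(AvgPool(pools[0]))
    c_in = spec.input_shape[2]
    for block in range(1, spec.conv_blocks + 1):
        c_out = spec.filters(block)
        if spec.arch_style == "plain_conv":
            layers += [Conv2D(c_in, c_out, k=3, rng=rng), ReLU(), BatchNorm(c_out)]
        elif spec.arch_style == "inception_style":
            branch = {1: c_out // 4, 3: c_out // 2, 5: c_out - c_out // 4 - c_out // 2}
            layers.append(InceptionBlock(c_in, branch, rng=rng))
        else:
            raise ValueError(f"unknown arch_style {spec.arch_style!r}")
        c_in = c_out
        if block in pools:
            layers.append(AvgPool(pools[block]))
    layers.append(GlobalAvgPool())
    f_in = c_in
    for units in spec.dense_units:
        layers += [Dense(f_in, units, rng=rng), ReLU()]
        f_in = units
    layers.append(Dense(f_in, 1, rng=rng))
    model = Sequential(layers)
    model.spec = spec
    return model


def _as_array(encodings) -> np.ndarray:
    if isinstance(encodings, np.ndarray):
        return encodings.astype(np.float32, copy=False)
    return np.stack([getattr(e, "values", e) for e in encodings]).astype(np.float32, copy=False)


def forward_logits(model: Sequential, x: np.ndarray, batch_size: int = 32) -> np.ndarray:
    """Batched inference-mode logits (keeps conv scratch buffers small)."""
    out = np.empty(len(x), dtype=np.float32)
    for i in range(0, len(x), batch_size):
        out[i : i + batch_size] = model.forward(x[i : i + batch_size], train=False)
    return out


def predict(model: Sequential, encodings, batch_size: int = 32) -> np.ndarray:
    """Somatic-mutation probabilities in [0,1], one per encoding.

    Batch composition cannot change scores (batch statistics are not used at
    inference), so batched and per-item evaluation agree to float precision.
    """
    x = _as_array(encodings)
    if x.ndim == 3:
        x = x[None]
    if tuple(x.shape[1:]) != tuple(model.spec.input_shape):
        raise ValueError(
            f"encoding shape {x.shape[1:]} does not match model input {model.spec.input_shape}"
        )
    return sigmoid(forward_logits(model, x, batch_size))


def train_model(
    model: Sequential,
    encodings,
    labels,
    config: TrainConfig | None = None,
    stop_callback=None,
) -> dict:
    """Train in place; returns the history dict.

    History records per-epoch training loss, validation loss and validation
    accuracy. Early stopping restores the best-validation-loss weights.
    ``stop_callback(history) -> bool`` is consulted after every epoch and
    may abort the run (the best weights seen are still restored).
    """
    config = config or TrainConfig()
    x = _as_array(encodings)
    y = np.asarray(labels, dtype=np.float32)
    if len(x) != len(y):
        raise ValueError("encodings and labels must align")
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("training set contains a single class; cannot train a classifier")

    rng = np.random.default_rng(config.seed)
    n_val = max(1, int(round(len(x) * config.validation_fraction)))
    perm = rng.permutation(len(x))
    val_idx, tr_idx = perm[:n_val], perm[n_val:]
    xtr, ytr, xval, yval = x[tr_idx], y[tr_idx], x[val_idx], y[val_idx]

    opt = Adam(model, lr=config.learning_rate)
    history = {"train_loss": [], "val_loss": [], "val_acc": []}
    best_loss, best_state, patience = np.inf, None, 0
    for epoch in range(config.epochs):
        order = rng.permutation(len(xtr))
        losses = []
        for i in range(0, len(order), config.batch_size):
            idx = order[i : i + config.batch_size]
            z = model.forward(xtr[idx], train=True)
            loss, dz = bce_loss(z, ytr[idx])
            model.backward(dz, need_input_grad=False)
            opt.step()
            losses.append(loss)
        zval = forward_logits(model, xval, config.batch_size)
        val_loss, _ = bce_loss(zval, yval)
        val_acc = float(np.mean((sigmoid(zval) >= 0.5) == (yval >= 0.5)))
        history["train_loss"].append(float(np.mean(losses)))
        history["val_loss"].append(val_loss)
        history["val_acc"].append(val_acc)
        if val_loss < best_loss - 1e-5:
            best_loss, patience = val_loss, 0
            best_state = {k: v.copy() for k, v in model.state_dict().items()}
        else:
            patience += 1
            if patience >= config.early_stopping_patience and epoch + 1 >= config.min_epochs:
                break
        if stop_callback is not None and stop_callback(history):
            break
    if best_state is not None:
        model.load_state_dict(best_state)
    return history


def save_model(model: Sequential, path: str) -> None:
    """Checkpoint = architecture spec (JSON) + parameter arrays (npz)."""
    spec = asdict(model.spec)
    with open(path, "wb") as fh:  # write to the exact path given
        np.savez_compressed(
            fh,
            __spec__=np.frombuffer(json.dumps(spec).encode(), dtype=np.uint8),
            **model.state_dict(),
        )


def load_model(path: str) -> Sequential:
    with np.load(path) as data:
        spec_dict = json.loads(bytes(data["__spec__"].tobytes()).decode())
        for key in ("input_shape", "pool_positions", "pool_sizes", "dense_units"):
            spec_dict[key] = tuple(spec_dict[key])
        model = build_model(NetSpec(**spec_dict))
        model.load_state_dict({k: data[k] for k in data.files if k != "__spec__"})
    return model
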
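"""Minimal CNN stack with explicit forward/backward passes.

Implemented directly on numpy so every gradient is inspectable: plain
backpropagation for training, and a guided mode for input attribution where
rectifier units zero the backward signal wherever either the forward
activation or the incoming gradient is negative. Convolutions are stride-1
'same' im2col GEMMs; the input-gradient is computed as a full convolution
with the rotated kernels (no scatter-adds). All arithmetic is float32.

This module knows nothing about genomics; :mod:`somaticnet.network` builds
the actual variant-classification architectures on top of it.
"""

from __future__ import annotations

import json

import numpy as np


class Layer:
    """Base layer: trainable params live in ``params``; matching gradients
    appear in ``grads`` after a training backward pass."""

    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray, guided: bool = False) -> np.ndarray:
        raise NotImplementedError

    @property
    def n_params(self) -> int:
        return sum(int(np.prod(v.shape)) for v in self.params.values())


class Conv2D(Layer):
    """Stride-1 'same' convolution on NHWC tensors.

    Evaluated tap-wise: for each of the k*k kernel taps, a contiguous shifted
    copy of the (zero-padded) input is multiplied against that tap's
    (c_in, c_out) matrix — one clean GEMM per tap, no strided gathers. The
    shifted copies double as the cache for the weight-gradient GEMMs, and the
    input gradient is the mirrored scatter of per-tap GEMMs back onto the
    padded grid. Scratch buffers are allocated once per input shape and
    reused; per-step allocator churn would otherwise dominate runtime.
    """

    def __init__(self, c_in: int, c_out: int, k: int = 3, bias: bool = False, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.k, self.c_in, self.c_out = k, c_in, c_out
        std = np.sqrt(2.0 / (k * k * c_in))
        self.params["W"] = rng.normal(0.0, std, (k, k, c_in, c_out)).astype(np.float32)
        if bias:
            self.params["b"] = np.zeros(c_out, dtype=np.float32)
        self._scratch: dict[tuple, dict] = {}

    def _buffers(self, n: int, h: int, w: int) -> dict:
        key = (n, h, w)
        buf = self._scratch.get(key)
        if buf is None:
            k, p = self.k, (self.k - 1) // 2
            buf = {
                "xp": np.zeros((n, h + 2 * p, w + 2 * p, self.c_in), dtype=np.float32),
                "taps": np.empty((k * k, n * h * w, self.c_in), dtype=np.float32),
                "y": np.empty((n * h * w, self.c_out), dtype=np.float32),
                "ytmp": np.empty((n * h * w, self.c_out), dtype=np.float32),
                "gx": np.empty((n * h * w, self.c_in), dtype=np.float32),
                "gxp": np.zeros((n, h + 2 * p, w + 2 * p, self.c_in), dtype=np.float32),
            }
            self._scratch[key] = buf
        return buf

    def forward(self, x, train=False):
        n, h, w, _ = x.shape
        self._shape = x.shape
        k, p = self.k, (self.k - 1) // 2
        buf = self._buffers(n, h, w)
        buf["xp"][:, p : p + h, p : p + w, :] = x
        taps3 = buf["taps"].reshape(k * k, n, h, w, self.c_in)
        for t in range(k * k):
            i, j = divmod(t, k)
            taps3[t] = buf["xp"][:, i : i + h, j : j + w, :]
        w3 = self.params["W"].reshape(k * k, self.c_in, self.c_out)
        np.dot(buf["taps"][0], w3[0], out=buf["y"])
        for t in range(1, k * k):
            np.dot(buf["taps"][t], w3[t], out=buf["ytmp"])
            buf["y"] += buf["ytmp"]
        if "b" in self.params:
            buf["y"] += self.params["b"]
        self._buf = buf
        # the returned view aliases scratch; it is only read (or rewritten
        # in place by the following ReLU) before this layer's next forward
        return buf["y"].reshape(n, h, w, self.c_out)

    def backward(self, dy, guided=False, need_input_grad=True):
        n, h, w, _ = dy.shape
        k, p = self.k, (self.k - 1) // 2
        buf = self._buf
        dy_flat = np.ascontiguousarray(dy.reshape(-1, self.c_out))
        w3 = self.params["W"].reshape(k * k, self.c_in, self.c_out)
        dW = np.empty_like(w3)
        gxp = buf["gxp"]
        if need_input_grad:
            gxp.fill(0.0)
        for t in range(k * k):
            i, j = divmod(t, k)
            np.dot(buf["taps"][t].T, dy_flat, out=dW[t])
            if need_input_grad:
                np.dot(dy_flat, w3[t].T, out=buf["gx"])
                gxp[:, i : i + h, j : j + w, :] += buf["gx"].reshape(n, h, w, self.c_in)
        self.grads["W"] = dW.reshape(self.params["W"].shape)
        if "b" in self.params:
            self.grads["b"] = dy_flat.sum(axis=0)
        if not need_input_grad:
            return None
        return gxp[:, p : p + h, p : p + w, :].copy()


class ReLU(Layer):
    def forward(self, x, train=False):
        self._mask = x > 0
        np.maximum(x, 0.0, out=x)  # callers hand over ownership of x
        return x

    def backward(self, dy, guided=False):
        np.multiply(dy, self._mask, out=dy)
        if guided:
            np.maximum(dy, 0.0, out=dy)
        return dy


class BatchNorm(Layer):
    """Per-channel batch normalization over (N, H, W) or (N,)."""

    def __init__(self, c: int, momentum: float = 0.9, eps: float = 1e-5):
        super().__init__()
        self.params["gamma"] = np.ones(c, dtype=np.float32)
        self.params["beta"] = np.zeros(c, dtype=np.float32)
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)
        self.momentum, self.eps = momentum, eps

    def _axes(self, x):
        return tuple(range(x.ndim - 1))

    def forward(self, x, train=False):
        axes = self._axes(x)
        if train:
            xf = x.reshape(-1, x.shape[-1])
            m_count = xf.shape[0]
            mean = xf.sum(axis=0) / m_count
            # single-pass variance; adequate for unit-scale activations
            var = np.einsum("nc,nc->c", xf, xf) / m_count - mean * mean
            np.maximum(var, 0.0, out=var)
            m = self.momentum
            self.running_mean = m * self.running_mean + (1 - m) * mean
            self.running_var = m * self.running_var + (1 - m) * var
            self._train_mode = True
        else:
            mean, var = self.running_mean, self.running_var
            self._train_mode = False
        self._std = np.sqrt(var + self.eps).astype(np.float32)
        self._xhat = (x - mean) / self._std
        return self.params["gamma"] * self._xhat + self.params["beta"]

    def backward(self, dy, guided=False):
        axes = self._axes(dy)
        xhat = self._xhat
        self.grads["gamma"] = (dy * xhat).sum(axis=axes)
        self.grads["beta"] = dy.sum(axis=axes)
        g_over_std = self.params["gamma"] / self._std
        if not self._train_mode:
            # inference statistics are constants: the map is affine
            return dy * g_over_std
        m = dy.size // dy.shape[-1]
        return (
            g_over_std
            / m
            * (m * dy - self.grads["beta"] - xhat * self.grads["gamma"])
        )


class AvgPool(Layer):
    """Non-overlapping average pooling; trailing rows/cols beyond a full
    window are dropped."""

    def __init__(self, size: int):
        super().__init__()
        self.size = size

    def forward(self, x, train=False):
        p = self.size
        n, h, w, c = x.shape
        h2, w2 = h // p, w // p
        self._shape = x.shape
        return x[:, : h2 * p, : w2 * p].reshape(n, h2, p, w2, p, c).mean(axis=(2, 4))

    def backward(self, dy, guided=False):
        p = self.size
        n, h, w, c = self._shape
        h2, w2 = dy.shape[1], dy.shape[2]
        dx = np.zeros(self._shape, dtype=dy.dtype)
        view = dx[:, : h2 * p, : w2 * p].reshape(n, h2, p, w2, p, c)
        view[:] = dy[:, :, None, :, None, :] / (p * p)
        return dx


class GlobalAvgPool(Layer):
    def forward(self, x, train=False):
        self._shape = x.shape
        return x.mean(axis=(1, 2))

    def backward(self, dy, guided=False):
        n, h, w, c = self._shape
        return np.broadcast_to(dy[:, None, None, :] / (h * w), self._shape).astype(dy.dtype)


class Dense(Layer):
    def __init__(self, f_in: int, f_out: int, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        std = np.sqrt(2.0 / f_in)
        self.params["W"] = rng.normal(0.0, std, (f_in, f_out)).astype(np.float32)
        self.params["b"] = np.zeros(f_out, dtype=np.float32)

    def forward(self, x, train=False):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dy, guided=False):
        self.grads["W"] = self._x.T @ dy
        self.grads["b"] = dy.sum(axis=0)
        return dy @ self.params["W"].T


class InceptionBlock(Layer):
    """Parallel 1x1 / 3x3 / 5x5 conv branches (each conv->BN->ReLU),
    concatenated along channels."""

    def __init__(self, c_in: int, branch_channels: dict[int, int], rng=None):
        super().__init__()
        self.branches: list[list[Layer]] = []
        self.splits: list[int] = []
        for k, c_out in sorted(branch_channels.items()):
            if c_out <= 0:
                continue
            self.branches.append(
                [Conv2D(c_in, c_out, k=k, rng=rng), BatchNorm(c_out), ReLU()]
            )
            self.splits.append(c_out)

    def sublayers(self):
        for branch in self.branches:
            yield from branch

    @property
    def n_params(self):
        return sum(l.n_params for l in self.sublayers())

    def forward(self, x, train=False):
        outs = []
        for branch in self.branches:
            h = x
            for layer in branch:
                h = layer.forward(h, train)
            outs.append(h)
        return np.concatenate(outs, axis=-1)

    def backward(self, dy, guided=False):
        dx = None
        offset = 0
        for branch, c in zip(self.branches, self.splits):
            d = dy[..., offset : offset + c]
            offset += c
            for layer in reversed(branch):
                d = layer.backward(d, guided)
            dx = d if dx is None else dx + d
        return dx


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_loss(z: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Binary cross-entropy on logits; returns (loss, dloss/dz)."""
    loss = float(np.mean(np.logaddexp(0.0, z) - y * z))
    dz = (sigmoid(z) - y) / z.size
    return loss, dz.astype(np.float32)


class Sequential:
    """A feed-forward stack ending in a single logit."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        h = np.asarray(x, dtype=np.float32)
        for layer in self.layers:
            h = layer.forward(h, train)
        return h[:, 0]  # (N,1) logits -> (N,)

    def backward(
        self, dz: np.ndarray, guided: bool = False, need_input_grad: bool = True
    ) -> np.ndarray | None:
        """Backpropagate; with ``need_input_grad=False`` the bottom conv
        skips its (unused) input-gradient work during training."""
        d = np.asarray(dz, dtype=np.float32)[:, None]
        for idx in range(len(self.layers) - 1, -1, -1):
            layer = self.layers[idx]
            if idx == 0 and not need_input_grad and isinstance(layer, Conv2D):
                return layer.backward(d, guided, need_input_grad=False)
            d = layer.backward(d, guided)
        return d

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return sigmoid(self.forward(x, train=False))

    # -- parameter plumbing ------------------------------------------------
    def _flat_layers(self):
        for layer in self.layers:
            if isinstance(layer, InceptionBlock):
                yield from layer.sublayers()
            else:
                yield layer

    def named_params(self):
        for i, layer in enumerate(self._flat_layers()):
            for name, value in layer.params.items():
                yield f"{i}.{name}", layer, name, value

    @property
    def n_params(self) -> int:
        return sum(l.n_params for l in self._flat_layers())

    def has_rectifiers(self) -> bool:
        return any(isinstance(l, ReLU) for l in self._flat_layers())

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {}
        for key, layer, name, value in self.named_params():
            state[key] = value
        for i, layer in enumerate(self._flat_layers()):
            if isinstance(layer, BatchNorm):
                state[f"{i}.running_mean"] = layer.running_mean
                state[f"{i}.running_var"] = layer.running_var
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for key, layer, name, _ in self.named_params():
            layer.params[name] = np.asarray(state[key], dtype=np.float32)
        for i, layer in enumerate(self._flat_layers()):
            if isinstance(layer, BatchNorm):
                layer.running_mean = np.asarray(state[f"{i}.running_mean"], dtype=np.float32)
                layer.running_var = np.asarray(state[f"{i}.running_var"], dtype=np.float32)


class Adam:
    """Adaptive-moment optimizer (beta1=0.9, beta2=0.999)."""

    def __init__(self, model: Sequential, lr: float = 1e-4, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.model = model
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m: dict[str, np.ndarray] = {}
        self.v: dict[str, np.ndarray] = {}

    def step(self) -> None:
        self.t += 1
        for key, layer, name, value in self.model.named_params():
            g = layer.grads.get(name)
            if g is None:
                continue
            m = self.m.setdefault(key, np.zeros_like(value))
            v = self.v.setdefault(key, np.zeros_like(value))
            m[:] = self.b1 * m + (1 - self.b1) * g
            v[:] = self.b2 * v + (1 - self.b2) * g * g
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            layer.params[name] = value - self.lr * mhat / (np.sqrt(vhat) + self.eps)
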
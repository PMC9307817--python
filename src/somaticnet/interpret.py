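"""Model interpretation: pixel-importance maps via guided backpropagation.

Guided backpropagation propagates the output gradient back to the input
while zeroing the backward signal at every rectifier wherever either the
forward activation or the incoming gradient is negative, yielding per-pixel
importance scores for a single pileup image. Averaging maps over many sites
exposes which image regions and channels the classifier habitually uses
(candidate columns, flanking context, quality channels).

Batch-normalization layers are backpropagated in inference mode (fixed
running statistics), so a map depends only on the encoding it explains.
"""

from __future__ import annotations

import warnings

import numpy as np

from .encoder import SiteEncoding
from .nn import Sequential


def _as_input(encoding) -> np.ndarray:
    values = encoding.values if isinstance(encoding, SiteEncoding) else np.asarray(encoding)
    return values.astype(np.float32)[None]


def guided_backprop(model: Sequential, encoding) -> np.ndarray:
    """Importance map of one encoding; same shape as the encoding.

    The map is the guided gradient of the output logit with respect to the
    input (the sigmoid is monotone, so the logit's gradient has the same
    sign structure as the probability's). For a model without rectifier
    units the guided rule has nothing to act on and the plain input gradient
    is returned with a warning.
    """
    guided = model.has_rectifiers()
    if not guided:
        warnings.warn(
            "model has no rectifier activations; returning the plain input gradient",
            stacklevel=2,
        )
    x = _as_input(encoding)
    model.forward(x, train=False)
    dx = model.backward(np.ones(1, dtype=np.float32), guided=guided)
    return dx[0]


def mean_importance(model: Sequential, encodings) -> np.ndarray:
    """Element-wise mean of guided-backprop maps over encodings.

    All encodings must share one shape; deterministic given the site sample.
    """
    total = None
    count = 0
    for enc in encodings:
        m = guided_backprop(model, enc)
        if total is None:
            total = np.zeros_like(m, dtype=np.float64)
        elif m.shape != total.shape:
            raise ValueError(f"mixed encoding shapes: {m.shape} vs {total.shape}")
        total += m
        count += 1
    if count == 0:
        raise ValueError("mean_importance requires at least one encoding")
    return (total / count).astype(np.float32)


def normalize_map(importance: np.ndarray) -> np.ndarray:
    """Scale a map to [-1, 1] by its maximum absolute value (for display)."""
    peak = np.abs(importance).max()
    return importance / peak if peak > 0 else importance


def render_heatmap(
    importance: np.ndarray,
    path: str,
    channels: tuple[str, ...] = (
        "base",
        "base_quality",
        "mapping_quality",
        "strand",
        "reference_base",
    ),
    title: str | None = None,
) -> None:
    """Write per-channel heatmap panels of an importance map to a PNG."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    norm = normalize_map(importance)
    n = importance.shape[-1]
    fig, axes = plt.subplots(1, n, figsize=(3.2 * n, 4), squeeze=False)
    for c in range(n):
        ax = axes[0, c]
        im = ax.imshow(norm[:, :, c], cmap="RdBu_r", vmin=-1, vmax=1, aspect="auto")
        ax.set_title(channels[c] if c < len(channels) else f"channel {c}", fontsize=9)
        ax.set_xlabel("column")
        if c == 0:
            ax.set_ylabel("read row")
    fig.colorbar(im, ax=axes.ravel().tolist(), shrink=0.7)
    if title:
        fig.suptitle(title)
    fig.savefig(path, dpi=110)
    plt.close(fig)
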
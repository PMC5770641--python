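"""Prepare a trained ANN for spiking simulation.

Two transformations are applied before a network is rate-coded:

1. **Batch-norm folding** — the affine transform ``BN(y) = gamma*(y-mu)/sigma
   + beta`` is absorbed into the preceding convolution or dense layer, which
   leaves the network function untouched while removing the batch-norm layers.
2. **Data-based parameter normalization** — weights and biases of each
   parameterized layer are jointly rescaled so that its activations on a
   calibration batch stay at or below 1, which keeps the corresponding spike
   rates below the simulator's maximum rate.  The per-layer scale lambda is
   either the maximum activation (``mode="max"``) or a high percentile of the
   activity distribution (``mode="percentile"``), the latter being robust to
   singular outlier samples.

Because ReLU is positively homogeneous, joint rescaling by
``W -> W * lambda(l-1)/lambda(l)``, ``b -> b / lambda(l)`` (with
``lambda(0) = 1`` for inputs in [0, 1]) changes every layer's activations only
by a positive per-layer factor, so classification decisions are preserved.
"""
from __future__ import annotations

import warnings

import numpy as np

from .network_model import (
    ActivationStats,
    NetworkModel,
    PARAM_KINDS,
    forward,
)


def fold_batchnorm(model: NetworkModel) -> NetworkModel:
    """Return an equivalent model with every batch-norm layer folded away.

    Each batch-norm layer must immediately follow a conv2d or dense layer;
    its parameters are absorbed as ``W~ = (gamma/sigma) * W`` and
    ``b~ = (gamma/sigma) * (b - mu) + beta`` (per output channel/unit).
    """
    layers = []
    for idx, layer in enumerate(model.layers):
        if layer.kind != "batchnorm":
            layers.append(layer.copy())
            continue
        if not layers or layers[-1].kind not in PARAM_KINDS:
            raise ValueError(
                f"layer {idx}: batchnorm must immediately follow a conv2d or dense layer"
            )
        prev = layers[-1]
        scale = layer.gamma / layer.std
        w = prev.weights
        # conv: scale per output channel (axis 0); dense: per output unit (axis 0)
        prev.weights = w * scale.reshape((-1,) + (1,) * (w.ndim - 1))
        b = prev.bias if prev.bias is not None else np.zeros(w.shape[0])
        prev.bias = scale * (b - layer.mean) + layer.beta
    return NetworkModel(layers, model.input_shape)


def _stat_activation_index(model: NetworkModel, layer: int) -> int:
    """Index of the activation associated with parameterized layer ``layer``:
    the output of the batchnorm/ReLU chain that directly follows it, if any."""
    j = layer
    while j + 1 < model.n_layers and model.layers[j + 1].kind in ("batchnorm", "relu"):
        j += 1
    return j


def collect_activation_stats(model: NetworkModel, batch: np.ndarray) -> ActivationStats:
    """Record per-layer ANN activations of ``batch`` for normalization.

    For each conv2d/dense layer the associated activation is the output of the
    immediately following batchnorm/ReLU chain (the layer's own output when no
    such chain follows, e.g. the final logits layer).
    """
    batch = np.asarray(batch, dtype=float)
    if batch.shape[0] == 0:
        raise ValueError("calibration batch is empty")
    acts = forward(model, batch)
    stats = ActivationStats()
    for idx, layer in enumerate(model.layers):
        if layer.kind in PARAM_KINDS:
            stats.samples[idx] = acts[_stat_activation_index(model, idx)].ravel().copy()
    return stats


def normalization_scales(
    model: NetworkModel,
    stats: ActivationStats,
    mode: str = "max",
    p: float = 99.9,
    include_zeros: bool = True,
) -> dict[int, float]:
    """Per-parameterized-layer scale lambda; layers whose calibration
    activations are all zero (or whose percentile is non-positive) get
    lambda = 1 with a warning, so they are left unscaled."""
    scales: dict[int, float] = {}
    for idx in stats.layers():
        lam = stats.scale(idx, mode=mode, p=p, include_zeros=include_zeros)
        if lam <= 0:
            warnings.warn(
                f"layer {idx}: non-positive activation scale; skipping normalization",
                stacklevel=2,
            )
            lam = 1.0
        scales[idx] = float(lam)
    _ = model  # signature symmetry; scales depend only on the stats
    return scales


def normalize_parameters(
    model: NetworkModel,
    stats: ActivationStats,
    mode: str = "max",
    p: float = 99.9,
    include_zeros: bool = True,
) -> NetworkModel:
    """Jointly rescale weights and biases by data-based activation scales.

    ``mode="max"`` uses lambda = max activation (all post-normalization
    calibration activations end up <= 1); ``mode="percentile"`` uses the p-th
    percentile of the activity distribution instead (robust normalization;
    ``p=100`` recovers max-norm exactly).  The model must not contain
    batch-norm layers — fold them first.
    """
    if any(l.kind == "batchnorm" for l in model.layers):
        raise ValueError("fold batch-norm layers before normalizing parameters")
    scales = normalization_scales(model, stats, mode=mode, p=p, include_zeros=include_zeros)
    out = model.copy()
    prev_lam = 1.0  # inputs are normalized to [0, 1]
    for idx, layer in enumerate(out.layers):
        if layer.kind not in PARAM_KINDS:
            continue
        if idx not in scales:
            raise ValueError(f"layer {idx}: no activation statistics available")
        lam = scales[idx]
        layer.weights = layer.weights * (prev_lam / lam)
        if layer.bias is not None:
            layer.bias = layer.bias / lam
        prev_lam = lam
    return out
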
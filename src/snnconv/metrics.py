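"""Operation accounting and accuracy-vs-operations trade-off curves.

The ANN cost of classifying one frame is the fixed count
``sum_l (2*f_in,l + 1) * n_l`` over the parameterized (conv/dense) layers:
each incoming connection costs a multiply and an add, plus one add for the
bias; pooling and softmax evaluation are not counted.  By default the
fan-in of a convolution neuron is the nominal kernel volume (kernel area x
input channels) regardless of border position, which is how the headline
GOps figures for 'same'-padded architectures are computed;
``border_aware=True`` instead counts only real (non-padding) connections.

The SNN cost is event-driven: every spike triggers one state update per
outgoing connection of the emitting neuron, so the cumulative synaptic
operations up to step t are ``sum_{t'<=t} sum_l f_out,l s_l(t')``.  Fan-out
is always border-aware (a spike cannot update a padding position).
"""
from __future__ import annotations

import numpy as np

from .network_model import NetworkModel, fan_in_map, fan_out_map
from .simulation import SimResult


def count_ann_ops(model: NetworkModel, border_aware: bool = False) -> int:
    """Floating-point operations of one ANN forward pass (ops/frame)."""
    total = 0
    shapes = model.layer_shapes()
    for idx, layer in enumerate(model.layers):
        if layer.kind == "conv2d":
            out_shape = shapes[idx][1]
            n_l = int(np.prod(out_shape))
            if border_aware:
                total_fan_in = int(fan_in_map(model, idx).sum())
            else:
                _, c_in, kh, kw = layer.weights.shape
                total_fan_in = kh * kw * c_in * n_l
            total += 2 * total_fan_in + n_l
        elif layer.kind == "dense":
            n_out, n_in = layer.weights.shape
            total += (2 * n_in + 1) * n_out
    return total


def count_snn_ops(result: SimResult, model: NetworkModel) -> np.ndarray:
    """Cumulative synaptic operations per image and step, recomputed from the
    recorded spike raster (requires ``run(..., record_raster=True)``).

    Returns an array ``(B, T)``; matches ``result.cum_ops`` exactly.
    """
    if result.raster is None:
        raise ValueError("result has no raster; simulate with record_raster=True")
    B, T = result.guesses.shape
    ops = np.zeros((B, T))
    for s, layer_idx in enumerate(result.stage_layer_indices):
        try:
            fo = fan_out_map(model, layer_idx).ravel().astype(float)
        except ValueError:
            continue  # terminal layer: spikes have no outgoing connections
        ops += np.abs(result.raster[s].astype(float)) @ fo
    return np.cumsum(ops, axis=1)


def tradeoff_curve(result: SimResult) -> tuple[np.ndarray, np.ndarray]:
    """Per-step ``(mean cumulative ops/frame, mean error rate)`` series.

    Both arrays have length T.  Requires labels to have been passed to
    :func:`~snnconv.simulation.run`.
    """
    if result.correct is None:
        raise ValueError("labels were not provided to run()")
    return result.cum_ops.mean(axis=0), result.error_rate()


def write_curve_csv(path: str, cum_ops: np.ndarray, error_rate: np.ndarray) -> None:
    """Write a trade-off curve as ``t,cum_ops_per_frame,error_rate`` rows."""
    with open(path, "w") as fh:
        fh.write("t,cum_ops_per_frame,error_rate\n")
        for t, (o, e) in enumerate(zip(cum_ops, error_rate), start=1):
            fh.write(f"{t},{o:.1f},{e:.6f}\n")


def agreement_curve(result: SimResult, reference: np.ndarray) -> np.ndarray:
    """Per-step fraction of images whose SNN readout matches ``reference``
    (typically the ANN argmax decisions)."""
    reference = np.asarray(reference, dtype=np.int64)
    return (result.guesses == reference[:, None]).mean(axis=0)
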
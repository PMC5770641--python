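"""End-to-end SNN inference: encoding, clamp scheduling, the T-step loop.

A converted model (batch-norm folded, parameters normalized) is unrolled into
a pipeline of spiking stages: every conv2d/dense/avgpool2d layer becomes an
integrate-and-fire layer, every maxpool2d layer becomes a rate-gated pooling
stage, ReLU and flatten dissolve into the stages around them (the IF neuron
itself realizes the rectification), and a trailing softmax becomes a
:class:`~snnconv.spiking_core.SpikingSoftmax` readout.  Layers update
synchronously within a time step, layer 1 -> L, each consuming the spikes its
predecessor emitted in the same step.

Input encoding is either *constant current* (the analog image drives the
first layer with the fixed charge ``z = V_thr (W x + b)`` every step, so
spiking begins at the first hidden layer) or *Poisson* (each pixel spikes
with probability ``x * r_max * dt`` per step).

Synaptic operations are accumulated per step as the fan-out of every spiking
neuron (one postsynaptic update per outgoing connection); constant-current
and bias-driven membrane additions are not counted, and under Poisson
encoding the input-pixel spikes themselves are outside the per-layer sum.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network_model import (
    NetworkModel,
    TRANSPARENT_KINDS,
    apply_layer,
    fan_out_map,
    forward,
)
from .spiking_core import (
    MaxPoolGate,
    SimConfig,
    SpikingSoftmax,
    SpikingState,
    step_layer,
)


def clamp_schedule(layer_depth: int, config: SimConfig) -> int:
    """Release step N(l) = d*l of the membrane clamp for spiking layer l
    (1-based depth); the layer is silent while t <= N(l)."""
    return config.clamp_d * layer_depth


def encode_constant_current(
    model: NetworkModel, x: np.ndarray, v_thr: float = 1.0
) -> np.ndarray:
    """Constant input charge ``z^1 = V_thr (W^1 x + b^1)`` of the first
    parameterized layer for an image batch ``x`` in [0, 1]."""
    x = np.asarray(x, dtype=float)
    if x.shape[1:] != model.input_shape:
        raise ValueError(
            f"input shape {x.shape[1:]} does not match model input {model.input_shape}"
        )
    for layer in model.layers:
        if layer.kind in TRANSPARENT_KINDS:
            x = apply_layer(layer, x)
            continue
        if layer.kind in ("conv2d", "dense"):
            return v_thr * apply_layer(layer, x)
        raise ValueError(
            "constant-current encoding requires the first wired layer to be conv2d or dense"
        )
    raise ValueError("model has no parameterized layer")


def encode_poisson(x: np.ndarray, rng: np.random.Generator, T: int) -> np.ndarray:
    """Poisson spike trains of shape ``(T,) + x.shape``: pixel i spikes at
    each step with probability ``x_i`` (per-step probability x*r_max*dt,
    which is x itself since r_max = 1/dt)."""
    x = np.asarray(x, dtype=float)
    return (rng.random((T,) + x.shape) < x).astype(float)


# ---------------------------------------------------------------------------
# spiking stages
# ---------------------------------------------------------------------------

class _IFStage:
    def __init__(self, layer_idx, layer, in_shape, out_shape, depth, fan_out_flat):
        self.layer_idx = layer_idx
        self.layer = layer
        self.in_shape = tuple(in_shape)
        self.out_shape = tuple(out_shape)
        self.depth = depth
        self.fan_out_flat = fan_out_flat
        self.state: SpikingState | None = None
        self.z_const: np.ndarray | None = None  # set for the first stage
        # under constant-current encoding

    def n_units(self) -> int:
        return int(np.prod(self.out_shape))

    def step(self, spikes_in: np.ndarray | None, t: int, config: SimConfig) -> np.ndarray:
        if self.z_const is not None:
            z = self.z_const
        else:
            x = spikes_in.reshape((spikes_in.shape[0],) + self.in_shape)
            z = config.v_thr * apply_layer(self.layer, x)
        if self.state is None:
            self.state = SpikingState.zeros(z.shape)
        clamped = t <= clamp_schedule(self.depth, config)
        return step_layer(self.state, z, config, clamped=clamped)


class _GateStage:
    def __init__(self, layer_idx, layer, in_shape, out_shape, fan_out_flat, window):
        self.layer_idx = layer_idx
        self.in_shape = tuple(in_shape)
        self.out_shape = tuple(out_shape)
        self.fan_out_flat = fan_out_flat
        self.gate = MaxPoolGate(
            in_shape, layer.pool_size, layer.stride or layer.pool_size, window=window
        )

    def n_units(self) -> int:
        return int(np.prod(self.out_shape))

    def step(self, spikes_in, t, config):
        x = spikes_in.reshape((spikes_in.shape[0],) + self.in_shape)
        return self.gate.step(x)


class _SoftmaxStage:
    def __init__(self, layer_idx, out_shape, config):
        self.layer_idx = layer_idx
        self.in_shape = tuple(out_shape)
        self.out_shape = tuple(out_shape)
        self.fan_out_flat = None
        self.softmax = SpikingSoftmax(
            int(np.prod(out_shape)), config.softmax_variant,
            clock_rate=config.poisson_clock_rate, dt=config.dt,
        )

    def n_units(self) -> int:
        return int(np.prod(self.out_shape))

    def step(self, spikes_in, t, config, rngs=None):
        z = config.v_thr * spikes_in.reshape(spikes_in.shape[0], -1)
        return self.softmax.step(z, rngs)


def build_stages(model: NetworkModel, config: SimConfig):
    """Unroll a converted model into spiking stages (internal)."""
    shapes = model.layer_shapes()
    stages = []
    depth = 0
    for idx, layer in enumerate(model.layers):
        if layer.kind in TRANSPARENT_KINDS:
            continue
        if layer.kind == "batchnorm":
            raise ValueError("fold batch-norm layers before simulating")
        in_shape, out_shape = shapes[idx]
        try:
            fo = fan_out_map(model, idx).ravel().astype(float)
        except ValueError:
            fo = None
        if layer.kind in ("conv2d", "dense", "avgpool2d"):
            depth += 1
            stages.append(_IFStage(idx, layer, in_shape, out_shape, depth, fo))
        elif layer.kind == "maxpool2d":
            stages.append(
                _GateStage(idx, layer, in_shape, out_shape, fo, config.maxpool_window)
            )
        elif layer.kind == "softmax":
            stages.append(_SoftmaxStage(idx, out_shape, config))
        else:  # pragma: no cover
            raise ValueError(f"layer {idx}: cannot simulate kind {layer.kind!r}")
    if not stages:
        raise ValueError("model has no simulatable layers")
    return stages


# ---------------------------------------------------------------------------
# results container
# ---------------------------------------------------------------------------

@dataclass
class SimResult:
    """Recorded outcome of a T-step simulation of an image batch.

    ``guesses[b, t]`` is the classification readout after step t+1 (argmax of
    cumulative output spike counts, or of softmax(V) under potential
    readout); ties and the no-output-evidence case resolve to class 0, the
    latter flagged in ``no_evidence``.  ``cum_ops[b, t]`` is the cumulative
    synaptic-operation count.  ``spikes_per_step[b, t, s]`` is the total
    number of spike events in stage s.  ``raster`` (optional) holds the full
    per-neuron spike trains as int8 arrays ``(B, T, n)`` per stage.
    """

    guesses: np.ndarray
    no_evidence: np.ndarray
    spikes_per_step: np.ndarray
    cum_ops: np.ndarray
    final_rates: list[np.ndarray]
    final_scores: np.ndarray
    stage_layer_indices: list[int]
    config: SimConfig
    labels: np.ndarray | None = None
    correct: np.ndarray | None = None
    raster: list[np.ndarray] | None = None

    @property
    def T(self) -> int:
        return self.guesses.shape[1]

    @property
    def decision(self) -> np.ndarray:
        """Final top-1 class per image."""
        return self.guesses[:, -1]

    def topk(self, k: int) -> np.ndarray:
        """Top-k classes per image from the final output scores."""
        order = np.argsort(-self.final_scores, axis=1, kind="stable")
        return order[:, :k]

    def error_rate(self) -> np.ndarray:
        """Per-step error rate over the batch (requires labels)."""
        if self.correct is None:
            raise ValueError("labels were not provided to run()")
        return 1.0 - self.correct.mean(axis=0)

    def raster_to_csv(self, path: str) -> None:
        """Export spike events as CSV rows ``t,layer,neuron,polarity``."""
        if self.raster is None:
            raise ValueError("run() was called without record_raster=True")
        with open(path, "w") as fh:
            fh.write("t,layer,neuron,polarity\n")
            for s, layer_idx in enumerate(self.stage_layer_indices):
                r = self.raster[s]
                for b, t, n in zip(*np.nonzero(r)):
                    fh.write(f"{t + 1},{layer_idx},{n},{int(r[b, t, n])}\n")


# ---------------------------------------------------------------------------
# main loop
# ---------------------------------------------------------------------------

def run(
    model: NetworkModel,
    x: np.ndarray,
    config: SimConfig,
    labels: np.ndarray | None = None,
    record_raster: bool = False,
) -> SimResult:
    """Simulate the SNN for ``config.T`` steps on an image batch.

    Images are simulated independently; all stochastic draws for image b use
    a generator seeded with ``config.seed + b``.
    """
    x = np.asarray(x, dtype=float)
    B = x.shape[0]
    stages = build_stages(model, config)
    rngs = [np.random.default_rng(config.seed + i) for i in range(B)]

    if config.encoding == "constant_current":
        first = stages[0]
        if not isinstance(first, _IFStage) or first.layer.kind not in ("conv2d", "dense"):
            raise ValueError(
                "constant-current encoding requires a conv2d/dense first layer"
            )
        first.z_const = encode_constant_current(model, x, v_thr=config.v_thr)

    S = len(stages)
    n_out = stages[-1].n_units()
    guesses = np.zeros((B, config.T), dtype=np.int64)
    no_evidence = np.zeros((B, config.T), dtype=bool)
    spikes_per_step = np.zeros((B, config.T, S))
    cum_ops = np.zeros((B, config.T))
    out_counts = np.zeros((B, n_out))
    raster = (
        [np.zeros((B, config.T, st.n_units()), dtype=np.int8) for st in stages]
        if record_raster
        else None
    )

    ops_running = np.zeros(B)
    for t in range(1, config.T + 1):
        if config.encoding == "poisson":
            cur = np.stack([(rngs[i].random(x.shape[1:]) < x[i]) for i in range(B)])
            cur = cur.astype(float)
        else:
            cur = None
        out_spikes = None
        for s, stage in enumerate(stages):
            if isinstance(stage, _SoftmaxStage):
                spk = stage.step(cur, t, config, rngs=rngs)
            else:
                spk = stage.step(cur, t, config)
            if spk is None:  # potential readout: no spike generation
                cur = None
                continue
            flat = np.abs(spk).reshape(B, -1)
            spikes_per_step[:, t - 1, s] = flat.sum(axis=1)
            if stage.fan_out_flat is not None:
                ops_running = ops_running + flat @ stage.fan_out_flat
            if raster is not None:
                raster[s][:, t - 1, :] = spk.reshape(B, -1).astype(np.int8)
            cur = spk
            out_spikes = spk
        cum_ops[:, t - 1] = ops_running

        # per-step readout
        last = stages[-1]
        if isinstance(last, _SoftmaxStage) and config.softmax_variant == "potential_readout":
            v = last.softmax.v
            guesses[:, t - 1] = np.argmax(v, axis=1)
            no_evidence[:, t - 1] = np.all(v == v[:, :1], axis=1)
        else:
            if out_spikes is not None:
                out_counts += out_spikes.reshape(B, -1)
            guesses[:, t - 1] = np.argmax(out_counts, axis=1)
            no_evidence[:, t - 1] = ~np.any(out_counts != 0, axis=1)

    final_rates = []
    for stage in stages:
        if isinstance(stage, _IFStage):
            final_rates.append(stage.state.rate(config.T).reshape(B, -1))
        elif isinstance(stage, _GateStage):
            final_rates.append(np.zeros((B, stage.n_units())))
        else:
            final_rates.append(stage.softmax.scores())

    last = stages[-1]
    if isinstance(last, _SoftmaxStage):
        final_scores = last.softmax.scores()
    else:
        final_scores = out_counts / config.T

    result = SimResult(
        guesses=guesses,
        no_evidence=no_evidence,
        spikes_per_step=spikes_per_step,
        cum_ops=cum_ops,
        final_rates=final_rates,
        final_scores=final_scores,
        stage_layer_indices=[st.layer_idx for st in stages],
        config=config,
        raster=raster,
    )
    if labels is not None:
        labels = np.asarray(labels, dtype=np.int64)
        result.labels = labels
        result.correct = guesses == labels[:, None]
    return result


def ann_argmax(model: NetworkModel, x: np.ndarray) -> np.ndarray:
    """Reference ANN decision (argmax of the final layer) for an image batch."""
    out = forward(model, x)[-1]
    return np.argmax(out.reshape(out.shape[0], -1), axis=1)
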
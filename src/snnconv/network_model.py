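"""Feed-forward network container, forward evaluation, and exact connectivity.

The network is an ordered list of :class:`LayerSpec` objects operating on
channel-first tensors ``(C, H, W)`` (or flat vectors ``(n,)`` after a
``flatten`` layer).  All indices are 0-based.  ``'same'`` padding pads with
zeros symmetrically, placing the extra pixel on the high side when the total
padding is odd; ``'valid'`` applies no padding.

Besides the forward pass, the module exposes exact per-neuron fan-in and
fan-out counts.  Fan-in under ``'same'`` padding counts only real
(non-padding) connections, since padded positions never carry activations or
spikes; fan-out is the matching transpose quantity, so for every layer pair
``sum(fan_out(l)) == sum(fan_in(l+1))``.

Models serialize to a JSON manifest (structure, hyperparameters) plus an
HDF5 container (exact binary tensors) sharing the same path stem.
"""
from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import h5py
import numpy as np

LAYER_KINDS = (
    "conv2d",
    "dense",
    "avgpool2d",
    "maxpool2d",
    "batchnorm",
    "relu",
    "softmax",
    "flatten",
)
#: Layers carrying trainable weights/biases.
PARAM_KINDS = ("conv2d", "dense")
#: Layers that only reshape or pass values through element-wise; they carry
#: no wiring of their own when connectivity is counted.
TRANSPARENT_KINDS = ("relu", "flatten")


@dataclass
class LayerSpec:
    """One layer of a feed-forward network.

    Only the fields relevant to ``kind`` are populated:

    * ``conv2d``: ``weights`` with shape ``(C_out, C_in, K_h, K_w)``,
      ``bias`` ``(C_out,)``, ``stride``, ``padding``.
    * ``dense``: ``weights`` ``(n_out, n_in)``, ``bias`` ``(n_out,)``.
    * ``avgpool2d`` / ``maxpool2d``: ``pool_size`` (square window, stride
      equal to the window unless ``stride`` is set); no trainable parameters.
    * ``batchnorm``: per-channel (or per-unit) ``gamma``, ``beta``, ``mean``,
      ``std`` with ``std > 0``.
    * ``relu`` / ``softmax`` / ``flatten``: no parameters.
    """

    kind: str
    weights: np.ndarray | None = None
    bias: np.ndarray | None = None
    stride: int | None = None
    padding: str = "same"
    pool_size: int | None = None
    gamma: np.ndarray | None = None
    beta: np.ndarray | None = None
    mean: np.ndarray | None = None
    std: np.ndarray | None = None

    def copy(self) -> "LayerSpec":
        def cp(a):
            return None if a is None else np.array(a, copy=True)

        return LayerSpec(
            kind=self.kind,
            weights=cp(self.weights),
            bias=cp(self.bias),
            stride=self.stride,
            padding=self.padding,
            pool_size=self.pool_size,
            gamma=cp(self.gamma),
            beta=cp(self.beta),
            mean=cp(self.mean),
            std=cp(self.std),
        )


@dataclass
class NetworkModel:
    """Ordered stack of layers plus the input shape ``(C, H, W)`` or ``(n,)``."""

    layers: list[LayerSpec]
    input_shape: tuple[int, ...]

    def __post_init__(self) -> None:
        self.input_shape = tuple(int(s) for s in self.input_shape)
        self.validate()

    # -- structure ---------------------------------------------------------
    @property
    def n_layers(self) -> int:
        return len(self.layers)

    def layer_shapes(self) -> list[tuple[tuple[int, ...], tuple[int, ...]]]:
        """Per-layer ``(input_shape, output_shape)`` (batch axis excluded)."""
        shapes = []
        cur = self.input_shape
        for idx, layer in enumerate(self.layers):
            out = _infer_out_shape(layer, cur, idx)
            shapes.append((cur, out))
            cur = out
        return shapes

    def unit_counts(self) -> list[int]:
        """Number of units ``M^l`` in each layer's output."""
        return [int(np.prod(out)) for _, out in self.layer_shapes()]

    def output_shape(self) -> tuple[int, ...]:
        return self.layer_shapes()[-1][1] if self.layers else self.input_shape

    def copy(self) -> "NetworkModel":
        return NetworkModel([l.copy() for l in self.layers], self.input_shape)

    def validate(self) -> None:
        """Check layer parameter consistency; raise ``ValueError`` on defects."""
        if not self.layers:
            raise ValueError("model has no layers")
        softmax_idx = [i for i, l in enumerate(self.layers) if l.kind == "softmax"]
        if len(softmax_idx) > 1:
            raise ValueError("more than one softmax layer")
        if softmax_idx and softmax_idx[0] != len(self.layers) - 1:
            raise ValueError("softmax must be the final layer")
        for idx, layer in enumerate(self.layers):
            if layer.kind not in LAYER_KINDS:
                raise ValueError(f"layer {idx}: unknown kind {layer.kind!r}")
            for name in ("weights", "bias", "gamma", "beta", "mean", "std"):
                arr = getattr(layer, name)
                if arr is not None and not np.all(np.isfinite(arr)):
                    raise ValueError(f"layer {idx}: non-finite values in {name}")
            if layer.kind == "batchnorm":
                for name in ("gamma", "beta", "mean", "std"):
                    if getattr(layer, name) is None:
                        raise ValueError(f"layer {idx}: batchnorm missing {name}")
                if np.any(np.asarray(layer.std) <= 0):
                    raise ValueError(f"layer {idx}: batchnorm std must be > 0")
            if layer.kind in ("avgpool2d", "maxpool2d"):
                if layer.weights is not None or layer.bias is not None:
                    raise ValueError(f"layer {idx}: pooling carries no parameters")
                if not layer.pool_size or layer.pool_size < 1:
                    raise ValueError(f"layer {idx}: invalid pool size")
            if layer.kind in PARAM_KINDS and layer.weights is None:
                raise ValueError(f"layer {idx}: {layer.kind} requires weights")
        # shape composition doubles as the structural check
        self.layer_shapes()
        if any(n <= 0 for n in self.unit_counts()):
            raise ValueError("all layer unit counts must be positive")


@dataclass
class ActivationStats:
    """Per-layer ANN activation samples gathered on a calibration batch.

    ``samples`` maps the index of each parameterized layer to the flat array
    of its associated activations (post-ReLU when a ReLU follows) over the
    whole batch.  Normalization scales lambda are derived from these via
    :meth:`scale`.
    """

    samples: dict[int, np.ndarray] = field(default_factory=dict)

    def layers(self) -> list[int]:
        return sorted(self.samples)

    def maximum(self, layer: int) -> float:
        return float(np.max(self.samples[layer])) if self.samples[layer].size else 0.0

    def percentile(self, layer: int, p: float, include_zeros: bool = True) -> float:
        """p-th percentile (linear interpolation between order statistics)."""
        a = self.samples[layer]
        if not include_zeros:
            a = a[a != 0]
        if a.size == 0:
            return 0.0
        return float(np.percentile(a, p))

    def scale(
        self,
        layer: int,
        mode: str = "max",
        p: float = 99.9,
        include_zeros: bool = True,
    ) -> float:
        """Normalization scale lambda for ``layer`` under the given mode."""
        if mode == "max":
            return self.maximum(layer)
        if mode == "percentile":
            return self.percentile(layer, p, include_zeros=include_zeros)
        raise ValueError(f"unknown normalization mode {mode!r}")


# ---------------------------------------------------------------------------
# shape inference and padding helpers
# ---------------------------------------------------------------------------

def _pad_1d(size: int, k: int, stride: int, padding: str) -> tuple[int, int]:
    """(low, high) zero padding along one spatial axis."""
    if padding == "valid":
        return 0, 0
    if padding == "same":
        out = -(-size // stride)
        total = max(0, (out - 1) * stride + k - size)
        lo = total // 2
        return lo, total - lo
    raise ValueError(f"unknown padding mode {padding!r}")


def _out_1d(size: int, k: int, stride: int, padding: str) -> int:
    lo, hi = _pad_1d(size, k, stride, padding)
    if size + lo + hi < k:
        raise ValueError(f"kernel size {k} exceeds padded input extent {size + lo + hi}")
    return (size + lo + hi - k) // stride + 1


def _infer_out_shape(layer: LayerSpec, in_shape: tuple[int, ...], idx: int):
    kind = layer.kind
    if kind == "conv2d":
        if len(in_shape) != 3:
            raise ValueError(f"layer {idx}: conv2d needs a (C,H,W) input, got {in_shape}")
        c_out, c_in, kh, kw = layer.weights.shape
        if c_in != in_shape[0]:
            raise ValueError(
                f"layer {idx}: conv2d expects {c_in} input channels, got {in_shape[0]}"
            )
        if layer.bias is not None and layer.bias.shape != (c_out,):
            raise ValueError(f"layer {idx}: bias shape {layer.bias.shape} != ({c_out},)")
        s = layer.stride or 1
        return (
            c_out,
            _out_1d(in_shape[1], kh, s, layer.padding),
            _out_1d(in_shape[2], kw, s, layer.padding),
        )
    if kind == "dense":
        n_out, n_in = layer.weights.shape
        if len(in_shape) != 1 or in_shape[0] != n_in:
            raise ValueError(
                f"layer {idx}: dense expects flat input of {n_in}, got {in_shape}"
            )
        if layer.bias is not None and layer.bias.shape != (n_out,):
            raise ValueError(f"layer {idx}: bias shape {layer.bias.shape} != ({n_out},)")
        return (n_out,)
    if kind in ("avgpool2d", "maxpool2d"):
        if len(in_shape) != 3:
            raise ValueError(f"layer {idx}: pooling needs a (C,H,W) input, got {in_shape}")
        k = layer.pool_size
        s = layer.stride or k
        c, h, w = in_shape
        if h < k or w < k:
            raise ValueError(f"layer {idx}: pool window {k} exceeds input {in_shape}")
        return (c, (h - k) // s + 1, (w - k) // s + 1)
    if kind == "batchnorm":
        n = in_shape[0]
        for name in ("gamma", "beta", "mean", "std"):
            arr = getattr(layer, name)
            if arr is not None and arr.shape != (n,):
                raise ValueError(
                    f"layer {idx}: batchnorm {name} shape {arr.shape} != ({n},)"
                )
        return in_shape
    if kind == "flatten":
        return (int(np.prod(in_shape)),)
    if kind in ("relu", "softmax"):
        return in_shape
    raise ValueError(f"layer {idx}: unknown kind {kind!r}")


# ---------------------------------------------------------------------------
# forward pass
# ---------------------------------------------------------------------------

def conv2d_forward(
    x: np.ndarray, weights: np.ndarray, bias: np.ndarray | None, stride: int, padding: str
) -> np.ndarray:
    """2-D cross-correlation of a ``(B, C, H, W)`` batch with ``(O, C, Kh, Kw)`` kernels."""
    kh, kw = weights.shape[2:]
    pt, pb = _pad_1d(x.shape[2], kh, stride, padding)
    pl, pr = _pad_1d(x.shape[3], kw, stride, padding)
    xp = np.pad(x, ((0, 0), (0, 0), (pt, pb), (pl, pr)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]
    out = np.einsum("bchwuv,ocuv->bohw", win, weights, optimize=True)
    if bias is not None:
        out = out + bias[None, :, None, None]
    return out


def _pool_windows(x: np.ndarray, k: int, stride: int) -> np.ndarray:
    win = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(2, 3))
    return win[:, :, ::stride, ::stride]


def apply_layer(layer: LayerSpec, x: np.ndarray) -> np.ndarray:
    """Evaluate one layer on a batch (first axis = batch)."""
    kind = layer.kind
    if kind == "conv2d":
        return conv2d_forward(x, layer.weights, layer.bias, layer.stride or 1, layer.padding)
    if kind == "dense":
        out = x @ layer.weights.T
        if layer.bias is not None:
            out = out + layer.bias
        return out
    if kind == "avgpool2d":
        return _pool_windows(x, layer.pool_size, layer.stride or layer.pool_size).mean(
            axis=(-2, -1)
        )
    if kind == "maxpool2d":
        return _pool_windows(x, layer.pool_size, layer.stride or layer.pool_size).max(
            axis=(-2, -1)
        )
    if kind == "batchnorm":
        shape = (1, -1) + (1,) * (x.ndim - 2)
        g = layer.gamma.reshape(shape)
        return g * (x - layer.mean.reshape(shape)) / layer.std.reshape(shape) + layer.beta.reshape(shape)
    if kind == "relu":
        return np.maximum(x, 0.0)
    if kind == "flatten":
        return x.reshape(x.shape[0], -1)
    if kind == "softmax":
        z = x - x.max(axis=-1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=-1, keepdims=True)
    raise ValueError(f"unknown layer kind {kind!r}")


def forward(
    model: NetworkModel, x: np.ndarray, check_input: bool = True
) -> list[np.ndarray]:
    """Run the ANN forward pass; return the activation of every layer.

    ``x`` has shape ``(B,) + model.input_shape`` with values in [0, 1]
    (checked unless ``check_input=False``).
    """
    x = np.asarray(x, dtype=float)
    if x.shape[1:] != model.input_shape:
        raise ValueError(
            f"input shape {x.shape[1:]} does not match model input {model.input_shape}"
        )
    if check_input and (x.min() < 0.0 or x.max() > 1.0):
        raise ValueError("input values must lie in [0, 1]")
    activations = []
    cur = x
    for layer in model.layers:
        cur = apply_layer(layer, cur)
        activations.append(cur)
    return activations


# ---------------------------------------------------------------------------
# connectivity: exact fan-in / fan-out
# ---------------------------------------------------------------------------

def _coverage_out(size: int, k: int, stride: int, padding: str) -> np.ndarray:
    """Per output index: number of kernel taps landing inside the real input."""
    lo, _ = _pad_1d(size, k, stride, padding)
    out = _out_1d(size, k, stride, padding)
    cov = np.empty(out, dtype=np.int64)
    for r in range(out):
        s0 = r * stride - lo
        cov[r] = min(s0 + k, size) - max(s0, 0)
    return cov


def _coverage_in(size: int, k: int, stride: int, padding: str) -> np.ndarray:
    """Per input index: number of output positions whose window covers it."""
    lo, _ = _pad_1d(size, k, stride, padding)
    out = _out_1d(size, k, stride, padding)
    cnt = np.zeros(size, dtype=np.int64)
    for r in range(out):
        s0 = r * stride - lo
        cnt[max(s0, 0) : min(s0 + k, size)] += 1
    return cnt


def fan_in_map(model: NetworkModel, layer: int) -> np.ndarray:
    """Exact incoming-connection count for every neuron of ``layer``.

    Returned array has the layer's output shape.  Element-wise layers
    (batchnorm, relu, softmax, flatten) have fan-in 1.
    """
    shapes = model.layer_shapes()
    if not 0 <= layer < model.n_layers:
        raise IndexError(f"layer index {layer} out of range")
    spec = model.layers[layer]
    in_shape, out_shape = shapes[layer]
    if spec.kind == "dense":
        return np.full(out_shape, in_shape[0], dtype=np.int64)
    if spec.kind == "conv2d":
        _, c_in, kh, kw = spec.weights.shape
        s = spec.stride or 1
        cov_h = _coverage_out(in_shape[1], kh, s, spec.padding)
        cov_w = _coverage_out(in_shape[2], kw, s, spec.padding)
        per_pos = np.outer(cov_h, cov_w) * c_in
        return np.broadcast_to(per_pos[None, :, :], out_shape).copy()
    if spec.kind in ("avgpool2d", "maxpool2d"):
        k = spec.pool_size
        s = spec.stride or k
        cov_h = _coverage_out(in_shape[1], k, s, "valid")
        cov_w = _coverage_out(in_shape[2], k, s, "valid")
        per_pos = np.outer(cov_h, cov_w)
        return np.broadcast_to(per_pos[None, :, :], out_shape).copy()
    return np.ones(out_shape, dtype=np.int64)


def fan_in(model: NetworkModel, layer: int, neuron: int) -> int:
    """Fan-in of one neuron (flat index into the layer's output)."""
    fmap = fan_in_map(model, layer).ravel()
    if not 0 <= neuron < fmap.size:
        raise IndexError(f"neuron index {neuron} out of range for layer {layer}")
    return int(fmap[neuron])


def next_wired_layer(model: NetworkModel, layer: int) -> int | None:
    """Index of the next layer with real wiring (relu/flatten are transparent)."""
    for j in range(layer + 1, model.n_layers):
        if model.layers[j].kind not in TRANSPARENT_KINDS:
            return j
    return None


def fan_out_map(model: NetworkModel, layer: int) -> np.ndarray:
    """Exact outgoing-connection count of each neuron of ``layer`` into the
    next wired layer, accounting for stride, padding, and border effects.

    Raises ``ValueError`` when no wired layer follows (last layer).
    """
    shapes = model.layer_shapes()
    if not 0 <= layer < model.n_layers:
        raise IndexError(f"layer index {layer} out of range")
    nxt = next_wired_layer(model, layer)
    if nxt is None:
        raise ValueError(f"layer {layer} has no successor; fan-out undefined")
    out_shape = shapes[layer][1]
    nspec = model.layers[nxt]
    if nspec.kind == "dense":
        return np.full(out_shape, nspec.weights.shape[0], dtype=np.int64)
    if nspec.kind == "conv2d":
        c_out, _, kh, kw = nspec.weights.shape
        s = nspec.stride or 1
        h, w = out_shape[1], out_shape[2]
        cov_h = _coverage_in(h, kh, s, nspec.padding)
        cov_w = _coverage_in(w, kw, s, nspec.padding)
        per_pos = np.outer(cov_h, cov_w) * c_out
        return np.broadcast_to(per_pos[None, :, :], out_shape).copy()
    if nspec.kind in ("avgpool2d", "maxpool2d"):
        k = nspec.pool_size
        s = nspec.stride or k
        h, w = out_shape[1], out_shape[2]
        cov_h = _coverage_in(h, k, s, "valid")
        cov_w = _coverage_in(w, k, s, "valid")
        per_pos = np.outer(cov_h, cov_w)  # channel-preserving
        return np.broadcast_to(per_pos[None, :, :], out_shape).copy()
    # batchnorm / softmax: element-wise wiring
    return np.ones(out_shape, dtype=np.int64)


def fan_out(model: NetworkModel, layer: int, neuron: int) -> int:
    fmap = fan_out_map(model, layer).ravel()
    if not 0 <= neuron < fmap.size:
        raise IndexError(f"neuron index {neuron} out of range for layer {layer}")
    return int(fmap[neuron])


# ---------------------------------------------------------------------------
# serialization: JSON manifest + HDF5 tensor store
# ---------------------------------------------------------------------------

_TENSOR_FIELDS = ("weights", "bias", "gamma", "beta", "mean", "std")
_TENSOR_NAMES = {"weights": "W", "bias": "b", "gamma": "gamma", "beta": "beta",
                 "mean": "mean", "std": "std"}
_FIELD_FOR_NAME = {v: k for k, v in _TENSOR_NAMES.items()}


def _h5_path(manifest_path: str) -> str:
    stem, _ = os.path.splitext(manifest_path)
    return stem + ".h5"


def save_model(model: NetworkModel, path: str) -> None:
    """Write ``path`` (JSON manifest) and the sibling ``.h5`` tensor store."""
    manifest = {"format": "snnconv-model-v1", "input_shape": list(model.input_shape),
                "layers": []}
    with h5py.File(_h5_path(path), "w") as h5:
        for idx, layer in enumerate(model.layers):
            entry: dict = {"kind": layer.kind}
            if layer.kind == "conv2d":
                entry["stride"] = layer.stride or 1
                entry["padding"] = layer.padding
            if layer.kind in ("avgpool2d", "maxpool2d"):
                entry["pool_size"] = layer.pool_size
                entry["stride"] = layer.stride or layer.pool_size
            tensors = []
            for fld in _TENSOR_FIELDS:
                arr = getattr(layer, fld)
                if arr is not None:
                    name = _TENSOR_NAMES[fld]
                    h5.create_dataset(f"layer{idx}/{name}", data=np.asarray(arr))
                    tensors.append(name)
            entry["tensors"] = tensors
            manifest["layers"].append(entry)
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=1)


def load_model(path: str) -> NetworkModel:
    """Load a model saved by :func:`save_model`; validates all invariants."""
    with open(path) as fh:
        manifest = json.load(fh)
    if manifest.get("format") != "snnconv-model-v1":
        raise ValueError(f"{path}: not a recognized model manifest")
    layers = []
    with h5py.File(_h5_path(path), "r") as h5:
        for idx, entry in enumerate(manifest["layers"]):
            kw: dict = {"kind": entry["kind"]}
            if "stride" in entry:
                kw["stride"] = int(entry["stride"])
            if "padding" in entry:
                kw["padding"] = entry["padding"]
            if "pool_size" in entry:
                kw["pool_size"] = int(entry["pool_size"])
            for name in entry.get("tensors", []):
                key = f"layer{idx}/{name}"
                if key not in h5:
                    raise ValueError(f"layer {idx}: tensor {name!r} missing from store")
                kw[_FIELD_FOR_NAME[name]] = h5[key][...]
            layers.append(LayerSpec(**kw))
    try:
        return NetworkModel(layers, tuple(manifest["input_shape"]))
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc
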
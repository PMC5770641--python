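"""Synthetic images and synthetic trained-like networks.

Everything the pipeline needs is generated deterministically from a seed, so
all stages are testable without external datasets:

* :func:`make_images` — class-conditional Gaussian-blob images in [0, 1]
  with balanced labels.  An optional fraction of images carries a saturated
  checkerboard patch: a rare structured texture that plays the role of the
  "singular outlier samples" which inflate the maximum activation of a layer
  far beyond its high percentiles.
* :func:`make_network` — random-weight CNNs whose calibration activations
  are mostly in [0, 1] (per-layer scales are calibrated on a probe batch at
  generation time), optionally with batch-norm layers and with an
  injectable fraction of high-gain checkerboard kernels that respond
  strongly only to the rare patch texture (heavy-tailed activations).
* :func:`make_classifier_fixture` — a prototype-matching network (weights
  set analytically from the class templates, no gradient training) with
  above-chance accuracy on its own batch, used for end-to-end SNN-vs-ANN
  agreement experiments.
* :func:`binarynet_cifar10` — the 9-parameterized-layer CIFAR-10
  architecture (six 3x3 convolutions of 128/128/256/256/512/512 channels
  with 2x2 max-pooling after layers 2, 4, 6, then dense 1024/1024/10) used
  for operation counting.
"""
from __future__ import annotations

import numpy as np

from .conversion import _stat_activation_index
from .network_model import LayerSpec, NetworkModel, forward

#: 3x3 alternating-sign pattern used both for outlier textures in images and
#: for the matching high-gain kernels in networks.
_CHECKER = np.array([[1.0, -1.0, 1.0], [-1.0, 1.0, -1.0], [1.0, -1.0, 1.0]])


def class_centers(n_classes: int, height: int, width: int) -> np.ndarray:
    """Blob centers, one per class, evenly spaced on a circle of radius
    0.28*min(H, W) around the image center (documented layout used by the
    blob-statistics checks)."""
    cy, cx = (height - 1) / 2.0, (width - 1) / 2.0
    rad = 0.28 * min(height, width)
    ang = 2.0 * np.pi * np.arange(n_classes) / n_classes
    centers = np.stack([cy + rad * np.sin(ang), cx + rad * np.cos(ang)], axis=1)
    return np.round(centers).astype(int)


def _gaussian_2d(height, width, cy, cx, sigma):
    y = np.arange(height)[:, None]
    x = np.arange(width)[None, :]
    return np.exp(-((y - cy) ** 2 + (x - cx) ** 2) / (2.0 * sigma**2))


def make_images(
    n: int,
    shape: tuple[int, int, int] = (1, 12, 12),
    n_classes: int = 4,
    seed: int = 0,
    noise: float = 0.08,
    amplitude: float = 0.9,
    blob_sigma: float = 1.6,
    jitter: int = 1,
    outlier_fraction: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic labeled batch of [0, 1] blob images.

    Labels are balanced (class ``i % n_classes`` before shuffling).  Each
    image is a Gaussian blob of the given amplitude/width at its class
    center, jittered by up to ``jitter`` pixels per axis, plus clipped
    Gaussian noise.  ``outlier_fraction`` of the images additionally get a
    saturated 3x3 checkerboard patch at a random position.
    Returns ``(images, labels)`` with ``images.shape == (n,) + shape``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    c, h, w = shape
    if c < 1 or h < 6 or w < 6:
        raise ValueError(f"invalid image shape {shape}")
    rng = np.random.default_rng(seed)
    centers = class_centers(n_classes, h, w)
    labels = rng.permutation(np.arange(n) % n_classes)
    images = np.empty((n, c, h, w))
    for i in range(n):
        cy, cx = centers[labels[i]] + rng.integers(-jitter, jitter + 1, size=2)
        blob = amplitude * _gaussian_2d(h, w, cy, cx, blob_sigma)
        img = blob[None, :, :] + rng.normal(0.0, noise, size=(c, h, w))
        images[i] = np.clip(img, 0.0, 1.0)
    n_out = int(round(outlier_fraction * n))
    if n_out > 0:
        patch = np.where(_CHECKER > 0, 1.0, 0.0)
        for i in rng.choice(n, size=n_out, replace=False):
            py = int(rng.integers(0, h - 3))
            px = int(rng.integers(0, w - 3))
            images[i, :, py : py + 3, px : px + 3] = patch
    return images, labels


# ---------------------------------------------------------------------------
# random trained-like networks
# ---------------------------------------------------------------------------

DEFAULT_ARCH = (
    ("conv2d", 6, 3),
    "relu",
    ("maxpool2d", 2),
    ("conv2d", 8, 3),
    "relu",
    "flatten",
    ("dense", 4),
    "softmax",
)


def _rand_bn(rng, n):
    return LayerSpec(
        kind="batchnorm",
        gamma=rng.uniform(0.5, 1.5, n),
        beta=rng.uniform(-0.3, 0.3, n),
        mean=rng.uniform(-0.5, 0.5, n),
        std=rng.uniform(0.5, 2.0, n),
    )


def make_network(
    arch=DEFAULT_ARCH,
    input_shape: tuple[int, ...] = (1, 12, 12),
    seed: int = 0,
    weight_scale: float = 1.0,
    outlier_fraction: float = 0.0,
    outlier_gain: float = 5.0,
    with_batchnorm: bool = False,
    calibrate: bool = True,
) -> NetworkModel:
    """Random-weight CNN from an architecture spec, seed-deterministic.

    ``arch`` entries: ``("conv2d", out_channels, kernel)``,
    ``("dense", units)``, ``("avgpool2d", k)``, ``("maxpool2d", k)``,
    ``"relu"``, ``"flatten"``, ``"softmax"``.  With ``with_batchnorm`` a
    random batch-norm layer is inserted directly after every conv/dense
    layer.  With ``calibrate`` each parameterized layer (or its batch-norm)
    is rescaled so the 99th percentile of its post-ReLU activations on a
    probe blob batch is 0.8, keeping calibration activations mostly in
    [0, 1].

    ``outlier_fraction`` > 0 overwrites ``max(1, round(f * W.size / 9))``
    kernel slices of the first convolution with the ``outlier_gain``-scaled
    checkerboard pattern after calibration.  Those kernels respond weakly to
    smooth blobs but strongly to the rare checkerboard texture of
    ``make_images(outlier_fraction=...)`` samples, producing the heavy
    activation tail (max far above the 99.9th percentile) that robust
    normalization is designed to resist.
    """
    rng = np.random.default_rng(seed)
    layers: list[LayerSpec] = []
    cur = tuple(input_shape)
    for entry in arch:
        kind = entry if isinstance(entry, str) else entry[0]
        if kind == "conv2d":
            _, c_out, k = entry
            c_in = cur[0]
            std = weight_scale / np.sqrt(k * k * c_in)
            layers.append(
                LayerSpec(
                    kind="conv2d",
                    weights=rng.normal(0.0, std, (c_out, c_in, k, k)),
                    bias=rng.normal(0.0, 0.05, c_out),
                    stride=1,
                    padding="same",
                )
            )
            cur = (c_out, cur[1], cur[2])
            if with_batchnorm:
                layers.append(_rand_bn(rng, c_out))
        elif kind == "dense":
            _, units = entry
            n_in = int(np.prod(cur))
            if len(cur) > 1:
                layers.append(LayerSpec(kind="flatten"))
                cur = (n_in,)
            std = weight_scale / np.sqrt(n_in)
            layers.append(
                LayerSpec(
                    kind="dense",
                    weights=rng.normal(0.0, std, (units, n_in)),
                    bias=rng.normal(0.0, 0.05, units),
                )
            )
            cur = (units,)
            if with_batchnorm:
                layers.append(_rand_bn(rng, units))
        elif kind in ("avgpool2d", "maxpool2d"):
            _, k = entry
            layers.append(LayerSpec(kind=kind, pool_size=k))
            cur = (cur[0], (cur[1] - k) // k + 1, (cur[2] - k) // k + 1)
        elif kind == "flatten":
            layers.append(LayerSpec(kind="flatten"))
            cur = (int(np.prod(cur)),)
        elif kind in ("relu", "softmax"):
            layers.append(LayerSpec(kind=kind))
        else:
            raise ValueError(f"unknown architecture entry {entry!r}")
    model = NetworkModel(layers, tuple(input_shape))
    if calibrate:
        _calibrate_scales(model, input_shape, seed)
    if outlier_fraction > 0:
        first_conv = next(l for l in model.layers if l.kind == "conv2d")
        w = first_conv.weights
        n_slices = max(1, int(round(outlier_fraction * w.size / 9.0)))
        c_out, c_in, kh, kw = w.shape
        if kh < 3 or kw < 3:
            raise ValueError("outlier injection needs kernels of at least 3x3")
        for _ in range(n_slices):
            o = int(rng.integers(0, c_out))
            ci = int(rng.integers(0, c_in))
            w[o, ci, :3, :3] = outlier_gain * _CHECKER
    return model


def _calibrate_scales(model, input_shape, seed, target=0.8, p=99.0):
    """Rescale each parameterized layer (via its batch-norm when present) so
    that the p-th percentile of its associated activation equals ``target``
    on a probe batch; done in layer order so upstream scaling is respected."""
    probe, _ = make_images(64, shape=input_shape, seed=seed + 1)
    param_idx = [i for i, l in enumerate(model.layers) if l.kind in ("conv2d", "dense")]
    for idx in param_idx:
        acts = forward(model, probe)
        a = acts[_stat_activation_index(model, idx)]
        level = np.percentile(a, p)
        if level <= 1e-12:
            continue
        c = target / level
        layer = model.layers[idx]
        follower = model.layers[idx + 1] if idx + 1 < model.n_layers else None
        if follower is not None and follower.kind == "batchnorm":
            follower.gamma = follower.gamma * c
            follower.beta = follower.beta * c
        else:
            layer.weights = layer.weights * c
            if layer.bias is not None:
                layer.bias = layer.bias * c


def random_architecture(rng: np.random.Generator):
    """Small random conv/pool/dense architecture for round-trip and folding
    tests (always ends in a dense layer + softmax)."""
    arch: list = []
    n_conv = int(rng.integers(1, 3))
    for _ in range(n_conv):
        arch += [("conv2d", int(rng.integers(2, 6)), int(rng.choice([3, 5]))), "relu"]
    if rng.random() < 0.5:
        arch.append((str(rng.choice(["maxpool2d", "avgpool2d"])), 2))
    arch += [("dense", int(rng.integers(3, 8))), "softmax"]
    return tuple(arch)


# ---------------------------------------------------------------------------
# analytic prototype-matching classifier
# ---------------------------------------------------------------------------

def make_classifier_fixture(
    seed: int = 0,
    n: int = 60,
    shape: tuple[int, int, int] = (1, 12, 12),
    n_classes: int = 4,
    noise: float = 0.08,
    amplitude: float = 0.9,
    blob_sigma: float = 1.6,
    outlier_gain: float = 0.0,
    outlier_fraction: float = 0.0,
):
    """Prototype-matching CNN plus a labeled batch it classifies well.

    The network is conv(5x5, matched Gaussian filters) -> ReLU ->
    maxpool(2x2) -> flatten -> dense(position templates) -> softmax, with all
    weights set analytically from the class templates (no gradient
    training).  With ``outlier_gain`` > 0 a decoy checkerboard channel with
    that gain is appended to the convolution; its downstream dense weights
    are zero, so ANN decisions are unchanged, but rare checkerboard-patch
    samples (``outlier_fraction`` of the batch) drive its activations far
    above the rest of the layer — an outlier-bearing fixture for comparing
    max-norm against robust percentile normalization.

    Returns ``(model, images, labels)``.
    """
    c_img, h, w = shape
    images, labels = make_images(
        n, shape=shape, n_classes=n_classes, seed=seed, noise=noise,
        amplitude=amplitude, blob_sigma=blob_sigma,
        outlier_fraction=outlier_fraction,
    )
    centers = class_centers(n_classes, h, w)

    # conv templates: matched filter at native width plus one broader filter
    k = 5
    g_narrow = _gaussian_2d(k, k, 2, 2, blob_sigma)
    g_broad = _gaussian_2d(k, k, 2, 2, 1.5 * blob_sigma)
    scale = amplitude * np.sum(g_narrow * g_narrow)
    kernels = [g_narrow / scale, g_broad / (amplitude * np.sum(g_broad * g_narrow))]
    n_decoy = 1 if outlier_gain > 0 else 0
    c_out = len(kernels) + n_decoy
    conv_w = np.zeros((c_out, c_img, k, k))
    for o, kern in enumerate(kernels):
        conv_w[o, :, :, :] = kern
    if n_decoy:
        conv_w[-1, :, 1:4, 1:4] = outlier_gain * _CHECKER
    conv_b = np.full(c_out, -0.2)
    if n_decoy:
        conv_b[-1] = 0.0

    ph, pw = h // 2, w // 2
    dense_w = np.zeros((n_classes, c_out * ph * pw))
    for cls in range(n_classes):
        row = np.zeros((c_out, ph, pw))
        for o, gain in zip(range(len(kernels)), (1.0, 0.5)):
            row[o] = gain * _gaussian_2d(ph, pw, centers[cls, 0] / 2.0,
                                         centers[cls, 1] / 2.0, 1.0)
        dense_w[cls] = 3.0 * row.ravel() / row.sum()
    layers = [
        LayerSpec(kind="conv2d", weights=conv_w, bias=conv_b, stride=1, padding="same"),
        LayerSpec(kind="relu"),
        LayerSpec(kind="maxpool2d", pool_size=2),
        LayerSpec(kind="flatten"),
        LayerSpec(kind="dense", weights=dense_w, bias=np.zeros(n_classes)),
        LayerSpec(kind="softmax"),
    ]
    model = NetworkModel(layers, shape)
    return model, images, labels


# ---------------------------------------------------------------------------
# architecture catalog for operation counting
# ---------------------------------------------------------------------------

def binarynet_cifar10() -> NetworkModel:
    """The CIFAR-10 architecture with six 'same'-padded stride-1 3x3
    convolutions (128, 128, 256, 256, 512, 512 channels), 2x2 max-pooling
    after convolutions 2, 4 and 6, and dense layers of 1024, 1024 and 10
    units.  Weights are zero-filled: the model exists for connectivity and
    operation counting, not for inference."""
    layers: list[LayerSpec] = []
    c_in = 3
    for i, c_out in enumerate([128, 128, 256, 256, 512, 512]):
        layers.append(
            LayerSpec(
                kind="conv2d",
                weights=np.zeros((c_out, c_in, 3, 3), dtype=np.float32),
                bias=np.zeros(c_out, dtype=np.float32),
                stride=1,
                padding="same",
            )
        )
        layers.append(LayerSpec(kind="relu"))
        if i % 2 == 1:
            layers.append(LayerSpec(kind="maxpool2d", pool_size=2))
        c_in = c_out
    layers.append(LayerSpec(kind="flatten"))
    n_in = 512 * 4 * 4
    for units in (1024, 1024, 10):
        layers.append(
            LayerSpec(
                kind="dense",
                weights=np.zeros((units, n_in), dtype=np.float32),
                bias=np.zeros(units, dtype=np.float32),
            )
        )
        layers.append(LayerSpec(kind="relu"))
        n_in = units
    layers.pop()  # no ReLU after the final 10-unit layer
    return NetworkModel(layers, (3, 32, 32))
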
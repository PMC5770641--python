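"""Shared fixtures and independent oracles.

The connectivity oracle builds explicit boolean connection matrices by
nested loops over output positions and kernel taps — deliberately naive and
separate from the analytic coverage arithmetic in the package — so fan-in,
fan-out and synaptic-operation counts can be checked against brute force.
"""
import numpy as np
import pytest

from snnconv import fixtures
from snnconv.network_model import (
    NetworkModel,
    _pad_1d,
    next_wired_layer,
)


@pytest.fixture
def rng():
    return np.random.default_rng(7)


@pytest.fixture(scope="session")
def classifier():
    """Prototype-matching classifier and its labeled batch (clean)."""
    return fixtures.make_classifier_fixture(seed=0, n=60)


@pytest.fixture(scope="session")
def outlier_classifier():
    """Classifier fixture with a decoy checkerboard channel and rare
    checkerboard-patch samples: heavy-tailed first-layer activations."""
    return fixtures.make_classifier_fixture(
        seed=1, n=60, outlier_gain=4.0, outlier_fraction=0.05
    )


def connectivity_matrix(model: NetworkModel, layer: int) -> np.ndarray:
    """Boolean (n_out, n_in) connection matrix of one layer, built by loops."""
    in_shape, out_shape = model.layer_shapes()[layer]
    spec = model.layers[layer]
    n_in, n_out = int(np.prod(in_shape)), int(np.prod(out_shape))
    C = np.zeros((n_out, n_in), dtype=bool)
    if spec.kind == "dense":
        C[:, :] = True
        return C
    if spec.kind == "conv2d":
        c_out, c_in, kh, kw = spec.weights.shape
        s = spec.stride or 1
        lo_h, _ = _pad_1d(in_shape[1], kh, s, spec.padding)
        lo_w, _ = _pad_1d(in_shape[2], kw, s, spec.padding)
        for o in range(c_out):
            for r in range(out_shape[1]):
                for c in range(out_shape[2]):
                    oi = (o * out_shape[1] + r) * out_shape[2] + c
                    for ci in range(c_in):
                        for u in range(kh):
                            for v in range(kw):
                                y, x = r * s - lo_h + u, c * s - lo_w + v
                                if 0 <= y < in_shape[1] and 0 <= x < in_shape[2]:
                                    C[oi, (ci * in_shape[1] + y) * in_shape[2] + x] = True
        return C
    if spec.kind in ("avgpool2d", "maxpool2d"):
        k = spec.pool_size
        s = spec.stride or k
        for ch in range(out_shape[0]):
            for r in range(out_shape[1]):
                for c in range(out_shape[2]):
                    oi = (ch * out_shape[1] + r) * out_shape[2] + c
                    for u in range(k):
                        for v in range(k):
                            y, x = r * s + u, c * s + v
                            if y < in_shape[1] and x < in_shape[2]:
                                C[oi, (ch * in_shape[1] + y) * in_shape[2] + x] = True
        return C
    # element-wise layers: identity wiring
    assert n_in == n_out
    return np.eye(n_in, dtype=bool)


def instrumented_synaptic_ops(model: NetworkModel, result) -> np.ndarray:
    """Brute-force synaptic-operation counter: replays the recorded raster
    through explicit connection matrices and counts every postsynaptic state
    update a spike causes.  Returns cumulative counts (B, T)."""
    B, T = result.guesses.shape
    ops = np.zeros((B, T), dtype=np.int64)
    for s, layer_idx in enumerate(result.stage_layer_indices):
        nxt = next_wired_layer(model, layer_idx)
        if nxt is None:
            continue
        C = connectivity_matrix(model, nxt)
        per_input_updates = C.sum(axis=0)  # updates caused by one spike of input j
        raster = np.abs(result.raster[s])  # (B, T, n)
        ops += raster.astype(np.int64) @ per_input_updates
    return np.cumsum(ops, axis=1)
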
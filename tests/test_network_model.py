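"""Forward pass, connectivity counts, and model serialization."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import connectivity_matrix
from snnconv import fixtures
from snnconv.network_model import (
    LayerSpec,
    NetworkModel,
    fan_in,
    fan_in_map,
    fan_out,
    fan_out_map,
    forward,
    load_model,
    save_model,
)


def dense_net(W, b, relu=True):
    layers = [LayerSpec("dense", weights=np.asarray(W, float), bias=np.asarray(b, float))]
    if relu:
        layers.append(LayerSpec("relu"))
    return NetworkModel(layers, (np.asarray(W).shape[1],))


def naive_conv2d(x, W, b, stride, padding):
    """Nested-loop convolution oracle (single image, channel-first)."""
    from snnconv.network_model import _out_1d, _pad_1d

    c_out, c_in, kh, kw = W.shape
    H, Wd = x.shape[1], x.shape[2]
    lo_h, _ = _pad_1d(H, kh, stride, padding)
    lo_w, _ = _pad_1d(Wd, kw, stride, padding)
    Ho, Wo = _out_1d(H, kh, stride, padding), _out_1d(Wd, kw, stride, padding)
    out = np.zeros((c_out, Ho, Wo))
    for o in range(c_out):
        for r in range(Ho):
            for c in range(Wo):
                acc = b[o]
                for ci in range(c_in):
                    for u in range(kh):
                        for v in range(kw):
                            y, xx = r * stride - lo_h + u, c * stride - lo_w + v
                            if 0 <= y < H and 0 <= xx < Wd:
                                acc += W[o, ci, u, v] * x[ci, y, xx]
                out[o, r, c] = acc
    return out


class TestForward:
    def test_single_dense_layer_relu(self):
        net = dense_net([[1.0, -1.0]], [0.0])
        acts = forward(net, np.array([[0.5, 0.2]]))
        assert np.allclose(acts[-1], [[0.3]])

    def test_zero_weights_nonpositive_bias_silent(self):
        net = dense_net(np.zeros((3, 4)), [-0.1, 0.0, -2.0])
        acts = forward(net, np.random.default_rng(0).uniform(0, 1, (5, 4)))
        assert np.all(acts[-1] == 0.0)

    @pytest.mark.parametrize("padding,stride", [("same", 1), ("valid", 1), ("same", 2)])
    def test_conv_matches_nested_loop_oracle(self, padding, stride):
        rng = np.random.default_rng(7)
        W1 = rng.normal(size=(3, 1, 3, 3))
        W2 = rng.normal(size=(2, 3, 3, 3))
        net = NetworkModel(
            [
                LayerSpec("conv2d", weights=W1, bias=rng.normal(size=3),
                          stride=stride, padding=padding),
                LayerSpec("relu"),
                LayerSpec("conv2d", weights=W2, bias=rng.normal(size=2),
                          stride=1, padding=padding),
            ],
            (1, 8, 8),
        )
        x, _ = fixtures.make_images(1, shape=(1, 8, 8), seed=7)
        acts = forward(net, x)
        ref1 = np.maximum(naive_conv2d(x[0], W1, net.layers[0].bias, stride, padding), 0)
        ref2 = naive_conv2d(ref1, W2, net.layers[2].bias, 1, padding)
        assert np.allclose(acts[1][0], ref1, atol=1e-6)
        assert np.allclose(acts[2][0], ref2, atol=1e-6)

    def test_relu_nonnegative_softmax_normalized(self, classifier):
        model, x, _ = classifier
        acts = forward(model, x)
        assert np.all(acts[1] >= 0)  # ReLU output
        assert np.allclose(acts[-1].sum(axis=1), 1.0, atol=1e-9)

    def test_shape_mismatch_rejected(self):
        net = dense_net([[1.0, -1.0]], [0.0])
        with pytest.raises(ValueError, match="shape"):
            forward(net, np.zeros((1, 3)))

    def test_out_of_range_input_rejected(self):
        net = dense_net([[1.0, -1.0]], [0.0])
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            forward(net, np.array([[1.5, 0.0]]))

    def test_nan_parameters_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            dense_net([[np.nan, 1.0]], [0.0])

    @settings(deadline=None, max_examples=20)
    @given(st.integers(1, 5), st.integers(1, 5), st.integers(0, 2**31 - 1))
    def test_dense_stack_equals_matmul_chain(self, n_in, n_mid, seed):
        rng = np.random.default_rng(seed)
        W1, W2 = rng.normal(size=(n_mid, n_in)), rng.normal(size=(2, n_mid))
        b1, b2 = rng.normal(size=n_mid), rng.normal(size=2)
        net = NetworkModel(
            [LayerSpec("dense", weights=W1, bias=b1), LayerSpec("relu"),
             LayerSpec("dense", weights=W2, bias=b2)],
            (n_in,),
        )
        x = rng.uniform(0, 1, (3, n_in))
        out = forward(net, x)[-1]
        ref = np.maximum(x @ W1.T + b1, 0) @ W2.T + b2
        assert np.allclose(out, ref, atol=1e-9)


class TestConnectivity:
    def test_dense_fan_in(self):
        net = dense_net(np.ones((5, 10)), np.zeros(5))
        assert all(fan_in(net, 0, i) == 10 for i in range(5))

    def test_conv_interior_fan_in(self):
        net = NetworkModel(
            [LayerSpec("conv2d", weights=np.zeros((2, 8, 3, 3)),
                       bias=np.zeros(2), stride=1, padding="same")],
            (8, 6, 6),
        )
        fmap = fan_in_map(net, 0)
        assert fmap[0, 3, 3] == 72  # 3*3*8 in the interior
        assert fmap[0, 0, 0] == 2 * 2 * 8  # cropped corner

    def test_dense_chain_fan_out(self):
        net = NetworkModel(
            [LayerSpec("dense", weights=np.ones((3, 4)), bias=np.zeros(3)),
             LayerSpec("relu"),
             LayerSpec("dense", weights=np.ones((5, 3)), bias=np.zeros(5))],
            (4,),
        )
        assert all(fan_out(net, 0, i) == 5 for i in range(3))

    def test_conv_conv_interior_fan_out(self):
        net = NetworkModel(
            [LayerSpec("conv2d", weights=np.zeros((4, 1, 3, 3)), bias=np.zeros(4),
                       stride=1, padding="same"),
             LayerSpec("relu"),
             LayerSpec("conv2d", weights=np.zeros((64, 4, 3, 3)), bias=np.zeros(64),
                       stride=1, padding="same")],
            (1, 8, 8),
        )
        assert fan_out_map(net, 0)[0, 4, 4] == 576  # 3*3*64

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_fan_maps_match_connectivity_oracle(self, seed):
        rng = np.random.default_rng(seed)
        model = fixtures.make_network(
            fixtures.random_architecture(rng), seed=seed, calibrate=False
        )
        for l in range(model.n_layers):
            C = connectivity_matrix(model, l)
            assert np.array_equal(fan_in_map(model, l).ravel(), C.sum(axis=1))
            from snnconv.network_model import next_wired_layer

            nxt = next_wired_layer(model, l)
            if nxt is not None:
                Cn = connectivity_matrix(model, nxt)
                fout = fan_out_map(model, l).ravel()
                assert np.array_equal(fout, Cn.sum(axis=0))
                # transpose identity: total outgoing = total incoming
                assert fout.sum() == fan_in_map(model, nxt).sum()

    def test_fan_out_of_last_layer_errors(self):
        net = dense_net(np.ones((2, 3)), np.zeros(2), relu=False)
        with pytest.raises(ValueError, match="no successor"):
            fan_out(net, 0, 0)

    def test_neuron_index_out_of_range(self):
        net = dense_net(np.ones((2, 3)), np.zeros(2), relu=False)
        with pytest.raises(IndexError):
            fan_in(net, 0, 99)


class TestSerialization:
    def test_round_trip_is_bit_exact(self, tmp_path, rng):
        model = fixtures.make_network(seed=5, with_batchnorm=True, calibrate=False)
        path = str(tmp_path / "m.json")
        save_model(model, path)
        loaded = load_model(path)
        assert loaded.input_shape == model.input_shape
        for a, b in zip(model.layers, loaded.layers):
            assert a.kind == b.kind
            for fld in ("weights", "bias", "gamma", "beta", "mean", "std"):
                va, vb = getattr(a, fld), getattr(b, fld)
                assert (va is None) == (vb is None)
                if va is not None:
                    assert np.array_equal(va, vb)

    def test_zero_std_batchnorm_rejected(self, tmp_path):
        model = fixtures.make_network(seed=5, with_batchnorm=True, calibrate=False)
        for layer in model.layers:
            if layer.kind == "batchnorm":
                layer.std = layer.std.copy()
                layer.std[0] = 1.0
        path = str(tmp_path / "m.json")
        save_model(model, path)
        import h5py

        with h5py.File(path[:-5] + ".h5", "r+") as h5:
            for key in h5:
                if "std" in h5[key]:
                    h5[key]["std"][0] = 0.0
                    break
        with pytest.raises(ValueError, match="std"):
            load_model(path)

    def test_inconsistent_shapes_rejected_with_layer_index(self):
        with pytest.raises(ValueError, match="layer 2"):
            NetworkModel(
                [LayerSpec("dense", weights=np.ones((3, 4)), bias=np.zeros(3)),
                 LayerSpec("relu"),
                 LayerSpec("dense", weights=np.ones((5, 7)), bias=np.zeros(5))],
                (4,),
            )

    def test_misplaced_softmax_rejected(self):
        with pytest.raises(ValueError, match="softmax"):
            NetworkModel(
                [LayerSpec("softmax"),
                 LayerSpec("dense", weights=np.ones((2, 2)), bias=np.zeros(2))],
                (2,),
            )
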
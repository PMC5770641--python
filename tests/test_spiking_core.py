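"""Integrate-and-fire dynamics, gated max-pooling, spiking softmax."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from snnconv.spiking_core import (
    MaxPoolGate,
    SimConfig,
    SpikingSoftmax,
    SpikingState,
    if_step,
    layer_input_currents,
    signed_spike_step,
    step_layer,
)


def trace(z_seq, v_thr=1.0, reset="subtract", signed=False):
    v = np.zeros(1)
    out = []
    for z in z_seq:
        v, s = if_step(v, np.array([z]), v_thr=v_thr, reset=reset, signed=signed)
        out.append((float(v[0]), float(s[0])))
    return out


class TestIFStep:
    def test_zero_input_never_spikes(self):
        tr = trace([0.0] * 10)
        assert all(v == 0.0 and s == 0.0 for v, s in tr)

    def test_half_charge_spikes_every_second_step(self):
        tr = trace([0.5] * 6, reset="subtract")
        spikes = [s for _, s in tr]
        assert spikes == [0, 1, 0, 1, 0, 1]
        # rate at even steps is exactly the input
        assert sum(spikes[:4]) / 4 == 0.5

    def test_reset_to_zero_discards_residual(self):
        # z=0.3: V reaches 1.2 at step 4, resets to 0, residual 0.2 lost
        tr = trace([0.3] * 12, reset="zero")
        spikes = [s for _, s in tr]
        assert spikes == [0, 0, 0, 1] * 3
        assert sum(spikes) / 12 == 0.25
        assert tr[3][0] == 0.0  # V back to zero after the spike

    def test_superthreshold_input_emits_single_spike_keeps_residual(self):
        tr = trace([2.5], reset="subtract")
        assert tr[0] == (1.5, 1.0)

    def test_tie_at_threshold_fires(self):
        tr = trace([1.0], reset="subtract")
        assert tr[0] == (0.0, 1.0)

    def test_reset_by_subtraction_conserves_charge(self):
        # V(t) = t*z - N(t)*V_thr at every step, for a dyadic grid of inputs
        z = np.array([k / 64 for k in range(0, 65, 4)])
        v = np.zeros_like(z)
        n = np.zeros_like(z)
        for t in range(1, 200):
            v, s = if_step(v, z)
            n += s
            assert np.allclose(v, t * z - n, atol=1e-9)

    @settings(deadline=None, max_examples=30)
    @given(st.integers(0, 2**31 - 1), st.integers(5, 60))
    def test_rate_bound_for_random_inputs(self, seed, T):
        rng = np.random.default_rng(seed)
        v = np.zeros(8)
        n = np.zeros(8)
        for t in range(1, T + 1):
            v, s = if_step(v, rng.uniform(-0.5, 1.5, 8))
            n += s
            assert np.all(0 <= n / t) and np.all(n / t <= 1.0)

    def test_optional_floor_clamps_membrane(self):
        v, _ = if_step(np.zeros(1), np.array([-5.0]), v_floor=0.0)
        assert v[0] == 0.0


class TestSignedSpikes:
    def test_negative_charge_mirror_rate(self):
        tr = trace([-0.5] * 6, signed=True)
        assert [s for _, s in tr] == [0, -1, 0, -1, 0, -1]

    def test_zero_input_silent(self):
        assert all(s == 0 for _, s in trace([0.0] * 5, signed=True))

    def test_alternating_input_nets_to_zero(self):
        tr = trace([1.0, -1.0], signed=True)
        assert [s for _, s in tr] == [1, -1]
        assert tr[-1][0] == 0.0

    def test_state_wrapper_accumulates_signed_counts(self):
        state = SpikingState.zeros(1)
        cfg = SimConfig(signed_spikes=True)
        for _ in range(4):
            signed_spike_step(state, np.array([-0.5]), cfg)
        assert state.n_spikes[0] == -2


class TestInputCurrents:
    def test_bias_drives_constant_current_without_spikes(self):
        z = layer_input_currents(np.zeros(3), np.zeros((2, 3)), np.array([0.2, 0.0]))
        assert np.allclose(z, [0.2, 0.0])

    def test_single_spike_through_weight(self):
        z = layer_input_currents(np.array([0.0, 1.0]), np.array([[0.1, 0.7]]))
        assert np.allclose(z, [0.7])

    def test_sparse_spikes_match_dense_matvec(self, rng):
        W = rng.normal(size=(6, 20))
        b = rng.normal(size=6)
        spikes = (rng.random(20) < 0.2).astype(float)
        z = layer_input_currents(spikes, W, b, v_thr=1.3)
        assert np.allclose(z, 1.3 * (W @ spikes + b), atol=1e-12)

    def test_threshold_scales_currents(self):
        z = layer_input_currents(np.ones(1), np.array([[0.5]]), v_thr=2.0)
        assert z[0] == 1.0


class TestMaxPoolGate:
    def test_passes_the_faster_input(self):
        gate = MaxPoolGate((1, 2, 2), pool_size=2)
        rng = np.random.default_rng(0)
        out_count = 0
        in_counts = np.zeros(4)
        rates = np.array([0.8, 0.2, 0.1, 0.05])
        for t in range(1, 201):
            spikes = (rng.random(4) < rates).astype(float).reshape(1, 1, 2, 2)
            in_counts += spikes.ravel()
            out_count += gate.step(spikes)[0, 0, 0, 0]
        # long-run output rate tracks the maximally firing input; a handful of
        # early steps may pass spikes of a transient leader
        assert abs(out_count - in_counts[0]) <= 5

    def test_silent_inputs_silent_output(self):
        gate = MaxPoolGate((1, 2, 2), pool_size=2)
        for _ in range(5):
            out = gate.step(np.zeros((1, 1, 2, 2)))
            assert np.all(out == 0)

    def test_tie_breaks_to_lowest_index(self):
        gate = MaxPoolGate((1, 2, 2), pool_size=2)
        # seed history so that after this step's update the running counts of
        # neurons 0 and 1 are tied at 2 while only neuron 1 spikes now
        gate.counts = np.array([2.0, 1.0, 0.0, 0.0]).reshape(1, 1, 2, 2)
        gate.t = 2
        out = gate.step(np.array([0.0, 1.0, 0.0, 0.0]).reshape(1, 1, 2, 2))
        # lowest-index winner (neuron 0) is gated through, and it is silent
        assert out[0, 0, 0, 0] == 0.0

    def test_windowed_estimator_tracks_rate_switch(self):
        gate = MaxPoolGate((1, 2, 2), pool_size=2, window=10)
        # neuron 0 fires for 30 steps, then neuron 1 takes over
        for t in range(60):
            spikes = np.zeros((1, 1, 2, 2))
            spikes[0, 0, 0, 1 if t >= 30 else 0] = 1.0
            out = gate.step(spikes)
        assert out[0, 0, 0, 0] == 1.0  # gate switched to the new leader


class TestSpikingSoftmax:
    def test_equal_potentials_spike_uniformly(self):
        sm = SpikingSoftmax(4, "potential_rate")
        rngs = [np.random.default_rng(0)]
        counts = np.zeros(4)
        for _ in range(10_000):
            counts += sm.step(np.zeros((1, 4)), rngs)[0]
        _, pval = sps.chisquare(counts)
        assert pval > 0.01

    @pytest.mark.parametrize("variant", ["external_clock", "potential_rate"])
    def test_dominant_potential_wins(self, variant):
        sm = SpikingSoftmax(3, variant)
        rngs = [np.random.default_rng(1)]
        counts = np.zeros(3)
        z = np.array([[5.0, 0.1, 0.1]])
        counts += sm.step(z, rngs)[0]
        for _ in range(999):
            counts += sm.step(np.zeros((1, 3)), rngs)[0]
        assert np.argmax(counts) == 0

    def test_potential_readout_immediate(self):
        sm = SpikingSoftmax(3, "potential_readout")
        assert sm.step(np.array([[1.0, 2.0, 3.0]]), [None]) is None
        assert np.argmax(sm.scores()[0]) == 2

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError, match="variant"):
            SpikingSoftmax(3, "magic")


class TestClampedStep:
    def test_clamped_layer_holds_potential_and_stays_silent(self):
        state = SpikingState.zeros(2)
        cfg = SimConfig()
        spikes = step_layer(state, np.array([5.0, 5.0]), cfg, clamped=True)
        assert np.all(spikes == 0) and np.all(state.v == 0)
        spikes = step_layer(state, np.array([5.0, 5.0]), cfg, clamped=False)
        assert np.all(spikes == 1)
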
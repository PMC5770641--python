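"""Time-stepped integrate-and-fire dynamics and spiking layer variants.

The neuron model is a simple non-leaky integrate-and-fire unit: the membrane
potential V accumulates the input current z(t) each step and a spike is
emitted when ``V(t-1) + z(t) >= V_thr`` (ties at exactly V_thr fire).  Two
reset rules are supported:

* ``reset="zero"`` — V is set back to 0 on a spike, discarding the residual
  charge above threshold (information loss; the steady-state rate falls short
  of the target activation).
* ``reset="subtract"`` — V_thr is subtracted on a spike, conserving the
  residual so that for constant input the exact bookkeeping
  ``V(t) = t*z - N(t)*V_thr`` holds at every step and the cumulative rate
  converges to the target activation.

With ``signed_spikes`` a mirror threshold at -V_thr lets a neuron emit
spikes of size -1 (used for networks whose activations take values in
{-1, +1}); at most one event is emitted per neuron per step in all modes.

Also provided are the spiking counterparts of max-pooling (a gate that
forwards only the spikes of the input with the highest running rate
estimate) and softmax (three variants operating on accumulated membrane
potentials).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

RESET_MODES = ("subtract", "zero")
ENCODINGS = ("constant_current", "poisson")
SOFTMAX_VARIANTS = ("external_clock", "potential_rate", "potential_readout")


@dataclass
class SimConfig:
    """All simulation knobs.

    Parameters
    ----------
    dt : simulation time step; the maximum rate is ``r_max = 1/dt``.
    T : number of time steps each input is presented for.
    v_thr : firing threshold (> 0).
    reset : ``"subtract"`` (reset by subtraction) or ``"zero"`` (reset to zero).
    encoding : ``"constant_current"`` (analog inputs as constant currents) or
        ``"poisson"`` (pixels emit Poisson spike trains with rate x*r_max).
    clamp_d : slope of the membrane-clamp schedule; spiking layer l is held
        at V=0 and silent for the first ``d*l`` steps (0 disables clamping).
    softmax_variant : behavior of the output softmax layer.
    signed_spikes : enable the second threshold at -V_thr.
    v_floor : optional lower clamp on the membrane potential (None = none).
    poisson_clock_rate : expected ticks per step of the external softmax clock.
    maxpool_window : FIR window length of the max-pool gate's rate estimate
        (None = full-history running average N(t)/t).
    seed : master seed; per-image streams are derived as seed + image index.
    """

    dt: float = 1.0
    T: int = 200
    v_thr: float = 1.0
    reset: str = "subtract"
    encoding: str = "constant_current"
    clamp_d: int = 0
    softmax_variant: str = "potential_readout"
    signed_spikes: bool = False
    v_floor: float | None = None
    poisson_clock_rate: float = 1.0
    maxpool_window: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.T < 1:
            raise ValueError("T must be >= 1")
        if self.v_thr <= 0:
            raise ValueError("v_thr must be > 0")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.reset not in RESET_MODES:
            raise ValueError(f"unknown reset mode {self.reset!r}")
        if self.encoding not in ENCODINGS:
            raise ValueError(f"unknown input encoding {self.encoding!r}")
        if self.softmax_variant not in SOFTMAX_VARIANTS:
            raise ValueError(f"unknown softmax variant {self.softmax_variant!r}")
        if self.clamp_d < 0:
            raise ValueError("clamp_d must be >= 0")

    @property
    def r_max(self) -> float:
        return 1.0 / self.dt


@dataclass
class SpikingState:
    """Per-layer spiking state: membrane potentials, cumulative spike counts,
    and the derived rate estimate ``r(t) = N(t)/t``."""

    v: np.ndarray
    n_spikes: np.ndarray

    @classmethod
    def zeros(cls, shape) -> "SpikingState":
        return cls(np.zeros(shape), np.zeros(shape))

    def rate(self, t: int) -> np.ndarray:
        return self.n_spikes / max(t, 1)


def if_step(
    v: np.ndarray,
    z: np.ndarray,
    v_thr: float = 1.0,
    reset: str = "subtract",
    signed: bool = False,
    v_floor: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """One integrate-and-fire update; returns ``(v_new, spikes)``.

    ``spikes`` is float-valued in {0, 1} (or {-1, 0, 1} when ``signed``).
    Inputs larger than V_thr in a single step still emit a single spike; the
    surplus is carried forward under reset-by-subtraction.
    """
    v_new = v + z
    if signed:
        spikes = (v_new >= v_thr).astype(float) - (v_new <= -v_thr).astype(float)
        v_new = v_new - v_thr * spikes
    else:
        spikes = (v_new >= v_thr).astype(float)
        if reset == "zero":
            v_new = np.where(spikes > 0, 0.0, v_new)
        elif reset == "subtract":
            v_new = v_new - v_thr * spikes
        else:
            raise ValueError(f"unknown reset mode {reset!r}")
    if v_floor is not None:
        v_new = np.maximum(v_new, v_floor)
    return v_new, spikes


def step_layer(
    state: SpikingState,
    z: np.ndarray,
    config: SimConfig,
    clamped: bool = False,
) -> np.ndarray:
    """Advance one spiking layer by one step, updating ``state`` in place.

    While ``clamped`` the membrane potential is held at 0 and no spikes are
    emitted (the input is discarded, not buffered).
    """
    if clamped:
        state.v[...] = 0.0
        return np.zeros_like(state.v)
    state.v, spikes = if_step(
        state.v, z, v_thr=config.v_thr, reset=config.reset,
        signed=config.signed_spikes, v_floor=config.v_floor,
    )
    state.n_spikes += spikes
    return spikes


def signed_spike_step(
    state: SpikingState, z: np.ndarray, config: SimConfig
) -> np.ndarray:
    """Two-threshold update emitting +1 above V_thr and -1 below -V_thr."""
    state.v, spikes = if_step(state.v, z, v_thr=config.v_thr, signed=True)
    state.n_spikes += spikes
    return spikes


def layer_input_currents(
    spikes: np.ndarray,
    weights: np.ndarray,
    bias: np.ndarray | None = None,
    v_thr: float = 1.0,
) -> np.ndarray:
    """Input current ``z = V_thr * (W @ spikes + b)`` for a dense layer.

    The bias contributes a constant current every step, independent of
    presynaptic spiking.  ``spikes`` may be a single vector ``(n_in,)`` or a
    batch ``(B, n_in)``.
    """
    z = spikes @ weights.T
    if bias is not None:
        z = z + bias
    return v_thr * z


class MaxPoolGate:
    """Gated spiking max-pooling.

    Each output unit forwards, at every step, the current spike of the input
    neuron in its pooling window whose running firing-rate estimate is
    highest (ties go to the lowest index); spikes of all other inputs are
    discarded.  The estimate is the full-history running average ``N(t)/t``
    by default, or a moving average over the last ``window`` steps.
    """

    def __init__(
        self,
        in_shape: tuple[int, int, int],
        pool_size: int,
        stride: int | None = None,
        window: int | None = None,
    ) -> None:
        self.in_shape = in_shape
        self.k = pool_size
        self.stride = stride or pool_size
        self.window = window
        self.counts = np.zeros((1,) + tuple(in_shape))
        self.t = 0
        self._ring: list[np.ndarray] = []

    def _estimate(self) -> np.ndarray:
        if self.window is None:
            return self.counts / max(self.t, 1)
        hist = self._ring[-self.window:]
        return sum(hist) / max(len(hist), 1)

    def step(self, spikes: np.ndarray) -> np.ndarray:
        """Update the rate estimates with ``spikes`` (B,C,H,W) and gate them."""
        self.t += 1
        mag = np.abs(spikes)
        if self.counts.shape[0] != spikes.shape[0]:
            self.counts = np.zeros_like(spikes)
        self.counts = self.counts + mag
        if self.window is not None:
            self._ring.append(mag)
            if len(self._ring) > self.window:
                self._ring.pop(0)
        est = self._estimate()
        est_win = _windows(est, self.k, self.stride)
        spk_win = _windows(spikes, self.k, self.stride)
        flat_est = est_win.reshape(est_win.shape[:4] + (-1,))
        flat_spk = spk_win.reshape(spk_win.shape[:4] + (-1,))
        winner = np.argmax(flat_est, axis=-1)  # argmax takes the first max
        return np.take_along_axis(flat_spk, winner[..., None], axis=-1)[..., 0]


def _windows(x: np.ndarray, k: int, stride: int) -> np.ndarray:
    win = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(2, 3))
    return win[:, :, ::stride, ::stride]


def softmax_probabilities(v: np.ndarray) -> np.ndarray:
    z = v - v.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


class SpikingSoftmax:
    """Output softmax on accumulated membrane potentials.

    The neurons never fire on their own; they integrate their input current
    into V.  Spike generation depends on the variant:

    * ``external_clock`` — a Poisson clock (``clock_rate`` expected ticks per
      step) triggers a winner-take-all draw from ``softmax(V)``; exactly one
      neuron spikes per tick.
    * ``potential_rate`` — every neuron spikes independently as a Bernoulli
      event with per-step probability ``softmax(V)_i``.
    * ``potential_readout`` — no spikes; the classification is read directly
      from ``softmax(V)``.
    """

    def __init__(self, n: int, variant: str, clock_rate: float = 1.0,
                 dt: float = 1.0) -> None:
        if variant not in SOFTMAX_VARIANTS:
            raise ValueError(f"unknown softmax variant {variant!r}")
        self.n = n
        self.variant = variant
        self.clock_rate = clock_rate
        self.dt = dt
        self.v = np.zeros((1, n))

    def step(self, z: np.ndarray, rngs: list[np.random.Generator]) -> np.ndarray | None:
        """Accumulate currents ``z`` (B, n); return spikes or None (readout)."""
        if self.v.shape[0] != z.shape[0]:
            self.v = np.zeros_like(z)
        self.v = self.v + z
        if self.variant == "potential_readout":
            return None
        probs = softmax_probabilities(self.v)
        spikes = np.zeros_like(self.v)
        if self.variant == "potential_rate":
            for i, rng in enumerate(rngs):
                spikes[i] = (rng.random(self.n) < probs[i]).astype(float)
        else:  # external_clock
            p_tick = min(1.0, self.clock_rate * self.dt)
            for i, rng in enumerate(rngs):
                if rng.random() < p_tick:
                    spikes[i, rng.choice(self.n, p=probs[i])] = 1.0
        return spikes

    def scores(self) -> np.ndarray:
        return softmax_probabilities(self.v)
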
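"""Closed-form firing-rate predictions for rate-coded IF neurons.

For a neuron driven by the constant charge ``z = V_thr * a`` (``a`` the ANN
activation), averaging the membrane recursion over time gives the cumulative
rate at step t:

* reset by subtraction::

      r(t) = a * r_max - V(t) / (t * V_thr)

  an unbiased approximation whose only error, the residual-membrane term,
  vanishes as 1/t.

* reset to zero::

      r(t) = a * r_max * V_thr / (V_thr + eps) - V(t) / (t * (V_thr + eps))

  where spikes occur every ``n = ceil(V_thr / z)`` steps and the threshold
  is overshot by the constant excess ``eps = n*z - V_thr`` which is
  discarded at each reset, leaving a persistent rate deficit.

For higher layers (reset by subtraction) the rate is the weighted sum of
presynaptic rates plus the bias rate, minus the same residual term::

    r^l = W^l r^{l-1} + r_max * b^l - V^l(t) / (t * V_thr)

so quantization errors of earlier layers propagate and accumulate with depth.

:func:`quantized_latency` gives the worst-case number of steps needed for the
cumulative rate N(t)/t to *exactly* equal an activation value drawn from a
quantization grid: for a = p/q in lowest terms this is t = q, hence 10 steps
for the {0, 0.1, ..., 1.0} grid and 2**16 steps for a 16-bit grid.
"""
from __future__ import annotations

from fractions import Fraction
from math import ceil

import numpy as np


def predict_rate_first_layer(
    a,
    v_thr: float = 1.0,
    t: int | None = None,
    v_t=0.0,
    mode: str = "subtract",
    dt: float = 1.0,
):
    """Predicted cumulative rate of a first-layer neuron with activation ``a``.

    ``v_t`` is the membrane potential at step ``t`` (pass the simulated value
    for an exact prediction, or 0 with ``t=None`` for the steady state).
    ``a`` may be a scalar or array; activations must be >= 0.
    """
    a = np.asarray(a, dtype=float)
    if np.any(a < 0):
        raise ValueError("activations must be nonnegative")
    r_max = 1.0 / dt
    v_t = np.asarray(v_t, dtype=float)
    resid = 0.0 if t is None else v_t / t
    if mode == "subtract":
        return a * r_max - resid / v_thr
    if mode == "zero":
        z = v_thr * a
        z_safe = np.where(z > 0, z, 1.0)
        n = np.ceil(v_thr / z_safe)
        eps = np.where(z > 0, n * z_safe - v_thr, 0.0)
        return np.where(
            z > 0, a * r_max * v_thr / (v_thr + eps) - resid / (v_thr + eps), 0.0
        )
    raise ValueError(f"unknown reset mode {mode!r}")


def predict_rate_higher_layer(
    weights: np.ndarray,
    r_prev: np.ndarray,
    bias: np.ndarray | None = None,
    v_t=0.0,
    t: int | None = None,
    v_thr: float = 1.0,
    dt: float = 1.0,
) -> np.ndarray:
    """Predicted rates ``r^l = W r^{l-1} + r_max b - V(t)/(t V_thr)`` for a
    reset-by-subtraction layer driven by presynaptic rates ``r_prev``."""
    r_max = 1.0 / dt
    r = r_prev @ np.asarray(weights).T
    if bias is not None:
        r = r + r_max * np.asarray(bias)
    if t is not None:
        r = r - np.asarray(v_t, dtype=float) / (t * v_thr)
    return r


def reset_to_zero_excess(a: float, v_thr: float = 1.0) -> tuple[int, float]:
    """Inter-spike interval n and discarded excess charge eps for constant
    input ``z = v_thr * a`` under reset to zero (``a`` in (0, 1])."""
    if not 0 < a <= 1:
        raise ValueError("a must lie in (0, 1]")
    z = v_thr * a
    n = ceil(v_thr / z)
    return n, n * z - v_thr


def _as_fraction(level) -> Fraction:
    # floats are taken at their exact binary value; pass Fraction or a
    # decimal string for grids such as {0, 0.1, ..., 1.0}
    f = Fraction(level) if not isinstance(level, Fraction) else level
    if not 0 <= f <= 1:
        raise ValueError(f"level {level} outside [0, 1]")
    return f


def exact_representation_time(level, method: str = "closed_form",
                              t_max: int = 10**6) -> int:
    """Earliest step t at which N(t)/t exactly equals ``level`` for a
    reset-by-subtraction neuron with V_thr = 1 and constant input z = level.

    With exact arithmetic ``N(t) = floor(t * a)``, so N(t)/t = a requires
    t*a to be an integer; the earliest such t is the denominator of a in
    lowest terms (1 for a = 0).  ``method="simulate"`` verifies this by
    stepping the neuron with rational arithmetic.
    """
    a = _as_fraction(level)
    if method == "closed_form":
        return 1 if a == 0 else a.denominator
    if method == "simulate":
        v = Fraction(0)
        n = 0
        for t in range(1, t_max + 1):
            v += a
            if v >= 1:
                v -= 1
                n += 1
            if Fraction(n, t) == a:
                return t
        raise RuntimeError(f"no exact representation within {t_max} steps")
    raise ValueError(f"unknown method {method!r}")


def quantized_latency(levels, method: str = "closed_form") -> int:
    """Worst-case exact-representation time over a set of activation levels.

    Returns ``max`` over the levels of :func:`exact_representation_time`; for
    the grid ``{k/q : k=0..q}`` this is q.
    """
    levels = list(levels)
    if not levels:
        raise ValueError("no levels given")
    return max(exact_representation_time(lv, method=method) for lv in levels)
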
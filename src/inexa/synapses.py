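"""Discrete-time Tsodyks-Markram (TM) presynaptic resource dynamics.

Every synapse tracks the fraction ``x`` of neurotransmitter resources
available in the terminal and the fraction ``u`` of those resources ready
for release.  A presynaptic spike at the start of a bin recruits an extra
increment ``U*`` of the non-ready resources, releases ``RR`` into the
cleft, and the synaptic weight for the next bin is proportional to that
released fraction.  Gliotransmitter bound at the presynaptic terminal
shifts ``U*`` between the synapse's basal release fraction and the
astrocytic set point ``alpha`` (potentiating whenever alpha exceeds
y_base / Y_max, which holds for the default parameters).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["TMParams", "update_tm", "synaptic_weight", "release_increment"]


@dataclass(frozen=True)
class TMParams:
    """TM rate constants and weight bounds (rates in 1/s)."""

    omega_d: float = 4.0405   # recovery rate of synaptic vesicles
    omega_f: float = 2.0      # decay rate of the ready-for-release fraction
    y_max_plus: float = 0.7   # upper bound of excitatory weights
    y_max_minus: float = -0.7  # lower bound of inhibitory weights
    alpha: float = 0.7        # gliotransmission set point for U*

    def __post_init__(self) -> None:
        if self.omega_d <= 0 or self.omega_f <= 0:
            raise ValueError("TM rates must be positive")
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must lie in (0, 1]")


def update_tm(x_prev, u_prev, u_star, s, params: TMParams, dt: float):
    """One synchronous TM step; returns (x, u, RR).

    With ``s`` the presynaptic spike indicator for this bin:

        RR = x_prev * [(1 - u_prev) U* s + u_prev] * s
        u  = [(1 - u_prev) U* s + u_prev] * exp(-Omega_f dt)
        x  = (x_prev - RR) + [1 - (x_prev - RR)] * (1 - exp(-Omega_d dt))

    All quantities stay in [0, 1] for inputs in [0, 1].
    """
    x_prev = np.asarray(x_prev, dtype=float)
    u_prev = np.asarray(u_prev, dtype=float)
    u_star = np.asarray(u_star, dtype=float)
    s = np.asarray(s, dtype=float)
    bump = (1.0 - u_prev) * u_star * s + u_prev
    rr = x_prev * bump * s
    u = bump * np.exp(-params.omega_f * dt)
    x_rem = x_prev - rr
    x = x_rem + (1.0 - x_rem) * (1.0 - np.exp(-params.omega_d * dt))
    return x, u, rr


def synaptic_weight(rr, y_max):
    """Weight proportional to the released fraction: y = Y_max * RR (the
    sign of Y_max carries the excitatory/inhibitory sign)."""
    return np.asarray(y_max, dtype=float) * np.asarray(rr, dtype=float)


def release_increment(y_base, y_max, g, alpha: float):
    """Release increment U* modulated by bound gliotransmitter receptors.

    U* = (y_base / Y_max) (1 - g) + alpha g.  Naked synapses have g = 0
    identically, so their U* is the constant y_base / Y_max.
    """
    y_max = np.asarray(y_max, dtype=float)
    if np.any(y_max == 0):
        raise ValueError("y_max must be non-zero")
    g = np.asarray(g, dtype=float)
    return (np.asarray(y_base, dtype=float) / y_max) * (1.0 - g) + alpha * g
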
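"""Local astrocytic IP3/calcium dynamics at enwrapped synapses.

Each tripartite synapse owns a "local area" of its astrocyte with
normalized IP3 and Ca2+ concentrations in [0, 1].  Glutamate released by
the presynaptic terminal (the TM released fraction RR) drives IP3, which
otherwise degrades exponentially; calcium relaxes slowly toward IP3
(amplitude-modulated encoding).  When calcium crosses the release
threshold from below, a gliotransmission event binds a fraction of the
free presynaptic receptors; the bound fraction then recovers at the slow
rate Omega_g.  While the owning astrocyte is in its active state the local
IP3 is clamped to 1, which keeps calcium above threshold and thereby
latches gliotransmission (no new release events until the astrocyte
deactivates and calcium falls below threshold again).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "LocalParams",
    "update_ip3",
    "update_calcium",
    "update_gliotransmitter",
]


@dataclass(frozen=True)
class LocalParams:
    omega_ip3: float = 152.3   # IP3 degradation rate, 1/s
    omega_acc: float = 0.05    # per-bin IP3 -> Ca accumulation gain
    ca_th: float = 0.1         # calcium threshold for gliotransmitter release
    g_r: float = 0.3           # fraction of unbound receptors recruited per event
    omega_g: float = 0.077     # receptor recovery rate, 1/s

    def __post_init__(self) -> None:
        if self.omega_ip3 <= 0 or self.omega_acc <= 0 or self.omega_g <= 0:
            raise ValueError("rates must be positive")
        if not 0 < self.ca_th < 1 or not 0 < self.g_r < 1:
            raise ValueError("ca_th and g_r must lie in (0, 1)")


def update_ip3(ip3_prev, rr, params: LocalParams, dt: float, forced=False):
    """Exponential IP3 degradation refilled toward 1 by synaptic release.

    ip3 = ip3_prev e^(-W dt) + (1 - ip3_prev e^(-W dt)) RR, or clamped to 1
    while the owning astrocyte is active (``forced``).
    """
    decayed = np.asarray(ip3_prev, dtype=float) * np.exp(-params.omega_ip3 * dt)
    driven = decayed + (1.0 - decayed) * np.asarray(rr, dtype=float)
    return np.where(forced, 1.0, driven)


def update_calcium(ca_prev, ip3, omega_acc: float):
    """One-bin relaxation of calcium toward the local IP3 level."""
    ca_prev = np.asarray(ca_prev, dtype=float)
    return ca_prev + omega_acc * (np.asarray(ip3, dtype=float) - ca_prev)


def update_gliotransmitter(g_prev, ca_prev, ca, params: LocalParams, dt: float):
    """Receptor binding on an upward calcium threshold crossing, otherwise
    pure exponential recovery.

    The crossing condition is strict on both sides (ca_prev < th < ca), so
    calcium sitting above threshold produces no further release events.
    """
    g_prev = np.asarray(g_prev, dtype=float)
    decay = np.exp(-params.omega_g * dt)
    crossing = (np.asarray(ca_prev, dtype=float) < params.ca_th) \
        & (params.ca_th < np.asarray(ca, dtype=float))
    released = (g_prev + (1.0 - g_prev) * params.g_r) * decay
    return np.where(crossing, released, g_prev * decay)
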
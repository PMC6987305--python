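"""Stochastic spiking of the neuronal population.

Each neuron carries a constant background-noise drive ``c_i`` drawn from a
triangular distribution on [0, C_max].  In every 5 ms bin its firing
propensity is the rectified sum of the noise, the signed synaptic inputs
from neurons that spiked in the previous bin, and a depressing term for
every presynaptic terminal currently enwrapped by an active astrocyte
(adenosine release).  A spike is then emitted as the single-event outcome
of an inhomogeneous Poisson process, so at most one spike can occur per
bin.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "draw_noise_rates",
    "firing_rate",
    "spike_probability",
    "sample_spikes",
]


def draw_noise_rates(n: int, c_max: float, rng: np.random.Generator) -> np.ndarray:
    """Per-neuron basal noise, triangular on [0, C_max] with mode C_max/2."""
    if c_max < 0:
        raise ValueError("c_max must be non-negative")
    if c_max == 0:
        return np.zeros(n)
    return rng.triangular(0.0, c_max / 2.0, c_max, size=n)


def firing_rate(c, synaptic_input, active_enwrapped=0, y_astro: float = 0.0):
    """Rectified firing propensity of a neuron.

    lambda = max(0, c + synaptic_input - y_astro * active_enwrapped)

    ``synaptic_input`` is the sum of y_ij * s_j over presynaptic partners
    (spikes from the previous bin, weights as recomputed after that bin);
    ``active_enwrapped`` counts the presynaptic synapses of this neuron
    whose astrocyte was active in the previous bin.
    """
    lam = np.asarray(c, dtype=float) + np.asarray(synaptic_input, dtype=float) \
        - y_astro * np.asarray(active_enwrapped, dtype=float)
    return np.maximum(0.0, lam)


def spike_probability(lam, dt: float):
    """Probability of exactly one Poisson event in a bin: exp(-l*dt)*l*dt.

    Peaks at exp(-1) for lam*dt = 1; multi-spike bins are neglected.
    """
    lam = np.asarray(lam, dtype=float)
    if np.any(lam < 0):
        raise ValueError("rates must be non-negative")
    x = lam * dt
    return np.exp(-x) * x


def sample_spikes(p, rng: np.random.Generator) -> np.ndarray:
    """Independent Bernoulli spike draws, one per neuron."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("spike probabilities must lie in [0, 1]")
    return rng.random(p.shape) < p
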
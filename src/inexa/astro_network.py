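"""Whole-cell astrocyte dynamics: the three-state UAR model on the
gap-junction network.

Every astrocyte is either dormant (U), active (A) or refractory (R).  An
active astrocyte splits a unit of IP3 flux among its non-active
gap-junction neighbours (propagation efficiency beta = 1/I_a); a dormant
astrocyte integrates that neighbour input together with the calcium
collected by its local areas into an activation propensity gamma, and can
activate once gamma exceeds a threshold that grows linearly with its
number of neighbours.  Activation, deactivation and recovery are
memoryless with time constants tau_A, tau_R, tau_U.  While active, an
astrocyte clamps the IP3 of all its local areas to 1 and exerts an
adenosine-mediated depression y_Astro on every enwrapped synapse.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "U", "A", "R",
    "UARParams",
    "propagation_efficiency",
    "activation_threshold",
    "activation_propensity",
    "update_states",
    "depression_counts",
]

# state encoding
U, A, R = 0, 1, 2


@dataclass(frozen=True)
class UARParams:
    b0: float = 0.02       # slope of the activation threshold in n_a
    b1: float = 0.205      # intercept of the activation threshold
    tau_a: float = 1.5     # s, mean waiting time of the U -> A transition
    tau_r: float = 7.0     # s, mean dwell time in the active state
    tau_u: float = 5.0     # s, mean dwell time in the refractory state
    m: float = 5.0         # scaling of the pooled local calcium input
    y_astro: float = 0.01  # depressing signal applied by active astrocytes

    def __post_init__(self) -> None:
        if min(self.b0, self.b1, self.tau_a, self.tau_r, self.tau_u,
               self.m, self.y_astro) <= 0:
            raise ValueError("all UAR parameters must be positive")


def propagation_efficiency(states: np.ndarray,
                           adjacency: np.ndarray) -> np.ndarray:
    """beta_a = 1 / I_a for active astrocytes, where I_a counts gap-coupled
    neighbours not currently active; 0 for non-active cells and when every
    neighbour is already active (no cell left to receive the signal)."""
    states = np.asarray(states)
    active = states == A
    degrees = adjacency.sum(axis=1)
    inactive_nbrs = degrees - adjacency @ active.astype(float)
    beta = np.zeros(len(states))
    ok = active & (inactive_nbrs > 0)
    beta[ok] = 1.0 / inactive_nbrs[ok]
    return beta


def activation_threshold(n_a, b0: float = 0.02, b1: float = 0.205):
    """theta = b0 * n_a + b1, linear in the gap-junction neighbour count."""
    return b0 * np.asarray(n_a, dtype=float) + b1


def activation_propensity(theta, neighbor_beta_sum, ca_sum, n_syn, m: float):
    """gamma = theta * sum(beta of neighbours) + M * (sum of local Ca) / N.

    N is the number of excitatory synapses enwrapped by the astrocyte; the
    calcium term vanishes for astrocytes without enwrapped synapses.
    """
    n_syn = np.asarray(n_syn, dtype=float)
    ca_term = np.divide(np.asarray(ca_sum, dtype=float), n_syn,
                        out=np.zeros_like(n_syn, dtype=float),
                        where=n_syn > 0)
    return np.asarray(theta, dtype=float) \
        * np.asarray(neighbor_beta_sum, dtype=float) + m * ca_term


def update_states(states: np.ndarray, gamma, theta, params: UARParams,
                  dt: float, rng: np.random.Generator) -> np.ndarray:
    """Synchronous probabilistic state transitions, one draw per astrocyte.

    U -> A with probability dt/tau_A when gamma > theta, A -> R with
    dt/tau_R, R -> U with dt/tau_U.  Transitions are evaluated against the
    incoming state, so a freshly activated cell cannot also deactivate in
    the same bin.
    """
    states = np.asarray(states)
    draw = rng.random(len(states))
    new = states.copy()
    new[(states == U) & (np.asarray(gamma) > np.asarray(theta))
        & (draw < dt / params.tau_a)] = A
    new[(states == A) & (draw < dt / params.tau_r)] = R
    new[(states == R) & (draw < dt / params.tau_u)] = U
    return new


def depression_counts(post: np.ndarray, synapse_astrocyte: np.ndarray,
                      states: np.ndarray, n_neurons: int) -> np.ndarray:
    """Number of presynaptic synapses of each neuron whose enwrapping
    astrocyte is currently active (multiplied by y_Astro this is the
    adenosine depression entering the firing rate)."""
    enwrapped = synapse_astrocyte >= 0
    if not np.any(enwrapped):
        return np.zeros(n_neurons)
    active = np.asarray(states)[synapse_astrocyte[enwrapped]] == A
    return np.bincount(post[enwrapped][active],
                       minlength=n_neurons).astype(float)
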
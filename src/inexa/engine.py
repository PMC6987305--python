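"""Simulation engine: scenario configuration and the synchronous update loop.

The model advances on a fixed 5 ms grid.  Within one bin the order is:
(1) firing propensities from the previous bin's spikes, weights and
astrocyte states; (2) Bernoulli spike draws; (3) TM resource update and
weight recomputation, with the release increment U* taken from the
previous bin's bound-receptor fraction; (4) local IP3/Ca2+/receptor
updates, with IP3 clamped for active astrocytes; (5) UAR propagation and
state transitions.

The noise drive c_i, the synaptic weights y_ij and the astrocytic
depression y_Astro are dimensionless per-bin spike expectations: the
rectified sum lambda enters the single-event Poisson probability as
lambda * e^(-lambda).  Equivalently, the instantaneous rate in 1/s is
lambda / dt.  This is the only reading under which the published network
regimes (noise-driven quiescence punctuated by synaptically amplified
population bursts that recruit the astrocytes) are attainable with the
default parameter set.

Four scenarios form a ladder of increasing astrocytic involvement:

* ``noise_only`` - unconnected neurons, background noise only;
* ``nn_only``    - recurrent neuronal network with TM synapses, no astrocytes;
* ``nn_psa``     - astrocyte processes enwrap excitatory presynapses and
  provide gliotransmission, but no gap-junction propagation (beta = 0) and
  no adenosine depression (y_Astro = 0);
* ``nn_a``       - the full coupled model.

Three noise levels times (noise_only + nn_only + nn_psa + three astrocyte
densities of nn_a) enumerate the 18 standard scenarios.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .astro_local import LocalParams, update_calcium, update_gliotransmitter, update_ip3
from .astro_network import (A, R, U, UARParams, activation_propensity,
                            activation_threshold, propagation_efficiency,
                            update_states)
from .neurons import draw_noise_rates, sample_spikes, spike_probability
from .synapses import TMParams, release_increment, synaptic_weight, update_tm
from .topology import (AstrocytePopulation, CultureGeometry, CultureTopology,
                       NeuronPopulation, assign_synapses_to_astrocytes,
                       build_gap_junctions, build_neuron_network, place_cells)

__all__ = [
    "SCENARIOS",
    "SimulationConfig",
    "SimulationResult",
    "build_scenario",
    "enumerate_scenarios",
    "build_topology",
    "simulate",
    "run_experiment",
    "parameter_sweep",
]

SCENARIOS = ("noise_only", "nn_only", "nn_psa", "nn_a")

# spawn keys of the named RNG streams derived from the master seed
_KEY_TOPOLOGY = 0   # neuron placement, connectivity, base weights
_KEY_NOISE = 1      # per-neuron noise draws
_KEY_ASTRO = 2      # astrocyte placement + synapse assignment (per run)
_KEY_SPIKES = 3     # Bernoulli spike draws (per run)
_KEY_UAR = 4        # astrocyte state transitions (per run)


def stream(seed: int, *key: int) -> np.random.Generator:
    """Independent, reproducible RNG stream identified by a spawn key."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


@dataclass(frozen=True)
class SimulationConfig:
    scenario: str = "nn_a"
    c_max: float = 0.02
    n_astrocytes: int = 107
    n_neurons: int = 250
    n_excitatory: int = 200
    t_total: float = 300.0
    dt: float = 0.005
    n_runs: int = 5
    seed: int = 0
    geometry: CultureGeometry = field(default_factory=CultureGeometry)
    tm: TMParams = field(default_factory=TMParams)
    local: LocalParams = field(default_factory=LocalParams)
    uar: UARParams = field(default_factory=UARParams)
    astro_init: str = "active"
    store_astro_states: bool = False
    monitor_synapses: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if self.astro_init not in ("active", "dormant"):
            raise ValueError("astro_init must be 'active' or 'dormant'")
        if self.dt <= 0 or self.t_total <= 0:
            raise ValueError("dt and t_total must be positive")
        if self.n_excitatory > self.n_neurons:
            raise ValueError("n_excitatory cannot exceed n_neurons")
        if self.scenario in ("noise_only", "nn_only") and self.n_astrocytes != 0:
            raise ValueError(f"{self.scenario} does not place astrocytes")

    # scenario switches -----------------------------------------------------
    @property
    def use_synapses(self) -> bool:
        return self.scenario != "noise_only"

    @property
    def use_astro_processes(self) -> bool:
        return self.scenario in ("nn_psa", "nn_a")

    @property
    def use_astro_network(self) -> bool:
        return self.scenario == "nn_a"

    @property
    def use_adenosine(self) -> bool:
        return self.scenario == "nn_a"

    @property
    def n_steps(self) -> int:
        return int(round(self.t_total / self.dt))

    def to_json(self, path) -> None:
        payload = dataclasses.asdict(self)
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def build_scenario(name: str, c_max: float,
                   astrocyte_count: int | None = None,
                   **overrides) -> SimulationConfig:
    """Configuration for one rung of the scenario ladder."""
    if name not in SCENARIOS:
        raise ValueError(f"unknown scenario {name!r}")
    if astrocyte_count is None:
        astrocyte_count = {"noise_only": 0, "nn_only": 0,
                           "nn_psa": 107, "nn_a": 107}[name]
    if name in ("noise_only", "nn_only"):
        astrocyte_count = 0
    return SimulationConfig(scenario=name, c_max=c_max,
                            n_astrocytes=astrocyte_count, **overrides)


def enumerate_scenarios(**overrides) -> list[SimulationConfig]:
    """The 18 standard scenarios: 3 noise levels x (noise_only, nn_only,
    nn_psa, and nn_a at three astrocyte densities)."""
    configs = []
    for c_max in (0.01, 0.02, 0.03):
        configs.append(build_scenario("noise_only", c_max, **overrides))
        configs.append(build_scenario("nn_only", c_max, **overrides))
        configs.append(build_scenario("nn_psa", c_max, **overrides))
        for count in (28, 63, 107):
            configs.append(build_scenario("nn_a", c_max, count, **overrides))
    return configs


# ---------------------------------------------------------------------------
# topology instantiation
# ---------------------------------------------------------------------------

def build_neuron_population(config: SimulationConfig) -> NeuronPopulation:
    rng = stream(config.seed, _KEY_TOPOLOGY)
    positions = place_cells(config.n_neurons, config.geometry.extent,
                            config.geometry.min_neuron_dist, rng)
    is_exc = np.zeros(config.n_neurons, dtype=bool)
    is_exc[:config.n_excitatory] = True
    return NeuronPopulation(positions, is_exc)


def build_topology(config: SimulationConfig, run: int = 0) -> CultureTopology:
    """Topology for one run: the neuronal network depends only on the master
    seed (shared across runs); astrocyte placement and synapse assignment are
    resampled per run."""
    rng_top = stream(config.seed, _KEY_TOPOLOGY)
    positions = place_cells(config.n_neurons, config.geometry.extent,
                            config.geometry.min_neuron_dist, rng_top)
    is_exc = np.zeros(config.n_neurons, dtype=bool)
    is_exc[:config.n_excitatory] = True
    neurons = NeuronPopulation(positions, is_exc)
    synapses = build_neuron_network(neurons, config.geometry, rng_top)

    rng_astro = stream(config.seed, _KEY_ASTRO, run)
    n_astro = config.n_astrocytes if config.use_astro_processes else 0
    astro_positions = (place_cells(n_astro, config.geometry.extent,
                                   config.geometry.min_astro_dist, rng_astro)
                       if n_astro else np.empty((0, 3)))
    astrocytes = AstrocytePopulation(astro_positions)
    if n_astro:
        synapses = assign_synapses_to_astrocytes(
            synapses, neurons, astrocytes, config.geometry, rng_astro)
    gaps = build_gap_junctions(astrocytes, config.geometry.gap_cutoff)
    return CultureTopology(config.geometry, neurons, astrocytes, synapses, gaps)


# ---------------------------------------------------------------------------
# results container
# ---------------------------------------------------------------------------

@dataclass
class SimulationResult:
    config: SimulationConfig
    topology: CultureTopology
    run: int
    spikes: np.ndarray               # (n_steps, n_neurons) bool
    astro_active: np.ndarray         # (n_steps,) active-astrocyte count
    astro_states: np.ndarray | None  # (n_steps, n_astro) int8, optional
    synapse_traces: dict[int, dict[str, np.ndarray]]

    @property
    def pooled(self) -> np.ndarray:
        """Network-wide spike count per 5 ms bin."""
        return self.spikes.sum(axis=1)

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.config.n_steps) * self.config.dt

    def spike_times(self, neuron: int) -> np.ndarray:
        return np.nonzero(self.spikes[:, neuron])[0] * self.config.dt

    def mean_spike_rate(self) -> float:
        """Average spike rate per neuron, spikes/min."""
        n = self.config.n_neurons
        return 60.0 * self.spikes.sum() / (n * self.config.t_total)

    def raster_dataframe(self) -> pd.DataFrame:
        step, neuron = np.nonzero(self.spikes)
        return pd.DataFrame({"time_s": step * self.config.dt,
                             "neuron_id": neuron})

    def save_raster_csv(self, path) -> None:
        self.raster_dataframe().to_csv(path, index=False)

    def astro_activity_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"time_s": self.times,
                             "active_astrocytes": self.astro_active})


# ---------------------------------------------------------------------------
# the update loop
# ---------------------------------------------------------------------------

def simulate(config: SimulationConfig, topology: CultureTopology | None = None,
             run: int = 0) -> SimulationResult:
    """Run one realization of the configured scenario."""
    if topology is None:
        topology = build_topology(config, run)
    geo, tm, loc, uar = config.geometry, config.tm, config.local, config.uar
    dt, n_steps = config.dt, config.n_steps
    n = config.n_neurons
    syn = topology.synapses

    rng_noise = stream(config.seed, _KEY_NOISE)
    rng_spikes = stream(config.seed, _KEY_SPIKES, run)
    rng_uar = stream(config.seed, _KEY_UAR, run)

    # per-neuron noise: a unit triangular draw scaled by C_max, so the same
    # neurons keep the same relative noise across noise levels
    c = draw_noise_rates(n, 1.0, rng_noise) * config.c_max

    # synapse arrays
    m = syn.n if config.use_synapses else 0
    pre = syn.pre[:m]
    post = syn.post[:m]
    y_max_signed = np.where(syn.sign[:m] > 0, tm.y_max_plus, tm.y_max_minus)
    u_base = syn.y_base[:m] / tm.y_max_plus  # baseline U* = y_base / |Y_max|
    x = np.ones(m)
    u = np.zeros(m)
    y = np.zeros(m)          # weights carried into the next bin

    # local areas exist only for enwrapped synapses
    enw_idx = np.nonzero(syn.enwrapped[:m])[0] if config.use_astro_processes \
        else np.empty(0, dtype=int)
    astro_of = syn.astrocyte[enw_idx]
    ip3 = np.zeros(len(enw_idx))
    ca = np.zeros(len(enw_idx))
    g = np.zeros(len(enw_idx))

    n_astro = topology.astrocytes.n
    adjacency = topology.gap_junctions.adjacency()
    theta = activation_threshold(topology.gap_junctions.degrees, uar.b0, uar.b1)
    n_syn_astro = np.bincount(astro_of, minlength=n_astro) if n_astro else \
        np.zeros(0, dtype=int)
    # The coupled system is bistable: a state with dormant astrocytes and a
    # collective "engaged" state in which gap-junction propagation keeps a
    # large astrocyte fraction cycling and regulating the neurons.  Starting
    # the astrocytes active relaxes the culture into the engaged attractor;
    # from an all-dormant start the astrocyte layer never self-nucleates.
    init_state = A if config.astro_init == "active" else U
    states = np.full(n_astro, init_state, dtype=np.int8)

    s = np.zeros(n, dtype=bool)
    spikes = np.zeros((n_steps, n), dtype=bool)
    astro_active = np.zeros(n_steps, dtype=np.int32)
    astro_states = (np.zeros((n_steps, n_astro), dtype=np.int8)
                    if config.store_astro_states else None)
    monitor = {idx: {k: np.zeros(n_steps) for k in
                     ("x", "u", "rr", "u_star", "ip3", "ca", "g")}
               for idx in config.monitor_synapses}
    enw_pos = {int(sidx): int(np.nonzero(enw_idx == sidx)[0][0])
               for sidx in config.monitor_synapses if sidx in set(enw_idx)}

    for k in range(n_steps):
        # (1) firing propensity from the previous bin
        lam = c.copy()
        if m:
            lam += np.bincount(post, weights=y * s[pre], minlength=n)
        if config.use_adenosine and len(enw_idx):
            active_pre = states[astro_of] == A
            if np.any(active_pre):
                lam -= uar.y_astro * np.bincount(
                    post[enw_idx[active_pre]], minlength=n)
        np.maximum(lam, 0.0, out=lam)

        # (2) spike draws (lam is a per-bin expectation; rate = lam/dt)
        p = spike_probability(lam / dt, dt)
        s_new = sample_spikes(p, rng_spikes)

        # (3) TM update and weights, U* from the previous bin's g
        if m:
            u_star = u_base
            if len(enw_idx):
                u_star = u_base.copy()
                u_star[enw_idx] = release_increment(
                    syn.y_base[enw_idx], tm.y_max_plus, g, tm.alpha)
            x, u, rr = update_tm(x, u, u_star, s_new[pre], tm, dt)
            y = synaptic_weight(rr, y_max_signed)

        # (4) local IP3 / calcium / gliotransmitter dynamics
        if len(enw_idx):
            forced = states[astro_of] == A
            ip3 = update_ip3(ip3, rr[enw_idx], loc, dt, forced)
            ca_prev = ca
            ca = update_calcium(ca, ip3, loc.omega_acc)
            g = update_gliotransmitter(g, ca_prev, ca, loc, dt)

        # (5) astrocyte network propagation and transitions
        if n_astro:
            if config.use_astro_network:
                beta = propagation_efficiency(states, adjacency)
                nb_beta = adjacency @ beta
            else:
                nb_beta = np.zeros(n_astro)
            ca_sum = (np.bincount(astro_of, weights=ca, minlength=n_astro)
                      if len(enw_idx) else np.zeros(n_astro))
            gamma = activation_propensity(theta, nb_beta, ca_sum,
                                          n_syn_astro, uar.m)
            states = update_states(states, gamma, theta, uar, dt, rng_uar)
            astro_active[k] = int(np.sum(states == A))
            if astro_states is not None:
                astro_states[k] = states

        spikes[k] = s_new
        s = s_new
        for sidx, trace in monitor.items():
            if sidx < m:
                trace["x"][k] = x[sidx]
                trace["u"][k] = u[sidx]
                trace["rr"][k] = rr[sidx]
                trace["u_star"][k] = u_star[sidx] if m else 0.0
            if sidx in enw_pos:
                j = enw_pos[sidx]
                trace["ip3"][k] = ip3[j]
                trace["ca"][k] = ca[j]
                trace["g"][k] = g[j]

    return SimulationResult(config, topology, run, spikes, astro_active,
                            astro_states, monitor)


def run_experiment(config: SimulationConfig) -> list[SimulationResult]:
    """n_runs realizations sharing one neuronal network; the astrocyte
    network (placement, assignment, gap junctions) is resampled per run."""
    return [simulate(config, build_topology(config, run), run)
            for run in range(config.n_runs)]


def parameter_sweep(config: SimulationConfig, tau_a_values, omega_g_values,
                    topology: CultureTopology | None = None,
                    n_runs: int = 1) -> np.ndarray:
    """Mean spike rate (spikes/min per neuron) on the tau_A x Omega_g grid.

    One run per grid cell by default (``n_runs`` averages several dynamics
    realizations), all cells sharing the same topology so the grid varies
    only the astrocytic time constants.
    """
    if topology is None:
        topology = build_topology(config, 0)
    rates = np.zeros((len(tau_a_values), len(omega_g_values)))
    for i, tau_a in enumerate(tau_a_values):
        for j, omega_g in enumerate(omega_g_values):
            cfg = dataclasses.replace(
                config,
                uar=dataclasses.replace(config.uar, tau_a=float(tau_a)),
                local=dataclasses.replace(config.local, omega_g=float(omega_g)),
            )
            rates[i, j] = float(np.mean(
                [simulate(cfg, topology, run).mean_spike_rate()
                 for run in range(n_runs)]))
    return rates
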
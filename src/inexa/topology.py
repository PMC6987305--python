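"""Spatial layout and connectivity of a virtual neuron-astrocyte culture.

Cells are scattered uniformly over a shallow 750 x 750 x 10 um box that
mimics the recording area of a multielectrode array (MEA).  Neurons connect
to each other with a distance-dependent Gaussian probability; each
excitatory synapse may in addition be enwrapped by a nearby astrocyte
(tripartite synapse), and astrocytes closer than a cutoff are coupled by
gap junctions.  The module also computes the summary statistics used to
characterise these networks (connectivity, degree, connection lengths,
synapses per astrocyte, fraction of "naked" synapses, ...).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd

__all__ = [
    "CultureGeometry",
    "NeuronPopulation",
    "AstrocytePopulation",
    "SynapseTable",
    "GapJunctionGraph",
    "CultureTopology",
    "TopologyStats",
    "place_cells",
    "neuron_connection_probability",
    "astrocyte_synapse_probability",
    "sample_base_weights",
    "build_neuron_network",
    "assign_synapses_to_astrocytes",
    "build_gap_junctions",
    "topology_statistics",
]

NAKED = -1  # astrocyte id of a synapse without an enwrapping astrocyte


@dataclass(frozen=True)
class CultureGeometry:
    """Geometry and connection-rule parameters of the virtual culture.

    All lengths are in micrometres.  ``synapse_site`` selects which point
    represents a synapse when measuring its distance to astrocyte somata:
    the postsynaptic soma (default), the presynaptic soma, or the midpoint
    between the two.
    """

    extent: tuple[float, float, float] = (750.0, 750.0, 10.0)
    min_neuron_dist: float = 10.0
    min_astro_dist: float = 30.0
    sigma_n: float = 200.0
    sigma_a: float = 150.0
    d_a: float = 70.0
    gap_cutoff: float = 100.0
    synapse_site: str = "post"

    def __post_init__(self) -> None:
        if any(e <= 0 for e in self.extent):
            raise ValueError("extent components must be positive")
        for name in ("min_neuron_dist", "min_astro_dist", "sigma_n",
                     "sigma_a", "d_a", "gap_cutoff"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.d_a > self.gap_cutoff:
            raise ValueError("d_a must not exceed gap_cutoff")
        if max(self.min_neuron_dist, self.min_astro_dist) >= min(self.extent[:2]):
            raise ValueError("minimum distances must fit inside the culture")
        if self.synapse_site not in ("post", "pre", "midpoint"):
            raise ValueError("synapse_site must be 'post', 'pre' or 'midpoint'")


@dataclass(frozen=True)
class NeuronPopulation:
    positions: np.ndarray            # (n, 3) um
    is_excitatory: np.ndarray        # (n,) bool

    @property
    def n(self) -> int:
        return len(self.positions)


@dataclass(frozen=True)
class AstrocytePopulation:
    positions: np.ndarray            # (n_a, 3) um

    @property
    def n(self) -> int:
        return len(self.positions)


@dataclass(frozen=True)
class SynapseTable:
    """Directed synapses, one row per realized pre -> post connection.

    ``y_base`` is the basal weight magnitude drawn from a triangular
    distribution on [0, 0.7]; ``sign`` is +1 for excitatory presynaptic
    neurons and -1 for inhibitory ones; ``astrocyte`` holds the id of the
    enwrapping astrocyte or ``NAKED`` (-1).
    """

    pre: np.ndarray        # (m,) int
    post: np.ndarray       # (m,) int
    y_base: np.ndarray     # (m,) float in [0, 0.7]
    sign: np.ndarray       # (m,) int, +1 or -1
    astrocyte: np.ndarray  # (m,) int, NAKED if unassigned

    def __post_init__(self) -> None:
        if np.any(self.pre == self.post):
            raise ValueError("self-connections are not allowed")
        if np.any((self.y_base < 0) | (self.y_base > 0.7)):
            raise ValueError("y_base must lie in [0, 0.7]")
        if np.any((self.astrocyte >= 0) & (self.sign < 0)):
            raise ValueError("only excitatory synapses may have an astrocyte")

    @property
    def n(self) -> int:
        return len(self.pre)

    @property
    def excitatory(self) -> np.ndarray:
        return self.sign > 0

    @property
    def enwrapped(self) -> np.ndarray:
        return self.astrocyte >= 0

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "pre_id": self.pre,
            "post_id": self.post,
            "y_base": self.y_base,
            "sign": self.sign,
            "astrocyte_id": self.astrocyte,
        })

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


@dataclass(frozen=True)
class GapJunctionGraph:
    """Undirected gap-junction adjacency over astrocytes."""

    n_astrocytes: int
    edges: np.ndarray          # (n_edges, 2) int, each pair once, a < b
    edge_lengths: np.ndarray   # (n_edges,) um

    @property
    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_astrocytes, dtype=int)
        if len(self.edges):
            np.add.at(deg, self.edges[:, 0], 1)
            np.add.at(deg, self.edges[:, 1], 1)
        return deg

    def neighbor_lists(self) -> list[np.ndarray]:
        nbrs: list[list[int]] = [[] for _ in range(self.n_astrocytes)]
        for a, b in self.edges:
            nbrs[a].append(b)
            nbrs[b].append(a)
        return [np.array(sorted(x), dtype=int) for x in nbrs]

    def adjacency(self) -> np.ndarray:
        adj = np.zeros((self.n_astrocytes, self.n_astrocytes), dtype=float)
        if len(self.edges):
            adj[self.edges[:, 0], self.edges[:, 1]] = 1.0
            adj[self.edges[:, 1], self.edges[:, 0]] = 1.0
        return adj


@dataclass(frozen=True)
class CultureTopology:
    """Complete spatial description of one simulated culture."""

    geometry: CultureGeometry
    neurons: NeuronPopulation
    astrocytes: AstrocytePopulation
    synapses: SynapseTable
    gap_junctions: GapJunctionGraph

    def to_json(self, path) -> None:
        payload = {
            "geometry": asdict(self.geometry),
            "neuron_positions": self.neurons.positions.tolist(),
            "is_excitatory": self.neurons.is_excitatory.astype(int).tolist(),
            "astrocyte_positions": self.astrocytes.positions.tolist(),
            "synapses": {
                "pre": self.synapses.pre.tolist(),
                "post": self.synapses.post.tolist(),
                "y_base": self.synapses.y_base.tolist(),
                "sign": self.synapses.sign.tolist(),
                "astrocyte": self.synapses.astrocyte.tolist(),
            },
            "gap_junction_edges": self.gap_junctions.edges.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "CultureTopology":
        with open(path) as fh:
            payload = json.load(fh)
        geo = CultureGeometry(**{**payload["geometry"],
                                 "extent": tuple(payload["geometry"]["extent"])})
        neurons = NeuronPopulation(
            positions=np.asarray(payload["neuron_positions"], dtype=float),
            is_excitatory=np.asarray(payload["is_excitatory"], dtype=bool),
        )
        astros = AstrocytePopulation(
            positions=np.asarray(payload["astrocyte_positions"], dtype=float))
        syn = payload["synapses"]
        table = SynapseTable(
            pre=np.asarray(syn["pre"], dtype=int),
            post=np.asarray(syn["post"], dtype=int),
            y_base=np.asarray(syn["y_base"], dtype=float),
            sign=np.asarray(syn["sign"], dtype=int),
            astrocyte=np.asarray(syn["astrocyte"], dtype=int),
        )
        gaps = build_gap_junctions(astros, geo.gap_cutoff)
        return cls(geo, neurons, astros, table, gaps)


@dataclass(frozen=True)
class TopologyStats:
    max_connections: int
    realized_connections: int
    connectivity_pct: float
    mean_connections_per_neuron: float
    mean_connection_length: float
    bidirectional_pairs: int
    synapses_per_astrocyte: float
    gap_junctions_per_astrocyte: float
    naked_synapse_pct: float
    mean_gap_distance: float

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# placement and connection rules
# ---------------------------------------------------------------------------

def place_cells(n: int, extent, min_dist: float, rng: np.random.Generator,
                max_attempts: int = 100_000) -> np.ndarray:
    """Scatter ``n`` somata uniformly in the box, at least ``min_dist`` apart.

    Candidate positions violating the minimum inter-soma distance are
    redrawn; after ``max_attempts`` redraws the packing is declared
    infeasible and a RuntimeError is raised.
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    extent = np.asarray(extent, dtype=float)
    positions = np.empty((n, 3), dtype=float)
    placed = 0
    attempts = 0
    while placed < n:
        candidate = rng.uniform(0.0, extent)
        if placed == 0 or np.min(
                np.linalg.norm(positions[:placed] - candidate, axis=1)) >= min_dist:
            positions[placed] = candidate
            placed += 1
        else:
            attempts += 1
            if attempts > max_attempts:
                raise RuntimeError(
                    f"could not place {n} cells with min_dist={min_dist} "
                    f"after {max_attempts} attempts")
    return positions


def neuron_connection_probability(d, sigma_n: float):
    """Gaussian fall-off of the neuron-to-neuron connection probability,
    exp(-d^2 / (2 sigma_N^2))."""
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("distances must be non-negative")
    return np.exp(-d ** 2 / (2.0 * sigma_n ** 2))


def astrocyte_synapse_probability(d, sigma_a: float, d_a: float):
    """Gaussian astrocyte-synapse connection probability with a hard cutoff.

    exp(-d^2/(2 sigma_A^2)) * H(d_A - d), where the Heaviside step is 1
    only for d strictly below the cutoff d_A (H(0) = 0).
    """
    d = np.asarray(d, dtype=float)
    return np.exp(-d ** 2 / (2.0 * sigma_a ** 2)) * (d < d_a)


def sample_base_weights(n: int, rng: np.random.Generator,
                        upper: float = 0.7) -> np.ndarray:
    # symmetric triangular distribution on [0, upper], mode at the midpoint
    return rng.triangular(0.0, upper / 2.0, upper, size=n)


def build_neuron_network(neurons: NeuronPopulation, geometry: CultureGeometry,
                         rng: np.random.Generator) -> SynapseTable:
    """Draw every ordered neuron pair independently with probability
    P_NN(d) and give each realized synapse a triangular base weight."""
    n = neurons.n
    if n < 2:
        empty = np.empty(0, dtype=int)
        return SynapseTable(empty, empty, np.empty(0), empty.astype(int), empty)
    diff = neurons.positions[:, None, :] - neurons.positions[None, :, :]
    dist = np.linalg.norm(diff, axis=-1)
    prob = neuron_connection_probability(dist, geometry.sigma_n)
    np.fill_diagonal(prob, 0.0)
    connected = rng.random((n, n)) < prob
    np.fill_diagonal(connected, False)
    pre, post = np.nonzero(connected)
    y_base = sample_base_weights(len(pre), rng)
    sign = np.where(neurons.is_excitatory[pre], 1, -1)
    astro = np.full(len(pre), NAKED, dtype=int)
    return SynapseTable(pre, post, y_base, sign.astype(int), astro)


def synapse_positions(synapses: SynapseTable, neurons: NeuronPopulation,
                      site: str) -> np.ndarray:
    if site == "post":
        return neurons.positions[synapses.post]
    if site == "pre":
        return neurons.positions[synapses.pre]
    if site == "midpoint":
        return 0.5 * (neurons.positions[synapses.pre]
                      + neurons.positions[synapses.post])
    raise ValueError(f"unknown synapse site {site!r}")


def assign_synapses_to_astrocytes(synapses: SynapseTable,
                                  neurons: NeuronPopulation,
                                  astrocytes: AstrocytePopulation,
                                  geometry: CultureGeometry,
                                  rng: np.random.Generator) -> SynapseTable:
    """Try astrocytes in increasing distance order for every excitatory
    synapse; each candidate succeeds with probability P_AN(d).

    Astrocytes beyond the cutoff d_A are never eligible, so a synapse can
    remain naked.  Inhibitory synapses are always naked.
    """
    astro_id = np.full(synapses.n, NAKED, dtype=int)
    if astrocytes.n > 0 and synapses.n > 0:
        exc_idx = np.nonzero(synapses.excitatory)[0]
        sites = synapse_positions(synapses, neurons, geometry.synapse_site)
        # distances from each excitatory synapse site to every astrocyte
        d = np.linalg.norm(sites[exc_idx, None, :]
                           - astrocytes.positions[None, :, :], axis=-1)
        order = np.argsort(d, axis=1)
        d_sorted = np.take_along_axis(d, order, axis=1)
        p_sorted = astrocyte_synapse_probability(
            d_sorted, geometry.sigma_a, geometry.d_a)
        undecided = np.ones(len(exc_idx), dtype=bool)
        for col in range(astrocytes.n):
            p_col = p_sorted[:, col]
            if not np.any(p_col[undecided] > 0):
                break
            draw = rng.random(len(exc_idx))
            success = undecided & (draw < p_col)
            astro_id[exc_idx[success]] = order[success, col]
            undecided &= ~success
            undecided &= p_col > 0  # beyond the cutoff no later try can succeed
        # note: each undecided synapse consumes one draw per candidate ring,
        # so assignment is reproducible for a fixed rng state
    return replace(synapses, astrocyte=astro_id)


def build_gap_junctions(astrocytes: AstrocytePopulation,
                        gap_cutoff: float) -> GapJunctionGraph:
    """Connect every astrocyte pair whose inter-soma distance is strictly
    below the cutoff (deterministic)."""
    n = astrocytes.n
    if n < 2:
        return GapJunctionGraph(n, np.empty((0, 2), dtype=int), np.empty(0))
    dist = np.linalg.norm(astrocytes.positions[:, None, :]
                          - astrocytes.positions[None, :, :], axis=-1)
    a, b = np.nonzero(np.triu(dist < gap_cutoff, k=1))
    edges = np.column_stack([a, b]).astype(int)
    return GapJunctionGraph(n, edges, dist[a, b])


# ---------------------------------------------------------------------------
# statistics (Tables of network measures)
# ---------------------------------------------------------------------------

def topology_statistics(topology: CultureTopology) -> TopologyStats:
    neurons, syn = topology.neurons, topology.synapses
    n = neurons.n
    max_conn = n * (n - 1)
    realized = syn.n
    lengths = np.linalg.norm(neurons.positions[syn.pre]
                             - neurons.positions[syn.post], axis=1)
    pair_codes = syn.pre * n + syn.post
    reverse_codes = syn.post * n + syn.pre
    bidirectional = int(np.isin(pair_codes, reverse_codes).sum() // 2)

    exc = syn.excitatory
    n_exc = int(exc.sum())
    naked_pct = (100.0 * np.sum(exc & ~syn.enwrapped) / n_exc
                 if n_exc else 0.0)
    n_astro = topology.astrocytes.n
    if n_astro:
        per_astro = np.bincount(syn.astrocyte[syn.enwrapped],
                                minlength=n_astro)
        synapses_per_astro = float(per_astro.mean())
        gap_deg = float(topology.gap_junctions.degrees.mean())
        gap_len = topology.gap_junctions.edge_lengths
        mean_gap = float(gap_len.mean()) if len(gap_len) else 0.0
    else:
        synapses_per_astro = 0.0
        gap_deg = 0.0
        mean_gap = 0.0

    return TopologyStats(
        max_connections=max_conn,
        realized_connections=realized,
        connectivity_pct=100.0 * realized / max_conn if max_conn else 0.0,
        mean_connections_per_neuron=realized / n if n else 0.0,
        mean_connection_length=float(lengths.mean()) if realized else 0.0,
        bidirectional_pairs=bidirectional,
        synapses_per_astrocyte=synapses_per_astro,
        gap_junctions_per_astrocyte=gap_deg,
        naked_synapse_pct=naked_pct,
        mean_gap_distance=mean_gap,
    )
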
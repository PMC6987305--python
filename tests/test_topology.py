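"""Placement, connection rules and network statistics of the virtual culture."""

import math

import numpy as np
import pytest

from inexa import (
    AstrocytePopulation,
    CultureGeometry,
    CultureTopology,
    NeuronPopulation,
    SynapseTable,
    assign_synapses_to_astrocytes,
    astrocyte_synapse_probability,
    build_gap_junctions,
    build_neuron_network,
    neuron_connection_probability,
    place_cells,
    topology_statistics,
)
from inexa.topology import NAKED, sample_base_weights


class TestPlacement:
    def test_empty_population(self, rng, geometry):
        assert place_cells(0, geometry.extent, 10.0, rng).shape == (0, 3)

    @pytest.mark.parametrize("n,min_dist", [(250, 10.0), (107, 30.0)])
    def test_min_distance_respected(self, geometry, n, min_dist):
        rng = np.random.default_rng(7)
        pos = place_cells(n, geometry.extent, min_dist, rng)
        assert pos.shape == (n, 3)
        assert np.all(pos >= 0) and np.all(pos <= geometry.extent)
        d = np.linalg.norm(pos[:, None] - pos[None], axis=-1)
        np.fill_diagonal(d, np.inf)
        assert d.min() >= min_dist

    def test_deterministic_given_seed(self, geometry):
        a = place_cells(50, geometry.extent, 10.0, np.random.default_rng(3))
        b = place_cells(50, geometry.extent, 10.0, np.random.default_rng(3))
        np.testing.assert_array_equal(a, b)

    def test_infeasible_packing_raises(self, rng):
        with pytest.raises(RuntimeError):
            place_cells(30, (50.0, 50.0, 10.0), 40.0, rng, max_attempts=2000)


class TestConnectionProbabilities:
    @pytest.mark.parametrize("d,sigma,expected", [
        (0.0, 200.0, 1.0),
        (200.0, 200.0, 0.6065306597126334),
        (600.0, 200.0, 0.011108996538242306),
    ])
    def test_neuron_gaussian(self, d, sigma, expected):
        assert neuron_connection_probability(d, sigma) == pytest.approx(
            expected, rel=1e-9)

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            neuron_connection_probability(-1.0, 200.0)

    @pytest.mark.parametrize("d,expected", [
        (0.0, 1.0),
        (50.0, 0.9459594689067654),
        (70.0, 0.0),       # Heaviside boundary: H(0) = 0
        (120.0, 0.0),
    ])
    def test_astrocyte_gaussian_with_cutoff(self, d, expected):
        assert astrocyte_synapse_probability(d, 150.0, 70.0) == pytest.approx(
            expected, rel=1e-9)


class TestNeuronNetwork:
    def test_single_neuron_gives_empty_table(self, geometry, rng):
        neurons = NeuronPopulation(np.array([[10.0, 10.0, 5.0]]),
                                   np.array([True]))
        assert build_neuron_network(neurons, geometry, rng).n == 0

    def test_no_self_connections_and_signs(self, small_geometry):
        rng = np.random.default_rng(5)
        pos = place_cells(60, small_geometry.extent, 10.0, rng)
        is_exc = np.arange(60) < 48
        syn = build_neuron_network(NeuronPopulation(pos, is_exc),
                                   small_geometry, rng)
        assert np.all(syn.pre != syn.post)
        np.testing.assert_array_equal(syn.sign, np.where(is_exc[syn.pre], 1, -1))
        assert np.all(syn.astrocyte == NAKED)

    def test_pair_connection_frequency_matches_closed_form(self, geometry):
        # two neurons 200 um apart: each direction realized w.p. e^(-1/2)
        pos = np.array([[100.0, 100.0, 5.0], [300.0, 100.0, 5.0]])
        neurons = NeuronPopulation(pos, np.array([True, True]))
        n_trials, hits = 4000, 0
        for seed in range(n_trials):
            hits += build_neuron_network(
                neurons, geometry, np.random.default_rng(seed)).n
        p = 0.6065306597126334
        se = math.sqrt(2 * n_trials * p * (1 - p))
        assert abs(hits - 2 * n_trials * p) < 4 * se

    def test_weights_triangular_support_and_symmetry(self, rng):
        w = sample_base_weights(20000, rng)
        assert w.min() >= 0 and w.max() <= 0.7
        assert abs(w.mean() - 0.35) < 0.005           # symmetric about midpoint
        assert abs(np.median(w) - 0.35) < 0.01

    def test_bidirectional_count_matches_independent_directions(self):
        # with independent per-direction draws, E[#bidirectional pairs]
        # equals the sum of squared pair probabilities
        geometry = CultureGeometry(extent=(400.0, 400.0, 10.0))
        rng = np.random.default_rng(11)
        pos = place_cells(40, geometry.extent, 10.0, rng)
        neurons = NeuronPopulation(pos, np.ones(40, dtype=bool))
        d = np.linalg.norm(pos[:, None] - pos[None], axis=-1)
        p = neuron_connection_probability(d, geometry.sigma_n)
        iu = np.triu_indices(40, k=1)
        expected = float((p[iu] ** 2).sum())
        counts = []
        for seed in range(300):
            syn = build_neuron_network(neurons, geometry,
                                       np.random.default_rng(1000 + seed))
            top = CultureTopology(geometry, neurons,
                                  AstrocytePopulation(np.empty((0, 3))), syn,
                                  build_gap_junctions(
                                      AstrocytePopulation(np.empty((0, 3))),
                                      geometry.gap_cutoff))
            counts.append(topology_statistics(top).bidirectional_pairs)
        se = np.std(counts) / math.sqrt(len(counts))
        assert abs(np.mean(counts) - expected) < 4 * max(se, 0.5)


class TestAstrocyteAssignment:
    def _network(self, geometry, seed=2):
        rng = np.random.default_rng(seed)
        pos = place_cells(80, geometry.extent, 10.0, rng)
        is_exc = np.arange(80) < 64
        neurons = NeuronPopulation(pos, is_exc)
        return neurons, build_neuron_network(neurons, geometry, rng), rng

    def test_no_astrocytes_all_naked(self, small_geometry):
        neurons, syn, rng = self._network(small_geometry)
        out = assign_synapses_to_astrocytes(
            syn, neurons, AstrocytePopulation(np.empty((0, 3))),
            small_geometry, rng)
        assert np.all(out.astrocyte == NAKED)

    def test_astrocyte_beyond_cutoff_never_assigned(self, small_geometry):
        neurons, syn, rng = self._network(small_geometry)
        far = AstrocytePopulation(np.array([[5000.0, 5000.0, 5.0]]))
        out = assign_synapses_to_astrocytes(syn, neurons, far,
                                            small_geometry, rng)
        assert np.all(out.astrocyte == NAKED)

    def test_assignment_respects_cutoff_and_excitatory_only(self, small_geometry):
        neurons, syn, rng = self._network(small_geometry)
        astro = AstrocytePopulation(
            place_cells(12, small_geometry.extent, 30.0, rng))
        out = assign_synapses_to_astrocytes(syn, neurons, astro,
                                            small_geometry, rng)
        assert np.any(out.astrocyte >= 0)  # something got enwrapped
        assigned = out.astrocyte >= 0
        # inhibitory synapses stay naked
        assert not np.any(assigned & (out.sign < 0))
        # no assignment at or beyond d_A
        sites = neurons.positions[out.post[assigned]]
        d = np.linalg.norm(sites - astro.positions[out.astrocyte[assigned]],
                           axis=1)
        assert d.max() < small_geometry.d_a

    def test_more_astrocytes_fewer_naked_synapses(self, geometry):
        rng = np.random.default_rng(9)
        pos = place_cells(120, geometry.extent, 10.0, rng)
        neurons = NeuronPopulation(pos, np.arange(120) < 96)
        syn = build_neuron_network(neurons, geometry, rng)
        naked = []
        for count in (20, 60, 110):
            astro = AstrocytePopulation(
                place_cells(count, geometry.extent, 30.0,
                            np.random.default_rng(77)))
            out = assign_synapses_to_astrocytes(
                syn, neurons, astro, geometry, np.random.default_rng(78))
            exc = out.excitatory
            naked.append(np.sum(exc & ~out.enwrapped) / exc.sum())
        assert naked[0] > naked[1] > naked[2]


class TestGapJunctions:
    def test_single_astrocyte_no_edges(self):
        g = build_gap_junctions(
            AstrocytePopulation(np.array([[0.0, 0.0, 0.0]])), 100.0)
        assert len(g.edges) == 0

    @pytest.mark.parametrize("dist,n_edges", [(99.0, 1), (101.0, 0)])
    def test_cutoff_is_strict(self, dist, n_edges):
        pos = np.array([[0.0, 0.0, 0.0], [dist, 0.0, 0.0]])
        g = build_gap_junctions(AstrocytePopulation(pos), 100.0)
        assert len(g.edges) == n_edges


class TestStatistics:
    def test_hand_computed_five_neuron_fixture(self):
        geometry = CultureGeometry()
        pos = np.array([[0.0, 0.0, 0.0], [100.0, 0.0, 0.0], [0.0, 100.0, 0.0],
                        [200.0, 0.0, 0.0], [0.0, 200.0, 0.0]])
        neurons = NeuronPopulation(pos, np.array([1, 1, 1, 1, 0], dtype=bool))
        # hand-placed synapses: 0->1, 1->0 (bidirectional), 0->2, 4->3
        syn = SynapseTable(pre=np.array([0, 1, 0, 4]),
                           post=np.array([1, 0, 2, 3]),
                           y_base=np.array([0.1, 0.2, 0.3, 0.4]),
                           sign=np.array([1, 1, 1, -1]),
                           astrocyte=np.array([NAKED] * 4))
        astro = AstrocytePopulation(np.empty((0, 3)))
        top = CultureTopology(geometry, neurons, astro, syn,
                              build_gap_junctions(astro, geometry.gap_cutoff))
        st = topology_statistics(top)
        assert st.max_connections == 20
        assert st.realized_connections == 4
        assert st.connectivity_pct == pytest.approx(20.0)
        assert st.mean_connections_per_neuron == pytest.approx(0.8)
        # lengths: 100, 100, 100, sqrt(200^2 + 200^2)
        expected_len = (300.0 + math.hypot(200.0, 200.0)) / 4
        assert st.mean_connection_length == pytest.approx(expected_len)
        assert st.bidirectional_pairs == 1
        assert st.naked_synapse_pct == pytest.approx(100.0)

    def test_standard_network_max_connections(self, geometry):
        rng = np.random.default_rng(0)
        pos = place_cells(250, geometry.extent, 10.0, rng)
        neurons = NeuronPopulation(pos, np.arange(250) < 200)
        syn = build_neuron_network(neurons, geometry, rng)
        astro = AstrocytePopulation(np.empty((0, 3)))
        top = CultureTopology(geometry, neurons, astro, syn,
                              build_gap_junctions(astro, geometry.gap_cutoff))
        assert topology_statistics(top).max_connections == 62250


def test_json_round_trip(tmp_path, small_geometry):
    rng = np.random.default_rng(4)
    pos = place_cells(30, small_geometry.extent, 10.0, rng)
    neurons = NeuronPopulation(pos, np.arange(30) < 24)
    syn = build_neuron_network(neurons, small_geometry, rng)
    astro = AstrocytePopulation(place_cells(6, small_geometry.extent, 30.0, rng))
    syn = assign_synapses_to_astrocytes(syn, neurons, astro, small_geometry, rng)
    top = CultureTopology(small_geometry, neurons, astro, syn,
                          build_gap_junctions(astro, small_geometry.gap_cutoff))
    path = tmp_path / "topology.json"
    top.to_json(path)
    loaded = CultureTopology.from_json(path)
    np.testing.assert_allclose(loaded.neurons.positions, top.neurons.positions)
    np.testing.assert_array_equal(loaded.synapses.astrocyte, top.synapses.astrocyte)
    np.testing.assert_array_equal(loaded.gap_junctions.edges, top.gap_junctions.edges)
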
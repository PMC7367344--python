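"""Contact graphs, cluster partitions, and geometric order parameters."""

import networkx as nx
import numpy as np
import pytest

from gelscape.brownian import ParticleFrame
from gelscape.clusters import (
    ContactGraph,
    ExperimentCriterion,
    SimulationCriterion,
    annotate_geometry,
    cluster_labels,
    contact_pairs,
    correlation_length,
    experiment_grouping,
    fractal_dimension,
    frame_metrics,
    gyration_radius,
    largest_clusters,
    mass_histogram,
    mean_coordination,
)
from gelscape.fixtures import FixtureSpec, assemble_frame, build_cluster
from gelscape.potentials import MiePotential, inflection_radius


def frame_from_positions(pos, L=100.0):
    pos = np.asarray(pos, dtype=float)
    n = len(pos)
    return ParticleFrame(time=0.0, box_edge=L, positions=np.mod(pos, L),
                         velocities=np.zeros((n, 3)),
                         species=np.zeros(n, dtype=np.int64),
                         radii=np.full(n, 0.5), masses=np.ones(n))


class TestContactCriteria:
    def test_simulation_cutoff_is_inflection(self):
        cut = inflection_radius(MiePotential())
        fr = frame_from_positions([[0, 0, 0], [1.05, 0, 0], [3, 0, 0],
                                   [3 + 1.2, 0, 0]])
        graph = contact_pairs(fr, SimulationCriterion(cutoff=cut))
        found = {tuple(sorted(p)) for p in graph.pairs.tolist()}
        assert (0, 1) in found           # 1.05 < 1.0827
        assert (2, 3) not in found       # 1.2 > 1.0827

    def test_experiment_bond_distance(self):
        # colloid radius r = 1: bonded below d0 = 2.6 r
        fr = frame_from_positions([[0, 0, 0], [2.5, 0, 0], [10, 0, 0],
                                   [12.7, 0, 0]])
        graph = contact_pairs(fr, ExperimentCriterion(d0=2.6))
        found = {tuple(sorted(p)) for p in graph.pairs.tolist()}
        assert found == {(0, 1)}

    def test_unknown_criterion_rejected(self):
        fr = frame_from_positions([[0, 0, 0]])
        with pytest.raises(TypeError):
            contact_pairs(fr, object())


class TestClusterLabels:
    def test_chain_and_singletons(self):
        g = ContactGraph(n=5, pairs=np.array([[0, 1], [1, 2]]))
        cs = cluster_labels(g)
        assert cs.n_clusters == 3
        assert sorted(cs.sizes.tolist()) == [1, 1, 3]

    def test_no_bonds_all_singletons(self):
        cs = cluster_labels(ContactGraph(n=7, pairs=np.empty((0, 2), dtype=int)))
        assert cs.n_clusters == 7

    def test_matches_networkx_on_random_graphs(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            n = 200
            m = rng.integers(50, 300)
            pairs = rng.integers(0, n, (m, 2))
            pairs = pairs[pairs[:, 0] != pairs[:, 1]]
            cs = cluster_labels(ContactGraph(n=n, pairs=pairs))
            G = nx.Graph()
            G.add_nodes_from(range(n))
            G.add_edges_from(map(tuple, pairs))
            expected = {frozenset(c) for c in nx.connected_components(G)}
            got = {}
            for p, lab in enumerate(cs.labels):
                got.setdefault(lab, set()).add(p)
            assert {frozenset(v) for v in got.values()} == expected

    def test_sizes_partition_particles(self):
        rng = np.random.default_rng(1)
        pairs = rng.integers(0, 100, (80, 2))
        pairs = pairs[pairs[:, 0] != pairs[:, 1]]
        cs = cluster_labels(ContactGraph(n=100, pairs=pairs))
        assert cs.sizes.sum() == 100


class TestCoordination:
    def test_linear_trimer(self):
        g = ContactGraph(n=3, pairs=np.array([[0, 1], [1, 2]]))
        assert mean_coordination(g) == pytest.approx(4.0 / 3.0)

    def test_isolated(self):
        assert mean_coordination(ContactGraph(n=5, pairs=np.empty((0, 2), int))) == 0.0

    def test_complete_tetrahedron(self):
        pairs = np.array([[i, j] for i in range(4) for j in range(i + 1, 4)])
        assert mean_coordination(ContactGraph(n=4, pairs=pairs)) == 3.0

    def test_monotone_in_bonds(self):
        pairs = np.array([[0, 1], [1, 2], [2, 3]])
        z3 = mean_coordination(ContactGraph(n=4, pairs=pairs))
        z2 = mean_coordination(ContactGraph(n=4, pairs=pairs[:2]))
        assert z3 > z2


class TestGyration:
    def test_dimer_half_separation(self):
        fr = frame_from_positions([[0, 0, 0], [0.8, 0, 0]])
        g = ContactGraph(n=2, pairs=np.array([[0, 1]]))
        rg, span = gyration_radius([0, 1], g, fr.positions, fr.box_edge)
        assert rg == pytest.approx(0.4)
        assert not span

    def test_collinear_trimer(self):
        fr = frame_from_positions([[0, 0, 0], [1, 0, 0], [2, 0, 0]])
        g = ContactGraph(n=3, pairs=np.array([[0, 1], [1, 2]]))
        rg, _ = gyration_radius([0, 1, 2], g, fr.positions, fr.box_edge)
        assert rg == pytest.approx(np.sqrt(2.0 / 3.0))

    def test_unwrapping_across_boundary(self):
        # dimer straddling the boundary: wrapped coordinates are far apart
        fr = frame_from_positions([[0.1, 5, 5], [9.7, 5, 5]], L=10.0)
        g = ContactGraph(n=2, pairs=np.array([[0, 1]]))
        rg, _ = gyration_radius([0, 1], g, fr.positions, fr.box_edge)
        assert rg == pytest.approx(0.2)

    def test_disconnected_cluster_rejected(self):
        fr = frame_from_positions([[0, 0, 0], [5, 0, 0]])
        g = ContactGraph(n=2, pairs=np.empty((0, 2), int))
        with pytest.raises(ValueError):
            gyration_radius([0, 1], g, fr.positions, fr.box_edge)


class TestCorrelationLength:
    def _clusters(self, sizes, rgs):
        cs = cluster_labels(ContactGraph(n=int(sum(sizes)), pairs=_chain_pairs(sizes)))
        cs.gyration_radii = np.asarray(rgs, dtype=float)
        return cs

    def test_single_cluster_sqrt_two(self):
        cs = self._clusters([4], [1.3])
        assert correlation_length(cs) == pytest.approx(np.sqrt(2) * 1.3)

    def test_all_singletons_zero(self):
        cs = self._clusters([1, 1, 1], [0, 0, 0])
        assert correlation_length(cs) == 0.0

    def test_hand_example(self):
        # (N, Rg) = (2, 1) and (4, 2): xi^2 = 2(4 + 64)/20 = 6.8
        cs = self._clusters([2, 4], [1.0, 2.0])
        assert correlation_length(cs) ** 2 == pytest.approx(6.8)

    def test_invariant_under_translation(self):
        spec = FixtureSpec(tau=1.5, k_c=10, d_f=2.0, n_clusters=25,
                           box_edge=80.0, seed=2)
        fr, _ = assemble_frame(spec)
        crit = SimulationCriterion(cutoff=1.1)
        m1 = frame_metrics(fr, crit)
        fr.positions = np.mod(fr.positions + np.array([3.7, -1.2, 9.9]),
                              fr.box_edge)
        m2 = frame_metrics(fr, crit)
        assert m2.xi == pytest.approx(m1.xi, rel=1e-9)
        assert m2.z == m1.z


def _chain_pairs(sizes):
    pairs, start = [], 0
    for s in sizes:
        for i in range(start, start + s - 1):
            pairs.append([i, i + 1])
        start += s
    return np.array(pairs, dtype=int) if pairs else np.empty((0, 2), int)


class TestMassHistogram:
    def test_plain_counts(self):
        cs = cluster_labels(ContactGraph(n=4, pairs=np.array([[2, 3]])))
        k, counts = mass_histogram(cs)
        assert dict(zip(k.tolist(), counts.tolist())) == {1: 2, 2: 1}

    def test_exclude_largest_removes_exactly_one(self):
        cs = cluster_labels(ContactGraph(n=6, pairs=np.array([[0, 1], [1, 2], [4, 5]])))
        k, counts = mass_histogram(cs, exclude_largest=True)
        assert counts.sum() == cs.n_clusters - 1

    def test_log_binning_aggregates_linear_counts(self):
        rng = np.random.default_rng(5)
        sizes = rng.integers(1, 300, 400)
        labels = np.repeat(np.arange(len(sizes)), sizes)
        cs = cluster_labels(ContactGraph(n=len(labels), pairs=_chain_pairs(sizes)))
        k_lin, c_lin = mass_histogram(cs)
        k_log, dens = mass_histogram(cs, log_bins=12)
        assert (dens > 0).all()
        # total counts are conserved across binnings
        edges = None
        assert c_lin.sum() == len(sizes)


class TestPercolation:
    def test_wrapping_chain_flags_spanning(self):
        L = 10.0
        pos = [[i + 0.5, 5, 5] for i in range(10)]   # spacing 1, wraps to itself
        fr = frame_from_positions(pos, L=L)
        crit = SimulationCriterion(cutoff=1.1)
        m = frame_metrics(fr, crit)
        assert m.percolating
        assert m.f_z == 1.0

    def test_open_chain_not_spanning(self):
        L = 20.0
        pos = [[i + 0.5, 5, 5] for i in range(10)]
        fr = frame_from_positions(pos, L=L)
        m = frame_metrics(fr, SimulationCriterion(cutoff=1.1))
        assert not m.percolating

    def test_two_equal_clusters(self):
        fr = frame_from_positions([[0, 0, 0], [1, 0, 0], [10, 10, 10], [11, 10, 10]],
                                  L=50.0)
        cs = cluster_labels(contact_pairs(fr, SimulationCriterion(cutoff=1.1)))
        cs.spanning = np.zeros(cs.n_clusters, bool)
        f1, f2, perc = largest_clusters(cs)
        assert f1 == f2 == 0.5 and not perc


class TestFractalDimension:
    @pytest.mark.parametrize("d_f", [1.0, 2.0, 3.0])
    def test_recovers_generator_dimension(self, d_f):
        rng = np.random.default_rng(17)
        sizes = np.geomspace(10, 800, 90).astype(int)
        rgs = []
        for s in sizes:
            blob = build_cluster(int(s), d_f, 1.0, rng=rng)
            com = blob.mean(axis=0)
            rgs.append(np.sqrt(((blob - com) ** 2).sum(axis=1).mean()))
        cs = cluster_labels(ContactGraph(n=int(sizes.sum()), pairs=_chain_pairs(sizes)))
        cs.gyration_radii = np.array(rgs)
        cs.spanning = np.zeros(cs.n_clusters, bool)
        fit = fractal_dimension(cs, size_window=(10, 800), seed=0)
        assert fit.exponent == pytest.approx(d_f, abs=0.1)

    def test_too_few_clusters_rejected(self):
        cs = cluster_labels(ContactGraph(n=6, pairs=np.array([[0, 1], [1, 2]])))
        cs.gyration_radii = np.array([1.0, 0, 0, 0])
        with pytest.raises(ValueError):
            fractal_dimension(cs)


class TestExperimentGrouping:
    def test_double_threshold(self):
        # r = 1: bonds at d0 = 2.6, grouping at dc = 3.5
        pts = np.array([[0, 0, 0], [3.0, 0, 0], [10, 0, 0], [12.0, 0, 0],
                        [20, 0, 0], [24.5, 0, 0]])
        bonds, cs = experiment_grouping(pts, d0=2.6, dc=3.5)
        bond_set = {tuple(sorted(p)) for p in bonds.pairs.tolist()}
        assert (0, 1) not in bond_set          # 3.0 > 2.6
        assert (2, 3) in bond_set              # 2.0 < 2.6
        labels = cs.labels
        assert labels[0] == labels[1]          # 3.0 < 3.5: same cluster
        assert labels[4] != labels[5]          # 4.5 > 3.5: separate


class TestFrameInvariants:
    def test_partition_mass_and_fz_consistency(self):
        spec = FixtureSpec(tau=1.8, k_c=15, d_f=2.0, n_clusters=30,
                           box_edge=90.0, seed=8)
        fr, truth = assemble_frame(spec)
        crit = SimulationCriterion(cutoff=1.1)
        graph = contact_pairs(fr, crit)
        cs = annotate_geometry(cluster_labels(graph), graph, fr)
        assert cs.sizes.sum() == fr.n
        f1, _, _ = largest_clusters(cs)
        assert f1 == truth["sizes"].max() / fr.n

    def test_rg_periodic_equals_open_for_small_cluster(self):
        blob = build_cluster(40, 2.0, 1.0, seed=3)
        com = blob.mean(axis=0)
        rg_open = np.sqrt(((blob - com) ** 2).sum(axis=1).mean())
        # place near a corner so it wraps
        fr = frame_from_positions(blob - blob.min(axis=0) + 47.0, L=50.0)
        crit = SimulationCriterion(cutoff=1.1)
        graph = contact_pairs(fr, crit)
        cs = annotate_geometry(cluster_labels(graph), graph, fr)
        assert cs.n_clusters == 1
        assert cs.gyration_radii[0] == pytest.approx(rg_open, rel=1e-9)
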
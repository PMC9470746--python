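"""Decomposition enumeration, length distributions and connectivity."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import mitomorph as mm
from mitomorph.length_interpreter import LengthDistribution

from conftest import chain_topology, star_topology
from oracles import brute_force_decompositions


class TestEnumerateDecompositions:
    def test_path_graph_has_single_forced_decomposition(self, tubule_fixture):
        _, _, graph = tubule_fixture
        decs, sampled = mm.enumerate_decompositions(graph)
        assert len(decs) == 1 and not sampled
        assert len(decs[0].path_lengths_um) == 1

    @pytest.mark.parametrize("n_arms, expected", [(3, 4), (4, 10), (5, 26)])
    def test_star_junction_counts_follow_involution_numbers(self, n_arms, expected):
        top = star_topology([2.0**i for i in range(n_arms)])
        decs, sampled = mm.enumerate_decompositions(top)
        assert len(decs) == expected and not sampled

    @pytest.mark.parametrize(
        "top_builder",
        [
            lambda: star_topology([1.0, 2.0, 4.0]),
            lambda: star_topology([1.0, 2.0, 4.0, 8.0]),
            lambda: chain_topology([[1.0], [2.0]], [4.0]),
            lambda: chain_topology([[1.0], [2.0], [4.0]], [8.0, 16.0]),
        ],
        ids=["Y", "X", "2-junction", "3-junction"],
    )
    def test_matches_brute_force_edge_partition_search(self, top_builder):
        """Stub-matching enumeration equals exhaustive search over all
        edge partitions into simple paths (distinct power-of-two lengths
        make the length multiset identify each partition)."""
        top = top_builder()
        decs, _ = mm.enumerate_decompositions(top)
        ours = sorted(tuple(sorted(round(x, 9) for x in d.path_lengths_um))
                      for d in decs)
        assert ours == brute_force_decompositions(top)

    def test_sampling_kicks_in_beyond_cap_and_is_seeded(self):
        top = star_topology([1.0] * 8)  # 764 matchings
        decs, sampled = mm.enumerate_decompositions(top, max_enumeration=100, seed=7)
        decs2, _ = mm.enumerate_decompositions(top, max_enumeration=100, seed=7)
        assert sampled and len(decs) == 100
        assert [d.path_lengths_um for d in decs] == [d.path_lengths_um for d in decs2]


class TestLengthDistribution:
    def test_single_tubule_mass_in_one_bin(self, tubule_fixture):
        _, _, graph = tubule_fixture
        dist = mm.length_distribution([graph])
        assert dist.masses.sum() == pytest.approx(1.0, abs=1e-9)
        i = np.searchsorted(dist.bin_edges_um, 4.0) - 1
        assert dist.masses[max(0, i - 1): i + 2].sum() == pytest.approx(1.0)

    def test_symmetric_y_weighting_convention(self):
        """Y with three 1 µm arms: the three through-pairings contribute
        two paths {2, 1} each, the all-terminate reading three 1 µm
        paths; with 1/D path counting the 1 µm mass is 6/9 = 2/3."""
        top = star_topology([1.0, 1.0, 1.0])
        dist = mm.length_distribution([top], bin_width_um=0.25)
        at1 = dist.masses[np.isclose(dist.bin_edges_um[:-1], 1.0)].sum()
        at2 = dist.masses[np.isclose(dist.bin_edges_um[:-1], 2.0)].sum()
        assert at1 == pytest.approx(2 / 3, abs=1e-9)
        assert at2 == pytest.approx(1 / 3, abs=1e-9)

    def test_junction_free_population_reduces_to_component_histogram(self):
        masks = [mm.generate_tubule_2d(L, orientation_deg=a)[0]
                 for L, a in [(1.0, 0), (3.0, 30), (5.0, 75)]]
        graphs = [mm.skeletonize(m, spacing_um=0.1)[0] for m in masks]
        dist = mm.length_distribution(graphs)
        lengths = [mm.component_length(g) for g in graphs]
        expected, _ = np.histogram(lengths, bins=dist.bin_edges_um)
        np.testing.assert_allclose(dist.masses, expected / expected.sum(), atol=1e-12)

    def test_two_tubules_equal_mass(self):
        g1 = mm.skeletonize(mm.generate_tubule_2d(1.0)[0], spacing_um=0.1)[0]
        g2 = mm.skeletonize(mm.generate_tubule_2d(3.0)[0], spacing_um=0.1)[0]
        dist = mm.length_distribution([g1, g2])
        assert dist.masses[dist.masses > 0].tolist() == [0.5, 0.5]

    def test_empty_cluster_list_raises(self):
        with pytest.raises(ValueError):
            mm.length_distribution([])


class TestConnectivity:
    def test_isolated_population_is_zero(self, tubule_fixture):
        _, _, graph = tubule_fixture
        s = mm.decompose_elements(graph)
        assert mm.connectivity([s, s, s]) == 0.0

    def test_worked_ratios(self, y_fixture, h_fixture):
        sy = mm.decompose_elements(y_fixture[2])
        sh = mm.decompose_elements(h_fixture[2])
        assert mm.connectivity([sy]) == pytest.approx(1 / 4)
        assert mm.connectivity([sh]) == pytest.approx(2 / 6)

    def test_adding_a_junction_increases_connectivity(self, tubule_fixture, y_fixture):
        st_, sy = mm.decompose_elements(tubule_fixture[2]), mm.decompose_elements(y_fixture[2])
        pop = [st_] * 5
        assert mm.connectivity(pop + [sy]) > mm.connectivity(pop + [st_])

    def test_pure_cycle_population_is_one_by_definition(self):
        ring = np.zeros((30, 30), bool)
        rr, cc = np.mgrid[0:30, 0:30]
        r = np.hypot(rr - 15, cc - 15)
        ring[(r > 8) & (r < 11)] = True
        g = mm.skeletonize(ring, spacing_um=0.1)[0]
        s = mm.decompose_elements(g)
        if s.n_ends + s.n_junctions == 0:  # clean ring skeleton
            assert mm.connectivity([s]) == 1.0


class TestFractionLongerThan:
    def test_point_mass_above_threshold(self):
        edges = np.arange(0, 10.25, 0.25)
        m = np.zeros(40)
        m[12] = 1.0  # 3.0-3.25 µm bin
        assert mm.fraction_longer_than(LengthDistribution(edges, m), 2.0) == 1.0

    def test_uniform_mass_split_at_midpoint(self):
        edges = np.linspace(0, 4, 17)
        dist = LengthDistribution(edges, np.full(16, 1 / 16))
        assert mm.fraction_longer_than(dist, 2.0) == pytest.approx(0.5)

    def test_straddling_bin_pro_rata(self):
        dist = LengthDistribution(np.array([0.0, 1.0, 2.0]), np.array([0.5, 0.5]))
        assert mm.fraction_longer_than(dist, 1.5) == pytest.approx(0.25)

    def test_threshold_outside_range_raises(self):
        dist = LengthDistribution(np.array([0.0, 1.0]), np.array([1.0]))
        with pytest.raises(ValueError):
            mm.fraction_longer_than(dist, 5.0)


@settings(max_examples=30, derandomize=True)
@given(st.lists(st.floats(0.01, 10.0), min_size=2, max_size=10),
       st.floats(0.1, 9.9))
def test_fraction_monotone_in_threshold(raw, thr):
    m = np.asarray(raw)
    edges = np.arange(0, 10.5, 0.5)
    counts, _ = np.histogram(np.linspace(0.2, 9.8, len(m)), bins=edges, weights=m)
    dist = LengthDistribution(edges, counts / counts.sum())
    lo = mm.fraction_longer_than(dist, max(0.0, thr - 0.1))
    hi = mm.fraction_longer_than(dist, thr)
    assert 0.0 <= hi <= lo <= 1.0 + 1e-12
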
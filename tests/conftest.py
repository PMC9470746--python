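"""Shared fixtures: rasterized fixture masks and topology builders."""

import networkx as nx
import numpy as np
import pytest

import mitomorph as mm


def star_topology(arm_lengths_um):
    """Topology multigraph of a single junction with one arm per length."""
    top = nx.MultiGraph()
    j = ("junction", 0)
    for i, L in enumerate(arm_lengths_um):
        top.add_edge(("end", (i,)), j, length_um=float(L))
    return top


def chain_topology(junction_arm_lengths, spine_lengths):
    """Caterpillar: junctions along a spine, each with pendant arms.

    ``spine_lengths`` has len(junctions)-1 entries; each junction j gets
    the pendant arms listed in ``junction_arm_lengths[j]`` plus spine
    edges to its neighbours, plus terminal spine stubs at both ends.
    """
    top = nx.MultiGraph()
    nj = len(junction_arm_lengths)
    js = [("junction", k) for k in range(nj)]
    eid = 0
    for k, arms in enumerate(junction_arm_lengths):
        for L in arms:
            top.add_edge(("end", (eid,)), js[k], length_um=float(L))
            eid += 1
    for k, L in enumerate(spine_lengths):
        top.add_edge(js[k], js[k + 1], length_um=float(L))
    # terminal stubs so end junctions reach degree >= 3
    top.add_edge(("end", (eid,)), js[0], length_um=0.5)
    top.add_edge(("end", (eid + 1,)), js[-1], length_um=0.5)
    return top


@pytest.fixture(scope="session")
def tubule_fixture():
    """4 µm straight tubule: mask, truth, skeleton graph."""
    mask, truth = mm.generate_tubule_2d(4.0, radius_um=0.15, orientation_deg=0.0)
    graphs = mm.skeletonize(mask, spacing_um=0.1)
    assert len(graphs) == 1
    return mask, truth, graphs[0]


@pytest.fixture(scope="session")
def y_fixture():
    """Y-shape (trunk with two branches at its terminus): 3 ends, 1
    junction, 3 tubules = 7 elements."""
    mask, truth = mm.generate_branched_2d(
        2.0, [1.5, 1.5], branch_positions=[1.0, 1.0],
        branch_angles_deg=[45, -45])
    graphs = mm.skeletonize(mask, spacing_um=0.1)
    assert len(graphs) == 1
    return mask, truth, graphs[0]


@pytest.fixture(scope="session")
def h_fixture():
    """Two-junction shape: 4 ends, 2 junctions, 5 tubules = 11 elements."""
    mask, truth = mm.generate_branched_2d(
        3.0, [1.5, 1.5], branch_positions=[0.33, 0.67],
        branch_angles_deg=[70, -70])
    graphs = mm.skeletonize(mask, spacing_um=0.1)
    assert len(graphs) == 1
    return mask, truth, graphs[0]


@pytest.fixture(scope="session")
def fused_beads_volume():
    """Two r=0.2 µm beads joined by a thin neck, fused into one label."""
    specs = mm.synthetic_data.fused_beads_spec_3d(
        2, bead_radius_um=0.2, neck_radius_um=0.06, center_um=(0.75, 0.4, 0.4))
    labels, truth = mm.generate_volume_3d(
        specs, voxel_size_um=(0.01, 0.01, 0.01), volume_shape=(80, 80, 150),
        fuse=True)
    return labels, truth
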
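"""Skeletonization and element decomposition of mitochondrial networks.

A binary mitochondrial mask (2D confocal-style or 3D FIB-SEM-style) is
reduced to a single-point-wide skeleton, and each connected component is
turned into a spatial graph. The graph is then decomposed into the three
element classes used throughout mitochondrial network morphometry:

* **end** — a skeleton node of degree 1;
* **junction** — a merged clump of skeleton nodes of degree >= 3;
* **tubule** — a maximal junction-free path between ends/junctions.

An isolated, unbranched mitochondrion therefore has exactly three
elements (two ends and one tubule), while fused networks accumulate
junctions and tubules; connected components with more than a configurable
number of elements are treated as clusters downstream.

All coordinates and lengths are physical (micrometres); anisotropic 3D
voxel spacing is honoured, and 3D thinning runs on an isotropically
resampled copy of the mask because thinning algorithms assume isotropy.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import ndimage as ndi
from skimage.morphology import skeletonize as _skimage_skeletonize

__all__ = [
    "SkeletonGraph",
    "ElementSummary",
    "skeletonize",
    "decompose_elements",
    "component_length",
]

#: chessboard radius (in skeleton grid steps) within which adjacent
#: degree->=3 pixels are merged into a single junction
JUNCTION_MERGE_RADIUS = 2

#: default spur-pruning threshold in micrometres
DEFAULT_PRUNE_SPUR_UM = 0.1


@dataclass
class SkeletonGraph:
    """Spatial graph of one connected skeleton component.

    Nodes are skeleton grid points (index tuples); each node carries a
    ``coord_um`` attribute with its physical coordinate. Edges connect
    neighbouring skeleton points (8-connected in 2D, 26-connected in 3D)
    and carry ``length_um``, the physical step length.
    """

    graph: nx.Graph
    spacing_um: tuple[float, ...]
    component_id: int = 0

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    def total_length_um(self) -> float:
        return float(sum(d["length_um"] for _, _, d in self.graph.edges(data=True)))

    def to_json(self) -> str:
        """Export nodes (µm coordinates, degree) and edges for inspection."""
        nodes = [
            {
                "id": list(map(int, n)),
                "coord_um": [float(c) for c in self.graph.nodes[n]["coord_um"]],
                "degree": int(self.graph.degree(n)),
            }
            for n in self.graph.nodes
        ]
        edges = [
            {"a": list(map(int, a)), "b": list(map(int, b)), "length_um": float(d["length_um"])}
            for a, b, d in self.graph.edges(data=True)
        ]
        return json.dumps(
            {"component_id": self.component_id, "spacing_um": list(self.spacing_um),
             "nodes": nodes, "edges": edges}
        )


@dataclass
class ElementSummary:
    """Element counts of one connected component.

    ``n_elements = n_ends + n_junctions + n_tubules`` is the quantity the
    cluster rule (> 7 elements) operates on. ``has_cycle`` flags
    components whose topology graph contains a loop; the Euler identity
    ``n_tubules = n_ends + sum_j(deg_j - 2) - 1`` holds only for acyclic
    components.
    """

    n_ends: int
    n_junctions: int
    n_tubules: int
    total_length_um: float
    has_cycle: bool = False
    junction_degrees: tuple[int, ...] = field(default_factory=tuple)

    @property
    def n_elements(self) -> int:
        return self.n_ends + self.n_junctions + self.n_tubules


def _neighbor_offsets(ndim: int) -> list[tuple[int, ...]]:
    offs = [o for o in itertools.product((-1, 0, 1), repeat=ndim) if any(o)]
    return offs


def _build_pixel_graph(coords: np.ndarray, spacing: np.ndarray) -> nx.Graph:
    """Graph over skeleton grid points; edges between full-neighbourhood
    neighbours with physical step lengths."""
    g = nx.Graph()
    index = {tuple(c): i for i, c in enumerate(map(tuple, coords))}
    for c in index:
        g.add_node(c, coord_um=np.asarray(c, dtype=float) * spacing)
    offsets = _neighbor_offsets(coords.shape[1])
    for c in index:
        for off in offsets:
            nb = tuple(np.add(c, off))
            if nb in index and nb > c:  # each pair once
                step = float(np.linalg.norm(np.asarray(off, dtype=float) * spacing))
                g.add_edge(c, nb, length_um=step)
    return g


def _prune_spurs(g: nx.Graph, prune_spur_um: float) -> None:
    """Remove terminal whiskers shorter than ``prune_spur_um``.

    Only branches hanging off a junction are pruned; a component that is
    a bare path is never shortened. Iterates until stable.
    """
    if prune_spur_um <= 0:
        return
    changed = True
    while changed:
        changed = False
        leaves = [n for n in g.nodes if g.degree(n) == 1]
        for leaf in leaves:
            if leaf not in g:
                continue
            # walk from the leaf to the first node of degree != 2
            path = [leaf]
            length = 0.0
            cur, prev = leaf, None
            while True:
                nbrs = [n for n in g.neighbors(cur) if n != prev]
                if g.degree(cur) >= 3 or not nbrs:
                    break
                if cur != leaf and g.degree(cur) != 2:
                    break
                nxt = nbrs[0]
                length += g.edges[cur, nxt]["length_um"]
                prev, cur = cur, nxt
                path.append(cur)
                if g.degree(cur) != 2:
                    break
            if g.degree(cur) >= 3 and length < prune_spur_um:
                g.remove_nodes_from(path[:-1])
                changed = True


def skeletonize(
    mask: np.ndarray,
    spacing_um: float | tuple[float, ...],
    prune_spur_um: float = DEFAULT_PRUNE_SPUR_UM,
) -> list[SkeletonGraph]:
    """Skeletonize a binary mask and return one :class:`SkeletonGraph` per
    connected foreground component.

    Parameters
    ----------
    mask
        2D or 3D boolean array. 3D arrays are in (z, y, x) axis order.
    spacing_um
        Physical size of one step along each axis, in the array's axis
        order; a scalar means isotropic.
    prune_spur_um
        Terminal skeleton branches shorter than this are removed before
        graph construction (medial-axis whiskers are not biology).

    Returns
    -------
    list of SkeletonGraph — empty for an empty mask.
    """
    mask = np.asarray(mask).astype(bool)
    if mask.ndim not in (2, 3):
        raise ValueError(f"mask must be 2D or 3D, got {mask.ndim}D")
    if np.isscalar(spacing_um):
        spacing = np.full(mask.ndim, float(spacing_um))
    else:
        spacing = np.asarray(spacing_um, dtype=float)
        if spacing.shape != (mask.ndim,):
            raise ValueError("spacing_um must match mask dimensionality")
    if (spacing <= 0).any():
        raise ValueError("spacing_um must be positive")
    if not mask.any():
        return []

    # 3D thinning assumes isotropy: resample to the minimum axis spacing.
    work_spacing = spacing
    work = mask
    if mask.ndim == 3 and not np.allclose(spacing, spacing[0]):
        iso = float(spacing.min())
        zoom = spacing / iso
        work = ndi.zoom(mask.astype(np.uint8), zoom, order=0).astype(bool)
        work_spacing = np.full(3, iso)

    skel = _skimage_skeletonize(work)
    if not skel.any():
        # degenerate tiny objects can thin away entirely; keep one point
        # per component at its centroid so the object is still reported
        structure = np.ones((3,) * mask.ndim, dtype=int)
        labels, n = ndi.label(work, structure=structure)
        skel = np.zeros_like(work)
        for com in ndi.center_of_mass(work, labels, range(1, n + 1)):
            skel[tuple(int(round(c)) for c in com)] = True

    structure = np.ones((3,) * skel.ndim, dtype=int)
    labels, n_comp = ndi.label(skel, structure=structure)
    graphs: list[SkeletonGraph] = []
    for cid in range(1, n_comp + 1):
        coords = np.argwhere(labels == cid)
        g = _build_pixel_graph(coords, work_spacing)
        _prune_spurs(g, prune_spur_um)
        if g.number_of_nodes() == 0:
            continue
        graphs.append(
            SkeletonGraph(graph=g, spacing_um=tuple(work_spacing), component_id=cid - 1)
        )
    return graphs


# ---------------------------------------------------------------------------
# topology condensation: pixel graph -> (ends, merged junctions, tubules)
# ---------------------------------------------------------------------------


def _junction_clusters(g: nx.Graph) -> list[set]:
    """Group degree->=3 pixels whose chessboard separation is within
    :data:`JUNCTION_MERGE_RADIUS` into single junctions."""
    jpix = [n for n in g.nodes if g.degree(n) >= 3]
    aux = nx.Graph()
    aux.add_nodes_from(jpix)
    for a, b in itertools.combinations(jpix, 2):
        if max(abs(x - y) for x, y in zip(a, b)) <= JUNCTION_MERGE_RADIUS:
            aux.add_edge(a, b)
    return [set(c) for c in nx.connected_components(aux)]


def _smoothed_chain_length(coords: list[np.ndarray], window: int = 2) -> float:
    """Polyline length of a pixel chain after endpoint-preserving
    moving-average smoothing.

    Raw step sums overestimate oblique digital lines by up to ~8%
    (staircase bias); averaging each interior point over its ±``window``
    neighbours removes the zigzag while leaving collinear chains — and
    hence axis-aligned and 45° paths — exactly unchanged.
    """
    pts = np.asarray(coords, dtype=float)
    n = len(pts)
    if n < 3:
        return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum()) if n == 2 else 0.0
    sm = pts.copy()
    for i in range(1, n - 1):
        lo, hi = max(0, i - window), min(n, i + window + 1)
        sm[i] = pts[lo:hi].mean(axis=0)
    return float(np.linalg.norm(np.diff(sm, axis=0), axis=1).sum())


def topology_graph(skel: SkeletonGraph) -> nx.MultiGraph:
    """Condense a pixel-level skeleton graph into the element topology.

    Returns a multigraph whose nodes are ``("end", pixel)`` /
    ``("junction", k)`` and whose edges are tubules carrying
    ``length_um``. Edges internal to a junction clump are absorbed into
    the junction (their tiny length is added to the adjacent tubule).
    A pure cycle (all degree-2) is returned as a single self-looped
    tubule on an arbitrary anchor node ``("cycle", pixel)``.
    """
    g = skel.graph
    clusters = _junction_clusters(g)
    pix2cluster: dict[tuple, int] = {}
    for k, cl in enumerate(clusters):
        for p in cl:
            pix2cluster[p] = k

    def node_of(p):
        if p in pix2cluster:
            return ("junction", pix2cluster[p])
        if g.degree(p) == 1 or g.degree(p) == 0:
            return ("end", p)
        return None  # interior path pixel

    top = nx.MultiGraph()
    if g.number_of_nodes() == 1:
        p = next(iter(g.nodes))
        top.add_node(("end", p))
        return top

    terminals = {p for p in g.nodes if node_of(p) is not None}
    for p in terminals:
        top.add_node(node_of(p))

    visited_edges: set[frozenset] = set()
    for start in terminals:
        for nb in g.neighbors(start):
            ekey = frozenset((start, nb))
            if ekey in visited_edges:
                continue
            if start in pix2cluster and nb in pix2cluster and \
                    pix2cluster[start] == pix2cluster[nb]:
                visited_edges.add(ekey)  # intra-junction edge: absorbed
                continue
            # walk the chain, collecting physical coordinates
            chain = [g.nodes[start]["coord_um"], g.nodes[nb]["coord_um"]]
            visited_edges.add(ekey)
            prev, cur = start, nb
            while cur not in terminals:
                nxts = [n for n in g.neighbors(cur) if n != prev]
                if not nxts:
                    break
                nxt = nxts[0]
                visited_edges.add(frozenset((cur, nxt)))
                chain.append(g.nodes[nxt]["coord_um"])
                prev, cur = cur, nxt
            end_node = node_of(cur) if cur in terminals else ("end", cur)
            top.add_edge(node_of(start), end_node,
                         length_um=_smoothed_chain_length(chain))

    # pure cycles: degree-2 loops reachable from no terminal
    leftover = [n for n in g.nodes if n not in terminals
                and not any(frozenset((n, nb)) in visited_edges for nb in g.neighbors(n))]
    if leftover:
        sub = g.subgraph(leftover)
        for comp in nx.connected_components(sub):
            comp_sub = g.subgraph(comp)
            length = sum(d["length_um"] for _, _, d in comp_sub.edges(data=True))
            anchor = ("cycle", min(comp))
            top.add_node(anchor)
            top.add_edge(anchor, anchor, length_um=length)
    return top


def decompose_elements(skel: SkeletonGraph) -> ElementSummary:
    """Count ends, junctions and tubules of one connected component.

    A single-point component is reported as an isolated mitochondrion
    (two ends, one tubule, zero length): the smallest observable object
    still carries the minimal three-element structure.
    """
    top = topology_graph(skel)
    if top.number_of_edges() == 0:
        return ElementSummary(
            n_ends=2, n_junctions=0, n_tubules=1,
            total_length_um=0.0, has_cycle=False,
        )
    n_ends = sum(1 for n in top.nodes if n[0] == "end")
    junctions = [n for n in top.nodes if n[0] == "junction"]
    n_tubules = top.number_of_edges()
    has_cycle = top.number_of_edges() >= nx.number_of_nodes(top)
    # MultiGraph cycle check: edges >= nodes works for connected graphs
    total = float(sum(d["length_um"] for _, _, d in top.edges(data=True)))
    return ElementSummary(
        n_ends=n_ends,
        n_junctions=len(junctions),
        n_tubules=n_tubules,
        total_length_um=total,
        has_cycle=has_cycle,
        junction_degrees=tuple(sorted(top.degree(j) for j in junctions)),
    )


def component_length(skel: SkeletonGraph) -> float:
    """Total geodesic skeleton length of a component, in micrometres.

    Summed over the component's tubules, each measured as a smoothed
    pixel-chain polyline (see :func:`_smoothed_chain_length`); for a
    straight or 45°-diagonal skeleton this equals the raw step sum, and
    a single-point skeleton has length 0.
    """
    top = topology_graph(skel)
    return float(sum(d["length_um"] for _, _, d in top.edges(data=True)))
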
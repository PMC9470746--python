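"""Probabilistic structure interpreter for skeletonized mitochondrial networks.

A 2D projection (or a fused 3D network) does not reveal which tubules
belong to the same physical mitochondrion: at every junction, two of the
incident branches may continue as one organelle, or organelles may
terminate there. The interpreter makes this ambiguity explicit by
enumerating *all* consistent readings of a network and averaging over
them.

At a junction of degree ``d`` the incident branch stubs can be pairwise
matched: a matching pairs some stubs (each pair continues through the
junction as one mitochondrion) and leaves the rest unpaired (a
mitochondrion terminates there). Every combination of one partial
matching per junction yields one *decomposition* of the component's
tubules into mitochondrial paths. For ``d`` stubs there are 1, 1, 2, 4,
10, 26, ... partial matchings (the involution numbers), so the space is
enumerable for realistic junctions and is sampled beyond a configurable
cap.

Each decomposition of a cluster receives weight ``1/D`` (``D`` = number
of decompositions of that cluster); within a decomposition each
constituent path contributes its length with that weight as a count.
Accumulated counts over all clusters are normalized globally into a
probability distribution over mitochondrial length. A junction-free
population therefore reduces exactly to the empirical histogram of
component lengths.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .skeleton_graph import ElementSummary, SkeletonGraph, topology_graph

__all__ = [
    "PathDecomposition",
    "LengthDistribution",
    "NetworkSummary",
    "enumerate_decompositions",
    "length_distribution",
    "connectivity",
    "fraction_longer_than",
]

DEFAULT_BIN_WIDTH_UM = 0.25
DEFAULT_BIN_MAX_UM = 10.0
DEFAULT_MAX_ENUMERATION = 10_000


@dataclass(frozen=True)
class PathDecomposition:
    """One reading of a cluster: a partition of its tubules into
    mitochondrial paths, each with its physical length."""

    path_lengths_um: tuple[float, ...]
    #: parallel to path_lengths_um; True where the path closed into a loop
    closed: tuple[bool, ...] = ()
    #: frozensets of tubule edge keys, parallel to path_lengths_um
    path_edges: tuple[frozenset, ...] = ()


@dataclass
class LengthDistribution:
    """Binned probability mass over mitochondrial length (µm)."""

    bin_edges_um: np.ndarray
    masses: np.ndarray
    #: True when decomposition spaces were subsampled rather than enumerated
    sampled: bool = False

    def __post_init__(self):
        self.bin_edges_um = np.asarray(self.bin_edges_um, dtype=float)
        self.masses = np.asarray(self.masses, dtype=float)
        if self.bin_edges_um.ndim != 1 or len(self.bin_edges_um) != len(self.masses) + 1:
            raise ValueError("bin_edges_um must have len(masses)+1 entries")
        if np.any(np.diff(self.bin_edges_um) <= 0):
            raise ValueError("bin edges must be strictly increasing")
        if (self.masses < -1e-12).any():
            raise ValueError("negative probability mass")
        total = self.masses.sum()
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"masses must sum to 1, got {total}")

    @property
    def bin_width_um(self) -> float:
        return float(self.bin_edges_um[1] - self.bin_edges_um[0])

    def midpoints(self) -> np.ndarray:
        return 0.5 * (self.bin_edges_um[:-1] + self.bin_edges_um[1:])

    def cdf(self) -> np.ndarray:
        return np.cumsum(self.masses)

    def median_um(self) -> float:
        """Midpoint of the first bin whose cumulative mass reaches 0.5
        (ties resolved to the lower bin)."""
        idx = int(np.searchsorted(self.cdf(), 0.5 - 1e-12))
        idx = min(idx, len(self.masses) - 1)
        return float(self.midpoints()[idx])

    def mean_um(self) -> float:
        return float(np.dot(self.midpoints(), self.masses))


@dataclass
class NetworkSummary:
    """Cell-level network statistics mirroring the standard morphometry
    readouts: element complexity, connectivity, phenotype coverage and
    the long-mitochondria fraction."""

    mean_elements_per_cluster: float
    connectivity: float
    area_fractions: dict[str, float] = field(default_factory=dict)
    fraction_length_gt_2um: float = 0.0


# ---------------------------------------------------------------------------
# stub matchings
# ---------------------------------------------------------------------------


def _partial_matchings(stubs: list) -> list[list[tuple]]:
    """All partial matchings (including the empty one) of a stub list."""
    if len(stubs) < 2:
        return [[]]
    first, rest = stubs[0], stubs[1:]
    out = [m for m in _partial_matchings(rest)]  # first unpaired
    for i, other in enumerate(rest):
        remaining = rest[:i] + rest[i + 1:]
        for m in _partial_matchings(remaining):
            out.append([(first, other)] + m)
    return out


def _involution_numbers(d: int) -> list[int]:
    # a(k) = a(k-1) + (k-1)*a(k-2): number of partial matchings of k items
    vals = [1, 1]
    for k in range(2, d + 1):
        vals.append(vals[k - 1] + (k - 1) * vals[k - 2])
    return vals


def _n_partial_matchings(d: int) -> int:
    return _involution_numbers(d)[d]


def _sample_partial_matching(stubs: list, rng) -> list[tuple]:
    """Draw one partial matching uniformly at random without enumerating
    the (super-exponential) matching space."""
    from fractions import Fraction

    a = _involution_numbers(len(stubs))
    pool = list(stubs)
    out = []
    while len(pool) >= 2:
        d = len(pool)
        # the first stub stays unpaired in a(d-1) of the a(d) matchings
        if rng.random() < float(Fraction(a[d - 1], a[d])):
            pool.pop(0)
        else:
            j = 1 + int(rng.integers(d - 1))
            out.append((pool[0], pool[j]))
            pool.pop(j)
            pool.pop(0)
    return out


def _paths_from_matching(edges: list[tuple], pairing: dict) -> list[tuple[float, bool, frozenset]]:
    """Chain tubule edges through stub pairings into mitochondrial paths.

    ``edges`` is a list of (key, u, v, length); stubs are (key, side).
    Returns (total length, closed?, edge-key set) per path.
    """
    lengths = {k: ln for k, _, _, ln in edges}
    visited: set = set()
    paths: list[tuple[float, bool, frozenset]] = []

    def other_side(stub):
        k, side = stub
        return (k, 1 - side)

    # open paths start at unpaired stubs
    all_stubs = [(k, s) for k, _, _, _ in edges for s in (0, 1)]
    start_stubs = [s for s in all_stubs if s not in pairing]
    for s0 in start_stubs:
        if s0[0] in visited:
            continue
        total = 0.0
        used = []
        stub = s0
        while True:
            k = stub[0]
            if k in visited:
                break
            visited.add(k)
            used.append(k)
            total += lengths[k]
            far = other_side(stub)
            if far not in pairing:
                break
            stub = pairing[far]
        paths.append((total, False, frozenset(used)))

    # remaining edges belong to closed chains
    for k, _, _, _ in edges:
        if k in visited:
            continue
        total = 0.0
        used = []
        stub = (k, 0)
        while stub[0] not in visited:
            kk = stub[0]
            visited.add(kk)
            used.append(kk)
            total += lengths[kk]
            far = other_side(stub)
            stub = pairing.get(far, far)
            if stub == far:  # unpaired far side should not happen here
                break
        paths.append((total, True, frozenset(used)))
    return paths


def enumerate_decompositions(
    skel: SkeletonGraph | nx.MultiGraph,
    max_enumeration: int = DEFAULT_MAX_ENUMERATION,
    seed: int = 0,
    keep_edges: bool = True,
) -> tuple[list[PathDecomposition], bool]:
    """Enumerate (or sample) all junction-pairing decompositions of a
    connected cluster.

    Returns ``(decompositions, sampled)`` where ``sampled`` is True when
    the combinatorial space exceeded ``max_enumeration`` and a seeded
    uniform sample of that size was drawn instead.
    """
    top = skel if isinstance(skel, nx.MultiGraph) else topology_graph(skel)
    edges = [
        (key, u, v, d["length_um"])
        for key, (u, v, d) in enumerate(
            (u, v, d) for u, v, d in top.edges(data=True)
        )
    ]
    if not edges:
        return [PathDecomposition(path_lengths_um=(0.0,), closed=(False,),
                                  path_edges=(frozenset(),))], False

    # self-loops anchored on a pure cycle are closed paths by construction
    cycle_keys = {key for key, u, v, _ in edges if u[0] == "cycle" or v[0] == "cycle"}

    # stubs per junction node
    junction_stubs: dict = {}
    for key, u, v, _ in edges:
        for side, node in ((0, u), (1, v)):
            if node[0] == "junction":
                junction_stubs.setdefault(node, []).append((key, side))

    junctions = sorted(junction_stubs)
    counts = [_n_partial_matchings(len(junction_stubs[j])) for j in junctions]
    total = 1
    for c in counts:  # exact big-int product; junction-rich graphs overflow int64
        total *= c
        if total > max_enumeration:
            break

    def decomp_from(per_junction_matchings: list[list[tuple]]) -> PathDecomposition:
        pairing: dict = {}
        for m in per_junction_matchings:
            for a, b in m:
                pairing[a] = b
                pairing[b] = a
        paths = _paths_from_matching(edges, pairing)
        paths.sort(key=lambda p: (p[0], sorted(p[2])))
        return PathDecomposition(
            path_lengths_um=tuple(p[0] for p in paths),
            closed=tuple(p[1] or bool(p[2] & cycle_keys) for p in paths),
            path_edges=tuple(p[2] for p in paths) if keep_edges else (),
        )

    sampled = total > max_enumeration
    decomps: list[PathDecomposition] = []
    if not sampled:
        matchings = [_partial_matchings(junction_stubs[j]) for j in junctions]
        import itertools as _it

        for combo in _it.product(*matchings) if junctions else [()]:
            decomps.append(decomp_from(list(combo)))
    else:
        rng = np.random.default_rng(seed)
        for _ in range(max_enumeration):
            combo = [_sample_partial_matching(junction_stubs[j], rng)
                     for j in junctions]
            decomps.append(decomp_from(combo))
    return decomps, sampled


# ---------------------------------------------------------------------------
# distribution assembly
# ---------------------------------------------------------------------------


def length_distribution(
    clusters: list[SkeletonGraph],
    bin_width_um: float = DEFAULT_BIN_WIDTH_UM,
    bin_max_um: float = DEFAULT_BIN_MAX_UM,
    max_enumeration: int = DEFAULT_MAX_ENUMERATION,
    seed: int = 0,
    include_closed: bool = True,
) -> LengthDistribution:
    """Whole-cell probability distribution over mitochondrial length.

    Every decomposition of a cluster carries equal weight ``1/D``;
    within a decomposition each constituent path contributes one count at
    that weight. Counts accumulate over all clusters and are normalized
    to unit mass at the end, so a cluster's total mass is proportional to
    its expected path count.
    """
    if not clusters:
        raise ValueError("length_distribution requires at least one cluster")
    if bin_width_um <= 0:
        raise ValueError("bin_width_um must be positive")

    # stream counts into bins: junction-rich clusters can carry 10^4
    # sampled decompositions with hundreds of paths each
    bin_counts: dict[int, float] = {}
    any_sampled = False
    for skel in clusters:
        decomps, sampled = enumerate_decompositions(
            skel, max_enumeration=max_enumeration, seed=seed, keep_edges=False
        )
        any_sampled = any_sampled or sampled
        w = 1.0 / len(decomps)
        for dec in decomps:
            for ln, closed in zip(dec.path_lengths_um, dec.closed):
                if closed and not include_closed:
                    continue
                idx = int(ln // bin_width_um)
                bin_counts[idx] = bin_counts.get(idx, 0.0) + w

    if not bin_counts:
        raise ValueError("no path mass accumulated")
    n_bins = max(int(np.ceil(round(bin_max_um / bin_width_um, 9))),
                 max(bin_counts) + 1)
    edges = np.arange(n_bins + 1) * bin_width_um
    counts = np.zeros(n_bins)
    for idx, c in bin_counts.items():
        counts[idx] = c
    return LengthDistribution(bin_edges_um=edges, masses=counts / counts.sum(),
                              sampled=any_sampled)


def connectivity(summaries: list[ElementSummary]) -> float:
    """Network connectivity: junctions / (junctions + ends), pooled over
    all components.

    0 for fully fragmented populations (no junctions); approaches 1 for
    hyperfused networks. A population with neither ends nor junctions
    (pure cycles) is defined as 1.
    """
    if not summaries:
        raise ValueError("connectivity requires at least one component")
    j = sum(s.n_junctions for s in summaries)
    e = sum(s.n_ends for s in summaries)
    if j + e == 0:
        return 1.0
    return j / (j + e)


def fraction_longer_than(dist: LengthDistribution, threshold_um: float) -> float:
    """Probability mass above a length threshold, with a linear pro-rata
    share of the bin the threshold falls in."""
    edges = dist.bin_edges_um
    if not (edges[0] <= threshold_um <= edges[-1]):
        raise ValueError("threshold outside the distribution's bin range")
    lo, hi = edges[:-1], edges[1:]
    full = dist.masses[lo >= threshold_um].sum()
    strad = (lo < threshold_um) & (hi > threshold_um)
    if strad.any():
        i = int(np.argmax(strad))
        share = (hi[i] - threshold_um) / (hi[i] - lo[i])
        full += dist.masses[i] * share
    return float(full)
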
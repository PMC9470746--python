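"""Synthetic mitochondria with exact ground truth.

Two families of scenes are produced:

* **2D confocal-style scenes** — tubular objects (straight or branched
  capsules) rasterized at a known pixel calibration, optionally rendered
  with a Gaussian PSF, Poisson shot noise, Gaussian read noise and a
  background offset, emulating TMRM-stained live confocal images.
* **3D FIB-SEM-style volumes** — digital capsules (cylinders with
  hemispherical end caps), branched tubes and fused bead clusters
  rasterized on an anisotropic voxel grid (default 5 nm in XY, 10 nm in
  Z, matching serial FIB-SEM acquisition).

Every generated object carries analytic ground truth: centerline length,
element counts derived from the construction topology, phenotype, and
(in 3D) the analytic capsule volume pi*r^2*L + 4/3*pi*r^3. Rasterization
is distance-to-centerline in *physical* units, so anisotropic voxels are
handled exactly and the truth does not depend on the grid.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import ndimage as ndi

__all__ = [
    "MitoSpec",
    "ObjectTruth",
    "SceneTruth",
    "generate_tubule_2d",
    "generate_branched_2d",
    "render_fluorescence_2d",
    "generate_scene_2d",
    "generate_volume_3d",
    "tubule_spec_3d",
    "fused_beads_spec_3d",
    "capsule_volume_um3",
]

DEFAULT_CALIBRATION_UM_PER_PX = 0.1  # assumed confocal pixel size
DEFAULT_VOXEL_SIZE_UM = (0.005, 0.005, 0.010)  # (x, y, z) FIB-SEM-like


@dataclass
class MitoSpec:
    """Geometric specification of one mitochondrion-like object.

    ``centerline`` is an ordered array of control points in µm, in (x, y)
    or (x, y, z) order; ``branches`` attach additional centerlines at
    points that must lie on an existing centerline.
    """

    shape_class: str  # tubule | branched | cluster
    centerline: np.ndarray
    radius_um: float
    branches: list[tuple[np.ndarray, np.ndarray]] = field(default_factory=list)
    # each branch: (attachment point on an existing centerline, branch centerline)

    def __post_init__(self):
        self.centerline = np.atleast_2d(np.asarray(self.centerline, dtype=float))
        if self.centerline.shape[0] < 2:
            raise ValueError("centerline needs at least 2 points")
        if self.radius_um <= 0:
            raise ValueError("radius_um must be positive")
        if self.shape_class not in ("tubule", "branched", "cluster"):
            raise ValueError(f"unknown shape_class {self.shape_class!r}")

    def all_polylines(self) -> list[np.ndarray]:
        out = [self.centerline]
        for _, bl in self.branches:
            out.append(np.atleast_2d(np.asarray(bl, dtype=float)))
        return out

    def total_length_um(self) -> float:
        return float(sum(np.linalg.norm(np.diff(pl, axis=0), axis=1).sum()
                         for pl in self.all_polylines()))


@dataclass
class ObjectTruth:
    """Ground truth for one generated object."""

    true_length_um: float
    true_element_counts: dict[str, int]
    true_phenotype: str
    true_volume_um3: float | None = None
    label: int | None = None


@dataclass
class SceneTruth:
    """Ground truth and provenance for a generated scene."""

    objects: list[ObjectTruth]
    calibration: tuple[float, ...] | float
    image_shape: tuple[int, ...]
    noise: dict = field(default_factory=dict)
    seed: int | None = None

    def to_json(self) -> str:
        def enc(o):
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, (np.integer, np.floating)):
                return o.item()
            raise TypeError(type(o))

        return json.dumps(dataclasses.asdict(self), default=enc, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "SceneTruth":
        d = json.loads(text)
        objs = [ObjectTruth(**o) for o in d.pop("objects")]
        cal = d.pop("calibration")
        cal = tuple(cal) if isinstance(cal, list) else cal
        return cls(objects=objs, calibration=cal,
                   image_shape=tuple(d.pop("image_shape")), **d)


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------


def _dist_to_segment(points: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Euclidean distance from each point (physical units) to segment ab."""
    ab = b - a
    denom = float(ab @ ab)
    if denom == 0:
        return np.linalg.norm(points - a, axis=-1)
    t = np.clip(((points - a) @ ab) / denom, 0.0, 1.0)
    proj = a + t[..., None] * ab
    return np.linalg.norm(points - proj, axis=-1)


def _rasterize_polylines_2d(
    polylines: list[np.ndarray],
    radius_um: float,
    calibration: float,
    image_shape: tuple[int, int],
) -> np.ndarray:
    """Capsule rasterization: pixel center within ``radius_um`` of any
    centerline segment (distances in µm)."""
    h, w = image_shape
    mask = np.zeros((h, w), dtype=bool)
    pad = radius_um / calibration + 1.5
    for pl in polylines:
        for a, b in zip(pl[:-1], pl[1:]):
            # bounding box in pixel coords (x, y µm -> col, row px)
            lo = np.minimum(a, b) / calibration - pad
            hi = np.maximum(a, b) / calibration + pad
            c0, r0 = int(max(0, np.floor(lo[0]))), int(max(0, np.floor(lo[1])))
            c1, r1 = int(min(w, np.ceil(hi[0]) + 1)), int(min(h, np.ceil(hi[1]) + 1))
            if c0 >= c1 or r0 >= r1:
                continue
            rr, cc = np.mgrid[r0:r1, c0:c1]
            pts = np.stack([(cc + 0.5) * calibration, (rr + 0.5) * calibration], axis=-1)
            d = _dist_to_segment(pts, a, b)
            mask[r0:r1, c0:c1] |= d <= radius_um
    return mask


def _check_fits_2d(polylines, radius_um, calibration, image_shape) -> None:
    h, w = image_shape
    for pl in polylines:
        lo = pl.min(axis=0) - radius_um
        hi = pl.max(axis=0) + radius_um
        if lo[0] < 0 or lo[1] < 0 or hi[0] > w * calibration or hi[1] > h * calibration:
            raise ValueError(
                f"object extent [{lo}, {hi}] µm exceeds image bounds "
                f"({w * calibration:.2f} x {h * calibration:.2f} µm)"
            )


def _topology_counts(polylines: list[np.ndarray], tol: float = 1e-6) -> dict[str, int]:
    """Analytic element counts from construction topology.

    Builds a graph whose nodes are polyline endpoints and attachment
    points; ends = degree-1 nodes, junctions = degree->=3 nodes, tubules
    = edges of the condensed graph (degree-2 nodes are pass-through, so a
    collinear attachment at a terminus does not create a junction).
    """
    def key(p):
        return tuple(np.round(np.asarray(p) / tol).astype(np.int64))

    g = nx.MultiGraph()
    # split polylines at points that coincide with other polylines' endpoints
    endpoints = [pl[i] for pl in polylines for i in (0, -1)]
    for pl in polylines:
        # find interior split points: endpoints of other polylines lying on pl
        cuts = [0.0, 1.0]
        seglens = np.linalg.norm(np.diff(pl, axis=0), axis=1)
        total = seglens.sum()
        cum = np.concatenate([[0.0], np.cumsum(seglens)])
        for p in endpoints:
            # arc position of p on pl, if on pl
            for i, (a, b) in enumerate(zip(pl[:-1], pl[1:])):
                d = _dist_to_segment(np.asarray(p, dtype=float)[None, :], a, b)[0]
                if d < tol * 10:
                    ab = b - a
                    t = float(((p - a) @ ab) / (ab @ ab)) if (ab @ ab) > 0 else 0.0
                    cuts.append((cum[i] + np.clip(t, 0, 1) * seglens[i]) / total)
        cuts = sorted(set(np.round(cuts, 9)))
        # nodes at each cut position
        def point_at(s):
            target = s * total
            i = int(np.searchsorted(cum[1:], target - 1e-12))
            i = min(i, len(seglens) - 1)
            t = (target - cum[i]) / seglens[i] if seglens[i] > 0 else 0.0
            return pl[i] + t * (pl[i + 1] - pl[i])

        for s0, s1 in zip(cuts[:-1], cuts[1:]):
            if s1 - s0 < 1e-12:
                continue
            g.add_edge(key(point_at(s0)), key(point_at(s1)),
                       length=(s1 - s0) * total)

    ends = sum(1 for n in g.nodes if g.degree(n) == 1)
    junctions = sum(1 for n in g.nodes if g.degree(n) >= 3)
    # condense degree-2 pass-through nodes: tubules = condensed edge count
    tubules = g.number_of_edges() - sum(1 for n in g.nodes if g.degree(n) == 2)
    return {"ends": ends, "junctions": junctions, "tubules": tubules}


def classify_truth(counts: dict[str, int], cluster_element_threshold: int = 7) -> str:
    n_el = counts["ends"] + counts["junctions"] + counts["tubules"]
    if n_el > cluster_element_threshold:
        return "clustered"
    if counts["junctions"] >= 1:
        return "branched"
    return "isolated"


# ---------------------------------------------------------------------------
# 2D generators
# ---------------------------------------------------------------------------


def generate_tubule_2d(
    length_um: float,
    radius_um: float = 0.15,
    orientation_deg: float = 0.0,
    calibration_um_per_px: float = DEFAULT_CALIBRATION_UM_PER_PX,
    image_shape: tuple[int, int] = (128, 128),
    center_um: tuple[float, float] | None = None,
) -> tuple[np.ndarray, SceneTruth]:
    """Rasterize one straight tubule of known length.

    The object is a capsule: all pixels whose center lies within
    ``radius_um`` of a centerline segment of length ``length_um``.
    Raises if the length is below two pixels or the capsule does not fit
    in the image.
    """
    cal = float(calibration_um_per_px)
    if length_um < 2 * cal:
        raise ValueError(f"length {length_um} µm is below 2 px at {cal} µm/px")
    h, w = image_shape
    if center_um is None:
        center_um = (w * cal / 2, h * cal / 2)
    theta = np.deg2rad(orientation_deg)
    d = np.array([np.cos(theta), np.sin(theta)])
    c = np.asarray(center_um, dtype=float)
    pl = np.stack([c - d * length_um / 2, c + d * length_um / 2])
    _check_fits_2d([pl], radius_um, cal, image_shape)
    mask = _rasterize_polylines_2d([pl], radius_um, cal, image_shape)
    counts = {"ends": 2, "junctions": 0, "tubules": 1}
    truth = SceneTruth(
        objects=[ObjectTruth(true_length_um=float(length_um),
                             true_element_counts=counts,
                             true_phenotype=classify_truth(counts))],
        calibration=cal, image_shape=tuple(image_shape),
    )
    return mask, truth


def generate_branched_2d(
    trunk_um: float,
    branch_lengths_um: list[float],
    calibration: float = DEFAULT_CALIBRATION_UM_PER_PX,
    image_shape: tuple[int, int] = (160, 160),
    branch_positions: list[float] | None = None,
    branch_angles_deg: list[float] | None = None,
    radius_um: float = 0.15,
    orientation_deg: float = 0.0,
) -> tuple[np.ndarray, SceneTruth]:
    """Rasterize a branched object: a straight trunk with branches
    attached at fractional positions along it.

    Element counts in the truth are computed analytically from the
    construction topology (attachments of total degree >= 3 are
    junctions; a single collinear branch at a trunk terminus merges into
    the trunk). Branches that would overlap away from their attachment
    point — silently merging the topology — raise an error.
    """
    if not branch_lengths_um:
        raise ValueError("need at least one branch")
    cal = float(calibration)
    h, w = image_shape
    cx, cy = w * cal / 2, h * cal / 2
    rot = np.deg2rad(orientation_deg)
    tdir = np.array([np.cos(rot), np.sin(rot)])
    trunk = np.stack([np.array([cx, cy]) - tdir * trunk_um / 2,
                      np.array([cx, cy]) + tdir * trunk_um / 2])
    nb = len(branch_lengths_um)
    if branch_positions is None:
        branch_positions = [(i + 1) / (nb + 1) for i in range(nb)]
    if branch_angles_deg is None:
        branch_angles_deg = [60.0 if i % 2 == 0 else -60.0 for i in range(nb)]
    polylines = [trunk]
    for L, t, ang in zip(branch_lengths_um, branch_positions, branch_angles_deg):
        if not (0.0 <= t <= 1.0):
            raise ValueError("branch attachment position must be in [0, 1]")
        attach = trunk[0] + t * (trunk[1] - trunk[0])
        th = np.deg2rad(ang) + rot
        tip = attach + L * np.array([np.cos(th), np.sin(th)])
        polylines.append(np.stack([attach, tip]))
    _check_fits_2d(polylines, radius_um, cal, image_shape)
    _check_no_spurious_overlap(polylines, radius_um)
    mask = _rasterize_polylines_2d(polylines, radius_um, cal, image_shape)
    counts = _topology_counts(polylines)
    total_len = float(sum(np.linalg.norm(np.diff(pl, axis=0), axis=1).sum()
                          for pl in polylines))
    truth = SceneTruth(
        objects=[ObjectTruth(true_length_um=total_len,
                             true_element_counts=counts,
                             true_phenotype=classify_truth(counts))],
        calibration=cal, image_shape=tuple(image_shape),
    )
    return mask, truth


def _check_no_spurious_overlap(polylines: list[np.ndarray], radius_um: float) -> None:
    """Reject constructions where two segments come within one tube
    diameter of each other away from a shared endpoint (the rasterized
    topology would differ from the analytic truth)."""
    segs = []
    for pi, pl in enumerate(polylines):
        for a, b in zip(pl[:-1], pl[1:]):
            segs.append((pi, a, b))
    for i in range(len(segs)):
        for j in range(i + 1, len(segs)):
            pi, a1, b1 = segs[i]
            pj, a2, b2 = segs[j]
            shared = any(np.allclose(p, q) for p in (a1, b1) for q in (a2, b2))
            # sample points along seg j, excluding the shared-junction zone
            ts = np.linspace(0, 1, 25)
            pts = a2 + ts[:, None] * (b2 - a2)
            d = _dist_to_segment(pts, a1, b1)
            if shared:
                # ignore the neighbourhood of the shared endpoint
                keep = np.ones(len(pts), dtype=bool)
                for p in (a1, b1):
                    keep &= np.linalg.norm(pts - p, axis=1) > 3 * radius_um
                d = d[keep]
            if d.size and d.min() < 2.2 * radius_um:
                # attachment contact (branch base on trunk) is fine:
                att_ok = shared or _dist_to_segment(a2[None, :], a1, b1)[0] < 1e-9 \
                    or _dist_to_segment(a1[None, :], a2, b2)[0] < 1e-9
                if not att_ok:
                    raise ValueError("branches overlap away from their attachment; "
                                     "topology truth would be wrong")
                # even for attached pairs, far ends must not collide
                far = d[np.linalg.norm(pts - a2, axis=1) > 3 * radius_um] \
                    if _dist_to_segment(a2[None, :], a1, b1)[0] < 1e-9 else d
                if far.size and far.min() < 2.2 * radius_um:
                    raise ValueError("branch folds back onto the trunk; "
                                     "topology truth would be wrong")


def render_fluorescence_2d(
    mask: np.ndarray,
    psf_sigma_um: float = 0.15,
    poisson_scale: float = 0.0,
    gaussian_sd: float = 0.0,
    background: float = 0.0,
    seed: int = 0,
    calibration_um_per_px: float = DEFAULT_CALIBRATION_UM_PER_PX,
) -> np.ndarray:
    """Forward-model a binary mask into a fluorescence-like image.

    signal = blur(mask + background) -> Poisson(signal*scale)/scale ->
    + Gaussian(0, sd). With zero blur and zero noise the output equals
    mask + background, so thresholding recovers the mask exactly.
    Deterministic for a fixed seed.
    """
    if psf_sigma_um < 0 or poisson_scale < 0 or gaussian_sd < 0 or background < 0:
        raise ValueError("noise/blur parameters must be non-negative")
    rng = np.random.default_rng(seed)
    img = mask.astype(float) + background
    if psf_sigma_um > 0:
        img = ndi.gaussian_filter(img, sigma=psf_sigma_um / calibration_um_per_px)
    if poisson_scale > 0:
        img = rng.poisson(np.clip(img, 0, None) * poisson_scale) / poisson_scale
    if gaussian_sd > 0:
        img = img + rng.normal(0.0, gaussian_sd, size=img.shape)
    return img


def generate_scene_2d(
    n_objects: int = 15,
    length_range_um: tuple[float, float] = (0.5, 7.0),
    branched_fraction: float = 0.2,
    radius_um: float = 0.15,
    calibration: float = DEFAULT_CALIBRATION_UM_PER_PX,
    image_shape: tuple[int, int] = (512, 512),
    seed: int = 0,
    max_tries: int = 200,
) -> tuple[np.ndarray, SceneTruth]:
    """Scatter non-overlapping tubules (and a fraction of Y-branched
    objects) across an image; lengths uniform over ``length_range_um``
    (the confocal study's observed 0.5–7 µm span).
    """
    rng = np.random.default_rng(seed)
    h, w = image_shape
    mask = np.zeros(image_shape, dtype=bool)
    objects: list[ObjectTruth] = []
    placed = 0
    tries = 0
    sep = 2 * radius_um + 2 * calibration
    while placed < n_objects and tries < max_tries * n_objects:
        tries += 1
        L = float(rng.uniform(*length_range_um))
        ang = float(rng.uniform(0, 180))
        is_branched = rng.random() < branched_fraction and L >= 1.0
        margin = (L / 2 + radius_um + 2 * calibration)
        cx = float(rng.uniform(margin, w * calibration - margin))
        cy = float(rng.uniform(margin, h * calibration - margin))
        try:
            if is_branched:
                bl = max(0.4, L * 0.4)
                sub, truth = generate_branched_2d(
                    trunk_um=L, branch_lengths_um=[bl], branch_positions=[0.5],
                    branch_angles_deg=[float(rng.uniform(35, 90))],
                    calibration=calibration, image_shape=image_shape,
                    radius_um=radius_um)
                # recenter by rolling the sub-mask
                dy = int(round((cy - h * calibration / 2) / calibration))
                dx = int(round((cx - w * calibration / 2) / calibration))
                sub = np.roll(np.roll(sub, dy, axis=0), dx, axis=1)
            else:
                sub, truth = generate_tubule_2d(
                    L, radius_um=radius_um, orientation_deg=ang,
                    calibration_um_per_px=calibration, image_shape=image_shape,
                    center_um=(cx, cy))
        except ValueError:
            continue
        grown = ndi.binary_dilation(sub, iterations=max(1, int(np.ceil(sep / calibration))))
        if (grown & mask).any():
            continue
        mask |= sub
        objects.append(truth.objects[0])
        placed += 1
    return mask, SceneTruth(objects=objects, calibration=calibration,
                            image_shape=tuple(image_shape), seed=seed)


# ---------------------------------------------------------------------------
# 3D generators
# ---------------------------------------------------------------------------


def capsule_volume_um3(length_um: float, radius_um: float) -> float:
    """Analytic volume of a capsule (cylinder + two hemispherical caps)."""
    return float(np.pi * radius_um**2 * length_um + 4.0 / 3.0 * np.pi * radius_um**3)


def tubule_spec_3d(
    length_um: float, radius_um: float,
    start_um: tuple[float, float, float],
    direction: tuple[float, float, float] = (1.0, 0.0, 0.0),
) -> MitoSpec:
    """Convenience: a straight 3D capsule spec (coordinates in µm, x/y/z)."""
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    a = np.asarray(start_um, dtype=float)
    return MitoSpec("tubule", np.stack([a, a + d * length_um]), radius_um)


def fused_beads_spec_3d(
    n_beads: int, bead_radius_um: float, neck_radius_um: float,
    center_um: tuple[float, float, float],
    spacing_um: float | None = None,
    axis: tuple[float, float, float] = (1.0, 0.0, 0.0),
) -> list[MitoSpec]:
    """A chain of near-spherical beads joined by thin necks — the fused
    cluster fixture watershed splitting must resolve.

    Each bead is a capsule with a very short centerline (≈ a sphere);
    necks are thin capsules linking consecutive bead centers.
    """
    if spacing_um is None:
        spacing_um = 2.2 * bead_radius_um
    ax = np.asarray(axis, dtype=float)
    ax = ax / np.linalg.norm(ax)
    c = np.asarray(center_um, dtype=float)
    start = c - ax * spacing_um * (n_beads - 1) / 2
    eps = bead_radius_um * 0.02
    specs = []
    centers = [start + ax * spacing_um * i for i in range(n_beads)]
    for bc in centers:
        specs.append(MitoSpec("tubule", np.stack([bc - ax * eps, bc + ax * eps]),
                              bead_radius_um))
    for a, b in zip(centers[:-1], centers[1:]):
        specs.append(MitoSpec("tubule", np.stack([a, b]), neck_radius_um))
    return specs


def _rasterize_spec_3d(spec: MitoSpec, voxel_size_xyz: np.ndarray,
                       shape_zyx: tuple[int, int, int]) -> np.ndarray:
    nz, ny, nx = shape_zyx
    vx, vy, vz = voxel_size_xyz
    mask = np.zeros(shape_zyx, dtype=bool)
    r = spec.radius_um
    for pl in spec.all_polylines():
        for a, b in zip(pl[:-1], pl[1:]):
            lo = np.minimum(a, b) - r
            hi = np.maximum(a, b) + r
            x0 = int(max(0, np.floor(lo[0] / vx - 1)))
            y0 = int(max(0, np.floor(lo[1] / vy - 1)))
            z0 = int(max(0, np.floor(lo[2] / vz - 1)))
            x1 = int(min(nx, np.ceil(hi[0] / vx + 1)))
            y1 = int(min(ny, np.ceil(hi[1] / vy + 1)))
            z1 = int(min(nz, np.ceil(hi[2] / vz + 1)))
            if x0 >= x1 or y0 >= y1 or z0 >= z1:
                continue
            zz, yy, xx = np.mgrid[z0:z1, y0:y1, x0:x1]
            pts = np.stack([(xx + 0.5) * vx, (yy + 0.5) * vy, (zz + 0.5) * vz],
                           axis=-1)
            d = _dist_to_segment(pts, a, b)
            mask[z0:z1, y0:y1, x0:x1] |= d <= r
    return mask


def generate_volume_3d(
    specs: list[MitoSpec],
    voxel_size_um: tuple[float, float, float] = DEFAULT_VOXEL_SIZE_UM,
    volume_shape: tuple[int, int, int] = (64, 128, 128),
    fuse: bool = False,
    seed: int | None = None,
) -> tuple[np.ndarray, SceneTruth]:
    """Rasterize 3D specs into a label volume (z, y, x axis order).

    With ``fuse=False`` each spec keeps its own label (later specs win on
    overlap); with ``fuse=True`` touching objects share one
    connectivity-derived label while the truth retains the individual
    identities — the fixture for watershed splitting. Truth volumes are
    the analytic capsule volumes.
    """
    vs = np.asarray(voxel_size_um, dtype=float)
    if (vs <= 0).any():
        raise ValueError("voxel sizes must be positive")
    nz, ny, nx = volume_shape
    extent = np.array([nx * vs[0], ny * vs[1], nz * vs[2]])
    labels = np.zeros(volume_shape, dtype=np.int32)
    objects: list[ObjectTruth] = []
    union = np.zeros(volume_shape, dtype=bool)
    for i, spec in enumerate(specs, start=1):
        for pl in spec.all_polylines():
            lo = pl.min(axis=0) - spec.radius_um
            hi = pl.max(axis=0) + spec.radius_um
            if (lo < 0).any() or (hi > extent).any():
                raise ValueError(f"spec {i} exceeds volume bounds {extent} µm")
        m = _rasterize_spec_3d(spec, vs, volume_shape)
        L = spec.total_length_um()
        counts = _topology_counts(spec.all_polylines())
        objects.append(ObjectTruth(
            true_length_um=L,
            true_element_counts=counts,
            true_phenotype=classify_truth(counts),
            true_volume_um3=capsule_volume_um3(L, spec.radius_um),
            label=i,
        ))
        labels[m] = i
        union |= m
    if fuse:
        structure = np.ones((3, 3, 3), dtype=int)
        fused, _ = ndi.label(union, structure=structure)
        labels = fused.astype(np.int32)
    truth = SceneTruth(objects=objects, calibration=tuple(vs),
                       image_shape=tuple(volume_shape), seed=seed)
    return labels, truth
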
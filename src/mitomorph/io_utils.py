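"""File I/O, run configuration and the end-to-end pipelines.

TIFF in, CSV/JSON out. 2D images carry their calibration in the TIFF
resolution tags (pixels per µm); 3D stacks are multi-page TIFFs whose
anisotropic voxel size comes from the run configuration. Every report
embeds a provenance block (package version, configuration, assumption
list) so a run is reproducible from its outputs.

Axis conventions: stacks are (z, y, x), 0-based; voxel sizes are stated
as (x, y, z) µm. All reported coordinates and lengths are physical µm.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from . import __version__
from .length_interpreter import (LengthDistribution, NetworkSummary,
                                 connectivity, fraction_longer_than,
                                 length_distribution)
from .phenotype2d import (ComponentRecord, area_coverage, classify_cell,
                          classify_component)
from .preprocess2d import CalibratedImage, binarize
from .skeleton_graph import decompose_elements, skeletonize
from .synthetic_data import SceneTruth
from .volume3d import LabelVolume, analyze_volume, volume_report

logger = logging.getLogger("mitomorph")

__all__ = [
    "RunConfig",
    "read_image",
    "read_stack",
    "write_image",
    "write_stack",
    "run_pipeline2d",
    "run_pipeline3d",
]

CSV_SCHEMA_VERSION = "1"

ASSUMPTIONS = [
    "threshold method and despeckle floor are configurable assumptions "
    "(no preprocessing is prescribed by the source protocol)",
    "junction merge radius 2 px; spurs < prune_spur_um pruned",
    "connectivity = junctions / (junctions + ends)",
    "cell phenotype from median length at thresholds (1, 2, 4) µm",
    "cluster rule: > cluster_element_threshold elements "
    "(3D also: >= 2 watershed sub-objects)",
    "decomposition weighting: each path counts 1/D per cluster, "
    "global normalization",
]


@dataclass
class RunConfig:
    """All tunables of one analysis run; round-trips through JSON."""

    calibration_um_per_px: float = 0.1
    voxel_size_um: tuple[float, float, float] = (0.005, 0.005, 0.010)
    threshold_method: str = "otsu"
    fixed_threshold: float | None = None
    min_object_area_um2: float = 0.04
    cluster_element_threshold: int = 7
    cell_thresholds_um: tuple[float, float, float] = (1.0, 2.0, 4.0)
    watershed_seed_min_distance_um: float = 0.15
    bin_width_um: float = 0.25
    prune_spur_um: float = 0.1
    max_enumeration: int = 10_000
    seed: int = 0
    out_dir: str = "."

    def __post_init__(self):
        for name in ("calibration_um_per_px", "min_object_area_um2",
                     "watershed_seed_min_distance_um", "bin_width_um"):
            if getattr(self, name) is not None and name != "min_object_area_um2" \
                    and getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if any(v <= 0 for v in self.voxel_size_um):
            raise ValueError("voxel sizes must be positive")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        d = json.loads(text)
        if "voxel_size_um" in d:
            d["voxel_size_um"] = tuple(d["voxel_size_um"])
        if "cell_thresholds_um" in d:
            d["cell_thresholds_um"] = tuple(d["cell_thresholds_um"])
        return cls(**d)

    def provenance(self) -> dict:
        cfg = self.to_json()
        return {
            "package": "mitomorph",
            "version": __version__,
            "csv_schema": CSV_SCHEMA_VERSION,
            "config": json.loads(cfg),
            "config_sha256": hashlib.sha256(cfg.encode()).hexdigest()[:16],
            "assumptions": ASSUMPTIONS,
        }


# ---------------------------------------------------------------------------
# TIFF I/O
# ---------------------------------------------------------------------------


def write_image(path: str | Path, pixels: np.ndarray, calibration_um_per_px: float,
                truth: SceneTruth | None = None) -> None:
    """Write a 2D image with its calibration in the resolution tags;
    optionally write a ground-truth JSON sidecar (`.truth.json`)."""
    ppu = 1.0 / calibration_um_per_px  # pixels per micrometre
    arr = pixels.astype(np.float32) if pixels.dtype.kind == "f" \
        else pixels.astype(np.uint8)
    tifffile.imwrite(path, arr, resolution=(ppu, ppu),
                     metadata={"unit": "um"})
    if truth is not None:
        Path(path).with_suffix(".truth.json").write_text(truth.to_json())


def write_stack(path: str | Path, data: np.ndarray,
                voxel_size_um: tuple[float, float, float],
                truth: SceneTruth | None = None) -> None:
    """Write a (z, y, x) stack as a multi-page TIFF; XY calibration in
    the resolution tags, Z spacing in the ImageJ metadata."""
    vx, vy, vz = voxel_size_um
    tifffile.imwrite(path, data.astype(np.int32), imagej=False,
                     resolution=(1.0 / vx, 1.0 / vy),
                     metadata={"unit": "um", "spacing": vz})
    if truth is not None:
        Path(path).with_suffix(".truth.json").write_text(truth.to_json())


def _calibration_from_tags(tif: tifffile.TiffFile) -> float | None:
    page = tif.pages[0]
    tag = page.tags.get("XResolution")
    if tag is None:
        return None
    num, den = tag.value
    if num == 0 or (num, den) == (1, 1):  # (1,1) is the writer default
        return None
    return den / num  # µm per pixel when unit is µm


def read_image(path: str | Path,
               calibration_um_per_px: float | None = None) -> CalibratedImage:
    """Read a single-channel 2D TIFF.

    Calibration comes from the TIFF resolution tags when present; an
    explicit ``calibration_um_per_px`` overrides them (with a logged
    warning on conflict) and is required when tags are missing.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        tag_cal = _calibration_from_tags(tif)
    if data.ndim == 3 and data.shape[-1] in (3, 4):
        raise ValueError(f"{path}: RGB images are not supported; "
                         "a single channel is required")
    if data.ndim != 2:
        raise ValueError(f"{path}: expected a 2D image, got shape {data.shape}")
    if calibration_um_per_px is not None:
        if tag_cal is not None and not np.isclose(tag_cal, calibration_um_per_px,
                                                  rtol=1e-3):
            logger.warning("%s: calibration %.4g µm/px overrides TIFF tag %.4g",
                           path, calibration_um_per_px, tag_cal)
        cal = calibration_um_per_px
    elif tag_cal is not None:
        cal = tag_cal
    else:
        raise ValueError(f"{path}: no resolution tags; pass a calibration")
    return CalibratedImage(pixels=data, calibration_um_per_px=cal)


def read_stack(path: str | Path,
               voxel_size_um: tuple[float, float, float] | None = None
               ) -> LabelVolume:
    """Read a multi-page TIFF as a (z, y, x) label volume."""
    path = Path(path)
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D stack, got shape {data.shape}")
    if voxel_size_um is None:
        raise ValueError(f"{path}: voxel size (x,y,z) in µm is required")
    return LabelVolume(data=np.asarray(data), voxel_size_um=tuple(voxel_size_um))


def read_truth_sidecar(path: str | Path) -> SceneTruth | None:
    sidecar = Path(path).with_suffix(".truth.json")
    if sidecar.exists():
        return SceneTruth.from_json(sidecar.read_text())
    return None


# ---------------------------------------------------------------------------
# pipelines
# ---------------------------------------------------------------------------


def analyze_mask_2d(mask_pixels: np.ndarray, calibration: float,
                    config: RunConfig):
    """Shared 2D core: mask -> component records + length distribution."""
    graphs = skeletonize(mask_pixels, spacing_um=calibration,
                         prune_spur_um=config.prune_spur_um)
    if not graphs:
        raise ValueError("no foreground components in the mask")
    from scipy import ndimage as ndi
    labels, n = ndi.label(mask_pixels, structure=np.ones((3, 3), dtype=int))
    areas = ndi.sum_labels(mask_pixels.astype(bool), labels,
                           index=np.arange(1, n + 1)) * calibration**2
    records = []
    summaries = []
    for i, g in enumerate(graphs):
        s = decompose_elements(g)
        summaries.append(s)
        # map graph to mask component via any skeleton pixel
        pix = next(iter(g.graph.nodes))
        comp = int(labels[pix]) if labels[pix] > 0 else i + 1
        records.append(ComponentRecord(
            component_id=i,
            summary=s,
            area_um2=float(areas[comp - 1]) if comp - 1 < len(areas) else
            float(mask_pixels.sum()) * calibration**2,
            phenotype=classify_component(s, config.cluster_element_threshold),
        ))
    dist = length_distribution(graphs, bin_width_um=config.bin_width_um,
                               max_enumeration=config.max_enumeration,
                               seed=config.seed)
    return records, summaries, dist


def run_pipeline2d(config: RunConfig, image_path: str | Path,
                   cell_id: str = "cell") -> dict:
    """Confocal-style pipeline: image -> mask -> skeleton graphs ->
    element summaries, length distribution, phenotypes, coverage.

    Writes per-component CSV, the binned distribution CSV and a JSON
    summary into ``config.out_dir``; returns the summary dict.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    image = read_image(image_path, config.calibration_um_per_px)
    mask = binarize(image, method=config.threshold_method,
                    fixed_threshold=config.fixed_threshold,
                    min_object_area_um2=config.min_object_area_um2)
    records, summaries, dist = analyze_mask_2d(
        mask.pixels, mask.calibration_um_per_px, config)
    coverage = area_coverage(records)
    cell = classify_cell(dist, config.cell_thresholds_um)
    net = NetworkSummary(
        mean_elements_per_cluster=float(np.mean([s.n_elements for s in summaries])),
        connectivity=connectivity(summaries),
        area_fractions=coverage.area_fractions,
        fraction_length_gt_2um=fraction_longer_than(dist, 2.0),
    )
    # per-component CSV
    pd.DataFrame([{
        "component_id": r.component_id,
        "n_ends": r.summary.n_ends,
        "n_junctions": r.summary.n_junctions,
        "n_tubules": r.summary.n_tubules,
        "n_elements": r.summary.n_elements,
        "total_length_um": r.summary.total_length_um,
        "area_um2": r.area_um2,
        "phenotype": r.phenotype,
    } for r in records]).to_csv(out / f"{cell_id}_components.csv", index=False)
    pd.DataFrame({
        "bin_low_um": dist.bin_edges_um[:-1],
        "bin_high_um": dist.bin_edges_um[1:],
        "mass": dist.masses,
    }).to_csv(out / f"{cell_id}_length_distribution.csv", index=False)
    summary = {
        "cell_id": cell_id,
        "threshold_used": mask.threshold_used,
        "n_components": len(records),
        "cell_phenotype": cell.label,
        "median_length_um": cell.median_length_um,
        "mean_elements_per_cluster": net.mean_elements_per_cluster,
        "connectivity": net.connectivity,
        "area_fractions": net.area_fractions,
        "fraction_length_gt_2um": net.fraction_length_gt_2um,
        "isolated_gt2um_area_fraction": coverage.isolated_gt2um_area_fraction,
        "provenance": config.provenance(),
    }
    (out / f"{cell_id}_summary.json").write_text(json.dumps(summary, indent=1))
    return summary


def run_pipeline3d(config: RunConfig, stack_path: str | Path,
                   scene_id: str = "volume") -> dict:
    """FIB-SEM-style pipeline: stack -> components -> watershed split ->
    per-object volume/Feret/elements -> population report."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    vol = read_stack(stack_path, config.voxel_size_um)
    records = analyze_volume(
        vol, seed_min_distance_um=config.watershed_seed_min_distance_um,
        cluster_element_threshold=config.cluster_element_threshold)
    if not records:
        raise ValueError("no objects in the volume")
    report = volume_report(records)
    pd.DataFrame([{
        "object_id": r.object_id,
        "parent_component_id": r.parent_component_id,
        "volume_um3": r.volume_um3,
        "feret_min_um": r.feret_min_um,
        "feret_max_um": r.feret_max_um,
        "n_elements": r.summary.n_elements if r.summary else None,
        "phenotype": r.phenotype,
    } for r in records]).to_csv(out / f"{scene_id}_objects.csv", index=False)
    summary = {
        "scene_id": scene_id,
        "n_objects": report.n_objects,
        "total_volume_um3": report.total_volume_um3,
        "abundance_fractions": report.abundance_fractions,
        "volume_fractions": report.volume_fractions,
        "isolated_length_bins": report.isolated_length_bins,
        "provenance": config.provenance(),
    }
    (out / f"{scene_id}_summary.json").write_text(json.dumps(summary, indent=1))
    return summary
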
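"""Phenotype classification and coverage statistics for 2D scenes.

Connected components are classified by their element content:

* **clustered** — more than ``cluster_element_threshold`` (default 7)
  elements, i.e. a connected network of several mitochondria;
* **branched** — at least one junction but not cluster-sized;
* **isolated** — an unbranched organelle (two ends, one tubule).

Whole cells are classified short / intermediate / long / very long from
the median of their mitochondrial length distribution (thresholds 1, 2
and 4 µm by default — the median is robust to a single large cluster).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .length_interpreter import LengthDistribution
from .skeleton_graph import ElementSummary

__all__ = [
    "ComponentRecord",
    "CellPhenotype",
    "CoverageReport",
    "classify_component",
    "area_coverage",
    "classify_cell",
]

DEFAULT_CLUSTER_ELEMENT_THRESHOLD = 7
DEFAULT_CELL_THRESHOLDS_UM = (1.0, 2.0, 4.0)
PHENOTYPES = ("isolated", "branched", "clustered")
CELL_LABELS = ("short", "intermediate", "long", "very long")


@dataclass
class ComponentRecord:
    """One connected 2D component: elements, physical area, phenotype."""

    component_id: int
    summary: ElementSummary
    area_um2: float
    phenotype: str

    def __post_init__(self):
        if self.area_um2 <= 0:
            raise ValueError("area must be positive")
        if self.phenotype not in PHENOTYPES:
            raise ValueError(f"unknown phenotype {self.phenotype!r}")


@dataclass
class CellPhenotype:
    label: str
    median_length_um: float


@dataclass
class CoverageReport:
    """Per-phenotype area fractions plus the size structure of the
    non-clustered population."""

    area_fractions: dict[str, float]
    total_area_um2: float
    #: total skeleton lengths (µm) of the non-clustered components
    non_cluster_lengths_um: list[float]
    #: fraction of isolated-component area held by components longer than 2 µm
    isolated_gt2um_area_fraction: float


def classify_component(
    summary: ElementSummary,
    cluster_element_threshold: int = DEFAULT_CLUSTER_ELEMENT_THRESHOLD,
) -> str:
    """Three-way phenotype from element counts: clustered iff
    ``n_elements > threshold``, else branched iff any junction, else
    isolated."""
    if summary.n_elements > cluster_element_threshold:
        return "clustered"
    if summary.n_junctions >= 1:
        return "branched"
    return "isolated"


def area_coverage(records: list[ComponentRecord]) -> CoverageReport:
    """Area fraction covered by each phenotype, plus the non-clustered
    size distribution and the share of isolated area held by organelles
    longer than 2 µm."""
    if not records:
        raise ValueError("area_coverage requires at least one component")
    total = sum(r.area_um2 for r in records)
    fractions = {p: 0.0 for p in PHENOTYPES}
    for r in records:
        fractions[r.phenotype] += r.area_um2
    fractions = {p: a / total for p, a in fractions.items()}
    non_cluster = [r for r in records if r.phenotype != "clustered"]
    isolated = [r for r in records if r.phenotype == "isolated"]
    iso_area = sum(r.area_um2 for r in isolated)
    iso_gt2 = sum(r.area_um2 for r in isolated if r.summary.total_length_um > 2.0)
    return CoverageReport(
        area_fractions=fractions,
        total_area_um2=total,
        non_cluster_lengths_um=sorted(r.summary.total_length_um for r in non_cluster),
        isolated_gt2um_area_fraction=(iso_gt2 / iso_area) if iso_area > 0 else 0.0,
    )


def classify_cell(
    dist: LengthDistribution,
    thresholds_um: tuple[float, float, float] = DEFAULT_CELL_THRESHOLDS_UM,
) -> CellPhenotype:
    """Cell-level phenotype from the median mitochondrial length.

    short if m < t0, intermediate if t0 <= m < t1, long if t1 <= m < t2,
    very long if m >= t2. When cumulative mass hits exactly 0.5 the
    median is taken from the lower bin (deterministic tie rule).
    """
    t0, t1, t2 = thresholds_um
    if not (0 < t0 < t1 < t2):
        raise ValueError("thresholds must be positive and increasing")
    m = dist.median_um()
    if m < t0:
        label = "short"
    elif m < t1:
        label = "intermediate"
    elif m < t2:
        label = "long"
    else:
        label = "very long"
    return CellPhenotype(label=label, median_length_um=m)
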
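"""Tissue-level competition readouts: mutant area coverage, epidermal
thickness maps, and proliferation/density counts.

Coverage is the mCherry-positive fraction of the analyzed basal-layer area
after excluding hair follicles; thickness is the pixelwise distance from
the air/cornified surface down to the dermo-epidermal interface; counts
are deduplicated 3D nucleus detections per unit area.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .surfaces import HeightMap

logger = logging.getLogger("epiredox")

__all__ = [
    "CoverageResult",
    "ThicknessMap",
    "CountDensity",
    "mutant_coverage",
    "thickness_map",
    "count_positive_nuclei",
    "basal_density",
]


@dataclass
class CoverageResult:
    region_id: str
    timepoint_days: float
    mutant_area_fraction: float
    analyzed_area_um2: float
    excluded_area_um2: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.mutant_area_fraction <= 1.0):
            raise ValueError("mutant_area_fraction must be in [0, 1]")


@dataclass
class ThicknessMap:
    thickness_um: np.ndarray  # NaN where undefined
    mean_thickness_um: float
    lateral_size_um: tuple[float, float]


@dataclass
class CountDensity:
    kind: str  # {PH3, BASAL_NUCLEI}
    count: int
    area_um2: float
    density_per_mm2: float


def mutant_coverage(
    genotype_mask: np.ndarray,
    exclusion_mask: np.ndarray | None,
    pixel_size_um: tuple[float, float],
    region_id: str = "region0",
    timepoint_days: float = 0.0,
) -> CoverageResult:
    """Mutant (mCherry-positive) fraction of the analyzed area.

    fraction = |genotype AND NOT excluded| / |NOT excluded|, in physical
    pixel area.  Hair follicles enter as the exclusion mask.
    """
    genotype_mask = np.asarray(genotype_mask, dtype=bool)
    if exclusion_mask is None:
        exclusion_mask = np.zeros_like(genotype_mask)
    exclusion_mask = np.asarray(exclusion_mask, dtype=bool)
    if genotype_mask.shape != exclusion_mask.shape:
        raise ValueError("genotype and exclusion masks must have the same shape")
    analyzed = ~exclusion_mask
    if not analyzed.any():
        raise ValueError("exclusion mask covers the whole field")
    px_area = float(pixel_size_um[0]) * float(pixel_size_um[1])
    n_analyzed = int(analyzed.sum())
    n_mutant = int((genotype_mask & analyzed).sum())
    fraction = n_mutant / n_analyzed
    logger.info(
        "coverage: %.4f (%d mutant px / %d analyzed px, %d excluded)",
        fraction, n_mutant, n_analyzed, int(exclusion_mask.sum()),
    )
    return CoverageResult(
        region_id=region_id,
        timepoint_days=timepoint_days,
        mutant_area_fraction=fraction,
        analyzed_area_um2=n_analyzed * px_area,
        excluded_area_um2=int(exclusion_mask.sum()) * px_area,
    )


def thickness_map(air: HeightMap, dermis: HeightMap) -> ThicknessMap:
    """Epidermal thickness: dermis depth minus air depth, pixelwise, in µm.

    Pixels where the surfaces cross (air deeper than dermis) are set to
    missing with a logged count; the mean is taken over defined pixels.
    """
    if air.depth_um.shape != dermis.depth_um.shape:
        raise ValueError("air and dermis height maps are not aligned")
    thickness = dermis.depth_um - air.depth_um
    crossing = thickness < 0
    n_cross = int(np.nansum(crossing))
    if n_cross:
        logger.warning("thickness: %d pixels with air below dermis set missing", n_cross)
        thickness = np.where(crossing, np.nan, thickness)
    defined = np.isfinite(thickness)
    if defined.mean() < 0.5:
        raise ValueError(
            f"only {defined.mean():.0%} of thickness pixels defined (<50%)"
        )
    return ThicknessMap(
        thickness_um=thickness,
        mean_thickness_um=float(np.nanmean(thickness)),
        lateral_size_um=air.lateral_size_um,
    )


def _merge_detections(points_um: np.ndarray, merge_radius_um: float) -> int:
    """Count detections after merging 3D-proximal duplicates (union-find)."""
    n = len(points_um)
    if n == 0:
        return 0
    parent = np.arange(n)

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    tree = cKDTree(points_um)
    for i, j in tree.query_pairs(merge_radius_um):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj
    return len({find(i) for i in range(n)})


def count_positive_nuclei(
    points_um: np.ndarray,
    field_area_um2: float,
    merge_radius_um: float = 3.0,
    kind: str = "PH3",
) -> CountDensity:
    """Density of positive nuclei per mm² from 3D detections.

    Detections of the same nucleus in adjacent z-slices (within
    ``merge_radius_um`` in physical 3D space) are counted once.
    """
    if field_area_um2 <= 0:
        raise ValueError("field area must be positive")
    points_um = np.atleast_2d(np.asarray(points_um, dtype=float))
    if points_um.size == 0:
        count = 0
    else:
        if points_um.shape[1] != 3:
            raise ValueError("detections must be (n, 3) physical coordinates in um")
        count = _merge_detections(points_um, merge_radius_um)
    density = count / (field_area_um2 / 1e6)  # per mm^2
    return CountDensity(kind=kind, count=count, area_um2=float(field_area_um2),
                        density_per_mm2=density)


def basal_density(
    cells_or_labels,
    band_area_um2: float,
    pixel_size_um: tuple[float, float] | None = None,
) -> CountDensity:
    """Basal nuclear density per mm² from a cell table or a 2D label map."""
    if band_area_um2 <= 0:
        raise ValueError("band area must be positive")
    if hasattr(cells_or_labels, "columns"):  # CellTable DataFrame
        cells = cells_or_labels
        if "flagged" in cells.columns:
            cells = cells.loc[~cells["flagged"].astype(bool)]
        count = int(cells["cell_id"].nunique())
    else:
        labels = np.asarray(cells_or_labels)
        count = int(len(np.unique(labels[labels > 0])))
    density = count / (band_area_um2 / 1e6)
    return CountDensity(kind="BASAL_NUCLEI", count=count,
                        area_um2=float(band_area_um2), density_per_mm2=density)
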
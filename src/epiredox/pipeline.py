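"""End-to-end convenience: stack in, per-cell redox table out.

Chains the stages in the order the analysis prescribes: collagen mask ->
dermis surface -> distance volume -> band projection -> segmentation ->
per-cell means.  Each stage remains individually accessible in its own
module; this wrapper only wires defaults together.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ImageStack, RunConfig
from .redox import per_cell_means, segment_cells
from .surfaces import (
    BandDirection,
    HeightMap,
    LayerBand,
    LayerProjection,
    SurfaceReference,
    collagen_mask,
    dermis_surface,
    distance_to_surface,
    extract_band,
)

__all__ = ["QuantifyResult", "quantify_stack"]


@dataclass
class QuantifyResult:
    cells: pd.DataFrame
    projection: LayerProjection
    dermis: HeightMap
    labels: np.ndarray
    distance_um: np.ndarray


def quantify_stack(
    stack: ImageStack,
    config: RunConfig | None = None,
    labels: np.ndarray | None = None,
    band: LayerBand | None = None,
    distance_mode: str = "euclidean",
    positive_genotype: str = "MUTANT",
) -> QuantifyResult:
    """Quantify per-cell redox ratios in the basal band of one stack.

    ``labels`` provides external ROIs (e.g. generator truth); otherwise
    watershed auto-segmentation is used.  The band defaults to the
    cytosolic 0-3 µm interval above the dermal interface.
    """
    config = config or RunConfig()
    band = band or LayerBand(
        SurfaceReference.DERMIS_SURFACE,
        *config.band_cytosolic_um,
        BandDirection.TOWARD_EPIDERMIS,
    )
    mask = collagen_mask(
        stack,
        method=config.threshold_method,
        fixed_threshold=config.fixed_threshold,
        min_object_voxels=config.min_object_voxels,
    )
    dermis = dermis_surface(mask, stack.voxel_size_um,
                            median_window=config.median_window)
    distance = distance_to_surface(stack.shape_zyx, stack.voxel_size_um, dermis,
                                   mode=distance_mode)
    projection = extract_band(stack, distance, band, method=config.projection_method)
    if labels is not None:
        label_map = segment_cells(projection, "labels_provided", labels=labels,
                                  min_cell_px=config.min_cell_px)
    else:
        label_map = segment_cells(projection, "auto", min_cell_px=config.min_cell_px)
    cells = per_cell_means(
        projection,
        label_map,
        fad_floor=config.fad_floor,
        positive_genotype=positive_genotype,
        min_cell_px=config.min_cell_px,
        mouse_id=stack.mouse_id,
        region_id=stack.region_id,
        timepoint_days=stack.timepoint_days,
    )
    return QuantifyResult(cells, projection, dermis, label_map, distance)
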
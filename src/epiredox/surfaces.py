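"""Dermo-epidermal interface and air-surface detection, physical distance
volumes, and distance-banded layer projections.

The basal stem-cell layer sits directly on the collagen (second-harmonic)
surface; isolating it means selecting voxels whose 3D Euclidean distance to
that undulating surface falls in a fixed physical band (0-3 µm for
cytosolic NAD(P)H, 0-5 µm for nuclear reporters), then projecting the band
laterally.  Distances are in µm; the distance sign is positive on the
epidermis (shallow) side of a surface and negative below it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage.filters import threshold_otsu
from skimage.morphology import remove_small_objects

from .io import ChannelName, ImageStack

logger = logging.getLogger("epiredox")

__all__ = [
    "HeightMap",
    "SurfaceReference",
    "BandDirection",
    "LayerBand",
    "LayerProjection",
    "collagen_mask",
    "dermis_surface",
    "air_surface",
    "distance_to_surface",
    "extract_band",
]


@dataclass
class HeightMap:
    """Per-(y, x) surface depth in µm from the shallowest acquired plane.

    Undetermined columns are NaN ("missing"), never silently zero.
    """

    depth_um: np.ndarray
    lateral_size_um: tuple[float, float]  # (dy, dx)

    def __post_init__(self) -> None:
        self.depth_um = np.asarray(self.depth_um, dtype=float)
        if self.depth_um.ndim != 2:
            raise ValueError("depth_um must be 2D (y, x)")
        if np.nanmin(self.depth_um, initial=0.0) < 0:
            raise ValueError("depths must be nonnegative")

    @property
    def missing(self) -> np.ndarray:
        return np.isnan(self.depth_um)

    def filled(self) -> np.ndarray:
        """Depths with missing columns nearest-neighbour interpolated."""
        depth = self.depth_um
        miss = self.missing
        if not miss.any():
            return depth.copy()
        if miss.all():
            raise ValueError("height map has no defined columns")
        dy, dx = self.lateral_size_um
        _, (iy, ix) = ndimage.distance_transform_edt(
            miss, sampling=(dy, dx), return_indices=True
        )
        logger.info("interpolated %d missing height-map columns", int(miss.sum()))
        return depth[iy, ix]


class SurfaceReference(str, Enum):
    DERMIS_SURFACE = "DERMIS_SURFACE"
    AIR_SURFACE = "AIR_SURFACE"


class BandDirection(str, Enum):
    TOWARD_EPIDERMIS = "TOWARD_EPIDERMIS"  # shallower than the surface
    TOWARD_DERMIS = "TOWARD_DERMIS"        # deeper than the surface


@dataclass(frozen=True)
class LayerBand:
    """Closed distance interval [d_min, d_max] µm on one side of a surface."""

    reference: SurfaceReference
    d_min_um: float
    d_max_um: float
    direction: BandDirection = BandDirection.TOWARD_EPIDERMIS

    def __post_init__(self) -> None:
        if not (0 <= self.d_min_um < self.d_max_um):
            raise ValueError("band must satisfy 0 <= d_min < d_max")


@dataclass
class LayerProjection:
    """Per-channel 2D projections of one distance band.

    Pixels whose column contributes no band voxels are NaN in every
    channel map and 0 in n_voxels_map.
    """

    channels: dict[str, np.ndarray]
    method: str
    band: LayerBand
    n_voxels_map: np.ndarray
    lateral_size_um: tuple[float, float]

    def channel(self, name: "str | ChannelName") -> np.ndarray:
        key = name.value if isinstance(name, ChannelName) else str(name).upper()
        return self.channels[key]


def collagen_mask(
    stack: ImageStack,
    method: str = "otsu",
    fixed_threshold: float | None = None,
    min_object_voxels: int = 27,
) -> np.ndarray:
    """Threshold the SHG channel into a boolean collagen/dermis mask.

    Speckle smaller than ``min_object_voxels`` is removed.  A constant SHG
    channel cannot be Otsu-thresholded and raises, advising a fixed
    threshold.
    """
    if not stack.has_channel(ChannelName.SHG):
        raise ValueError("stack has no SHG channel; collagen mask undefined")
    shg = np.asarray(stack.channel(ChannelName.SHG), dtype=float)
    if method == "otsu":
        if float(shg.max()) == float(shg.min()):
            raise ValueError(
                "SHG channel is constant; Otsu thresholding is degenerate - "
                "use method='fixed' with an explicit threshold"
            )
        threshold = float(threshold_otsu(shg))
    elif method == "fixed":
        if fixed_threshold is None:
            raise ValueError("method='fixed' requires fixed_threshold")
        threshold = float(fixed_threshold)
    else:
        raise ValueError(f"unknown threshold method {method!r}")
    mask = shg >= threshold
    if min_object_voxels > 1:
        # drop speckle strictly smaller than min_object_voxels
        mask = remove_small_objects(mask, max_size=min_object_voxels - 1)
    logger.info(
        "collagen mask: method=%s threshold=%.6g true_voxels=%d",
        method, threshold, int(mask.sum()),
    )
    return mask


def _first_true_depth(mask: np.ndarray, dz: float) -> np.ndarray:
    """Depth (µm) of the shallowest True voxel per lateral column; NaN where none."""
    any_col = mask.any(axis=0)
    first = np.argmax(mask, axis=0).astype(float) * dz
    first[~any_col] = np.nan
    return first


def _smooth_heightmap(
    depth: np.ndarray,
    lateral_size_um: tuple[float, float],
    median_window: int,
    max_missing_frac: float,
    what: str,
) -> HeightMap:
    miss = np.isnan(depth)
    frac = float(miss.mean())
    if frac > max_missing_frac:
        raise ValueError(
            f"{what}: {frac:.0%} of columns undetermined (> {max_missing_frac:.0%}); "
            "surface not detectable"
        )
    hm = HeightMap(depth, lateral_size_um)
    if median_window and median_window > 1:
        smoothed = ndimage.median_filter(hm.filled(), size=median_window, mode="nearest")
        smoothed[miss] = np.nan
        hm = HeightMap(smoothed, lateral_size_um)
    if frac > 0:
        logger.info("%s: %d missing columns (%.1f%%)", what, int(miss.sum()), 100 * frac)
    return hm


def dermis_surface(
    mask: np.ndarray,
    voxel_size_um: tuple[float, float, float],
    median_window: int = 5,
    max_missing_frac: float = 0.5,
) -> HeightMap:
    """Depth of the dermo-epidermal interface from the collagen mask.

    Per lateral column, the shallowest mask-true voxel; median-filtered to
    suppress speckle.  Columns with no collagen are missing (NaN).
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 3:
        raise ValueError("mask must be a (z, y, x) volume")
    if not mask.any():
        raise ValueError("empty collagen mask; no dermis surface")
    dz, dy, dx = voxel_size_um
    depth = _first_true_depth(mask, dz)
    return _smooth_heightmap(depth, (dy, dx), median_window, max_missing_frac,
                             "dermis surface")


def air_surface(
    stack: ImageStack,
    background_channel: "str | ChannelName" = ChannelName.MCHERRY,
    fraction_of_max: float = 0.1,
    median_window: int = 5,
    max_missing_frac: float = 0.5,
) -> HeightMap:
    """Depth of the air/cornified surface from tissue background signal.

    Per column, the first voxel exceeding ``fraction_of_max`` of the column
    maximum (the artificial air surface of the live-thickness workflow).
    """
    vol = np.asarray(stack.channel(background_channel), dtype=float)
    dz, dy, dx = stack.voxel_size_um
    colmax = vol.max(axis=0)
    if not np.any(colmax > 0):
        raise ValueError("background channel is all zero; air surface undetectable")
    above = vol > (fraction_of_max * colmax)[None]
    above[:, colmax <= 0] = False
    depth = _first_true_depth(above, dz)
    return _smooth_heightmap(depth, (dy, dx), median_window, max_missing_frac,
                             "air surface")


def distance_to_surface(
    shape_zyx: tuple[int, int, int],
    voxel_size_um: tuple[float, float, float],
    surface: HeightMap,
    mode: str = "euclidean",
) -> np.ndarray:
    """Signed distance (µm) of every voxel to a surface height map.

    The surface is the point set {(h[y,x], y*dy, x*dx)} sampled at pixel
    centres; the magnitude is the minimum 3D Euclidean distance with
    anisotropic voxel scaling (``mode='euclidean'``) or the vertical
    distance only (``mode='vertical'``, documented fast approximation).
    Positive on the epidermis (shallow) side, negative below the surface.
    Missing surface columns are nearest-neighbour interpolated.
    """
    nz, ny, nx = shape_zyx
    dz, dy, dx = voxel_size_um
    height = surface.filled()
    if height.shape != (ny, nx):
        raise ValueError(
            f"surface shape {height.shape} does not match lateral shape {(ny, nx)}"
        )
    zs = np.arange(nz, dtype=float) * dz
    vertical = height[None, :, :] - zs[:, None, None]  # >0 above (epidermis side)
    if mode == "vertical":
        return vertical.astype(np.float64)
    if mode != "euclidean":
        raise ValueError(f"unknown distance mode {mode!r}")

    ys = np.arange(ny, dtype=float) * dy
    xs = np.arange(nx, dtype=float) * dx
    gy, gx = np.meshgrid(ys, xs, indexing="ij")
    points = np.column_stack([height.ravel(), gy.ravel(), gx.ravel()])
    tree = cKDTree(points)
    vz, vy, vx = np.meshgrid(zs, ys, xs, indexing="ij")
    queries = np.column_stack([vz.ravel(), vy.ravel(), vx.ravel()])
    dist, _ = tree.query(queries, k=1)
    dist = dist.reshape(shape_zyx)
    return np.sign(vertical) * dist


def extract_band(
    stack: ImageStack,
    distance_um: np.ndarray,
    band: LayerBand,
    method: str = "mean",
) -> LayerProjection:
    """Project every channel over one distance band.

    A voxel contributes when its signed distance d satisfies
    d_min <= d <= d_max on the band's side of the surface (closed
    interval; the interface voxel itself is included).
    """
    if distance_um.shape != stack.shape_zyx:
        raise ValueError("distance volume is not aligned with the stack")
    if method not in ("mean", "max"):
        raise ValueError("projection method must be 'mean' or 'max'")
    if band.direction == BandDirection.TOWARD_EPIDERMIS:
        selected = (distance_um >= band.d_min_um) & (distance_um <= band.d_max_um)
    else:
        selected = (distance_um <= -band.d_min_um) & (distance_um >= -band.d_max_um)
    n_voxels = selected.sum(axis=0)
    if not selected.any():
        raise ValueError(
            f"band [{band.d_min_um}, {band.d_max_um}] um ({band.direction.value}) "
            "lies entirely outside the stack's depth range"
        )

    channels: dict[str, np.ndarray] = {}
    sel = selected.astype(np.float64)
    for spec in stack.channels:
        vol = np.asarray(stack.channel(spec.name), dtype=np.float64)
        if method == "mean":
            with np.errstate(invalid="ignore"):
                proj = (vol * sel).sum(axis=0) / n_voxels
        else:
            masked = np.where(selected, vol, -np.inf)
            proj = masked.max(axis=0)
            proj = np.where(n_voxels > 0, proj, np.nan)
        proj = np.where(n_voxels > 0, proj, np.nan)
        channels[spec.name.value] = proj
    logger.info(
        "band [%g, %g] um %s: %d voxels over %d/%d pixels",
        band.d_min_um, band.d_max_um, band.direction.value,
        int(selected.sum()), int((n_voxels > 0).sum()), n_voxels.size,
    )
    _, dy, dx = stack.voxel_size_um
    return LayerProjection(channels, method, band, n_voxels, (dy, dx))
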
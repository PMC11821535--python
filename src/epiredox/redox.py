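"""Per-pixel NAD(P)H/FAD ratio images, per-cell redox statistics,
normalization conventions and mutant-vs-WT redox differentials.

The optical redox ratio used throughout is NAD(P)H intensity divided by
FAD intensity: a *drop* indicates a more oxidized cellular state.  Per
cell, the ratio is the ratio of channel means (not the mean of pixel
ratios), which is robust at low FAD counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.feature import peak_local_max
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import label as cc_label
from skimage.segmentation import watershed

from .io import ChannelName, empty_cell_table
from .surfaces import LayerBand, LayerProjection

logger = logging.getLogger("epiredox")

__all__ = [
    "MASK_OK",
    "MASK_FAD_BELOW_FLOOR",
    "MASK_NO_VOXELS",
    "RatioImage",
    "ratio_image",
    "default_fad_floor",
    "segment_cells",
    "per_cell_means",
    "normalize_to_baseline",
    "redox_differential",
    "paired_shift",
    "phase_effect",
]

# per-pixel mask reason codes
MASK_OK = 0
MASK_FAD_BELOW_FLOOR = 1
MASK_NO_VOXELS = 2


@dataclass
class RatioImage:
    """Per-pixel NAD(P)H/FAD map with an explicit exclusion reason per pixel."""

    ratio: np.ndarray          # NaN where masked
    mask_reason: np.ndarray    # int8 codes above
    fad_floor: float
    source_band: LayerBand | None = None

    @property
    def valid(self) -> np.ndarray:
        return self.mask_reason == MASK_OK


def default_fad_floor(fad_map: np.ndarray) -> float:
    """1% of the 99th-percentile FAD intensity (excludes division by
    near-zero FAD; the acquisition itself defines no floor)."""
    finite = np.asarray(fad_map)[np.isfinite(fad_map)]
    if finite.size == 0:
        return 0.0
    return 0.01 * float(np.percentile(finite, 99))


def ratio_image(
    nadph_map: np.ndarray,
    fad_map: np.ndarray,
    fad_floor: float,
    band: LayerBand | None = None,
) -> RatioImage:
    """Elementwise NAD(P)H/FAD where FAD >= floor; masked elsewhere."""
    nadph = np.asarray(nadph_map, dtype=float)
    fad = np.asarray(fad_map, dtype=float)
    if nadph.shape != fad.shape:
        raise ValueError(f"shape mismatch: {nadph.shape} vs {fad.shape}")
    if fad_floor < 0:
        raise ValueError("fad_floor must be nonnegative")
    reason = np.full(nadph.shape, MASK_OK, dtype=np.int8)
    no_voxels = ~np.isfinite(fad) | ~np.isfinite(nadph)
    reason[no_voxels] = MASK_NO_VOXELS
    below = (fad < fad_floor) | (fad <= 0)
    reason[below & ~no_voxels] = MASK_FAD_BELOW_FLOOR
    ok = reason == MASK_OK
    ratio = np.full(nadph.shape, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio[ok] = nadph[ok] / fad[ok]
    n_masked = int((~ok).sum())
    if n_masked:
        logger.info("ratio image: %d/%d pixels masked (floor=%.4g)",
                    n_masked, reason.size, fad_floor)
    return RatioImage(ratio, reason, float(fad_floor), band)


def segment_cells(
    projection: LayerProjection,
    mode: str = "labels_provided",
    labels: np.ndarray | None = None,
    min_cell_px: int = 9,
    smoothing_sigma_um: float = 0.8,
    min_distance_um: float = 2.0,
) -> np.ndarray:
    """Return an integer label map of cells on a band projection.

    ``labels_provided`` validates and passes through an external ROI mask
    (the analysis' manual-ROI stand-in); ``auto`` seeds a watershed from
    smoothed local maxima of the nuclear (mCherry) or NAD(P)H channel and
    discards regions smaller than ``min_cell_px``.
    """
    shape = projection.n_voxels_map.shape
    if mode == "labels_provided":
        if labels is None:
            raise ValueError("labels_provided mode requires a label mask")
        labels = np.asarray(labels)
        if labels.shape != shape:
            raise ValueError(
                f"label mask shape {labels.shape} does not match projection {shape}"
            )
        return labels.astype(np.int32)
    if mode != "auto":
        raise ValueError(f"unknown segmentation mode {mode!r}")

    # FAD outlines every cell at a ratio-independent level; NAD(P)H next;
    # the mCherry reporter marks only recombined cells and comes last
    for key in (ChannelName.FAD.value, ChannelName.NADPH.value,
                ChannelName.MCHERRY.value):
        if key in projection.channels:
            img = np.nan_to_num(projection.channels[key], nan=0.0)
            break
    else:
        raise ValueError("auto segmentation requires a FAD, NAD(P)H or mCherry channel")
    if img.max() <= 0:
        logger.warning("auto segmentation on a blank image: zero labels")
        return np.zeros(shape, dtype=np.int32)

    dy, dx = projection.lateral_size_um
    sigma_px = max(smoothing_sigma_um / dx, 0.5)
    smoothed = gaussian(img, sigma=sigma_px, preserve_range=True)
    try:
        thr = threshold_otsu(smoothed)
    except ValueError:
        logger.warning("degenerate intensity histogram; zero labels")
        return np.zeros(shape, dtype=np.int32)
    foreground = smoothed > thr
    # seed from ridges of the foreground distance transform: robust centre
    # finding for round, near-touching cells
    edt = ndimage.distance_transform_edt(foreground)
    peaks = peak_local_max(
        edt,
        min_distance=max(int(round(min_distance_um / dx)), 1),
        labels=cc_label(foreground),
        exclude_border=False,
    )
    markers = np.zeros(shape, dtype=np.int32)
    for i, (py, px) in enumerate(peaks, start=1):
        markers[py, px] = i
    labels = watershed(-edt, markers, mask=foreground)
    # drop undersized fragments
    sizes = np.bincount(labels.ravel())
    small = np.flatnonzero(sizes < min_cell_px)
    labels[np.isin(labels, small)] = 0
    n = len(np.unique(labels)) - 1
    logger.info("auto segmentation: %d cells (min size %d px)", n, min_cell_px)
    return labels


def per_cell_means(
    projection: LayerProjection,
    labels: np.ndarray,
    fad_floor: float | None = None,
    mcherry_threshold: "float | str" = "otsu",
    positive_genotype: str = "MUTANT",
    min_cell_px: int = 1,
    mouse_id: str = "mouse0",
    region_id: str = "region0",
    timepoint_days: float = 0.0,
) -> pd.DataFrame:
    """Per-label channel means and the per-cell redox ratio.

    The ratio is mean(NAD(P)H)/mean(FAD) over the cell's unmasked pixels.
    Genotype is called from the mean mCherry per cell: positive cells get
    ``positive_genotype`` (MUTANT, or CONTROL_RECOMBINED for reporter-only
    littermates), negative cells WT.  Phase comes from Fucci channel means
    when present.  Cells fully under the FAD floor are flagged
    (``flagged`` column) and excluded from downstream statistics.
    """
    labels = np.asarray(labels)
    if labels.shape != projection.n_voxels_map.shape:
        raise ValueError("labels are not aligned with the projection")
    nadph = projection.channel(ChannelName.NADPH)
    fad = projection.channel(ChannelName.FAD)
    if fad_floor is None:
        fad_floor = default_fad_floor(fad)
    pixel_ok = np.isfinite(nadph) & np.isfinite(fad) & (fad >= fad_floor) & (fad > 0)

    ids = np.unique(labels)
    ids = ids[ids > 0]
    if ids.size == 0:
        return empty_cell_table().assign(flagged=pd.Series(dtype=bool))

    lab_ok = np.where(pixel_ok, labels, 0)
    index = np.arange(1, ids.max() + 1)
    n_pix = ndimage.sum_labels(pixel_ok, labels, index=ids).astype(int)
    n_pix_total = ndimage.sum_labels(np.ones_like(labels), labels, index=ids).astype(int)

    def _mean(channel: np.ndarray) -> np.ndarray:
        vals = np.where(pixel_ok, np.nan_to_num(channel, nan=0.0), 0.0)
        sums = ndimage.sum_labels(vals, labels, index=ids)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n_pix > 0, sums / np.maximum(n_pix, 1), np.nan)

    mean_nadph = _mean(nadph)
    mean_fad = _mean(fad)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where((n_pix > 0) & (mean_fad > 0), mean_nadph / mean_fad, np.nan)
    flagged = (n_pix == 0) | (n_pix_total < min_cell_px)
    if flagged.any():
        logger.info("per_cell_means: %d/%d cells flagged (all-masked or undersized)",
                    int(flagged.sum()), ids.size)

    genotype = np.full(ids.shape, "WT", dtype=object)
    if ChannelName.MCHERRY.value in projection.channels:
        mch = _mean(projection.channel(ChannelName.MCHERRY))
        finite = np.isfinite(mch)
        if finite.any():
            vals = mch[finite]
            if mcherry_threshold == "otsu":
                # degenerate (unimodal/constant) mCherry means all-negative
                if vals.size >= 2 and (vals.max() - vals.min()) > 1e-6 * max(vals.max(), 1.0):
                    thr = float(threshold_otsu(vals))
                else:
                    thr = np.inf
            else:
                thr = float(mcherry_threshold)
            genotype[finite & (mch > thr)] = positive_genotype

    phase = np.full(ids.shape, "UNKNOWN", dtype=object)
    if (ChannelName.FUCCI_G1.value in projection.channels
            and ChannelName.FUCCI_SG2.value in projection.channels):
        g1 = _mean(projection.channel(ChannelName.FUCCI_G1))
        sg2 = _mean(projection.channel(ChannelName.FUCCI_SG2))
        has = np.isfinite(g1) & np.isfinite(sg2) & ((g1 > 0) | (sg2 > 0))
        phase[has & (g1 >= sg2)] = "G1"
        phase[has & (g1 < sg2)] = "SG2"

    table = pd.DataFrame(
        {
            "cell_id": ids.astype(int),
            "mouse_id": mouse_id,
            "region_id": region_id,
            "timepoint_days": float(timepoint_days),
            "genotype": genotype,
            "phase": phase,
            "mean_nadph": mean_nadph,
            "mean_fad": mean_fad,
            "ratio": ratio,
            "normalized_ratio": np.nan,
            "n_pixels": n_pix,
            "flagged": flagged,
        }
    )
    return table


def _active(cells: pd.DataFrame) -> pd.DataFrame:
    if "flagged" in cells.columns:
        return cells.loc[~cells["flagged"].astype(bool)]
    return cells


def normalize_to_baseline(
    cells: pd.DataFrame,
    baseline_selector: str = "day0_same_mouse",
    value_col: str = "ratio",
) -> pd.DataFrame:
    """Divide per-cell ratios by each mouse's baseline mean.

    ``day0_same_mouse``: baseline cells are the mouse's earliest-timepoint
    cells (the pre-induction revisit).  ``wt_cells_same_mouse``: baseline is
    the WT-neighbour mean of the same mouse and timepoint.  Baseline cells
    have mean normalized value 1 by construction.
    """
    cells = cells.copy()
    active = _active(cells)
    out = np.full(len(cells), np.nan)
    if baseline_selector == "day0_same_mouse":
        for mouse, sub in active.groupby("mouse_id"):
            day0 = sub["timepoint_days"].min()
            base = sub.loc[sub["timepoint_days"] == day0, value_col]
            if len(base) == 0 or not np.isfinite(base.mean()):
                raise ValueError(f"mouse {mouse!r} has no baseline (day-0) cells")
            sel = cells["mouse_id"] == mouse
            out[sel.to_numpy()] = cells.loc[sel, value_col] / base.mean()
    elif baseline_selector == "wt_cells_same_mouse":
        for (mouse, day), sub in active.groupby(["mouse_id", "timepoint_days"]):
            base = sub.loc[sub["genotype"] == "WT", value_col]
            if len(base) == 0 or not np.isfinite(base.mean()):
                raise ValueError(
                    f"mouse {mouse!r} day {day} has no WT baseline cells"
                )
            sel = (cells["mouse_id"] == mouse) & (cells["timepoint_days"] == day)
            out[sel.to_numpy()] = cells.loc[sel, value_col] / base.mean()
    else:
        raise ValueError(f"unknown baseline selector {baseline_selector!r}")
    cells["normalized_ratio"] = out
    return cells


def redox_differential(
    cells: pd.DataFrame,
    value_col: str = "ratio",
    min_cells: int = 5,
) -> pd.DataFrame:
    """WT-mean / mutant-mean per (mouse, timepoint).

    The differential is > 1 when WT neighbours sit above the mutant cells
    (the βcatGOF regime) and ~1 when the differential has flattened (the
    Hras^G12V day-10 regime).  Entries with fewer than ``min_cells`` of
    either genotype are omitted with a log message.
    """
    rows = []
    for (mouse, day), sub in _active(cells).groupby(["mouse_id", "timepoint_days"]):
        wt = sub.loc[sub["genotype"] == "WT", value_col].dropna()
        mut = sub.loc[sub["genotype"] == "MUTANT", value_col].dropna()
        if len(wt) < min_cells or len(mut) < min_cells:
            logger.info(
                "redox_differential: omitting mouse=%s day=%s (%d WT, %d mutant cells)",
                mouse, day, len(wt), len(mut),
            )
            continue
        rows.append(
            {
                "mouse_id": mouse,
                "timepoint_days": day,
                "wt_mean": wt.mean(),
                "mutant_mean": mut.mean(),
                "differential": wt.mean() / mut.mean(),
                "n_wt": len(wt),
                "n_mutant": len(mut),
            }
        )
    return pd.DataFrame(rows)


def paired_shift(
    cells_pre: pd.DataFrame,
    cells_post: pd.DataFrame,
    value_col: str = "ratio",
) -> pd.DataFrame:
    """Per-mouse percentage change of the mean redox ratio, post vs pre.

    The cyanide-injection readout: 100 * (post mean / pre mean - 1).
    """
    pre_mice = set(cells_pre["mouse_id"])
    post_mice = set(cells_post["mouse_id"])
    if pre_mice != post_mice:
        raise ValueError(
            f"unmatched mice: pre-only {sorted(pre_mice - post_mice)}, "
            f"post-only {sorted(post_mice - pre_mice)}"
        )
    rows = []
    pre_means = _active(cells_pre).groupby("mouse_id")[value_col].mean()
    post_means = _active(cells_post).groupby("mouse_id")[value_col].mean()
    for mouse in sorted(pre_mice):
        rows.append(
            {
                "mouse_id": mouse,
                "pre_mean": pre_means[mouse],
                "post_mean": post_means[mouse],
                "shift_percent": 100.0 * (post_means[mouse] / pre_means[mouse] - 1.0),
            }
        )
    return pd.DataFrame(rows)


def phase_effect(cells: pd.DataFrame, value_col: str = "mean_nadph"):
    """Cell-cycle effect on NAD(P)H: per-mouse G1 and S/G2 means and the
    nested (per-mouse collapse) test of G1 vs S/G2.

    Returns (per_mouse DataFrame, TestResult).  The effect is signed: a
    G1/SG2 mean ratio > 1 reproduces the lower NAD(P)H of S/G2 cells.
    """
    from .stats import nested_t_test

    active = _active(cells)
    sub = active[active["phase"].isin(["G1", "SG2"])]
    counts = sub.groupby("phase")["mouse_id"].nunique()
    if counts.get("G1", 0) < 2 or counts.get("SG2", 0) < 2:
        raise ValueError("phase effect requires both phases in >=2 mice")
    per_mouse = (
        sub.groupby(["mouse_id", "phase"])[value_col].mean().unstack("phase")
    )
    per_mouse["g1_over_sg2"] = per_mouse["G1"] / per_mouse["SG2"]
    g1 = {m: sub.loc[(sub["mouse_id"] == m) & (sub["phase"] == "G1"), value_col]
          for m in per_mouse.index}
    sg2 = {m: sub.loc[(sub["mouse_id"] == m) & (sub["phase"] == "SG2"), value_col]
           for m in per_mouse.index}
    result = nested_t_test(g1, sg2, name="nested t, G1 vs S/G2 NAD(P)H")
    return per_mouse.reset_index(), result
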
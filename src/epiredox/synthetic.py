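"""Synthetic two-photon stacks, redox timecourses and isotopologue tables
with exact ground truth.

The generator states a simplified telogen ear epidermis: an undulating
dermo-epidermal interface (separable sinusoid, optionally plus a low-pass
random field) with SHG collagen signal below it, a single basal layer of
spherical cells sitting on the interface (hard-sphere placement, minimum
centre spacing 1.8x the cell radius), optional suprabasal layers above,
mosaic H2BmCherry recombination, per-cell NAD(P)H/FAD ratios with
genotype-, day- and cell-cycle-dependence, and Poisson photon noise plus
Gaussian read noise.  Every stated quantity is recorded in a
:class:`SyntheticTruth` so each pipeline stage can be validated.

NAD(P)H and FAD channels are zero outside cells so that band projection
followed by ratio-of-channel-means recovers each cell's planted ratio
exactly in the noise-free limit; the mCherry channel carries a uniform
epidermal background used to detect the air/cornified surface.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .io import ChannelName, DEFAULT_CHANNELS, ImageStack
from .surfaces import HeightMap

logger = logging.getLogger("epiredox")

__all__ = [
    "NoiseModel",
    "TissueModel",
    "RedoxModel",
    "SyntheticTruth",
    "TIMECOURSE_PRESETS",
    "generate_stack",
    "generate_timecourse",
    "generate_isotopologues",
    "generate_mosaic_field",
    "sample_cell_table",
    "DEFAULT_PHOTONS_PER_CELL",
]


@dataclass(frozen=True)
class NoiseModel:
    """Two-photon detection noise: Poisson on scaled intensities then
    additive Gaussian read noise.  poisson_scale is photons per unit
    intensity; zero in both fields means noise-free."""

    poisson_scale: float = 50.0
    gaussian_sd: float = 0.01

    @property
    def enabled(self) -> bool:
        return self.poisson_scale > 0 or self.gaussian_sd > 0


@dataclass
class TissueModel:
    """Geometry of the synthetic skin patch (µm everywhere)."""

    field_um: tuple[float, float] = (300.0, 300.0)  # (Ly, Lx), imaging field
    interface_mean_depth_um: float = 15.0
    interface_amplitude_um: float = 3.0
    interface_wavelength_um: float = 60.0
    random_field_amplitude_um: float = 0.0  # optional low-pass random undulation
    n_basal_cells: int = 700                # ~7,800 cells/mm^2, telogen basal layer
    cell_radius_um: float = 2.5
    suprabasal_layers: int = 1
    suprabasal_offset_um: float = 8.0       # first suprabasal centre above interface
    follicle_regions: Sequence[tuple[float, float, float]] = field(default_factory=list)
    outgrowths: Sequence[tuple[float, float, float, float]] = field(default_factory=list)
    air_depth_um: float = 2.0
    air_amplitude_um: float = 0.0           # planted cornified undulation
    shg_margin_um: float = 3.0              # collagen depth below deepest interface
    n_z: int | None = None                  # None -> computed to fit the geometry
    mcherry_background: float = 0.2
    shg_intensity: float = 1.0
    fad_level: float = 1.0


@dataclass
class RedoxModel:
    """Per-genotype redox state and its day dependence (ratios are
    normalized NAD(P)H/FAD; 1.0 is the homoeostatic baseline)."""

    wt_ratio: float = 1.0
    wt_ratio_by_day: Mapping[float, float] = field(default_factory=dict)
    mutant_ratio_by_day: Mapping[float, float] = field(default_factory=dict)
    g1_nadph_boost: float = 1.1     # G1 cells carry more NAD(P)H than S/G2
    phase_fraction_g1: float = 0.8  # ~490 G1 vs ~120 S/G2 cells at homoeostasis
    noise_model: NoiseModel = field(default_factory=NoiseModel)

    def __post_init__(self) -> None:
        if self.wt_ratio <= 0 or any(v <= 0 for v in self.wt_ratio_by_day.values()):
            raise ValueError("all ratios must be positive")
        if any(v <= 0 for v in self.mutant_ratio_by_day.values()):
            raise ValueError("all ratios must be positive")
        if not (0.0 <= self.phase_fraction_g1 <= 1.0):
            raise ValueError("phase_fraction_g1 must be in [0, 1]")
        if self.g1_nadph_boost < 1.0:
            raise ValueError("g1_nadph_boost must be >= 1")

    def ratios_for_day(self, day: float) -> tuple[float, float]:
        wt = self.wt_ratio_by_day.get(day, self.wt_ratio)
        mut = self.mutant_ratio_by_day.get(day, wt)
        return wt, mut


@dataclass
class SyntheticTruth:
    """Exact (pre-noise) ground truth for one generated stack."""

    interface: HeightMap
    air: HeightMap
    cells: pd.DataFrame  # cell_id, y_um, x_um, depth_um, genotype, phase, true_ratio
    mutant_fraction: float
    label_map: np.ndarray      # 2D basal-cell labels; 0 = background/contested
    exclusion_mask: np.ndarray  # 2D hair-follicle exclusion
    thickness: HeightMap
    flux_truth: dict | None = None
    params: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# geometry helpers


def _interface_height(tissue: TissueModel, ys: np.ndarray, xs: np.ndarray,
                      rng: np.random.Generator) -> np.ndarray:
    gy, gx = np.meshgrid(ys, xs, indexing="ij")
    h = tissue.interface_mean_depth_um + tissue.interface_amplitude_um * np.sin(
        2 * np.pi * gy / tissue.interface_wavelength_um
    ) * np.sin(2 * np.pi * gx / tissue.interface_wavelength_um)
    if tissue.random_field_amplitude_um > 0:
        from scipy.ndimage import gaussian_filter

        noise = rng.standard_normal(gy.shape)
        low = gaussian_filter(noise, sigma=max(len(ys), len(xs)) / 12)
        low *= tissue.random_field_amplitude_um / max(low.std(), 1e-12)
        h = h + low
    for cy, cx, radius, extra in tissue.outgrowths:
        rho = np.hypot(gy - cy, gx - cx)
        bump = np.where(rho < radius, 0.5 * (1 + np.cos(np.pi * rho / radius)), 0.0)
        h = h + extra * bump
    if h.min() <= tissue.air_depth_um:
        raise ValueError("interface reaches the air surface; geometry infeasible")
    return h


def _air_height(tissue: TissueModel, ys: np.ndarray, xs: np.ndarray) -> np.ndarray:
    gy, gx = np.meshgrid(ys, xs, indexing="ij")
    return tissue.air_depth_um + tissue.air_amplitude_um * np.sin(
        2 * np.pi * gy / tissue.interface_wavelength_um
    ) * np.cos(2 * np.pi * gx / tissue.interface_wavelength_um)


def _place_cells(tissue: TissueModel, rng: np.random.Generator) -> np.ndarray:
    """Hard-sphere dart throwing on the interface sheet; returns (n, 2)
    lateral centres (y, x) in µm."""
    r = tissue.cell_radius_um
    spacing = 1.8 * r
    ly, lx = tissue.field_um
    points: list[tuple[float, float]] = []
    max_tries = 400 * tissue.n_basal_cells
    tries = 0
    arr = np.empty((0, 2))
    while len(points) < tissue.n_basal_cells and tries < max_tries:
        tries += 1
        p = rng.uniform([r, r], [ly - r, lx - r])
        if any(
            (p[0] - cy) ** 2 + (p[1] - cx) ** 2 < fr * fr
            for cy, cx, fr in tissue.follicle_regions
        ):
            continue
        if len(points) and np.min(np.sum((arr - p) ** 2, axis=1)) < spacing**2:
            continue
        points.append((float(p[0]), float(p[1])))
        arr = np.asarray(points)
    if len(points) < tissue.n_basal_cells:
        raise ValueError(
            f"could only place {len(points)}/{tissue.n_basal_cells} cells at "
            f"spacing {spacing:.2f} um; density infeasible"
        )
    return arr


def _render_sphere(
    target_owner: np.ndarray,
    owner_dist2: np.ndarray,
    centre_um: tuple[float, float, float],
    radius_um: float,
    voxel_size_um: tuple[float, float, float],
    owner_id: int,
) -> None:
    """Mark voxels inside a sphere with owner_id wherever this centre is the
    nearest owner so far (resolves slight sphere overlap consistently)."""
    zc, yc, xc = centre_um
    dz, dy, dx = voxel_size_um
    nz, ny, nx = target_owner.shape
    z0 = max(int(math.floor((zc - radius_um) / dz)), 0)
    z1 = min(int(math.ceil((zc + radius_um) / dz)) + 1, nz)
    y0 = max(int(math.floor((yc - radius_um) / dy)), 0)
    y1 = min(int(math.ceil((yc + radius_um) / dy)) + 1, ny)
    x0 = max(int(math.floor((xc - radius_um) / dx)), 0)
    x1 = min(int(math.ceil((xc + radius_um) / dx)) + 1, nx)
    if z0 >= z1 or y0 >= y1 or x0 >= x1:
        return
    zs = (np.arange(z0, z1) * dz - zc) ** 2
    ys = (np.arange(y0, y1) * dy - yc) ** 2
    xs = (np.arange(x0, x1) * dx - xc) ** 2
    dist2 = zs[:, None, None] + ys[None, :, None] + xs[None, None, :]
    inside = dist2 <= radius_um**2
    view_owner = target_owner[z0:z1, y0:y1, x0:x1]
    view_dist = owner_dist2[z0:z1, y0:y1, x0:x1]
    take = inside & (dist2 < view_dist)
    view_owner[take] = owner_id
    view_dist[take] = dist2[take]


def _apply_noise(vol: np.ndarray, noise: NoiseModel, rng: np.random.Generator) -> np.ndarray:
    out = vol
    if noise.poisson_scale > 0:
        out = rng.poisson(out * noise.poisson_scale).astype(np.float64) / noise.poisson_scale
    if noise.gaussian_sd > 0:
        out = out + rng.normal(0.0, noise.gaussian_sd, size=out.shape)
    return np.clip(out, 0.0, None)


# ---------------------------------------------------------------------------
# stack generation


def generate_stack(
    tissue: TissueModel,
    redox: RedoxModel,
    mutant_fraction: float = 0.0,
    voxel_size_um: tuple[float, float, float] = (0.5, 0.5, 0.5),
    seed: int = 0,
    timepoint_days: float = 0.0,
    include_fucci: bool = False,
    mouse_id: str = "mouse0",
    region_id: str = "region0",
    placement_seed: int | None = None,
) -> tuple[ImageStack, SyntheticTruth]:
    """Render one multi-channel stack and its exact ground truth.

    Exactly ``round(mutant_fraction * n_basal_cells)`` cells are drawn
    mutant without replacement.  ``placement_seed`` (defaulting to
    ``seed``) fixes cell positions and genotypes so revisit timecourses
    re-image the same region; ``seed`` alone drives phases and noise.
    """
    if not (0.0 <= mutant_fraction <= 1.0):
        raise ValueError("mutant_fraction must be in [0, 1]")
    dz, dy, dx = voxel_size_um
    ly, lx = tissue.field_um
    ny, nx = int(round(ly / dy)), int(round(lx / dx))
    ys = np.arange(ny) * dy
    xs = np.arange(nx) * dx

    rng_geom = np.random.default_rng(placement_seed if placement_seed is not None else seed)
    rng_day = np.random.default_rng(seed)

    height = _interface_height(tissue, ys, xs, rng_geom)
    air = _air_height(tissue, ys, xs)
    h_max = float(height.max())
    nz_needed = int(math.ceil((h_max + tissue.shg_margin_um) / dz)) + 1
    nz = tissue.n_z if tissue.n_z is not None else nz_needed
    if (nz - 1) * dz < h_max:
        raise ValueError(
            f"stack of {nz} planes (depth {(nz - 1) * dz:.1f} um) cannot contain "
            f"the interface (max depth {h_max:.1f} um)"
        )

    centres = _place_cells(tissue, rng_geom)
    n = len(centres)
    n_mut = int(round(mutant_fraction * n))
    mutant = np.zeros(n, dtype=bool)
    mutant[rng_geom.choice(n, size=n_mut, replace=False)] = True
    g1 = rng_day.random(n) < redox.phase_fraction_g1
    wt_ratio, mut_ratio = redox.ratios_for_day(timepoint_days)
    base = np.where(mutant, mut_ratio, wt_ratio)
    true_ratio = base * np.where(g1, redox.g1_nadph_boost, 1.0)

    # nearest-pixel interface depth under each cell centre
    iy = np.clip(np.round(centres[:, 0] / dy).astype(int), 0, ny - 1)
    ix = np.clip(np.round(centres[:, 1] / dx).astype(int), 0, nx - 1)
    depth = height[iy, ix] - tissue.cell_radius_um  # centre one radius above interface

    owner = np.zeros((nz, ny, nx), dtype=np.int32)
    owner_dist2 = np.full((nz, ny, nx), np.inf, dtype=np.float32)
    for i in range(n):
        _render_sphere(owner, owner_dist2, (depth[i], centres[i, 0], centres[i, 1]),
                       tissue.cell_radius_um, voxel_size_um, i + 1)
    # suprabasal layers: jittered copies above the basal sheet, WT-like redox
    n_supra = 0
    for layer in range(tissue.suprabasal_layers):
        offset = tissue.suprabasal_offset_um + layer * 2.4 * tissue.cell_radius_um
        jitter = rng_geom.uniform(-1.0, 1.0, size=centres.shape)
        for i in range(n):
            zc = height[iy[i], ix[i]] - tissue.cell_radius_um - offset
            if zc < air[iy[i], ix[i]] + tissue.cell_radius_um:
                continue
            n_supra += 1
            _render_sphere(
                owner, owner_dist2,
                (zc, centres[i, 0] + jitter[i, 0], centres[i, 1] + jitter[i, 1]),
                tissue.cell_radius_um, voxel_size_um, n + n_supra,
            )

    zs_depth = np.arange(nz)[:, None, None] * dz
    in_tissue = (zs_depth >= air[None]) & (zs_depth <= height[None])

    nadph = np.zeros((nz, ny, nx), dtype=np.float64)
    fad = np.zeros_like(nadph)
    mcherry = np.where(in_tissue, tissue.mcherry_background, 0.0)
    shg = np.where(zs_depth >= height[None], tissue.shg_intensity, 0.0)
    fucci_g1 = np.zeros_like(nadph)
    fucci_sg2 = np.zeros_like(nadph)

    basal = (owner > 0) & (owner <= n)
    idx = owner[basal] - 1
    fad[basal] = tissue.fad_level
    nadph[basal] = true_ratio[idx] * tissue.fad_level
    mcherry[basal] = np.where(mutant[idx], 1.0, mcherry[basal])
    if include_fucci:
        fucci_g1[basal] = np.where(g1[idx], 1.0, 0.0)
        fucci_sg2[basal] = np.where(g1[idx], 0.0, 1.0)
    supra = owner > n
    fad[supra] = tissue.fad_level
    nadph[supra] = wt_ratio * tissue.fad_level

    # 2D truth labels: nearest basal centre within one radius; pixels
    # contested between two cells are excluded (conservative ROIs)
    gy, gx = np.meshgrid(ys, xs, indexing="ij")
    pix = np.column_stack([gy.ravel(), gx.ravel()])
    tree = cKDTree(centres)
    k = min(2, n)
    dist, nearest = tree.query(pix, k=k)
    dist = np.atleast_2d(dist.T).T.reshape(len(pix), k)
    nearest = np.atleast_2d(nearest.T).T.reshape(len(pix), k)
    label_map = np.zeros(ny * nx, dtype=np.int32)
    within = dist[:, 0] <= tissue.cell_radius_um
    label_map[within] = nearest[within, 0] + 1
    if k == 2:
        contested = within & (dist[:, 1] <= tissue.cell_radius_um)
        label_map[contested] = 0
        if contested.any():
            logger.info("generate_stack: %d contested label pixels excluded",
                        int(contested.sum()))
    label_map = label_map.reshape(ny, nx)

    exclusion = np.zeros((ny, nx), dtype=bool)
    for cy, cx, radius in tissue.follicle_regions:
        exclusion |= (gy - cy) ** 2 + (gx - cx) ** 2 < radius**2

    channel_names = [ChannelName.NADPH, ChannelName.FAD, ChannelName.MCHERRY,
                     ChannelName.SHG]
    volumes = [nadph, fad, mcherry, shg]
    if include_fucci:
        channel_names += [ChannelName.FUCCI_G1, ChannelName.FUCCI_SG2]
        volumes += [fucci_g1, fucci_sg2]
    if redox.noise_model.enabled:
        volumes = [_apply_noise(v, redox.noise_model, rng_day) for v in volumes]
    voxels = np.stack(volumes).astype(np.float32)

    stack = ImageStack(
        voxels=voxels,
        voxel_size_um=voxel_size_um,
        channels=[DEFAULT_CHANNELS[c] for c in channel_names],
        region_id=region_id,
        timepoint_days=timepoint_days,
        mouse_id=mouse_id,
    )
    cells = pd.DataFrame(
        {
            "cell_id": np.arange(1, n + 1),
            "y_um": centres[:, 0],
            "x_um": centres[:, 1],
            "depth_um": depth,
            "genotype": np.where(mutant, "MUTANT", "WT"),
            "phase": np.where(g1, "G1", "SG2"),
            "true_ratio": true_ratio,
        }
    )
    truth = SyntheticTruth(
        interface=HeightMap(height, (dy, dx)),
        air=HeightMap(air, (dy, dx)),
        cells=cells,
        mutant_fraction=n_mut / n if n else 0.0,
        label_map=label_map,
        exclusion_mask=exclusion,
        thickness=HeightMap(height - air, (dy, dx)),
        params={
            "wt_ratio": wt_ratio,
            "mutant_ratio": mut_ratio,
            "timepoint_days": timepoint_days,
            "n_mutant": n_mut,
            "n_cells": n,
        },
    )
    return stack, truth


# ---------------------------------------------------------------------------
# timecourse presets

#: day -> (WT ratio, mutant ratio), piecewise by revisit window: baseline
#: (day < 2.5), early drop (2.5 <= day < 7.5, the day 4-6 revisit) and late
#: (day >= 7.5, the day 9-13 revisit).
TIMECOURSE_PRESETS: dict[str, dict] = {
    # Both genotypes drop by day ~5; WT alone recovers so the WT/mutant
    # differential reaches 2.8 by day ~10.
    "BCAT_GOF": {
        "mutant_fraction": 0.8,
        "windows": [
            (2.5, (1.0, 1.0)),
            (7.5, (0.70, 0.40)),
            (np.inf, (1.0, 1.0 / 2.8)),
        ],
    },
    # Both drop at day ~5 with mutant below WT; the differential is
    # flattened (1.0) by day ~10-13.
    "HRAS_G12V": {
        "mutant_fraction": 0.8,
        "windows": [
            (2.5, (1.0, 1.0)),
            (7.5, (0.75, 0.50)),
            (np.inf, (0.85, 0.85)),
        ],
    },
    # Paired pre/post acquisition; the post/pre increase is drawn in the
    # physiological envelope [1.28, 1.37] per run.
    "CYANIDE": {"mutant_fraction": 0.0, "shift_range": (1.28, 1.37)},
    # Metformin-treated mosaics: no day-5 drop in either genotype.
    "METFORMIN_FLAT": {
        "mutant_fraction": 0.8,
        "windows": [(np.inf, (1.0, 1.0))],
    },
    # Reporter-only littermates: constant ratios.
    "WT_CONTROL": {
        "mutant_fraction": 0.0,
        "windows": [(np.inf, (1.0, 1.0))],
    },
}


def _preset_ratios(preset: str, day: float, shift: float | None = None
                   ) -> tuple[float, float]:
    spec = TIMECOURSE_PRESETS[preset]
    if preset == "CYANIDE":
        base = 1.0
        return (base * shift, base * shift) if day > 0 else (base, base)
    for upper, (wt, mut) in spec["windows"]:
        if day < upper:
            return wt, mut
    raise AssertionError("unreachable")


def generate_timecourse(
    preset: str,
    days: Sequence[float],
    seed: int = 0,
    tissue: TissueModel | None = None,
    redox: RedoxModel | None = None,
    voxel_size_um: tuple[float, float, float] = (0.5, 0.5, 0.5),
    mouse_id: str = "mouse0",
    region_id: str = "region0",
) -> list[tuple[ImageStack, SyntheticTruth]]:
    """Revisit series for one mouse/region under a named competition preset.

    The same cells (positions, genotypes) are re-imaged at every day; only
    the planted redox state (and the noise realization) changes.  Truth
    ``params`` carries the exact per-day ratios, the planted WT/mutant
    differential and, for the cyanide preset, the drawn shift.
    """
    if preset not in TIMECOURSE_PRESETS:
        raise ValueError(
            f"unknown preset {preset!r}; choose from {sorted(TIMECOURSE_PRESETS)}"
        )
    days = list(days)
    if days != sorted(days):
        raise ValueError("days must be sorted ascending")
    tissue = tissue or TissueModel()
    redox = redox or RedoxModel(g1_nadph_boost=1.0)
    spec = TIMECOURSE_PRESETS[preset]
    rng = np.random.default_rng(seed)
    shift = None
    if preset == "CYANIDE":
        lo, hi = spec["shift_range"]
        shift = float(rng.uniform(lo, hi))

    out = []
    for i, day in enumerate(days):
        wt, mut = _preset_ratios(preset, day, shift)
        day_redox = replace(
            redox,
            wt_ratio=wt,
            wt_ratio_by_day={},
            mutant_ratio_by_day={day: mut},
        )
        stack, truth = generate_stack(
            tissue,
            day_redox,
            mutant_fraction=spec["mutant_fraction"],
            voxel_size_um=voxel_size_um,
            seed=int(rng.integers(0, 2**31 - 1)),
            timepoint_days=day,
            mouse_id=mouse_id,
            region_id=region_id,
            placement_seed=seed,
        )
        truth.params.update(
            {
                "preset": preset,
                "wt_ratio": wt,
                "mutant_ratio": mut,
                "differential": wt / mut,
                "shift": shift,
            }
        )
        out.append((stack, truth))
    return out


# ---------------------------------------------------------------------------
# isotopologue tables

#: Anchor enrichments: alanine m+3 reflects the glycolytic labelling of the
#: pyruvate pool; glucose m+6 the arterial tracer enrichment.
_ANCHOR_ALANINE_M3 = 0.15
_ANCHOR_GLUCOSE_M6 = 0.30

#: Default ratio truths for unspecified panel members (homoeostatic WT-like:
#: ~60% of TCA entry from glucose, no glutamine dilution or anaplerotic
#: label dilution).
_DEFAULT_RATIOS = {
    "v_pdh_vcs_acetylcoa": 0.6,
    "co2_per_glucose": 0.10,
    "pyruvate_per_glucose": 0.65,
    "lactate_per_glucose": 0.65,
    "glutamate_per_acetylcoa": 1.0,
    "malate_per_glutamate": 1.0,
}


def _enrichments_from_truth(truth: Mapping[str, float]) -> dict[str, float]:
    from .flux import RATIO_DEFS

    unknown = set(truth) - set(RATIO_DEFS)
    if unknown:
        raise ValueError(f"ratio names outside the supported panel: {sorted(unknown)}")
    if any(v < 0 for v in truth.values()):
        raise ValueError("truth ratios must be >= 0")
    get = lambda k: truth.get(k, _DEFAULT_RATIOS.get(k))
    ala = _ANCHOR_ALANINE_M3
    glc = _ANCHOR_GLUCOSE_M6
    acetyl = get("v_pdh_vcs_acetylcoa") * ala
    if "v_pdh_vcs_glutamate" in truth:
        glut = truth["v_pdh_vcs_glutamate"] * ala
    else:
        glut = get("glutamate_per_acetylcoa") * acetyl
    pyr = get("pyruvate_per_glucose") * glc
    if "lactate_per_pyruvate" in truth:
        lac = truth["lactate_per_pyruvate"] * pyr
    else:
        lac = get("lactate_per_glucose") * glc
    return {
        "GLUCOSE_M6": glc,
        "ALANINE_M3": ala,
        "PYRUVATE_M3": pyr,
        "LACTATE_M3": lac,
        "ACETYLCOA_M2": acetyl,
        "GLUTAMATE_C4C5_M2": glut,
        "MALATE_C2C3_M2": get("malate_per_glutamate") * glut,
        "CO2_M1": get("co2_per_glucose") * glc,
    }


def generate_isotopologues(
    group_truth: Mapping[str, Mapping[str, float]],
    n_per_group: "int | Mapping[str, int]" = 8,
    noise_cv: float = 0.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Long-format isotopologue enrichment table with planted flux ratios.

    Each sample is one mouse.  Multiplicative lognormal noise with
    coefficient of variation ``noise_cv`` perturbs every enrichment
    independently (unit mean); noise_cv = 0 reproduces the planted ratios
    to machine precision.  Returns (table, per-group enrichment truth).
    """
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    rng = np.random.default_rng(seed)
    sigma = math.sqrt(math.log(1 + noise_cv**2)) if noise_cv > 0 else 0.0
    rows = []
    truth_out = {}
    for group, ratios in group_truth.items():
        enrich = _enrichments_from_truth(ratios)
        truth_out[group] = enrich
        n = n_per_group[group] if isinstance(n_per_group, Mapping) else int(n_per_group)
        for i in range(n):
            sample = f"{group}_s{i + 1}"
            for metabolite, value in enrich.items():
                noisy = value
                if sigma > 0:
                    noisy = value * rng.lognormal(-0.5 * sigma**2, sigma)
                if noisy > 1.0:
                    logger.warning("enrichment clipped to 1.0 for %s/%s", sample,
                                   metabolite)
                    noisy = 1.0
                rows.append(
                    {
                        "sample_id": sample,
                        "mouse_id": sample,
                        "group": group,
                        "metabolite": metabolite,
                        "enrichment": noisy,
                    }
                )
    return pd.DataFrame(rows), truth_out


# ---------------------------------------------------------------------------
# lateral mosaic fields (coverage fixtures) and fast cell-table sampling


def generate_mosaic_field(
    mutant_fraction: float,
    tissue: TissueModel | None = None,
    pixel_size_um: float = 0.5,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Lateral basal-layer mosaic: genotype and follicle-exclusion masks.

    Cells are placed as in :func:`generate_stack`; every pixel is assigned
    to its nearest cell (a Voronoi tiling of the confluent basal sheet) so
    that the mCherry-positive area fraction estimates the planted mutant
    cell fraction.  Returns (genotype_mask, exclusion_mask, truth dict).
    """
    tissue = tissue or TissueModel()
    rng = np.random.default_rng(seed)
    centres = _place_cells(tissue, rng)
    n = len(centres)
    n_mut = int(round(mutant_fraction * n))
    mutant = np.zeros(n, dtype=bool)
    mutant[rng.choice(n, size=n_mut, replace=False)] = True

    ly, lx = tissue.field_um
    ny, nx = int(round(ly / pixel_size_um)), int(round(lx / pixel_size_um))
    ys = np.arange(ny) * pixel_size_um
    xs = np.arange(nx) * pixel_size_um
    gy, gx = np.meshgrid(ys, xs, indexing="ij")
    tree = cKDTree(centres)
    _, nearest = tree.query(np.column_stack([gy.ravel(), gx.ravel()]))
    genotype_mask = mutant[nearest].reshape(ny, nx)

    exclusion = np.zeros((ny, nx), dtype=bool)
    for cy, cx, radius in tissue.follicle_regions:
        exclusion |= (gy - cy) ** 2 + (gx - cx) ** 2 < radius**2
    truth = {
        "mutant_fraction": n_mut / n,
        "n_cells": n,
        "n_mutant": n_mut,
        "pixel_size_um": pixel_size_um,
    }
    return genotype_mask, exclusion, truth


#: Photon budget of one cell at the default noise preset: ~150 in-band
#: voxels at 50 photons per unit intensity and unit FAD level.
DEFAULT_PHOTONS_PER_CELL = 7500.0


def sample_cell_table(
    n_cells: int,
    true_ratio: "float | np.ndarray",
    mouse_id: str = "mouse0",
    genotype: str = "WT",
    phase: str = "UNKNOWN",
    timepoint_days: float = 0.0,
    photons_per_cell: float = DEFAULT_PHOTONS_PER_CELL,
    seed: "int | None" = 0,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Fast per-cell measurement sampler for Monte-Carlo studies.

    Draws each cell's summed NAD(P)H and FAD photon counts from the same
    Poisson model the image generator's default preset uses, skipping the
    voxel rendering; ``photons_per_cell = 0`` gives noise-free
    measurements.  Returns a CellTable-shaped DataFrame.
    """
    rng = rng if rng is not None else np.random.default_rng(seed)
    ratios = np.broadcast_to(np.asarray(true_ratio, dtype=float), (n_cells,)).copy()
    if photons_per_cell > 0:
        fad = rng.poisson(photons_per_cell, n_cells) / photons_per_cell
        nadph = rng.poisson(photons_per_cell * ratios) / photons_per_cell
        fad = np.maximum(fad, 1.0 / photons_per_cell)  # guard empty denominators
    else:
        fad = np.ones(n_cells)
        nadph = ratios.copy()
    return pd.DataFrame(
        {
            "cell_id": np.arange(1, n_cells + 1),
            "mouse_id": mouse_id,
            "region_id": "region0",
            "timepoint_days": float(timepoint_days),
            "genotype": genotype,
            "phase": phase,
            "mean_nadph": nadph,
            "mean_fad": fad,
            "ratio": nadph / fad,
            "normalized_ratio": np.nan,
            "n_pixels": 150,
            "flagged": False,
        }
    )
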
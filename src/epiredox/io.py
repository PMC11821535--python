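"""Stack and table I/O, channel registry and run configuration.

Image stacks are multi-channel 3D voxel grids (channel, z, y, x) with
physical voxel sizes in micrometres.  z index 0 is the shallowest plane
(air side) and depth increases with z: ``depth_um = z_index * dz``.
All tables are plain CSV; configuration is TOML.
"""

from __future__ import annotations

import hashlib
import json
import logging
import tomllib
from dataclasses import dataclass, asdict
from enum import Enum
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import tifffile

logger = logging.getLogger("epiredox")

__all__ = [
    "ChannelName",
    "ChannelSpec",
    "ImageStack",
    "RunConfig",
    "DEFAULT_CHANNELS",
    "read_stack",
    "write_stack",
    "read_cell_table",
    "write_cell_table",
    "load_config",
    "save_config",
    "write_run_log",
]


class ChannelName(str, Enum):
    """Fluorescence channels of the two-photon acquisition scheme."""

    NADPH = "NADPH"          # 425-475 nm emission, reduced NAD(P)H
    FAD = "FAD"              # 500-550 nm emission, oxidized FAD
    MCHERRY = "MCHERRY"      # H2BmCherry recombination reporter
    SHG = "SHG"              # second harmonic signal from fibrillar collagen
    FUCCI_G1 = "FUCCI_G1"    # Cdt1 reporter, G1 cells
    FUCCI_SG2 = "FUCCI_SG2"  # Geminin reporter, S/G2 cells
    PH3 = "PH3"              # phospho-histone H3 mitosis stain
    OTHER = "OTHER"


@dataclass(frozen=True)
class ChannelSpec:
    """One acquisition channel: name, excitation and emission band (nm)."""

    name: ChannelName
    excitation_nm: float
    emission_band_nm: tuple[float, float]

    def __post_init__(self) -> None:
        lo, hi = self.emission_band_nm
        if not (0 < lo < hi):
            raise ValueError(
                f"emission band must satisfy 0 < low < high, got {self.emission_band_nm}"
            )
        if self.excitation_nm <= 0:
            raise ValueError("excitation_nm must be positive")


#: Default channel registry matching the acquisition wavelengths used for
#: label-free redox imaging in mouse epidermis.
DEFAULT_CHANNELS: dict[ChannelName, ChannelSpec] = {
    ChannelName.NADPH: ChannelSpec(ChannelName.NADPH, 750.0, (425.0, 475.0)),
    ChannelName.FAD: ChannelSpec(ChannelName.FAD, 890.0, (500.0, 550.0)),
    ChannelName.MCHERRY: ChannelSpec(ChannelName.MCHERRY, 1040.0, (572.0, 647.5)),
    ChannelName.SHG: ChannelSpec(ChannelName.SHG, 890.0, (425.0, 475.0)),
    ChannelName.FUCCI_G1: ChannelSpec(ChannelName.FUCCI_G1, 1040.0, (572.0, 647.5)),
    ChannelName.FUCCI_SG2: ChannelSpec(ChannelName.FUCCI_SG2, 940.0, (500.0, 550.0)),
    ChannelName.PH3: ChannelSpec(ChannelName.PH3, 1040.0, (650.0, 700.0)),
}


def _as_channel_name(name: "str | ChannelName") -> ChannelName:
    return name if isinstance(name, ChannelName) else ChannelName(str(name).upper())


@dataclass
class ImageStack:
    """Multi-channel 3D stack with physical voxel geometry.

    voxels has shape (n_channels, nz, ny, nx) and nonnegative intensities.
    voxel_size_um is (dz, dy, dx).
    """

    voxels: np.ndarray
    voxel_size_um: tuple[float, float, float]
    channels: list[ChannelSpec]
    region_id: str = "region0"
    timepoint_days: float = 0.0
    mouse_id: str = "mouse0"

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 4:
            raise ValueError("voxels must be (channel, z, y, x)")
        if self.voxels.shape[0] != len(self.channels):
            raise ValueError(
                f"channel count {len(self.channels)} does not match first axis "
                f"length {self.voxels.shape[0]}"
            )
        if any(s <= 0 for s in self.voxel_size_um):
            raise ValueError("all voxel sizes must be positive")
        if self.timepoint_days < 0:
            raise ValueError("timepoint_days must be nonnegative")

    @property
    def shape_zyx(self) -> tuple[int, int, int]:
        return self.voxels.shape[1:]

    def channel_index(self, name: "str | ChannelName") -> int:
        name = _as_channel_name(name)
        for i, spec in enumerate(self.channels):
            if spec.name == name:
                return i
        raise KeyError(f"channel {name.value} not present in stack")

    def has_channel(self, name: "str | ChannelName") -> bool:
        try:
            self.channel_index(name)
            return True
        except KeyError:
            return False

    def channel(self, name: "str | ChannelName") -> np.ndarray:
        """Return the (z, y, x) volume for a named channel."""
        return self.voxels[self.channel_index(name)]


@dataclass
class RunConfig:
    """Stage parameters; every analysis knob lives here, not in code.

    band_cytosolic_um/band_nuclear_um are distances from the dermal
    interface toward the epidermis, in µm (cytosolic NAD(P)H 0-3 µm,
    nuclear reporters 0-5 µm).
    """

    band_cytosolic_um: tuple[float, float] = (0.0, 3.0)
    band_nuclear_um: tuple[float, float] = (0.0, 5.0)
    fad_floor: float | None = None  # None -> 1% of 99th-percentile FAD
    projection_method: str = "mean"  # {max, mean}
    seed: int = 0
    threshold_method: str = "otsu"  # {otsu, fixed}
    fixed_threshold: float | None = None
    median_window: int = 5
    min_object_voxels: int = 27
    min_cell_px: int = 9
    air_fraction_of_max: float = 0.1
    fallback_voxel_size_um: tuple[float, float, float] = (0.5, 0.3, 0.3)

    def __post_init__(self) -> None:
        for band in (self.band_cytosolic_um, self.band_nuclear_um):
            lo, hi = band
            if not (0 <= lo < hi):
                raise ValueError(f"band {band} must have 0 <= low < high")
        if self.projection_method not in ("max", "mean"):
            raise ValueError("projection_method must be 'max' or 'mean'")
        if self.threshold_method not in ("otsu", "fixed"):
            raise ValueError("threshold_method must be 'otsu' or 'fixed'")
        if self.seed < 0:
            raise ValueError("seed must be nonnegative")


def load_config(path: "str | Path") -> RunConfig:
    """Read a RunConfig from a TOML file (unknown keys rejected)."""
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    known = RunConfig().__dict__.keys()
    unknown = set(raw) - set(known)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for key in ("band_cytosolic_um", "band_nuclear_um", "fallback_voxel_size_um"):
        if key in raw:
            raw[key] = tuple(raw[key])
    return RunConfig(**raw)


def save_config(config: RunConfig, path: "str | Path") -> None:
    """Write a RunConfig as TOML (simple scalar/array values only)."""
    lines = []
    for key, value in asdict(config).items():
        if value is None:
            continue
        if isinstance(value, str):
            lines.append(f'{key} = "{value}"')
        elif isinstance(value, (tuple, list)):
            lines.append(f"{key} = [{', '.join(repr(float(v)) for v in value)}]")
        elif isinstance(value, bool):
            lines.append(f"{key} = {str(value).lower()}")
        else:
            lines.append(f"{key} = {value}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# stacks


def write_stack(stack: ImageStack, path: "str | Path") -> None:
    """Write a stack as OME-TIFF with voxel sizes and channel names."""
    data = np.asarray(stack.voxels, dtype=np.float32)
    dz, dy, dx = stack.voxel_size_um
    metadata = {
        "axes": "CZYX",
        "PhysicalSizeX": dx,
        "PhysicalSizeXUnit": "µm",
        "PhysicalSizeY": dy,
        "PhysicalSizeYUnit": "µm",
        "PhysicalSizeZ": dz,
        "PhysicalSizeZUnit": "µm",
        "Channel": {"Name": [c.name.value for c in stack.channels]},
    }
    extra = json.dumps(
        {
            "region_id": stack.region_id,
            "timepoint_days": stack.timepoint_days,
            "mouse_id": stack.mouse_id,
            "channels": [
                {
                    "name": c.name.value,
                    "excitation_nm": c.excitation_nm,
                    "emission_band_nm": list(c.emission_band_nm),
                }
                for c in stack.channels
            ],
        }
    )
    tifffile.imwrite(
        path,
        data,
        ome=True,
        metadata=metadata,
        description=None,
        extratags=[(65000, "s", 0, extra, True)],
    )


def read_stack(
    path: "str | Path",
    channel_map: Mapping[str, int] | None = None,
    config: RunConfig | None = None,
) -> ImageStack:
    """Read a TIFF/OME-TIFF stack.

    channel_map maps channel names to first-axis indices; when omitted, the
    channel registry written by :func:`write_stack` is used.  Missing
    voxel-size metadata falls back to ``config.fallback_voxel_size_um`` with
    a logged warning.
    """
    config = config or RunConfig()
    try:
        with tifffile.TiffFile(path) as tif:
            data = tif.asarray()
            extra = None
            for tag in tif.pages[0].tags.values():
                if tag.code == 65000:
                    extra = json.loads(tag.value)
            ome_meta = tif.ome_metadata
    except (OSError, ValueError, tifffile.TiffFileError) as exc:
        raise OSError(f"unreadable TIFF file {path!r}: {exc}") from exc

    if data.ndim == 2:
        data = data[None, None]
    elif data.ndim == 3:
        data = data[None]
    elif data.ndim != 4:
        raise ValueError(f"expected <=4D TIFF, got shape {data.shape}")

    voxel_size = None
    if ome_meta is not None:
        import re

        sizes = {}
        for axis in "ZYX":
            m = re.search(rf'PhysicalSize{axis}="([0-9.eE+-]+)"', ome_meta)
            if m:
                sizes[axis] = float(m.group(1))
        if set(sizes) == {"Z", "Y", "X"}:
            voxel_size = (sizes["Z"], sizes["Y"], sizes["X"])
    if voxel_size is None:
        voxel_size = tuple(config.fallback_voxel_size_um)
        logger.warning(
            "no voxel-size metadata in %s; falling back to %s um", path, voxel_size
        )

    n_channels = data.shape[0]
    if extra is not None and channel_map is None:
        channels = [
            ChannelSpec(
                ChannelName(c["name"]),
                c["excitation_nm"],
                tuple(c["emission_band_nm"]),
            )
            for c in extra["channels"]
        ]
    else:
        if channel_map is None:
            raise ValueError("channel_map required for stacks without embedded registry")
        for name, idx in channel_map.items():
            if not (0 <= int(idx) < n_channels):
                raise ValueError(
                    f"channel_map index {idx} for {name!r} out of range for a "
                    f"{n_channels}-channel file"
                )
        ordered = sorted(channel_map.items(), key=lambda kv: kv[1])
        if [idx for _, idx in ordered] != list(range(n_channels)):
            raise ValueError("channel_map must cover every channel exactly once")
        channels = []
        for name, _ in ordered:
            cname = _as_channel_name(name)
            spec = DEFAULT_CHANNELS.get(cname)
            channels.append(spec or ChannelSpec(cname, 800.0, (400.0, 700.0)))

    kwargs = {}
    if extra is not None:
        kwargs = {
            "region_id": extra["region_id"],
            "timepoint_days": extra["timepoint_days"],
            "mouse_id": extra["mouse_id"],
        }
    return ImageStack(np.asarray(data), voxel_size, channels, **kwargs)


# ---------------------------------------------------------------------------
# cell tables

#: Canonical per-cell record columns (the violin-plot substrate).
CELL_TABLE_COLUMNS: dict[str, type] = {
    "cell_id": int,
    "mouse_id": str,
    "region_id": str,
    "timepoint_days": float,
    "genotype": str,  # {MUTANT, WT, CONTROL_RECOMBINED}
    "phase": str,  # {G1, SG2, UNKNOWN}
    "mean_nadph": float,
    "mean_fad": float,
    "ratio": float,
    "normalized_ratio": float,
    "n_pixels": int,
}


def empty_cell_table() -> pd.DataFrame:
    return pd.DataFrame({k: pd.Series(dtype=t if t is not str else object)
                         for k, t in CELL_TABLE_COLUMNS.items()})


def validate_cell_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = set(CELL_TABLE_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"cell table missing columns: {sorted(missing)}")
    return table


def write_cell_table(table: pd.DataFrame, path: "str | Path") -> None:
    """Write a per-cell table as CSV, numerics at full precision."""
    validate_cell_table(table)
    table.to_csv(path, index=False, float_format="%.12g")


def read_cell_table(path: "str | Path") -> pd.DataFrame:
    """Read a per-cell CSV; malformed numeric fields raise a parse error
    naming the row and column."""
    table = pd.read_csv(path, dtype=object)
    if len(table) == 0:
        return empty_cell_table()
    validate_cell_table(table)
    out = {}
    for col, typ in CELL_TABLE_COLUMNS.items():
        if typ is str:
            out[col] = table[col].astype(str)
            continue
        converted = pd.to_numeric(table[col], errors="coerce")
        allow_nan = col == "normalized_ratio"
        raw_na = table[col].isna()
        bad = converted.isna() & ~(raw_na if allow_nan else pd.Series(False, index=table.index))
        if bad.any():
            row = int(bad.idxmax())
            raise ValueError(
                f"non-numeric value {table.loc[row, col]!r} in column {col!r}, row {row}"
            )
        out[col] = converted.astype(float if typ is float else int, errors="ignore")
        if typ is int:
            out[col] = converted.astype(int)
    return pd.DataFrame(out)


def write_run_log(path: "str | Path", config: RunConfig, seed: int,
                  counts: Mapping[str, int] | None = None) -> None:
    """Machine-readable run log: config hash, seed, versions, exclusion counts."""
    cfg = asdict(config)
    payload = {
        "config": cfg,
        "config_sha256": hashlib.sha256(
            json.dumps(cfg, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "seed": int(seed),
        "versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "tifffile": tifffile.__version__,
        },
        "counts": dict(counts or {}),
    }
    Path(path).write_text(json.dumps(payload, indent=2, default=str) + "\n")
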
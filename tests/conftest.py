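"""Shared fixtures: small synthetic stacks with exact ground truth."""

import numpy as np
import pytest

from epiredox.io import ChannelName, DEFAULT_CHANNELS, ImageStack
from epiredox.synthetic import NoiseModel, RedoxModel, TissueModel, generate_stack


@pytest.fixture(scope="session")
def small_tissue() -> TissueModel:
    """A 60x60 um patch with an undulating interface and one suprabasal layer."""
    return TissueModel(
        field_um=(60.0, 60.0),
        n_basal_cells=60,
        interface_mean_depth_um=12.0,
        interface_amplitude_um=2.0,
        interface_wavelength_um=30.0,
        suprabasal_layers=1,
    )


@pytest.fixture(scope="session")
def noise_free_mosaic(small_tissue):
    """Noise-free half-mutant stack: WT ratio 1.0, mutant 0.5."""
    redox = RedoxModel(
        wt_ratio=1.0,
        mutant_ratio_by_day={0.0: 0.5},
        g1_nadph_boost=1.0,
        noise_model=NoiseModel(0.0, 0.0),
    )
    return generate_stack(small_tissue, redox, mutant_fraction=0.5, seed=11)


@pytest.fixture(scope="session")
def noisy_mosaic(small_tissue):
    """Same stated world at the default photon-noise preset."""
    redox = RedoxModel(
        wt_ratio=1.0, mutant_ratio_by_day={0.0: 0.5}, g1_nadph_boost=1.0
    )
    return generate_stack(small_tissue, redox, mutant_fraction=0.5, seed=11)


def flat_stack(depth_um=10.0, dz=0.5, n_xy=8, n_z=None, shg_value=100.0):
    """Minimal two-channel stack with a flat collagen interface."""
    nz = n_z or int(depth_um / dz) + 6
    shg = np.zeros((nz, n_xy, n_xy))
    zs = np.arange(nz) * dz
    shg[zs >= depth_um] = shg_value
    nadph = np.ones_like(shg)
    voxels = np.stack([nadph, shg]).astype(np.float32)
    channels = [DEFAULT_CHANNELS[ChannelName.NADPH], DEFAULT_CHANNELS[ChannelName.SHG]]
    return ImageStack(voxels, (dz, 0.5, 0.5), channels)
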
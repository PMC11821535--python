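"""Tissue-level competition readouts: mutant coverage, epidermal thickness
and basal density.

A mosaic basal sheet with hair-follicle exclusions tests area coverage
(planted mutant fraction 0.25, the late 'loser' regime); a stack with a
planted epidermal outgrowth (placode-like, 20 um deeper) tests the
air-to-dermis thickness map; truth labels give the basal nuclear density.
"""

import numpy as np

from epiredox.competition import basal_density, mutant_coverage, thickness_map
from epiredox.surfaces import air_surface, collagen_mask, dermis_surface
from epiredox.synthetic import (
    NoiseModel,
    RedoxModel,
    TissueModel,
    generate_mosaic_field,
    generate_stack,
)

# --- coverage on a 300x300 um field with two follicle discs
mosaic_tissue = TissueModel(follicle_regions=[(70.0, 80.0, 25.0), (220.0, 200.0, 30.0)])
genotype, exclusion, truth = generate_mosaic_field(0.25, mosaic_tissue, seed=2)
cov = mutant_coverage(genotype, exclusion, (0.5, 0.5))
print(f"mutant coverage: {100 * cov.mutant_area_fraction:.1f}% of "
      f"{cov.analyzed_area_um2 / 1e4:.1f} x 10^4 um^2 analyzed "
      f"(planted {100 * truth['mutant_fraction']:.1f}%, "
      f"{cov.excluded_area_um2 / 1e4:.1f} x 10^4 um^2 follicles excluded)")

# --- thickness with a planted outgrowth
out_tissue = TissueModel(
    field_um=(80.0, 80.0), n_basal_cells=64,
    interface_mean_depth_um=20.0, interface_amplitude_um=3.0,
    interface_wavelength_um=40.0, outgrowths=[(40.0, 40.0, 15.0, 20.0)],
)
stack, struth = generate_stack(
    out_tissue, RedoxModel(g1_nadph_boost=1.0, noise_model=NoiseModel(0, 0)), seed=4
)
dermis = dermis_surface(collagen_mask(stack), stack.voxel_size_um)
thick = thickness_map(air_surface(stack), dermis)
print(f"thickness: mean {thick.mean_thickness_um:.1f} um, "
      f"max {np.nanmax(thick.thickness_um):.1f} um "
      f"(planted max {struth.thickness.depth_um.max():.1f} um at the outgrowth)")

# --- basal nuclear density from truth labels
density = basal_density(struth.label_map, 80.0 * 80.0)
print(f"basal density: {density.count} nuclei -> "
      f"{density.density_per_mm2:.0f} per mm^2")
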
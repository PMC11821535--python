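# Methods

This note documents the models, conventions and numerical choices behind
`epiredox`, and what the synthetic-data tests do and do not establish.

## Coordinate and sign conventions

Voxel indices are 0-based; depth is `z_index * dz` µm measured from the
shallowest acquired plane (air side). All distances and band limits are
physical µm. Signed distances to a surface are **positive on the
epidermis (shallow) side** and negative below it; layer bands are closed
intervals `[d_min, d_max]`, so the interface voxel itself belongs to the
basal band.

## Surface detection and distance bands

- **Collagen mask**: intensity threshold on the SHG channel (Otsu by
  default — the original analysis used a manually chosen threshold, so a
  fixed override is available), followed by removal of connected
  components below `min_object_voxels` (default 27 ≈ a 1.5 µm speckle at
  0.5 µm voxels). A constant SHG channel makes Otsu degenerate and raises
  with advice to use a fixed threshold.
- **Dermis surface**: per lateral column, the depth of the shallowest
  mask voxel, then a median filter (default 5×5; the smoothing the
  commercial surface tool applies is unknown, so the window is a config
  parameter). Columns without collagen are *missing* (NaN, never zero);
  missing columns are nearest-neighbour interpolated with a logged count,
  and more than 50% missing aborts.
- **Air/cornified surface**: per column, the first voxel exceeding a
  configurable fraction (default 0.1) of the column maximum of a
  background channel — the reporter-background convention of the
  live-thickness workflow.
- **Distance volume**: exact 3D Euclidean distance to the surface point
  set sampled at pixel centres, with anisotropic voxel scaling, via a
  KD-tree query; this matches a surface-object distance transform and is
  verified against an exhaustive brute-force oracle. A vertical-only mode
  exists as a documented fast approximation (it overestimates distance on
  slopes).
- **Bands**: cytosolic NAD(P)H 0–3 µm, nuclear reporters 0–5 µm above the
  dermal interface; projections are mean (default) or max per channel,
  with a per-pixel count of contributing voxels; zero-count pixels are
  masked in every channel.

## Per-cell redox quantification

The per-pixel ratio image divides NAD(P)H by FAD wherever FAD is at least
the floor (default 1% of the 99th-percentile FAD intensity — no floor is
stated by the acquisition, but division by near-zero must be excluded
explicitly; masked pixels carry a reason code). Per cell the ratio is
**mean(NAD(P)H)/mean(FAD)** over unmasked pixels — ratio of means, more
robust at low FAD counts than the mean of pixel ratios, and gain-invariant.
Segmentation accepts external ROI masks (the stand-in for the original
manual ROIs; both cytoplasmic and whole-cell ROI styles are supported via
the mask) or an automatic mode: Gaussian smoothing (0.8 µm), Otsu
foreground, watershed seeded from distance-transform peaks ≥2 µm apart.
Genotype is called mutant when the cell-mean mCherry exceeds an Otsu
threshold over cell means (no numeric cutoff exists in the source
workflow); a degenerate mCherry distribution means no recombined cells.
No FAD↔NAD(P)H bleed-through correction is applied (none is described for
the acquisition), and NADH/NADPH are pooled.

Normalization divides each cell's ratio by a baseline mean: the same
mouse's earliest-timepoint cells (`day0_same_mouse`) or its WT neighbours
at the same timepoint (`wt_cells_same_mouse`). The redox differential is
WT mean / mutant mean per (mouse, timepoint) — >1 when WT sits higher —
and is reported only where both genotypes have a minimum number of cells
(default 5), logged otherwise.

## Competition metrics

Coverage = mutant pixel area / analyzed pixel area after subtracting the
follicle exclusion mask (exclusions are inputs, as in the original manual
workflow). Thickness = dermis depth − air depth per pixel; crossings are
set missing with a warning and the mean is over defined pixels. The 3D
straightening used for late-timepoint projections in the original
workflow is subsumed here by distance-band extraction (a documented
equivalence assumption). Nucleus counts merge 3D detections within a
merge radius (default 3 µm) via union-find, so one nucleus seen in
adjacent z-slices counts once.

## Flux-ratio panel

Inputs are natural-abundance-corrected enrichment fractions in [0, 1];
isotope correction itself is out of scope. Eight per-sample ratios are
computed (see `flux.RATIO_DEFS`); a missing metabolite or zero denominator
flags the ratio undefined (NaN) rather than zero, and noisy ratios above 1
are reported uncapped. The m+2 malate value is the integrated average of
the two unmeasurable positional isotopologues, carried as a single
`MALATE_C2C3_M2` enrichment. Whether CO₂ enrichment is per-carbon or
per-molecule normalized is not specified upstream; the ratio is
implemented literally as CO₂ enrichment / glucose m+6 enrichment.
Ratios are computed per sample and then summarized per group (never
ratio-of-group-means), matching per-mouse plotting.

## Statistics

The "nested t-test" is implemented as collapse-to-unit-means followed by
an equal-variance two-sample t. The commercial nested test fits a mixed
model, which differs under strongly unbalanced unit sizes; per-unit and
per-value n are reported so users can judge. With one value per unit the
test reduces exactly to the classical two-sample t. Comparisons vs
control after one-way ANOVA use Holm adjustment — slightly conservative
relative to Dunnett but free of multivariate-t quantiles; the upstream
analysis names no correction, so this is a package choice. Normality is
assumed and not tested, mirroring the source workflow. Repeated-measures
ANOVA is not provided; the paired t covers the implemented revisit
designs.

## Synthetic data: the stated world

The generator emulates a telogen ear-skin patch:

- **Geometry**: separable sinusoidal interface (defaults: mean depth
  15 µm, amplitude 3 µm, wavelength 60 µm) plus optional low-pass random
  field and cosine-tapered outgrowth bumps; flat air surface at 2 µm with
  optional undulation; SHG fills everything at/below the interface.
  Default field 300×300 µm (the standard scan field) with 700 basal cells
  (~7,800 /mm², realistic telogen basal density).
- **Cells**: hard spheres (radius 2.5 µm) placed by dart throwing with a
  minimum centre spacing of 1.8× the radius, sitting one radius above the
  interface; suprabasal layers are jittered copies 8 µm higher, placed so
  they cannot enter the nuclear band. Exactly `round(f·n)` cells are
  drawn mutant without replacement. G1 cells (fraction 0.8, matching the
  observed ~490:120 G1:S/G2 split) carry a 1.1× NAD(P)H boost — the
  source reports direction only, so the magnitude is a free parameter.
- **Intensities**: NAD(P)H and FAD are zero outside cells so that band
  projection followed by ratio-of-means recovers each planted per-cell
  ratio *exactly* in the noise-free limit (background pixels scale both
  channels identically). mCherry carries a uniform tissue background
  (0.2) for air-surface detection, with mutant nuclei at 1.0. Absolute
  photon budgets are free parameters: only fold-changes of normalized
  ratios are stated upstream.
- **Noise**: Poisson on intensities scaled by 50 photons/unit, then
  Gaussian read noise (σ = 0.01), clipped at zero — the standard
  two-photon detection model. This gives ~2% per-cell ratio noise for a
  ~150-voxel cell, hence ~0.2% group-mean noise at 100 cells/group.
- **Timecourse presets** pin per-day (WT, mutant) ratios in three revisit
  windows (baseline / day ~5 / day ≥10): the β-catenin preset ends with a
  WT/mutant differential of 2.8 (the reported WT recovery), the Hras
  preset flattens to 1.0, the cyanide preset draws its paired shift
  uniformly in the 28–37% physiological envelope, and the metformin
  preset suppresses the day-5 drop.
- **Truth label maps** exclude lateral pixels contested between two basal
  cells (whose projection column would mix two cells' intensities) —
  conservative ROIs, as the manual originals were. Auto-segmentation is
  still validated against these labels by IoU matching.
- **Isotopologue tables** anchor alanine m+3 at 0.15 and glucose m+6 at
  0.30 and derive the other six enrichments from planted ratios
  (defaults: V_PDH/V_CS 0.6, no glutamine/anaplerotic dilution);
  multiplicative lognormal noise with unit mean and the requested CV.
  Ratio noise then carries a small O(CV²) positive bias (~1% at CV 0.1),
  below every tolerance used.

What a green synthetic test does **not** establish: performance under
depth-dependent scattering and attenuation, optical PSF blur, spectral
bleed-through, real nuclear texture, hair-cycle or follicle 3D structure,
or segmentation of touching irregular cells — none of which the generator
models.

## Monte-Carlo scale-down

Replicate-heavy calibration and power checks (paired-shift detection,
phase-direction detection, flux-separation power, nested-test type-I
error) sample per-cell measurements directly from the same Poisson photon
model as the image generator's default preset (`sample_cell_table`,
7,500 photons/cell/channel ≈ 150 voxels × 50 photons), skipping voxel
rendering to fit a desk-scale compute budget. Voxel-level criteria
(surface RMSE, per-cell exactness, trajectory, coverage, thickness) run
the full image pipeline. Coverage recovery is evaluated as the mean over
three seeded fields because a single ~700-cell Voronoi mosaic has an
inherent area-fraction sampling s.d. (~0.02) of the same order as the
recovery tolerance; averaging estimates the planted value without
touching generator parameters.

## Known limitations

- The exact per-cell ROI style, SHG threshold and surface smoothing of
  the original commercial-software workflow are unknown; all are exposed
  as configuration with documented defaults.
- The air surface for fixed whole-mount thickness originally used
  fixation autofluorescence for the lower surface; here the dermal
  height map plays that role (equivalence assumed, not established).
- The KD-tree distance volume is exact but O(N log M); the vertical mode
  is the documented fast path for large mosaics.
- `nested_t_test` is not a mixed model; see Statistics above.
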
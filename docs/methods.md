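# Methods

This note documents the models, rules and numerical choices behind
`sxtcell`, and what the synthetic phantoms do and do not establish about
real tomograms.

## The measurement model

A soft x-ray tomogram is treated as a 3D grid of linear absorption
coefficients (LAC, μm⁻¹) on an isotropic 35-nm voxel lattice (the voxel
edge is configurable; 35 nm matches a 60-nm-optic reconstruction and makes
the 175-nm proximity shells exactly 5 voxels). Voxel indices are 0-based;
physical coordinates are voxel-center positions in nm; all distances are
center-to-center.

## Segmentation rules

The interactive workflow used on real β-cell tomograms — manual PM/nucleus
tracing plus a "magic wand" that selects connected voxels within an LAC
window — is re-expressed as deterministic rules. PM and nucleus masks are
supplied externally (from phantom ground truth here; from any tracing tool
in general). Inside the cytoplasm, candidate voxels with LAC above a floor
(default 0.28 μm⁻¹ = the lowest classification window edge minus 0.02) are
grouped into 26-connected components and classified with precedence:

1. spherical and max LAC ≥ 0.68 μm⁻¹ → **lipid droplet** (inclusive ≥);
2. spherical, mean LAC in [0.35, 0.67] μm⁻¹, equivalent diameter ≥ 90 nm
   → **insulin vesicle** (the 90-nm cutoff excludes synaptic-like
   microvesicles);
3. elongated, mean LAC in [0.30, 0.40] μm⁻¹ → **mitochondrion**;
4. otherwise rejected with a reason code (microvesicle, ambiguous shape,
   LAC outside windows).

Shape is operationalized through the principal-axis ratio
√(λ_max/λ_min) of the voxel-coordinate covariance, regularized by adding
the 1/12 single-voxel variance per axis (a single voxel is then exactly
spherical, and a one-voxel-thick rod still registers as elongated).
"Spherical" means ratio ≤ 2, "elongated" ratio ≥ 3; the gap band is
rejected as ambiguous rather than guessed. The droplet rule outranks the
vesicle rule because a bright spherical object whose *mean* falls in the
vesicle window is still a droplet by the max-LAC criterion. The
mitochondria window [0.30, 0.40] is centered on the reported mean
0.34 ± 0.02 μm⁻¹; only a mean is reported for mitochondria, so the window
half-width (3 SD) is this package's choice. Classification windows are
applied to per-object mean LAC; during interactive region growing the
window applies per voxel — both behaviours are exposed.

Per-cell LAC values can be rescaled by `reference / capillary_mean` using
the glass-capillary wall as an internal standard; raw values are always
kept alongside the normalized columns.

## Morphometry

Equivalent diameter is (6V/π)^⅓ from the voxel-count volume — robust to
rasterization and exact for ideal spheres. Cytosol is defined as cell
minus nucleus minus all segmented organelles, so compartment volumes
partition the cell volume exactly. Vesicle counts are normalized by cell
volume as `count × reference / cell_volume`, with the cohort mean cell
volume as the default reference (cells generated at the reference volume
therefore report normalized ≈ raw counts).

## PM-distance statistics

PM distances come from a Euclidean distance transform of the cell mask
(distance of each inside voxel center to the nearest outside voxel
center). Each vesicle contributes the distance-field value of its centroid
voxel; distances are normalized by the cell's maximum possible PM distance
D_C, binned over [0, 1] (default 20 bins), and divided by the vesicle
count to give a probability distribution. Compared distributions must
share bin edges.

Mitochondria–vesicle proximity is the distance of each vesicle center to
the nearest mitochondrial voxel, summarized as fractions per 175-nm shell
([0, 175], (175, 350], (350, ∞) nm by default; shells are closed on the
right, so a distance of exactly 350 nm falls in the second shell). A
"normalized by cell volume" variant for these distances is dimensionally
ambiguous in the source material; raw nm distances are the primary output
and a cube-root-of-volume normalization is available behind a flag without
asserting either reading.

## Null models and divergence

For each cell, random vesicle placements are drawn in the observed
geometry: the allowed volume is the cytoplasm (cell minus nucleus minus
mitochondria) restricted by PM distance — class 1 ≤ T, class 2
unrestricted, class 3 > T, with T = 20% of D_C. Ties at exactly T go to
class 1 (the source wording "smaller than"/"larger than" leaves the
boundary open; the tie set is a measure-small voxel shell). Points are
voxel centers drawn uniformly by rejection sampling with a hard-core
exclusion of ≥ 4 voxels (Euclidean, voxel units), `max_attempts`
defaulting to 100·n with an explicit infeasibility error reporting the
achieved count. Ensembles hold 50 replicates at the observed vesicle
count, each binned on the observed distribution's edges.

Dissimilarity is the discrete-histogram Bhattacharyya distance
BD = −ln Σᵢ √(pᵢqᵢ): symmetric, zero iff equal, +∞ when supports are
disjoint. No smoothing is applied by default — the +∞ sentinel is
honest for disjoint supports — but additive smoothing is available (and
used by the report pipeline at 1e-6) where finite scatter values are
needed for plotting. A docked phantom scores lowest against class 1 and
highest against class 3; a diffuse phantom scores lowest against class 2 —
the qualitative identification the method is designed to make.

## Confined-diffusion control

The spherical-cell control runs free Brownian dynamics of non-interacting
point particles between a reflecting spherical nucleus and PM: Gaussian
steps of per-axis variance 2·D·dt, radial mirror reflection at both
surfaces (a rejection-resampling alternative sits behind a flag).
Defaults: 1000 μs total, sampled every 50 μs for frames at ≥ 900 μs. The
diffusion coefficient is not reported in the source material and only sets
the equilibration rate — the tested property (uniform density ⇒ shell
occupancy proportional to shell volume) is D-independent at equilibrium;
the default D = 10⁴ nm²/μs makes the RMS free displacement over the
burn-in exceed the cell diameter. The radial-mirror reflection is exact
only as dt → 0; its bias scales like (step SD / radius)², so the default
step SD (≈ 141 nm, 4% of the cell radius) keeps the bias an order of
magnitude below sampling noise at 10⁴ samples. Tests use step SDs ≤ 6% of
the radius for the same reason.

## The phantom generator

The generator emulates what the analysis consumes — an LAC volume with
compartment structure — not the imaging physics. A run places, in order:
a cylindrical glass-capillary wall at the grid margin (the normalization
reference), a spherical cell (optional smooth radial deformation; spheres
are adequate for distance statistics, which is exactly what the
confined-diffusion control establishes), an off-center spherical nucleus,
capsule-shaped mitochondria, dense-core lipid droplets, and insulin
vesicles in one of four arrangements:

* **docked** — all centers within 20% of D_C of the PM;
* **clustered** — half docked, half drawn around 4 interior cluster seeds
  (Gaussian spread 800 nm), reproducing the bimodal docked-plus-clusters
  distance profile of glucose-stimulated cells;
* **chains** — collinear runs of 4–8 vesicles spaced 1.2× diameter;
* **diffuse** — uniform over the cytoplasm.

All objects respect hard non-overlap with a 2-voxel surface gap — this
guarantees distinct 26-connected components, so noiseless segmentation is
an exact inverse of generation. Placement is rejection sampling with a
bounded attempt budget and an explicit failure naming the object class.

Per-object diameters and LAC values are truncated-normal draws around the
per-condition preset means (mean ± SD is all the source data report).
Vesicle and mitochondria LAC draws are clipped 0.005 μm⁻¹ inside their
classification windows so that every generated object is classifiable by
construction; the clip moves the realized means by < 0.002 μm⁻¹. Lipid
droplets get a dense core (inner 30% of the radius at 0.70 μm⁻¹) with the
shell value solved from the *rasterized* voxel counts so the object's
voxel-mean LAC equals its drawn mean exactly while max LAC ≥ 0.68 μm⁻¹
holds. Noise is additive Gaussian on LAC, default SD 0.01 μm⁻¹ (the
smallest reported SD scale). Per-cell compartment values (nucleus LAC
0.26 ± 0.02, cytosol 0.20 ± 0.01, capillary 0.30 ± 0.005 μm⁻¹) are drawn
once per cell to emulate cell-to-cell variability; cohort generation also
draws each cell's vesicle count from the condition mean ± the reported SD.

Default geometry is a 3.6-μm-radius cell with a 1.7-μm nucleus on a 256³
grid — smaller than a real ~10-μm β cell so a whole cell plus capillary
fits the default grid, while holding the *absolute* per-condition vesicle
counts (319, 788, …), which are the quantities under test. Packing was
checked feasible at the largest preset (the hard-core exclusion occupies
≈ 10–25% of the allowed band, well below the random-sequential-adsorption
limit). Mitochondria default to 40 capsules of radius 150 nm and length
1500 ± 300 nm; counts and dimensions are not reported per cell in the
source material and were fixed once at values giving a realistic
mitochondria/cytosol volume ratio of a few percent.

### What the phantoms do not emulate

No projection/reconstruction artifacts (missing wedge, beam damage, ring
artifacts), no partial-volume blur at organelle boundaries, no ER/Golgi,
no spatial correlation between a vesicle's LAC and its PM distance
(maturation state and position are treated as independent), and no
irregular nucleus shapes. Passing tests therefore demonstrate that the
*analysis* is correct and unbiased on geometrically faithful inputs — not
that segmentation of real, artifact-bearing tomograms achieves the same
accuracy.

## Problem sizes

Full-size cohorts (8 cells × 256³ voxels) run in a few minutes on one
CPU; the test suite exercises the same code paths mostly on 96³ phantoms
with proportionally scaled-down object counts, which preserves every
geometric constraint while keeping unit tests fast.

## File formats

LAC volumes are MRC 2014 mode 2 (float32) with the voxel size in the
header, label maps mode 6 (uint16); both also round-trip through
multi-page TIFF with the voxel size in the image description. The MRC
codec is a minimal single-volume implementation of the MRC 2014 subset
this package writes. Tables are CSV with explicit precision; non-finite
values are refused rather than silently serialized.
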
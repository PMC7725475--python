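# sxtcell

Whole-cell topology analysis for soft x-ray tomography (SXT) of secretory
cells — built around the insulin-secreting β cell.

SXT images intact, cryo-preserved cells in the water window, where each
voxel carries a linear absorption coefficient (LAC, μm⁻¹) proportional to
local molecular density. Dense-core insulin vesicles, lipid droplets,
mitochondria and the nucleus all separate by LAC, size and shape, so a
whole cell can be segmented and its organelle topology quantified — how
vesicle pools redistribute between the plasma membrane (PM) and the cell
interior under glucose or incretin stimulation, and how close vesicles sit
to mitochondria.

`sxtcell` implements that analysis pipeline end to end, plus a synthetic
phantom generator with ground truth so every stage is testable without
access to tomograms:

* **phantom** — synthetic LAC volumes of a ~7-μm cell inside a glass
  capillary: nucleus, elongated mitochondria, dense-core lipid droplets,
  and insulin vesicles placed *docked / clustered / chains / diffuse*,
  with per-condition presets (`unstimulated`, `glucose_30min`, …).
* **segmentation** — deterministic re-expression of the interactive
  magic-wand workflow: LAC-window region growing, 26-connected components,
  classification (spherical + max LAC ≥ 0.68 μm⁻¹ → lipid droplet;
  spherical + mean LAC ∈ [0.35, 0.67] μm⁻¹ + diameter ≥ 90 nm → insulin
  vesicle; elongated + mean LAC ∈ [0.30, 0.40] μm⁻¹ → mitochondrion), and
  per-cell capillary LAC normalization.
* **morphometry** — per-object volumes, equivalent diameters
  ((6V/π)^⅓), axis ratios, mean/max LAC; per-cell summaries with
  volume-normalized vesicle counts and the mitochondria/cytosol ratio.
* **spatial** — Euclidean-distance-transform PM distances, normalized as
  d = d_obs/D_C ∈ [0, 1] (D_C = the cell's maximum possible PM distance),
  binned into probability distributions; mitochondria–vesicle nearest
  distances and 175-nm shell fractions.
* **nullmodels** — three classes of constrained random placements in the
  observed cell geometry (near-PM, whole cytoplasm, interior; threshold
  T = 0.2·D_C, points ≥ 4 voxels apart, 50 replicates at the observed n).
* **divergence** — Bhattacharyya distance BD = −ln Σᵢ √(pᵢqᵢ) between
  observed and null distance distributions.
* **diffusion** — Brownian-dynamics control in a spherical cell (1000 μs,
  sampled every 50 μs after 900 μs) verifying that equilibrium shell
  occupancies follow shell volumes.

## Worked example

```python
from sxtcell import (preset_params, generate_cell_phantom, segment_cell,
                     cell_summary)

params = preset_params("unstimulated", seed=3)
volume, truth = generate_cell_phantom(params)          # 256³ voxels, 35 nm
labels, table = segment_cell(volume,
                             truth.label_map.cell_mask(),
                             truth.label_map.mask("nucleus"))
s = cell_summary(labels, volume, table)
print(f"vesicles: {s.vesicle_count}")
print(f"mean vesicle LAC: {s.mean_vesicle_lac:.4f} µm⁻¹")
print(f"mean vesicle diameter: {s.mean_vesicle_diameter_nm:.1f} nm")
print(f"mean mitochondria LAC: {s.mean_mitochondria_lac:.4f} µm⁻¹")
```

prints

```
vesicles: 319
mean vesicle LAC: 0.3904 µm⁻¹
mean vesicle diameter: 244.6 nm
mean mitochondria LAC: 0.3405 µm⁻¹
```

i.e. the segmentation recovers, object by object, the vesicle population
the generator placed (319 vesicles of mean LAC 0.39 μm⁻¹ and diameter
≈ 243 nm in this condition) — the round trip that validates both stages.

The same analysis is scriptable from the shell:

```bash
sxtcell generate --preset unstimulated --seed 3 --out-dir run/
sxtcell segment --volume run/unstimulated_0.mrc \
                --labels run/unstimulated_0_labels.mrc --out run/objects.csv
sxtcell nullmodel --labels run/unstimulated_0_labels.mrc \
                  --table run/objects.csv --out run/divergence.csv
sxtcell report --preset unstimulated --preset glucose_30min \
               --cells 8 --seed 0 --out-dir report/
```

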
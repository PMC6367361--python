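# mechanocyte

Quantitative analysis of cell biomechanics and morphology for
cancer-cell-mechanics studies: atomic force microscopy (AFM) force-volume
maps, quantitative phase imaging (QPI), fluorescence morphometrics, and
functional assays (colony forming, impedance-based invasion, migration),
plus the normality-gated statistics such studies report.

It is aimed at groups who measure how treatments (cytostatic drugs, metal
supplementation) change the stiffness, dry mass, shape and motility of
adherent cells, and who want those measurements reproducible in code rather
than in vendor GUIs.

## What it computes

**Force spectroscopy.** Each force-distance curve F(z) is fitted with the
Hertz-Sneddon contact model, jointly estimating the Young's modulus E, the
contact point z0 and the force baseline, with the indentation corrected for
cantilever bending, delta = (z - z0) - F/k:

- cone: F = (2/pi) * E/(1-nu^2) * tan(theta) * delta^2
- four-sided pyramid: F = 0.7453 * E/(1-nu^2) * tan(theta) * delta^2
- sphere: F = (4/3) * E/(1-nu^2) * sqrt(R) * delta^(3/2)

Force-volume maps become per-pixel images of E and "setpoint height" (the
piezo position where the commanded maximum force is reached, a topography
proxy). Cells are segmented on the height image by watershed with a
replayable manual-correction script, and per-cell mean E / height are
extracted.

**QPI dry mass.** Phase phi (rad) converts to dry-mass surface density

    m = phi * lambda / (2 * pi * alpha)   [pg/um^2]

with wavelength lambda (0.65 um default) and specific refraction increment
alpha (0.18 um^3/pg). Cells are segmented by watershed with saddle-ratio
region merging; per-cell total dry mass, mean density, centroid and
circularity 4*pi*A/P^2 (Crofton perimeter) are reported.

**Fluorescence morphometrics.** Whole-cell and 4-um peripheral-band
intensities for actin/tubulin, cell shape (area, maximum Feret diameter,
roundness, aspect ratio, circularity), per-fibre length/orientation/
intensity, and the circular standard deviation sqrt(-2 ln Rbar) of fibre
angles (raw or axial mode).

**Assays.** Colony photographs are rigidly registered to a reference and
the stained fraction inside the region of interest is measured by a fixed
CIELAB b-channel threshold. Impedance records become Cell Index
CI = (Z - Z_blank)/Z_nominal, normalised to 1 at the treatment time.
Cell tracks yield per-cell speeds, a speed-weighted rose histogram, and the
directional summary vector (net displacement over total path length).

**Statistics dispatch.** Shapiro-Wilk gates each comparison into ANOVA
(repeated-measures when paired) or Kruskal-Wallis, and each correlation
into Pearson or Spearman; qRT-PCR tables are reduced by the comparative Ct
method (2^-ddCt).

Every modality has a seeded synthetic generator with exact ground truth
(`mechanocyte.synthetic`), used throughout the test suite.

## Worked example

```python
import numpy as np
from mechanocyte import synthetic as syn
from mechanocyte.afm_mapping import build_stiffness_map, segment_height_map, extract_cell_mechanics
from mechanocyte.qpi import phase_to_drymass, remove_background_phase, segment_qpi, cell_qpi_features

# a 32x32 force-volume map with two cells of known stiffness
fmap, truth = syn.gen_force_map(seed=7, cell_E=(700.0, 1200.0))
smap = build_stiffness_map(fmap, truth["tip"])
mask = segment_height_map(smap.setpoint_height_image)
for rec in extract_cell_mechanics(smap, mask):
    print(f"cell {rec.label}: mean E = {rec.mean_E:.0f} Pa, "
          f"height = {rec.mean_setpoint_height:.2f} um, area = {rec.area:.0f} um^2")

# a phase image with one 300 pg cell
img, _ = syn.gen_phase_image(seed=7, cell_masses=(300.0,))
mass = phase_to_drymass(remove_background_phase(img))
for rec in cell_qpi_features(mass, segment_qpi(mass)):
    print(f"cell {rec.label}: dry mass = {rec.total_dry_mass:.1f} pg, "
          f"circularity = {rec.circularity:.3f}")
```

Output:

```
cell 1: mean E = 700 Pa, height = 5.95 um, area = 377 um^2
cell 2: mean E = 1201 Pa, height = 5.71 um, area = 316 um^2
cell 1: dry mass = 299.8 pg, circularity = 0.986
```

The recovered per-cell moduli match the generator's 700/1200 Pa inputs
within a fraction of a percent, and the integrated dry mass recovers the
deposited 300 pg; the setpoint height combines the 3-um cell topography
with the extra indentation depth soft material requires.

A `mechanocyte` console script exposes the same pipelines on files
(`fit-curves`, `map`, `segment-afm`, `cell-stats`, `qpi`, `fluor`,
`colony`, `rtca`, `tracks`, `synth`); run `mechanocyte --help`.

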
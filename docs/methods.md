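# Methods

## The geometric model

The thorax of a supine rodent, seen between the carina and the
diaphragmatic cupola, is approximated by a conical frustum.  Three
distances are measured on a reoriented scan (vertebrae and sternum
aligned in the axial plane, contralateral ribs level in coronal view):

* `d_small` — carina-level span, external lung limit to the contralateral
  limit, coronal view.  When no lung is visible at this level the
  rib-to-rib inner span substitutes; the phantom manifest carries both so
  the fallback is testable.
* `d_large` — diaphragm-level span, ventral vertebral aspect to abdominal
  wall, sagittal view.
* `height` — carina-to-diaphragm distance.

The frustum volume is `V = (π·h/3)(R1² + R2² + R1·R2)`.  The measured
spans cross the whole thorax, so they are treated as diameters and halved
to radii by default.  That convention is exposed
(`halve_diameters=False`) for sensitivity analysis: it rescales all
thoracic volumes by a constant factor 4, which the downstream regression
absorbs, but raw frustum volumes depend on it.

The frustum is deliberately a *model*, not a segmentation: the true
thoracic cavity is neither circular in cross-section nor perfectly
tapered.  The regression stage exists to absorb exactly this systematic
discrepancy, so the end-point of the protocol is the calibrated
*theoretical lung volume* `Y = a·X + b`, fitted per animal model against
manually delineated lung volumes (a single global model is possible but
per-model calibration is the default workflow, since the thoracic
anatomy/lung relation varies between strains and disease models).
Predictions outside the training thoracic range emit a warning rather
than an error, because pathologic thoraces routinely exceed the healthy
calibration range.  Percent deviation from the gold standard is reported
as a magnitude, `100·|Y − gold|/gold`.

## Supporting pipeline

**Coordinates.** Arrays are `(z, y, x)` = (axial, coronal, sagittal),
0-based, voxel centers at `index × spacing` mm.  All distances are mm and
volumes mm³.

**Hounsfield calibration** is the standard two-point map: arithmetic
means (no trimming) of an air VOI and a water VOI are anchored to
−1000 HU and 0 HU.  Calibration is per scan session and persists as JSON.
Applying a calibration to an already-calibrated volume is rejected.

**Threshold segmentation** selects voxels in an inclusive HU window,
default −700..−300 HU (alternate preset −700..−400 HU), the standard
window for aerated mouse parenchyma whose modal density is ≈ −500 HU.
Connected components touching the volume border are removed (exterior air
shares the window's tail once noise is present; inside an animal this
exclusion is implicit) and components under 27 voxels are discarded as
specks.  No smoothing or filtering is applied anywhere in the package, so
voxel intensities remain exactly as acquired or generated.

**Manual delineation** is emulated from closed polygons on a subset of
axial slices.  Annotated slices rasterize with the even-odd rule (nested
contours cut holes, so an annular lung section needs no special casing);
gaps interpolate linearly between the signed distance transforms of the
bounding annotated slices.  The interactive tools used in practice do not
document their interpolation, so equivalence is claimed at the volume
level, not voxel-by-voxel; on convex bodies, refining the annotation
changes the volume by well under 1%.

**Reorientation** treats multiples of 90° as exact voxel permutations;
arbitrary rotations resample trilinearly (masks: nearest-neighbour) about
the grid center on the same spacing, and require isotropic voxels since a
rotation mixing anisotropic axes would shear physical space.  The fill
value defaults to the data minimum, i.e. background air.

## Statistics

* **Bland-Altman**: differences of paired volumes against pair means;
  bias ± 1.96·sd (sample sd, n−1) as 95% limits of agreement.  The
  normal-theory 1.96 is used rather than a t-quantile — the protocol's
  agreement criterion is the conventional fixed-limit plot.
* **Gage R&R**: balanced crossed two-way ANOVA with interaction,
  variance components by the expected-mean-squares equations
  (`σ²_rep = MS_E`, `σ²_int = (MS_int − MS_E)/r`,
  `σ²_op = (MS_op − MS_int)/(p·r)`, `σ²_part = (MS_part − MS_int)/(o·r)`).
  Negative estimates truncate to zero; when the interaction mean square
  falls below the error mean square the interaction is pooled into
  repeatability before solving.  The headline reproducibility figure is
  the operator-plus-interaction share of total variance.
* **Sensitivity/specificity**: each scan's lung volume is compared to the
  mean of the sham-control group (`reference="auto"`); deviation strictly
  over 5% is positive.  The boundary is deliberately strict — exactly 5%
  classifies negative — and pinned by a test.  The end-to-end pipeline
  classifies on the theoretical lung volume, the protocol's endpoint.

## The synthetic phantoms

**Thorax.**  The thoracic cavity is a solid of revolution with elliptical
cross-section (dorso-ventral/left-right aspect 0.85), radius tapering
linearly from the carina to the diaphragm with a 12% sinusoidal
mid-thorax bulge.  It is therefore *close to* but not exactly a frustum:
the landmark model retains a genuine systematic error for the regression
to absorb, as in real anatomy.  Around it sit a soft-tissue body
(40 HU), a dorsal vertebral column and a periodic rib shell (700 HU), a
tracheal air column ending at the carina, and background air (−1000 HU).
The lung is the outermost `lung_fraction` of cavity voxels (the spared
central core plays the mediastinum and heart); aerated parenchyma draws
from a truncated Gaussian, mean −500 HU, sd 80 HU, support (−700, −300)
HU.  Non-aerated tissue (vessels at 60 HU; lesions at 30 HU, either
blob-like nodules or a dorso-caudally biased consolidation) is selected
by thresholding smooth Gaussian random fields at exact voxel counts, so
every manifest volume equals its mask's voxel count × voxel volume
exactly.  Additive white Gaussian noise (default sd 25 HU) is applied
last.  Defaults: 256³ grid at 0.05 mm, carina width 6.0 mm, diaphragm
depth 7.6 mm, height 9.0 mm (≈ 390 mm³ cavity), lung fraction 0.62,
aeration 0.88 — ratios in the healthy-animal regime.

**Calibration tube.**  Two stacked cylindrical compartments with designed
raw grey means (air 10 000, water 30 000) and VOIs strictly inside each;
with zero noise the VOI means equal the designed values exactly, and with
sd 50 grey on >10⁴-voxel VOIs the anchors hold within 3 HU (6σ of the
standard error 0.5).

**Cohorts.**  `generate_cohort` draws thoracic volumes from a truncated
Normal (mean 900 mm³, sd 190 mm³, bounds 520–1450 mm³ — matching the
mean and ~21% coefficient of variation of healthy adult mice, truncated
below so the lung target stays feasible), heights uniform on 9–12 mm and
taper ratios on 1.35–1.6, then solves the cavity-width that yields the
drawn volume from the analytic solid-of-revolution integral.  The true
lung volume target `a·X + b + ε` is evaluated on the *voxelized* thoracic
volume and realized as an exact voxel count, so at ε = 0 an OLS fit of
the truths returns (a, b) to one-voxel rounding (~10⁻³ mm³).  Defaults
a = 0.20, b = 300 mm³, ε ~ N(0, 20² mm³).  Cohort phantoms default to a
16 × 19.2 × 22.4 mm grid at 0.1 mm spacing; the end-to-end pipeline uses
0.15–0.18 mm grids and cohorts of 6–12 scans, sizes chosen so a full run
stays interactive while leaving every statistical conclusion unchanged
(the estimators' sampling error, not the voxel size, dominates).

**What the phantoms do not model** — and hence what passing tests do not
establish about real data: photon noise and beam hardening, cardiac and
respiratory motion (real protocols gate or accept free-breathing blur),
anatomical texture of real parenchyma, partial-volume effects at the
scale of real vessel trees, and operator variability in landmark
placement (landmarks come from the manifest; the Gage R&R machinery is
exercised on simulated operator effects instead).  Ground-truth recovery
here validates the *software chain*, not the biological accuracy of the
frustum approximation in vivo.

## Numerical choices and edge cases

* Window endpoints are inclusive; parenchyma is generated on the open
  interval, so zero-noise threshold recovery is exact by construction.
* Signed-permutation rotation matrices are detected at 1e−9 and applied
  exactly; rotation matrices must be orthonormal within 1e−6 and proper
  (det +1) — reflections are rejected.
* The regression requires n ≥ 3 and non-degenerate predictor variance;
  Pearson r and the OLS slope come from the same least-squares solve, and
  `r_squared == pearson_r²` is enforced at 1e−9.
* Gage R&R on perfectly constant data attributes 100% to repeatability
  (zero total variance has no meaningful decomposition).
* Classification with no pathologic scans reports sensitivity as NaN
  rather than inventing a rate; `reference="auto"` requires at least one
  control.
* Pipeline outputs are byte-stable: JSON with sorted keys, CSV with fixed
  float format, SVG with a pinned hash salt and no timestamp.

## Known limitations

* The frustum-to-cavity ratio is fixed by phantom geometry; real
  inter-animal shape variation is wider, so in-vivo R² will be lower than
  the synthetic ~0.85.
* Contour-based delineation assumes polygons are simple; self-intersection
  is not detected, only vertex sanity.
* Off-axis reorientation of raw integer volumes rounds back to integers
  after trilinear resampling, a small irreversible quantization.
* The 27-voxel speck threshold is resolution-dependent (chosen for
  0.035–0.1 mm isotropic grids); at much coarser spacing it may remove
  genuine structure.
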
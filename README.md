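# conelung

Fast geometrical lung volumetry for rodent microCT.

Quantifying lung volume in preclinical microCT normally means manually
delineating the lung slice by slice (15–20 min per scan, operator
dependent) or threshold-segmenting aerated tissue, which underestimates
the lung as soon as pathology turns parenchyma radiodense.  `conelung`
implements a much faster geometric alternative: the thorax is approximated
by a **conical frustum** whose small base sits at the carina, whose large
base sits at the diaphragmatic cupola, and whose height spans the two.
From the three landmark distances the thoracic volume is

```
V = (π·h/3) · (R1² + R2² + R1·R2),      R1 = d_small/2,  R2 = d_large/2
```

and a per-model linear regression `Y = a·X + b` calibrated against
manually delineated lung volumes converts the thoracic volume `X` into a
**theoretical lung volume** `Y`.  Because the estimate rests on thoracic
anatomy rather than tissue radiodensity, it stays usable in animals whose
lungs have consolidated.

The package is aimed at preclinical imaging scientists and provides:

- `ct_io` — NIfTI-1 / MetaImage volume and mask I/O, rigid reorientation
  into the standard analysis frame (axial / coronal / sagittal);
- `hu_calibration` — two-point Hounsfield calibration from air and water
  VOIs (air → −1000 HU, water → 0 HU);
- `segmentation` — aerated-lung threshold segmentation (reference window
  −700..−300 HU, alternate −700..−400 HU) and emulated manual delineation
  from slice contours with signed-distance inter-slice interpolation;
- `geometry` — landmark measurement and the frustum volume;
- `calibration_model` — the thoracic→lung regression and percent
  deviation from a gold standard;
- `agreement_stats` — volume ratios, Bland-Altman limits of agreement,
  crossed Gage R&R ANOVA variance components, and the 5%-deviation
  sensitivity/specificity screen;
- `phantom` — synthetic mouse-thorax and air/water-tube phantoms with
  exact ground-truth manifests, plus seeded cohort generation;
- a `conelung` CLI and an end-to-end `run_protocol` pipeline.

## Worked example

```python
import conelung as cl

# a zero-noise synthetic thorax with known ground truth
ph = cl.generate_thorax_phantom(cl.PhantomSpec(noise_sd_hu=0.0, seed=11))

m, v = cl.thoracic_volume_from_image(ph.volume, ph.truth.landmarks)
print(m, v)                       # landmark distances and frustum volume
seg = cl.threshold_segment(ph.volume)
print(cl.mask_volume_mm3(seg))    # aerated lung volume

# a 40-scan cohort whose lung volumes follow 0.20·thoracic + 300 mm³
cohort = cl.generate_cohort(40, noise_sd=20.0, seed=1, render_volumes=False)
model = cl.fit_lung_regression(
    [(p.truth.thoracic_volume_mm3, p.truth.lung_volume_mm3) for p in cohort]
)
print(f"Y = {model.slope:.4f} X + {model.intercept:.2f}  R2={model.r_squared:.4f}")
```

prints

```
ThoraxMeasure(d_small=6.0, d_large=7.6, height=9.0) 328.36
214.80
Y = 0.2107 X + 287.46  R2=0.8578
```

Reading the numbers: the landmark spans (6.0 × 7.6 × 9.0 mm) give a
frustum volume of 328.4 mm³, a smooth-but-not-conical underestimate of the
true 393.7 mm³ cavity — exactly the systematic error the regression stage
absorbs.  The threshold segmentation recovers the manifest's aerated
volume (214.80 mm³) to within a voxel.  On the cohort, ordinary least
squares recovers the generating line (slope 0.20, intercept 300 mm³)
within sampling error at an R² in the 0.7–0.9 range typical of healthy
cohorts.

The same protocol is available from the shell:

```sh
conelung phantom --n 3 --seed 7 --out scans/
conelung cone --landmarks lm.json scans/phantom-000.nii.gz
conelung fit --table cohort.csv --out model.json
conelung predict --model model.json --thoracic 900
conelung run --seed 7 --out run/
```

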
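# retmorph

Retinal vascular morphometry from binary fundus masks, with a calibrated
synthetic-data layer and the cohort statistics used in pediatric
fundus-angiography studies.

## What it does

Wide-field pediatric fundus fluorescein angiography (FFA, e.g. RetCam 3:
1,600 × 1,200 px frames at 12.2 µm/px) yields segmentations of the retinal
vessels and the optic disc. Given those two binary masks, `retmorph`
computes the five structural readouts used to describe early retinal
vascular development:

* **Optic-disc diameter (DD)** — long axis of the minimum outer rectangle
  of the disc mask, in px and mm.
* **Fractal dimension (FD)** — box-counting dimension of the skeletonized
  vascular tree: the slope of log N(s) vs log(1/s) over dyadic box sizes s.
* **Mean vessel caliber** — lumen width perpendicular to the centerline,
  sampled at every skeleton pixel inside the analysis annulus, in µm.
* **Vessel density** — vessel-pixel fraction of the annulus.
* **Mean curvature** — reciprocal circumradius 1/R of centerline triples
  A–P–B spaced a fixed arclength apart (px⁻¹; log-transformed as lnC for
  regression).

The vascular metrics are evaluated in the posterior annulus spanning
0.5–3.0 DD around the disc center. A segmentation-evaluation module
provides pixelwise accuracy, sensitivity, specificity and IoU, and a
statistics module reproduces the cohort analysis: per-metric OLS on age in
days, segmented regression for caliber with a fixed breakpoint at 1,095
days (3 years), density–FD Pearson correlation, one-way ANOVA across six
one-year age groups with Tukey HSD, per-group sex t-tests and
D'Agostino–Pearson normality verdicts.

Because no patient-level data are public, the package ships first-class
generators: vascular-tree scenes with known ground-truth geometry (for
validating every operator against analytic oracles) and synthetic cohorts
of n = 146 whose metrics are drawn from the published regression models
with noise calibrated so refits reproduce each printed R².

## Worked example

```python
import retmorph as rm

scene = rm.generate_vessel_tree(rm.VesselTreeParams(seed=3))
m = rm.measure_all(scene.vessel_mask, scene.disc_mask)
print(m.as_dict())
```

prints (seed 3):

```
{'disc_diameter_mm': 1.3542, 'fractal_dimension': 1.3050,
 'caliber_um': 61.069, 'density': 0.1191, 'curvature_px_inv': 0.005456}
```

The disc measures 1.35 mm (the generator drew a 110.6-px disc at
12.2 µm/px, i.e. 1.35 mm — the minimum-rectangle estimate lands within a
pixel); the tree's skeleton has box-counting dimension 1.31; mean lumen
width is 61 µm; vessels cover 11.9 % of the 0.5–3.0 DD annulus (the
generator's ground-truth density is 0.1190, recovered to 3 × 10⁻⁵); and
the sinusoidally tortuous centerlines average 0.0055 px⁻¹ of curvature.

Cohort side:

```python
table = rm.generate_cohort(rm.CohortParams(seed=1))   # 146 eyes
report = rm.analyze_cohort(table)
print(report["metrics"]["fractal_dimension"]["linear_fit"]["slope"])
# -1.92e-05 on this one replicate; averaged over replicates the refit
# converges to the configured model slope of -2.6e-05
```

The same flows are scriptable: `retmorph simulate-scene`,
`simulate-cohort`, `measure`, `evaluate-seg`, `analyze-cohort`, `run-all`.

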
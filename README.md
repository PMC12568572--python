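# retinavasc

Retinal vascular and optic-nerve-head morphometry for disc-centered fundus
photographs, with a synthetic two-cohort study harness. The package
implements the full measurement chain used in AI-based pediatric fundus
studies — vessel segmentation → centerline graph → quantitative parameters
→ peripapillary zonal analysis → covariate-adjusted group comparison — and
ships a scene generator with exact ground truth, so every stage is
testable without any clinical data.

It is written for researchers who want a transparent, scored reference
pipeline for fundus morphometry: the classical segmenter is a stand-in
behind a small interface that a learned model can replace, while the
measurement and statistics layers are the deliverable.

## What is measured

Per eye, globally and per peripapillary zone (annuli at 0.5–1.0 … 2.0–2.5
disc diameters (PD) from the disc border, and superior/nasal/inferior/
temporal quadrants of the 0.5–2.5 PD band):

| symbol | parameter | definition |
| --- | --- | --- |
| VDf | vascular fractal dimension | box-counting slope of log N(s) vs log s |
| VC | vascular caliber (µm) | mean centerline-orthogonal width (2 × medial radius × pitch) |
| VT | vascular tortuosity | arc/chord − 1 per segment, length-weighted |
| VD | vascular density | vessel pixel fraction of the region |
| VBA | vascular branching angle (°) | angle between daughter lines fitted near each bifurcation within 2 PD |
| AVR | arteriole-to-venule ratio | mean artery caliber / mean vein caliber |
| disc, cup area (mm²), C/D | optic nerve head | fitted ellipse areas and their ratio |

Cohorts are compared with ANCOVA (`outcome ~ group + age + sex + axial
length`), alongside baseline t-tests and chi-square, with both eyes
entering as rows.

## Worked example

```python
from retinavasc.simulate import default_scene
from retinavasc.segmentation import preprocess, segment_vessels, detect_disc_cup, mask_quality
from retinavasc.graph import skeletonize, build_graph
from retinavasc.morphometry import region_metrics
from retinavasc.simulate import disc_to_ellipse

image, truth = default_scene(seed=0)           # 1024x1024 fundus + exact truth
pre = preprocess(image)
mask = segment_vessels(pre)
print(mask_quality(mask, truth.vessel_mask, pre.roi))
# {'sensitivity': 0.978, 'specificity': 0.984, ...}

graph = build_graph(skeletonize(mask, 5), mask, truth.artery_mask, truth.vein_mask)
rec = region_metrics(graph, mask, image.pixel_pitch, "Global",
                     disc_ellipse=disc_to_ellipse(truth.disc))
print(round(rec.VDf, 3), round(rec.VC, 1), round(rec.VD, 3), round(rec.VBA, 1))
# 1.427 75.2 0.052 53.5
```

The sensitivity/specificity pair says 97.8% of true vessel pixels were
recovered while 98.4% of background pixels were left untouched; the
metric record reads: fractal dimension 1.43 (a normally dense vascular
pattern), mean caliber ≈ 75 µm, 5.2% of the frame vascularized, and a mean
branching angle of ≈ 54°.

The `analysis/` scripts run the same chain as a small narrative study:

```bash
python analysis/01_simulate_cohort.py     # render a 3-subjects/group cohort
python analysis/02_segment_and_measure.py # segment + measure all eyes
python analysis/03_zonal_profiles.py      # radial/quadrant profiles
python analysis/04_group_statistics.py    # 100/group truth-level ANCOVA
```

`03` prints the peripapillary fall-off (density 0.113 → 0.006, caliber
79 → 58 µm from the innermost to the outermost annulus, both monotone);
`04` reports the covariate-adjusted group effects, e.g. a −2.8 µm adjusted
caliber difference (p = 0.03) for the highland group at its default −4 µm
injected effect.

There is also a CLI (`retinavasc simulate|segment|metrics|stats|run|validate`)
for file-based use; `retinavasc run --seed 1 --out runs/demo` executes the
whole pipeline and writes metrics, reports, and a manifest.

## Layout

```
src/retinavasc/     simulate, segmentation, graph, morphometry, zones,
                    stats, validation, pipeline, cli
analysis/           numbered study drivers (write under results/)
tests/              pytest suite incl. the acceptance gates
docs/methods.md     models, estimators, defaults, and their rationale
```
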
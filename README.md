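# petvol

Threshold-based PET tumor volume delineation, benchmarked on synthetic SUV
phantoms.

## The problem

Somatostatin-receptor PET shows meningiomas with very high lesion-to-
background contrast, which makes it attractive for radiotherapy and surgery
planning — but there is no standard rule for turning the SUV image into a
tumor volume. Candidate rules fall into three families:

1. **fixed SUV** — keep every VOI voxel with SUV ≥ T (e.g. T = 4.0);
2. **isocontour** — threshold at a percentage of the lesion's SUVmax
   (e.g. 45% SUVmax);
3. **reference tissue** — threshold at a multiple of a background tissue's
   SUVmean (e.g. 150% of bone-marrow SUVmean), or at the SUVmean "minus X%",
   i.e. (1 − X/100)·SUVmean (e.g. pituitary minus 70% → 0.30·SUVmean).

A fourth, inverse procedure — *backwards thresholding* — asks, per lesion,
which absolute SUV reproduces the reference volume, and summarizes the
dispersion of those per-lesion thresholds.

`petvol` implements the full benchmarking pipeline for these rules: a
synthetic phantom generator with known ground truth (the stand-in for a
manually contoured CT reference), exact voxel-center delineation geometry,
the threshold battery, the backwards inversion, and the agreement
statistics used to score each rule — Shapiro–Wilk-gated Pearson/Spearman
correlation, Bland–Altman bias ± 1.96·SD limits of agreement, and
coefficients of variation. It is aimed at researchers studying PET
segmentation thresholds who need a controlled test bed where the true
volume is known exactly.

## The model

Each phantom scene is an ellipsoidal lesion at a uniform plateau SUV on a
uniform 0.5-SUV background, plus 10 mm reference cubes for bone marrow,
parotid gland and pituitary gland with SUVmeans drawn independently and
uniformly from the observed clinical ranges (1.26 (0.67–1.89),
1.42 (0.63–2.09) and 9.64 (5.86–15.23) respectively). The scene is blurred
with a Gaussian point-spread function (default FWHM 5 mm), which produces
the partial-volume effects that make the threshold choice non-trivial:
small lesions lose apparent uptake at their edges, and low thresholds grow
a blur halo around large lesions. Lesion reference volumes are log-uniform
on 1.1–6.1 mL, the observed cohort range (19 lesions by default).

Delineation keeps VOI voxels with SUV ≥ threshold (voxel-center geometry,
volume by voxel counting, 1 voxel = spacing product). Backwards
thresholding searches the exact volume-vs-threshold step function over all
observed SUVs and returns the nearest attainable volume, ties toward the
larger threshold.

## Worked example

The numbered scripts under `analysis/` run the pipeline end to end on the
default seeded cohort. For example:

```bash
python analysis/03_backwards_thresholding.py
```

prints

```
Backwards thresholding over 19 lesions:
  matched threshold 5.74 +/- 1.49 SUV (CoV 25.9%)
  reapplied cohort-mean threshold: r = 0.887 (r^2 = 0.787, p = 4.1e-07, spearman), bias -0.07 mL
Wrote /root/pkg/results/backwards.csv
```

i.e. the per-lesion volume-matching thresholds scatter with a CoV of ~26%
across the cohort, and reapplying their mean as a single fixed rule still
correlates strongly (Spearman ρ = 0.89) with the true volumes. Similarly,
`analysis/04_agreement_statistics.py` evaluates all 47 threshold rules and
reports, per family, the rule with the highest correlation, its
Bland–Altman bias and limits of agreement, and the background-tissue
dispersion (CoV 18–26%) and mutual independence (max |r| = 0.32 at n = 19).
The subtractive reference rules (minus 40–80%) systematically overestimate
volume, and the overestimation grows with lesion size — the blur-halo
effect the Bland–Altman slope diagnostic is designed to catch.

Library use mirrors the scripts:

```python
from petvol import PhantomConfig, RunConfig, run_all, best_per_family

res = run_all(RunConfig(phantom=PhantomConfig(seed=1)), out_dir="results")
print(best_per_family(res.agreement))
```

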
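# synthecv

Fully automated, blood-draw-free **synthetic ECV** quantification from
paired native / post-contrast cardiac T1 maps, together with the complete
method-agreement statistics suite needed to validate such a pipeline — all
testable against a bundled digital phantom generator with known ground
truth.

The pipeline mirrors the automated workflow used in clinical research
systems:

1. **Segmentation** of the epicardial border, the endocardial border
   (cavity including papillary muscles) and the RV blood pool, via
   pluggable backends: a ground-truth *oracle* (for phantoms), a
   model-free *classical* intensity backend (hierarchical Otsu +
   connected components), and an optional trainable *learned* backend.
2. **Refinement**: myocardial ring = epicardium minus endocardium, shrunk
   by a 3×3 binary erosion to pull away from partial-volume borders;
   papillary muscles removed from the blood pool by Otsu's threshold over
   cavity voxels (blood is the high-T1 class on native maps, the low-T1
   class post-contrast), followed by the same 3×3 erosion.
3. **Quantification**: median T1 per measurement mask; synthetic
   hematocrit predicted from native blood-pool R1 via sex/field-stratified
   OLS models (calibrated from data or supplied as published
   coefficients); ECV = (1 − HCT) · ΔR1(myo) / ΔR1(blood); classification
   against configurable thresholds (default 30% and the adapted 29.5%).
4. **Agreement statistics**: Bland–Altman with CIs and strata, Pearson +
   paired t, McNemar (continuity-corrected χ² and exact), concordance
   tables, ICC(2,1)/ICC(2,k), Dice and Hausdorff.

## Digital phantom

`synthecv.phantom` generates 2D short-axis scenes (LV cavity, myocardial
ring, papillary muscles, RV crescent) with per-subject ground truth: HCT
and ECV drawn from truncated-normal priors, native blood T1 coupled to HCT
through a linear R1 model, and the post-contrast myocardial T1 derived by
inverting the ECV formula — so on noiseless phantoms the pipeline must
recover the true ECV exactly. Optional per-voxel Gaussian noise and a
one-voxel 50/50 partial-volume band provide realism. Everything is
reproducible from `(seed, subject index)`.

## CLI

```bash
# generate a phantom cohort (NIfTI maps + labels, cohort CSV, manifest)
synthecv generate --out-dir cohort/ --n-subjects 50 --seed 1

# segment one map
synthecv segment --native cohort/phantom_0000_native.nii.gz \
    --labels cohort/phantom_0000_labels.nii.gz --backend oracle \
    --out-prefix masks/phantom_0000

# quantify a cohort and produce the agreement report
synthecv quantify --cohort-dir cohort/ --out-dir out/ --backend classical

# everything in one go
synthecv run-all --out-dir out/ --n-subjects 50 --seed 1 --backend classical

# recompute a report from an existing results CSV
synthecv validate --results out/results.csv --out out/report.json
```

Units: files store HCT/ECV as fractions; reports render percent. All
numeric columns carry units in their names (`_ms`, `_fraction`).

## Layout

```
src/synthecv/
  phantom.py         # ground-truth cohort generator
  segmentation.py    # oracle + classical backends, mask invariants
  learned.py         # optional trainable backend (patch classifier)
  refinement.py      # 3x3 erosion, Otsu blood-pool separation
  quantification.py  # medians, synthetic HCT, ECV, classification
  agreement.py       # Bland-Altman, ICC, McNemar, Dice, Hausdorff, report
  pipeline.py        # cohort-level orchestration
  io.py              # NIfTI maps/masks, CSV cohort tables, JSON reports
  cli.py             # click-based CLI (synthecv ...)
```
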
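# radtrap

Radiomics-driven **t**argeted **ra**diotherapy **p**lanning for prostate
cancer: detect tumour voxels on multiparametric MRI, carry the detections
onto planning CT by deformable registration, and turn them into focal
radiotherapy plans that can be compared dosimetrically against conventional
whole-gland treatment.

The package is aimed at researchers in quantitative prostate imaging and
radiotherapy physics who want an executable, fully testable version of this
three-stage workflow. No patient data are required: a synthetic-phantom
module generates paired mpMRI/CT pelvis cases with known lesions, scanner
drift and a known prostate-local deformation, so every stage runs against
analytic ground truth.

## The method

1. **Detection.** T2w volumes are intensity-standardized by landmark
   piecewise-linear histogram mapping. Each peripheral-zone voxel
   <b>x</b><sub>i</sub> gets a 308-dimensional radiomic feature vector
   <b>f</b><sub>i</sub> (154 per sequence from T2w and ADC: intensity,
   first-order statistics, Sobel gradients, Haralick co-occurrence
   statistics, Gabor responses, Laws texture energy). Minimum-redundancy
   maximum-relevance (mRMR) selection keeps an 11-feature panel
   (greedy difference criterion: maximize I(f; l) − mean I(f; s) over
   selected s), a quadratic discriminant (per-class Gaussian) classifier is
   trained on labelled voxels, and its smoothed posterior map
   p<sub>i</sub> = P(malignant | <b>f</b><sub>i</sub>) is evaluated by
   ROC/AUC.
2. **Transference.** A rigid transform T<sub>r</sub> between the planning
   (large-FOV) MRI and CT is found by multi-resolution Powell ascent on
   normalized mutual information, NMI = (H(A)+H(B))/H(A,B); a B-spline
   deformation T<sub>d</sub> restricted to the prostate+rectum region
   follows, so only the gland deforms while bones stay aligned. Probability
   maps and masks move to CT through T<sub>d</sub>(T<sub>r</sub>(·));
   registration quality is scored with the Dice similarity coefficient
   2|A∩B|/(|A|+|B|).
3. **Planning.** Thresholding p<sub>i</sub> inside the capsule gives the
   GTV; margins give PTVs. Three plans are built and compared — whole-gland
   homogeneous (P<sup>WH</sup>, 145 Gy brachytherapy prescription), focal
   (P<sup>RF</sup>, GTV + 5 mm escalated to 150 %), and whole-gland with a
   focal boost (P<sup>WF</sup>, GTV + 2 mm) — with a TG-43-style point-source
   seed kernel on MRI and a coverage-field EBRT surrogate on CT
   (79.2 Gy / 85.8 Gy boost), reporting D90/V100/V150/V200/Dxcc-style DVH
   metrics per structure and plan-to-plan deltas.

## Worked example

Run the bundled phantom experiment (5 training / 3 held-out synthetic
cases) end to end:

```bash
radtrap run-all --seed 7 --out-dir runs/demo
```

which prints the per-case detection AUCs of the held-out cases:

```
  case      auc
test00 0.999583
test01 0.999515
test02 0.999704
```

and writes plain-text reports into `runs/demo/`: `auc_per_case.tsv` (the
table above), `selected_features.tsv` (the 11-feature mRMR panel),
`dice_per_case.tsv` with prostate Dice after each registration stage,

```
case    dice_rigid  dice_deformable
test00  0.941299    0.959197
test01  0.914293    0.953735
```

per-plan DVH tables (`brachy_P_WH_dvh.tsv`, …), seed tables, and the
P<sup>RF</sup>−P<sup>WH</sup> / P<sup>WF</sup>−P<sup>WH</sup> delta tables.
Reading them: every held-out case is detected essentially perfectly at
these study conditions (lesion contrast 0.4, 10 % noise); the deformable
stage recovers most of the 6 mm ground-truth prostate deformation that the
rigid stage cannot (Dice 0.91–0.94 → 0.95–0.96); and the focal plan covers
its target with far fewer seeds and much less bladder/urethra dose than the
whole-gland plan, while the focal boost changes organ-at-risk doses only
marginally.

The same stages are available as granular subcommands (`standardize`,
`extract`, `select`, `train`, `predict`, `evaluate`, `register-rigid`,
`register-deformable`, `transfer`, `eval-dice`, `make-targets`, `plan`,
`compare`, `make-phantoms`) operating on NIfTI volumes and text tables, and
as a Python API (`radtrap.pipeline.run_detect` / `run_transfer` /
`run_plan`).

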
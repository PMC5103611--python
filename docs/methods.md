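# Methods

`radtrap` implements a three-stage framework for focal prostate
radiotherapy planning driven by quantitative imaging: (1) voxel-wise cancer
detection on multiparametric MRI (T2-weighted + ADC) with radiomic texture
features and a quadratic discriminant classifier, (2) transference of the
predicted cancer probability map from MRI to planning CT by two-stage
(rigid + B-spline) registration maximizing normalized mutual information,
and (3) generation and dosimetric comparison of whole-gland, focal, and
focal-boost treatment plans for brachytherapy (on the MRI grid) and an
external-beam surrogate (on the CT grid). Because no patient data ship with
the package, every stage is exercised on synthetic pelvis phantoms with
analytic ground truth.

## Data model and geometry

Volumes are axis-aligned 3D scalar grids with per-axis spacing and an
origin in millimetres; voxel `(i, j, k)` sits at `origin + index * spacing`
with axis 0 = x (fastest varying on disk), axis 2 = the slice axis. NIfTI-1
is the on-disk format; oblique orientation matrices are rejected rather
than silently reoriented, because the phantoms (and the pipeline's
contracts) are axis-aligned. Structure sets are one binary label volume per
structure plus a plain-text manifest.

## Synthetic phantoms

The generator defines all anatomy analytically in a single subject frame:
a prostate ellipsoid (semi-axes 22 x 18 x 16 mm) whose posterior shell of
10 mm is the peripheral zone (PZ), a urethra, rectum (air lumen), bladder,
penile bulb, femoral heads, a pelvic fat compartment, and a body outline.
Because masks are evaluated analytically on any grid, a voxel is a lesion
voxel exactly when its centre lies in a generative lesion sphere — there is
no boundary ambiguity between masks and intensities.

Lesions are spheres (default two, radius 4 mm) placed by seeded rejection
sampling fully inside the PZ; infeasible placements (radius exceeding the
shell) raise an error after bounded retries. Lesions are hypo-intense on
both sequences: expected intensity `background * (1 - contrast)` with
contrast 0.4 by default against PZ backgrounds of 400 (T2w, arbitrary
units) and 1400 (ADC, 1e-6 mm^2/s). Acquisition noise is additive Gaussian
with standard deviation 10 % of the PZ background per sequence; CT noise is
Gaussian with a Poisson-like scaling in bright tissue. The PZ additionally
carries a smooth multiplicative-free texture field (Gaussian-filtered white
noise, 1.5 mm correlation length, amplitude 40) whose amplitude drops by 60 %
inside lesions; the correlation length is chosen at the scale of glandular
texture so that co-occurrence, texture-energy and Gabor families all see
the texture contrast, not just one of them. T2w scanner drift is an affine
`gain * I + offset` map (clipped at zero) applied per case.

The pelvic fat compartment (bright on T2w, -80 HU on CT) is load-bearing:
it gives the CT prostate a realistic boundary contrast. Without it the
gland would sit in uniform 30 HU soft tissue with ~15 HU of edge contrast —
*less* than a real pelvis — and an intensity-based deformable registration
has nearly no signal to work with.

The small-FOV diagnostic T2w (64x64x16 at 1x1x3 mm) and the large-FOV
planning T2w (96x96x20 at 1.5x1.5x3 mm) render the same subject on two
grids, making the "implicitly registered" relation between the two MRI FOVs
literal. The CT is rendered by evaluating the anatomy at ground-truth
transformed positions `psi(x) = T_r(x + d(x))` (resampling convention:
fixed/CT points map to moving/MRI points), where `T_r` is a rigid transform
(default 3 degrees + (4, 3, -2) mm) and `d` a sum of three Gaussian bumps
centred in the prostate, windowed by a cosine taper to vanish identically
beyond the prostate neighbourhood, rescaled to a 6 mm maximum and checked
for a positive Jacobian determinant. All randomness flows from the single
spec seed.

What the phantoms do *not* emulate: MR physics (bias fields, coil
profiles), brachytherapy seed artifacts on CT, transition-zone anatomy or
lesions, oblique acquisitions, and inter-patient anatomical variability
beyond the sampled lesion/deformation configurations. Passing phantom tests
therefore demonstrates internal correctness and the direction of the
method's contrasts, not clinical performance.

## Intensity standardization

T2w intensities are standardized by the landmark method: percentiles
{1, 10, 20, ..., 90, 99} of the prostate-region intensities are mapped
piecewise-linearly onto template landmarks learned as the cohort mean after
rescaling each scan's outer landmarks to a fixed standard range [0, 1000].
Beyond the outer landmarks the adjacent segment's slope extrapolates before
clamping. The mapping is monotone by construction, idempotent up to
quantization, and a single volume may serve as its own template. ADC maps
are quantitative and pass through unchanged. When no prostate mask is
available, an Otsu foreground stands in for the region.

## Radiomic feature bank

154 features per sequence (308 total), all computed in-plane per slice
because slice thickness (3 mm) is far coarser than in-plane resolution:

| family     | members                                                   | count |
|------------|-----------------------------------------------------------|-------|
| intensity  | standardized signal intensity                             | 1     |
| firstorder | mean / std / median / range, windows 3, 5, 7              | 12    |
| sobel      | gx, gy, magnitude, two diagonal 3x3 gradients             | 5     |
| haralick   | 13 co-occurrence statistics x windows {5, 7} x d {1, 2}   | 52    |
| gabor      | 6 orientations x 7 frequencies (0.06-0.45 cyc/voxel)      | 42    |
| laws       | 21 separable 5x5 kernels x energy windows {5, 7}          | 42    |

The composition is a declared reconstruction: only the totals and the
families are fixed externally, so the registry is data-driven and
auditable. The Laws set keeps all 20 ordered pairs of distinct vectors
(order matters: L5W5 and W5L5 are distinct, as the selected panel requires)
plus R5R5; the non-zero-sum L5L5 is excluded as redundant with the
first-order mean. Haralick matrices are built per voxel from the window's
own min-max range quantized to 16 levels (symmetric, accumulated over four
directions per offset distance, normalized to sum 1); this local-range
quantization makes the statistics invariant to affine intensity remapping.
Degenerate windows concentrate all mass in one cell (energy 1, entropy 0);
correlation is defined as 0 when a marginal is degenerate. Gabor kernels
have the even part mean-subtracted (zero DC) and an envelope capped at
sigma 3.5 voxels so kernels stay local on small fields of view.
Convolutions use reflective padding; window statistics truncate at slice
edges. The per-voxel co-occurrence loop is numba-compiled.

## Selection, classification, evaluation

Greedy mRMR (difference criterion) ranks features by mutual information
with the voxel label after equal-frequency 8-bin discretization, penalizing
the mean MI with the already-selected set; the default panel size is 11.
The classifier is a two-class Gaussian discriminant with class priors from
voxel frequencies and covariances shrunk toward their own diagonal
(`(1 - r) S + r diag(S)`, r = 1e-3 by default) because in-mask voxel
samples are heavily spatially correlated and raw covariances can be
ill-conditioned. No class balancing is applied, so the posterior scale
reflects lesion prevalence — relevant to the threshold that planning
consumes. Probability maps are smoothed with a mask-normalized Gaussian
(sigma 1.5 mm, physical units; out-of-mask voxels carry zero weight), and
evaluated by ROC/AUC with rank-average tie handling. Training and test
cohorts are split by case id, never by voxel.

## Registration and transference

Stage 1 is a 3D rigid registration (fixed CT, moving large-FOV MRI) by
multi-resolution (shrink 4/2/1) Powell ascent on normalized mutual
information, `NMI = (H(a) + H(b)) / H(a, b)` over a 32-bin joint histogram.
The optimizer's objective *is* the package's `nmi` function, initialization
aligns foreground intensity centroids, and the result is never returned if
it scores below the initialization. Stage 2 fits a cubic B-spline (control
spacing 15 mm) between the CT and the rigidly resampled MRI on a crop
around the prostate+rectum metric region, using SimpleITK's registration
machinery with Mattes mutual information as the optimizer's objective —
the library does not expose NMI to its optimizer — while acceptance of the
result is decided by the package's own NMI over the region: if the fitted
deformation does not increase it, the stage returns the identity. The
fitted transform is converted to a dense displacement field that is capped
at one control spacing (mutual information has no gradient in flat tissue,
where an unconstrained optimizer drifts), lightly smoothed, windowed to
vanish outside the dilated (5 mm) metric region — enforcing "only the
prostate deforms" by construction — and checked for a positive Jacobian,
with smoothing retries on folding. A 15 mm control spacing (rather than
10 mm) is used because finer grids overfit the featureless gland interior
on these phantoms (12-23 mm spurious displacements, folding) while 15 mm
recovers the 6 mm ground-truth deformations reliably.

Probability maps transfer to CT with linear interpolation (a convex
combination, so values stay in [0, 1]); masks with nearest neighbour. Dice
evaluation optionally restricts to slices where both masks are present.

## Dose engines and plans

The dose engines are deliberate simplifications — the comparisons between
plan types are the product, not clinical dose values. Brachytherapy uses a
TG-43-style point source: air-kerma strength 0.5 U, dose-rate constant
0.965 cGy/(h U), inverse square, a small built-in radial dose function
table representative of published I-125 seed data (linear interpolation,
anisotropy omitted), integrated over the full decay of a permanent implant
(1.44 x 59.4 d half-life); distances are capped below at half a voxel.
Seeds are placed greedily on a 5 mm template grid (needles = shared in-plane
positions), each step adding the candidate nearest the coldest target
voxel until the target D90 reaches the prescription (145 Gy) or a 250-seed
budget is exhausted. Whole-gland placement keeps seeds 2 mm off the
urethra; focal targets use a 4 mm urethral-sparing standoff and a 3 mm
urethral avoidance zone subtracted from escalated margins, mirroring the
clinical constraint that focal dose must not spill into the urethra.

Plan types: `P_WH` covers the prostate at 145 Gy; `P_RF` covers only the
focal PTV (GTV + 5 mm, cropped to the capsule, urethra excluded) at the
escalation level of 150 % (217.5 Gy); `P_WF` adds seeds to `P_WH` until
GTV + 2 mm reaches the escalation level. The EBRT surrogate paints
normalized coverage fields from 7 coplanar beams (a rasterized aperture of
the projected target with a 4 mm linear penumbra, averaged over beams) and
scales so the target D95 equals 79.2 Gy (whole gland) or 85.8 Gy (focal
boost).

DVH metrics are computed from the voxel dose multiset with voxel-volume
weighting: Dx is the minimum dose of the hottest x % (ceil-rank
convention), Vy the percent volume at or above y % of prescription, Dxcc
the minimum dose of the hottest x cm^3 (near-min/near-max via 0.03 cc);
structures smaller than a requested absolute volume are flagged and
reported over the full structure. The GTV is the thresholded probability
map (default 0.5, a clinical choice; a Youden-index suggestion can be
computed from phantom ROC but is never applied silently) inside the
capsule, with connected components below 0.05 cm^3 removed as speckle.

## Pipeline sizes and defaults

The bundled experiment trains on 5 phantoms and tests on 3 (disjoint
seeds, per-case scanner drift sampled from the case seed), registers and
transfers 2 test cases, and plans on the first test case; these sizes give
stable properties on a single CPU while keeping a full `run-all` to a few
minutes. All reports are plain-text tables; two runs with the same config
and seed are byte-identical.

## Known limitations

Dosimetry is schematic (no anisotropy, heterogeneity, beamlet
optimization, or protocol compliance auditing); DCE-MRI and transition-zone
analysis are out of scope; orientation handling is axis-aligned only; the
deformable stage's optimizer ascends Mattes MI rather than NMI itself (the
two share optima in practice here, and NMI gates acceptance); and the
urethra-D10 contrast between focal and whole-gland plans can genuinely
invert for lesions abutting the urethra if the urethral-sparing constraints
are relaxed.
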
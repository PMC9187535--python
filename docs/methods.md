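# Methods

`ctriage` implements a weakly supervised screening pipeline for head CT:
a voxel-wise Gaussian normative model of normal anatomy, confidence-interval
outlier detection, patient-level anomaly scoring, and two-threshold triage
into *normal / inconclusive / pathological*, together with the
screening-test statistics used to evaluate such a system. Because no
clinical scans ship with the package, a synthetic head-phantom generator
provides the cohorts on which everything is exercised end to end.

## The normative model

Let $x_v^{(i)}$ be the HU value of voxel $v$ in the $i$-th of $n$
co-registered normal training scans. The model treats voxels as
independent Gaussians and estimates, per voxel,

$$\hat\mu_v = \tfrac1n \sum_i x_v^{(i)}, \qquad
  \hat\sigma_v = \sqrt{\tfrac{1}{n-1}\sum_i (x_v^{(i)}-\hat\mu_v)^2},$$

with $\hat\sigma_v$ clamped from below by a floor $\sigma_{\min}$
(default 1 HU) so that degenerate training variance can never produce a
zero-width interval. The two-sided confidence bounds at level $c$
(default 0.90) are

$$L_v = \hat\mu_v - z\,\hat\sigma_v, \qquad U_v = \hat\mu_v + z\,\hat\sigma_v,
\qquad z = \Phi^{-1}\!\big(\tfrac{1+c}{2}\big) \approx 1.6449 .$$

A test-scan voxel inside the brain mask is an **outlier** iff its value is
strictly below $L_v$ or strictly above $U_v$; values exactly on a bound are
inliers (a fixed convention so results are exactly testable). The sign of
the deviation (hypodense vs hyperdense) is carried alongside the flag.

Assumptions worth stating: voxel independence (no spatial covariance model
— a region-level multivariate extension is an explicit extension point),
Gaussian marginals, and anatomical correspondence established by
registration. On held-out in-distribution data the expected raw outlier
fraction is slightly above $1-c$ because the plug-in bounds ignore
estimation error in $\hat\mu,\hat\sigma$ (with $n=40$ the expected rate is
$\approx 0.11$ rather than $0.10$); the package deliberately uses the
plug-in bounds, as a prediction-interval correction is a calibration
refinement the triage thresholds absorb anyway.

## From voxels to a patient score

1. **Cluster cleaning.** 26-connected components of the outlier flags are
   labelled *per polarity* and components smaller than
   `min_cluster_mm3` (default 200 mm³ ≈ a 3.6 mm-radius sphere) are
   removed. Per-polarity labelling matters: at $c=0.90$ the noise outlier
   rate (~11%) is *above* the 3D site-percolation threshold of
   26-connectivity (~9.7%), so pooling both polarities lets pure noise
   form one giant component that would survive any size filter; split by
   sign (~5.6% each) noise stays subcritical and the surviving noise
   fraction is ~0.1–0.3% of the brain. Physically a contiguous finding has
   one polarity anyway (an infarct is hypodense, a dense vessel
   hyperdense). The 200 mm³ floor keeps the smallest clinically targeted
   lesion class (lacunar defects, >15 mm diameter ⇒ ≳1700 mm³) far above
   the cutoff.
2. **Pooling.** With $f$ the cleaned outlier fraction of the brain mask,
   the anomaly score is the saturating ramp
   $s = \min(1, f / f_{\text{sat}})$, $f_{\text{sat}} = 0.05$: an anomaly
   occupying ≥5% of the brain saturates the score. This is the simplest
   monotone bounded statistic; it is isolated behind one function so a
   soft alternative (e.g. a sigmoid) is a drop-in replacement.

## Triage calibration

On a labelled validation set the two score cutoffs are set as

* $t_{\text{low}} = \min\{s_i : \text{truth}_i = \text{pathological}\}$ —
  no pathological validation case can be labelled normal (false omission
  rate 0);
* $t_{\text{high}} = \max\{s_i : \text{truth}_i = \text{normal}\}$ — no
  normal validation case gets a definite pathological label (the minimum
  achievable number of definite false positives, namely zero).

If the classes separate ($t_{\text{low}} > t_{\text{high}}$) both collapse
to their midpoint and the inconclusive band vanishes. Scores exactly equal
to a cutoff are rated inconclusive — ties never receive a definite label,
the conservative choice for a screening tool. An optional margin δ
(default 0) widens the band symmetrically for deployment conservatism.
Calibration is per cohort; multi-scanner threshold banks are out of scope.

## Evaluation statistics

Screening pooling treats inconclusive ratings as test-positive: diseased
inconclusive cases count as true positives (mode `as_published`), or only
when their lesion was actually overlapped by the anomaly mask (mode
`strict`, using the per-case `detected` flag); non-diseased inconclusive
cases are false positives. Sensitivity, specificity, PPV and NPV are
exact ratios with zero denominators reported as explicitly undefined.
ROC/AUC uses the trapezoidal rule over the empirical ROC (equivalent to
the Mann–Whitney statistic with midrank ties — enforced against an
enumeration oracle in the tests); the Youden index $J=\max(\text{sens} +
\text{spec} - 1)$ is maximized over observed scores with ties broken
toward the higher cutoff, and the AUC gets a seeded percentile-bootstrap
95% CI (default 2000 replicates). Proportions of definite ratings are
compared with a two-sided Fisher exact test.

## The phantom generator

Phantoms are stylized heads on a 64³ grid at 2 mm isotropic spacing:
an ellipsoidal skull shell (800 HU, ~4 mm thick) enclosing a cortical
grey rind (38 HU) over a white-matter core (25 HU) with paired lateral
ventricles (8 HU) off the midline, air (−1000 HU) outside, plus additive
independent Gaussian scanner noise (default σ = 3 HU). The paired
ventricles are both more anatomically faithful than a single central
cavity and necessary to make affine registration well-posed: a fully
concentric-ellipsoid head is nearly rotation-degenerate.

Four lesion classes are injectable with exact ground-truth masks, all
configurable, with defaults chosen once from typical imaging appearance:

| class | geometry | default size | ΔHU |
|---|---|---|---|
| chronic ischemia | cortical/subcortical cone sector (wedge) | 25 mm chord | −20 |
| subacute ischemia | smaller wedge | 20 mm chord | −10 |
| lacunar DWM infarct | deep sphere | 9 mm radius | −15 |
| hyperdense vessel sign | tube near the skull base | 40 mm × 3.5 mm radius | +40 |

The deltas make chronic obvious and subacute subtle (early ischemic
change is the hardest finding); the HVS tube's radius reflects
partial-volume spread of a proximal-artery thrombus on the coarse 2 mm
grid, and its density satisfies the clinical criterion of >1.2× the
contralateral attenuation. Lesion edges are feathered: the full ΔHU is
applied inside the mask and half of it on the 1-voxel ring outside.
A ±1 voxel boundary band aside, injection changes nothing outside the
returned mask.

What the phantoms do **not** model: partial-volume averaging beyond the
feather ring, beam hardening and streak artefacts, anatomical variability
between subjects (all phantoms share one geometry; only noise varies),
and inter-scanner intensity shifts. Consequently the synthetic study is a
*mechanism* test — it shows the atlas/score/triage machinery behaves as
designed under its own assumptions — not evidence about clinical
performance, where anatomy varies and registration residuals dominate.

## Registration

Input scans are aligned to the atlas template with a rigid stage followed
by a full 12-parameter affine stage, maximizing normalized
cross-correlation (robust to a global HU offset) with Powell's
gradient-free method. The schedule is: Gaussian-smoothed levels at
downsampling factors 4 and 2, a sparsely sampled native-resolution stage
(metric evaluated on a stride-2 grid against unsmoothed intensities), and
a short densely sampled full-resolution refinement; iteration caps are
fixed and sampling is deterministic, so registration is reproducible.
The pose is initialized by aligning grid centers; if the final NCC is
worse than the initial one the initial transform is returned, and results
below an NCC floor (default 0.5) are flagged low-confidence. On
noise-free phantoms, rigid perturbations up to ±10 mm / ±10° are recovered
to ~0.1–0.2 mm mean corner-landmark error in ~10 s per volume.

Deformable registration is deliberately omitted: phantoms share geometry,
and the normative model tolerates residual affine-scale misalignment. A
user with an externally computed dense deformation can resample volumes
before entering the pipeline.

Because cohort phantoms are generated directly in template space, the
pipeline's registration stage is off by default (`RunConfig.register`);
it exists for scans that arrive in their own frame.

## Problem sizes and numerical choices

The default synthetic study uses 40 training normals, a mixed validation
split of 10 normals + 10 lesioned phantoms, and a test split of 20
normals + 20 lesioned phantoms (5 per class) — small enough to run in
about a minute on one core while leaving the score distributions cleanly
measurable. Per-subject seeds derive deterministically from one master
seed (`numpy` SeedSequence spawning), so cohorts are byte-reproducible.
Geometry comparisons use a 1e-5 mm tolerance; voxel values are stored as
float64 throughout so atlas statistics are exact; masks resample
nearest-neighbour, intensities trilinear with out-of-field voxels set to
air (−1000 HU).

## Known limitations

* Per-voxel univariate Gaussians; no spatial covariance or regional
  multivariate structure.
* The score's noise floor means normal scans do not score 0 (by design the
  triage thresholds, not the score, absorb this); with a 90% CI the raw
  outlier rate is ~11%, and the cleaned noise floor depends on the
  connectivity/size-filter choices described above.
* Single-cohort calibration: the empirical min/max rule is sensitive to
  validation outliers and provides no guarantee beyond exchangeability
  with the test distribution.
* The phantom cohort shares one anatomy; the system's robustness to true
  anatomical variability is untested by construction.
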
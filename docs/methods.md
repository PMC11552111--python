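# Methods

## Scope and model

The package implements quantitative stand-ins for two visual PET response
scales — the intracranial metabolic score (IMS), which grades residual lesion
uptake against CSF, white matter and gray matter, and the Deauville score
(DS), which grades it against the mediastinal blood pool and liver — together
with the statistics used to evaluate them as prognostic markers
(Kaplan–Meier, log-rank, Cox proportional hazards, contingency-derived
diagnostic metrics, ROC/AUC, Cohen's kappa, chi-square cohort comparison).
Because no patient-level data exist publicly for this setting, the package
also contains the synthetic-data machinery that makes every stage testable:
a covariate/outcome simulator and a digital PET phantom.

## Scoring conventions

The scale definitions use strict inequalities ("greater than gray matter"),
so boundary ties resolve to the lower level.  Two visual judgements have no
printed numeric width and are therefore declared conventions here, both
configurable:

* **IMS 3, "similar to white matter"** — a symmetric relative band of
  ±10 % around the white-matter SUVmax (`ims3_band`, default 0.10, must be
  < 0.5).  Levels then partition the nonnegative axis as
  1: ≤ CSF · 2: (CSF, 0.9 WM) · 3: [0.9 WM, 1.1 WM] · 4: (1.1 WM, GM] ·
  5: > GM, provided CSF < 0.9 WM; a panel violating that ordering is
  rejected rather than silently mis-banded.
* **Patient-level score = hottest lesion** — any single lesion above a
  reference drives visual positivity; multi-lesion reading rules are not
  otherwise specified in the clinical literature for these scales.

A new lesion forces level 5 on both scales regardless of uptake.  DS is
reported only when the panel contains liver and mediastinum; head-only
PET/MR panels raise a "score inapplicable" error instead of guessing.

## SUV quantification

SUV = activity (mCi/mL) × body weight (g) / injected dose (mCi); units are
fixed at mCi/g internally and converted at the I/O boundary.  Reference ROIs
are placed automatically at the deepest interior point of each structure
(argmax of the Euclidean distance transform in mm; ties break to the lowest
linear voxel index), a deterministic surrogate for manual placement:

* gray matter, white matter, CSF (lateral ventricle): 1 cm spheres — the
  protocol floor — with gray/white matter restricted to the hemisphere
  contralateral to the uptake-weighted lesion centroid;
* liver: a 3 cm sphere; mediastinum: a 1.5 cm axis-aligned cylinder over
  contiguous slices of the descending aorta after one-voxel erosion of the
  vessel mask (wall exclusion).

A deliberate design choice: gray/white/CSF ROIs use the fixed 1 cm protocol
size rather than the largest inscribed sphere.  A maximal ROI touches its
structure's boundary by construction, and under PSF blur its SUVmax is then
dominated by spill-in from any hotter neighbour (white matter abutting gray
matter, ventricle abutting white matter) — exactly what human readers avoid.
With 1 cm ROIs at the deepest point, quantified SUVmax stays within a few
percent of the generating target at default noise (see below); with noise
and PSF disabled the round trip is exact to float32 precision.

## The digital phantom

Analytic shapes on an isotropic grid (default 2 mm voxels, 128³ head;
PET/CT mode prepends an 80-slice torso slab): a spherical gray-matter shell
(outer radius 80 mm) around a white-matter core (60 mm), two ellipsoidal
lateral ventricles (semi-axes 10 × 30 × 14 mm), a liver ellipsoid
(45 × 35 × 30 mm) and a 12 mm-radius aorta cylinder in the torso, and up to
four 7 mm-radius lesions at fixed left-hemisphere white-matter sites.  A
coarse 3 mm / 64³ variant is provided for fast tests and demos; all anatomy
is defined in millimetres so the two presets agree.

Per-structure target SUVmax values are drawn from normals truncated at
SUV 0.1, with means/SDs defaulting to published reference-structure
statistics (GM 9.45 ± 2.01, liver 2.96 ± 0.42, WM 2.81 ± 0.58, mediastinum
1.80 ± 0.36, CSF 1.50 ± 0.34).  The truncation point lies > 4 SD below every
default mean, so calibration bias is negligible.  Panel draws are
independent and rejection-free, so empirical means/SDs converge to the
configuration; only when a drawn panel cannot host a patient's lesion band
(e.g. CSF reaching the white-matter band, ~5 % of draws at default
calibration) is it redrawn inside the phantom builder.

Voxel activity is set to SUV × dose/weight — the exact inverse of the SUV
formula — with lesion uptake drawn from the central 70 % of the band implied
by the patient's true IMS (hotter lesion carries the band value; additional
lesions sit below it), so simulated visual scores stay stable under noise.
Multiplicative Gaussian noise (CV 0.05) is applied to the activity and then
smoothed with an isotropic Gaussian PSF (FWHM 5 mm, a typical reconstructed
resolution): reconstruction smooths noisy data, and this ordering is also
what keeps ROI SUVmax within a few percent of target — the maximum of
unsmoothed multiplicative noise over an ROI would bias SUVmax upward by
several times the CV.

What the phantom does **not** emulate: real anatomy, scanner physics
(attenuation, scatter, OSEM/TOF/PSF reconstruction), partial-volume
heterogeneity within structures, lesion segmentation uncertainty, or
count-rate-dependent noise.  Passing tests therefore demonstrate the
correctness of the quantification/scoring logic and the statistical
machinery, not clinical performance on real scans.

## Cohort and outcome model

Covariates are drawn from configurable marginal prevalences chosen to
resemble a mixed PCNSL cohort (median age near 60, slight male excess,
about half ECOG 2–3, one-third each superficial/deep/both lesion sites).
The IELSG score counts five risk factors (age > 60, ECOG > 1, elevated LDH,
elevated CSF protein, deep lesion; group "0–1" vs "2–3", with the rare 4–5
folded into the high group); the MSKCC score uses the standard three-class
recursive partitioning (0: age ≤ 50; 1: age > 50 & KPS ≥ 70; 2: age > 50 &
KPS < 70) — the only mapping consistent with three reported classes.

True IMS levels default to the empirical distributions of the reference
cohorts (8/9/11/5/5 of 38 for PET/CT; 10/9/12/9/5 of 45 for PET/MR).
Survival is exponential proportional hazards: progression hazard
λ₀·exp(β₁·1[IMS ≥ 4] + β₂·1[IMS = 5]) with λ₀ = ln 2/900 d⁻¹ (median PFS
≈ 30 months in good responders), β₁ = log 9.04 and β₂ = log(9.50/9.04)
matching the reported group contrasts; censoring is the minimum of an
independent exponential dropout (rate 1/2500 d⁻¹) and an administrative
horizon (2000 d).  Overall survival is constructed as PFS plus an
exponential post-progression interval (median 240 d) for progressors,
observed only before the shared censoring time — which enforces
OS ≥ PFS by construction, where independent draws would not.  The censoring
and accrual pattern of the real studies is unknown; these defaults are
explicit and configurable.

Randomness: one master seed; per-patient substreams derived by SHA-256
hashing of the patient id into a `SeedSequence` spawn key, so enlarging a
cohort never reshuffles existing patients and runs are bit-reproducible.

## Statistical engines

Kaplan–Meier, the k-sample log-rank test and the chi-square test are wrapped
from lifelines/scipy behind the package's validation contracts (the median
is the smallest t with S(t) ≤ 0.5, undefined when the curve stays above ½;
chi-square is uncorrected Pearson by default, which is what standard
packages print for cohort comparisons — Yates' correction is a flag).  The
Cox solver is authored in-package: Newton iteration with step-halving on the
partial likelihood, Breslow (default) or Efron ties, convergence when the
log-likelihood changes by < 1e-9 (max 100 iterations), Wald CIs and
p-values.  Monotone likelihood (complete separation, e.g. all events in one
arm) is detected as a coefficient exceeding |log HR| = 15 and flagged
`converged=False` with a diagnostic, so report tables can print "not
available" instead of a meaningless number.  The test suite cross-checks
the solver against brute-force grid maximisation of the partial likelihood
and against lifelines' independent implementation.

Diagnostic metrics come from integer 2×2 tables; zero-denominator metrics
are reported as undefined, never 0.  The AUC of a dichotomised score is the
two-point trapezoid (sensitivity + specificity)/2; the ordinal (5-level)
AUC is the tie-corrected rank statistic with a Hanley–McNeil interval.
Published diagnostic columns are validated by reconstruction: cohort size,
event count, positive count and one printed metric determine the unique
integer table (anchor reproduced to ≤ 0.05 percentage points), from which
all remaining cells are recomputed.  One published cell (the PET/MR IMS-5
OS column's NPV) is internally inconsistent with its own column and is
documented as such in the test suite rather than matched.

## Problem sizes and numerical choices

Simulation-based validation uses: 200 replicates of n = 2000 for Cox
parameter recovery (mean log-HR within 3 Monte-Carlo SEs of log 9.04; Wald
coverage 95 % ± 3 %), 1000 replicates for null log-rank calibration
(rejection 5 % ± 2 %), 1000 draws for generator calibration (means and SDs
within 3 SEs), and the coarse 3 mm phantom for image-level tests, with the
zero-noise round trip exact by construction.  Score labels use ASCII
hyphens ("4-5") in all outputs for CSV/JSON friendliness.

## Known limitations

* The phantom's schematic geometry cannot probe registration, segmentation
  or partial-volume correction; lesion masks are inputs by design.
* Inter-reader disagreement is modelled as a symmetric ±1-level perturbation
  with a configurable keep probability — a calibration device for kappa
  computations, not a model of why readers disagree.
* Published multivariate hazard ratios cannot be reproduced without
  patient-level data; the Cox stage is validated by parameter recovery on
  synthetic cohorts instead.
* The DS "moderately vs markedly above liver" boundary is implemented purely
  as the 2 × liver rule; no additional visual nuance is modelled.
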
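# Methods

`dosescreen` implements a hybrid patient-specific QA (PSQA) screening
workflow for stereotactic radiotherapy plans: an independent ("secondary")
3D dose calculation is compared against the treatment-planning-system (TPS)
calculation through a fixed set of dosimetric criteria, per-criterion action
limits are derived from a commissioning cohort, and any plan — or, for
multi-lesion radiosurgery, any individual lesion — whose disagreement
exceeds a limit is flagged for measurement-based QA.  This note records the
models, conventions and numerical choices behind each stage.

## Data model and conventions

Dose grids are regular 3D arrays in `(x, y, z)` order in the patient frame,
with physical positions in millimetres and absorbed dose in Gy.  The grid
origin is the **centre** of voxel `(0, 0, 0)` and dose values are point
samples at voxel centres; all interpolation is trilinear on those samples.
Two geometries compare equal within 10⁻⁶ mm.  Comparison operations require
matched geometry; `resample` is provided as an explicit pre-step (trilinear,
zero-filled outside the source extent, with an outside-point count returned
on request) and nothing resamples silently.

Structure-set contours are rasterized slice by slice with the
voxel-centre-inside-polygon rule (even-odd); several contours on one plane
combine by exclusive-or, so holes behave as drawn.  A contour more than half
a slice spacing from every grid plane is rasterized to the nearest plane
with a logged warning.  Mask volume is the true-voxel count times the voxel
volume, so rasterized volumes converge to the analytic contour volume as
spacing shrinks (verified in the tests at two spacings).

## Dosimetric criteria

Per site, the screening criteria are:

* **Lung SBRT** — isocentre point dose, PTV maximum and mean dose, PTV D90
  and D95, and a plan-level 3D gamma inside the external contour (40%
  low-dose threshold).
* **Multi-lesion SRS (MLSRS)** — per-lesion PTV-centroid point dose, PTV
  max/mean/D90/D95, and one plan-level 3D gamma (10% threshold).

Dose criteria are compared as the signed percentage difference
`100 × (secondary − TPS) / TPS`; negative means the secondary calculation is
colder than the TPS.  The TPS value is the denominator because it is the
quantity being verified.  The target centroid is the unweighted mean of the
PTV mask's voxel-centre coordinates.

`Dxx` (dose to the hottest xx% of the volume) uses whole-voxel counting on
the sorted in-mask doses.  By default the dose is linearly interpolated on
the coverage grid `k/n` of the descending order statistics; an
`interpolate=False` variant returns the largest observed dose with coverage
at least `xx`%.  Both agree wherever `xx·n/100` is an integer; no
partial-volume weighting is attempted because voxel counting is the simplest
auditable rule.

## 3D gamma analysis

For each reference voxel `r` above the dose threshold,

    γ(r) = min_p sqrt( (ΔD(r,p) / (p_dose·N))² + (‖r−p‖ / p_dta)² ),

with candidates `p` on a dense cubic lattice (default step `dta/10`) inside
a search sphere (default radius `3·dta`), the evaluated dose trilinearly
interpolated at each candidate, and `N` the global normalization dose — the
maximum reference dose inside the analysis mask, unless an explicit
normalization dose (e.g. a prescription) is supplied.  Local normalization
replaces `N` by the local reference dose.  The default criteria are 3%/1 mm,
global, as is standard for stereotactic QA.

Conventions chosen where practice varies:

* The low-dose threshold applies to the **reference** dose as a percentage
  of the **global** normalization value, and sub-threshold voxels are
  excluded from the pass-rate denominator.  They carry a NaN sentinel in the
  gamma map — never a silent pass.  If no voxel clears the threshold the
  pass rate is explicitly undefined (`None`), never 100%.
* The analysis mask defaults to the external contour; any mask can be
  passed.
* Candidate points outside the evaluated grid's extent are skipped rather
  than extrapolated.

The production search (`gamma_map`) visits candidates in order of
increasing distance and retires a reference point once its running minimum
γ² is no larger than the squared distance term of the nearest unprocessed
candidate; this bound is exact, so the result is identical to the
exhaustive search.  A separate brute-force oracle (`gamma_bruteforce`)
evaluates every lattice candidate with no shortcuts and is size-guarded to
20³ voxels; the test suite drives both over mixed-perturbation cases and
requires identical pass counts and γ agreement to 10⁻⁶.  Because both
routes share one lattice definition, agreement is a check of the search
logic, not of interpolation round-off.

`threshold_sweep` exploits the fact that γ values do not depend on the
threshold (it only selects which points are evaluated): the search runs once
at the lowest requested threshold and pass rates are re-counted per
threshold over the corresponding reference subsets.  On a case that is cold
in the high-dose core and matched elsewhere, the 40% threshold yields a
strictly lower pass rate than 10% — the mechanism that makes the higher
threshold the more sensitive screening choice.

## Action limits (TG-119 confidence limits)

For each criterion the cohort mean and standard deviation (n−1 denominator)
of the percentage differences give the 95% confidence limit

    CL = |mean| + 1.96 × SD.

The absolute value on the mean makes the CL a symmetric band on |%Δ| even
for cohorts with a systematic offset; screening is two-sided on |%Δ|.  The
gamma criterion is handled on the **failure-rate** scale (100 − pass rate)
and its limit re-expressed as a minimum acceptable pass rate.  Dose limits
round to the nearest integer percent and gamma limits to one decimal, ties
away from zero — matching how such limits are quoted in practice.  A
difference exactly at the limit passes (the limit itself is acceptable).
An optional uniform simplification replaces every dose-criterion limit with
a single value (e.g. 3% or 5%), recorded as "simplified", while the gamma
limit stays as derived.

Per-lesion criteria are pooled over all lesions of all plans when deriving
limits (each lesion is one sample); the plan-level gamma is one sample per
plan, and the per-criterion sample size is recorded in the limits table.
Screening uses the rounded limit, since that is what is quoted as the
action limit.  By construction, limits derived from a zero-mean Normal
cohort flag ≈5% of an i.i.d. replicate cohort; the tests verify this by
simulation.

Pearson correlation between two verification sources (e.g. the secondary
calculation and a log-reconstructed delivery) is computed per criterion
over pairs matched on case, criterion and lesion, with gamma correlated on
the pass rate; zero-variance criteria are reported as undefined rather than
dropped silently.

## Synthetic cases and perturbations

The generator produces the two cohort archetypes with analytic dose fields:
a radial logistic fall-off per target,
`D(r) = bg + Σ_t A_t / (1 + exp((r_t − R50_t)/w))`, with penumbra width `w`
(default 3 mm lung, 1.5 mm MLSRS), half-dose radius placed so the PTV
surface receives exactly the prescription, and the prescription sitting on
the 76% isodose of the in-target plateau (typical of stereotactic plans, so
the PTV interior is at or above prescription by construction and D95 ≥ Rx
exactly for the radial field).  Lung cases carry one target (ITV + 5 mm PTV
margin, 50 Gy PTV / 60 Gy ITV on a 1.25 mm grid); MLSRS cases carry several
disjoint spherical targets (GTV + 1 mm margin, 18–22 Gy, 1 mm grid) placed
by rejection sampling inside the body sphere.  Everything is deterministic
given the seed, with named substreams per purpose so adding a perturbation
type does not reorder existing draws.

Perturbations compose in a fixed order — rigid shift (trilinear), penumbra
widening (Gaussian blur), global scaling, a signed multiplicative error in a
shell straddling each PTV surface, voxel-wise Gaussian noise, then a clip at
zero.  The shell term is a mechanistic stand-in for the
interface-concentrated disagreement seen between dose algorithms near
heterogeneities; it moves coverage metrics (D90/D95) more than the PTV mean,
which is the qualitative signature of the poorer-agreeing algorithms.  A
pure global scale of k% propagates into every dose criterion as exactly k%
(verified to 10⁻⁶), which makes parameter recovery a sharp test rather than
a statistical one.

Two cohort generators exist deliberately:

* `make_cohort` draws a `Perturbation` per case from a `PerturbationModel`
  (fixed values or Normal parameters per field) and produces full grid-level
  cases.  A single physical perturbation moves all dose criteria together,
  so it cannot give each criterion an independent marginal distribution.
* `sample_cohort_comparisons` draws each criterion's %Δ directly from an
  independent Normal with a preset's per-criterion (mean, SD) — the three
  presets carry the disagreement statistics of an AAA-planned lung cohort, an
  Acuros-XB-planned lung cohort, and a pencil-beam MLSRS cohort.  This
  statistical surrogate is what validates the confidence-limit machinery at
  large n: a 2000-case cohort recovers |μ| + 1.96σ within sampling error
  (±1 percentage point) for every criterion.  Gamma pass rates are sampled
  unclipped so the sample moments are unbiased; a physical pass rate cannot
  exceed 100%, so these draws are statistics, not plans.

What the synthetic data does *not* emulate: beam geometry and fluence,
tissue heterogeneity, MLC/delivery effects, and the skewed, bounded shapes
of real disagreement histograms.  Passing tests therefore demonstrate that
the metrics, gamma search and limit arithmetic are correct and that the
pipeline recovers known injected disagreements — not that any particular
clinical algorithm pair will reproduce a given cohort's statistics.

## Problem sizes and numerical choices

Unit and property tests run on coarse small-body cases (2 mm spacing,
~30³ grids) where every operation is cheap but nothing is degenerate;
oracle-equivalence batches use 10³-voxel grids with a 0.25 mm candidate
step and 2 mm search radius, which keeps the exhaustive oracle exact on the
shared lattice while bounding its cost.  Cohort-level recovery uses
n = 2000 statistical draws.  Geometry equality uses a 10⁻⁶ mm tolerance;
gamma equivalence demands 10⁻⁶ on γ and exact pass-count equality;
fixture round trips are bit-exact (checked by SHA-256 of the array payload).

## Known limitations

* The DICOM reader assumes axis-aligned orientation (identity
  ImageOrientationPatient) and uniform frame offsets; oblique dose grids are
  out of scope.
* Point-dose criteria interpolate a single point; volume averaging of a
  detector is not modelled.
* The gamma search lattice is a convention (step `dta/10`); γ values from
  other software using different interpolation conventions can differ in the
  third decimal even when both are internally consistent.
* Clinical flagged counts and cross-source correlation coefficients depend
  on patient data and specific algorithm pairs; the package reproduces the
  mechanisms, not those numbers.
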
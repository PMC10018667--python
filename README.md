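# dosescreen

Hybrid patient-specific QA (PSQA) screening for stereotactic radiotherapy
plans.

Measurement-based PSQA of every lung SBRT or multi-lesion SRS plan is
labour-intensive, and for single-isocentre multi-lesion SRS it is often not
even practical to measure every target.  `dosescreen` implements the
computational screening stage of a hybrid workflow: an independent
("secondary") 3D dose calculation is compared against the
treatment-planning-system (TPS) calculation through a fixed set of
dosimetric criteria, per-criterion action limits are derived from a
commissioning cohort, and only the plans — or individual lesions — whose
disagreement exceeds a limit are sent on to phantom measurement.

The screening criteria are the isocentre (lung) or per-lesion PTV-centroid
(SRS) point dose, PTV maximum and mean dose, PTV D90 and D95 — each as a
signed percentage difference `100·(D_sec − D_TPS)/D_TPS` — plus a plan-level
3D gamma pass rate (3%/1 mm, global normalization) inside the external
contour, with a 40% low-dose threshold for lung SBRT and 10% for multi-lesion
SRS.  Action limits follow the TG-119 confidence-limit formalism

```
CL = |mean| + 1.96 × SD
```

over the cohort's per-criterion differences, with the gamma criterion
handled on the failure-rate scale (100 − pass rate) and reported as a
minimum acceptable pass rate.  A plan is flagged when any criterion exceeds
its limit; a value exactly at the limit passes.

The package provides:

* `grids` / `dicom_io` / `fixtures` — dose-grid and structure data model,
  DICOM RT Dose + RT Structure Set readers (contours rasterized by the
  voxel-centre rule), trilinear resampling, and a lossless text+array
  fixture container;
* `metrics` — point-dose and DVH criteria and case comparison;
* `gamma` — 3D gamma with a distance-ordered search whose early
  termination is exact, a brute-force lattice oracle for verification, and
  threshold sweeps;
* `screening` — confidence limits, action-limit tables, screening
  decisions, cross-source Pearson correlation;
* `synthetic` / `presets` — seeded synthetic lung-SBRT and multi-lesion-SRS
  cases with analytic dose fields, controlled ground-truth perturbations,
  and cohort presets carrying published disagreement statistics;
* a thin `dosescreen` CLI (`simulate`, `compare`, `derive-limits`,
  `screen`, `correlate`).

See `docs/methods.md` for the model details and conventions, and
`examples/` for runnable walk-throughs.

## Worked example

Derive a cohort's action limits and screen a deliberately cold lesion
(`examples/04_screen_cohort.py`, abbreviated):

```python
from dosescreen import (PerturbationModel, Site, SyntheticSpec, compare_case,
                        derive_action_limits, make_cohort, screen_case)

spec = SyntheticSpec(site=Site.MLSRS, seed=0, spacing_mm=1.5, body_radius_mm=32.0,
                     n_targets=3, target_radius_mm=(4.0, 5.0, 3.0),
                     prescription_gy=(20.0, 18.0, 22.0))
model = PerturbationModel(global_scale_pct=(-1.0, 1.5), noise_sd_pct=0.2)
cohort = make_cohort(spec, 12, model, seed=99)
limits = derive_action_limits([compare_case(c) for c in cohort], site="MLSRS")
```

prints limits derived from the cohort's own 95% confidence bands,

```
  CENTROID_DOSE   mean  -0.12  SD  1.57  limit 3%
  PTV_MEAN        mean  -0.13  SD  1.56  limit 3%
  PTV_D95         mean  -0.14  SD  1.54  limit 3%
  GAMMA_3D        mean  +0.15  SD  0.51  limit 1.2% fail
```

and screening a new plan whose third lesion is ~9% cold flags exactly that
lesion while clearing the other two:

```
case mlsrs-0: FLAGGED for measurement
  PASS PTV_D95[1]: -0.50% vs +/-3%
  PASS PTV_D95[2]: -0.50% vs +/-3%
  FAIL PTV_D95[3]: -9.46% vs +/-3%
  FAIL GAMMA_3D: pass rate 98.4% vs minimum 98.8%
  targets to measure: 3
```

The mean/SD columns are the cohort's per-criterion disagreement statistics
in percent; `limit` is the rounded `|mean| + 1.96·SD` band, and the gamma
limit is quoted as a maximum failure rate (equivalently a minimum pass
rate).

The same pipeline runs from the shell:

```
dosescreen simulate --preset AXB_LUNG_LIKE --n 22 --seed 7 --out cases/
dosescreen compare --cases cases/ --out results.csv
dosescreen derive-limits --results results.csv --out limits.json
dosescreen screen --results results.csv --limits limits.json
```

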
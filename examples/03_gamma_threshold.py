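"""3D gamma analysis and the effect of the low-dose threshold.

The secondary dose is made 6% cold inside the PTV and left matched
elsewhere.  With a 10% threshold the many agreeing low-dose points dilute
the failures; a 40% threshold restricts the analysis to the high-dose
region, where the disagreement lives, and the pass rate drops — the reason
a 40% threshold is the stricter screening choice for lung SBRT.
"""

import numpy as np

from dosescreen import (
    DoseGrid,
    GammaCriteria,
    Role,
    Site,
    SyntheticSpec,
    gamma_map,
    make_case,
    threshold_sweep,
)

case = make_case(SyntheticSpec(site=Site.LUNG_SBRT, seed=3, spacing_mm=2.0,
                               body_radius_mm=28.0, target_radius_mm=(7.0,)))
ptv = case.mask(Role.PTV, target_id=1)
external = case.mask(Role.EXTERNAL)

cold = case.tps_dose.values.copy()
cold[ptv.voxels] *= 0.94  # 6% cold core
evaluated = DoseGrid(case.tps_dose.geometry, cold, label="secondary")

criteria = GammaCriteria(dose_pct=3, dta_mm=1, normalization="GLOBAL", threshold_pct=10)
result = gamma_map(case.tps_dose, evaluated, external, criteria)
print(f"gamma 3%/1 mm global, 10% threshold: pass rate {result.pass_rate:.1f}% "
      f"over {result.n_evaluated} points "
      f"(normalization {result.normalization_value:.1f} Gy)")
print(f"worst gamma: {np.nanmax(result.gamma):.2f}")

print("\nthreshold sweep:")
for t, rate, n in threshold_sweep(case.tps_dose, evaluated, external, criteria,
                                  [5, 10, 20, 40, 60]):
    print(f"  threshold {t:4.0f}%  pass rate {rate:6.2f}%  ({n} points)")

print("""
The same gamma map, re-counted over shrinking high-dose subsets: the pass
rate falls as the threshold rises because the failing points are
concentrated in the (cold) target.""")
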
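"""Derive TG-119 confidence-limit action limits from cohort statistics.

Feeds the per-criterion disagreement moments of the three bundled cohort
presets through CL = |mean| + 1.96 x SD.  Dose criteria round to the nearest
integer percent; the 3D gamma criterion is computed on the failure-rate
scale (100 - pass rate) and re-expressed as a minimum acceptable pass rate.
"""

from dosescreen import PRESETS, Rounding, Scale, confidence_limit_from_moments

for name, preset in PRESETS.items():
    print(f"\n{name} ({preset.n_plans} plans, site {preset.site.value})")
    for crit, (mean, sd) in preset.dose_stats.items():
        al = confidence_limit_from_moments(mean, sd, Rounding.INT)
        print(f"  {crit.value:15s} mean {mean:+6.2f}%  SD {sd:5.2f}%  "
              f"-> CL {al.cl_raw:6.2f}%  action limit {al.limit:.0f}%")
    mean_pass, sd = preset.gamma_stats
    al = confidence_limit_from_moments(100 - mean_pass, sd, Rounding.ONE_DECIMAL,
                                       scale=Scale.GAMMA_FAIL)
    print(f"  {'GAMMA_3D':15s} mean pass {mean_pass:5.1f}%  SD {sd:5.2f}%  "
          f"-> CL {al.limit:.1f}% fail, i.e. minimum pass rate {al.min_pass_rate:.1f}%")

print("""
Each action limit is the band expected to contain ~95% of future
secondary-vs-TPS differences for that cohort; a plan outside any band is
flagged for measurement-based QA.""")
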
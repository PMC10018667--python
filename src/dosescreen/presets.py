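"""Cohort disagreement presets and the statistical cohort sampler.

Each preset records, per criterion, the mean and SD of the secondary-vs-TPS
percentage difference observed in a published screening cohort (and the mean
and SD of the plan-level 3D gamma pass rate).  Three presets are provided:

* ``AAA_LUNG_LIKE``   — lung SBRT planned with AAA (22 plans): large, cold
  target-coverage disagreement (convolution/superposition secondary vs AAA).
* ``AXB_LUNG_LIKE``   — lung SBRT planned with Acuros XB (22 plans): tight
  agreement.
* ``MLSRS_LIKE``      — single-isocentre multi-lesion SRS planned with a
  pencil-beam engine (30 plans, 82 targets): intermediate agreement.

:func:`sample_cohort_comparisons` draws per-criterion differences from
independent Normals with those parameters.  It is a *statistical* surrogate:
it reproduces cohort-level moments (and therefore the derived action limits)
without simulating dose grids, which is exactly what is needed to validate
the confidence-limit machinery at large n.  Gamma pass rates are sampled
unclipped so the sample moments are unbiased estimates of the preset
parameters; a physical pass rate cannot exceed 100%, so treat the sampled
cohorts as statistics, not as plans.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import CohortError, ConfigurationError
from .grids import Site
from .metrics import PER_TARGET_CRITERIA, Criterion, CriterionId, MetricComparison

__all__ = ["CohortPreset", "PRESETS", "sample_cohort_comparisons"]


@dataclass(frozen=True)
class CohortPreset:
    """Per-criterion (mean, SD) of %Δ plus gamma pass-rate statistics."""

    name: str
    site: Site
    n_plans: int
    dose_stats: dict[Criterion, tuple[float, float]]  # % difference (mean, sd)
    gamma_stats: tuple[float, float]  # pass rate (mean, sd), %
    gamma_threshold_pct: float


PRESETS: dict[str, CohortPreset] = {
    "AAA_LUNG_LIKE": CohortPreset(
        name="AAA_LUNG_LIKE",
        site=Site.LUNG_SBRT,
        n_plans=22,
        dose_stats={
            Criterion.ISOCENTRE_DOSE: (0.16, 1.38),
            Criterion.PTV_MAX: (0.49, 1.42),
            Criterion.PTV_MEAN: (-2.67, 2.68),
            Criterion.PTV_D90: (-4.77, 4.6),
            Criterion.PTV_D95: (-5.55, 5.31),
        },
        gamma_stats=(91.3, 10.1),
        gamma_threshold_pct=40.0,
    ),
    "AXB_LUNG_LIKE": CohortPreset(
        name="AXB_LUNG_LIKE",
        site=Site.LUNG_SBRT,
        n_plans=22,
        dose_stats={
            Criterion.ISOCENTRE_DOSE: (0.72, 1.48),
            Criterion.PTV_MAX: (-0.09, 0.97),
            Criterion.PTV_MEAN: (-1.00, 1.03),
            Criterion.PTV_D90: (-1.61, 1.39),
            Criterion.PTV_D95: (-1.9, 1.53),
        },
        gamma_stats=(99.3, 1.09),
        gamma_threshold_pct=40.0,
    ),
    "MLSRS_LIKE": CohortPreset(
        name="MLSRS_LIKE",
        site=Site.MLSRS,
        n_plans=30,
        dose_stats={
            Criterion.CENTROID_DOSE: (-0.35, 1.72),
            Criterion.PTV_MAX: (-0.88, 2.23),
            Criterion.PTV_MEAN: (-1.08, 2.3),
            Criterion.PTV_D90: (-1.22, 2.62),
            Criterion.PTV_D95: (-1.13, 2.66),
        },
        gamma_stats=(99.4, 2.87),
        gamma_threshold_pct=10.0,
    ),
}


def sample_cohort_comparisons(
    preset: CohortPreset | str,
    n: int,
    seed: int = 0,
    reference_dose_gy: float = 50.0,
) -> list[list[MetricComparison]]:
    """Draw n cases' worth of per-criterion comparisons from a preset.

    Each dose criterion's %Δ is an independent Normal(mean, sd) draw; the
    implied secondary value is reconstructed around ``reference_dose_gy``.
    The gamma pass rate is Normal(mean, sd), unclipped (see module notes).
    """
    if isinstance(preset, str):
        try:
            preset = PRESETS[preset]
        except KeyError:
            raise ConfigurationError(
                f"unknown preset '{preset}'; available: {sorted(PRESETS)}"
            ) from None
    if n < 2:
        raise CohortError(f"a cohort needs n >= 2 cases, got {n}")
    rng = np.random.default_rng([int(seed), 31])
    cohort: list[list[MetricComparison]] = []
    for _ in range(n):
        comps: list[MetricComparison] = []
        for crit, (mu, sd) in preset.dose_stats.items():
            d = float(rng.normal(mu, sd))
            tid = 1 if crit in PER_TARGET_CRITERIA else None
            comps.append(
                MetricComparison(
                    CriterionId(crit, tid),
                    reference_dose_gy,
                    reference_dose_gy * (1.0 + d / 100.0),
                    d,
                )
            )
        g_mu, g_sd = preset.gamma_stats
        comps.append(
            MetricComparison(
                CriterionId(Criterion.GAMMA_3D), 100.0, float(rng.normal(g_mu, g_sd)), None
            )
        )
        cohort.append(comps)
    return cohort
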
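"""Dosimetric comparison criteria: point doses, DVH metrics and signed
percentage differences between a secondary calculation and the TPS.

The screening criteria mirror common stereotactic QA practice: isocentre or
per-target centroid point dose, PTV maximum and mean dose, PTV D90 and D95,
plus a plan-level 3D gamma pass rate inside the external contour.  Dose
criteria are compared as signed percentage differences with the TPS value in
the denominator; a *negative* difference means the secondary calculation is
colder than the TPS.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DomainError
from .grids import DoseGrid, PlanCase, RegionMask, Role, Site, interpolate_at

__all__ = [
    "Criterion",
    "CriterionId",
    "MetricComparison",
    "point_dose",
    "dvh_metric",
    "dose_at_volume",
    "percent_diff",
    "default_criteria",
    "compare_case",
    "comparisons_to_frame",
    "frame_to_comparisons",
]


class Criterion(str, enum.Enum):
    ISOCENTRE_DOSE = "ISOCENTRE_DOSE"
    CENTROID_DOSE = "CENTROID_DOSE"
    PTV_MAX = "PTV_MAX"
    PTV_MEAN = "PTV_MEAN"
    PTV_D90 = "PTV_D90"
    PTV_D95 = "PTV_D95"
    GAMMA_3D = "GAMMA_3D"


#: criteria evaluated per target (carry a target_id in multi-lesion plans)
PER_TARGET_CRITERIA = frozenset(
    {Criterion.CENTROID_DOSE, Criterion.PTV_MAX, Criterion.PTV_MEAN,
     Criterion.PTV_D90, Criterion.PTV_D95}
)


@dataclass(frozen=True)
class CriterionId:
    """A criterion, optionally bound to one target of a multi-lesion plan.

    The 3D gamma criterion is plan-level and never carries a target id.
    """

    name: Criterion
    target_id: int | None = None

    def __post_init__(self) -> None:
        if isinstance(self.name, str) and not isinstance(self.name, Criterion):
            object.__setattr__(self, "name", Criterion(self.name))
        if self.name == Criterion.GAMMA_3D and self.target_id is not None:
            raise ConfigurationError("GAMMA_3D is plan-level and carries no target_id")

    def __str__(self) -> str:
        if self.target_id is None:
            return self.name.value
        return f"{self.name.value}[{self.target_id}]"


@dataclass
class MetricComparison:
    """One criterion's TPS value, secondary value and signed % difference.

    For GAMMA_3D the two values are gamma pass rates (%) and ``pct_diff`` is
    ``None``: gamma is screened on the pass rate itself, not a ratio.
    """

    criterion: CriterionId
    tps_value: float
    secondary_value: float
    pct_diff: float | None

    @property
    def is_gamma(self) -> bool:
        return self.criterion.name == Criterion.GAMMA_3D


def point_dose(grid: DoseGrid, point_mm) -> float:
    """Trilinearly interpolated dose (Gy) at a physical point (mm)."""
    pt = np.asarray(point_mm, dtype=float).reshape(1, 3)
    if not bool(grid.geometry.contains(pt)[0]):
        raise DomainError(f"point {tuple(pt[0])} lies outside the grid extent")
    return float(interpolate_at(grid, pt)[0])


_DXX_RE = re.compile(r"^D(\d+(?:\.\d+)?)$")


def dose_at_volume(
    doses: np.ndarray, xx: float, *, interpolate: bool = True
) -> float:
    """Dose received by at least ``xx`` % of the sampled volume.

    Whole-voxel counting on the sorted doses.  With ``interpolate`` (default)
    the dose is linearly interpolated on the coverage grid ``k/n`` of the
    descending order statistics; without it, the result is the largest
    observed dose ``D`` with ``count(dose >= D)/n >= xx/100``.
    """
    if not 0 < xx < 100:
        raise DomainError(f"Dxx requires 0 < xx < 100, got {xx}")
    d = np.sort(np.asarray(doses, dtype=float))[::-1]  # descending
    n = d.size
    if n == 0:
        raise DomainError("Dxx of an empty sample is undefined")
    frac = xx / 100.0
    if not interpolate:
        k = int(np.ceil(frac * n))  # smallest k with k/n >= frac
        return float(d[k - 1])
    coverage = np.arange(1, n + 1) / n
    if frac <= coverage[0]:
        return float(d[0])
    return float(np.interp(frac, coverage, d))


def dvh_metric(
    grid: DoseGrid, mask: RegionMask, metric: str, *, interpolate: bool = True
) -> float:
    """DVH metric of the in-mask dose: ``"DMAX"``, ``"DMEAN"`` or ``"Dxx"``
    (e.g. ``"D95"``), in Gy."""
    if mask.geometry != grid.geometry:
        raise DomainError("mask geometry does not match the dose grid")
    doses = grid.values[mask.voxels]
    if doses.size == 0:
        raise DomainError("DVH metric of an empty mask is undefined")
    key = metric.upper()
    if key == "DMAX":
        return float(doses.max())
    if key == "DMEAN":
        return float(doses.mean())
    m = _DXX_RE.match(key)
    if m:
        return dose_at_volume(doses, float(m.group(1)), interpolate=interpolate)
    raise DomainError(f"unknown DVH metric '{metric}'")


def percent_diff(secondary: float, tps: float) -> float:
    """Signed percentage difference, 100 x (secondary - tps) / tps."""
    if tps <= 0:
        raise DomainError(f"percent difference requires a positive TPS value, got {tps}")
    return 100.0 * (secondary - tps) / tps


def default_criteria(case: PlanCase) -> list[CriterionId]:
    """The site's standard criterion list.

    Lung SBRT: isocentre dose + PTV max/mean/D90/D95 + plan gamma.
    Multi-lesion SRS: centroid dose + PTV max/mean/D90/D95 per target + plan gamma.
    """
    crits: list[CriterionId] = []
    point = Criterion.ISOCENTRE_DOSE if case.site == Site.LUNG_SBRT else Criterion.CENTROID_DOSE
    for tid in case.target_ids:
        if point == Criterion.CENTROID_DOSE:
            crits.append(CriterionId(point, tid))
        for c in (Criterion.PTV_MAX, Criterion.PTV_MEAN, Criterion.PTV_D90, Criterion.PTV_D95):
            crits.append(CriterionId(c, tid))
    if point == Criterion.ISOCENTRE_DOSE:
        crits.insert(0, CriterionId(point))
    crits.append(CriterionId(Criterion.GAMMA_3D))
    return crits


def _ptv_mask(case: PlanCase, target_id: int | None) -> RegionMask:
    m = case.mask(Role.PTV, target_id=target_id)
    if m is None:
        raise ConfigurationError(f"no PTV mask for target {target_id}")
    return m


def compare_case(
    case: PlanCase,
    criteria: list[CriterionId] | None = None,
    *,
    secondary_label: str = "secondary",
    gamma_criteria=None,
) -> list[MetricComparison]:
    """Evaluate every criterion on the TPS grid and the chosen comparison grid.

    ``secondary_label`` selects which grid plays the evaluated role
    ("secondary" or "delivered").  The gamma criterion is evaluated within the
    external contour with site defaults (3%/1 mm global; threshold 40% for
    lung SBRT, 10% for multi-lesion SRS) unless ``gamma_criteria`` overrides.
    """
    from . import gamma as _gamma  # deferred: gamma imports this module's types

    tps = case.tps_dose
    other = case.grid(secondary_label)
    if criteria is None:
        criteria = default_criteria(case)
    out: list[MetricComparison] = []
    for cid in criteria:
        name = cid.name
        if name == Criterion.GAMMA_3D:
            ext = case.mask(Role.EXTERNAL)
            if ext is None:
                raise ConfigurationError("GAMMA_3D requires an EXTERNAL contour mask")
            gc = gamma_criteria or _gamma.GammaCriteria.site_default(case.site)
            res = _gamma.gamma_map(tps, other, ext, gc)
            if res.pass_rate is None:
                raise DomainError("gamma pass rate undefined: no points above threshold")
            out.append(MetricComparison(cid, 100.0, res.pass_rate, None))
            continue
        if name == Criterion.ISOCENTRE_DOSE:
            tv = point_dose(tps, case.isocentre)
            sv = point_dose(other, case.isocentre)
        elif name == Criterion.CENTROID_DOSE:
            if cid.target_id not in case.target_centroids:
                raise ConfigurationError(f"no centroid recorded for target {cid.target_id}")
            pt = case.target_centroids[cid.target_id]
            tv = point_dose(tps, pt)
            sv = point_dose(other, pt)
        else:
            mask = _ptv_mask(case, cid.target_id)
            metric = {
                Criterion.PTV_MAX: "DMAX",
                Criterion.PTV_MEAN: "DMEAN",
                Criterion.PTV_D90: "D90",
                Criterion.PTV_D95: "D95",
            }[name]
            tv = dvh_metric(tps, mask, metric)
            sv = dvh_metric(other, mask, metric)
        out.append(MetricComparison(cid, tv, sv, percent_diff(sv, tv)))
    return out


def comparisons_to_frame(
    results: dict[str, list[MetricComparison]] | list[MetricComparison],
    site: Site | None = None,
) -> pd.DataFrame:
    """Flatten comparison results to one row per case x criterion.

    Accepts either a single case's list or a mapping ``case_id -> list``.
    Columns: case_id, site, criterion, target_id, tps_value, secondary_value,
    pct_diff.
    """
    if isinstance(results, list):
        results = {"case": results}
    rows = []
    for case_id, comps in results.items():
        for c in comps:
            rows.append(
                {
                    "case_id": case_id,
                    "site": site.value if site is not None else "",
                    "criterion": c.criterion.name.value,
                    "target_id": c.criterion.target_id,
                    "tps_value": c.tps_value,
                    "secondary_value": c.secondary_value,
                    "pct_diff": c.pct_diff,
                }
            )
    return pd.DataFrame(rows)


def frame_to_comparisons(frame: pd.DataFrame) -> dict[str, list[MetricComparison]]:
    """Inverse of :func:`comparisons_to_frame`: rebuild per-case comparison
    lists from a flat results table (insertion order preserved)."""
    out: dict[str, list[MetricComparison]] = {}
    for row in frame.itertuples(index=False):
        tid = None if pd.isna(row.target_id) else int(row.target_id)
        cid = CriterionId(Criterion(row.criterion), tid)
        pct = None if pd.isna(row.pct_diff) else float(row.pct_diff)
        out.setdefault(str(row.case_id), []).append(
            MetricComparison(cid, float(row.tps_value), float(row.secondary_value), pct)
        )
    return out
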
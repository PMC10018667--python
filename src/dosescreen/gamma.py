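"""3D gamma-index analysis between a reference and an evaluated dose grid.

The gamma index at a reference point r is

    gamma(r) = min_p sqrt( (dD(r,p) / (dose_pct% * N))^2 + (|r-p| / dta_mm)^2 )

over candidate points p on a dense lattice within ``search_radius_mm`` of r,
where dD is the difference between the evaluated dose (trilinearly
interpolated at p) and the reference dose at r, and N is the normalization
dose — the maximum reference dose inside the analysis mask for GLOBAL
normalization, or the local reference dose for LOCAL.

Reference points are evaluated only where the reference dose is at least
``threshold_pct`` % of the *global* normalization value; sub-threshold voxels
carry a NaN sentinel in the gamma map and are excluded from the pass-rate
denominator.  The pass rate is the percentage of evaluated points with
gamma <= 1.

Two routes compute the same contract:

* :func:`gamma_map` — distance-ordered search with exact early termination
  (a point stops once its running minimum cannot be beaten by any farther
  candidate, because the distance term alone already exceeds it).
* :func:`gamma_bruteforce` — exhaustive dense search over the identical
  candidate lattice, no shortcuts; a small-grid verification oracle.

Both use the same lattice (step ``eval_step_mm``, sphere of radius
``search_radius_mm``), so they agree to floating-point round-off.
Candidate points falling outside the evaluated grid's extent are skipped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import map_coordinates

from .errors import DomainError, GeometryError, SizeError
from .grids import DoseGrid, RegionMask, Site

__all__ = [
    "GammaCriteria",
    "GammaResult",
    "gamma_map",
    "gamma_bruteforce",
    "threshold_sweep",
]

#: largest voxel count the brute-force oracle accepts
_BRUTEFORCE_MAX_VOXELS = 20**3


@dataclass(frozen=True)
class GammaCriteria:
    """Gamma analysis settings (3%/1 mm global is the stereotactic default)."""

    dose_pct: float = 3.0
    dta_mm: float = 1.0
    normalization: str = "GLOBAL"  # GLOBAL or LOCAL
    threshold_pct: float = 10.0
    search_radius_mm: float | None = None  # default 3 x dta_mm
    eval_step_mm: float | None = None  # default dta_mm / 10

    def __post_init__(self) -> None:
        if self.dose_pct <= 0:
            raise DomainError("dose_pct must be > 0")
        if self.dta_mm <= 0:
            raise DomainError("dta_mm must be > 0")
        if not 0 <= self.threshold_pct < 100:
            raise DomainError("threshold_pct must be in [0, 100)")
        if self.normalization not in ("GLOBAL", "LOCAL"):
            raise DomainError(f"unknown normalization '{self.normalization}'")
        if self.search_radius_mm is None:
            object.__setattr__(self, "search_radius_mm", 3.0 * self.dta_mm)
        if self.eval_step_mm is None:
            object.__setattr__(self, "eval_step_mm", self.dta_mm / 10.0)
        if self.search_radius_mm < self.dta_mm:
            raise DomainError("search_radius_mm must be at least dta_mm")
        if self.eval_step_mm <= 0:
            raise DomainError("eval_step_mm must be > 0")

    @classmethod
    def site_default(cls, site: Site) -> "GammaCriteria":
        """3%/1 mm global with the site's customary low-dose threshold:
        40% for lung SBRT, 10% for multi-lesion SRS."""
        thr = 40.0 if site == Site.LUNG_SBRT else 10.0
        return cls(dose_pct=3.0, dta_mm=1.0, normalization="GLOBAL", threshold_pct=thr)

    @classmethod
    def parse(cls, text: str) -> "GammaCriteria":
        """Parse a compact settings string ``dose/dta/norm/threshold``,
        e.g. ``"3/1/global/40"``."""
        parts = text.split("/")
        if len(parts) != 4:
            raise DomainError(f"gamma settings '{text}' are not 'dose/dta/norm/threshold'")
        return cls(
            dose_pct=float(parts[0]),
            dta_mm=float(parts[1]),
            normalization=parts[2].upper(),
            threshold_pct=float(parts[3]),
        )


@dataclass
class GammaResult:
    """Outcome of one gamma analysis.

    ``pass_rate`` is ``None`` (never a silent 100%) when no reference point
    exceeded the dose threshold.  ``gamma`` holds per-voxel gamma values with
    NaN at unevaluated voxels.
    """

    pass_rate: float | None
    n_evaluated: int
    n_passed: int
    gamma: np.ndarray
    criteria: GammaCriteria
    normalization_value: float
    meta: dict = field(default_factory=dict)


def _candidate_offsets(criteria: GammaCriteria) -> tuple[np.ndarray, np.ndarray]:
    """Offsets (mm) of the candidate lattice within the search sphere,
    sorted by distance from the origin; returns (offsets, distances)."""
    step = criteria.eval_step_mm
    n = int(np.floor(criteria.search_radius_mm / step + 1e-9))
    ax = np.arange(-n, n + 1) * step
    ox, oy, oz = np.meshgrid(ax, ax, ax, indexing="ij")
    offs = np.column_stack([ox.ravel(), oy.ravel(), oz.ravel()])
    dist = np.linalg.norm(offs, axis=1)
    keep = dist <= criteria.search_radius_mm + 1e-9
    offs, dist = offs[keep], dist[keep]
    order = np.argsort(dist, kind="stable")
    return offs[order], dist[order]


def _eval_doses(evaluated: DoseGrid, points_mm: np.ndarray) -> np.ndarray:
    """Evaluated dose at physical points; NaN outside the grid extent."""
    idx = evaluated.geometry.world_to_index(points_mm)
    vals = map_coordinates(
        evaluated.values, idx.T, order=1, mode="constant", cval=np.nan, prefilter=False
    )
    hi = np.asarray(evaluated.geometry.shape) - 1
    outside = np.any((idx < -1e-9) | (idx > hi + 1e-9), axis=1)
    vals[outside] = np.nan
    return vals


def _setup(reference: DoseGrid, evaluated: DoseGrid, mask: RegionMask,
           criteria: GammaCriteria, normalization_dose: float | None = None):
    if reference.geometry != evaluated.geometry or mask.geometry != reference.geometry:
        raise GeometryError("reference, evaluated and mask must share one geometry")
    in_mask = mask.voxels
    if not in_mask.any():
        raise DomainError("gamma analysis mask is empty")
    norm = (
        float(reference.values[in_mask].max())
        if normalization_dose is None
        else float(normalization_dose)
    )
    if norm <= 0:
        raise DomainError("normalization value must be positive")
    ref_sel = in_mask & (reference.values >= criteria.threshold_pct / 100.0 * norm)
    idx = np.argwhere(ref_sel)
    pts = reference.geometry.index_to_world(idx)
    ref_doses = reference.values[ref_sel]
    if criteria.normalization == "GLOBAL":
        denom = np.full(ref_doses.shape, criteria.dose_pct / 100.0 * norm)
    else:
        denom = criteria.dose_pct / 100.0 * ref_doses
    return norm, idx, pts, ref_doses, denom


def _result(
    gamma_sq: np.ndarray,
    idx: np.ndarray,
    shape: tuple[int, int, int],
    criteria: GammaCriteria,
    norm: float,
) -> GammaResult:
    gvals = np.sqrt(gamma_sq)
    gmap = np.full(shape, np.nan)
    gmap[tuple(idx.T)] = gvals
    n_eval = int(gvals.size)
    n_pass = int(np.count_nonzero(gvals <= 1.0))
    rate = 100.0 * n_pass / n_eval if n_eval else None
    return GammaResult(rate, n_eval, n_pass, gmap, criteria, norm)


def gamma_map(
    reference: DoseGrid,
    evaluated: DoseGrid,
    mask: RegionMask,
    criteria: GammaCriteria,
    *,
    normalization_dose: float | None = None,
    chunk: int = 1024,
) -> GammaResult:
    """Gamma analysis with a distance-ordered candidate search.

    Candidates are processed in order of increasing distance in chunks; a
    reference point retires as soon as its running minimum gamma^2 is no
    greater than the squared distance term of the nearest unprocessed
    candidate — beyond that, no candidate can improve it.  The retirement
    rule is exact, so the result equals the exhaustive search's.

    ``normalization_dose`` overrides the default global normalization (the
    in-mask reference maximum), e.g. to normalize to a prescription dose.
    """
    norm, idx, pts, ref_doses, denom = _setup(
        reference, evaluated, mask, criteria, normalization_dose
    )
    n_ref = pts.shape[0]
    if n_ref == 0:
        return GammaResult(None, 0, 0, np.full(reference.geometry.shape, np.nan),
                           criteria, norm)
    offs, dist = _candidate_offsets(criteria)
    dta2 = criteria.dta_mm**2

    best = np.full(n_ref, np.inf)
    active = np.arange(n_ref)
    start = 0
    while start < offs.shape[0] and active.size:
        stop = min(start + chunk, offs.shape[0])
        # keep chunk boundaries between distinct distances so the exit bound
        # (distance of the next unprocessed candidate) is well defined
        while stop < offs.shape[0] and dist[stop] == dist[stop - 1]:
            stop += 1
        chunk_offs = offs[start:stop]
        chunk_d2 = (dist[start:stop] ** 2) / dta2
        cand = pts[active][:, None, :] + chunk_offs[None, :, :]
        ev = _eval_doses(evaluated, cand.reshape(-1, 3)).reshape(active.size, -1)
        dd = (ev - ref_doses[active][:, None]) / denom[active][:, None]
        g2 = dd**2 + chunk_d2[None, :]
        with np.errstate(invalid="ignore"):
            g2min = np.nanmin(g2, axis=1)
        improved = g2min < best[active]
        best[active[improved]] = g2min[improved]
        if stop < offs.shape[0]:
            bound = (dist[stop] ** 2) / dta2
            active = active[best[active] > bound]
        start = stop
    return _result(best, idx, reference.geometry.shape, criteria, norm)


def gamma_bruteforce(
    reference: DoseGrid,
    evaluated: DoseGrid,
    mask: RegionMask,
    criteria: GammaCriteria,
    *,
    normalization_dose: float | None = None,
) -> GammaResult:
    """Exhaustive-search gamma oracle: every candidate on the lattice is
    visited for every reference point.  Guarded to small grids; used to
    verify :func:`gamma_map` in tests."""
    if int(np.prod(reference.geometry.shape)) > _BRUTEFORCE_MAX_VOXELS:
        raise SizeError(
            f"brute-force gamma is limited to {_BRUTEFORCE_MAX_VOXELS} voxels"
        )
    norm, idx, pts, ref_doses, denom = _setup(
        reference, evaluated, mask, criteria, normalization_dose
    )
    if pts.shape[0] == 0:
        return GammaResult(None, 0, 0, np.full(reference.geometry.shape, np.nan),
                           criteria, norm)
    offs, dist = _candidate_offsets(criteria)
    d2 = (dist**2) / criteria.dta_mm**2
    best = np.empty(pts.shape[0])
    for i in range(pts.shape[0]):
        ev = _eval_doses(evaluated, pts[i] + offs)
        dd = (ev - ref_doses[i]) / denom[i]
        with np.errstate(invalid="ignore"):
            best[i] = np.nanmin(dd**2 + d2)
    return _result(best, idx, reference.geometry.shape, criteria, norm)


def threshold_sweep(
    reference: DoseGrid,
    evaluated: DoseGrid,
    mask: RegionMask,
    criteria: GammaCriteria,
    thresholds: list[float],
) -> list[tuple[float, float | None, int]]:
    """Pass rate as a function of the low-dose threshold.

    Gamma values do not depend on the threshold (it only selects which
    reference points are evaluated), so the search runs once at the lowest
    requested threshold and the pass rate is re-counted per threshold over
    the corresponding reference subset.  Returns
    ``[(threshold_pct, pass_rate, n_evaluated), ...]``.
    """
    if not thresholds:
        raise DomainError("thresholds list is empty")
    base = GammaCriteria(
        dose_pct=criteria.dose_pct,
        dta_mm=criteria.dta_mm,
        normalization=criteria.normalization,
        threshold_pct=min(thresholds),
        search_radius_mm=criteria.search_radius_mm,
        eval_step_mm=criteria.eval_step_mm,
    )
    res = gamma_map(reference, evaluated, mask, base)
    out: list[tuple[float, float | None, int]] = []
    for t in thresholds:
        sel = mask.voxels & (reference.values >= t / 100.0 * res.normalization_value)
        g = res.gamma[sel]
        g = g[~np.isnan(g)]
        n = int(g.size)
        rate = 100.0 * int(np.count_nonzero(g <= 1.0)) / n if n else None
        out.append((t, rate, n))
    return out
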
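"""Seeded synthetic plan cases with analytic dose fields and controlled
perturbations.

The generator emulates the two stereotactic cohorts this package targets:

* **Lung SBRT**: one target, 60 Gy to the ITV and 50 Gy to the PTV (a 5 mm
  expansion of the ITV), 1.25 mm dose grid.
* **Multi-lesion SRS (MLSRS)**: several disjoint brain targets around a
  shared isocentre, 18-22 Gy to each PTV (a 1 mm expansion of the GTV),
  1 mm dose grid.

The planned dose is a radial logistic fall-off per target,

    D(r) = background + sum_t A_t / (1 + exp((r_t - R50_t) / w)),

with the half-dose radius R50_t placed so the PTV surface receives exactly
the prescription (the prescription sits on the ~76% isodose of the in-target
plateau, as is typical for stereotactic plans, so the PTV interior is at or
above prescription by construction).  There is no beam geometry: the field
is a deliberately simple surrogate whose every metric can be reasoned about
in closed form, not a dose engine.

A :class:`Perturbation` turns the planning grid into a "secondary" or
"delivered" grid by composing, in order: rigid shift, penumbra widening
(Gaussian blur), global dose scaling, a signed error confined to a shell at
each target surface (a stand-in for heterogeneity-driven algorithm
disagreement, which concentrates at interfaces), and voxel-wise Gaussian
noise.  The injected record is kept on the case so tests can check recovery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter, shift as nd_shift

from .errors import CohortError, ConfigurationError, GenerationError
from .grids import DoseGrid, GridGeometry, PlanCase, RegionMask, Role, Site

__all__ = [
    "SyntheticSpec",
    "Perturbation",
    "PerturbationModel",
    "PERTURBATION_MODELS",
    "make_case",
    "apply_perturbation",
    "make_cohort",
]

#: the prescription isodose as a fraction of the in-target plateau dose
PRESCRIPTION_ISODOSE_FRACTION = 0.76


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic plan.

    Defaults reproduce the study conditions per site; pass a smaller
    ``body_radius_mm`` or coarser ``spacing_mm`` for cheap test cases.
    """

    site: Site = Site.LUNG_SBRT
    seed: int = 0
    spacing_mm: float | None = None  # default: 1.25 lung, 1.0 MLSRS
    body_radius_mm: float | None = None  # default: 40 lung, 50 MLSRS
    n_targets: int | None = None  # 1 for lung; default 5 for MLSRS
    target_radius_mm: tuple[float, ...] | None = None  # ITV (lung) / GTV (MLSRS) radii
    ptv_margin_mm: float | None = None  # default: 5 lung, 1 MLSRS
    prescription_gy: tuple[float, ...] | None = None  # per-target PTV prescription
    itv_prescription_gy: float = 60.0  # lung only
    penumbra_sigma_mm: float | None = None  # default: 3.0 lung, 1.5 MLSRS
    background_fraction: float = 0.03
    fractions: int | None = None  # default: 4 lung, 1 MLSRS

    def resolved(self) -> "SyntheticSpec":
        """Fill site-dependent defaults."""
        lung = self.site == Site.LUNG_SBRT
        n = self.n_targets if self.n_targets is not None else (1 if lung else 5)
        if lung and n != 1:
            raise ConfigurationError("lung SBRT cases are single-target")
        radii = self.target_radius_mm
        if radii is None:
            radii = (10.0,) * n if lung else tuple(
                np.random.default_rng([int(self.seed), 101]).uniform(3.0, 8.0, n).round(2)
            )
        if len(radii) != n:
            raise ConfigurationError("target_radius_mm length must equal n_targets")
        rx = self.prescription_gy
        if rx is None:
            rx = (50.0,) * n if lung else tuple(
                np.random.default_rng([int(self.seed), 102]).integers(18, 23, n).astype(float)
            )
        if len(rx) != n:
            raise ConfigurationError("prescription_gy length must equal n_targets")
        return replace(
            self,
            spacing_mm=self.spacing_mm if self.spacing_mm is not None else (1.25 if lung else 1.0),
            body_radius_mm=self.body_radius_mm
            if self.body_radius_mm is not None
            else (40.0 if lung else 50.0),
            n_targets=n,
            target_radius_mm=tuple(float(r) for r in radii),
            ptv_margin_mm=self.ptv_margin_mm
            if self.ptv_margin_mm is not None
            else (5.0 if lung else 1.0),
            prescription_gy=tuple(float(r) for r in rx),
            penumbra_sigma_mm=self.penumbra_sigma_mm
            if self.penumbra_sigma_mm is not None
            else (3.0 if lung else 1.5),
            fractions=self.fractions if self.fractions is not None else (4 if lung else 1),
        )


@dataclass(frozen=True)
class Perturbation:
    """A controlled disagreement applied to a copy of the planning grid.

    All percentages are signed; the zero perturbation is the identity.
    ``boundary_error_pct`` acts in a shell of width ``boundary_shell_mm``
    straddling each PTV surface.
    """

    global_scale_pct: float = 0.0
    shift_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    penumbra_widen_mm: float = 0.0
    boundary_error_pct: float = 0.0
    boundary_shell_mm: float = 3.0
    noise_sd_pct: float = 0.0

    def __post_init__(self) -> None:
        vals = [self.global_scale_pct, *self.shift_mm, self.penumbra_widen_mm,
                self.boundary_error_pct, self.boundary_shell_mm, self.noise_sd_pct]
        if not all(math.isfinite(v) for v in vals):
            raise ConfigurationError("perturbation fields must be finite")
        if self.penumbra_widen_mm < 0 or self.noise_sd_pct < 0:
            raise ConfigurationError("widths and noise SD must be non-negative")

    @property
    def is_identity(self) -> bool:
        return (
            self.global_scale_pct == 0
            and self.shift_mm == (0.0, 0.0, 0.0)
            and self.penumbra_widen_mm == 0
            and self.boundary_error_pct == 0
            and self.noise_sd_pct == 0
        )

    def as_dict(self) -> dict:
        return {
            "global_scale_pct": self.global_scale_pct,
            "shift_mm": list(self.shift_mm),
            "penumbra_widen_mm": self.penumbra_widen_mm,
            "boundary_error_pct": self.boundary_error_pct,
            "boundary_shell_mm": self.boundary_shell_mm,
            "noise_sd_pct": self.noise_sd_pct,
        }


def _sphere_mask(geo: GridGeometry, centre, radius: float) -> np.ndarray:
    x, y, z = geo.centre_mesh()
    return (x - centre[0]) ** 2 + (y - centre[1]) ** 2 + (z - centre[2]) ** 2 <= radius**2


def _radial_distance(geo: GridGeometry, centre) -> np.ndarray:
    x, y, z = geo.centre_mesh()
    return np.sqrt((x - centre[0]) ** 2 + (y - centre[1]) ** 2 + (z - centre[2]) ** 2)


def _place_targets(spec: SyntheticSpec, rng: np.random.Generator) -> list[np.ndarray]:
    """Target centres: origin for the single lung target; rejection-sampled
    non-overlapping positions for MLSRS."""
    if spec.site == Site.LUNG_SBRT:
        return [np.zeros(3)]
    ptv_radii = [r + spec.ptv_margin_mm for r in spec.target_radius_mm]
    max_r = spec.body_radius_mm - max(ptv_radii) - 3.0
    if max_r <= 0:
        raise GenerationError("targets cannot fit inside the body")
    centres: list[np.ndarray] = []
    for i in range(spec.n_targets):
        for _ in range(500):
            c = rng.uniform(-max_r, max_r, 3)
            if np.linalg.norm(c) > max_r:
                continue
            ok = all(
                np.linalg.norm(c - cj) >= ptv_radii[i] + ptv_radii[j] + 4.0
                for j, cj in enumerate(centres)
            )
            if ok:
                centres.append(c)
                break
        else:
            raise GenerationError(
                f"could not place target {i} after 500 attempts; "
                "reduce n_targets or target radii"
            )
    return centres


def make_case(spec: SyntheticSpec) -> PlanCase:
    """Build a deterministic synthetic plan case from a spec (same spec and
    seed always give bit-identical grids)."""
    spec = spec.resolved()
    lung = spec.site == Site.LUNG_SBRT
    rng_place = np.random.default_rng([int(spec.seed), 1])

    extent = spec.body_radius_mm + 4.0 * spec.spacing_mm
    n_vox = int(np.ceil(2 * extent / spec.spacing_mm)) + 1
    half = (n_vox - 1) / 2.0 * spec.spacing_mm
    geo = GridGeometry(
        origin=(-half, -half, -half),
        spacing=(spec.spacing_mm,) * 3,
        shape=(n_vox,) * 3,
    )

    centres = _place_targets(spec, rng_place)
    w = spec.penumbra_sigma_mm
    x0 = math.log(PRESCRIPTION_ISODOSE_FRACTION / (1 - PRESCRIPTION_ISODOSE_FRACTION))

    amplitudes = [rx / PRESCRIPTION_ISODOSE_FRACTION for rx in spec.prescription_gy]
    background = spec.background_fraction * max(amplitudes)
    dose = np.full(geo.shape, background)
    structures: list[RegionMask] = []
    centroids: dict[int, tuple[float, float, float]] = {}
    prescriptions: dict[int, float] = {}

    for i, (c, r_core, rx, amp) in enumerate(
        zip(centres, spec.target_radius_mm, spec.prescription_gy, amplitudes)
    ):
        tid = i + 1
        r_ptv = r_core + spec.ptv_margin_mm
        r50 = r_ptv + w * x0  # puts exactly rx on the PTV surface
        r = _radial_distance(geo, c)
        dose += amp / (1.0 + np.exp((r - r50) / w))
        ptv = RegionMask(geo, _sphere_mask(geo, c, r_ptv), Role.PTV, target_id=tid,
                         name=f"PTV{tid}")
        structures.append(ptv)
        inner_role = Role.ITV if lung else Role.GTV
        structures.append(
            RegionMask(geo, _sphere_mask(geo, c, r_core), inner_role, target_id=tid,
                       name=f"{inner_role.value}{tid}")
        )
        centroids[tid] = tuple(ptv.centroid_mm())
        prescriptions[tid] = rx

    structures.append(
        RegionMask(geo, _sphere_mask(geo, (0, 0, 0), spec.body_radius_mm),
                   Role.EXTERNAL, name="External")
    )

    iso = centres[0] if lung else np.mean(np.asarray(centres), axis=0)
    tps = DoseGrid(geo, dose, label="TPS")
    return PlanCase(
        case_id=f"{spec.site.value.lower()}-{spec.seed}",
        site=spec.site,
        tps_dose=tps,
        secondary_dose=tps.with_values(dose.copy(), label="secondary"),
        structures=structures,
        isocentre=tuple(float(v) for v in iso),
        prescription_gy=prescriptions,
        target_centroids=centroids,
        fractions=spec.fractions,
        meta={"spec_seed": spec.seed, "perturbations": {}},
    )


def apply_perturbation(
    case: PlanCase,
    p: Perturbation,
    which: str = "secondary",
    seed: int | None = None,
) -> PlanCase:
    """Return a copy of the case whose ``which`` grid is the TPS grid under
    the perturbation (shift -> blur -> scale -> boundary shell -> noise).

    The injected perturbation is recorded in ``case.meta['perturbations']``
    so ground-truth recovery can be asserted in tests.
    """
    if which not in ("secondary", "delivered"):
        raise ConfigurationError(f"perturbation target must be secondary/delivered, not '{which}'")
    geo = case.tps_dose.geometry
    vals = case.tps_dose.values.copy()

    if p.shift_mm != (0.0, 0.0, 0.0):
        # a rigid shift by +s carries dose at r-s to r
        shift_vox = np.asarray(p.shift_mm) / np.asarray(geo.spacing)
        margin = np.linalg.norm(p.shift_mm)
        ext = case.mask(Role.EXTERNAL)
        for tid in case.target_ids:
            ptv = case.mask(Role.PTV, target_id=tid)
            if ptv is not None and ext is not None:
                c = np.asarray(case.target_centroids[tid]) + np.asarray(p.shift_mm)
                body_r = (3.0 * ext.volume_cc * 1000.0 / (4.0 * np.pi)) ** (1 / 3)
                if np.linalg.norm(c) + margin > body_r + max(geo.spacing):
                    raise GenerationError(f"shift moves target {tid} outside the body")
        vals = nd_shift(vals, shift_vox, order=1, mode="nearest")
    if p.penumbra_widen_mm > 0:
        vals = gaussian_filter(vals, sigma=p.penumbra_widen_mm / np.asarray(geo.spacing))
    if p.global_scale_pct != 0:
        vals = vals * (1.0 + p.global_scale_pct / 100.0)
    if p.boundary_error_pct != 0:
        for tid in case.target_ids:
            ptv = case.mask(Role.PTV, target_id=tid)
            r_ptv = (3.0 * ptv.volume_cc * 1000.0 / (4.0 * np.pi)) ** (1 / 3)
            r = _radial_distance(geo, case.target_centroids[tid])
            shell = np.abs(r - r_ptv) <= p.boundary_shell_mm / 2.0
            vals = np.where(shell, vals * (1.0 + p.boundary_error_pct / 100.0), vals)
    if p.noise_sd_pct > 0:
        rng = np.random.default_rng(
            [int(case.meta.get("spec_seed", 0)), 7 if which == "secondary" else 8]
            if seed is None
            else int(seed)
        )
        vals = vals * (1.0 + p.noise_sd_pct / 100.0 * rng.standard_normal(vals.shape))
    vals = np.clip(vals, 0.0, None)

    grid = DoseGrid(geo, vals, label=which)
    meta = dict(case.meta)
    meta["perturbations"] = {**case.meta.get("perturbations", {}), which: p.as_dict()}
    kwargs = dict(secondary_dose=case.secondary_dose, delivered_dose=case.delivered_dose)
    kwargs[f"{which}_dose"] = grid
    return replace(case, meta=meta, **kwargs)


@dataclass(frozen=True)
class PerturbationModel:
    """Distribution over perturbations for cohort generation.

    Each field is either a fixed value or a ``(mu, sigma)`` pair sampled
    from a Normal, independently per case.
    """

    global_scale_pct: float | tuple[float, float] = 0.0
    shift_mm_sd: float = 0.0  # isotropic Normal per axis
    penumbra_widen_mm: float | tuple[float, float] = 0.0
    boundary_error_pct: float | tuple[float, float] = 0.0
    boundary_shell_mm: float = 3.0
    noise_sd_pct: float = 0.0

    def draw(self, rng: np.random.Generator) -> Perturbation:
        def _one(v, lo=None):
            out = rng.normal(*v) if isinstance(v, tuple) else float(v)
            if lo is not None:
                out = max(lo, out)
            return out

        return Perturbation(
            global_scale_pct=_one(self.global_scale_pct),
            shift_mm=tuple(rng.normal(0.0, self.shift_mm_sd, 3)) if self.shift_mm_sd > 0
            else (0.0, 0.0, 0.0),
            penumbra_widen_mm=_one(self.penumbra_widen_mm, lo=0.0),
            boundary_error_pct=_one(self.boundary_error_pct),
            boundary_shell_mm=self.boundary_shell_mm,
            noise_sd_pct=self.noise_sd_pct,
        )


#: grid-level perturbation models per cohort preset.  The global-scale
#: component carries the published mean-dose disagreement exactly (a uniform
#: scale propagates unchanged into every dose criterion); boundary-shell and
#: shift components add the extra coverage-metric spread seen in the poorer
#: algorithms.  These are mechanistic surrogates, not fitted dose engines.
PERTURBATION_MODELS: dict[str, PerturbationModel] = {
    "AAA_LUNG_LIKE": PerturbationModel(
        global_scale_pct=(-2.67, 2.68),
        shift_mm_sd=0.4,
        boundary_error_pct=(-6.0, 5.0),
        boundary_shell_mm=4.0,
        noise_sd_pct=0.3,
    ),
    "AXB_LUNG_LIKE": PerturbationModel(
        global_scale_pct=(-1.0, 1.03),
        shift_mm_sd=0.2,
        boundary_error_pct=(-1.5, 1.5),
        boundary_shell_mm=3.0,
        noise_sd_pct=0.2,
    ),
    "MLSRS_LIKE": PerturbationModel(
        global_scale_pct=(-1.08, 2.3),
        shift_mm_sd=0.2,
        boundary_error_pct=(-0.5, 1.5),
        boundary_shell_mm=2.0,
        noise_sd_pct=0.2,
    ),
}


def make_cohort(
    spec: SyntheticSpec,
    n: int,
    model: PerturbationModel,
    seed: int = 0,
) -> list[PlanCase]:
    """Generate n i.i.d. perturbed cases; reproducible from the seed.

    Case k uses an independent substream of the master seed for both its
    geometry (MLSRS target placement, prescriptions) and its perturbation
    draw, so cohorts are stable under reordering of perturbation types.
    """
    if n < 2:
        raise CohortError(f"a cohort needs n >= 2 cases, got {n}")
    cases = []
    for k in range(n):
        case_seed = int(np.random.default_rng([int(seed), k, 11]).integers(0, 2**31 - 1))
        case = make_case(replace(spec, seed=case_seed))
        case.case_id = f"{spec.site.value.lower()}-c{k:04d}"
        rng = np.random.default_rng([int(seed), k, 12])
        case = apply_perturbation(case, model.draw(rng), "secondary",
                                  seed=int(rng.integers(0, 2**31 - 1)))
        cases.append(case)
    return cases
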
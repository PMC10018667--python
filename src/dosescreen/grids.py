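"""Geometric data model: dose grids, region masks and plan cases.

Conventions
-----------
* All physical positions are in millimetres, in the patient coordinate
  frame, with a fixed ``(x, y, z)`` axis order for arrays: ``values[ix, iy, iz]``.
* ``GridGeometry.origin`` is the physical position of the **centre** of voxel
  ``(0, 0, 0)``; dose values are point samples at voxel centres.
* Dose is absolute dose in Gy for the full course unless a caller chooses
  otherwise; all percentage metrics downstream are unit-free.
* Comparison operations require *matched* geometry.  :func:`resample` is the
  explicit, reported pre-step for mismatched grids — nothing resamples
  silently.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import map_coordinates

from .errors import DomainError, GeometryError

__all__ = [
    "GridGeometry",
    "DoseGrid",
    "RegionMask",
    "PlanCase",
    "Role",
    "Site",
    "interpolate_at",
    "resample",
]

#: tolerance (mm) within which two geometries compare equal
GEOMETRY_TOL_MM = 1e-6


class Role(str, enum.Enum):
    """Anatomical role of a region mask."""

    PTV = "PTV"
    ITV = "ITV"
    GTV = "GTV"
    EXTERNAL = "EXTERNAL"
    OTHER = "OTHER"


class Site(str, enum.Enum):
    """Treatment site of a plan case."""

    LUNG_SBRT = "LUNG_SBRT"
    MLSRS = "MLSRS"


@dataclass(frozen=True)
class GridGeometry:
    """Origin/spacing/shape of a regular 3D grid (mm, voxel-centre convention)."""

    origin: tuple[float, float, float]
    spacing: tuple[float, float, float]
    shape: tuple[int, int, int]

    def __post_init__(self) -> None:
        object.__setattr__(self, "origin", tuple(float(v) for v in self.origin))
        object.__setattr__(self, "spacing", tuple(float(v) for v in self.spacing))
        object.__setattr__(self, "shape", tuple(int(v) for v in self.shape))
        if len(self.origin) != 3 or len(self.spacing) != 3 or len(self.shape) != 3:
            raise GeometryError("origin, spacing and shape must be 3-vectors")
        if any(s <= 0 for s in self.spacing):
            raise GeometryError(f"spacing must be strictly positive, got {self.spacing}")
        if any(n < 1 for n in self.shape):
            raise GeometryError(f"shape components must be >= 1, got {self.shape}")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GridGeometry):
            return NotImplemented
        return (
            self.shape == other.shape
            and all(abs(a - b) <= GEOMETRY_TOL_MM for a, b in zip(self.origin, other.origin))
            and all(abs(a - b) <= GEOMETRY_TOL_MM for a, b in zip(self.spacing, other.spacing))
        )

    def __hash__(self) -> int:  # frozen dataclass with custom __eq__
        return hash(self.shape)

    @property
    def voxel_volume_cc(self) -> float:
        """Volume of one voxel in cm^3."""
        return float(np.prod(self.spacing)) / 1000.0

    def axis_coords(self, axis: int) -> np.ndarray:
        """Physical coordinates (mm) of voxel centres along one axis."""
        return self.origin[axis] + self.spacing[axis] * np.arange(self.shape[axis])

    def world_to_index(self, points_mm: np.ndarray) -> np.ndarray:
        """Map physical points (mm) to fractional voxel indices. ``points_mm``
        has shape ``(n, 3)`` (or ``(3,)``)."""
        p = np.atleast_2d(np.asarray(points_mm, dtype=float))
        return (p - np.asarray(self.origin)) / np.asarray(self.spacing)

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        i = np.atleast_2d(np.asarray(idx, dtype=float))
        return np.asarray(self.origin) + i * np.asarray(self.spacing)

    def contains(self, points_mm: np.ndarray, tol: float = 1e-9) -> np.ndarray:
        """True where a point lies within the voxel-centre extent of the grid."""
        idx = self.world_to_index(points_mm)
        hi = np.asarray(self.shape) - 1
        return np.all((idx >= -tol) & (idx <= hi + tol), axis=1)

    def centre_mesh(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Voxel-centre coordinate arrays, broadcastable to ``shape``."""
        x = self.axis_coords(0)[:, None, None]
        y = self.axis_coords(1)[None, :, None]
        z = self.axis_coords(2)[None, None, :]
        return x, y, z


@dataclass
class DoseGrid:
    """A 3D absorbed-dose field (Gy) on a :class:`GridGeometry`."""

    geometry: GridGeometry
    values: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != self.geometry.shape:
            raise GeometryError(
                f"values shape {self.values.shape} != geometry shape {self.geometry.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise DomainError("dose values must all be finite")
        if np.any(self.values < 0):
            raise DomainError("dose values must be non-negative")

    def with_values(self, values: np.ndarray, label: str | None = None) -> "DoseGrid":
        return DoseGrid(self.geometry, values, self.label if label is None else label)


@dataclass
class RegionMask:
    """Boolean voxel mask aligned to a dose grid, labelled by anatomical role."""

    geometry: GridGeometry
    voxels: np.ndarray
    role: Role = Role.OTHER
    target_id: int | None = None
    name: str = ""

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=bool)
        if isinstance(self.role, str):
            self.role = Role(self.role)
        if self.voxels.shape != self.geometry.shape:
            raise GeometryError(
                f"mask shape {self.voxels.shape} != geometry shape {self.geometry.shape}"
            )

    @property
    def n_voxels(self) -> int:
        return int(np.count_nonzero(self.voxels))

    @property
    def volume_cc(self) -> float:
        """Mask volume in cm^3: true-voxel count times voxel volume."""
        return self.n_voxels * self.geometry.voxel_volume_cc

    def centroid_mm(self) -> np.ndarray:
        """Unweighted mean of the voxel-centre coordinates of true voxels."""
        if self.n_voxels == 0:
            raise DomainError("centroid of an empty mask is undefined")
        idx = np.argwhere(self.voxels)
        return self.geometry.index_to_world(idx).mean(axis=0)


@dataclass
class PlanCase:
    """One plan: paired dose grids, structures and prescription context.

    ``tps_dose`` is the planning-system calculation; ``secondary_dose`` is the
    independent verification calculation; ``delivered_dose`` optionally holds a
    log-reconstructed delivery.  All grids and masks share one geometry.
    """

    case_id: str
    site: Site
    tps_dose: DoseGrid
    secondary_dose: DoseGrid
    structures: list[RegionMask]
    isocentre: tuple[float, float, float]
    prescription_gy: dict[int, float]
    target_centroids: dict[int, tuple[float, float, float]] = field(default_factory=dict)
    delivered_dose: DoseGrid | None = None
    fractions: int = 1
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if isinstance(self.site, str):
            self.site = Site(self.site)
        geo = self.tps_dose.geometry
        for g in (self.secondary_dose, self.delivered_dose):
            if g is not None and g.geometry != geo:
                raise GeometryError(f"dose grid '{g.label}' geometry differs from TPS grid")
        for m in self.structures:
            if m.geometry != geo:
                raise GeometryError(f"mask '{m.name}' geometry differs from TPS grid")
        if self.fractions < 1:
            raise DomainError("fractions must be a positive integer")
        for tid in self.prescription_gy:
            if self.mask(Role.PTV, target_id=tid) is None:
                raise GeometryError(f"target {tid} has a prescription but no PTV mask")
            if tid not in self.target_centroids:
                raise GeometryError(f"target {tid} has a prescription but no centroid")

    def mask(self, role: Role, target_id: int | None = None) -> RegionMask | None:
        """First structure matching role (and target_id when given), else None."""
        for m in self.structures:
            if m.role == role and (target_id is None or m.target_id == target_id):
                return m
        return None

    def grid(self, which: str) -> DoseGrid:
        """Fetch a dose grid by label: 'tps', 'secondary' or 'delivered'."""
        try:
            g = {
                "tps": self.tps_dose,
                "secondary": self.secondary_dose,
                "delivered": self.delivered_dose,
            }[which]
        except KeyError:
            raise DomainError(f"unknown grid '{which}'") from None
        if g is None:
            raise DomainError(f"case {self.case_id} has no '{which}' dose grid")
        return g

    @property
    def target_ids(self) -> list[int]:
        return sorted(self.prescription_gy)


def interpolate_at(grid: DoseGrid, points_mm: np.ndarray, fill: float = 0.0) -> np.ndarray:
    """Trilinear interpolation of dose at physical points (mm).

    Points outside the voxel-centre extent receive ``fill``.
    """
    idx = grid.geometry.world_to_index(points_mm)
    return map_coordinates(
        grid.values, idx.T, order=1, mode="constant", cval=fill, prefilter=False
    )


def resample(
    grid: DoseGrid, target: GridGeometry, *, return_report: bool = False
) -> DoseGrid | tuple[DoseGrid, int]:
    """Resample a dose grid onto a target geometry by trilinear interpolation.

    Target voxel centres outside the source extent are filled with 0 Gy and
    counted; the count is returned when ``return_report`` is true.  A target
    with no spatial overlap at all raises :class:`GeometryError`.
    """
    if target == grid.geometry:
        out = grid.with_values(grid.values.copy())
        return (out, 0) if return_report else out
    x, y, z = np.meshgrid(
        target.axis_coords(0), target.axis_coords(1), target.axis_coords(2), indexing="ij"
    )
    pts = np.column_stack([x.ravel(), y.ravel(), z.ravel()])
    inside = grid.geometry.contains(pts)
    n_outside = int(np.count_nonzero(~inside))
    if n_outside == pts.shape[0]:
        raise GeometryError("target geometry has no spatial overlap with the source grid")
    vals = interpolate_at(grid, pts, fill=0.0).reshape(target.shape)
    out = DoseGrid(target, vals, label=grid.label)
    return (out, n_outside) if return_report else out
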
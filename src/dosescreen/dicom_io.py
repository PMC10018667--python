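"""DICOM RT Dose and RT Structure Set readers (plus a minimal RT Dose writer
used to produce round-trip fixtures).

Axis conventions: DICOM stores dose frames as (frame, row, column) =
(z, y, x); this module transposes to the package's (x, y, z) order.  The
grid origin is the ImagePositionPatient of the first frame — the centre of
the first stored voxel — which matches the package's voxel-centre convention
directly.
"""

from __future__ import annotations

import logging
import re

import numpy as np
import pydicom
from matplotlib.path import Path as MplPath
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

from .errors import FormatError, GeometryError
from .grids import DoseGrid, GridGeometry, RegionMask, Role

__all__ = ["read_rtdose", "write_rtdose", "read_structures", "DEFAULT_ROLE_PATTERNS"]

log = logging.getLogger(__name__)

_RTDOSE_SOP_CLASS = "1.2.840.10008.5.1.4.1.1.481.2"

#: ROI-name regexes mapped to roles (first match wins, case-insensitive)
DEFAULT_ROLE_PATTERNS: list[tuple[str, Role]] = [
    (r"^(external|body|skin)", Role.EXTERNAL),
    (r"ptv", Role.PTV),
    (r"itv", Role.ITV),
    (r"gtv", Role.GTV),
]


def _require(ds: Dataset, attr: str) -> object:
    if not hasattr(ds, attr):
        raise FormatError(f"RT Dose file is missing required attribute {attr}")
    return getattr(ds, attr)


def read_rtdose(path) -> DoseGrid:
    """Read a DICOM RT Dose file into a :class:`DoseGrid` in Gy.

    The dose-grid scaling factor is applied; the geometry comes from
    ImagePositionPatient, PixelSpacing and the GridFrameOffsetVector.
    Non-uniform frame offsets raise :class:`GeometryError`.
    """
    ds = path if isinstance(path, Dataset) else pydicom.dcmread(path)
    scaling = float(_require(ds, "DoseGridScaling"))
    ipp = [float(v) for v in _require(ds, "ImagePositionPatient")]
    pixel_spacing = [float(v) for v in _require(ds, "PixelSpacing")]  # [row(y), col(x)]
    frames = ds.pixel_array  # (nframes, rows, cols) or (rows, cols)
    if frames.ndim == 2:
        frames = frames[None]
    n_frames = frames.shape[0]
    if n_frames > 1:
        offsets = np.asarray([float(v) for v in _require(ds, "GridFrameOffsetVector")])
        if offsets.size != n_frames:
            raise FormatError("GridFrameOffsetVector length does not match frame count")
        steps = np.diff(offsets)
        if steps.size and (np.any(steps <= 0) or np.ptp(steps) > 1e-6):
            raise GeometryError(f"non-uniform slice spacing in GridFrameOffsetVector: {offsets}")
        dz = float(steps[0])
        z0 = ipp[2] + float(offsets[0])
    else:
        raw = getattr(ds, "GridFrameOffsetVector", [0.0])
        first = float(raw[0]) if hasattr(raw, "__iter__") else float(raw)
        dz = float(getattr(ds, "SliceThickness", 1.0) or 1.0)
        z0 = ipp[2] + first
    geometry = GridGeometry(
        origin=(ipp[0], ipp[1], z0),
        spacing=(pixel_spacing[1], pixel_spacing[0], dz),
        shape=(frames.shape[2], frames.shape[1], n_frames),
    )
    values = (frames.astype(np.float64) * scaling).transpose(2, 1, 0)  # (z,y,x)->(x,y,z)
    return DoseGrid(geometry, values, label=str(getattr(ds, "SeriesDescription", "RTDOSE")))


def write_rtdose(grid: DoseGrid, path, scaling: float | None = None) -> None:
    """Write a minimal single-series RT Dose file.

    Values are stored as 32-bit unsigned integers under ``scaling`` (Gy per
    stored unit).  The round trip is exact when every dose is an integer
    multiple of the scaling factor; otherwise it quantizes to ``scaling``.
    """
    if scaling is None:
        vmax = float(grid.values.max())
        scaling = max(vmax, 1e-6) / (2**31)
    stored = np.round(grid.values / scaling).astype(np.uint32)
    if np.any(grid.values / scaling > 2**32 - 1):
        raise FormatError("dose exceeds the uint32 range for the chosen scaling")

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = _RTDOSE_SOP_CLASS
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian

    ds = Dataset()
    ds.file_meta = meta
    ds.SOPClassUID = _RTDOSE_SOP_CLASS
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "RTDOSE"
    ds.SeriesDescription = grid.label or "RTDOSE"
    ds.DoseUnits = "GY"
    ds.DoseType = "PHYSICAL"
    ds.DoseSummationType = "PLAN"
    ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
    ds.ImagePositionPatient = [grid.geometry.origin[0], grid.geometry.origin[1],
                               grid.geometry.origin[2]]
    ds.PixelSpacing = [grid.geometry.spacing[1], grid.geometry.spacing[0]]  # [row, col]
    ds.SliceThickness = grid.geometry.spacing[2]
    nx, ny, nz = grid.geometry.shape
    ds.Rows = ny
    ds.Columns = nx
    ds.NumberOfFrames = nz
    ds.FrameIncrementPointer = pydicom.tag.Tag(0x3004, 0x000C)
    ds.GridFrameOffsetVector = [float(k * grid.geometry.spacing[2]) for k in range(nz)]
    ds.DoseGridScaling = scaling
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 32
    ds.BitsStored = 32
    ds.HighBit = 31
    ds.PixelRepresentation = 0
    ds.PixelData = stored.transpose(2, 1, 0).tobytes()  # (x,y,z) -> (frame,row,col)
    ds.save_as(path, enforce_file_format=True)


def assign_role(
    name: str, patterns: list[tuple[str, Role]] | None = None
) -> tuple[Role, int | None]:
    """Map an ROI name to a role (and a trailing-integer target id, if any)."""
    patterns = DEFAULT_ROLE_PATTERNS if patterns is None else patterns
    role = Role.OTHER
    for pat, r in patterns:
        if re.search(pat, name, flags=re.IGNORECASE):
            role = r
            break
    target_id = None
    if role in (Role.PTV, Role.GTV, Role.ITV):
        m = re.search(r"(\d+)\s*$", name)
        if m:
            target_id = int(m.group(1))
    return role, target_id


def _rasterize_polygon(
    xy: np.ndarray, geometry: GridGeometry
) -> np.ndarray:
    """2D mask of voxel centres (x, y plane) inside a closed polygon
    (even-odd rule via matplotlib's path predicate)."""
    gx = geometry.axis_coords(0)
    gy = geometry.axis_coords(1)
    xx, yy = np.meshgrid(gx, gy, indexing="ij")
    pts = np.column_stack([xx.ravel(), yy.ravel()])
    inside = MplPath(np.asarray(xy)).contains_points(pts)  # implicitly closed
    return inside.reshape(len(gx), len(gy))


def read_structures(
    path,
    geometry: GridGeometry,
    role_patterns: list[tuple[str, Role]] | None = None,
) -> list[RegionMask]:
    """Rasterize every ROI of a DICOM RT Structure Set onto a grid.

    Each planar contour is rasterized with the voxel-centre-inside-polygon
    rule on its nearest grid plane (a warning is logged when the contour
    plane is farther than half a slice spacing).  Multiple contours on one
    plane combine by exclusive-or, so holes and islands behave as drawn.
    ROIs without contour data are skipped with a warning.
    """
    ds = path if isinstance(path, Dataset) else pydicom.dcmread(path)
    rois = {int(r.ROINumber): str(r.ROIName) for r in getattr(ds, "StructureSetROISequence", [])}
    masks: list[RegionMask] = []
    for rc in getattr(ds, "ROIContourSequence", []):
        name = rois.get(int(rc.ReferencedROINumber), f"ROI{rc.ReferencedROINumber}")
        contours = getattr(rc, "ContourSequence", None)
        if not contours:
            log.warning("ROI '%s' has no contour data; skipped", name)
            continue
        vox = np.zeros(geometry.shape, dtype=bool)
        for contour in contours:
            data = np.asarray([float(v) for v in contour.ContourData]).reshape(-1, 3)
            z = float(np.mean(data[:, 2]))
            iz = int(round((z - geometry.origin[2]) / geometry.spacing[2]))
            iz = min(max(iz, 0), geometry.shape[2] - 1)
            plane_z = geometry.origin[2] + iz * geometry.spacing[2]
            if abs(z - plane_z) > geometry.spacing[2] / 2 + 1e-9:
                log.warning(
                    "contour of '%s' at z=%.3f mm is not on a grid plane; "
                    "rasterized to the nearest plane z=%.3f mm", name, z, plane_z,
                )
            vox[:, :, iz] ^= _rasterize_polygon(data[:, :2], geometry)
        role, target_id = assign_role(name, role_patterns)
        masks.append(RegionMask(geometry, vox, role, target_id=target_id, name=name))
    return masks
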
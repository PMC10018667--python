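"""Self-contained fixture container for plan cases.

A case is stored as two files sharing a base path: a compressed NumPy
archive (``<base>.npz``) holding the dose grids and structure masks, and a
JSON sidecar (``<base>.json``) holding the geometry, prescriptions and
other metadata plus a SHA-256 checksum of the array payload.  The round trip
is bit-exact for dose values and exact for geometry (floats pass through
JSON unchanged).

Schema version: ``dosescreen/case/1``.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np

from .errors import FormatError, VersionError
from .grids import DoseGrid, GridGeometry, PlanCase, RegionMask, Role, Site

__all__ = ["write_fixture", "read_fixture"]

SCHEMA = "dosescreen/case/1"


def _paths(path) -> tuple[Path, Path]:
    base = Path(path)
    if base.suffix in (".npz", ".json"):
        base = base.with_suffix("")
    return base.with_suffix(".npz"), base.with_suffix(".json")


def _payload_digest(arrays: dict[str, np.ndarray]) -> str:
    h = hashlib.sha256()
    for key in sorted(arrays):
        h.update(key.encode())
        h.update(np.ascontiguousarray(arrays[key]).tobytes())
    return h.hexdigest()


def write_fixture(case: PlanCase, path) -> None:
    """Write a case to ``<path>.npz`` + ``<path>.json``."""
    npz_path, json_path = _paths(path)
    arrays: dict[str, np.ndarray] = {
        "tps": case.tps_dose.values,
        "secondary": case.secondary_dose.values,
    }
    if case.delivered_dose is not None:
        arrays["delivered"] = case.delivered_dose.values
    for i, m in enumerate(case.structures):
        arrays[f"mask_{i}"] = m.voxels
    geo = case.tps_dose.geometry
    meta = {
        "schema": SCHEMA,
        "case_id": case.case_id,
        "site": case.site.value,
        "geometry": {"origin": list(geo.origin), "spacing": list(geo.spacing),
                     "shape": list(geo.shape)},
        "isocentre": list(case.isocentre),
        "prescription_gy": {str(k): v for k, v in case.prescription_gy.items()},
        "target_centroids": {str(k): list(v) for k, v in case.target_centroids.items()},
        "fractions": case.fractions,
        "grid_labels": {k: getattr(case, f"{'tps' if k == 'tps' else k}_dose").label
                        for k in ("tps", "secondary")},
        "structures": [
            {"index": i, "role": m.role.value, "target_id": m.target_id, "name": m.name}
            for i, m in enumerate(case.structures)
        ],
        "meta": case.meta,
        "payload_sha256": _payload_digest(arrays),
    }
    np.savez_compressed(npz_path, **arrays)
    json_path.write_text(json.dumps(meta, indent=2))


def read_fixture(path) -> PlanCase:
    """Read a case written by :func:`write_fixture`; integrity-checked."""
    npz_path, json_path = _paths(path)
    if not json_path.exists():
        raise FormatError(f"missing fixture sidecar {json_path}")
    meta = json.loads(json_path.read_text())
    if meta.get("schema") != SCHEMA:
        raise VersionError(
            f"fixture schema {meta.get('schema')!r} is not supported (expected {SCHEMA})"
        )
    with np.load(npz_path) as z:
        arrays = {k: z[k] for k in z.files}
    if _payload_digest(arrays) != meta["payload_sha256"]:
        raise FormatError(f"fixture payload checksum mismatch for {npz_path}")
    g = meta["geometry"]
    geo = GridGeometry(tuple(g["origin"]), tuple(g["spacing"]), tuple(g["shape"]))
    structures = [
        RegionMask(
            geo,
            arrays[f"mask_{s['index']}"],
            Role(s["role"]),
            target_id=s["target_id"],
            name=s["name"],
        )
        for s in meta["structures"]
    ]
    labels = meta.get("grid_labels", {})
    delivered = (
        DoseGrid(geo, arrays["delivered"], label="delivered") if "delivered" in arrays else None
    )
    return PlanCase(
        case_id=meta["case_id"],
        site=Site(meta["site"]),
        tps_dose=DoseGrid(geo, arrays["tps"], label=labels.get("tps", "TPS")),
        secondary_dose=DoseGrid(geo, arrays["secondary"],
                                label=labels.get("secondary", "secondary")),
        structures=structures,
        isocentre=tuple(meta["isocentre"]),
        prescription_gy={int(k): float(v) for k, v in meta["prescription_gy"].items()},
        target_centroids={int(k): tuple(v) for k, v in meta["target_centroids"].items()},
        delivered_dose=delivered,
        fractions=int(meta["fractions"]),
        meta=meta.get("meta", {}),
    )
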
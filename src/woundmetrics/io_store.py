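"""Visit database and format I/O.

Each patient examination is stored under ``store_dir/patient_id/date/`` as a
JSON metadata file plus PLY mesh assets — a flat, auditable directory layout
keyed by patient ID and ISO date.  Writes go to a temporary directory that
is atomically renamed into place, so a crash mid-save never leaves a
half-written visit visible.
"""

from __future__ import annotations

import csv
import io
import json
import os
import shutil
import tempfile
from dataclasses import dataclass
from datetime import date as _date

import numpy as np
import trimesh

from .config import StoreError
from .som_mesh import QuadMesh
from .wound_params import WoundReport

_MESH_FILE = "mesh.ply"
_RECORD_FILE = "record.json"


@dataclass
class VisitRecord:
    """One examination: report + 3D assets, keyed by (patient_id, date)."""

    patient_id: str
    date: str  # ISO-8601
    report: WoundReport
    mesh: QuadMesh | None = None
    perimeter_points: np.ndarray | None = None   # (n, 3) mm
    tissue_labels: dict | None = None
    fiducials_3d: np.ndarray | None = None       # (n, 3) mm

    def __post_init__(self) -> None:
        _date.fromisoformat(self.date)  # validates ISO format

    @property
    def key(self) -> str:
        return f"{self.patient_id}/{self.date}"


def _arr(x):
    return None if x is None else np.asarray(x, float).tolist()


def save_visit(record: VisitRecord, store_dir: str, overwrite: bool = False
               ) -> str:
    """Persist a visit atomically; returns its ``patient_id/date`` key."""
    dest = os.path.join(store_dir, record.patient_id, record.date)
    if os.path.exists(dest) and not overwrite:
        raise StoreError(f"visit {record.key!r} already exists")
    os.makedirs(os.path.dirname(dest), exist_ok=True)
    tmp = tempfile.mkdtemp(dir=os.path.dirname(dest), prefix=".tmp-")
    try:
        payload = {
            "patient_id": record.patient_id,
            "date": record.date,
            "report": record.report.to_dict(),
            "perimeter_points": _arr(record.perimeter_points),
            "tissue_labels": record.tissue_labels,
            "fiducials_3d": _arr(record.fiducials_3d),
            "mesh_shape": list(record.mesh.shape) if record.mesh else None,
            "mesh_file": _MESH_FILE if record.mesh else None,
        }
        if record.mesh is not None:
            payload["mesh_vertices"] = record.mesh.points.tolist()
            record.mesh.export(os.path.join(tmp, _MESH_FILE))
        with open(os.path.join(tmp, _RECORD_FILE), "w") as fh:
            json.dump(payload, fh, indent=1)
        if os.path.exists(dest):
            shutil.rmtree(dest)
        os.replace(tmp, dest)
    except Exception:
        shutil.rmtree(tmp, ignore_errors=True)
        raise
    return record.key


def list_visits(store_dir: str, patient_id: str | None = None) -> list[str]:
    """All ``patient/date`` keys in the store, sorted."""
    keys = []
    if not os.path.isdir(store_dir):
        return keys
    patients = [patient_id] if patient_id else sorted(os.listdir(store_dir))
    for pid in patients:
        pdir = os.path.join(store_dir, pid)
        if not os.path.isdir(pdir):
            continue
        for d in sorted(os.listdir(pdir)):
            if os.path.isfile(os.path.join(pdir, d, _RECORD_FILE)):
                keys.append(f"{pid}/{d}")
    return keys


def load_visit(store_dir: str, patient_id: str, date: str = "latest"
               ) -> VisitRecord:
    """Load a visit; ``date`` may be ISO, ``"latest"``, or ``"previous:<iso>"``
    (the latest visit strictly before ``<iso>``)."""
    keys = list_visits(store_dir, patient_id)
    dates = [k.split("/", 1)[1] for k in keys]
    if not dates:
        raise StoreError(f"no visits for patient {patient_id!r}")
    if date == "latest":
        date = dates[-1]
    elif date.startswith("previous"):
        _, _, ref = date.partition(":")
        ref = ref or dates[-1]
        earlier = [d for d in dates if d < ref]
        if not earlier:
            raise StoreError(f"no visit before {ref} for {patient_id!r}")
        date = earlier[-1]
    vdir = os.path.join(store_dir, patient_id, date)
    rec_path = os.path.join(vdir, _RECORD_FILE)
    if not os.path.isfile(rec_path):
        raise StoreError(f"visit {patient_id}/{date} not found")
    with open(rec_path) as fh:
        payload = json.load(fh)

    mesh = None
    if payload.get("mesh_shape"):
        r, c = payload["mesh_shape"]
        verts = np.array(payload["mesh_vertices"]).reshape(r, c, 3)
        mesh = QuadMesh(vertices=verts)
        ply = os.path.join(vdir, payload["mesh_file"])
        try:
            trimesh.load(ply)
        except Exception as exc:
            raise StoreError(f"corrupt mesh asset {ply}: {exc}") from exc

    def opt(name):
        v = payload.get(name)
        return None if v is None else np.array(v, float)

    return VisitRecord(
        patient_id=payload["patient_id"], date=payload["date"],
        report=WoundReport.from_dict(payload["report"]), mesh=mesh,
        perimeter_points=opt("perimeter_points"),
        tissue_labels=payload.get("tissue_labels"),
        fiducials_3d=opt("fiducials_3d"))


_CSV_FIELDS = ["patient_id", "date", "depth_mm", "perimeter_mm", "area3d_mm2",
               "areaproj_mm2", "axis_major_mm", "axis_minor_mm", "volume_mm3"]


def export_report(record: VisitRecord, fmt: str = "json") -> str:
    """Serialize a visit's report as canonical JSON or a CSV row."""
    rep = record.report
    if fmt == "json":
        d = rep.to_dict()
        d["patient_id"] = record.patient_id
        d["date"] = record.date
        if d.get("tissue_fractions"):
            d["tissue_fractions"] = {k: round(v, 4)
                                     for k, v in d["tissue_fractions"].items()}
        return json.dumps(d, indent=1, sort_keys=True)
    if fmt == "csv":
        buf = io.StringIO()
        w = csv.DictWriter(buf, fieldnames=_CSV_FIELDS)
        w.writeheader()
        row = {k: getattr(rep, k) for k in _CSV_FIELDS[2:]}
        row.update(patient_id=record.patient_id, date=record.date)
        w.writerow(row)
        return buf.getvalue()
    raise StoreError(f"unknown export format {fmt!r}")
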
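"""Cohort bundle and results I/O.

A cohort is stored as one HDF5 container (``/patients/<i>/contours``,
``/patients/<i>/dose``, ``/patients/<i>/grades``) plus a JSON sidecar
echoing the generating :class:`~drmap.cohort.CohortSpec`; the toxicity table
exports to CSV.  Dose-surface maps export as 91-row x 90-column CSV with a
JSON metadata sidecar (organ, dose kind, run-length encoded validity).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .cohort import CohortSpec, SyntheticPatient
from .geometry import DoseGrid, DoseSurfaceMap, OrganContours
from .toxicity import ToxicityRecord

__all__ = [
    "save_cohort",
    "load_cohort",
    "toxicity_table",
    "save_dsm_csv",
    "load_dsm_csv",
]

_GRADE_NA = -1  # missing-grade sentinel inside the HDF5 container


def save_cohort(path, patients: list[SyntheticPatient],
                spec: CohortSpec | None = None) -> None:
    """Write a cohort bundle (HDF5 + JSON sidecar next to it)."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        grp = f.create_group("patients")
        for i, p in enumerate(patients):
            g = grp.create_group(str(i))
            c = g.create_group("contours")
            c.attrs["organ"] = p.contours.organ
            c.create_dataset("z", data=p.contours.z_positions)
            for j, (_, verts) in enumerate(p.contours.slices):
                c.create_dataset(f"slice_{j:03d}", data=verts)
            d = g.create_group("dose")
            d.create_dataset("values", data=p.dose.values)
            d.attrs["spacing"] = p.dose.spacing
            d.attrs["origin"] = p.dose.origin
            g.attrs["n_fractions"] = p.n_fractions
            g.attrs["truth_event_probability"] = p.truth_event_probability
            grades = np.array(
                [[(_GRADE_NA if v is None else v)
                  for v in (r.grade_baseline, r.grade_12m, r.grade_24m)]
                 for r in p.toxicity], dtype=int)
            tg = g.create_dataset("grades", data=grades)
            tg.attrs["endpoints"] = [r.endpoint for r in p.toxicity]
    if spec is not None:
        sidecar = dataclasses.asdict(spec)
        sidecar["planted_region"] = [list(rc) for rc in spec.planted_region]
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def load_cohort(path) -> list[SyntheticPatient]:
    """Read a cohort bundle written by :func:`save_cohort`."""
    patients = []
    with h5py.File(path, "r") as f:
        grp = f["patients"]
        for key in sorted(grp, key=int):
            g = grp[key]
            c = g["contours"]
            zs = c["z"][...]
            slices = tuple(
                (float(zs[j]), c[f"slice_{j:03d}"][...]) for j in range(len(zs)))
            contours = OrganContours(slices=slices, organ=c.attrs["organ"])
            d = g["dose"]
            dose = DoseGrid(values=d["values"][...],
                            spacing=tuple(d.attrs["spacing"]),
                            origin=tuple(d.attrs["origin"]))
            grades = g["grades"][...]
            endpoints = [s.decode() if isinstance(s, bytes) else s
                         for s in g["grades"].attrs["endpoints"]]
            records = tuple(
                ToxicityRecord(
                    endpoint=ep,
                    grade_baseline=None if row[0] == _GRADE_NA else int(row[0]),
                    grade_12m=None if row[1] == _GRADE_NA else int(row[1]),
                    grade_24m=None if row[2] == _GRADE_NA else int(row[2]),
                    patient_id=int(key))
                for ep, row in zip(endpoints, grades))
            patients.append(SyntheticPatient(
                contours=contours, dose=dose,
                n_fractions=int(g.attrs["n_fractions"]),
                toxicity=records,
                truth_event_probability=float(g.attrs["truth_event_probability"])))
    return patients


def toxicity_table(patients: list[SyntheticPatient]) -> pd.DataFrame:
    """Tidy toxicity table: patient_id, endpoint, grade_baseline/_12m/_24m."""
    rows = [
        (i, r.endpoint, r.grade_baseline, r.grade_12m, r.grade_24m)
        for i, p in enumerate(patients) for r in p.toxicity
    ]
    return pd.DataFrame(rows, columns=[
        "patient_id", "endpoint", "grade_baseline", "grade_12m", "grade_24m"])


def _rle(mask: np.ndarray) -> list[int]:
    """Run lengths of a flattened boolean mask, starting with a False run."""
    flat = np.asarray(mask, dtype=bool).ravel()
    runs, current, count = [], False, 0
    for v in flat:
        if v == current:
            count += 1
        else:
            runs.append(count)
            current, count = v, 1
    runs.append(count)
    return runs


def _unrle(runs: list[int], shape) -> np.ndarray:
    out = np.zeros(int(np.prod(shape)), dtype=bool)
    pos, val = 0, False
    for n in runs:
        out[pos:pos + n] = val
        pos += n
        val = not val
    return out.reshape(shape)


def save_dsm_csv(path, dsm: DoseSurfaceMap) -> None:
    """91x90 CSV (header = phi column indices) + JSON metadata sidecar."""
    path = Path(path)
    df = pd.DataFrame(dsm.doses, columns=[str(j) for j in range(dsm.doses.shape[1])])
    df.to_csv(path, index=False, float_format="%.6g")
    meta = {"organ": dsm.organ, "dose_kind": dsm.dose_kind,
            "valid_rle": _rle(dsm.valid), "shape": list(dsm.doses.shape)}
    path.with_suffix(".json").write_text(json.dumps(meta))


def load_dsm_csv(path) -> DoseSurfaceMap:
    path = Path(path)
    doses = pd.read_csv(path).to_numpy(dtype=float)
    meta = json.loads(path.with_suffix(".json").read_text())
    valid = _unrle(meta["valid_rle"], tuple(meta["shape"]))
    doses = np.where(valid, doses, np.nan)
    return DoseSurfaceMap(doses, valid, organ=meta["organ"],
                          dose_kind=meta["dose_kind"])
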
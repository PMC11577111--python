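"""NIfTI and tabular I/O.

Volumes and label maps are stored as NIfTI-1 with a diagonal affine built
from spacing and origin.  Displacement fields are 4D NIfTI (three mm
components on the last axis) with a JSON sidecar recording the warping
convention tag.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .containers import PULLBACK, DisplacementField, Grid, LabelVolume, Volume


def _affine(grid: Grid) -> np.ndarray:
    aff = np.eye(4)
    aff[:3, :3] = np.diag(grid.spacing)
    aff[:3, 3] = grid.origin
    return aff


def _grid_from_nifti(img) -> Grid:
    aff = img.affine
    spacing = tuple(np.abs(np.diag(aff)[:3]))
    origin = tuple(aff[:3, 3])
    return Grid(img.shape[:3], spacing, origin)


def write_volume(vol: Volume, path) -> Path:
    path = Path(path)
    nib.save(nib.Nifti1Image(np.asarray(vol.data, dtype=np.float64), _affine(vol.grid)), path)
    return path


def read_volume(path) -> Volume:
    img = nib.load(str(path))
    return Volume(np.asanyarray(img.dataobj, dtype=np.float64), _grid_from_nifti(img))


def write_labels(lab: LabelVolume, path) -> Path:
    path = Path(path)
    nib.save(nib.Nifti1Image(np.asarray(lab.data, dtype=np.int16), _affine(lab.grid)), path)
    sidecar = path.with_name(path.name.split(".")[0] + "_labels.json")
    sidecar.write_text(json.dumps({str(k): v for k, v in lab.labels.items()}, sort_keys=True))
    return path


def read_labels(path) -> LabelVolume:
    path = Path(path)
    img = nib.load(str(path))
    sidecar = path.with_name(path.name.split(".")[0] + "_labels.json")
    if sidecar.exists():
        labels = {int(k): v for k, v in json.loads(sidecar.read_text()).items()}
    else:
        labels = {int(v): f"label_{int(v)}" for v in np.unique(np.asanyarray(img.dataobj))}
    return LabelVolume(
        np.asanyarray(img.dataobj).astype(np.int16), _grid_from_nifti(img), labels
    )


def write_field(fieldv: DisplacementField, path) -> Path:
    path = Path(path)
    nib.save(nib.Nifti1Image(np.asarray(fieldv.data, dtype=np.float64), _affine(fieldv.grid)), path)
    sidecar = path.with_name(path.name.split(".")[0] + "_field.json")
    sidecar.write_text(json.dumps({"convention": fieldv.convention, "units": "mm"}))
    return path


def read_field(path) -> DisplacementField:
    path = Path(path)
    img = nib.load(str(path))
    sidecar = path.with_name(path.name.split(".")[0] + "_field.json")
    convention = PULLBACK
    if sidecar.exists():
        convention = json.loads(sidecar.read_text()).get("convention", PULLBACK)
    data = np.asanyarray(img.dataobj, dtype=np.float64)
    if data.ndim != 4 or data.shape[-1] != 3:
        raise ValueError(f"{path} is not a 3-component displacement field")
    return DisplacementField(data, _grid_from_nifti(img), convention)
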
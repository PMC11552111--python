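"""NIfTI volume / label-map I/O with metadata sidecars, and cohort CSV I/O.

Volumes are stored as NIfTI-1 in RAS+ orientation with float32 activity in
mCi/mL; acquisition metadata (injected dose in mCi, body weight in g,
modality) lives in a JSON sidecar next to the image (``name.json``).  Label
maps are uint8 NIfTI with the label-name mapping in their sidecar.  Round
trips preserve voxel data bit-exactly.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd

from .cohort import PatientRecord, records_to_dataframe
from .errors import ValidationError
from .quantify import LabelMap, PetVolume

__all__ = ["read_volume", "write_volume", "read_labelmap", "write_labelmap",
           "write_cohort_csv", "read_cohort_csv"]

_VOLUME_FIELDS = ("injected_dose_mci", "body_weight_g", "modality")


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".json")
    return path.with_suffix(".json")


def _affine(voxel_size: Sequence[float]) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = voxel_size
    return aff


def write_volume(volume: PetVolume, path: str | Path) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(volume.voxels, dtype=np.float32),
                          _affine(volume.voxel_size))
    img.header.set_xyzt_units(xyz="mm")
    nib.save(img, str(path))
    sidecar = _sidecar_path(path)
    sidecar.write_text(json.dumps({
        "injected_dose_mci": volume.injected_dose,
        "body_weight_g": volume.body_weight,
        "modality": volume.modality,
    }, indent=2))
    return path


def read_volume(path: str | Path) -> PetVolume:
    path = Path(path)
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several parse-error types
        raise ValidationError(f"cannot parse NIfTI volume {path}: {exc}") from exc
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise ValidationError(f"missing metadata sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    for f in _VOLUME_FIELDS:
        if f not in meta:
            raise ValidationError(f"sidecar {sidecar} lacks required field {f!r}")
    voxel_size = tuple(float(z) for z in img.header.get_zooms()[:3])
    return PetVolume(voxels=np.asarray(img.dataobj, dtype=np.float32),
                     voxel_size=voxel_size,
                     injected_dose=float(meta["injected_dose_mci"]),
                     body_weight=float(meta["body_weight_g"]),
                     modality=str(meta["modality"]))


def write_labelmap(labels: LabelMap, voxel_size: Sequence[float],
                   path: str | Path) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(labels.voxels, dtype=np.uint8),
                          _affine(voxel_size))
    nib.save(img, str(path))
    _sidecar_path(path).write_text(json.dumps({"labels": dict(labels.labels)},
                                              indent=2))
    return path


def read_labelmap(path: str | Path) -> LabelMap:
    path = Path(path)
    try:
        img = nib.load(str(path))
    except Exception as exc:
        raise ValidationError(f"cannot parse NIfTI label map {path}: {exc}") from exc
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise ValidationError(f"missing label sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    if "labels" not in meta:
        raise ValidationError(f"sidecar {sidecar} lacks required field 'labels'")
    return LabelMap(voxels=np.asarray(img.dataobj).astype(np.int32),
                    labels={str(k): int(v) for k, v in meta["labels"].items()})


def write_cohort_csv(records_or_df, path: str | Path) -> Path:
    df = (records_or_df if isinstance(records_or_df, pd.DataFrame)
          else records_to_dataframe(records_or_df))
    path = Path(path)
    df.to_csv(path, index=False)
    return path


def read_cohort_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
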
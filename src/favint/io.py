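"""File formats: NIfTI-1 volumes, events/cluster tables, configs, manifests."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Union

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .acquisition import AcquisitionSpec
from .containers import BoldDataset, ContrastImage

PathLike = Union[str, Path]

__all__ = [
    "save_bold",
    "load_bold",
    "save_contrast",
    "load_contrast",
    "save_mask",
    "load_mask",
    "save_events",
    "load_events",
    "save_table",
    "save_yaml",
    "load_yaml",
    "save_manifest",
]


def save_bold(bold: BoldDataset, path: PathLike, motion_path: Optional[PathLike] = None) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(bold.data.astype(np.float32), bold.affine)
    img.header["pixdim"][4] = bold.spec.tr
    img.to_filename(str(path))
    if motion_path is not None and bold.motion is not None:
        np.savetxt(motion_path, bold.motion, fmt="%.6f")
    return path


def load_bold(path: PathLike, spec: AcquisitionSpec, motion_path: Optional[PathLike] = None,
              subject_id: str = "sub-00") -> BoldDataset:
    img = nib.load(str(path))
    motion = np.loadtxt(motion_path) if motion_path is not None else None
    return BoldDataset(
        data=np.asarray(img.dataobj, dtype=float),
        spec=spec,
        motion=motion,
        subject_id=subject_id,
    )


def save_contrast(contrast: ContrastImage, path: PathLike, sidecar: bool = True,
                  **sidecar_fields) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(contrast.values.astype(np.float32), contrast.affine)
    img.header["descrip"] = contrast.name.encode()[:79]
    img.to_filename(str(path))
    if sidecar:
        meta = dict(subject=contrast.subject_id, contrast=contrast.name, **sidecar_fields)
        side = path.with_name(path.name.split(".")[0] + ".json")
        side.write_text(json.dumps(meta, indent=2, default=str))
    return path


def load_contrast(path: PathLike, name: str = "contrast", subject_id: str = "sub-00") -> ContrastImage:
    img = nib.load(str(path))
    side = Path(path).with_name(Path(path).name.split(".")[0] + ".json")
    if side.exists():
        meta = json.loads(side.read_text())
        name = meta.get("contrast", name)
        subject_id = meta.get("subject", subject_id)
    return ContrastImage(
        values=np.asarray(img.dataobj, dtype=float),
        affine=img.affine,
        name=name,
        subject_id=subject_id,
    )


def save_mask(mask: np.ndarray, affine: np.ndarray, path: PathLike) -> Path:
    path = Path(path)
    nib.Nifti1Image(np.asarray(mask, dtype=np.uint8), affine).to_filename(str(path))
    return path


def load_mask(path: PathLike) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.dataobj) > 0, img.affine


def save_events(events: pd.DataFrame, path: PathLike) -> Path:
    path = Path(path)
    events.to_csv(path, sep="\t", index=False)
    return path


def load_events(path: PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def save_table(table: pd.DataFrame, path: PathLike) -> Path:
    path = Path(path)
    table.to_csv(path, sep="\t", index=False, float_format="%.6g")
    return path


def _to_builtin(obj):
    """Recursively convert numpy scalars/arrays for YAML/JSON round-trips."""
    if isinstance(obj, dict):
        return {_to_builtin(k): _to_builtin(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_builtin(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def save_yaml(obj, path: PathLike) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump(_to_builtin(obj), sort_keys=False))
    return path


def load_yaml(path: PathLike):
    return yaml.safe_load(Path(path).read_text())


def save_manifest(path: PathLike, **fields) -> Path:
    path = Path(path)
    path.write_text(json.dumps(fields, indent=2, sort_keys=True, default=str))
    return path
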
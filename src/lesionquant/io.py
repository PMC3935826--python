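"""File I/O: NIfTI volumes, JSON/YAML sidecars, CSV tables."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml


def voxel_affine(voxel_size) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = voxel_size
    return aff


def save_nifti(path, data: np.ndarray, voxel_size) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if data.dtype == bool:
        data = data.astype(np.uint8)
    img = nib.Nifti1Image(np.asarray(data), voxel_affine(voxel_size))
    nib.save(img, str(path))


def load_nifti(path) -> tuple:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    voxel_size = tuple(float(z) for z in img.header.get_zooms()[:3])
    return data, voxel_size


class _Encoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, np.integer):
            return int(o)
        if isinstance(o, np.floating):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return dataclasses.asdict(o)
        return super().default(o)


def save_json(path, obj) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, cls=_Encoder) + "\n")


def load_json(path):
    return json.loads(Path(path).read_text())


def save_yaml(path, obj) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(yaml.safe_dump(obj, sort_keys=True))


def load_yaml(path):
    return yaml.safe_load(Path(path).read_text())


def save_subject(outdir, scan, truth=None, atlas=None) -> None:
    """Write one subject's volumes (and optional ground truth / atlas) as NIfTI
    plus a JSON inventory of the ground-truth lesions."""
    outdir = Path(outdir)
    vs = scan.voxel_size
    save_nifti(outdir / "pd.nii.gz", scan.pd, vs)
    save_nifti(outdir / "t2.nii.gz", scan.t2, vs)
    save_nifti(outdir / "t1.nii.gz", scan.t1, vs)
    save_nifti(outdir / "brain_mask.nii.gz", scan.brain_mask, vs)
    meta = {"subject_id": scan.subject_id, "protocol": scan.protocol,
            "voxel_size_mm": list(vs)}
    if atlas is not None:
        save_nifti(outdir / "atlas_labels.nii.gz", atlas.labels, vs)
        save_nifti(outdir / "atlas_tissue.nii.gz", atlas.tissue, vs)
    if truth is not None:
        save_nifti(outdir / "gt_t2_lesions.nii.gz", truth.t2_lesion_mask, vs)
        save_nifti(outdir / "gt_t1_lesions.nii.gz", truth.t1_lesion_mask, vs)
        save_nifti(outdir / "gt_bias_field.nii.gz", truth.true_bias_field, vs)
        meta["lesions"] = [dataclasses.asdict(r) for r in truth.lesions]
        meta["template_transform"] = truth.template_transform.tolist()
    save_json(outdir / "subject.json", meta)
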
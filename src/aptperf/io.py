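"""NIfTI and YAML I/O helpers."""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

__all__ = ["load_nifti", "save_nifti", "load_yaml", "save_yaml"]


def load_nifti(path):
    """Load a NIfTI volume as (data, affine)."""
    img = nib.load(str(path))
    return np.asarray(img.get_fdata()), img.affine


def save_nifti(data: np.ndarray, path, affine=None, descrip: str = ""):
    """Save an array as NIfTI; ``descrip`` annotates units in the header."""
    img = nib.Nifti1Image(np.asarray(data, np.float32),
                          affine if affine is not None else np.eye(4))
    if descrip:
        img.header["descrip"] = descrip.encode()[:79]
    nib.save(img, str(path))


def load_yaml(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def save_yaml(obj: dict, path):
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=False)
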
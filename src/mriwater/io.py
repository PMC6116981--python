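"""NIfTI and configuration file I/O."""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

__all__ = ["read_volume", "write_volume", "load_config_file", "save_config_file"]


def read_volume(path) -> tuple[np.ndarray, np.ndarray]:
    """Load a NIfTI volume; returns (data, affine).

    Raises
    ------
    IOError
        With a descriptive message when the file is missing or malformed.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"volume not found: {path}")
    try:
        img = nib.load(str(path))
    except Exception as exc:
        raise IOError(f"cannot read NIfTI volume {path}: {exc}") from exc
    return np.asarray(img.dataobj, dtype=np.float64), img.affine


def write_volume(data: np.ndarray, affine: np.ndarray, path) -> None:
    """Write a volume as NIfTI-1, preserving the affine."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float64), np.asarray(affine)), str(path))


def load_config_file(path) -> dict:
    path = Path(path)
    if not path.exists():
        raise IOError(f"config not found: {path}")
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise IOError(f"config {path} did not parse to a mapping")
    return cfg


def save_config_file(cfg: dict, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
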
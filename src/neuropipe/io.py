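"""File-format helpers: NIfTI volumes, 4x4 affine text matrices, tables."""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np


def save_nifti(path: str | Path, data: np.ndarray,
               affine: np.ndarray | None = None) -> None:
    if affine is None:
        affine = np.eye(4)
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32)
                          if data.dtype != bool
                          else data.astype(np.uint8), affine)
    nib.save(img, str(path))


def load_nifti(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.get_fdata()), img.affine


def save_affine_text(path: str | Path, affine: np.ndarray) -> None:
    """Write a 4x4 affine as 4 whitespace-delimited lines (FLIRT dialect)."""
    np.savetxt(str(path), np.asarray(affine, dtype=float), fmt="%.10f")


def load_affine_text(path: str | Path) -> np.ndarray:
    mat = np.loadtxt(str(path))
    if mat.shape != (4, 4):
        raise ValueError(f"expected a 4x4 matrix in {path}, got {mat.shape}")
    return mat
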
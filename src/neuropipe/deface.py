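"""Structural-image defacing by linear back-projection of box masks.

Face and ear regions are defined as axis-aligned boxes in a standard
coordinate space, entirely outside the standard-space brain.  Only the
linear (affine) transform between native and standard space is used to
back-project the boxes onto the native grid, where voxels under the
rasterised mask are zeroed.  A brain-overlap audit counts voxels shared
between the defacing mask and the (non-defaced) brain mask.

Rasterisation rule: a voxel is masked iff its world-space centre maps
inside any box, with half-open bounds (min inclusive, max exclusive) so
that boxes sharing a face never double-count.  Coordinates are world mm
in RAS+ convention; voxel indices are 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "DefaceBox",
    "DefaceBoxes",
    "default_phantom_boxes",
    "build_deface_mask",
    "apply_deface",
    "overlap_report",
]

BOX_TAGS = ("eyes", "nose", "mouth", "ear_left", "ear_right")


@dataclass(frozen=True)
class DefaceBox:
    """One axis-aligned box in standard space, corners in mm."""

    tag: str
    minimum: tuple[float, float, float]
    maximum: tuple[float, float, float]

    def __post_init__(self):
        if any(mx <= mn for mn, mx in zip(self.minimum, self.maximum)):
            raise ValueError(f"degenerate box {self.tag}: min must be < max")


@dataclass(frozen=True)
class DefaceBoxes:
    boxes: tuple[DefaceBox, ...]

    def __iter__(self):
        return iter(self.boxes)


def default_phantom_boxes() -> DefaceBoxes:
    """Face/ear boxes for the shipped phantom space.

    The phantom brain is an ellipsoid of semi-axes (58, 72, 56) mm centred
    at the origin (x right, y anterior, z superior).  The boxes sit
    anterior-inferior (eyes, nose, mouth) and lateral-inferior (ears),
    entirely outside that ellipsoid.
    """
    return DefaceBoxes(boxes=(
        DefaceBox("eyes", (-35.0, 77.0, -35.0), (35.0, 100.0, -5.0)),
        DefaceBox("nose", (-15.0, 72.0, -65.0), (15.0, 100.0, -28.0)),
        DefaceBox("mouth", (-25.0, 58.0, -100.0), (25.0, 100.0, -58.0)),
        DefaceBox("ear_left", (-110.0, -30.0, -70.0), (-61.0, 30.0, -20.0)),
        DefaceBox("ear_right", (61.0, -30.0, -70.0), (110.0, 30.0, -20.0)),
    ))


def build_deface_mask(boxes: DefaceBoxes, affine_std_to_native: np.ndarray,
                      grid_shape: tuple[int, int, int],
                      native_affine: np.ndarray) -> np.ndarray:
    """Rasterise standard-space boxes onto the native voxel grid.

    ``affine_std_to_native`` maps standard-space mm to native-space mm;
    ``native_affine`` maps native voxel indices to native mm.  Each voxel
    centre is mapped back to standard space through the inverse of the
    standard-to-native affine, and tested against the half-open boxes.
    Only the linear transform is ever used.
    """
    A = np.asarray(affine_std_to_native, dtype=float)
    if A.shape != (4, 4):
        raise ValueError("affine must be 4x4")
    det = np.linalg.det(A[:3, :3])
    if abs(det) < 1e-12:
        raise np.linalg.LinAlgError("singular standard-to-native affine")
    native_to_std = np.linalg.inv(A)

    nx, ny, nz = grid_shape
    ii, jj, kk = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz),
                             indexing="ij")
    vox = np.stack([ii.ravel(), jj.ravel(), kk.ravel(),
                    np.ones(ii.size)], axis=0)
    world_native = np.asarray(native_affine, dtype=float) @ vox
    world_std = native_to_std @ world_native
    xs, ys, zs = world_std[0], world_std[1], world_std[2]

    mask = np.zeros(ii.size, dtype=bool)
    for box in boxes:
        mn, mx = box.minimum, box.maximum
        mask |= ((xs >= mn[0]) & (xs < mx[0])
                 & (ys >= mn[1]) & (ys < mx[1])
                 & (zs >= mn[2]) & (zs < mx[2]))
    return mask.reshape(grid_shape)


def apply_deface(volume: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Zero voxels under the mask; every other voxel is bit-identical."""
    if volume.shape != mask.shape:
        raise ValueError(
            f"grid mismatch: volume {volume.shape} vs mask {mask.shape}")
    out = volume.copy()
    out[mask.astype(bool)] = 0
    return out


def overlap_report(brain_mask: np.ndarray, deface_mask: np.ndarray) -> dict:
    """Exact voxel overlap between brain and defacing masks."""
    if brain_mask.shape != deface_mask.shape:
        raise ValueError("grid mismatch between brain mask and deface mask")
    brain = brain_mask.astype(bool)
    overlap = int(np.count_nonzero(brain & deface_mask.astype(bool)))
    n_brain = int(np.count_nonzero(brain))
    return {
        "overlap_voxels": overlap,
        "brain_voxels": n_brain,
        "overlap_fraction": overlap / n_brain if n_brain else float("nan"),
    }
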
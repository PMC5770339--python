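"""Selection of the best b=0 volume for fieldmap estimation.

From a series of co-aligned b=0 volumes, the volume that best correlates
with all the others (mean of its off-diagonal Pearson correlations) is
selected.  Because the chosen volume defines the reference space for the
subsequent distortion-correction steps, and the first b=0 is acquired
closest in time to the fMRI and the first diffusion-weighted volume, a
selection bias towards the first volume applies: if its mean correlation
to the others reaches the threshold (default 0.98) it is selected even
when a later volume scores higher.  AP and PA series are selected
independently with the same rule, then paired.

Alignment is pluggable: volumes may be pre-aligned by any rigid-body
tool; the built-in helper searches integer translations only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "B0SelectionParams",
    "align_translation",
    "correlation_matrix",
    "select_best_b0",
    "find_b0_indices",
]


@dataclass(frozen=True)
class B0SelectionParams:
    """First-volume preference threshold (correlation) and switch."""

    first_volume_threshold: float = 0.98
    prefer_first: bool = True

    def __post_init__(self):
        if not (0.0 < self.first_volume_threshold <= 1.0):
            raise ValueError("threshold must be in (0, 1]")


def find_b0_indices(bvals, b0_max: float = 50.0) -> list[int]:
    """Indices of b=0 volumes in a b-value table (b <= 50 counts as b=0)."""
    bvals = np.asarray(bvals, dtype=float).ravel()
    return [int(i) for i in np.nonzero(bvals <= b0_max)[0]]


def align_translation(reference: np.ndarray, volume: np.ndarray,
                      max_shift: int = 2) -> np.ndarray:
    """Integer-shift alignment maximising correlation with the reference.

    A desk-scale stand-in for 6-DOF rigid registration; the selection
    interface accepts pre-aligned volumes so a full registration tool can
    be substituted.
    """
    best, best_r = volume, -np.inf
    for dx in range(-max_shift, max_shift + 1):
        for dy in range(-max_shift, max_shift + 1):
            for dz in range(-max_shift, max_shift + 1):
                shifted = np.roll(volume, (dx, dy, dz), axis=(0, 1, 2))
                r = np.corrcoef(reference.ravel(), shifted.ravel())[0, 1]
                if r > best_r:
                    best_r, best = r, shifted
    return best


def correlation_matrix(volumes: list[np.ndarray],
                       mask: np.ndarray | None = None) -> np.ndarray:
    """Pairwise Pearson correlation of co-aligned volumes over mask voxels."""
    if len(volumes) < 2:
        raise ValueError("need at least 2 volumes")
    shape = volumes[0].shape
    if any(v.shape != shape for v in volumes):
        raise ValueError("all volumes must share one grid")
    if mask is None:
        data = np.stack([v.ravel() for v in volumes])
    else:
        m = mask.astype(bool)
        data = np.stack([v[m] for v in volumes])
    stds = data.std(axis=1)
    for i, s in enumerate(stds):
        if s == 0:
            raise ValueError(f"volume {i} is constant; correlation undefined")
    corr = np.corrcoef(data)
    np.fill_diagonal(corr, 1.0)
    return corr


def select_best_b0(volumes: list[np.ndarray],
                   params: B0SelectionParams = B0SelectionParams(),
                   mask: np.ndarray | None = None
                   ) -> tuple[int, np.ndarray]:
    """Select the b=0 volume that best correlates with all others.

    score(i) = mean of the off-diagonal correlations of volume i.  With
    the first-volume preference on, index 0 is selected whenever
    score(0) >= threshold (boundary inclusive); otherwise the argmax of
    the scores wins, ties broken by the lowest index.

    Returns ``(selected_index, score_vector)``.
    """
    corr = correlation_matrix(volumes, mask=mask)
    n = corr.shape[0]
    scores = (corr.sum(axis=1) - 1.0) / (n - 1)
    if params.prefer_first and scores[0] >= params.first_volume_threshold:
        return 0, scores
    return int(np.argmax(scores)), scores
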
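"""Susceptibility-weighted MRI processing.

The chain: per-coil high-pass phase filtering, complex coil combination,
vein-enhanced (venogram) reconstruction from the phase, R2*/T2*
relaxometry from the two-echo magnitude decay, in-plane median filtering
with hole-filling dilation, and per-structure median T2* summaries.

Phase filtering is homodyne-style: the complex image is divided by a
Gaussian-smoothed copy of itself, leaving only the phase structure finer
than the kernel.  The venogram multiplies the magnitude by a power of a
phase-derived mask: diamagnetic phase (opposite the configured
paramagnetic sign) leaves the magnitude untouched, while paramagnetic
phase up to pi suppresses it as (1 - phi/pi)**exponent — the classic
fourth-power vein mask at the default exponent 4.

R2* comes from the log-ratio of the two echo magnitudes scaled by the
echo-time difference; T2* is its inverse.  Voxels where the inversion is
undefined (non-positive magnitudes, or no decay between echoes) are
flagged missing and later filled by the limited dilation step.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .phantom import SwmriAcquisition

__all__ = [
    "VenogramParams",
    "highpass_phase",
    "combine_coils",
    "venogram",
    "r2star_t2star",
    "filter_t2star",
    "roi_median_t2star",
]


@dataclass(frozen=True)
class VenogramParams:
    """Vein-mask configuration: mask exponent (default 4), paramagnetic
    phase sign convention (+1: positive phase is paramagnetic), and the
    clamp value in radians."""

    exponent: int = 4
    paramagnetic_sign: int = 1
    phase_clamp: float = np.pi

    def __post_init__(self):
        if self.exponent < 1:
            raise ValueError("mask exponent must be >= 1")
        if self.paramagnetic_sign not in (-1, 1):
            raise ValueError("paramagnetic sign must be +1 or -1")


def highpass_phase(complex_image: np.ndarray, kernel_size: int = 33) -> np.ndarray:
    """High-pass filter one coil's phase by complex division.

    The complex image is divided (in phase) by a Gaussian low-pass of
    itself; smoothing acts in-plane (first two axes) with sigma =
    kernel_size / 6 voxels so the kernel support spans roughly
    ``kernel_size`` voxels.  Output phase lies in (-pi, pi]; voxels of
    zero magnitude get phase 0.
    """
    if kernel_size < 3 or kernel_size % 2 == 0:
        raise ValueError("kernel size must be odd and >= 3")
    img = np.asarray(complex_image, dtype=complex)
    sigma = kernel_size / 6.0
    sigmas = [sigma, sigma] + [0.0] * (img.ndim - 2)
    low = ndimage.gaussian_filter(img.real, sigmas) \
        + 1j * ndimage.gaussian_filter(img.imag, sigmas)
    ratio = img * np.conj(low)
    phase = np.angle(ratio)
    phase[np.abs(img) == 0] = 0.0
    return phase


def combine_coils(acq: SwmriAcquisition,
                  filtered_phases: list[list[np.ndarray]]
                  ) -> tuple[list[np.ndarray], np.ndarray]:
    """Combine coils per echo from unfiltered magnitude and filtered phase.

    Per echo, the combined complex image is the coil sum of
    ``|image| * exp(i * filtered_phase)``.  Returns the combined magnitude
    for each echo and the final phase, taken from the second echo (which
    carries the greater venous contrast).
    """
    acq.validate()
    if len(filtered_phases) != acq.n_coils \
            or any(len(p) != 2 for p in filtered_phases):
        raise ValueError("need one filtered phase per coil per echo")
    shape = acq.data[0][0].shape
    magnitudes = []
    combined_echo2 = None
    for e in range(2):
        combined = np.zeros(shape, dtype=complex)
        for c in range(acq.n_coils):
            img, ph = acq.data[c][e], filtered_phases[c][e]
            if img.shape != shape or ph.shape != shape:
                raise ValueError("grid mismatch between coils/echoes")
            combined += np.abs(img) * np.exp(1j * ph)
        magnitudes.append(np.abs(combined))
        if e == 1:
            combined_echo2 = combined
    final_phase = np.angle(combined_echo2)
    return magnitudes, final_phase


def venogram(magnitude_te2: np.ndarray, final_phase: np.ndarray,
             params: VenogramParams = VenogramParams()) -> np.ndarray:
    """Vein-enhanced image from second-echo magnitude and phase.

    With s the paramagnetic sign and phi' = clamp(s*phase, 0, clamp):
    mask = (1 - phi'/pi) ** exponent, applied multiplicatively.
    Diamagnetic voxels (s*phase <= 0) keep mask 1 — their magnitude is
    untouched; maximal paramagnetic phase (pi) fully suppresses signal.
    """
    if magnitude_te2.shape != final_phase.shape:
        raise ValueError("magnitude and phase must share one grid")
    s = params.paramagnetic_sign
    phi = np.clip(s * np.asarray(final_phase, dtype=float),
                  0.0, params.phase_clamp)
    mask = (1.0 - phi / np.pi) ** params.exponent
    return np.asarray(magnitude_te2, dtype=float) * mask


def r2star_t2star(mag_te1: np.ndarray, mag_te2: np.ndarray,
                  te1: float, te2: float
                  ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Two-echo R2*/T2* estimation.

    R2* = ln(S1/S2) / (te2 - te1) reported in 1/s (echo times in ms);
    T2* = 1/R2* in ms.  Voxels with S1 <= 0, S2 <= 0 or S1 <= S2 (no
    decay — not invertible) are flagged missing and set to NaN.

    Returns ``(r2star_per_s, t2star_ms, missing_mask)``.
    """
    if te2 <= te1:
        raise ValueError("need te2 > te1")
    s1 = np.asarray(mag_te1, dtype=float)
    s2 = np.asarray(mag_te2, dtype=float)
    if s1.shape != s2.shape:
        raise ValueError("echo images must share one grid")
    missing = (s1 <= 0) | (s2 <= 0) | (s1 <= s2)
    valid = ~missing
    r2_per_ms = np.full(s1.shape, np.nan)
    r2_per_ms[valid] = np.log(s1[valid] / s2[valid]) / (te2 - te1)
    t2star_ms = np.full(s1.shape, np.nan)
    t2star_ms[valid] = 1.0 / r2_per_ms[valid]
    r2star_per_s = r2_per_ms * 1000.0
    return r2star_per_s, t2star_ms, missing


_NEIGHBOURS_2D = [(di, dj) for di in (-1, 0, 1) for dj in (-1, 0, 1)]


def _shift_stack(vol: np.ndarray, offsets) -> np.ndarray:
    """Stack in-plane shifted copies (NaN padding) along a new first axis."""
    stack = np.full((len(offsets),) + vol.shape, np.nan)
    nx, ny = vol.shape[0], vol.shape[1]
    for k, (di, dj) in enumerate(offsets):
        src_i = slice(max(0, -di), min(nx, nx - di))
        src_j = slice(max(0, -dj), min(ny, ny - dj))
        dst_i = slice(max(0, di), min(nx, nx + di))
        dst_j = slice(max(0, dj), min(ny, ny + dj))
        stack[(k, dst_i, dst_j)] = vol[src_i, src_j]
    return stack


def filter_t2star(t2star: np.ndarray, missing: np.ndarray,
                  n_dilation_passes: int = 2
                  ) -> tuple[np.ndarray, np.ndarray]:
    """3x3x1 in-plane median filter plus limited hole-filling dilation.

    The median at each voxel is taken over the non-missing members of its
    in-plane 3x3 neighbourhood (the through-plane axis has size 1 because
    of the anisotropic slice thickness).  Then up to
    ``n_dilation_passes`` passes assign each still-missing voxel the
    median of its non-missing in-plane 8-neighbourhood; voxels that
    remain unfilled stay flagged missing (NaN).

    Returns ``(filtered, still_missing)``.
    """
    vals = np.asarray(t2star, dtype=float).copy()
    miss = np.asarray(missing, dtype=bool)
    vals[miss] = np.nan

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        med = np.nanmedian(_shift_stack(vals, _NEIGHBOURS_2D), axis=0)
    out = np.where(miss, np.nan, med)
    # A valid voxel whose whole neighbourhood is missing keeps its value.
    lonely = ~miss & np.isnan(out)
    out[lonely] = vals[lonely]

    ring = [o for o in _NEIGHBOURS_2D if o != (0, 0)]
    for _ in range(n_dilation_passes):
        still = np.isnan(out)
        if not still.any():
            break
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            fill = np.nanmedian(_shift_stack(out, ring), axis=0)
        out[still] = fill[still]
    return out, np.isnan(out)


def roi_median_t2star(t2star_filtered: np.ndarray,
                      labels: np.ndarray,
                      label_names: dict[int, str] | None = None) -> pd.DataFrame:
    """Median T2* (ms) per labelled structure, over non-missing voxels.

    Labels with no valid voxels are omitted from the table.
    """
    if t2star_filtered.shape != labels.shape:
        raise ValueError("T2* map and label map must share one grid")
    rows = []
    for lab in np.unique(labels):
        if lab == 0:
            continue
        vals = t2star_filtered[labels == lab]
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            continue
        name = label_names.get(int(lab), str(int(lab))) if label_names \
            else str(int(lab))
        rows.append({"label": int(lab), "structure": name,
                     "median_t2star_ms": float(np.median(vals)),
                     "n_voxels": int(vals.size)})
    return pd.DataFrame(rows, columns=["label", "structure",
                                       "median_t2star_ms", "n_voxels"])
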
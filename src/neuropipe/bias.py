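"""Bias-field transfer and the white-matter intensity IQR statistic.

A multiplicative intensity bias field estimated on one structural
contrast (the T1) is divided out of another (the T2 FLAIR) acquired in
the same session, exploiting the fact that receive-field inhomogeneity
is largely shared between back-to-back acquisitions.  Normalisation
quality is quantified by the inter-quartile range of white-matter
intensities: WM is nearly homogeneous tissue, so a tighter (smaller)
IQR after correction means a flatter residual bias.

The IQR statistic is unit-free: WM intensities are rescaled by their
median before the Q3 - Q1 spread is taken, with linear-interpolation
quantiles.
"""

from __future__ import annotations

import numpy as np

__all__ = ["apply_bias_correction", "wm_intensity_iqr"]


def apply_bias_correction(volume: np.ndarray, bias: np.ndarray,
                          mask: np.ndarray) -> np.ndarray:
    """Divide the multiplicative bias field out of ``volume`` inside ``mask``.

    Voxels outside the mask are returned unchanged.  Raises if the bias
    field is not strictly positive anywhere inside the mask.
    """
    if volume.shape != bias.shape or volume.shape != mask.shape:
        raise ValueError("volume, bias and mask must share one grid")
    m = mask.astype(bool)
    if np.any(bias[m] <= 0):
        raise ValueError("bias field must be strictly positive inside the mask")
    out = volume.astype(float).copy()
    out[m] = volume[m] / bias[m]
    return out


def wm_intensity_iqr(volume: np.ndarray, wm_mask: np.ndarray) -> float:
    """Median-rescaled inter-quartile range of white-matter intensities.

    Intensities under the WM mask are divided by their median, then
    IQR = Q3 - Q1 with linear-interpolation quantiles.  Invariant to a
    global intensity scaling; 0 for constant WM.
    """
    if volume.shape != wm_mask.shape:
        raise ValueError("volume and WM mask must share one grid")
    vals = np.asarray(volume, dtype=float)[wm_mask.astype(bool)]
    if vals.size < 4:
        raise ValueError("need at least 4 white-matter voxels for an IQR")
    med = np.median(vals)
    if med == 0:
        raise ValueError("white-matter median intensity is zero")
    scaled = vals / med
    q1, q3 = np.percentile(scaled, [25.0, 75.0])
    return float(q3 - q1)
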
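"""Resting- and task-fMRI numerics: temporal filtering, incremental
group PCA, dual regression, network matrices and ROI summaries.

The resting-state chain: each subject's timeseries is highpass filtered
(Gaussian-weighted least-squares straight-line fitting, sigma 50 s),
demeaned and variance normalised; group PCA is computed incrementally
(MIGP) so the concatenated group data never has to be held in memory;
group spatial maps are regressed onto each subject's data (dual
regression stage 1) to give one timeseries per map ("node"); artefactual
node timeseries are regressed out of the others and discarded, leaving
Dg nodes; full-correlation and L2-regularised (ridge, rho = 0.5)
partial-correlation netmats are formed, converted from r to z with an
empirical temporal-autocorrelation correction, and unwrapped column-wise
above the diagonal into a vector of Dg(Dg-1)/2 values.

The task chain contributes Gaussian spatial smoothing (FWHM in mm) and
ROI activation summaries: median and 90th percentile of percent signal
change (relative to the overall-image-mean baseline) and of the
z-statistic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "HighpassParams",
    "MigpParams",
    "NetmatParams",
    "NetmatResult",
    "highpass_filter",
    "normalise_ts",
    "migp",
    "dual_regression_stage1",
    "clean_nodes",
    "full_netmat",
    "partial_netmat_ridge",
    "r_to_z",
    "unwrap_netmat",
    "rewrap_netmat",
    "gaussian_smooth",
    "roi_activation_summary",
]

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class HighpassParams:
    """Highpass cutoff sigma in seconds and the repetition time."""

    sigma: float = 50.0
    tr: float = 0.735

    def __post_init__(self):
        if self.sigma <= 0 or self.tr <= 0:
            raise ValueError("sigma and tr must be positive")


@dataclass(frozen=True)
class MigpParams:
    """Number of group components kept and the internal working dimension
    (defaults to twice the kept components)."""

    n_components: int
    working_dim: int | None = None

    def resolved_working_dim(self) -> int:
        w = self.working_dim if self.working_dim is not None \
            else 2 * self.n_components
        if w < self.n_components:
            raise ValueError("working dimension must be >= components kept")
        return w


@dataclass(frozen=True)
class NetmatParams:
    """Group dimensionality D, artefact node ids (0-based) and ridge rho."""

    n_nodes: int
    artifact_ids: tuple[int, ...] = ()
    rho: float = 0.5

    def __post_init__(self):
        if self.rho < 0:
            raise ValueError("rho must be >= 0")

    @property
    def dg(self) -> int:
        return self.n_nodes - len(self.artifact_ids)


@dataclass
class NetmatResult:
    """Node timeseries plus full/partial netmats and the z vector."""

    node_ts: np.ndarray          # T x Dg
    full: np.ndarray             # Dg x Dg, unit diagonal
    partial: np.ndarray          # Dg x Dg, zero diagonal
    z_full_vector: np.ndarray    # Dg(Dg-1)/2
    z_partial_vector: np.ndarray


def highpass_filter(ts: np.ndarray, params: HighpassParams) -> np.ndarray:
    """Gaussian-weighted least-squares straight-line highpass filter.

    At each timepoint a straight line (intercept + slope) is fitted to
    the full series with Gaussian weights of standard deviation
    sigma/tr samples centred on that timepoint, and its fitted value is
    subtracted; each column's grand mean is added back.  Removes slow
    drifts while preserving fluctuations much faster than sigma.
    """
    x = np.asarray(ts, dtype=float)
    one_d = x.ndim == 1
    if one_d:
        x = x[:, None]
    T = x.shape[0]
    if T < 3:
        raise ValueError("need at least 3 timepoints")
    sig = params.sigma / params.tr
    t = np.arange(T, dtype=float)

    # Row k of the smoother matrix evaluates the weighted line fit at k.
    S = np.empty((T, T))
    for k in range(T):
        d = t - k
        w = np.exp(-0.5 * (d / sig) ** 2)
        sw, swd, swd2 = w.sum(), (w * d).sum(), (w * d * d).sum()
        det = sw * swd2 - swd ** 2
        # fitted value at centre = beta0 of the (1, d) design
        S[k] = (swd2 * w - swd * (w * d)) / det
    filtered = x - S @ x + x.mean(axis=0, keepdims=True)
    return filtered[:, 0] if one_d else filtered


def normalise_ts(ts: np.ndarray) -> np.ndarray:
    """Demean and variance-normalise each column (zero mean, unit std).

    Zero-variance columns carry no signal and are dropped with a warning.
    """
    x = np.asarray(ts, dtype=float)
    x = x - x.mean(axis=0, keepdims=True)
    std = x.std(axis=0)
    keep = std > 0
    if not keep.all():
        dropped = np.nonzero(~keep)[0].tolist()
        warnings.warn(f"dropping zero-variance columns {dropped}",
                      stacklevel=2)
    return x[:, keep] / std[keep]


def migp(subject_ts: list[np.ndarray], params: MigpParams) -> np.ndarray:
    """Incremental group PCA over subjects' (T x V) timeseries.

    Maintains a running stack W of weighted spatial eigenvectors.  For
    each subject, W is stacked with that subject's timeseries, the
    temporal covariance of the stack is eigen-decomposed, and the top
    ``working_dim`` weighted spatial eigenvectors are retained.  The
    final output is the top ``n_components`` rows — a close approximation
    to the PCA of all subjects' temporally concatenated data.
    """
    if not subject_ts:
        raise ValueError("need at least one subject")
    V = subject_ts[0].shape[1]
    if any(s.shape[1] != V for s in subject_ts):
        raise ValueError("all subjects must share the voxel dimension")
    wdim = params.resolved_working_dim()
    total_t = sum(s.shape[0] for s in subject_ts)
    if wdim > total_t:
        raise ValueError("working dimension exceeds total timepoints")

    W: np.ndarray | None = None
    for ts in subject_ts:
        A = ts if W is None else np.vstack([W, ts])
        k = min(wdim, A.shape[0])
        cov = A @ A.T
        vals, vecs = np.linalg.eigh(cov)
        order = np.argsort(vals)[::-1][:k]
        # Weighted spatial eigenvectors: rows are sigma_i * v_i^T.
        W = vecs[:, order].T @ A
    return W[:params.n_components]


def dual_regression_stage1(maps: np.ndarray, data: np.ndarray) -> np.ndarray:
    """Stage-1 dual regression: one timeseries per spatial map.

    Multiple spatial regression of all maps (components x V) against each
    row of the subject data (T x V) simultaneously:
    ``ts = data @ pinv(maps)``.
    """
    M = np.asarray(maps, dtype=float)
    if np.linalg.matrix_rank(M) < M.shape[0]:
        raise np.linalg.LinAlgError("spatial maps are rank deficient")
    return np.asarray(data, dtype=float) @ np.linalg.pinv(M)


def clean_nodes(node_ts: np.ndarray, artifact_ids) -> np.ndarray:
    """Regress artefact node timeseries out of the others, then drop them.

    Each non-artefact column is residualised (with intercept) against all
    artefact columns; the artefact columns are removed, leaving Dg nodes.
    """
    x = np.asarray(node_ts, dtype=float)
    ids = sorted(set(int(i) for i in artifact_ids))
    if not ids:
        return x.copy()
    if any(i < 0 or i >= x.shape[1] for i in ids):
        raise ValueError("artifact ids out of range")
    keep = [j for j in range(x.shape[1]) if j not in ids]
    conf = np.column_stack([np.ones(x.shape[0]), x[:, ids]])
    beta, *_ = np.linalg.lstsq(conf, x[:, keep], rcond=None)
    return x[:, keep] - conf @ beta


def full_netmat(node_ts: np.ndarray) -> np.ndarray:
    """Full normalised temporal correlation between all node pairs."""
    x = np.asarray(node_ts, dtype=float)
    if x.shape[1] < 2:
        raise ValueError("need at least 2 nodes")
    corr = np.corrcoef(x, rowvar=False)
    np.fill_diagonal(corr, 1.0)
    return corr


def partial_netmat_ridge(node_ts: np.ndarray, rho: float = 0.5) -> np.ndarray:
    """L2-regularised partial correlation between node timeseries.

    The node covariance is rescaled so the mean of its squared diagonal
    is 1 (the FSLNets ridge convention, making rho comparable across
    datasets), the precision (C + rho I)^-1 is formed, and partial
    correlations are read off as -P_ij / sqrt(P_ii P_jj) with a zero
    diagonal.
    """
    x = np.asarray(node_ts, dtype=float)
    if x.shape[1] < 2:
        raise ValueError("need at least 2 nodes")
    xc = x - x.mean(axis=0, keepdims=True)
    C = xc.T @ xc / (x.shape[0] - 1)
    C = C / np.sqrt(np.mean(np.diag(C) ** 2))
    P = np.linalg.inv(C + rho * np.eye(C.shape[0]))
    d = np.sqrt(np.diag(P))
    partial = -P / np.outer(d, d)
    np.fill_diagonal(partial, 0.0)
    return partial


def effective_df(node_ts: np.ndarray, max_lag: int | None = None) -> float:
    """Effective temporal degrees of freedom under autocorrelation.

    Bartlett-style correction: df_eff = T / (1 + 2 * sum_l rho_l^2) with
    rho_l the lag-l autocorrelation averaged over nodes, summed to
    L = min(T/4, 50) lags.  White-noise series give df_eff near T;
    autocorrelated series give strictly fewer effective samples.
    """
    x = np.asarray(node_ts, dtype=float)
    T = x.shape[0]
    if max_lag is None:
        max_lag = min(T // 4, 50)
    xc = x - x.mean(axis=0, keepdims=True)
    var = (xc ** 2).mean(axis=0)
    acc = 0.0
    for lag in range(1, max_lag + 1):
        rho_l = np.mean((xc[lag:] * xc[:-lag]).mean(axis=0) / var)
        acc += rho_l ** 2
    return T / (1.0 + 2.0 * acc)


def r_to_z(netmat: np.ndarray, node_ts: np.ndarray) -> np.ndarray:
    """Fisher r-to-z with empirical autocorrelation correction.

    z = arctanh(r) * sqrt(df_eff - 3), using the effective degrees of
    freedom from :func:`effective_df`.  The diagonal is set to 0.
    """
    r = np.asarray(netmat, dtype=float).copy()
    off = ~np.eye(r.shape[0], dtype=bool)
    if np.any(np.abs(r[off]) >= 1.0):
        raise ValueError("off-diagonal |r| must be < 1")
    df = effective_df(node_ts)
    z = np.zeros_like(r)
    z[off] = np.arctanh(r[off]) * np.sqrt(max(df - 3.0, 0.0))
    return z


def unwrap_netmat(matrix: np.ndarray) -> np.ndarray:
    """Column-wise unwrap of the strictly-upper triangle.

    Traversal order (1-based): (1,2), (1,3), (2,3), (1,4), (2,4), (3,4)…
    giving a vector of length n(n-1)/2.
    """
    m = np.asarray(matrix)
    if m.shape[0] != m.shape[1]:
        raise ValueError("matrix must be square")
    if not np.allclose(m, m.T, equal_nan=True):
        raise ValueError("matrix must be symmetric")
    n = m.shape[0]
    return np.concatenate([m[:j, j] for j in range(1, n)]) \
        if n > 1 else np.empty(0)


def rewrap_netmat(vector: np.ndarray, n: int, diagonal: float = 0.0) -> np.ndarray:
    """Inverse of :func:`unwrap_netmat` for a symmetric matrix."""
    v = np.asarray(vector, dtype=float)
    if v.size != n * (n - 1) // 2:
        raise ValueError("vector length does not match n(n-1)/2")
    out = np.full((n, n), diagonal)
    pos = 0
    for j in range(1, n):
        out[:j, j] = v[pos:pos + j]
        out[j, :j] = v[pos:pos + j]
        pos += j
    return out


def gaussian_smooth(volume: np.ndarray, fwhm_mm: float,
                    voxel_size) -> np.ndarray:
    """Separable spatial Gaussian smoothing of a 3D or 4D volume.

    sigma = fwhm / (2 sqrt(2 ln 2)) per axis, converted to voxel units;
    a 4th (time) axis is left unsmoothed.
    """
    if fwhm_mm <= 0:
        raise ValueError("fwhm must be positive")
    vol = np.asarray(volume, dtype=float)
    vox = np.broadcast_to(np.asarray(voxel_size, dtype=float), (3,))
    sigma_vox = [fwhm_mm * FWHM_TO_SIGMA / v for v in vox]
    if vol.ndim == 4:
        sigma_vox = sigma_vox + [0.0]
    elif vol.ndim != 3:
        raise ValueError("volume must be 3D or 4D")
    return ndimage.gaussian_filter(vol, sigma_vox)


def roi_activation_summary(effect_map: np.ndarray, z_map: np.ndarray,
                           roi_mask: np.ndarray,
                           baseline: float) -> dict[str, float]:
    """ROI summaries of activation effect size and statistical effect size.

    The effect is expressed as percent signal change relative to the
    overall-image-mean baseline; both it and the z-statistic are
    summarised by the median and the 90th percentile across ROI voxels
    (linear-interpolation percentiles).
    """
    roi = roi_mask.astype(bool)
    if not roi.any():
        raise ValueError("ROI mask is empty")
    if baseline == 0:
        raise ValueError("baseline must be nonzero")
    pct = 100.0 * effect_map[roi] / baseline
    z = z_map[roi]
    return {
        "percent_signal_median": float(np.percentile(pct, 50.0)),
        "percent_signal_p90": float(np.percentile(pct, 90.0)),
        "z_median": float(np.percentile(z, 50.0)),
        "z_p90": float(np.percentile(z, 90.0)),
    }
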
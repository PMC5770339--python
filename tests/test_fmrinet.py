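"""fMRI numerics: highpass, MIGP, dual regression, netmats, summaries."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neuropipe.fmrinet import (
    HighpassParams,
    MigpParams,
    clean_nodes,
    dual_regression_stage1,
    effective_df,
    full_netmat,
    gaussian_smooth,
    highpass_filter,
    migp,
    normalise_ts,
    partial_netmat_ridge,
    r_to_z,
    rewrap_netmat,
    roi_activation_summary,
    unwrap_netmat,
)
from neuropipe.phantom import generate_fmri_group


def _principal_angles(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Angles between the row spaces of two matrices."""
    qa, _ = np.linalg.qr(a.T)
    qb, _ = np.linalg.qr(b.T)
    s = np.linalg.svd(qa.T @ qb, compute_uv=False)
    return np.arccos(np.clip(s, -1.0, 1.0))


class TestHighpass:
    def test_linear_trend_is_removed_mean_preserved(self):
        T = 400
        t = np.arange(T, dtype=float)
        ts = 5.0 + 0.02 * t
        out = highpass_filter(ts, HighpassParams(sigma=50.0, tr=0.735))
        assert np.abs(out[20:-20] - ts.mean()).max() < 0.05
        assert out.mean() == pytest.approx(ts.mean(), rel=1e-3)

    def test_fast_oscillation_passes_through(self):
        T = 400
        params = HighpassParams(sigma=50.0, tr=0.735)
        t = np.arange(T) * params.tr
        fast = np.sin(2 * np.pi * t / 10.0)  # 10 s period << sigma
        out = highpass_filter(fast, params)
        interior = slice(50, -50)
        resid = out[interior] - fast[interior]
        assert np.abs(resid).max() < 0.05

    def test_columns_filtered_independently(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(200, 3))
        params = HighpassParams()
        out = highpass_filter(x, params)
        np.testing.assert_allclose(out[:, 1],
                                   highpass_filter(x[:, 1], params))

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError):
            highpass_filter(np.zeros(2), HighpassParams())


class TestNormalise:
    def test_zero_mean_unit_std(self):
        rng = np.random.default_rng(1)
        out = normalise_ts(rng.uniform(5, 10, (100, 4)))
        np.testing.assert_allclose(out.mean(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(out.std(axis=0), 1.0, atol=1e-12)

    def test_zero_variance_column_dropped_with_warning(self):
        x = np.random.default_rng(2).normal(size=(50, 3))
        x[:, 1] = 4.0
        with pytest.warns(UserWarning, match="zero-variance"):
            out = normalise_ts(x)
        assert out.shape == (50, 2)


class TestMigp:
    def test_single_subject_equals_batch_pca_subspace(self):
        rng = np.random.default_rng(3)
        ts = rng.normal(size=(60, 300))
        out = migp([ts], MigpParams(n_components=10))
        _, _, vt = np.linalg.svd(ts, full_matrices=False)
        assert _principal_angles(out, vt[:10]).max() < 1e-6

    def test_multi_subject_noiseless_matches_batch_pca(self):
        rng = np.random.default_rng(4)
        true_maps = rng.normal(size=(8, 500))
        subjects = [rng.normal(size=(40, 8)) @ true_maps for _ in range(5)]
        out = migp(subjects, MigpParams(n_components=8))
        concat = np.vstack(subjects)
        _, _, vt = np.linalg.svd(concat, full_matrices=False)
        assert _principal_angles(out, vt[:8]).max() < 1e-6

    def test_rows_ordered_by_decreasing_energy(self):
        rng = np.random.default_rng(5)
        ts = rng.normal(size=(50, 200))
        out = migp([ts], MigpParams(n_components=6))
        energies = np.linalg.norm(out, axis=1)
        assert (np.diff(energies) <= 1e-9).all()

    def test_validation(self):
        with pytest.raises(ValueError):
            migp([], MigpParams(n_components=2))
        with pytest.raises(ValueError):
            migp([np.zeros((10, 5)), np.zeros((10, 6))],
                 MigpParams(n_components=2))
        with pytest.raises(ValueError):
            MigpParams(n_components=5, working_dim=3).resolved_working_dim()


class TestDualRegression:
    def test_orthonormal_maps_invert_exactly(self):
        g = generate_fmri_group(1, 4, 60, np.eye(4), seed=6,
                                orthonormal_maps=True, noise_sigma=0.0)
        ts = dual_regression_stage1(g.maps, g.subject_data[0])
        np.testing.assert_allclose(ts, g.subject_ts[0], atol=1e-10)

    def test_rank_deficient_maps_rejected(self):
        maps = np.ones((3, 50))
        with pytest.raises(np.linalg.LinAlgError):
            dual_regression_stage1(maps, np.zeros((10, 50)))


class TestCleanNodes:
    def test_artifact_columns_removed_and_regressed_out(self):
        rng = np.random.default_rng(7)
        T = 2000
        art = rng.normal(size=(T, 1))
        clean = rng.normal(size=(T, 2))
        mixed = np.column_stack([clean[:, 0] + 2.0 * art[:, 0],
                                 art[:, 0],
                                 clean[:, 1]])
        out = clean_nodes(mixed, [1])
        assert out.shape == (T, 2)
        # residual of column 0 is orthogonal to the artefact series
        r = np.corrcoef(out[:, 0], art[:, 0])[0, 1]
        assert abs(r) < 1e-10

    def test_no_artifacts_is_identity(self):
        x = np.random.default_rng(8).normal(size=(30, 3))
        np.testing.assert_array_equal(clean_nodes(x, []), x)

    def test_out_of_range_ids_rejected(self):
        with pytest.raises(ValueError):
            clean_nodes(np.zeros((10, 3)), [3])


class TestNetmats:
    def test_full_netmat_is_corrcoef(self):
        x = np.random.default_rng(9).normal(size=(100, 5))
        np.testing.assert_allclose(full_netmat(x),
                                   np.corrcoef(x, rowvar=False), atol=1e-12)

    def test_ridge_partial_recovers_chain_structure(self):
        # x -> y -> z chain: full correlation links x and z, partial does not
        rng = np.random.default_rng(10)
        T = 10000
        x = rng.normal(size=T)
        y = x + rng.normal(size=T)
        z = y + rng.normal(size=T)
        ts = np.column_stack([x, y, z])
        full = full_netmat(ts)
        partial = partial_netmat_ridge(ts, rho=0.01)
        assert full[0, 2] > 0.3
        assert abs(partial[0, 2]) < 0.05
        assert partial[0, 1] > 0.3 and partial[1, 2] > 0.3

    def test_zero_rho_matches_unregularised_inverse(self):
        rng = np.random.default_rng(11)
        ts = rng.normal(size=(500, 4))
        partial = partial_netmat_ridge(ts, rho=0.0)
        xc = ts - ts.mean(axis=0)
        C = xc.T @ xc / (ts.shape[0] - 1)
        P = np.linalg.inv(C / np.sqrt(np.mean(np.diag(C) ** 2)))
        d = np.sqrt(np.diag(P))
        oracle = -P / np.outer(d, d)
        np.fill_diagonal(oracle, 0.0)
        np.testing.assert_allclose(partial, oracle, atol=1e-10)

    def test_partial_matrix_symmetric_zero_diagonal(self):
        ts = np.random.default_rng(12).normal(size=(200, 6))
        p = partial_netmat_ridge(ts)
        np.testing.assert_allclose(p, p.T, atol=1e-12)
        np.testing.assert_array_equal(np.diag(p), 0.0)


class TestEffectiveDf:
    def test_white_noise_df_near_t(self):
        ts = np.random.default_rng(13).normal(size=(500, 4))
        df = effective_df(ts)
        assert 0.9 * 500 < df <= 500 * 1.05

    def test_autocorrelation_strictly_reduces_df(self):
        rng = np.random.default_rng(14)
        T = 500
        ar = np.zeros((T, 2))
        eps = rng.normal(size=(T, 2))
        for t in range(1, T):
            ar[t] = 0.9 * ar[t - 1] + eps[t]
        assert effective_df(ar) < 0.5 * T


class TestRtoZ:
    def test_scaling_by_sqrt_df_minus_3(self):
        ts = np.random.default_rng(15).normal(size=(400, 3))
        r = full_netmat(ts)
        z = r_to_z(r, ts)
        df = effective_df(ts)
        off = ~np.eye(3, dtype=bool)
        np.testing.assert_allclose(
            z[off], np.arctanh(r[off]) * np.sqrt(df - 3.0), atol=1e-12)
        np.testing.assert_array_equal(np.diag(z), 0.0)

    def test_unit_correlation_rejected(self):
        r = np.ones((2, 2))
        with pytest.raises(ValueError):
            r_to_z(r, np.random.default_rng(16).normal(size=(50, 2)))


class TestUnwrap:
    def test_column_major_traversal_order(self):
        m = np.zeros((4, 4))
        vals = iter(range(1, 7))
        for j in range(1, 4):
            for i in range(j):
                m[i, j] = m[j, i] = next(vals)
        np.testing.assert_array_equal(unwrap_netmat(m), [1, 2, 3, 4, 5, 6])

    def test_21_nodes_give_210_values(self):
        rng = np.random.default_rng(17)
        a = rng.normal(size=(21, 21))
        m = (a + a.T) / 2
        assert unwrap_netmat(m).size == 210

    @settings(deadline=None, max_examples=20)
    @given(n=st.integers(min_value=2, max_value=12),
           seed=st.integers(min_value=0, max_value=10**6))
    def test_rewrap_inverts_unwrap(self, n, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=(n, n))
        m = (a + a.T) / 2
        np.fill_diagonal(m, 0.0)
        np.testing.assert_allclose(rewrap_netmat(unwrap_netmat(m), n), m)

    def test_asymmetric_matrix_rejected(self):
        m = np.zeros((3, 3))
        m[0, 1] = 1.0
        with pytest.raises(ValueError):
            unwrap_netmat(m)


class TestSmoothing:
    def test_total_signal_conserved(self):
        vol = np.zeros((20, 20, 20))
        vol[10, 10, 10] = 100.0
        out = gaussian_smooth(vol, fwhm_mm=5.0, voxel_size=2.0)
        assert out.sum() == pytest.approx(100.0, rel=1e-6)
        assert out.max() < 100.0

    def test_time_axis_untouched(self):
        rng = np.random.default_rng(18)
        vol = rng.normal(size=(10, 10, 10, 3))
        out = gaussian_smooth(vol, 5.0, 2.0)
        for t in range(3):
            np.testing.assert_allclose(
                out[..., t], gaussian_smooth(vol[..., t], 5.0, 2.0))

    def test_invalid_fwhm_rejected(self):
        with pytest.raises(ValueError):
            gaussian_smooth(np.zeros((4, 4, 4)), 0.0, 2.0)


class TestRoiSummary:
    def test_percentile_oracle(self):
        effect = np.zeros((10, 1, 1))
        effect[:, 0, 0] = np.arange(10.0)
        z = 2.0 * effect
        roi = np.ones_like(effect, dtype=bool)
        out = roi_activation_summary(effect, z, roi, baseline=100.0)
        assert out["percent_signal_median"] == pytest.approx(
            np.percentile(np.arange(10.0), 50))
        assert out["z_p90"] == pytest.approx(
            np.percentile(2.0 * np.arange(10.0), 90))

    def test_empty_roi_and_zero_baseline_rejected(self):
        e = np.ones((3, 3, 3))
        with pytest.raises(ValueError):
            roi_activation_summary(e, e, np.zeros_like(e, dtype=bool), 1.0)
        with pytest.raises(ValueError):
            roi_activation_summary(e, e, np.ones_like(e, dtype=bool), 0.0)
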
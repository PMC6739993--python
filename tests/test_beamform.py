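"""Delay law, subarray covariance, eigenstructure, DAS/MV/ESBMV, detection."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import ucpwi.beamform as bf
from ucpwi.beamform import (
    CovarianceEstimate,
    beamform_image,
    das,
    default_delta,
    delay_and_gather,
    diagonal_load,
    eigendecompose,
    envelope_detect,
    esbmv,
    log_compress,
    max_eigenvalue_map,
    mv,
    subarray_covariance,
    threshold_detect,
    _mv_weight,
)
from ucpwi.rf_sim import ChannelData, Phantom, ProbeGeometry, simulate_plane_wave_rx


@pytest.fixture(scope="module")
def point_frame():
    """Single point scatterer at (0, 20 mm), 128 elements, no noise."""
    g = ProbeGeometry()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return simulate_plane_wave_rx(
            Phantom(tissue_scatterers=[[0.0, 0.020, 1.0]]), g, seed=0, n_samples=1400
        )


class TestDelays:
    def test_on_axis_delay_reduces_to_two_way(self):
        """For the element directly above the pixel the delay is 2 z / c0."""
        g = ProbeGeometry(n_elements=2, pitch=1e-3)
        z = 0.01
        tab = bf.delay_table(g, g.element_x[0], np.array([z]))
        assert tab[0, 0] == pytest.approx(2 * z / g.c0 * g.fs, rel=1e-12)

    def test_pixel_at_scatterer_aligns_elements(self, point_frame):
        """Delayed element signals are time-aligned within one sample when
        the pixel column passes through the scatterer (cross-correlation
        lag against the central element)."""
        g = point_frame.geometry
        depths = np.linspace(0.0185, 0.0215, 301)
        X = bf.gather_line(point_frame, 0.0, depths)
        dz = depths[1] - depths[0]
        sample_z = g.c0 / (2 * g.fs)
        ref = X[:, 64]
        for e in (0, 32, 96, 127):
            xc = np.correlate(X[:, e], ref, mode="full")
            lag = (xc.argmax() - (len(ref) - 1)) * dz
            assert abs(lag) <= sample_z

    def test_silent_region_is_near_zero(self, point_frame):
        sig = delay_and_gather(point_frame, (0.0, 0.035))
        assert np.abs(sig.x_d).max() < 1e-6

    def test_out_of_window_flagged(self, point_frame):
        sig = delay_and_gather(point_frame, (0.0, 0.060))
        assert sig.out_of_window

    def test_nonpositive_depth_rejected(self, point_frame):
        with pytest.raises(ValueError):
            delay_and_gather(point_frame, (0.0, 0.0))


class TestSubarrayCovariance:
    def test_subarray_count_and_shape(self):
        """M = 128, L = 32 averages 97 sliding outer products."""
        rng = np.random.default_rng(0)
        v = rng.normal(size=128)
        est = subarray_covariance(v, 32)
        assert est.R.shape == (32, 32)
        sub = np.lib.stride_tricks.sliding_window_view(v, 32)
        assert sub.shape[0] == 97
        manual = sum(np.outer(s, s) for s in sub) / 97
        assert np.allclose(est.R, manual)

    def test_all_ones_gives_rank_one(self):
        est = subarray_covariance(np.ones(64), 16)
        assert np.allclose(est.R, 1.0)
        assert np.linalg.matrix_rank(est.R) == 1

    def test_full_length_subarray_is_outer_product(self):
        v = np.arange(8.0)
        est = subarray_covariance(v, 8)
        assert np.allclose(est.R, np.outer(v, v))

    def test_invalid_length_rejected(self):
        with pytest.raises(ValueError):
            subarray_covariance(np.ones(16), 17)

    def test_hermitian_by_construction(self):
        v = np.random.default_rng(1).normal(size=48)
        est = subarray_covariance(v, 12)
        assert np.allclose(est.R, est.R.T)


class TestDiagonalLoading:
    def test_identity_with_delta_one_over_L(self):
        est = diagonal_load(np.eye(4), delta=0.25)
        assert est.epsilon == pytest.approx(1.0)
        assert np.allclose(est.R, 2 * np.eye(4))

    def test_zero_trace_is_noop(self):
        est = diagonal_load(np.zeros((8, 8)))
        assert est.epsilon == 0.0
        assert np.allclose(est.R, 0.0)

    def test_eigenvalues_shift_by_epsilon(self):
        rng = np.random.default_rng(2)
        A = rng.normal(size=(10, 10))
        R = A @ A.T
        est = diagonal_load(R, 0.05)
        lo_before = np.linalg.eigvalsh(R).min()
        lo_after = np.linalg.eigvalsh(est.R).min()
        assert lo_after == pytest.approx(lo_before + est.epsilon, rel=1e-10)

    @pytest.mark.parametrize("delta", [0.0, -0.1, 0.6])
    def test_delta_out_of_range_rejected(self, delta):
        with pytest.raises(ValueError):
            diagonal_load(np.eye(4), delta)


class TestEigendecomposition:
    def test_two_by_two_alpha_rule(self):
        est = eigendecompose(np.diag([4.0, 1.0]), alpha=0.4)
        assert np.allclose(est.eigvals, [4.0, 1.0])
        assert est.N == 1
        assert np.allclose(np.abs(est.eigvecs[:, 0]), [1.0, 0.0])

    def test_identity_keeps_full_subspace(self):
        est = eigendecompose(np.eye(5), alpha=0.4)
        assert est.N == 5

    def test_non_hermitian_rejected(self):
        with pytest.raises(ValueError, match="Hermitian"):
            eigendecompose(np.array([[1.0, 2.0], [0.0, 1.0]]))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000), st.integers(2, 32))
    def test_reconstruction_and_subspace_split(self, seed, L):
        """U Lambda U^H rebuilds R~, and the signal/noise split is exact."""
        rng = np.random.default_rng(seed)
        A = rng.normal(size=(L, L))
        R = A @ A.T
        est = eigendecompose(R, alpha=0.4)
        scale = np.abs(R).max()
        rec = est.eigvecs @ np.diag(est.eigvals) @ est.eigvecs.T
        assert np.abs(rec - R).max() < 1e-10 * max(scale, 1.0)
        Us, Up = est.eigvecs[:, : est.N], est.eigvecs[:, est.N :]
        split = (
            Us @ np.diag(est.eigvals[: est.N]) @ Us.T
            + Up @ np.diag(est.eigvals[est.N :]) @ Up.T
        )
        assert np.abs(split - R).max() < 1e-10 * max(scale, 1.0)
        assert np.all(np.diff(est.eigvals) <= 1e-12 * max(scale, 1.0))


class TestBeamformers:
    def test_das_is_element_mean(self):
        v = np.arange(16.0)
        assert das(v) == pytest.approx(v.mean())

    def test_two_by_two_hand_solved_weight(self):
        """R~ = [[2,1],[1,2]], d = 1: the Capon weight is (1/2, 1/2)."""
        w = _mv_weight(np.array([[2.0, 1.0], [1.0, 2.0]]), np.ones(2))
        assert np.allclose(w, [0.5, 0.5])

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_distortionless_constraint(self, seed):
        """w^H d = 1 to 1e-10 for any loaded covariance."""
        rng = np.random.default_rng(seed)
        L = int(rng.integers(2, 33))
        A = rng.normal(size=(L, L))
        est = diagonal_load(A @ A.T)
        w = _mv_weight(est.R, np.ones(L))
        assert abs(w @ np.ones(L) - 1.0) < 1e-10

    def test_identity_covariance_equivalences(self):
        """R~ = I: MV = ESBMV, and both equal DAS up to the subarray-mean
        convention."""
        rng = np.random.default_rng(3)
        v = rng.normal(size=128)
        est = CovarianceEstimate(R=np.eye(32), L=32)
        out_mv = mv(v, est)
        out_es = esbmv(v, est)
        sub = np.lib.stride_tricks.sliding_window_view(v, 32)
        das_subarray = sub.mean(axis=0).mean()
        assert out_mv == pytest.approx(out_es, abs=1e-12)
        assert out_mv == pytest.approx(das_subarray, abs=1e-12)
        assert das(v) == pytest.approx(v.mean())

    def test_full_subspace_projection_is_identity(self):
        rng = np.random.default_rng(4)
        v = rng.normal(size=64)
        A = rng.normal(size=(16, 16))
        est = diagonal_load(A @ A.T / 16)
        # alpha tiny: every eigenvector is kept, projection is a no-op
        full = eigendecompose(est, alpha=1e-12)
        assert full.N == 16
        assert esbmv(v, full) == pytest.approx(mv(v, est), abs=1e-10)

    def test_silent_pixel_falls_back_to_das_weights(self):
        v = np.zeros(64)
        est = diagonal_load(subarray_covariance(v, 16))
        assert mv(v, est) == 0.0
        assert esbmv(v, est) == 0.0

    def test_engine_matches_reference_implementations(self, point_frame):
        """The vectorised per-line engine equals the single-pixel functions."""
        g = point_frame.geometry
        depths = np.array([0.018, 0.020, 0.022])
        lx = g.element_x[60]
        X = bf.gather_line(point_frame, lx, depths)
        img_mv = beamform_image(point_frame, "mv", line_x=np.array([lx]), depths=depths)
        img_es = beamform_image(point_frame, "esbmv", line_x=np.array([lx]), depths=depths)
        for k in range(len(depths)):
            est = diagonal_load(subarray_covariance(X[k], 32), default_delta(32))
            assert img_mv.pixels["mv"][0, k] == pytest.approx(mv(X[k], est), abs=1e-10)
            dec = eigendecompose(est, 0.4)
            assert img_es.pixels["esbmv"][0, k] == pytest.approx(
                esbmv(X[k], dec), abs=1e-10
            )

    def test_point_target_resolution_and_sidelobe_ordering(self, point_frame):
        """MV mainlobe no wider than DAS; ESBMV sidelobes below MV's."""
        lx = np.linspace(-6e-3, 6e-3, 121)
        depths = np.linspace(0.0195, 0.0205, 21)
        prof = {}
        for m in ("das", "mv", "esbmv"):
            img = beamform_image(point_frame, m, line_x=lx, depths=depths)
            env = envelope_detect(img.pixels[m])
            prof[m] = env.max(axis=1)

        def width(p):
            above = np.flatnonzero(p >= 0.5 * p.max())
            return above[-1] - above[0]

        def sidelobe(p):
            c = p.argmax()
            out = np.concatenate([p[: max(c - 15, 0)], p[c + 16 :]])
            return out.max() / p.max()

        assert width(prof["mv"]) <= width(prof["das"])
        assert sidelobe(prof["esbmv"]) <= sidelobe(prof["mv"])
        assert sidelobe(prof["mv"]) <= sidelobe(prof["das"])


class TestEigenvalueDetection:
    def test_threshold_rule_simple_profile(self):
        lam = np.array([[10.0, 1.0, 1.0]])
        mask = threshold_detect(lam, c=0.15)
        assert mask.tolist() == [[True, False, False]]

    def test_uniform_line_all_flagged(self):
        mask = threshold_detect(np.full((2, 5), 3.0), c=0.15)
        assert np.all(mask)

    def test_zero_line_no_detections(self):
        lam = np.array([[0.0, 0.0], [1.0, 0.1]])
        mask = threshold_detect(lam, c=0.15)
        assert not mask[0].any()
        assert mask[1, 0]

    @pytest.mark.parametrize("c", [0.0, 1.0, -0.2])
    def test_fraction_out_of_range_rejected(self, c):
        with pytest.raises(ValueError):
            threshold_detect(np.ones((2, 2)), c=c)

    def test_lambda_separates_bubble_from_tissue(self, tube_frame):
        """Median lambda_1 over true bubble pixels exceeds the tissue median."""
        from ucpwi.rf_sim import BUBBLE, TISSUE

        lam = max_eigenvalue_map(tube_frame, depth_decimation=4)
        g = tube_frame.geometry
        depths = bf.default_depth_grid(tube_frame, 4)
        # map truth mask (samples x elements) onto the pixel grid
        samp = np.clip((depths * 2 * g.fs / g.c0).round().astype(int), 0, tube_frame.n_samples - 1)
        truth_pix = tube_frame.truth_mask[samp, :].T  # (lines, depths)
        med_b = np.median(lam[truth_pix == BUBBLE])
        med_t = np.median(lam[truth_pix == TISSUE])
        assert med_b > med_t


class TestDisplay:
    def test_log_compress_range(self):
        env = np.array([[1.0, 0.1, 1e-6]])
        db = log_compress(env, 60.0)
        assert db.max() == 0.0
        assert db.min() == -60.0
        assert db[0, 1] == pytest.approx(-20.0)

    def test_all_zero_envelope_is_floor(self):
        db = log_compress(np.zeros((2, 3)), 60.0)
        assert np.all(db == -60.0)
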
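import numpy as np
import pytest

from oracles import covariance_bruteforce, noncentered_bruteforce, power_iteration_spectrum
from stcnc import ensemble, moments, stimulus, synth
from stcnc.ensemble import SpikeTriggeredEnsemble


def make_ste(S, f=None, window=None):
    M = S.shape[1]
    if f is None:
        f, window = M, (1, 1)
    return SpikeTriggeredEnsemble(S=np.asarray(S, float), f=f, window=window)


class TestSta:
    def test_identical_rows(self):
        v = np.array([1.0, -2.0, 3.0])
        sta = moments.compute_sta(make_ste(np.tile(v, (5, 1))))
        np.testing.assert_array_equal(sta.vector, v)

    def test_symmetric_rows_cancel(self):
        v = np.array([1.0, -2.0, 3.0])
        sta = moments.compute_sta(make_ste(np.vstack([v, -v, v, -v])))
        np.testing.assert_allclose(sta.vector, 0, atol=1e-15)

    def test_streaming_sta_equals_ensemble_sta(self):
        cfg = stimulus.StimulusConfig(grid_rows=5, grid_cols=5, seed=6)
        movie = stimulus.generate_white_noise(cfg, 300)
        counts = np.random.default_rng(0).poisson(0.3, 300)
        f = 7
        direct = moments.compute_sta(ensemble.build_ste(movie, counts, f))
        streamed = moments.compute_sta_streaming(movie, counts, f)
        np.testing.assert_allclose(direct.vector, streamed.vector, atol=1e-12)


class TestMomentMatrices:
    def test_covariance_of_antipodal_pair(self):
        v = np.array([1.0, 2.0, -1.0])
        C = moments.compute_covariance(make_ste(np.vstack([v, -v])))
        np.testing.assert_allclose(C, 2.0 * np.outer(v, v), atol=1e-12)

    def test_covariance_of_identical_rows_is_zero(self):
        v = np.array([1.0, 2.0])
        C = moments.compute_covariance(make_ste(np.tile(v, (4, 1))))
        np.testing.assert_allclose(C, 0, atol=1e-14)

    def test_covariance_matches_bruteforce(self):
        rng = np.random.default_rng(3)
        S = rng.standard_normal((50, 6))
        C = moments.compute_covariance(make_ste(S))
        np.testing.assert_allclose(C, covariance_bruteforce(S), atol=1e-10)

    def test_noncentered_matches_bruteforce_and_rank1_cases(self):
        rng = np.random.default_rng(4)
        S = rng.standard_normal((30, 5))
        M = moments.compute_noncentered_moment(make_ste(S))
        np.testing.assert_allclose(M, noncentered_bruteforce(S), atol=1e-10)
        v = np.array([1.0, -1.0, 2.0])
        M2 = moments.compute_noncentered_moment(make_ste(np.vstack([v, -v])))
        np.testing.assert_allclose(M2, np.outer(v, v), atol=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_identity_M_equals_CN_plus_outer_sta(self, seed):
        """Mmat = C_N + A A^T with C_N the 1/N-normalized covariance."""
        rng = np.random.default_rng(seed)
        S = rng.standard_normal((40, 8)) + rng.standard_normal(8)
        ste = make_ste(S)
        A = moments.compute_sta(ste).vector
        M = moments.compute_noncentered_moment(ste)
        Sc = S - A
        C_N = Sc.T @ Sc / S.shape[0]
        err = np.abs(M - (C_N + np.outer(A, A))).max() / np.abs(M).max()
        assert err < 1e-10


class TestEigenanalysis:
    def test_rank_one_second_moment(self):
        v = np.array([3.0, 0.0, -4.0])
        filt = moments.stc_nc_filter(np.outer(v, v))
        assert np.isclose(filt.eigenvalue, 25.0)
        # sign convention: largest-|element| positive
        np.testing.assert_allclose(filt.vector, np.array([-0.6, 0.0, 0.8]))

    def test_spectrum_sorted_and_trace_identity(self):
        C = np.diag([3.0, 1.0, 2.0])
        w, V = moments.stc_spectrum(C)
        np.testing.assert_array_equal(w, [3.0, 2.0, 1.0])
        assert np.isclose(w.sum(), np.trace(C))
        np.testing.assert_allclose(np.abs(V), np.eye(3)[:, [0, 2, 1]], atol=1e-12)

    @pytest.mark.parametrize("m", [4, 7, 10])
    def test_spectrum_matches_power_iteration_oracle(self, m):
        rng = np.random.default_rng(m)
        B = rng.standard_normal((m, m))
        C = B @ B.T
        w, V = moments.stc_spectrum(C)
        w_o, V_o = power_iteration_spectrum(C)
        np.testing.assert_allclose(w, w_o, atol=1e-8)
        for j in range(m):
            assert abs(abs(V[:, j] @ V_o[:, j]) - 1.0) < 1e-8

    def test_nonsymmetric_rejected(self):
        with pytest.raises(ValueError):
            moments.stc_nc_filter(np.array([[1.0, 2.0], [0.0, 1.0]]))


class TestProjectOutSta:
    def test_parallel_row_zeroed_orthogonal_kept(self):
        sta = moments.LinearFilter(np.array([1.0, 0.0, 0.0]), (3, 1, 1))
        S = np.array([[2.0, 0, 0], [0, 1.0, -1.0]])
        out = moments.project_out_sta(make_ste(S), sta)
        np.testing.assert_allclose(out.S[0], 0, atol=1e-12)
        np.testing.assert_allclose(out.S[1], S[1], atol=1e-12)

    def test_idempotent_and_orthogonal(self):
        rng = np.random.default_rng(5)
        ste = make_ste(rng.standard_normal((20, 6)))
        sta = moments.compute_sta(ste)
        once = moments.project_out_sta(ste, sta)
        twice = moments.project_out_sta(once, sta)
        np.testing.assert_allclose(once.S, twice.S, atol=1e-12)
        assert np.abs(once.S @ (sta.vector / sta.norm)).max() < 1e-10


class TestSignalStrength:
    def test_concentrated_sta_is_strong(self):
        v = np.zeros(100)
        v[13] = 1.0
        filt = moments.LinearFilter(v, (4, 5, 5))
        assert moments.sta_signal_strength(filt) > 6

    def test_pure_noise_sta_rarely_passes_six_sd(self):
        """Null calibration: white-noise STAs stay below the 6 s.d. gate."""
        rng = np.random.default_rng(8)
        n_pass = 0
        for _ in range(300):
            v = rng.standard_normal(600)  # ~ a 30x(4x5) STA of pure noise
            filt = moments.LinearFilter(v, (30, 4, 5))
            if moments.sta_signal_strength(filt) >= 6:
                n_pass += 1
        assert n_pass == 0

    def test_ring_strength_construction_and_sign_invariance(self):
        rng = np.random.default_rng(9)
        arr = 0.01 * rng.standard_normal((20, 5, 5))
        arr[7, 2, 2] = 0.5
        filt = moments.LinearFilter(arr.ravel(), (20, 5, 5))
        s = moments.stcnc_signal_strength(filt)
        ring = np.zeros((5, 5), bool)
        ring[0] = ring[-1] = ring[:, 0] = ring[:, -1] = True
        expected = 0.5 / arr[:, ring].std()
        assert np.isclose(s, expected)
        flipped = moments.LinearFilter(-arr.ravel(), (20, 5, 5))
        assert np.isclose(moments.stcnc_signal_strength(flipped), s)

    def test_padded_border_excluded(self):
        arr = np.zeros((3, 5, 5))
        arr[:, 2, 2] = 1.0
        arr[:, 1:4, 1:4] += 0.01 * np.random.default_rng(1).standard_normal((3, 3, 3))
        pad = np.ones((5, 5), bool)
        pad[1:4, 1:4] = False  # only the inner 3x3 is real
        filt = moments.LinearFilter(arr.ravel(), (3, 5, 5), pad_mask=pad)
        with pytest.raises(ValueError):
            moments.stcnc_signal_strength(filt)


class TestConvergence:
    def test_final_projection_is_one_and_deterministic_cell_converges(self):
        rng = np.random.default_rng(10)
        v = np.zeros(50)
        v[5] = 1.0
        S = np.outer(rng.choice([-1.0, 1.0], 600), v)
        S += 0.05 * rng.standard_normal(S.shape)
        cc = moments.convergence_curve(make_ste(S), step=100)
        assert np.isclose(cc.projections[-1], 1.0)
        assert cc.converged
        assert np.all(cc.projections > 0.99)

    def test_too_few_spikes_rejected(self):
        S = np.random.default_rng(0).standard_normal((150, 4))
        with pytest.raises(ValueError):
            moments.convergence_curve(make_ste(S), step=100)


class TestProjectedOutSpectrum:
    def test_removing_sta_removes_the_rectified_cells_top_direction(self):
        """For a rectified (ON-like) ensemble the raw STC-NC direction is
        nearly the STA; after projecting the STA out, the leading
        direction of the remaining energy departs from it."""
        rng = np.random.default_rng(21)
        u = rng.standard_normal(30)
        u /= np.linalg.norm(u)
        amp = np.abs(rng.standard_normal(1500)) * 1.5  # one-signed drive
        S = np.outer(amp, u) + rng.standard_normal((1500, 30))
        ste = make_ste(S)
        sta = moments.compute_sta(ste)
        sta_u = sta.vector / sta.norm
        raw_top = moments.stc_nc_filter(moments.compute_noncentered_moment(ste))
        removed = moments.project_out_sta(ste, sta)
        red_top = moments.stc_nc_filter(moments.compute_noncentered_moment(removed))
        agree_raw = abs(raw_top.vector @ sta_u)
        agree_removed = abs(red_top.vector @ sta_u)
        assert agree_raw > 0.9
        assert agree_removed < agree_raw - 0.5


class TestStaFailureStcncSuccess:
    def test_symmetric_ensemble_breaks_sta_not_stcnc(self):
        """With s and -s equally likely given a spike, the STA vanishes
        while the top non-centered eigenvalue stays separated from the
        bulk — the core asymmetry between the two estimators."""
        rng = np.random.default_rng(11)
        u = rng.standard_normal(40)
        u /= np.linalg.norm(u)
        signs = rng.choice([-1.0, 1.0], 2000)
        amp = rng.standard_normal(2000) * 2.0
        S = np.outer(signs * np.abs(amp), u) + rng.standard_normal((2000, 40))
        ste = make_ste(S)
        sta = moments.compute_sta(ste)
        assert np.linalg.norm(sta.vector) < 0.2
        M = moments.compute_noncentered_moment(ste)
        w = np.linalg.eigvalsh(M)
        assert w[-1] > 2.0 * w[-2]  # clear spectral gap
        filt = moments.stc_nc_filter(M)
        assert abs(filt.vector @ u) > 0.95
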
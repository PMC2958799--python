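import numpy as np
import pytest
from scipy import stats

from stcnc import ensemble, lnmodel, moments, stimulus, synth
from stcnc.ensemble import SpikeTriggeredEnsemble


def make_ste(S, f=None, window=None):
    M = S.shape[1]
    if f is None:
        f, window = M, (1, 1)
    return SpikeTriggeredEnsemble(S=np.asarray(S, float), f=f, window=window)


def lf(v):
    return moments.LinearFilter(np.asarray(v, float), (len(v), 1, 1))


@pytest.fixture(scope="module")
def driven_cell():
    """A rectified-linear ON cell and its white-noise ensembles, shared
    across the nonlinearity-recovery tests."""
    cfg = stimulus.StimulusConfig(grid_rows=10, grid_cols=10, seed=13)
    movie = stimulus.generate_white_noise(cfg, 25000)
    nl = synth.NonlinearitySpec(
        kind="rectified_on", baseline=0.002, exponent=1.0,
        gain=synth.calibrate_gain("rectified_on", 0.15, 0.002,
                                  stimulus.truncated_gaussian_sd(cfg)),
    )
    cell = synth.make_cell("ON", cfg, (500, 500), 70, nonlinearity=nl)
    counts = ensemble.bin_spikes(
        synth.simulate_spikes(cell, movie, seed=1), movie.frame_times
    ).counts
    center = cell.filter.center_checker
    ste = ensemble.build_ste(movie, counts, 20, center=center, spatial=(3, 3))
    rss = ensemble.build_rss(movie, 20, center=center, spatial=(3, 3))
    truth = cell.filter.windowed_vector(center, (3, 3))
    filt = moments.LinearFilter(truth, (20, 3, 3))
    return cell, ste, rss, filt


class TestOrient:
    def test_flips_negative_peak(self):
        f = lf([0.1, -0.4, 0.2])
        out, flipped = lnmodel.orient_filter(f)
        assert flipped and out.vector[1] == 0.4

    def test_on_filter_unchanged_and_idempotent(self):
        f = lf([0.1, 0.4, -0.2])
        out, flipped = lnmodel.orient_filter(f)
        assert not flipped
        out2, flipped2 = lnmodel.orient_filter(out)
        assert not flipped2
        np.testing.assert_array_equal(out.vector, out2.vector)

    def test_zero_filter_rejected(self):
        with pytest.raises(ValueError):
            lnmodel.orient_filter(lf([0.0, 0.0]))


class TestProjectAndBin:
    def test_rss_projection_near_gaussian(self, driven_cell):
        _, ste, rss, filt = driven_cell
        hist = lnmodel.project_and_bin(filt, rss, ste)
        p = rss.S @ (filt.vector / np.linalg.norm(filt.vector))
        d, _ = stats.kstest((p - p.mean()) / p.std(), "norm")
        assert d < 0.01

    def test_discarded_fraction_matches_tail_mass(self, driven_cell):
        """Beyond 2.5 s.d. a true Gaussian keeps 2*Phi(-2.5) ~ 1.24% of
        mass; the truncated projection discards slightly less."""
        _, ste, rss, filt = driven_cell
        hist = lnmodel.project_and_bin(filt, rss, ste)
        frac = hist.discarded_rss / rss.n_spikes
        assert frac < 2 * stats.norm.cdf(-2.5) + 0.004
        assert frac > 0.001

    def test_identical_ste_rows_occupy_single_bin(self):
        rng = np.random.default_rng(0)
        rss = make_ste(rng.standard_normal((500, 4)))
        row = rng.standard_normal(4)
        ste = make_ste(np.tile(row, (20, 1)))
        hist = lnmodel.project_and_bin(lf(np.ones(4)), rss, ste)
        assert (hist.L_STE > 0).sum() == 1
        assert hist.L_STE.max() == 20


class TestRecoverNonlinearity:
    def test_equal_histograms_give_unit_nonlinearity(self):
        hist = lnmodel.ProjectionHistogram(
            bin_edges=np.linspace(-1, 1, 6), L_RSS=np.full(5, 7),
            L_STE=np.full(5, 7), rss_sd=0.4,
        )
        nl = lnmodel.recover_nonlinearity(hist)
        np.testing.assert_array_equal(nl.N, 1.0)

    def test_no_negative_spikes_means_zero_p_off(self):
        hist = lnmodel.ProjectionHistogram(
            bin_edges=np.linspace(-1, 1, 7), L_RSS=np.full(6, 10),
            L_STE=np.array([0, 0, 0, 2, 5, 9]), rss_sd=0.4,
        )
        nl = lnmodel.recover_nonlinearity(hist)
        assert nl.p_off == 0.0 and nl.bias == 1.0

    def test_roundtrip_recovers_rectified_linear_g(self, driven_cell):
        """The binned L_STE/L_RSS ratio reproduces the generator's own
        rectified-linear nonlinearity (R^2 >= 0.95)."""
        cell, ste, rss, filt = driven_cell
        hist = lnmodel.project_and_bin(filt, rss, ste)
        nl = lnmodel.recover_nonlinearity(hist)
        g = cell.nonlinearity.rate(nl.bin_centers)  # expected spikes/frame
        ss_res = np.sum((nl.N - g) ** 2)
        ss_tot = np.sum((g - g.mean()) ** 2)
        assert 1 - ss_res / ss_tot >= 0.95

    def test_bias_of_driven_on_cell_is_high(self, driven_cell):
        _, ste, rss, filt = driven_cell
        nl = lnmodel.recover_nonlinearity(
            lnmodel.project_and_bin(filt, rss, ste)
        )
        assert nl.bias > 0.9


class TestBias:
    def test_even_nonlinearity_zero_bias(self):
        x = np.linspace(-1, 1, 25)
        x = x[x != 0]
        nl = lnmodel.StaticNonlinearity(
            bin_centers=x, N=x**2, p_on=lnmodel._halfline_integral(x, x**2, True),
            p_off=lnmodel._halfline_integral(x, x**2, False),
        )
        assert abs(nl.bias) < 1e-12

    def test_unbalanced_cell_bias_matches_quadrature_oracle(self):
        """w_on:w_off = 3:1 linear lobes: the analytic bias of the true g
        is (3-1)/(3+1) = 0.5; the histogram estimate lands within 0.05."""
        cfg = stimulus.StimulusConfig(grid_rows=8, grid_cols=8, seed=17)
        movie = stimulus.generate_white_noise(cfg, 25000)
        nl_spec = synth.NonlinearitySpec(
            kind="unbalanced", w_on=3.0, w_off=1.0, exponent=1.0, baseline=0.0,
            gain=synth.calibrate_gain("unbalanced", 0.15, 0.0,
                                      stimulus.truncated_gaussian_sd(cfg),
                                      w_on=3.0, w_off=1.0),
        )
        cell = synth.make_cell("ON_OFF", cfg, (400, 400), 70, nonlinearity=nl_spec)
        counts = ensemble.bin_spikes(
            synth.simulate_spikes(cell, movie, seed=2), movie.frame_times
        ).counts
        center = cell.filter.center_checker
        ste = ensemble.build_ste(movie, counts, 20, center=center, spatial=(3, 3))
        rss = ensemble.build_rss(movie, 20, center=center, spatial=(3, 3))
        filt = moments.LinearFilter(
            cell.filter.windowed_vector(center, (3, 3)), (20, 3, 3)
        )
        nl = lnmodel.recover_nonlinearity(lnmodel.project_and_bin(filt, rss, ste))
        # quadrature oracle on the true g over the same +/-2.5 sd span
        sd = (rss.S @ filt.vector).std()
        xs = np.linspace(-2.5 * sd, 2.5 * sd, 20001)
        g = cell.nonlinearity.rate(xs)
        p_on = np.trapezoid(g[xs > 0], xs[xs > 0])
        p_off = np.trapezoid(g[xs < 0], xs[xs < 0])
        oracle = (p_on - p_off) / (p_on + p_off)
        assert np.isclose(oracle, 0.5, atol=1e-6)
        assert abs(nl.bias - oracle) < 0.05

    def test_bias_in_range_and_sign_flips_with_filter(self, driven_cell):
        cell, ste, rss, filt = driven_cell
        nl = lnmodel.recover_nonlinearity(lnmodel.project_and_bin(filt, rss, ste))
        assert -1 <= nl.bias <= 1
        # projecting onto the negated (then un-oriented) filter flips the
        # sign structure of the histogram
        neg = moments.LinearFilter(-filt.vector, filt.shape3)
        nl2 = lnmodel.recover_nonlinearity(lnmodel.project_and_bin(neg, rss, ste))
        assert np.sign(nl2.bias) == -np.sign(nl.bias)

    def test_shared_rss_histogram_matches_per_filter_bias(self, driven_cell):
        """The speed option (one L_RSS pooled over 10 random filters)
        changes the recovered bias only marginally."""
        _, ste, rss, filt = driven_cell
        exact = lnmodel.recover_nonlinearity(lnmodel.project_and_bin(filt, rss, ste))
        shared = lnmodel.pooled_rss_histogram(rss, n_filters=10, seed=1)
        pooled = lnmodel.recover_nonlinearity(
            lnmodel.project_and_bin(filt, None, ste, shared_rss=shared)
        )
        assert abs(pooled.bias - exact.bias) < 0.05

    def test_scale_invariance(self, driven_cell):
        _, ste, rss, filt = driven_cell
        nl1 = lnmodel.recover_nonlinearity(lnmodel.project_and_bin(filt, rss, ste))
        big = moments.LinearFilter(17.0 * filt.vector, filt.shape3)
        nl2 = lnmodel.recover_nonlinearity(lnmodel.project_and_bin(big, rss, ste))
        np.testing.assert_allclose(nl1.N, nl2.N)
        assert np.isclose(nl1.bias, nl2.bias)


class TestSplitSpikes:
    def test_on_cell_off_side_nearly_empty(self, driven_cell):
        _, ste, rss, filt = driven_cell
        split = lnmodel.split_spikes(filt, ste)
        assert split.n_off / ste.n_spikes < 0.1

    def test_balanced_onoff_splits_evenly_and_inverted(self):
        """Matched-kernel symmetric cell: the ON- and OFF-spike STAs are
        spatiotemporally overlapping and inverted (cosine <= -0.8)."""
        cfg = stimulus.StimulusConfig(grid_rows=8, grid_cols=8, seed=19)
        movie = stimulus.generate_white_noise(cfg, 30000)
        cell = synth.make_cell("ON_OFF", cfg, (400, 400), 70)
        counts = ensemble.bin_spikes(
            synth.simulate_spikes(cell, movie, seed=3), movie.frame_times
        ).counts
        center = cell.filter.center_checker
        ste = ensemble.build_ste(movie, counts, 20, center=center, spatial=(5, 5))
        v = moments.stc_nc_filter(moments.compute_noncentered_moment(ste), ste)
        oriented, _ = lnmodel.orient_filter(v)
        split = lnmodel.split_spikes(oriented, ste)
        n = ste.n_spikes
        # binomial balance at ~5 sigma
        assert abs(split.n_on - n / 2) < 5 * np.sqrt(n) / 2
        a, b = split.sta_on.vector, split.sta_off.vector
        cos = a @ b / (np.linalg.norm(a) * np.linalg.norm(b))
        assert cos <= -0.8

    def test_empty_side_flagged(self):
        S = np.tile([1.0, 0.5], (10, 1))
        split = lnmodel.split_spikes(lf([1.0, 0.0]), make_ste(S))
        assert split.sta_off is None and split.n_off == 0
        assert split.n_on == 10
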
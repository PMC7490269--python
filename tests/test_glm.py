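import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from popfail.glm import (
    CosineBasis,
    GLMParams,
    GLMPopulation,
    SpikeRaster,
    _causal_conv,
    _spike_feedback,
    compute_psth,
    conditional_intensity,
    explained_variance,
    fit_glm,
    logexp2,
    simulate_spikes,
    stimulus_drive,
    upsample_stimulus,
)
from popfail.stimuli import generate_white_noise


class TestLogexp2:
    def test_value_at_zero(self):
        assert logexp2(0.0) == pytest.approx(np.log(2.0) ** 2)

    @given(st.floats(-50, 50))
    def test_positive_and_monotone(self, g):
        f = logexp2(g)
        assert f > 0
        assert logexp2(g + 0.1) > f

    def test_asymptotics(self):
        # large g: ~ g^2; very negative g: -> 0
        assert logexp2(40.0) == pytest.approx(1600.0, rel=0.01)
        assert logexp2(-40.0) < 1e-10


class TestCosineBasis:
    def test_shape_and_support(self):
        b = CosineBasis(8, 0.10, 0.001)
        assert b.matrix.shape == (100, 8)
        assert b.support_bins == 100

    def test_columns_nonnegative_and_tile(self):
        b = CosineBasis(8, 0.10, 0.001)
        assert (b.matrix >= 0).all()
        # every time bin is covered by at least one bump
        assert (b.matrix.sum(axis=1) > 0).all()

    def test_kernel_linear_in_weights(self):
        b = CosineBasis(4, 0.05, 0.001)
        w1, w2 = np.arange(4.0), np.ones(4)
        assert np.allclose(b.kernel(w1 + 2 * w2), b.kernel(w1) + 2 * b.kernel(w2))


class TestConvolutions:
    @given(st.integers(0, 50))
    def test_causal_conv_matches_direct(self, seed):
        rng = np.random.default_rng(seed)
        s, k = rng.standard_normal(40), rng.standard_normal(7)
        out = _causal_conv(s, k)
        t = 15
        direct = sum(k[tau] * s[t - tau] for tau in range(len(k)))
        assert out[t] == pytest.approx(direct)

    def test_spike_feedback_strictly_causal(self):
        counts = np.zeros(20)
        counts[5] = 1.0
        k = np.arange(1.0, 4.0)
        out = _spike_feedback(counts, k)
        assert np.allclose(out[:6], 0.0)  # nothing at or before the spike bin
        assert np.allclose(out[6:9], k)


class TestUpsampleStimulus:
    def test_zero_order_hold(self):
        m = generate_white_noise(3, (1, 1), seed=0, refresh=10.0)
        bins = upsample_stimulus(m, dt=0.025)  # 4 bins per frame
        assert bins.shape == (12, 1)
        x = m.contrast().reshape(3, -1)
        assert np.allclose(bins[:4], x[0])
        assert np.allclose(bins[4:8], x[1])

    def test_noninteger_ratio(self):
        m = generate_white_noise(4, (1, 1), seed=1, refresh=30.0)
        bins = upsample_stimulus(m, dt=0.001)
        assert len(bins) == round(4 / 30.0 / 0.001)
        # frame index = floor(t * refresh)
        assert np.allclose(bins[33], m.contrast().reshape(4, -1)[0])
        assert np.allclose(bins[34], m.contrast().reshape(4, -1)[1])


@pytest.fixture(scope="module")
def toy_population():
    """One-cell population with known filters on a 1-pixel stimulus."""
    dt = 0.001
    sb = CosineBasis(8, 0.10, dt)
    hb = CosineBasis(8, 0.10, dt)
    cb = CosineBasis(8, 0.05, dt)
    tw = np.zeros(8)
    tw[1] = 1.5
    hw = np.zeros(8)
    hw[:2] = [-5.0, -2.0]
    cell = GLMParams(np.array([1.0]), tw, hw, {}, dc=1.0)
    return GLMPopulation(
        cells=[cell], positions=np.zeros((1, 2)), dt=dt,
        stim_basis=sb, hist_basis=hb, coup_basis=cb, pixel_grid=(1, 1),
    )


class TestSimulation:
    def test_counts_shape_and_type(self, toy_population):
        m = generate_white_noise(60, (1, 1), seed=2, refresh=30.0)
        r = simulate_spikes(toy_population, m, 3, seed=0)
        assert r.counts.shape == (3, 1, 2000)
        assert r.trial_type == "repeated"
        assert (r.counts >= 0).all()

    def test_seed_reproducible(self, toy_population):
        m = generate_white_noise(30, (1, 1), seed=2, refresh=30.0)
        a = simulate_spikes(toy_population, m, 2, seed=7)
        b = simulate_spikes(toy_population, m, 2, seed=7)
        assert np.array_equal(a.counts, b.counts)

    def test_refractory_history_suppresses_rate_after_spike(self, toy_population):
        """Negative history filter lowers the conditional intensity after a spike."""
        m = generate_white_noise(30, (1, 1), seed=3, refresh=30.0)
        n_bins = 1000
        quiet = np.zeros((1, n_bins))
        spiked = quiet.copy()
        spiked[0, 500] = 1.0
        lam_q = conditional_intensity(toy_population, 0, m, quiet)
        lam_s = conditional_intensity(toy_population, 0, m, spiked)
        # strictly causal: the spike bin itself is untouched ...
        assert lam_s[500] == lam_q[500]
        # ... and the following bins are suppressed
        assert (lam_s[501:520] < lam_q[501:520]).all()

    def test_mean_rate_tracks_intensity(self, toy_population):
        m = generate_white_noise(600, (1, 1), seed=4, refresh=30.0)
        r = simulate_spikes(toy_population, m, 1, seed=2)
        lam = conditional_intensity(toy_population, 0, m, r.counts[0])
        expected = lam.mean() * toy_population.dt * r.n_bins
        observed = r.counts.sum()
        assert abs(observed - expected) < 5 * np.sqrt(expected)

    def test_coupling_excites_target_after_source_spike(self):
        """A positive coupling filter raises the target's conditional intensity
        in the bins following a source spike, strictly causally."""
        dt = 0.001
        sb = CosineBasis(8, 0.10, dt)
        hb = CosineBasis(8, 0.10, dt)
        cb = CosineBasis(8, 0.05, dt)
        hw = np.zeros(8)
        hw[:2] = [-5.0, -2.0]
        cw = np.zeros(8)
        cw[:2] = [1.5, 0.8]
        src = GLMParams(np.array([0.0]), np.zeros(8), hw, {}, dc=1.2)
        tgt = GLMParams(np.array([0.0]), np.zeros(8), hw, {0: cw}, dc=0.0)
        m = generate_white_noise(30, (1, 1), seed=5, refresh=30.0)
        pop = GLMPopulation(
            cells=[src, tgt], positions=np.zeros((2, 2)), dt=dt, stim_basis=sb,
            hist_basis=hb, coup_basis=cb, neighbor_graph={1: [0]}, pixel_grid=(1, 1),
        )
        history = np.zeros((2, 1000))
        spiked = history.copy()
        spiked[0, 500] = 1.0  # source spike only
        lam_q = conditional_intensity(pop, 1, m, history)
        lam_s = conditional_intensity(pop, 1, m, spiked)
        assert lam_s[500] == lam_q[500]
        assert (lam_s[501:510] > lam_q[501:510]).all()
        # the source's own intensity is unaffected by the target
        src_q = conditional_intensity(pop, 0, m, history)
        src_s = conditional_intensity(pop, 0, m, spiked)
        assert (src_s[:500] == src_q[:500]).all()


class TestRaster:
    def test_rebin_conserves_counts(self):
        rng = np.random.default_rng(0)
        r = SpikeRaster(rng.poisson(0.05, (2, 3, 1000)), dt=0.001)
        rb = r.rebin(0.005)
        assert rb.counts.sum() == r.counts.sum()
        assert rb.n_bins == 200

    def test_rebin_requires_multiple(self):
        r = SpikeRaster(np.zeros((1, 1, 10), dtype=int), dt=0.001)
        with pytest.raises(ValueError):
            r.rebin(0.0015)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            SpikeRaster(np.full((1, 1, 4), -1), dt=0.001)


@pytest.fixture(scope="module")
def fitted(small_recording, fast_fit_config):
    """Independent fit of the central cell on the short session."""
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pop = fit_glm(
            small_recording.raster_fit,
            small_recording.stimulus_fit,
            config=fast_fit_config,
            coupled=False,
            cells=[0],
        )
    return pop


class TestFitting:
    def test_spatial_filter_recovered(self, fitted, small_population):
        truth = small_population.cells[0].spatial_filter
        est = fitted.cells[0].spatial_filter
        c = np.corrcoef(truth, est)[0, 1]
        assert c > 0.8

    def test_temporal_kernel_recovered(self, fitted, small_population):
        kt_t = small_population.stim_basis.kernel(
            small_population.cells[0].temporal_weights
        )
        kt_e = fitted.stim_basis.kernel(fitted.cells[0].temporal_weights)
        assert np.corrcoef(kt_t, kt_e)[0, 1] > 0.75

    def test_spatial_filter_unit_norm(self, fitted):
        assert np.linalg.norm(fitted.cells[0].spatial_filter) == pytest.approx(1.0)

    def test_fit_requires_single_trial(self, small_recording):
        with pytest.raises(ValueError, match="single"):
            fit_glm(small_recording.raster_test, small_recording.stimulus_test)

    def test_psth_explained_variance_positive(
        self, fitted, small_population, small_recording
    ):
        """Fitted model predicts the repeated-stimulus PSTH far above chance."""
        stim = small_recording.stimulus_test
        sim = simulate_spikes(fitted, stim, 150, seed=9)
        pred = compute_psth(sim, 0.02)[0]
        obs = compute_psth(
            SpikeRaster(
                small_recording.raster_test.counts[:, [0], :],
                small_recording.raster_test.dt,
            ),
            0.02,
        )[0]
        assert explained_variance(pred, obs) > 0.2


class TestEvaluation:
    def test_psth_units(self):
        counts = np.zeros((4, 1, 100), dtype=int)
        counts[:, 0, 10] = 1  # every trial spikes once in bin 10
        r = SpikeRaster(counts, dt=0.001)
        psth = compute_psth(r, 0.005)
        assert psth[0, 2] == pytest.approx(200.0)  # 1 spike / 5 ms
        assert psth.sum() == pytest.approx(200.0)

    def test_explained_variance_perfect_and_zero(self):
        obs = np.array([1.0, 2.0, 3.0, 2.0])
        assert explained_variance(obs, obs) == pytest.approx(1.0)
        assert explained_variance(np.full(4, obs.mean()), obs) == pytest.approx(0.0)

    def test_constant_observed_rejected(self):
        with pytest.raises(ValueError):
            explained_variance(np.ones(4), np.ones(4))
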
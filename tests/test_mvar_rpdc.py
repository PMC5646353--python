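"""MVAR fitting, RPDC spectra, bootstrap significance and time reversal."""

import numpy as np
import pytest

import restconn as rc
from restconn import rpdc as R
from restconn import synthetic
from restconn.mvar import fit_mvar, is_stable, simulate_mvar


class TestSimulateMVARSources:
    def test_uncoupled_white_source_has_unit_variance(self):
        spec = synthetic.ConnectivitySpec(n_sources=1, noise_sd=1.0)
        src = synthetic.simulate_mvar_sources(spec, 10_000, seed=0)
        assert src.data[0].var() == pytest.approx(1.0, rel=0.10)

    def test_lagged_chain_cross_correlation(self):
        spec = synthetic.ConnectivitySpec(n_sources=2, coupling=[(0, 1, 1, 0.5)])
        src = synthetic.simulate_mvar_sources(spec, 10_000, seed=1)
        x, y = src.data
        # closed form: corr(x(t), y(t+1)) = 0.5 / sqrt(1.25) ~ 0.447
        r = np.corrcoef(x[:-1], y[1:])[0, 1]
        assert r > 0.3

    def test_deterministic_given_seed(self):
        spec = synthetic.ConnectivitySpec(n_sources=3, coupling=[(0, 1, 1, 0.4)])
        a = synthetic.simulate_mvar_sources(spec, 2000, seed=42)
        b = synthetic.simulate_mvar_sources(spec, 2000, seed=42)
        np.testing.assert_array_equal(a.data, b.data)

    def test_unstable_spec_rejected_with_radius(self):
        spec = synthetic.ConnectivitySpec(
            n_sources=2, coupling=[(0, 1, 1, 1.2), (1, 0, 1, 1.2)]
        )
        with pytest.raises(ValueError, match="spectral radius"):
            synthetic.simulate_mvar_sources(spec, 1000, seed=0)

    def test_stationary_variance_no_trend(self):
        spec = synthetic.ConnectivitySpec(n_sources=2, band_center_hz=10.0)
        src = synthetic.simulate_mvar_sources(spec, 20_000, seed=3)
        halves = np.split(src.data[0], 2)
        assert halves[0].var() == pytest.approx(halves[1].var(), rel=0.25)


class TestFitMVAR:
    def test_order_recovery_on_known_system(self):
        # order-2 system: resonant oscillators; AIC should find p = 2
        hits = 0
        spec = synthetic.ConnectivitySpec(
            n_sources=2, coupling=[(0, 1, 2, 0.3)], band_center_hz=10.0
        )
        for seed in range(20):
            src = synthetic.simulate_mvar_sources(spec, 10_000, seed=seed)
            model = fit_mvar(src, max_order=6)
            hits += int(model.order == 2)
        assert hits >= 18

    def test_coefficient_recovery(self):
        spec = synthetic.ConnectivitySpec(n_sources=2, coupling=[(0, 1, 1, 0.5)])
        src = synthetic.simulate_mvar_sources(spec, 10_000, seed=0)
        model = fit_mvar(src, order=1)
        truth = synthetic.coefficient_matrices(spec, 256.0)
        assert np.abs(model.A[0] - truth[0]).max() < 0.1

    def test_white_noise_fits_small_coefficients(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal((2, 10_000))
        model = fit_mvar(x, max_order=6)
        assert model.order <= 2
        off = model.A[:, ~np.eye(2, dtype=bool)]
        assert np.abs(off).max() < 0.05

    def test_univariate_matches_yule_walker(self):
        rng = np.random.default_rng(6)
        a_true = 0.6
        n = 20_000
        x = np.zeros(n)
        e = rng.standard_normal(n)
        for t in range(1, n):
            x[t] = a_true * x[t - 1] + e[t]
        model = fit_mvar(x[None, :], order=1)
        # Yule-Walker: a = acov(1) / acov(0)
        xc = x - x.mean()
        a_yw = (xc[1:] @ xc[:-1]) / (xc @ xc)
        assert model.A[0, 0, 0] == pytest.approx(a_yw, abs=1e-2)

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            fit_mvar(np.zeros((3, 100)), max_order=20)


class TestRPDCSpectrum:
    def test_no_coupling_gives_null_level_statistic(self):
        rng = np.random.default_rng(7)
        x = rng.standard_normal((2, 5000))
        model = fit_mvar(x, order=2)
        lam = rc.rpdc_spectrum(model, np.arange(8, 13.25, 0.25), 256.0)
        # Wald statistic ~ chi2(2) under the null: band means stay modest
        off = lam[~np.eye(2, dtype=bool)]
        assert np.nanmean(off) < 10

    def test_directed_chain_asymmetry(self):
        spec = synthetic.ConnectivitySpec(n_sources=2, coupling=[(0, 1, 1, 0.5)])
        src = synthetic.simulate_mvar_sources(spec, 5000, seed=0)
        model = fit_mvar(src, max_order=5)
        lam = rc.rpdc_spectrum(model, np.arange(8, 13.25, 0.25), 256.0)
        assert np.nanmean(lam[1, 0]) > 100 * np.nanmean(lam[0, 1])

    def test_scale_invariance_under_source_rescaling(self):
        spec = synthetic.ConnectivitySpec(n_sources=2, coupling=[(0, 1, 1, 0.5)])
        src = synthetic.simulate_mvar_sources(spec, 5000, seed=1)
        freqs = np.arange(8, 13.25, 0.25)
        lam1 = rc.rpdc_spectrum(fit_mvar(src.data, order=2), freqs, 256.0)
        scaled = src.data * np.array([[1.0], [100.0]])
        lam2 = rc.rpdc_spectrum(fit_mvar(scaled, order=2), freqs, 256.0)
        np.testing.assert_allclose(lam1[1, 0], lam2[1, 0], rtol=1e-6)
        np.testing.assert_allclose(lam1[0, 1], lam2[0, 1], rtol=1e-6)

    def test_display_mapping_monotone_and_bounded(self):
        raw = np.array([0.0, 0.5, 2.0, 100.0, np.inf])
        disp = rc.display_rpdc(raw)
        assert (np.diff(disp[:-1]) > 0).all()
        assert disp[0] == 0.0 and disp[-1] == 1.0
        assert ((disp >= 0) & (disp <= 1)).all()


class TestBootstrapSignificance:
    def test_direction_recovery_two_nodes(self):
        spec = synthetic.ConnectivitySpec(n_sources=2, coupling=[(0, 1, 1, 0.5)])
        hits = 0
        for seed in range(10):
            src = synthetic.simulate_mvar_sources(spec, 5000, seed=seed)
            res = rc.analyze_connectivity(
                src, rc.BANDS["alpha"], max_order=5, n_boot=100, seed=seed
            )
            hits += int(res.boot_sig[1, 0] and not res.boot_sig[0, 1])
        assert hits >= 9

    def test_strong_coupling_always_detected(self):
        spec = synthetic.ConnectivitySpec(n_sources=2, coupling=[(0, 1, 1, 0.8)])
        for seed in range(5):
            src = synthetic.simulate_mvar_sources(spec, 5000, seed=seed)
            model = fit_mvar(src, max_order=5)
            res = R.connectivity_spectrum(model, rc.BANDS["alpha"], src.fs)
            res._model_order = model.order
            R.apply_bootstrap(res, src, model, n_boot=100, seed=seed)
            assert res.boot_sig[1, 0]

    def test_small_bootstrap_rejected(self):
        spec = synthetic.ConnectivitySpec(n_sources=2, coupling=[(0, 1, 1, 0.5)])
        src = synthetic.simulate_mvar_sources(spec, 3000, seed=0)
        model = fit_mvar(src, max_order=3)
        with pytest.raises(ValueError):
            rc.bootstrap_significance(src, model, rc.BANDS["alpha"], n_boot=10)


class TestTimeReversal:
    def test_lagged_coupling_survives_trt(self):
        spec = synthetic.ConnectivitySpec(n_sources=2, coupling=[(0, 1, 1, 0.5)])
        hits = 0
        for seed in range(10):
            src = synthetic.simulate_mvar_sources(spec, 5000, seed=seed)
            res = rc.analyze_connectivity(
                src, rc.BANDS["alpha"], max_order=5, n_boot=100, seed=seed
            )
            hits += int(res.trt_pass[1, 0])
        assert hits >= 9

    def test_instantaneous_mixing_rejected(self):
        from scipy.signal import lfilter

        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            n = 3000
            r, th = 0.95, 2 * np.pi * 10 / 256
            s = lfilter([1.0], [1.0, -2 * r * np.cos(th), r * r], rng.standard_normal(n))
            x = np.vstack(
                [0.8 * s + 0.3 * rng.standard_normal(n),
                 0.6 * s + 0.4 * rng.standard_normal(n)]
            )
            res = rc.analyze_connectivity(
                rc.SourceSignals(x, 256.0), rc.BANDS["alpha"],
                max_order=8, n_boot=100, seed=seed,
            )
            hits += int(not res.trt_pass.any())
        assert hits >= 9

    def test_no_significant_pairs_passes_through(self):
        rng = np.random.default_rng(11)
        x = rng.standard_normal((2, 3000))
        model = fit_mvar(x, max_order=3)
        res = R.connectivity_spectrum(model, rc.BANDS["alpha"], 256.0)
        res._model_order = model.order
        res.boot_sig = np.zeros((2, 2), dtype=bool)
        out = rc.time_reversal_test(x, res, fs=256.0)
        assert not out.trt_pass.any()


class TestFlowSummaries:
    def _result_with_band_mean(self, bm):
        m = bm.shape[0]
        band = rc.BANDS["alpha"]
        raw = np.repeat(bm[:, :, None], 3, axis=2)
        return R.ConnectivityResult(
            band=band, freqs=np.array([9.0, 10.0, 11.0]), rpdc_raw=raw,
            rpdc_display=raw, band_mean_raw=bm, band_mean=bm,
        )

    def test_constant_field(self):
        bm = np.full((3, 3), 0.2)
        np.fill_diagonal(bm, np.nan)
        fs = rc.flow_summaries(self._result_with_band_mean(bm))
        assert fs["outflow"] == pytest.approx([0.2] * 3)
        assert fs["inflow"] == pytest.approx([0.2] * 3)
        assert fs["global_mean"] == pytest.approx(0.2)

    def test_single_edge_arithmetic(self):
        bm = np.zeros((3, 3))
        np.fill_diagonal(bm, np.nan)
        bm[1, 0] = 0.6  # single directed edge 0 -> 1 among 6 pairs
        fs = rc.flow_summaries(self._result_with_band_mean(bm))
        assert fs["global_mean"] == pytest.approx(0.6 / 6)

    def test_chain_head_outflow_exceeds_inflow(self):
        spec = synthetic.ConnectivitySpec(
            n_sources=3, coupling=[(0, 1, 1, 0.5), (1, 2, 1, 0.5)]
        )
        src = synthetic.simulate_mvar_sources(spec, 5000, seed=2)
        model = fit_mvar(src, max_order=5)
        res = R.connectivity_spectrum(model, rc.BANDS["alpha"], src.fs)
        fs = rc.flow_summaries(res)
        assert fs["outflow"][0] > fs["inflow"][0]


class TestSimulateMVARHelpers:
    def test_stability_check(self):
        A = np.array([[[0.5, 0.0], [0.4, 0.5]]])
        assert is_stable(A)
        assert not is_stable(np.array([[[1.01, 0.0], [0.0, 0.5]]]))

    def test_simulation_batch_consistency(self):
        A = np.array([[[0.6]]])
        rng = np.random.default_rng(0)
        e = rng.standard_normal((4, 1200, 1))
        x = simulate_mvar(A, e, burn_in=200)
        assert x.shape == (4, 1, 1000)
        # each replicate matches a scalar recursion over its own innovations
        x0 = np.zeros(1200)
        for t in range(1, 1200):
            x0[t] = 0.6 * x0[t - 1] + e[0, t, 0]
        x0[0] = e[0, 0, 0]
        np.testing.assert_allclose(x[0, 0], x0[200:], atol=1e-10)
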
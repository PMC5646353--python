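"""CSD estimation, beamformer filters, coherence maps and source search."""

import numpy as np
import pytest

import restconn as rc
from restconn import dics, synthetic

from conftest import make_noise_recording, single_dipole_recording


def identity_filter(band, n=2):
    """Source-level 'filter' passing channels through unchanged."""

    class _LF:
        spacing = 1.0
        grid = np.zeros((n, 3))

    return dics.SpatialFilter(
        band=band, weights=np.eye(n), orientations=np.zeros((n, 3)),
        lf=_LF(), reg_frac=0.0,
    )


class TestCSDMatrix:
    def test_identical_channels_fully_coherent(self, alpha_band):
        r = np.random.default_rng(0)
        x = r.standard_normal(256 * 30)
        rec = rc.Recording(["a", "b"], 256.0, np.vstack([x, x]))
        csd = rc.csd_matrix(rc.segment(rec), alpha_band)
        coh = np.abs(csd.S[0, 1]) ** 2 / (csd.S[0, 0].real * csd.S[1, 1].real)
        assert coh == pytest.approx(1.0, abs=1e-6)

    def test_independent_noise_low_coherence(self, alpha_band):
        rec = make_noise_recording(n_channels=2, seconds=300.0, seed=1)
        csd = rc.csd_matrix(rc.segment(rec), alpha_band)
        coh = np.abs(csd.S[0, 1]) ** 2 / (csd.S[0, 0].real * csd.S[1, 1].real)
        assert coh < 0.1

    def test_flat_channel_named_in_error(self, alpha_band):
        r = np.random.default_rng(2)
        data = r.standard_normal((3, 256 * 20))
        data[1] = 0.0
        rec = rc.Recording(["a", "flat", "c"], 256.0, data)
        with pytest.raises(ValueError, match="flat"):
            rc.csd_matrix(rc.segment(rec), alpha_band)

    def test_too_few_segments_rejected(self, alpha_band):
        rec = make_noise_recording(n_channels=2, seconds=10.0)
        with pytest.raises(ValueError, match="segments"):
            rc.csd_matrix(rc.segment(rec), alpha_band)

    def test_hermitian_with_nonnegative_diagonal(self, alpha_band):
        rec = make_noise_recording(n_channels=4, seconds=30.0, seed=3)
        csd = rc.csd_matrix(rc.segment(rec), alpha_band)
        np.testing.assert_allclose(csd.S, csd.S.conj().T, atol=1e-15)
        assert (np.diag(csd.S).real >= 0).all()


class TestDICSFilter:
    def test_unit_gain_at_every_voxel(self, coarse_lead_field, alpha_band):
        rec, _ = single_dipole_recording(coarse_lead_field, 100, seconds=30.0)
        csd = rc.csd_matrix(rc.segment(rec), alpha_band)
        filt = rc.dics_filter(csd, coarse_lead_field)
        l_or = np.einsum(
            "vca,va->vc", coarse_lead_field.gains, filt.orientations
        )
        gains = np.einsum("vc,vc->v", filt.weights, l_or)
        np.testing.assert_allclose(gains, 1.0, rtol=1e-8)

    def test_single_dipole_localized_within_one_step(self, coarse_lead_field, alpha_band):
        vox = coarse_lead_field.nearest_voxel([20, 30, 25])
        rec, _ = single_dipole_recording(coarse_lead_field, vox, seconds=30.0, snr_db=10.0)
        csd = rc.csd_matrix(rc.segment(rec), alpha_band)
        filt = rc.dics_filter(csd, coarse_lead_field)
        est = int(np.argmax(rc.power_map(csd, filt)))
        dist = np.linalg.norm(
            coarse_lead_field.grid[est] - coarse_lead_field.grid[vox]
        )
        assert dist <= coarse_lead_field.spacing

    def test_negative_regularization_rejected(self, coarse_lead_field, alpha_band):
        rec = make_noise_recording(n_channels=60, seconds=30.0)
        rec.channel_labels = list(coarse_lead_field.channel_labels)
        csd = rc.csd_matrix(rc.segment(rec), alpha_band)
        with pytest.raises(ValueError):
            rc.dics_filter(csd, coarse_lead_field, reg_frac=-0.1)


class TestCoherenceMap:
    def test_self_coherence_is_one(self, coarse_lead_field, alpha_band):
        rec, _ = single_dipole_recording(coarse_lead_field, 50, seconds=30.0)
        csd = rc.csd_matrix(rc.segment(rec), alpha_band)
        filt = rc.dics_filter(csd, coarse_lead_field)
        for ref in (0, 50, coarse_lead_field.n_voxels - 1):
            coh = rc.coherence_map(csd, filt, ref)
            assert coh[ref] == pytest.approx(1.0, abs=1e-9)

    def test_values_bounded(self, coarse_lead_field, alpha_band):
        rec, _ = single_dipole_recording(coarse_lead_field, 50, seconds=30.0)
        csd = rc.csd_matrix(rc.segment(rec), alpha_band)
        filt = rc.dics_filter(csd, coarse_lead_field)
        coh = rc.coherence_map(csd, filt, 50)
        assert (coh >= 0).all() and (coh <= 1 + 1e-9).all()

    def test_coherent_partner_found_near_second_dipole(self, coarse_lead_field, alpha_band):
        spec = synthetic.ConnectivitySpec(
            n_sources=2, coupling=[(0, 1, 6, 0.7)], band_center_hz=[10.0, None]
        )
        src = synthetic.simulate_mvar_sources(spec, 256 * 120, fs=256.0, seed=4)
        va = coarse_lead_field.nearest_voxel([-30, 20, 25])
        vb = coarse_lead_field.nearest_voxel([30, -20, 25])
        rec = synthetic.project_to_scalp(
            src, coarse_lead_field.grid[[va, vb]], [[0, 0, 1.0]] * 2,
            coarse_lead_field, sensor_noise_snr=10.0, seed=5,
        )
        csd = rc.csd_matrix(rc.segment(rec), alpha_band)
        filt = rc.dics_filter(csd, coarse_lead_field)
        coh = rc.coherence_map(csd, filt, va)
        coh[va] = 0.0  # ignore the reference itself
        est = int(np.argmax(coh))
        dist = np.linalg.norm(coarse_lead_field.grid[est] - coarse_lead_field.grid[vb])
        assert dist <= coarse_lead_field.spacing

    def test_reference_outside_grid_rejected(self, coarse_lead_field, alpha_band):
        rec, _ = single_dipole_recording(coarse_lead_field, 50, seconds=30.0)
        csd = rc.csd_matrix(rc.segment(rec), alpha_band)
        filt = rc.dics_filter(csd, coarse_lead_field)
        with pytest.raises(IndexError):
            rc.coherence_map(csd, filt, coarse_lead_field.n_voxels)


class TestSurrogateThreshold:
    def test_independent_sources_rarely_exceed(self, alpha_band):
        # source-level calibration at the study's recording length
        exceed = 0
        for rep in range(20):
            spec = synthetic.ConnectivitySpec(n_sources=2, band_center_hz=10.0)
            src = synthetic.simulate_mvar_sources(spec, 256 * 240, fs=256.0, seed=rep)
            ep = rc.segment(rc.Recording(["a", "b"], 256.0, src.data))
            csd = rc.csd_matrix(ep, alpha_band)
            filt = identity_filter(alpha_band)
            coh = rc.coherence_map(csd, filt, 0)
            thr = rc.surrogate_threshold(ep, alpha_band, filt, 0, n_perm=100, seed=rep)
            exceed += int(coh[1] > thr[1])
        assert exceed <= 2  # ~1% nominal; tolerate sampling noise at 20 reps

    def test_coherent_pair_exceeds_threshold(self, alpha_band):
        spec = synthetic.ConnectivitySpec(
            n_sources=2, coupling=[(0, 1, 6, 0.7)], band_center_hz=[10.0, None]
        )
        src = synthetic.simulate_mvar_sources(spec, 256 * 120, fs=256.0, seed=0)
        ep = rc.segment(rc.Recording(["a", "b"], 256.0, src.data))
        csd = rc.csd_matrix(ep, alpha_band)
        filt = identity_filter(alpha_band)
        coh = rc.coherence_map(csd, filt, 0)
        thr = rc.surrogate_threshold(ep, alpha_band, filt, 0, n_perm=100, seed=1)
        assert coh[1] > thr[1]

    def test_too_few_permutations_rejected(self, alpha_band):
        src = synthetic.simulate_mvar_sources(
            synthetic.ConnectivitySpec(n_sources=2), 256 * 60, seed=0
        )
        ep = rc.segment(rc.Recording(["a", "b"], 256.0, src.data))
        with pytest.raises(ValueError):
            rc.surrogate_threshold(ep, alpha_band, identity_filter(alpha_band), 0, n_perm=10)


class TestFindCoherentSources:
    def test_three_node_network_recovered(self, coarse_lead_field, alpha_band):
        spec = synthetic.ConnectivitySpec(
            n_sources=3, coupling=[(0, 1, 6, 0.7), (1, 2, 6, 0.7)],
            band_center_hz=[10.0, None, None],
        )
        pos = coarse_lead_field.grid[
            [coarse_lead_field.nearest_voxel(p)
             for p in ([0, 40, 25], [-35, -20, 25], [35, -20, 25])]
        ]
        ok = 0
        n_seeds = 6
        for seed in range(n_seeds):
            src = synthetic.simulate_mvar_sources(spec, 256 * 120, fs=256.0, seed=seed)
            rec = synthetic.project_to_scalp(
                src, pos, [[0, 0, 1.0]] * 3, coarse_lead_field,
                sensor_noise_snr=10.0, seed=seed + 100,
            )
            ss = rc.find_coherent_sources(
                rc.segment(rec), alpha_band, coarse_lead_field, n_perm=40, seed=seed
            )
            hits = sum(
                1 for q in pos
                if np.linalg.norm(ss.positions - q, axis=1).min() <= coarse_lead_field.spacing
            )
            ok += int(ss.n_sources == 3 and hits == 3)
        assert ok >= round(0.9 * n_seeds)

    def test_single_dipole_yields_single_source(self, coarse_lead_field, alpha_band):
        vox = coarse_lead_field.nearest_voxel([20, 30, 25])
        rec, _ = single_dipole_recording(coarse_lead_field, vox, seconds=60.0, snr_db=10.0)
        ss = rc.find_coherent_sources(
            rc.segment(rec), alpha_band, coarse_lead_field, n_perm=40, seed=0
        )
        assert ss.n_sources == 1
        assert ss.flagged


class TestExtractSourceTimecourses:
    def test_noise_free_extraction_matches_truth(self, coarse_lead_field, alpha_band):
        vox = coarse_lead_field.nearest_voxel([20, 30, 25])
        rec, src = single_dipole_recording(
            coarse_lead_field, vox, seconds=30.0, snr_db=np.inf
        )
        ep = rc.segment(rec)
        csd = rc.csd_matrix(ep, alpha_band)
        filt = rc.dics_filter(csd, coarse_lead_field)
        ss = dics.SourceSet(
            band=alpha_band, voxel_indices=[vox],
            positions=coarse_lead_field.grid[[vox]],
            orientations=filt.orientations[[vox]], power=np.ones(1),
            coherence_to_ref=np.ones(1), surrogate_threshold=np.array([np.nan]),
        )
        tc = rc.extract_source_timecourses(ep, ss, filt)
        n = tc.data.shape[1]
        r = abs(np.corrcoef(tc.data[0], src.data[0][:n])[0, 1])
        assert r >= 0.99

    def test_shape_contract(self, coarse_lead_field, alpha_band):
        rec, _ = single_dipole_recording(coarse_lead_field, 60, seconds=30.0)
        ep = rc.segment(rec)
        csd = rc.csd_matrix(ep, alpha_band)
        filt = rc.dics_filter(csd, coarse_lead_field)
        ss = dics.SourceSet(
            band=alpha_band, voxel_indices=[10, 20],
            positions=coarse_lead_field.grid[[10, 20]],
            orientations=filt.orientations[[10, 20]], power=np.ones(2),
            coherence_to_ref=np.ones(2), surrogate_threshold=np.full(2, np.nan),
        )
        tc = rc.extract_source_timecourses(ep, ss, filt)
        assert tc.data.shape == (2, ep.n_windows * ep.windows.shape[2])
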
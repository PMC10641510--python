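"""Preprocessing chain: QC, artifact handling, dOD, filtering, Beer-Lambert."""
import numpy as np
import pytest
from scipy import signal as sps

from nirsnet.core import Interval, RawRecording, default_montage
from nirsnet.optics import dpf_general, extinction_matrix
from nirsnet.parafac import cp_als
from nirsnet.preprocess import (
    bandpass,
    beer_lambert,
    cardiac_coherence_qc,
    detect_artifacts,
    global_signal_regression,
    mark_exclusions,
    parafac_correct,
    preprocess_recording,
    to_delta_od,
)

FS = 7.8


def _raw_from_od(od, fs=FS, montage=None):
    montage = montage or default_montage(od.shape[0])
    return RawRecording(10.0 ** (-od), fs, (760.0, 850.0), montage)


class TestCardiacCoherenceQC:
    def _od(self, rng, n_ch=12, dur=720.0, noise=2e-4):
        t = np.arange(int(dur * FS)) / FS
        shared = 2e-3 * np.sin(2 * np.pi * 1.2 * t)
        return shared[None, None, :] + noise * rng.standard_normal((n_ch, 2, t.size))

    def test_shared_cardiac_tone_retains_all(self, rng):
        raw = _raw_from_od(self._od(rng))
        assert cardiac_coherence_qc(raw).all()

    def test_pure_noise_channel_excluded(self, rng):
        od = self._od(rng)
        od[4] = 2e-4 * rng.standard_normal(od.shape[1:])
        kept = cardiac_coherence_qc(_raw_from_od(od))
        assert not kept[4]
        assert kept.sum() == od.shape[0] - 1

    def test_identical_channels_all_retained(self, rng):
        t = np.arange(int(720 * FS)) / FS
        one = 2e-3 * np.sin(2 * np.pi * 1.0 * t) + 1e-4 * rng.standard_normal(t.size)
        od = np.tile(one, (6, 2, 1))
        assert cardiac_coherence_qc(_raw_from_od(od)).all()

    def test_too_short_recording_raises(self, rng):
        od = self._od(rng, dur=30.0)
        with pytest.raises(ValueError):
            cardiac_coherence_qc(_raw_from_od(od))


class TestDetectArtifacts:
    def _base(self, rng, n_ch=50, dur=300.0):
        return rng.standard_normal((n_ch, int(dur * FS)))

    def test_step_on_ten_percent_of_channels_detected(self, rng):
        x = self._base(rng)
        sl = slice(int(100 * FS), int(104 * FS))
        x[:5, sl] += 25.0  # 5/50 channels = 10%
        det = detect_artifacts(x, FS)
        assert len(det) == 1
        iv = det.intervals[0]
        assert iv.onset_s < 100.5 and iv.end_s > 103.5

    def test_below_channel_fraction_rule_ignored(self, rng):
        x = self._base(rng)
        x[0, int(100 * FS) : int(104 * FS)] += 25.0  # 2% of channels
        assert len(detect_artifacts(x, FS)) == 0

    def test_nearby_events_merged(self, rng):
        """Qualifying intervals less than 2 s apart come back as one event."""
        x = self._base(rng)
        a = slice(int(100 * FS), int(104 * FS))
        b = slice(int(105 * FS), int(109 * FS))  # 1 s gap
        x[:5, a] += 25.0
        x[:5, b] -= 25.0
        det = detect_artifacts(x, FS)
        assert len(det) == 1
        assert det.intervals[0].duration_s > 7.0

    def test_correlated_channels_added_to_event(self, rng):
        x = self._base(rng)
        sl = slice(int(50 * FS), int(54 * FS))
        bump = np.linspace(0, 1, sl.stop - sl.start) * 25.0
        x[:5, sl] += bump
        x[10, sl] += bump * 0.25  # same shape, below the run-length rule alone
        det = detect_artifacts(x, FS)
        assert len(det) == 1
        assert 10 in det.intervals[0].channels

    def test_short_series_raises(self, rng):
        with pytest.raises(ValueError):
            detect_artifacts(rng.standard_normal((3, 10)), FS)


class TestParafac:
    def test_rank1_artifact_removed(self, rng):
        t = np.arange(int(120 * FS)) / FS
        clean = np.stack(
            [
                np.stack([0.01 * np.sin(2 * np.pi * 0.05 * t + p)] * 2)
                for p in rng.uniform(0, 6, 15)
            ]
        )
        iv = Interval(50.0, 5.0, "artifact")
        sl = iv.sample_slice(FS)
        bump = np.zeros(t.size)
        bump[sl] = 0.2 * np.hanning(sl.stop - sl.start)
        art = (
            rng.uniform(0.5, 1.5, 15)[:, None, None]
            * np.array([1.0, 0.8])[None, :, None]
            * bump[None, None, :]
        )
        fixed, info = parafac_correct(clean + art, iv, FS, rank=3)
        assert info["corrected"]
        resid = fixed[:, :, sl] - clean[:, :, sl]
        rel = np.sqrt((resid**2).mean()) / np.sqrt((art[:, :, sl] ** 2).mean())
        assert rel < 0.10

    def test_no_artifact_leaves_signal_unchanged(self, rng):
        t = np.arange(int(60 * FS)) / FS
        clean = np.stack(
            [np.stack([0.01 * np.sin(2 * np.pi * 0.05 * t + p)] * 2) for p in rng.uniform(0, 6, 8)]
        )
        fixed, info = parafac_correct(clean, Interval(30.0, 4.0, "artifact"), FS, rank=2)
        if not info["corrected"]:
            np.testing.assert_array_equal(fixed, clean)
        else:
            assert np.abs(fixed - clean).max() < 0.1 * np.abs(clean).max()

    def test_exact_rank2_tensor_recovered(self, rng):
        a = rng.standard_normal((40, 2))
        b = rng.standard_normal((10, 2))
        c = rng.standard_normal((2, 2))
        tensor = np.einsum("ir,jr,kr->ijk", a, b, c)
        fit = cp_als(tensor, 2, seed=0)
        assert 1 - fit.rel_error**2 >= 0.999


class TestMaskingAndDOD:
    def test_empty_annotations_all_valid(self):
        from nirsnet.core import AnnotationSet

        mask = mark_exclusions(AnnotationSet(), 1000, FS)
        assert mask.all()

    def test_thirty_second_exclusion_sample_count(self):
        from nirsnet.core import AnnotationSet

        n = int(720 * FS)
        ann = AnnotationSet([Interval(100.0, 30.0, "exclusion")])
        mask = mark_exclusions(ann, n, FS)
        assert (~mask).sum() == int(np.ceil(130.0 * FS)) - int(np.floor(100.0 * FS))

    def test_overlapping_intervals_union(self):
        from nirsnet.core import AnnotationSet

        n = int(200 * FS)
        ann = AnnotationSet(
            [Interval(50.0, 30.0, "exclusion"), Interval(60.0, 30.0, "artifact")]
        )
        mask = mark_exclusions(ann, n, FS, long_noise_s=10.0)
        expected = int(np.ceil(90.0 * FS)) - int(np.floor(50.0 * FS))
        assert (~mask).sum() == expected

    def test_delta_od_definition(self):
        const = np.full((2, 2, 100), 3.0)
        assert np.allclose(to_delta_od(const), 0.0)
        x = np.ones((1, 2, 10))
        x[0, :, 4] = np.mean(x[0, 0]) / 10  # a dip to I_ref/10 -> dOD ~ 1
        dod = to_delta_od(x)
        assert dod[0, 0, 4] == pytest.approx(1.0, abs=0.05)

    def test_delta_od_round_trip(self, rng):
        intensity = np.exp(rng.normal(0, 0.01, (3, 2, 500)))
        dod = to_delta_od(intensity)
        ref = intensity.mean(axis=-1, keepdims=True)
        np.testing.assert_allclose(ref * 10.0 ** (-dod), intensity, rtol=1e-12)

    def test_nonpositive_intensity_rejected(self):
        with pytest.raises(ValueError):
            to_delta_od(np.zeros((1, 2, 10)))


class TestBandpass:
    def test_passband_tone_unit_gain_zero_lag(self):
        t = np.arange(int(720 * FS)) / FS
        x = np.sin(2 * np.pi * 0.1 * t)
        y, _ = bandpass(x[None, :], FS)
        seg = slice(t.size // 4, 3 * t.size // 4)
        gain = y[0, seg].std() / x[seg].std()
        assert 0.95 <= gain <= 1.0
        lag = np.argmax(np.correlate(y[0, seg], x[seg], "full")) - (x[seg].size - 1)
        assert lag == 0

    def test_stopband_attenuation_matches_squared_response(self):
        """Forward-backward filtering squares the 4th-order magnitude: a
        1.5 Hz tone is suppressed by >60 dB (a single 4th-order pass would
        only give ~42 dB)."""
        t = np.arange(int(720 * FS)) / FS
        x = np.sin(2 * np.pi * 1.5 * t)
        y, _ = bandpass(x[None, :], FS)
        seg = slice(t.size // 4, 3 * t.size // 4)
        assert y[0, seg].std() / x[seg].std() < 1e-3

    def test_dc_rejected(self):
        y, _ = bandpass(np.ones((1, int(720 * FS))), FS)
        assert np.abs(y[0, 100:-100]).max() < 1e-10

    def test_masked_segments_filtered_independently(self, rng):
        n = int(400 * FS)
        x = rng.standard_normal((2, n))
        mask = np.ones(n, bool)
        mask[n // 2 : n // 2 + 100] = False
        y, mask_out = bandpass(x, FS, valid_mask=mask)
        assert not y[:, n // 2 : n // 2 + 100].any()
        # filtering the first segment alone gives the same result
        y_first, _ = bandpass(x[:, : n // 2], FS)
        np.testing.assert_allclose(y[:, : n // 2], y_first, atol=1e-12)

    def test_short_segment_dropped_with_warning(self, rng):
        n = int(100 * FS)
        mask = np.zeros(n, bool)
        mask[:50] = True
        with pytest.warns(UserWarning):
            _, mask_out = bandpass(rng.standard_normal((1, n)), FS, valid_mask=mask)
        assert not mask_out.any()


class TestBeerLambert:
    def test_zero_od_zero_concentration(self, montage20):
        dod = np.zeros((20, 2, 50))
        hbo, hbr, _ = beer_lambert(dod, (760.0, 850.0), 10.0, montage20)
        assert not hbo.any() and not hbr.any()

    def test_forward_inverse_round_trip(self, rng, montage20):
        """Projecting known concentrations to dOD and inverting recovers
        them to 1e-10 relative error."""
        hbo_true = rng.normal(0, 1.0, (20, 300))
        hbr_true = rng.normal(0, 0.4, (20, 300))
        age = 9.0
        eps = extinction_matrix((760.0, 850.0))
        dpf = np.array([dpf_general(lam, age) for lam in (760.0, 850.0)])
        dist = montage20.distance_mm / 10.0
        dod = np.einsum("wk,kct->cwt", eps, np.stack([hbo_true, hbr_true])) * (
            dist[:, None, None] * dpf[None, :, None]
        )
        hbo, hbr, _ = beer_lambert(dod, (760.0, 850.0), age, montage20)
        np.testing.assert_allclose(hbo, hbo_true, rtol=1e-10, atol=1e-12)
        np.testing.assert_allclose(hbr, hbr_true, rtol=1e-10, atol=1e-12)

    def test_doubling_dpf_halves_concentrations(self, rng, montage20):
        dod = rng.normal(0, 0.01, (20, 2, 100))
        hbo1, hbr1, dpf = beer_lambert(dod, (760.0, 850.0), 10.0, montage20)
        hbo2, hbr2, _ = beer_lambert(
            dod, (760.0, 850.0), 10.0, montage20, dpf_override=(2 * dpf[0], 2 * dpf[1])
        )
        np.testing.assert_allclose(hbo2, hbo1 / 2)
        np.testing.assert_allclose(hbr2, hbr1 / 2)

    def test_singular_extinction_rejected(self, montage20):
        with pytest.raises(ValueError):
            beer_lambert(
                np.zeros((20, 2, 10)),
                (760.0, 850.0),
                10.0,
                montage20,
                extinction_override=((1.0, 2.0), (2.0, 4.0)),
            )


class TestGlobalSignalRegression:
    def test_identical_channels_zero_residual(self, rng):
        x = np.tile(rng.standard_normal(500), (5, 1))
        resid = global_signal_regression(x)
        assert np.abs(resid).max() < 1e-10

    def test_residuals_orthogonal_to_global_mean(self, rng):
        x = rng.standard_normal((10, 2000))
        resid = global_signal_regression(x)
        g = x.mean(axis=0)
        g = g - g.mean()
        for c in range(10):
            r = resid[c] - resid[c].mean()
            assert abs(np.dot(r, g) / (np.linalg.norm(r) * np.linalg.norm(g))) < 1e-10

    def test_orthogonal_channel_passes_through(self, rng):
        g = np.sin(2 * np.pi * 0.01 * np.arange(4000))
        orth = np.cos(2 * np.pi * 0.01 * np.arange(4000))
        # global mean is g/2: the orth channel is orthogonal to it
        x = np.vstack([g, g, orth, -orth])
        resid = global_signal_regression(x)
        np.testing.assert_allclose(resid[2], orth - orth.mean(), atol=1e-8)


def test_full_preprocess_chain_runs(short_cfg):
    """Stage order smoke: QC -> detection -> correction -> dOD -> filter ->
    Beer-Lambert -> GSR, with masks carried through."""
    from nirsnet.simcohort import generate_subject

    cfg = short_cfg
    rec, ann, _ = generate_subject(cfg, seed=8)
    series, report = preprocess_recording(rec, ann, seed=0)
    assert series.hbo.shape == (cfg.n_channels, rec.n_times)
    assert series.valid_mask.shape == (rec.n_times,)
    assert np.isfinite(series.hbo[:, series.valid_mask]).all()
    assert 0 < report.percent_valid <= 100
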
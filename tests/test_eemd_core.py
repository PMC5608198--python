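import numpy as np
import pytest

from emtqa.eemd_core import (
    IMFSet,
    dominant_frequency,
    eemd,
    emd,
    fourier_area,
    identify_breathing_imfs,
    protection_scores,
    remove_breathing,
    select_protected_imfs,
)

FS = 40.0


def _two_tone(T=1200, f_hi=2.0, f_lo=0.25, a_hi=1.0, a_lo=3.0):
    t = np.arange(T) / FS
    return (a_hi * np.sin(2 * np.pi * f_hi * t),
            a_lo * np.sin(2 * np.pi * f_lo * t), t)


class TestEMD:
    def test_monotone_ramp_is_trend_only(self):
        imfset = emd(np.linspace(0.0, 10.0, 200))
        assert imfset.n_imfs == 1
        assert np.allclose(imfset.trend, np.linspace(0.0, 10.0, 200))

    def test_exact_additive_reconstruction(self, rng):
        x = rng.normal(size=500) + np.linspace(0, 5, 500)
        imfset = emd(x)
        assert np.allclose(imfset.reconstruction(), x, atol=1e-8)

    def test_separates_well_spaced_tones(self):
        hi, lo, _ = _two_tone()
        imfset = emd(hi + lo)
        corr_hi = abs(np.corrcoef(imfset.imfs[0], hi)[0, 1])
        assert corr_hi > 0.95
        best_lo = max(abs(np.corrcoef(c, lo)[0, 1]) for c in imfset.imfs[1:])
        assert best_lo > 0.9

    def test_imfs_ordered_by_decreasing_dominant_frequency(self):
        t = np.arange(1600) / FS
        x = (np.sin(2 * np.pi * 4.0 * t) + 2 * np.sin(2 * np.pi * 0.8 * t)
             + 3 * np.sin(2 * np.pi * 0.15 * t))
        imfset = emd(x)
        freqs = [dominant_frequency(c, 1 / FS) for c in imfset.imfs[:-1]]
        assert all(a >= b * 0.9 for a, b in zip(freqs, freqs[1:]))

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            emd(np.arange(4.0))

    def test_non_oscillating_trend_has_almost_no_extrema(self, rng):
        # sifting stops once the residual lacks two maxima or two minima,
        # so the trend carries at most three interior extrema
        x = rng.normal(size=600) + np.linspace(0, 8, 600)
        trend = emd(x).trend
        d = np.sign(np.diff(trend))
        d = d[d != 0]
        sign_changes = np.sum(d[1:] != d[:-1])
        assert sign_changes <= 3


class TestEEMD:
    def test_degenerate_ensemble_equals_emd(self, rng):
        x = rng.normal(size=300)
        a = eemd(x, E=1, noise_sd=0.0, seed=0)
        b = emd(x)
        assert np.array_equal(a.imfs, b.imfs)

    def test_deterministic_under_seed(self, rng):
        x = rng.normal(size=300)
        a = eemd(x, E=5, noise_sd=0.2, seed=3)
        b = eemd(x, E=5, noise_sd=0.2, seed=3)
        assert np.array_equal(a.imfs, b.imfs)

    def test_reconstruction_within_ensemble_noise_tolerance(self, rng):
        x = rng.normal(size=400) + np.linspace(0, 4, 400)
        E, noise_sd = 10, 0.2
        imfset = eemd(x, E=E, noise_sd=noise_sd, seed=1)
        residual_sd = np.std(imfset.reconstruction() - x)
        assert residual_sd <= noise_sd * np.std(x) / np.sqrt(E) + 1e-6

    def test_ensemble_no_worse_than_single_run_on_noisy_tones(self):
        hi, lo, _ = _two_tone(T=800)
        scores_e1, scores_e10 = [], []
        for seed in range(5):
            noisy = hi + lo + np.random.default_rng(seed).normal(0, 0.3, 800)
            for E, out in ((1, scores_e1), (10, scores_e10)):
                imfset = eemd(noisy, E=E, noise_sd=0.2, seed=seed)
                out.append(max(abs(np.corrcoef(c, lo)[0, 1])
                               for c in imfset.imfs))
        assert np.mean(scores_e10) >= np.mean(scores_e1) - 0.02


class TestFourierArea:
    def test_zero_series(self):
        assert fourier_area(np.zeros(64), T_s=1 / FS) == 0.0

    def test_unit_impulse_closed_form(self):
        # |C(r)| = 1 for every r, so A = T / (T * T_s) = 1 / T_s = 40
        x = np.zeros(40)
        x[0] = 1.0
        assert fourier_area(x, T_s=1 / 40) == pytest.approx(40.0)

    def test_homogeneous_in_amplitude(self, rng):
        x = rng.normal(size=128)
        assert fourier_area(3.5 * x, 1 / FS) == pytest.approx(
            3.5 * fourier_area(x, 1 / FS))


class TestProtection:
    def test_all_zero_areas_protect_nothing(self):
        imfset = IMFSet(imfs=np.zeros((3, 100)))
        assert select_protected_imfs(imfset, A_th=0.04) == set()

    def test_threshold_on_explicit_areas(self):
        imfset = IMFSet(imfs=np.zeros((2, 10)))
        assert select_protected_imfs(
            imfset, A_th=0.04, areas=np.array([0.05, 0.01])) == {0}

    def test_negative_threshold_protects_everything(self, rng):
        imfset = IMFSet(imfs=rng.normal(size=(4, 200)))
        assert select_protected_imfs(imfset, A_th=-1.0) == {0, 1, 2, 3}

    def test_broadband_scores_high_narrowband_scores_low(self, rng):
        t = np.arange(2000) / FS
        broadband = rng.normal(size=2000)
        narrow = np.sin(2 * np.pi * 0.3 * t)
        imfset = IMFSet(imfs=np.vstack([broadband, narrow]))
        scores = protection_scores(imfset)
        assert scores[0] > 0.04 > scores[1]


class TestIdentifyAndRemove:
    def _sets(self, sensor_rows, breathing_rows):
        return (IMFSet(imfs=np.asarray(sensor_rows)),
                IMFSet(imfs=np.asarray(breathing_rows)))

    def test_identical_mode_is_flagged_under_pcc(self):
        t = np.arange(1000) / FS
        tone = np.sin(2 * np.pi * 0.3 * t)
        trend = np.linspace(0, 1, 1000)
        sensor, breathing = self._sets([tone, trend], [tone, 0.1 * trend])
        assert identify_breathing_imfs(sensor, breathing, "pcc", 0.5) == {0}

    def test_zero_breathing_flags_nothing(self):
        t = np.arange(1000) / FS
        sensor, breathing = self._sets(
            [np.sin(2 * np.pi * 0.3 * t)], np.zeros((2, 1000)))
        assert identify_breathing_imfs(sensor, breathing, "pcc", 0.5) == set()

    def test_protected_modes_are_never_flagged(self):
        t = np.arange(1000) / FS
        tone = np.sin(2 * np.pi * 0.3 * t)
        sensor, breathing = self._sets([tone, np.zeros(1000)], [tone, np.zeros(1000)])
        flagged = identify_breathing_imfs(sensor, breathing, "pcc", 0.5,
                                          protected={0})
        assert flagged == set()

    def test_out_of_band_modes_are_not_flagged(self):
        t = np.arange(4000) / FS
        slow = np.sin(2 * np.pi * 0.02 * t)  # 50 s period: not breathing
        sensor, breathing = self._sets([slow, np.zeros(4000)],
                                       [slow, np.zeros(4000)])
        assert identify_breathing_imfs(sensor, breathing, "pcc", 0.5) == set()

    def test_unknown_measure_rejected(self):
        sensor, breathing = self._sets(np.ones((2, 50)), np.ones((2, 50)))
        with pytest.raises(ValueError, match="unknown similarity measure"):
            identify_breathing_imfs(sensor, breathing, measure="cosine")

    def test_injected_tone_flagged_under_all_measures(self):
        t = np.arange(2000) / FS
        breathing_tone = 3 * np.sin(2 * np.pi * 0.3 * t)
        track = np.cumsum(np.random.default_rng(0).normal(0, 0.02, 2000))
        sensor_imfs = emd(track + breathing_tone)
        breathing_imfs = emd(breathing_tone + 1e-3 * np.random.default_rng(1).normal(size=2000))
        oracle = int(np.argmax([abs(np.corrcoef(c, breathing_tone)[0, 1])
                                for c in sensor_imfs.imfs]))
        for measure in ("pcc", "kld", "jsd"):
            flagged = identify_breathing_imfs(
                sensor_imfs, breathing_imfs, measure)  # default thresholds
            assert oracle in flagged, measure

    def test_empty_flag_set_reproduces_signal(self, rng):
        x = rng.normal(size=400)
        imfset = emd(x)
        out = remove_breathing(x, set(), imfset)
        assert np.allclose(out, x, atol=1e-8)

    def test_flagging_all_non_trend_leaves_trend(self, rng):
        x = rng.normal(size=400) + np.linspace(0, 5, 400)
        imfset = emd(x)
        flagged = set(range(imfset.n_imfs - 1))
        assert np.array_equal(remove_breathing(x, flagged, imfset), imfset.trend)

    def test_removal_reduces_rms_against_known_track(self):
        t = np.arange(2000) / FS
        tone = 3 * np.sin(2 * np.pi * 0.3 * t)
        track = 0.05 * np.arange(2000)
        noisy = track + tone
        sensor_imfs = eemd(noisy, E=5, noise_sd=0.1, seed=0)
        breathing_imfs = emd(tone + 1e-3 * np.random.default_rng(2).normal(size=2000))
        protected = select_protected_imfs(sensor_imfs)
        protected.add(sensor_imfs.trend_index)
        flagged = identify_breathing_imfs(sensor_imfs, breathing_imfs,
                                          "pcc", 0.4, protected)
        assert flagged
        cleaned = remove_breathing(noisy, flagged, sensor_imfs)
        assert (np.sqrt(np.mean((cleaned - track) ** 2))
                < np.sqrt(np.mean((noisy - track) ** 2)))
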
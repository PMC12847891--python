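"""TF-peak detection: multitaper spectrogram, baseline flattening,
watershed segmentation + merging, extraction filters, brute-force oracle."""

import numpy as np
import pytest

from somnipeak.synthdata import generate_background
from somnipeak.tfpeaks import (Spectrogram, TFPeakConfig, brute_force_peaks,
                               detect_tfpeaks, extract_peaks, flatten_baseline,
                               merge_regions, multitaper_spectrogram,
                               watershed_segment)

FS = 100.0


def db_surface(values):
    """Wrap a 2-D array as a flattened (dB) spectrogram on unit grids."""
    values = np.asarray(values, dtype=float)
    return Spectrogram(values, np.arange(values.shape[0], dtype=float),
                       np.arange(values.shape[1], dtype=float), db=True)


def gaussian_bump(shape, ci, cj, amp, si=3.0, sj=2.0):
    tt, ff = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
    return amp * np.exp(-(((tt - ci) / si) ** 2 + ((ff - cj) / sj) ** 2))


class TestMultitaper:
    def test_parseval(self):
        x = np.random.default_rng(0).standard_normal(1000)
        spec = multitaper_spectrogram(x, FS)
        total = (spec.power.mean(axis=0) * spec.df).sum()
        assert total == pytest.approx(x.var(), rel=0.15)

    def test_sinusoid_peak_bin(self):
        t = np.arange(1000) / FS
        spec = multitaper_spectrogram(np.sin(2 * np.pi * 13 * t), FS)
        peak_f = spec.freqs[spec.power.mean(axis=0).argmax()]
        assert abs(peak_f - 13.0) <= spec.df

    def test_zero_signal(self):
        spec = multitaper_spectrogram(np.zeros(500), FS)
        assert np.all(spec.power == 0.0)

    def test_too_short_signal(self):
        with pytest.raises(ValueError):
            multitaper_spectrogram(np.zeros(50), FS, window_s=1.0)


class TestFlattenBaseline:
    def test_stationary_noise_near_zero(self):
        x = generate_background(60_000, FS, 1.0, seed=4)
        flat = flatten_baseline(multitaper_spectrogram(x, FS))
        # most cells cluster a few dB above the 2nd-percentile baseline
        frac = np.mean(np.abs(flat.power - np.median(flat.power)) <= 3.0)
        assert frac > 0.6
        assert np.median(flat.power) < 10.0

    def test_shift_invariance(self):
        x = generate_background(20_000, FS, 1.0, seed=5)
        spec = multitaper_spectrogram(x, FS)
        a = flatten_baseline(spec)
        spec10 = Spectrogram(spec.power * 10.0, spec.times, spec.freqs)
        b = flatten_baseline(spec10)
        assert np.allclose(a.power, b.power, atol=1e-9)

    def test_burst_on_silence_localized(self):
        t = np.arange(3000) / FS
        x = 0.01 * np.random.default_rng(6).standard_normal(3000)
        burst = np.zeros(3000)
        mid = 1500
        burst[mid - 40:mid + 41] = np.hanning(81) * np.cos(2 * np.pi * 13 * t[:81])
        flat = flatten_baseline(multitaper_spectrogram(x + burst, FS))
        ti = np.argmin(np.abs(flat.times - 15.0))
        fi = np.argmin(np.abs(flat.freqs - 13.0))
        assert flat.power[ti, fi] > 20.0


class TestWatershed:
    def test_two_separated_bumps(self):
        img = np.full((100, 60), -20.0)
        img += gaussian_bump(img.shape, 25, 15, 30.0)
        img += gaussian_bump(img.shape, 75, 45, 25.0)
        labels = watershed_segment(db_surface(img))
        assert labels.max() == 2

    def test_single_bump_argmax(self):
        img = np.full((50, 30), -20.0) + gaussian_bump((50, 30), 20, 10, 30.0)
        flat = db_surface(img)
        labels = watershed_segment(flat)
        peaks = extract_peaks(labels, flat, fmin=0, fmax=30, dur_min_s=0,
                              dur_max_s=np.inf, bw_min_hz=0, bw_max_hz=np.inf)
        assert len(peaks) == 1
        assert (peaks[0].time_s, peaks[0].freq_hz) == (20.0, 10.0)

    def test_constant_surface_empty(self):
        labels = watershed_segment(db_surface(np.full((20, 20), 5.0)))
        assert labels.max() == 0

    def test_every_masked_cell_labeled(self):
        img = np.full((60, 40), -20.0)
        img += gaussian_bump(img.shape, 20, 10, 30.0)
        img += gaussian_bump(img.shape, 40, 30, 28.0)
        labels = watershed_segment(db_surface(img))
        assert np.all((labels > 0) == (img > 0.0))


class TestMergeRegions:
    def _two_bump_flat(self, saddle_gap):
        """Two bumps along the time axis whose saddle sits ``saddle_gap`` dB
        below the lower peak."""
        img = np.full((80, 20), -30.0)
        x = np.arange(80)
        lower_peak, saddle = 10.0, 10.0 - saddle_gap
        prof = np.interp(x, [10, 30, 40, 50, 70],
                         [-30.0, 12.0, saddle, lower_peak, -30.0])
        img[:, 8] = prof
        return db_surface(img)

    def test_shallow_saddle_merges(self):
        flat = self._two_bump_flat(0.2)
        labels = watershed_segment(flat)
        assert labels.max() == 2
        merged = merge_regions(labels, flat, prominence_min_db=1.0)
        assert merged.max() == 1

    def test_deep_saddle_survives(self):
        flat = self._two_bump_flat(0.2)
        labels = watershed_segment(flat)
        merged = merge_regions(labels, flat, prominence_min_db=0.1)
        assert merged.max() == 2

    def test_isolated_regions_untouched(self):
        img = np.full((100, 60), -20.0)
        img += gaussian_bump(img.shape, 25, 15, 30.0)
        img += gaussian_bump(img.shape, 75, 45, 25.0)
        flat = db_surface(img)
        labels = watershed_segment(flat)
        merged = merge_regions(labels, flat, prominence_min_db=5.0)
        assert merged.max() == labels.max()

    def test_count_monotone_in_prominence(self):
        rng = np.random.default_rng(9)
        img = rng.standard_normal((120, 40)) * 3 + 5.0
        flat = db_surface(img)
        labels = watershed_segment(flat)
        counts = [merge_regions(labels, flat, prominence_min_db=h).max()
                  for h in (0.5, 1.0, 2.0, 4.0)]
        assert counts == sorted(counts, reverse=True)


class TestExtractPeaks:
    def test_out_of_band_excluded(self):
        img = np.full((50, 50), -20.0) + gaussian_bump((50, 50), 25, 30, 30.0)
        flat = db_surface(img)
        labels = watershed_segment(flat)
        assert extract_peaks(labels, flat, fmin=4, fmax=25) == []

    def test_empty_region_set(self):
        flat = db_surface(np.full((10, 10), -5.0))
        assert extract_peaks(np.zeros((10, 10), np.int32), flat) == []


class TestBruteForce:
    def test_isolated_spike(self):
        img = np.full((10, 10), -5.0)
        img[4, 7] = 3.0
        out = brute_force_peaks(db_surface(img))
        assert out == [(4.0, 7.0)]

    def test_constant_empty(self):
        assert brute_force_peaks(db_surface(np.full((5, 5), 2.0))) == []


class TestOracleEquivalence:
    """Watershed extraction must match the exhaustive scan on noise-free
    surfaces of isolated bumps (cell-exact)."""

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force(self, seed):
        from somnipeak.experiments import _random_bump_surface

        img = _random_bump_surface(seed)
        flat = db_surface(img)
        labels = watershed_segment(flat)
        peaks = extract_peaks(labels, flat, fmin=0, fmax=img.shape[1],
                              dur_min_s=0, dur_max_s=np.inf,
                              bw_min_hz=0, bw_max_hz=np.inf)
        got = sorted((p.time_s, p.freq_hz) for p in peaks)
        assert got == sorted(brute_force_peaks(flat))


class TestDetectionPerformance:
    def test_injected_bursts_recovered(self, n2_recording):
        rec, events, _ = n2_recording
        peaks = detect_tfpeaks(rec.channel("C3"), FS)
        pt = np.array([p.time_s for p in peaks])
        pf = np.array([p.freq_hz for p in peaks])
        hits = sum(
            bool(np.any((np.abs(pt - t) <= 0.5) & (np.abs(pf - f) <= 1.5)))
            for t, f in events[["time_s", "freq_hz"]].to_numpy())
        assert hits / len(events) >= 0.9

    def test_false_positive_rate_on_noise(self):
        from somnipeak.synthdata import generate_so

        so = generate_so(["N2"] * 12, FS, 2.0, seed=51)
        noise = generate_background(len(so.signal), FS, 1.0, seed=52) + so.signal
        peaks = detect_tfpeaks(noise, FS)
        assert len(peaks) / 6.0 < 5.0

    def test_peak_fields_within_bounds(self, n2_recording):
        rec, _, _ = n2_recording
        cfg = TFPeakConfig()
        for p in detect_tfpeaks(rec.channel("C3"), FS, cfg):
            assert cfg.fmin_hz <= p.freq_hz <= cfg.fmax_hz
            assert cfg.dur_min_s <= p.duration_s <= cfg.dur_max_s
            assert cfg.bw_min_hz <= p.bandwidth_hz <= cfg.bw_max_hz
            assert p.prominence_db >= 0
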
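"""SO-state estimation and coupling histograms."""

import numpy as np
import pandas as pd
import pytest

from somnipeak.preprocess import ConditionMask, StagedRecording, condition_mask
from somnipeak.socoupling import (CoupledHistogram, SOSeries, annotate_peaks,
                                  compute_so_series, default_freq_edges,
                                  group_average_and_diff, phase_histogram,
                                  power_histogram, rem_iqr_filter,
                                  so_phase_series, so_power_series,
                                  to_percentile)

FS = 100.0


def sinusoid(freq, seconds=60.0, amp=1.0):
    t = np.arange(int(seconds * FS)) / FS
    return amp * np.cos(2 * np.pi * freq * t)


class TestSoPowerSeries:
    def test_zero_signal(self):
        _, p, _ = so_power_series(np.zeros(6000), FS, np.ones(6000, bool))
        assert np.allclose(p, 0.0)

    def test_amplitude_scaling(self):
        x = sinusoid(0.75)
        _, p1, _ = so_power_series(x, FS, np.ones(len(x), bool))
        _, p2, _ = so_power_series(2 * x, FS, np.ones(len(x), bool))
        mid = slice(len(p1) // 4, -len(p1) // 4)
        assert np.allclose(p2[mid], 4 * p1[mid], rtol=0.02)

    def test_band_selectivity(self):
        so = sinusoid(0.75)
        fast = sinusoid(10.0)
        ones = np.ones(len(so), bool)
        _, p_so, _ = so_power_series(so, FS, ones)
        _, p_fast, _ = so_power_series(fast, FS, ones)
        assert p_so.mean() / max(p_fast.mean(), 1e-30) > 10

    def test_short_mask_rejected(self):
        with pytest.raises(ValueError):
            so_power_series(np.zeros(6000), FS, np.zeros(6000, bool))


class TestToPercentile:
    def test_average_rank_formula(self):
        out = to_percentile(np.array([1.0, 2, 3, 4, 5] + [0] * 5),
                            np.array([True] * 5 + [False] * 5))
        assert np.allclose(out[:5], [10, 30, 50, 70, 90])
        assert np.all(np.isnan(out[5:]))

    def test_monotone_invariance(self):
        rng = np.random.default_rng(3)
        raw = rng.random(50)
        valid = np.ones(50, bool)
        assert np.allclose(to_percentile(raw, valid),
                           to_percentile(np.exp(3 * raw), valid))

    def test_constant_series(self):
        with pytest.warns(UserWarning):
            out = to_percentile(np.ones(20), np.ones(20, bool))
        assert np.all(out == 50.0)


class TestSoPhaseSeries:
    def test_trough_is_zero(self):
        x = sinusoid(0.75)
        phase, ok = so_phase_series(x, FS)
        assert ok.all()
        minima = np.flatnonzero((x[1:-1] < x[:-2]) & (x[1:-1] < x[2:])) + 1
        inner = minima[(minima > 500) & (minima < len(x) - 500)]
        assert np.abs(phase[inner]).max() < 0.05

    def test_peak_is_pi(self):
        x = sinusoid(0.75)
        phase, _ = so_phase_series(x, FS)
        maxima = np.flatnonzero((x[1:-1] > x[:-2]) & (x[1:-1] > x[2:])) + 1
        inner = maxima[(maxima > 500) & (maxima < len(x) - 500)]
        assert (np.pi - np.abs(phase[inner])).max() < 0.05

    def test_cycle_slope(self):
        x = sinusoid(0.75, seconds=120.0)
        phase, _ = so_phase_series(x, FS)
        un = np.unwrap(phase[1000:-1000])
        slope = np.polyfit(np.arange(len(un)) / FS, un, 1)[0]
        assert slope == pytest.approx(2 * np.pi * 0.75, rel=0.01)

    def test_zero_signal_flagged(self):
        phase, ok = so_phase_series(np.zeros(2000), FS)
        assert not ok.any()


class TestAnnotate:
    @staticmethod
    def _series():
        times = np.arange(100) * 0.1 + 15.0
        return SOSeries(times=times, power_raw=np.ones(100),
                        power_pct=np.linspace(0, 99, 100),
                        phase_rad=np.linspace(-3, 3, 100),
                        valid=np.r_[np.zeros(10, bool), np.ones(90, bool)],
                        step_s=0.1)

    def test_exact_timestamp(self):
        so = self._series()
        peaks = pd.DataFrame({"time_s": [so.times[50]], "freq_hz": [13.0]})
        out, dropped = annotate_peaks(peaks, so)
        assert dropped == 0
        assert out["power_pct"].iloc[0] == pytest.approx(so.power_pct[50])
        assert out["phase_rad"].iloc[0] == pytest.approx(so.phase_rad[50], abs=1e-6)

    def test_invalid_sample_dropped(self):
        so = self._series()
        peaks = pd.DataFrame({"time_s": [so.times[5]], "freq_hz": [13.0]})
        out, dropped = annotate_peaks(peaks, so)
        assert len(out) == 0 and dropped == 1

    def test_nearest_mode_matches_linear_search(self):
        so = self._series()
        rng = np.random.default_rng(7)
        t = rng.uniform(so.times[0], so.times[-1], 1000)
        peaks = pd.DataFrame({"time_s": t, "freq_hz": np.full(1000, 13.0)})
        out, _ = annotate_peaks(peaks, so, interpolate=False)
        # brute-force nearest-sample oracle
        kept, expected = [], []
        for ti in t:
            j = int(np.argmin(np.abs(so.times - ti)))
            if so.valid[j]:
                expected.append(so.power_pct[j])
        assert np.allclose(out["power_pct"].to_numpy(), expected)


class TestRemIqr:
    def test_rules(self):
        peaks = pd.DataFrame({"time_s": [1, 2, 3], "freq_hz": [13.0] * 3,
                              "power_pct": [80.0, 50.0, 20.0],
                              "phase_rad": [0.0] * 3})
        rem = rem_iqr_filter(peaks, "REM")
        assert rem["power_pct"].tolist() == [50.0]
        nrem = rem_iqr_filter(peaks, "NREM")
        assert len(nrem) == 3


class TestPowerHistogram:
    @staticmethod
    def _series(minutes=20.0):
        n = int(minutes * 600)
        times = np.arange(n) * 0.1 + 15.0
        rng = np.random.default_rng(0)
        pct = (np.argsort(np.argsort(rng.random(n))) + 0.5) / n * 100
        return SOSeries(times, np.ones(n), pct, np.zeros(n),
                        np.ones(n, bool), 0.1)

    def test_density_division(self):
        so = self._series(minutes=20.0)
        peaks = pd.DataFrame({"time_s": [16.0] * 10, "freq_hz": [13.5] * 10,
                              "power_pct": [90.0] * 10, "phase_rad": [0.0] * 10})
        hist = power_histogram(peaks, so)
        fi = np.flatnonzero((hist.freq_edges[:-1] <= 13.5)
                            & (hist.freq_edges[1:] > 13.5))[0]
        assert hist.values[fi, 3] == pytest.approx(10 / hist.minutes_per_coupling_bin[3])
        assert hist.values.sum() == hist.values[fi, 3]

    def test_no_peaks(self):
        hist = power_histogram(pd.DataFrame(columns=["time_s", "freq_hz",
                                                     "power_pct", "phase_rad"]),
                               self._series())
        assert np.all(hist.values == 0.0)

    def test_conservation_and_quartile_minutes(self, n2_recording):
        from somnipeak.tfpeaks import detect_tfpeaks, peaks_to_frame

        rec, _, _ = n2_recording
        sig = rec.channel("C3")
        so = compute_so_series(sig, FS, condition_mask(rec, "NREM"))
        ann, _ = annotate_peaks(peaks_to_frame(detect_tfpeaks(sig, FS)), so)
        hist = power_histogram(ann, so)
        total = (hist.values * hist.minutes_per_coupling_bin[None, :]).sum()
        assert total == pytest.approx(hist.n_peaks, rel=1e-6)
        quarter = hist.minutes_per_coupling_bin.sum() / 4
        assert np.allclose(hist.minutes_per_coupling_bin, quarter, rtol=0.05)


class TestPhaseHistogram:
    def test_single_cell(self):
        peaks = pd.DataFrame({"time_s": [1.0] * 5, "freq_hz": [13.5] * 5,
                              "power_pct": [50.0] * 5, "phase_rad": [0.01] * 5})
        hist = phase_histogram(peaks)
        assert hist.values.sum() == pytest.approx(1.0)
        assert (hist.values > 0).sum() == 1

    def test_uniform_marginal(self):
        rng = np.random.default_rng(8)
        n = 18000
        peaks = pd.DataFrame({
            "time_s": np.arange(n, dtype=float), "freq_hz": rng.uniform(4, 25, n),
            "power_pct": np.full(n, 50.0),
            "phase_rad": rng.uniform(-np.pi, np.pi, n)})
        hist = phase_histogram(peaks)
        marginal = hist.values.sum(axis=0)
        se = np.sqrt((1 / 18) * (1 - 1 / 18) / n)
        assert np.abs(marginal - 1 / 18).max() < 3 * se

    def test_sum_to_one(self, n2_recording):
        from somnipeak.tfpeaks import detect_tfpeaks, peaks_to_frame

        rec, _, _ = n2_recording
        sig = rec.channel("C3")
        so = compute_so_series(sig, FS, condition_mask(rec, "NREM"))
        ann, _ = annotate_peaks(peaks_to_frame(detect_tfpeaks(sig, FS)), so)
        hist = phase_histogram(ann)
        assert hist.values.sum() == pytest.approx(1.0)


class TestGroupAverage:
    def _hist(self, fill, subject):
        edges = default_freq_edges()
        return CoupledHistogram("phase", edges, np.linspace(-np.pi, np.pi, 19),
                                np.full((len(edges) - 1, 18), fill),
                                subject=subject)

    def test_reference_diff_zero(self):
        hists = [self._hist(1.0, "a"), self._hist(1.0, "b")]
        _, diffs = group_average_and_diff(hists, ["control", "control"], "control")
        assert np.allclose(diffs["control"], 0.0)

    def test_patient_minus_control_sign(self):
        hists = [self._hist(1.5, "a"), self._hist(2.0, "b")]
        means, diffs = group_average_and_diff(hists, ["control", "patient"],
                                              "control")
        assert np.allclose(diffs["patient"], 0.5)

    def test_grid_mismatch_rejected(self):
        a = self._hist(1.0, "a")
        b = CoupledHistogram("phase", default_freq_edges(),
                             np.linspace(-np.pi, np.pi, 10),
                             np.zeros((21, 9)), subject="b")
        with pytest.raises(ValueError):
            group_average_and_diff([a, b], ["control", "patient"], "control")
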
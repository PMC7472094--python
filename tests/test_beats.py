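"""Beat detection: Pan–Tompkins, AO windowed maxima, NN construction/filtering."""

import numpy as np
import pytest

from mechanohrv import (BeatTimes, HRVTruthParams, MorphologyParams, Waveform,
                        bandpass_mcg, corrupt, detect_ao, filter_nn,
                        generate_nn, nn_from_beats, pan_tompkins, smooth_ma,
                        synthesize_ecg, synthesize_mcg)
from mechanohrv.beats import FLAG_FALLBACK, FLAG_MISSING, FLAG_OK
from tests.conftest import make_nn


@pytest.fixture(scope="module")
def clean_beat_setup():
    nn = generate_nn(HRVTruthParams(mean_nn=900, sd_nn=30, duration=60,
                                    seed=11))
    ecg, r_times = synthesize_ecg(nn)
    scg, ao_times = synthesize_mcg(nn, morph=MorphologyParams(ao_delay=40.0))
    return nn, ecg, r_times, scg, ao_times


class TestPanTompkins:
    def test_clean_ecg_all_beats_within_10ms(self, clean_beat_setup):
        _, ecg, r_times, _, _ = clean_beat_setup
        beats = pan_tompkins(ecg)
        assert len(beats) == r_times.size
        for t in r_times:
            assert np.min(np.abs(beats.times - t)) <= 0.010

    def test_amplitude_scale_invariance(self, clean_beat_setup):
        _, ecg, _, _, _ = clean_beat_setup
        scaled = Waveform(ecg.samples * 1000.0, ecg.fs)
        assert np.array_equal(pan_tompkins(ecg).times,
                              pan_tompkins(scaled).times)

    def test_noisy_ecg_sensitivity_and_ppv(self, clean_beat_setup):
        _, ecg, r_times, _, _ = clean_beat_setup
        noisy = corrupt(ecg, MorphologyParams(noise_snr=10.0), seed=7)
        det = pan_tompkins(noisy).times
        used = np.zeros(det.size, dtype=bool)
        tp = 0
        for t in r_times:
            d = np.abs(det - t)
            i = int(np.argmin(d))
            if d[i] <= 0.050 and not used[i]:
                tp += 1
                used[i] = True
        assert tp / r_times.size >= 0.99    # sensitivity
        assert tp / det.size >= 0.99        # positive predictivity

    def test_refractory_spacing_enforced(self, clean_beat_setup):
        _, ecg, _, _, _ = clean_beat_setup
        beats = pan_tompkins(ecg)
        assert np.all(np.diff(beats.times) >= 0.2)

    def test_too_short_input_rejected(self):
        with pytest.raises(ValueError):
            pan_tompkins(Waveform(np.zeros(400), fs=800.0))


class TestMcgFilters:
    def test_stopband_and_passband(self):
        fs = 800.0
        t = np.arange(0, 20, 1 / fs)
        slow = Waveform(np.sin(2 * np.pi * 0.2 * t), fs)
        out = bandpass_mcg(slow)
        assert np.std(out.samples) < 0.05 * np.std(slow.samples)
        mid = Waveform(np.sin(2 * np.pi * 25 * t), fs)
        out = bandpass_mcg(mid)
        # measure away from the filter edges
        sl = slice(int(2 * fs), int(18 * fs))
        assert abs(np.std(out.samples[sl]) / np.std(mid.samples[sl]) - 1) < 0.05

    def test_bandpass_is_zero_phase(self):
        fs = 800.0
        t = np.arange(0, 4, 1 / fs)
        burst = np.exp(-0.5 * ((t - 2) / 0.05) ** 2) * np.cos(2 * np.pi * 25 * (t - 2))
        w = Waveform(burst, fs)
        out = bandpass_mcg(w).samples
        lags = np.arange(-50, 51)
        xc = [np.dot(out, np.roll(burst, k)) for k in lags]
        assert lags[int(np.argmax(xc))] == 0

    def test_moving_average_constant_and_variance(self, rng):
        fs = 800.0
        const = Waveform(np.full(1000, 2.0), fs)
        assert np.allclose(smooth_ma(const).samples, 2.0)
        noise = Waveform(rng.normal(0, 1, 200000), fs)
        out = smooth_ma(noise, width_ms=15.0)  # 13 taps at 800 Hz
        ratio = np.var(out.samples) / np.var(noise.samples)
        assert abs(ratio - 1 / 13) < 0.1 / 13

    def test_moving_average_impulse_response_symmetric(self):
        x = np.zeros(101)
        x[50] = 1.0
        h = smooth_ma(Waveform(x, 800.0), width_ms=15.0).samples
        assert np.array_equal(h, h[::-1])


class TestDetectAO:
    def test_clean_scg_recovers_delay_exactly(self, clean_beat_setup):
        _, _, r_times, scg, ao_times = clean_beat_setup
        r = BeatTimes(r_times, modality="ecg")
        det = detect_ao(scg, r, modality="scg")
        assert det.flags[:-1] == [FLAG_OK] * (len(det) - 1)
        ok = [i for i, f in enumerate(det.flags) if f == FLAG_OK]
        err = np.abs(det.times[ok] - ao_times[ok])
        assert np.max(err) <= 1.0 / scg.fs

    def test_ao_containment_in_100ms_window(self, clean_beat_setup):
        _, _, r_times, scg, _ = clean_beat_setup
        r = BeatTimes(r_times, modality="ecg")
        det = detect_ao(scg, r, modality="scg")
        lag = det.times - r_times[: len(det)]
        ok = np.array(det.flags) != FLAG_MISSING
        assert np.all(lag[ok] > 0) and np.all(lag[ok] <= 0.100 + 1e-12)

    def test_monotone_window_falls_back_to_first_sample(self):
        fs = 800.0
        x = np.linspace(1.0, 0.0, 400)  # monotone decreasing, no interior max
        w = Waveform(x, fs)
        r = BeatTimes(np.array([0.1]), modality="ecg")
        det = detect_ao(w, r, raw=False)
        assert det.flags == [FLAG_FALLBACK]
        assert det.times[0] == pytest.approx(0.1 + 1 / fs)

    def test_window_past_signal_end_flagged_missing(self):
        fs = 800.0
        w = Waveform(np.ones(100), fs)  # 125 ms long
        r = BeatTimes(np.array([0.05]), modality="ecg")
        det = detect_ao(w, r, raw=False)
        assert det.flags == [FLAG_MISSING]

    def test_empty_r_times_rejected(self):
        w = Waveform(np.ones(1000), 800.0)
        with pytest.raises(ValueError):
            detect_ao(w, BeatTimes(np.array([]), flags=[]), raw=False)


class TestNNConstruction:
    def test_simple_differences(self):
        beats = BeatTimes(np.array([0.0, 0.8, 1.6]))
        nn = nn_from_beats(beats)
        np.testing.assert_allclose(nn.intervals, [800.0, 800.0])
        np.testing.assert_allclose(nn.onset_times, [0.8, 1.6])

    def test_n_beats_give_n_minus_1_intervals(self):
        times = np.cumsum(np.full(61, 0.9))
        nn = nn_from_beats(BeatTimes(times))
        assert len(nn) == 60

    def test_missing_beat_produces_flagged_spanning_interval(self):
        times = np.array([0.0, 0.8, 1.6, 2.4, 3.2])
        flags = [FLAG_OK, FLAG_OK, FLAG_MISSING, FLAG_OK, FLAG_OK]
        nn = nn_from_beats(BeatTimes(times, flags=flags))
        np.testing.assert_allclose(nn.intervals, [800.0, 1600.0, 800.0])
        assert nn.flags == [FLAG_OK, "spanning", FLAG_OK]

    def test_non_increasing_times_rejected(self):
        with pytest.raises(ValueError):
            BeatTimes(np.array([0.0, 0.5, 0.5]))

    def test_nn_equals_beat_time_differences_exactly(self, clean_beat_setup):
        _, ecg, _, _, _ = clean_beat_setup
        beats = pan_tompkins(ecg)
        nn = nn_from_beats(beats)
        np.testing.assert_array_equal(nn.intervals,
                                      np.diff(beats.times) * 1000.0)


class TestFilterNN:
    def test_physiological_series_unchanged(self, rng):
        nn = make_nn(rng.normal(900, 20, 100))
        out = filter_nn(nn)
        assert np.array_equal(out.intervals, nn.intervals)

    def test_single_gross_outlier_removed(self, rng):
        vals = list(rng.normal(900, 10, 50))
        vals[25] = 5000.0
        out = filter_nn(make_nn(vals))
        assert len(out) == 49
        assert 5000.0 not in out.intervals

    def test_matches_brute_force_rule(self, rng):
        vals = rng.normal(900, 30, 300)
        idx = rng.choice(300, size=15, replace=False)
        vals[idx] *= rng.choice([0.25, 1.6], size=15)
        nn = make_nn(vals)
        out = filter_nn(nn)
        # independent application of the stated rule
        keep = []
        for i, v in enumerate(vals):
            lo, hi = max(0, i - 5), min(vals.size, i + 6)
            med = np.median(vals[lo:hi])
            keep.append(300.0 <= v <= 2000.0 and abs(v - med) <= 0.2 * med)
        np.testing.assert_array_equal(out.intervals, nn.intervals[np.array(keep)])

    def test_cross_modality_nn_identical_to_one_sample(self):
        # noise-free record: ECG-, SCG- and GCG-derived NN series agree to
        # within one sample period per interval
        from mechanohrv import generate_record
        from mechanohrv.agreement import analyze_record
        rec, _ = generate_record(HRVTruthParams(mean_nn=900, sd_nn=30,
                                                duration=120, seed=7))
        nn = analyze_record(rec, min_beats=10)["nn"]
        n = min(len(nn[m]) for m in ("ecg", "scg", "gcg"))
        period_ms = 1000.0 / rec.fs
        for m in ("scg", "gcg"):
            dev = np.abs(nn["ecg"].intervals[:n] - nn[m].intervals[:n])
            assert np.max(dev) <= period_ms + 1e-9
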
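"""Heartbeat detection and NN-series construction.

R waves in the ECG are found with the classical Pan–Tompkins detector
(band-pass, derivative, squaring, moving-window integration, dual adaptive
thresholds with search-back).  AO/gJ waves in the mechanical channels are
found relative to those R waves: the seismo-/gyrocardiogram is band-passed
(4–50 Hz Butterworth, zero phase), smoothed with a 15 ms zero-phase moving
average, and the largest local maximum within 100 ms after each R wave is
taken as the aortic-valve-opening instant.

NN series (inter-beat intervals in ms, stamped with the time of the
interval-ending beat) are the substrate of every HRV index downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .records import Waveform

ECG_REFRACTORY_S = 0.200   # minimum physiological R-R gap
AO_WINDOW_MS = 100.0       # AO wave occurs within 100 ms after the R wave

FLAG_OK = "ok"
FLAG_FALLBACK = "fallback"
FLAG_MISSING = "missing"


@dataclass
class BeatTimes:
    """Strictly increasing event times for one modality, with quality flags."""

    times: np.ndarray
    modality: str = "ecg"
    flags: list[str] = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.flags is None:
            self.flags = [FLAG_OK] * self.times.size
        if len(self.flags) != self.times.size:
            raise ValueError("flags length must match times")
        if self.times.size > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("beat times must be strictly increasing")

    def __len__(self) -> int:
        return self.times.size


@dataclass
class NNSeries:
    """Inter-beat intervals in ms with the time of each interval-ending beat."""

    intervals: np.ndarray
    onset_times: np.ndarray
    modality: str = "ecg"
    flags: list[str] = None

    def __post_init__(self) -> None:
        self.intervals = np.asarray(self.intervals, dtype=float)
        self.onset_times = np.asarray(self.onset_times, dtype=float)
        if self.intervals.size != self.onset_times.size:
            raise ValueError("intervals and onset_times must have equal length")
        if np.any(self.intervals <= 0):
            raise ValueError("intervals must be positive")
        if self.flags is None:
            self.flags = [FLAG_OK] * self.intervals.size

    def __len__(self) -> int:
        return self.intervals.size

    @property
    def mean_nn(self) -> float:
        return float(np.mean(self.intervals))


# ---------------------------------------------------------------------------
# Pan–Tompkins QRS detection
# ---------------------------------------------------------------------------

def _pt_stages(x: np.ndarray, fs: float):
    """Filtering stages: band-passed ECG, derivative, integrated signal."""
    nyq = fs / 2
    b, a = signal.butter(2, [5 / nyq, 15 / nyq], btype="band")
    bp = signal.filtfilt(b, a, x)
    deriv = np.convolve(bp, np.array([2, 1, 0, -1, -2]) / 8.0, mode="same")
    squared = deriv ** 2
    win = max(1, int(round(0.150 * fs)))
    mwi = np.convolve(squared, np.ones(win) / win, mode="same")
    return bp, deriv, mwi


def pan_tompkins(ecg: Waveform) -> BeatTimes:
    """Detect R waves with the classical Pan–Tompkins algorithm.

    Stages: 5–15 Hz band-pass, five-point derivative, squaring, 150 ms
    moving-window integration, then dual adaptive thresholds tracking
    signal/noise peak levels, a 200 ms refractory period, rejection of
    T waves among candidates arriving within 360 ms of the previous beat
    (by comparing peak slopes), and a search-back at half threshold when no
    beat arrives within 1.66× the running R-R average.  Detections are
    refined to the R-peak location in the band-passed ECG, so the output is
    invariant to positive amplitude scaling of the input.
    """
    fs = ecg.fs
    if fs < 200:
        raise ValueError("pan_tompkins requires fs >= 200 Hz")
    if ecg.duration < 2.0:
        raise ValueError("pan_tompkins requires at least 2 s of ECG")
    x = ecg.samples
    bp, deriv, mwi = _pt_stages(x, fs)

    min_dist = int(round(ECG_REFRACTORY_S * fs))
    cand, _ = signal.find_peaks(mwi, distance=min_dist)
    if cand.size == 0:
        return BeatTimes(np.array([]), modality="ecg", flags=[])

    # learning phase: first 2 s set the initial signal/noise levels
    head = mwi[: int(2 * fs)]
    spki = 0.25 * float(np.max(head)) if head.size else float(mwi[cand[0]])
    npki = 0.5 * float(np.mean(head)) if head.size else 0.0

    def slope_at(i: int) -> float:
        lo, hi = max(0, i - int(0.075 * fs)), min(deriv.size, i + int(0.075 * fs))
        return float(np.max(np.abs(deriv[lo:hi]))) if hi > lo else 0.0

    beats: list[int] = []
    rr_hist: list[float] = []
    thr1 = npki + 0.25 * (spki - npki)
    noise_cand: list[int] = []

    for i in cand:
        thr1 = npki + 0.25 * (spki - npki)
        peak = float(mwi[i])
        accept = False
        if peak > thr1:
            accept = True
            if beats and (i - beats[-1]) / fs < 0.360:
                # T-wave check: slope less than half the previous QRS slope
                if slope_at(i) < 0.5 * slope_at(beats[-1]):
                    accept = False
        if accept:
            spki = 0.125 * peak + 0.875 * spki
            if beats:
                rr_hist.append((i - beats[-1]) / fs)
                if len(rr_hist) > 8:
                    rr_hist.pop(0)
            beats.append(i)
            noise_cand.clear()
        else:
            npki = 0.125 * peak + 0.875 * npki
            noise_cand.append(i)
            # search-back: no beat within 1.66x the running RR average
            if beats and rr_hist:
                rr_avg = float(np.mean(rr_hist))
                if (i - beats[-1]) / fs > 1.66 * rr_avg:
                    thr2 = 0.5 * thr1
                    back = [j for j in noise_cand
                            if mwi[j] > thr2 and (j - beats[-1]) >= min_dist]
                    if back:
                        j = max(back, key=lambda k: mwi[k])
                        spki = 0.25 * float(mwi[j]) + 0.75 * spki
                        rr_hist.append((j - beats[-1]) / fs)
                        if len(rr_hist) > 8:
                            rr_hist.pop(0)
                        beats.append(j)
                        beats.sort()
                        noise_cand.clear()

    # refine each detection to the R peak of the band-passed ECG
    half = int(round(0.100 * fs))
    refined = []
    for i in beats:
        lo, hi = max(0, i - half), min(bp.size, i + half + 1)
        refined.append(lo + int(np.argmax(np.abs(bp[lo:hi]))))
    refined = np.unique(refined)
    # enforce refractory spacing after refinement (keep the larger peak)
    keep: list[int] = []
    for i in refined:
        if keep and i - keep[-1] < min_dist:
            if abs(bp[i]) > abs(bp[keep[-1]]):
                keep[-1] = int(i)
        else:
            keep.append(int(i))
    times = ecg.t0 + np.array(keep) / fs
    return BeatTimes(times, modality="ecg")


# ---------------------------------------------------------------------------
# AO detection in SCG/GCG
# ---------------------------------------------------------------------------

def bandpass_mcg(w: Waveform, low: float = 4.0, high: float = 50.0,
                 order: int = 3) -> Waveform:
    """Zero-phase 3rd-order Butterworth band-pass (4–50 Hz) for SCG/GCG.

    Forward–backward application cancels the filter's phase delay so that
    AO peak timing is preserved; this also removes the gravitational offset
    and baseline wander of the mechanical channels.
    """
    if w.fs <= 2 * high:
        raise ValueError("sampling rate too low for the 4-50 Hz passband")
    nyq = w.fs / 2
    b, a = signal.butter(order, [low / nyq, high / nyq], btype="band")
    return w.replace_samples(signal.filtfilt(b, a, w.samples))


def smooth_ma(w: Waveform, width_ms: float = 15.0) -> Waveform:
    """Centered (zero-phase FIR) moving average of ``width_ms`` milliseconds.

    The tap count is forced odd so the impulse response is symmetric about
    its center and introduces no delay.
    """
    n = max(1, int(round(width_ms * w.fs / 1000.0)))
    if n % 2 == 0:
        n += 1
    from scipy.ndimage import uniform_filter1d
    return w.replace_samples(
        uniform_filter1d(w.samples, size=n, mode="nearest"))


def detect_ao(mcg: Waveform, r_times: BeatTimes,
              window_ms: float = AO_WINDOW_MS, raw: bool = True,
              modality: str = "scg") -> BeatTimes:
    """Detect AO/gJ waves as windowed local maxima after each ECG R wave.

    For each R time t_R the AO time is the largest-amplitude local maximum
    of the processed signal in the half-open window (t_R, t_R + window_ms];
    ties break toward the earlier peak.  If the window contains no interior
    local maximum the window's global maximum is used and the beat is
    flagged ``fallback``.  Windows that run past the end of the signal
    yield a beat flagged ``missing`` (excluded from NN construction).

    With ``raw=True`` the band-pass (4–50 Hz) and 15 ms moving-average
    smoothing are applied first.
    """
    if len(r_times) == 0:
        raise ValueError("detect_ao requires at least one R time")
    w = mcg
    if raw:
        w = smooth_ma(bandpass_mcg(w))
    x = w.samples
    fs = w.fs
    win = window_ms / 1000.0
    times = []
    flags = []
    for t_r in r_times.times:
        i_lo = int(np.floor((t_r - w.t0) * fs)) + 1      # exclusive of t_R
        i_hi = int(np.floor((t_r - w.t0 + win) * fs))     # inclusive end
        if i_hi >= x.size:
            # cannot evaluate the full window; mark and place at window start
            times.append(t_r + 1.0 / fs)
            flags.append(FLAG_MISSING)
            continue
        seg = x[i_lo: i_hi + 1]
        interior = np.nonzero(
            (seg[1:-1] > seg[:-2]) & (seg[1:-1] > seg[2:]))[0] + 1
        if interior.size:
            best = interior[int(np.argmax(seg[interior]))]
            flags.append(FLAG_OK)
        else:
            best = int(np.argmax(seg))
            flags.append(FLAG_FALLBACK)
        times.append(w.t0 + (i_lo + best) / fs)
    return BeatTimes(np.asarray(times), modality=modality, flags=flags)


# ---------------------------------------------------------------------------
# NN construction and filtering
# ---------------------------------------------------------------------------

def nn_from_beats(beats: BeatTimes) -> NNSeries:
    """Successive beat-time differences in ms.

    Beats flagged ``missing`` are skipped; an interval spanning a skipped
    beat is flagged ``spanning`` so downstream filtering can drop it.
    N kept beats produce N−1 intervals, each stamped with the time of its
    ending beat.
    """
    kept = [(t, f) for t, f in zip(beats.times, beats.flags) if f != FLAG_MISSING]
    if len(kept) < 2:
        raise ValueError("nn_from_beats requires at least 2 usable beats")
    times = np.array([t for t, _ in kept])
    if np.any(np.diff(times) <= 0):
        raise ValueError("beat times must be strictly increasing")
    skipped_any = len(kept) != len(beats)
    intervals = np.diff(times) * 1000.0
    flags = []
    all_times = beats.times
    for a, b in zip(times[:-1], times[1:]):
        spanning = skipped_any and np.any(
            (all_times > a) & (all_times < b))
        flags.append("spanning" if spanning else FLAG_OK)
    return NNSeries(intervals=intervals, onset_times=times[1:],
                    modality=beats.modality, flags=flags)


def filter_nn(nn: NNSeries, lower_ms: float = 300.0, upper_ms: float = 2000.0,
              median_window: int = 11, max_rel_dev: float = 0.20,
              drop_spanning: bool = True) -> NNSeries:
    """Reject non-physiological intervals.

    An interval is removed when it falls outside ``[lower_ms, upper_ms]``
    or deviates from the running median (centered window of
    ``median_window`` intervals, truncated at the edges) by more than
    ``max_rel_dev`` of that median.  Intervals flagged ``spanning`` (they
    cross a skipped beat) are dropped as well.  Onset times of retained
    intervals are preserved.
    """
    x = nn.intervals
    n = x.size
    half = median_window // 2
    keep = np.ones(n, dtype=bool)
    for i in range(n):
        med = np.median(x[max(0, i - half): min(n, i + half + 1)])
        if not lower_ms <= x[i] <= upper_ms:
            keep[i] = False
        elif med > 0 and abs(x[i] - med) > max_rel_dev * med:
            keep[i] = False
        elif drop_spanning and nn.flags[i] == "spanning":
            keep[i] = False
    return NNSeries(intervals=x[keep], onset_times=nn.onset_times[keep],
                    modality=nn.modality,
                    flags=[f for f, k in zip(nn.flags, keep) if k])
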
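"""Synthetic tri-modal cardiac records with known beat times and HRV structure.

Every downstream stage (detection, spectral indices, agreement statistics) is
tested against records produced here, where the ground truth — R-wave times,
aortic-valve-opening (AO) times and the NN series — is known exactly.

The generator imposes heart-rate variability directly on the interval
durations: each NN interval is the sum of a mean level, slow (VLF), low
frequency (LF) and high frequency (HF) sinusoidal modulations evaluated at
the beat time, plus Gaussian jitter.  This gives an analytically known band
structure for the spectral-recovery tests.  The ECG channel is a train of
Gaussian P/Q/R/S/T deflections; the mechanical channels (SCG z-axis, GCG
y-axis) carry, per beat, a damped oscillation burst whose largest positive
peak marks the AO wave at a fixed (optionally jittered) delay after the R
wave, always inside the physiological (0, 100] ms window.

All randomness flows from explicit integer seeds; generation is a pure
function of (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .records import Record, Waveform, DEFAULT_FS

MIN_NN_MS = 200.0  # physiological floor; shorter intervals indicate bad params


@dataclass
class HRVTruthParams:
    """Ground-truth NN-series parameters.

    Units: intervals/amplitudes in ms, frequencies in Hz (beat-time domain),
    duration in s.  Frequencies must lie in (0, 0.5) Hz — the spectral bands
    of interest end at 0.4 Hz.
    """

    mean_nn: float = 955.0
    sd_nn: float = 25.0
    lf_freq: float = 0.1
    hf_freq: float = 0.25
    lf_amp: float = 30.0
    hf_amp: float = 25.0
    vlf_amp: float = 10.0
    vlf_freq: float = 0.01
    duration: float = 180.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mean_nn <= 0:
            raise ValueError("mean_nn must be positive")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        for name in ("lf_freq", "hf_freq", "vlf_freq"):
            f = getattr(self, name)
            if not 0 < f < 0.5:
                raise ValueError(f"{name} must lie in (0, 0.5) Hz, got {f}")
        for name in ("lf_amp", "hf_amp", "vlf_amp", "sd_nn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class MorphologyParams:
    """Waveform-shape and artifact parameters for one mechanical modality.

    ao_delay
        R-to-AO latency in ms; must lie strictly inside (0, 100) ms, the
        physiological window the detector searches.
    ao_jitter_ms
        Per-beat Gaussian jitter of the latency (clipped so the AO wave
        stays inside the window).
    ao_freq
        Carrier frequency of the AO oscillation burst in Hz.
    noise_snr
        Broadband-noise level as signal-to-noise ratio in dB; ``None``
        disables noise.
    baseline_amp, baseline_freqs
        Baseline-wander amplitude (signal units) and component frequencies
        (all below 0.5 Hz).
    spike_count, spike_amp
        Leading-spike artifact: number of corrupted initial samples
        (0–17) and amplitude as a multiple of the clean-signal maximum.
    """

    ao_delay: float = 40.0
    ao_jitter_ms: float = 0.0
    ao_freq: float = 20.0
    ao_amp: float = 1.0
    secondary_amp: float = 0.4
    noise_snr: float | None = None
    baseline_amp: float = 0.0
    baseline_freqs: tuple[float, ...] = (0.12, 0.33)
    spike_count: int = 0
    spike_amp: float = 8.0

    def __post_init__(self) -> None:
        if not 0 < self.ao_delay < 100:
            raise ValueError(f"ao_delay must lie in (0, 100) ms, got {self.ao_delay}")
        if not 0 <= self.spike_count <= 17:
            raise ValueError("spike_count must lie in [0, 17]")
        if any(f >= 0.5 for f in self.baseline_freqs):
            raise ValueError("baseline wander frequencies must be below 0.5 Hz")


@dataclass
class SyntheticTruth:
    """Ground truth accompanying one generated record."""

    r_times: np.ndarray
    ao_times_scg: np.ndarray
    ao_times_gcg: np.ndarray
    nn_true: "NNSeries"  # noqa: F821 - forward ref, defined in beats module
    params: HRVTruthParams = None

    def __post_init__(self) -> None:
        for name in ("ao_times_scg", "ao_times_gcg"):
            ao = getattr(self, name)
            if len(ao) != len(self.r_times):
                raise ValueError(f"{name} length differs from r_times")
            lag = ao - self.r_times
            if np.any(lag <= 0) or np.any(lag > 0.1):
                raise ValueError(f"{name}: AO-R lag outside (0, 0.1] s")


def generate_nn(params: HRVTruthParams):
    """Generate a ground-truth NN series with known band structure.

    NN_i = mean_nn + vlf_amp·sin(2π·vlf_freq·t_i) + lf_amp·sin(2π·lf_freq·t_i)
    + hf_amp·sin(2π·hf_freq·t_i) + N(0, sd_nn²), with t_i the onset (start)
    time of the i-th interval, accumulated from the preceding intervals.

    Raises if any generated interval falls at or below 200 ms, which signals
    a non-physiological parameter combination rather than usable data.
    """
    from .beats import NNSeries

    rng = np.random.default_rng(params.seed)
    intervals = []
    onsets = []
    t = 0.0
    while t < params.duration:
        nn = (params.mean_nn
              + params.vlf_amp * np.sin(2 * np.pi * params.vlf_freq * t)
              + params.lf_amp * np.sin(2 * np.pi * params.lf_freq * t)
              + params.hf_amp * np.sin(2 * np.pi * params.hf_freq * t)
              + rng.normal(0.0, params.sd_nn))
        if nn <= MIN_NN_MS:
            raise ValueError(
                f"generated NN interval {nn:.1f} ms <= {MIN_NN_MS:.0f} ms; "
                "parameter combination is non-physiological")
        t += nn / 1000.0
        intervals.append(nn)
        onsets.append(t)  # interval is stamped with its ending beat time
    return NNSeries(intervals=np.array(intervals),
                    onset_times=np.array(onsets),
                    modality="truth")


def _add_gaussian(x: np.ndarray, fs: float, center_s: float, sigma_s: float,
                  amp: float) -> None:
    """Accumulate a Gaussian bump into x in place (windowed to ±5σ)."""
    lo = max(0, int(np.floor((center_s - 5 * sigma_s) * fs)))
    hi = min(x.size, int(np.ceil((center_s + 5 * sigma_s) * fs)) + 1)
    if hi <= lo:
        return
    t = np.arange(lo, hi) / fs
    x[lo:hi] += amp * np.exp(-0.5 * ((t - center_s) / sigma_s) ** 2)


# (offset s, width s, amplitude) of the five ECG deflections relative to R.
_ECG_WAVES = (
    (-0.180, 0.025, 0.12),   # P
    (-0.028, 0.010, -0.12),  # Q
    (0.0, 0.011, 1.0),       # R — unique global extremum of each beat
    (0.030, 0.010, -0.25),   # S
    (0.250, 0.045, 0.30),    # T
)


def synthesize_ecg(nn, fs: float = DEFAULT_FS):
    """Render an NN series as a clean ECG waveform.

    Returns ``(Waveform, r_times)`` where ``r_times`` are the cumulative NN
    sums (seconds).  Each beat is a sum of Gaussian P/Q/R/S/T deflections;
    the R deflection is the unique global extremum within each beat.
    """
    if fs < 200:
        raise ValueError("fs must be at least 200 Hz for ECG synthesis")
    r_times = np.concatenate([[0.0], np.cumsum(nn.intervals) / 1000.0])
    # lead-in so the first beat has a complete P wave; pad one beat at the end
    t0_pad = 0.3
    r_times = r_times + t0_pad
    total = r_times[-1] + 0.6
    x = np.zeros(int(np.ceil(total * fs)))
    for r in r_times:
        for off, width, amp in _ECG_WAVES:
            _add_gaussian(x, fs, r + off, width, amp)
    return Waveform(x, fs=fs, label="ecg"), r_times


def _add_burst(x: np.ndarray, fs: float, center_s: float, freq: float,
               sigma_s: float, amp: float) -> None:
    """Damped oscillation burst: Gaussian envelope × cosine peaking at center."""
    lo = max(0, int(np.floor((center_s - 5 * sigma_s) * fs)))
    hi = min(x.size, int(np.ceil((center_s + 5 * sigma_s) * fs)) + 1)
    if hi <= lo:
        return
    t = np.arange(lo, hi) / fs
    env = np.exp(-0.5 * ((t - center_s) / sigma_s) ** 2)
    x[lo:hi] += amp * env * np.cos(2 * np.pi * freq * (t - center_s))


def synthesize_mcg(nn, fs: float = DEFAULT_FS,
                   morph: MorphologyParams | None = None,
                   modality: str = "scg", seed: int = 0):
    """Render an NN series as a mechanocardiogram (SCG or GCG) waveform.

    Per beat, a damped oscillation burst whose largest positive peak sits at
    ``r_time + ao_delay`` (plus optional per-beat jitter, clipped to keep the
    AO wave strictly inside (0, 100) ms after R), with a smaller secondary
    deflection later in the cycle mimicking the aortic-closure complex.

    Returns ``(Waveform, ao_times)``; ``ao_times`` are exact.
    """
    if morph is None:
        morph = MorphologyParams()
    if not 0 < morph.ao_delay < 100:
        raise ValueError("ao_delay must lie in (0, 100) ms")
    rng = np.random.default_rng(seed)
    _, r_times = synthesize_ecg(nn, fs=fs)
    delays_ms = np.full(r_times.size, morph.ao_delay)
    if morph.ao_jitter_ms > 0:
        delays_ms = delays_ms + rng.normal(0.0, morph.ao_jitter_ms, r_times.size)
        delays_ms = np.clip(delays_ms, 2.0, 98.0)
    # snap AO times onto the sample grid so the stored truth matches the
    # rendered peak exactly
    ao_times = np.round((r_times + delays_ms / 1000.0) * fs) / fs
    x = np.zeros(int(np.ceil((r_times[-1] + 0.6) * fs)))
    sigma = 0.015  # ~15 ms burst envelope
    for r, ao in zip(r_times, ao_times):
        _add_burst(x, fs, ao, morph.ao_freq, sigma, morph.ao_amp)
        _add_burst(x, fs, r + 0.300, morph.ao_freq * 0.9, sigma,
                   morph.ao_amp * morph.secondary_amp)
    label = "scg_z" if modality == "scg" else "gcg_y"
    return Waveform(x, fs=fs, label=label), ao_times


def corrupt(w: Waveform, morph: MorphologyParams, seed: int = 0) -> Waveform:
    """Add the artifacts the preprocessing chain is built to remove.

    (i) a leading spike over the first ``spike_count`` ≤ 17 samples,
    (ii) baseline wander as a sum of sinusoids below 0.5 Hz,
    (iii) white Gaussian noise scaled so the clean-signal-to-noise power
    ratio equals ``noise_snr`` dB.  Deterministic under ``seed``; with all
    artifact amplitudes zero the input is returned unchanged (bitwise).
    """
    rng = np.random.default_rng(seed)
    x = w.samples.copy()
    clean_power = float(np.mean(x ** 2))
    touched = False
    if morph.spike_count > 0:
        k = morph.spike_count
        amp = morph.spike_amp * np.max(np.abs(x))
        x[:k] += amp * rng.choice([-1.0, 1.0], size=k)
        touched = True
    if morph.baseline_amp > 0:
        t = w.times
        for i, f in enumerate(morph.baseline_freqs):
            phase = rng.uniform(0, 2 * np.pi)
            x += morph.baseline_amp * np.sin(2 * np.pi * f * t + phase)
        touched = True
    if morph.noise_snr is not None:
        sigma = np.sqrt(clean_power / 10 ** (morph.noise_snr / 10))
        x += rng.normal(0.0, sigma, x.size)
        touched = True
    if not touched:
        return w
    return w.replace_samples(x)


def generate_record(params: HRVTruthParams,
                    morph_scg: MorphologyParams | None = None,
                    morph_gcg: MorphologyParams | None = None,
                    morph_ecg: MorphologyParams | None = None,
                    fs: float = DEFAULT_FS,
                    subject_id: str = "synthetic",
                    full_axes: bool = False):
    """Generate a complete tri-modal record plus its ground truth.

    By default the SCG and GCG use distinct AO delays (35 vs 45 ms) so the
    modalities are distinguishable.  ``full_axes`` adds the off-analysis
    axes (scg_x/y, gcg_x/z) as attenuated noisy copies of the main axis.

    Returns ``(Record, SyntheticTruth)``.
    """
    if morph_scg is None:
        morph_scg = MorphologyParams(ao_delay=35.0)
    if morph_gcg is None:
        morph_gcg = MorphologyParams(ao_delay=45.0)
    nn = generate_nn(params)
    seed = params.seed
    ecg, r_times = synthesize_ecg(nn, fs=fs)
    scg, ao_scg = synthesize_mcg(nn, fs=fs, morph=morph_scg, modality="scg",
                                 seed=seed + 1)
    gcg, ao_gcg = synthesize_mcg(nn, fs=fs, morph=morph_gcg, modality="gcg",
                                 seed=seed + 2)
    if morph_ecg is not None:
        ecg = corrupt(ecg, morph_ecg, seed=seed + 3)
    scg = corrupt(scg, morph_scg, seed=seed + 4)
    gcg = corrupt(gcg, morph_gcg, seed=seed + 5)
    n = min(len(ecg), len(scg), len(gcg))
    channels = {
        "ecg": ecg.replace_samples(ecg.samples[:n]),
        "scg_z": scg.replace_samples(scg.samples[:n]),
        "gcg_y": gcg.replace_samples(gcg.samples[:n]),
    }
    if full_axes:
        rng = np.random.default_rng(seed + 6)
        for label, src in (("scg_x", channels["scg_z"]), ("scg_y", channels["scg_z"]),
                           ("gcg_x", channels["gcg_y"]), ("gcg_z", channels["gcg_y"])):
            noisy = 0.3 * src.samples + rng.normal(0, 0.1 * src.samples.std(), n)
            channels[label] = Waveform(noisy, fs=fs, label=label)
    rec = Record(channels=channels, subject_id=subject_id)
    truth = SyntheticTruth(r_times=r_times, ao_times_scg=ao_scg,
                           ao_times_gcg=ao_gcg, nn_true=nn, params=params)
    return rec, truth


def generate_cohort(n_subjects: int = 20, duration: float = 600.0,
                    snr_db: float = 10.0, seed: int = 0):
    """Generate the synthetic study cohort: tri-modal records with truth.

    Conditions emulate the study population (healthy adults, supine
    10-minute recordings at 800 Hz): per subject, mean NN drawn uniformly in
    850–1060 ms, interval jitter 20–60 ms, LF (0.1 Hz) and HF (0.25 Hz)
    modulation amplitudes 15–40 / 15–35 ms, VLF amplitude 5–15 ms.  The SCG
    carries the AO wave 40 ms after R with 3 ms per-beat timing jitter; the
    GCG 45 ms after R with 1 ms jitter — the smaller GCG jitter mirrors the
    gyrocardiogram's greater tolerance to disturbances.  Every channel gets
    broadband noise at ``snr_db``; the ECG additionally gets a leading
    spike (10 samples) and sub-0.5 Hz baseline wander.

    Returns a list of ``(Record, SyntheticTruth)`` pairs.
    """
    rng = np.random.default_rng(seed)
    cohort = []
    for i in range(n_subjects):
        sub_seed = int(rng.integers(0, 2 ** 31 - 1))
        params = HRVTruthParams(
            mean_nn=float(rng.uniform(850, 1060)),
            sd_nn=float(rng.uniform(20, 60)),
            lf_amp=float(rng.uniform(15, 40)),
            hf_amp=float(rng.uniform(15, 35)),
            vlf_amp=float(rng.uniform(5, 15)),
            duration=duration,
            seed=sub_seed,
        )
        morph_scg = MorphologyParams(ao_delay=40.0, ao_jitter_ms=3.0,
                                     noise_snr=snr_db)
        morph_gcg = MorphologyParams(ao_delay=45.0, ao_jitter_ms=1.0,
                                     noise_snr=snr_db)
        morph_ecg = MorphologyParams(ao_delay=40.0, noise_snr=snr_db,
                                     spike_count=10, baseline_amp=0.3)
        cohort.append(generate_record(params, morph_scg, morph_gcg,
                                      morph_ecg, subject_id=f"S{i + 1:02d}"))
    return cohort
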
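"""Time-domain and frequency-domain HRV indices.

Time domain: AVNN (mean NN), SDNN (sample standard deviation), RMSSD (root
mean square of successive differences) and pNN50 (proportion of successive
differences exceeding 50 ms, reported as a fraction in [0, 1]).

Frequency domain: Lomb–Scargle periodogram of the mean-removed NN series at
its (unevenly spaced) beat times, evaluated on a 1024-point linear grid up
to 0.4 Hz and normalized so that the rectangle-rule integral of the power
density over (0, f_max] approximates the NN variance in ms².  Band powers:
VLF 0.0033–0.04 Hz, LF 0.04–0.15 Hz, HF 0.15–0.4 Hz, TP = everything up to
0.4 Hz (hence TP ≥ VLF+LF+HF), plus the LF/HF ratio.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import lombscargle

from .beats import NNSeries

VLF_BAND = (0.0033, 0.04)
LF_BAND = (0.04, 0.15)
HF_BAND = (0.15, 0.4)
DEFAULT_N_FREQ = 1024
DEFAULT_F_MAX = 0.4


@dataclass
class TimeDomainIndices:
    avnn: float   # ms
    sdnn: float   # ms
    rmssd: float  # ms
    pnn50: float  # proportion in [0, 1]


@dataclass
class SpectrumEstimate:
    """Lomb–Scargle power density of an NN series."""

    freqs: np.ndarray   # Hz, strictly increasing in (0, f_max]
    power: np.ndarray   # ms^2/Hz, >= 0
    n_freq: int
    f_max: float

    @property
    def df(self) -> float:
        return self.f_max / self.n_freq


@dataclass
class FreqDomainIndices:
    vlf: float     # ms^2
    lf: float      # ms^2
    hf: float      # ms^2
    lf_hf: float   # ratio; NaN marks undefined (hf == 0)
    tp: float      # ms^2
    bands: dict = None


def time_domain(nn: NNSeries, pnn50_denominator: str = "diffs") -> TimeDomainIndices:
    """Compute AVNN, SDNN, RMSSD, pNN50.

    SDNN uses the sample (N−1) denominator.  pNN50 counts successive
    differences strictly exceeding 50 ms; its denominator is the number of
    successive differences (``"diffs"``, conventional) or the number of
    intervals (``"intervals"``).
    """
    x = nn.intervals
    if x.size < 2:
        raise ValueError("time_domain requires at least 2 intervals")
    d = np.diff(x)
    denom = d.size if pnn50_denominator == "diffs" else x.size
    return TimeDomainIndices(
        avnn=float(np.mean(x)),
        sdnn=float(np.std(x, ddof=1)),
        rmssd=float(np.sqrt(np.mean(d ** 2))),
        pnn50=float(np.sum(np.abs(d) > 50.0)) / denom,
    )


def lomb(nn: NNSeries, n_freq: int = DEFAULT_N_FREQ,
         f_max: float = DEFAULT_F_MAX) -> SpectrumEstimate:
    """Lomb–Scargle periodogram of the NN series at its beat times.

    The mean-removed intervals (ms) are analyzed at their onset times (s) on
    ``n_freq`` evenly spaced frequencies in (0, f_max].  The raw periodogram
    is rescaled by 2·T/N (T the time span, N the interval count) so that a
    rectangle-rule integral over the grid recovers the series variance:
    the sharp peak of a pure sinusoidal modulation has height ≈ A²T/2 and
    main-lobe width ≈ 1/T, integrating to the tone variance A²/2.
    """
    if len(nn) < 8:
        raise ValueError("lomb requires at least 8 intervals")
    t = nn.onset_times
    y = nn.intervals - np.mean(nn.intervals)
    freqs = np.linspace(f_max / n_freq, f_max, n_freq)
    pgram = lombscargle(t, y, 2 * np.pi * freqs)
    span = float(t[-1] - t[0])
    power = pgram * (2.0 * span / y.size)
    return SpectrumEstimate(freqs=freqs, power=np.maximum(power, 0.0),
                            n_freq=n_freq, f_max=f_max)


def band_powers(spec: SpectrumEstimate) -> FreqDomainIndices:
    """Integrate the spectrum over the canonical HRV bands (rectangle rule).

    VLF/LF/HF integrate [0.0033, 0.04), [0.04, 0.15), [0.15, 0.4]; TP
    integrates the whole grid (0, f_max], so TP ≥ VLF+LF+HF.  ``lf_hf`` is
    NaN (undefined marker) when HF is zero.
    """
    if spec.f_max < HF_BAND[1]:
        raise ValueError("spectrum must cover frequencies up to 0.4 Hz")
    f, p, df = spec.freqs, spec.power, spec.df

    def integrate(lo, hi, closed_hi=False):
        if closed_hi:
            m = (f >= lo) & (f <= hi)
        else:
            m = (f >= lo) & (f < hi)
        return float(np.sum(p[m]) * df)

    vlf = integrate(*VLF_BAND)
    lf = integrate(*LF_BAND)
    hf = integrate(HF_BAND[0], HF_BAND[1], closed_hi=True)
    tp = float(np.sum(p) * df)
    lf_hf = lf / hf if hf > 0 else float("nan")
    return FreqDomainIndices(vlf=vlf, lf=lf, hf=hf, lf_hf=lf_hf, tp=tp,
                             bands={"vlf": VLF_BAND, "lf": LF_BAND,
                                    "hf": HF_BAND})


def freq_domain(nn: NNSeries, n_freq: int = DEFAULT_N_FREQ,
                f_max: float = DEFAULT_F_MAX) -> FreqDomainIndices:
    """Convenience wrapper: Lomb spectrum then band powers."""
    return band_powers(lomb(nn, n_freq=n_freq, f_max=f_max))
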
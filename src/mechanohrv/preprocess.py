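"""ECG cleanup chain: leading-spike removal, median filtering, EMD detrending.

The raw recordings exhibit three artifact families handled here:

* an acquisition spike confined to the first handful of samples (≤ 17),
* impulsive noise removed with a 5th-order median filter,
* baseline wander removed by empirical mode decomposition (EMD): the signal
  is split into intrinsic mode functions (IMFs) by iterative sifting with
  piecewise-cubic-Hermite (PCHIP) envelope interpolation, and the slow
  residual — which carries the wander — is dropped (or a chosen IMF range
  is kept) at reconstruction.

Per-recording detrending choices are expressed as :class:`DetrendRecipe`
config entries rather than hard-coded branches.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.ndimage import median_filter

from .records import Waveform

DEFAULT_MAX_IMF = 10
DEFAULT_MAX_SIFT = 100
DEFAULT_SIFT_TOL = 0.2        # Cauchy-type normalized-change threshold
DEFAULT_ENERGY_RATIO_DB = 20  # signal-to-residual energy-ratio stop
DEFAULT_SPIKE_FACTOR = 8.0    # MAD multiples marking a leading-spike sample


@dataclass
class EMDResult:
    """Decomposition into intrinsic mode functions plus a residual."""

    imfs: list[Waveform]
    residual: Waveform

    def reconstruct(self) -> np.ndarray:
        out = self.residual.samples.copy()
        for imf in self.imfs:
            out += imf.samples
        return out


@dataclass
class DetrendRecipe:
    """How to rebuild a signal from its EMD for baseline-wander removal.

    mode
        ``drop_residual`` — subtract the residual (keep all IMFs);
        ``keep_imfs`` — keep only IMFs ``imf_range`` (1-based, inclusive);
        ``crop_then_keep_imfs`` — first drop ``crop_samples`` leading
        samples, then proceed as ``keep_imfs``.
    """

    mode: str = "drop_residual"
    imf_range: tuple[int, int] | None = None
    crop_samples: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("drop_residual", "keep_imfs", "crop_then_keep_imfs"):
            raise ValueError(f"unknown detrend mode {self.mode!r}")
        if self.crop_samples < 0:
            raise ValueError("crop_samples must be non-negative")
        if self.mode != "drop_residual" and self.imf_range is None:
            raise ValueError(f"mode {self.mode!r} requires imf_range")


def strip_leading_spike(w: Waveform, max_samples: int = 17,
                        spike_factor: float = DEFAULT_SPIKE_FACTOR) -> Waveform:
    """Remove an acquisition spike confined to the first ``max_samples`` samples.

    A sample among the first ``max_samples`` is flagged as spike when it
    deviates from the median of the remainder of the signal by more than
    ``spike_factor`` × the remainder's robust scale (1.4826·MAD).  The
    flagged prefix (up to its last flagged sample) is replaced by the first
    non-spike value; length is unchanged.  Clean inputs pass through
    untouched.
    """
    x = w.samples
    if x.size <= max_samples + 1:
        return w
    rest = x[max_samples:]
    center = np.median(rest)
    scale = 1.4826 * np.median(np.abs(rest - center))
    if scale == 0:
        scale = np.std(rest) or 1.0
    head = x[:max_samples]
    flagged = np.abs(head - center) > spike_factor * scale
    if not flagged.any():
        return w
    k = int(np.max(np.nonzero(flagged)[0]))  # last flagged sample
    out = x.copy()
    out[: k + 1] = x[k + 1]
    return w.replace_samples(out)


def median_filter5(w: Waveform) -> Waveform:
    """5th-order (5-sample centered window) median filter.

    Edges use nearest-value padding so the output keeps the input length
    without introducing boundary spikes.
    """
    if len(w) < 5:
        raise ValueError("median_filter5 requires at least 5 samples")
    return w.replace_samples(median_filter(w.samples, size=5, mode="nearest"))


def _extrema(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices of local maxima and minima; plateaus register at their end."""
    d = np.sign(np.diff(x))
    # forward-fill zeros so plateaus inherit the preceding slope direction
    nz = d != 0
    idx = np.where(nz, np.arange(d.size), -1)
    np.maximum.accumulate(idx, out=idx)
    filled = np.where(idx >= 0, d[np.maximum(idx, 0)], 0)
    turn = np.nonzero(filled[:-1] != filled[1:])[0] + 1
    maxima = turn[(filled[turn] < 0) & (filled[turn - 1] > 0)]
    minima = turn[(filled[turn] > 0) & (filled[turn - 1] < 0)]
    return maxima, minima


def _envelope(t: np.ndarray, idx: np.ndarray, x: np.ndarray,
              n: int) -> np.ndarray:
    """PCHIP envelope through extrema, mirror-extended beyond both ends."""
    ti, xi = t[idx], x[idx]
    # mirror up to two extrema about each endpoint to tame edge swings
    k = min(2, ti.size)
    t_ext = np.concatenate([2 * t[0] - ti[:k][::-1], ti, 2 * t[-1] - ti[-k:][::-1]])
    x_ext = np.concatenate([xi[:k][::-1], xi, xi[-k:][::-1]])
    order = np.argsort(t_ext)
    t_ext, x_ext = t_ext[order], x_ext[order]
    keep = np.concatenate([[True], np.diff(t_ext) > 0])
    return PchipInterpolator(t_ext[keep], x_ext[keep])(t)


def emd(w: Waveform, max_imf: int = DEFAULT_MAX_IMF,
        max_sift: int = DEFAULT_MAX_SIFT,
        sift_tol: float = DEFAULT_SIFT_TOL,
        energy_ratio_db: float = DEFAULT_ENERGY_RATIO_DB) -> EMDResult:
    """Classical empirical mode decomposition.

    Envelopes are PCHIP interpolants of the local extrema (mirror-extended
    at the boundaries).  Sifting of each mode stops after ``max_sift``
    iterations or when the normalized change between consecutive sifts
    falls below ``sift_tol`` (Cauchy-type criterion).  The decomposition
    stops at ``max_imf`` modes, when the signal-to-residual energy ratio
    exceeds ``energy_ratio_db``, or when the residual has too few extrema
    to sift (monotone residual).  By construction
    ``sum(imfs) + residual == input`` to numerical precision.

    A monotone input yields zero IMFs with ``residual == input``.
    """
    x = w.samples.astype(float)
    if x.size < 4:
        raise ValueError("emd requires at least 4 samples")
    t = np.arange(x.size, dtype=float)
    total_energy = float(np.sum(x ** 2))
    residual = x.copy()
    imfs: list[np.ndarray] = []
    while len(imfs) < max_imf:
        maxima, minima = _extrema(residual)
        if maxima.size < 2 or minima.size < 2:
            break
        h = residual.copy()
        for _ in range(max_sift):
            maxima, minima = _extrema(h)
            if maxima.size < 2 or minima.size < 2:
                break
            mean_env = 0.5 * (_envelope(t, maxima, h, x.size)
                              + _envelope(t, minima, h, x.size))
            h_new = h - mean_env
            denom = float(np.sum(h ** 2))
            sd = float(np.sum(mean_env ** 2)) / denom if denom > 0 else 0.0
            h = h_new
            if sd < sift_tol:
                break
        # Mode validity: the envelope anchors must span the record — a
        # near-monotone trend whose only extrema are edge ripples would
        # otherwise be extracted on an extrapolated (meaningless) envelope.
        # Such candidates are left in the residual, ending the decomposition.
        maxima, minima = _extrema(h)
        if maxima.size < 2 or minima.size < 2:
            break
        anchors = np.sort(np.concatenate([[0], maxima, minima, [x.size - 1]]))
        if np.max(np.diff(anchors)) > x.size / 3:
            break
        imfs.append(h)
        residual = residual - h
        res_energy = float(np.sum(residual ** 2))
        if res_energy == 0 or (total_energy > 0 and
                               10 * np.log10(total_energy / res_energy)
                               > energy_ratio_db):
            break
    return EMDResult(
        imfs=[w.replace_samples(m) for m in imfs],
        residual=w.replace_samples(residual),
    )


def detrend_emd(w: Waveform, recipe: DetrendRecipe | None = None,
                decomposition: EMDResult | None = None, **emd_kwargs) -> Waveform:
    """Remove baseline wander by EMD reconstruction per a recipe.

    ``drop_residual`` subtracts the slow residual from the input;
    ``keep_imfs`` sums only IMFs in the 1-based inclusive ``imf_range``;
    ``crop_then_keep_imfs`` drops ``crop_samples`` leading samples first
    (for recordings whose start is unusable) and then keeps the IMF range.
    """
    if recipe is None:
        recipe = DetrendRecipe()
    if recipe.mode == "crop_then_keep_imfs":
        if recipe.crop_samples >= len(w):
            raise ValueError("crop_samples exceeds signal length")
        w = w.replace_samples(w.samples[recipe.crop_samples:])
        decomposition = None  # decomposition of the uncropped signal is void
        recipe = DetrendRecipe(mode="keep_imfs", imf_range=recipe.imf_range)
    if decomposition is None:
        decomposition = emd(w, **emd_kwargs)
    if recipe.mode == "drop_residual":
        return w.replace_samples(w.samples - decomposition.residual.samples)
    lo, hi = recipe.imf_range
    n_imf = len(decomposition.imfs)
    if not 1 <= lo <= hi:
        raise ValueError(f"invalid imf_range {recipe.imf_range}")
    if hi > n_imf:
        raise ValueError(
            f"imf_range {recipe.imf_range} exceeds available IMFs ({n_imf})")
    out = np.zeros(len(w))
    for m in decomposition.imfs[lo - 1:hi]:
        out += m.samples
    return w.replace_samples(out)


def clean_ecg(w: Waveform, spike_max_samples: int = 17,
              detrend: DetrendRecipe | None = None) -> Waveform:
    """Full cleanup chain: spike removal → median filter → optional EMD detrend."""
    out = strip_leading_spike(w, max_samples=spike_max_samples)
    out = median_filter5(out)
    if detrend is not None:
        out = detrend_emd(out, detrend)
    return out
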
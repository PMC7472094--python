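"""Cross-modality HRV agreement: windowing, index panels, error and correlation.

The analysis runs in two variants: *full* (one index panel per recording and
modality) and *windowed* (panels on 179 s sliding windows advanced in 15 s
steps — 179 s because the shortest recordings last 3 min).  Agreement
between the ECG-derived reference and each mechanical modality is
summarized per index as the mean and standard deviation of the relative
error |test − ref|/|ref| and as the Pearson correlation coefficient with
its two-sided p-value; ρ > 0.7 is flagged as strong correlation and the
reporting threshold for significance is p < 0.001.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .beats import (NNSeries, detect_ao, filter_nn, nn_from_beats,
                    pan_tompkins)
from .hrv import freq_domain, time_domain
from .poincare import poincare_indices
from .preprocess import clean_ecg
from .records import Record, validate_record

#: The fixed panel row order (time domain, frequency domain, Poincaré).
PANEL_KEYS = ("avnn", "sdnn", "rmssd", "pnn50",
              "vlf", "lf", "hf", "lf_hf", "tp",
              "sd1", "sd2", "sd_ratio", "ea", "vai", "vli")

STRONG_RHO = 0.7
P_THRESHOLD = 1e-3
DEFAULT_MIN_BEATS = 30

MODALITY_CHANNEL = {"scg": "scg_z", "gcg": "gcg_y"}


@dataclass
class WindowSpec:
    """Sliding-window layout; defaults follow the 179 s / 15 s scheme."""

    length_s: float = 179.0
    step_s: float = 15.0

    def __post_init__(self) -> None:
        if not self.length_s > self.step_s > 0:
            raise ValueError("require length_s > step_s > 0")

    def n_windows(self, duration_s: float) -> int:
        """Closed form: floor((T − length)/step) + 1 full windows (0 if T < length)."""
        if duration_s + 1e-9 < self.length_s:
            return 0
        return int(np.floor((duration_s - self.length_s) / self.step_s + 1e-9)) + 1


def window_nn(nn: NNSeries, spec: WindowSpec | None = None,
              duration: float | None = None,
              min_beats: int = DEFAULT_MIN_BEATS) -> list[NNSeries]:
    """Split an NN series into overlapping windows by interval onset time.

    Window k covers onset times in [k·step, k·step + length); only windows
    fully contained in ``duration`` (default: the last onset time) are
    produced, and windows with fewer than ``min_beats`` intervals are
    dropped.
    """
    if spec is None:
        spec = WindowSpec()
    if len(nn) == 0:
        return []
    if duration is None:
        duration = float(nn.onset_times[-1])
    return list(window_nn_map(nn, spec, duration, min_beats).values())


def window_nn_map(nn: NNSeries, spec: WindowSpec | None = None,
                  duration: float | None = None,
                  min_beats: int = DEFAULT_MIN_BEATS) -> dict[int, NNSeries]:
    """Like :func:`window_nn` but keyed by window index, for cross-modality
    pairing of the same time span."""
    if spec is None:
        spec = WindowSpec()
    if len(nn) == 0:
        return {}
    if duration is None:
        duration = float(nn.onset_times[-1])
    out: dict[int, NNSeries] = {}
    for k in range(spec.n_windows(duration)):
        lo = k * spec.step_s
        hi = lo + spec.length_s
        m = (nn.onset_times >= lo) & (nn.onset_times < hi)
        if int(m.sum()) < min_beats:
            continue
        out[k] = NNSeries(intervals=nn.intervals[m],
                          onset_times=nn.onset_times[m],
                          modality=nn.modality,
                          flags=[f for f, keep in zip(nn.flags, m) if keep])
    return out


def panel(nn: NNSeries, min_beats: int = DEFAULT_MIN_BEATS) -> dict[str, float]:
    """All 15 HRV indices for one NN series (one recording or window).

    Undefined entries (e.g. LF/HF with zero HF power) are NaN, never a
    silent zero.  Raises when fewer than ``min_beats`` intervals remain.
    """
    if len(nn) < min_beats:
        raise ValueError(
            f"panel requires at least {min_beats} intervals, got {len(nn)}")
    td = time_domain(nn)
    fd = freq_domain(nn)
    pc = poincare_indices(nn)
    return {
        "avnn": td.avnn, "sdnn": td.sdnn, "rmssd": td.rmssd, "pnn50": td.pnn50,
        "vlf": fd.vlf, "lf": fd.lf, "hf": fd.hf, "lf_hf": fd.lf_hf, "tp": fd.tp,
        "sd1": pc.sd1, "sd2": pc.sd2, "sd_ratio": pc.sd_ratio,
        "ea": pc.ea, "vai": pc.vai, "vli": pc.vli,
    }


def relative_error(ref: dict[str, float], test: dict[str, float]):
    """Per-index relative error |test − ref| / |ref| plus absolute difference.

    A zero (or undefined) reference yields NaN — excluded from cohort
    aggregation rather than propagated as infinity.
    """
    if set(ref) != set(test):
        raise ValueError("panels have mismatched index keys")
    rel, absd = {}, {}
    for k in ref:
        r, t = ref[k], test[k]
        absd[k] = abs(t - r) if np.isfinite(r) and np.isfinite(t) else float("nan")
        if not np.isfinite(r) or not np.isfinite(t) or r == 0:
            rel[k] = float("nan")
        else:
            rel[k] = abs(t - r) / abs(r)
    return rel, absd


def pearson(x, y) -> tuple[float, float]:
    """Pearson product-moment correlation with two-sided p-value.

    The p-value comes from the exact t transform with n−2 degrees of
    freedom.  Zero variance in either input yields (NaN, NaN).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("pearson requires paired samples with n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan"), float("nan")
    if np.array_equal(x, y):
        return 1.0, 0.0  # self-comparison is exact, not 1 − eps
    rho, p = stats.pearsonr(x, y)
    return float(rho), float(p)


def analyze_record(rec: Record, min_beats: int = DEFAULT_MIN_BEATS,
                   windows: WindowSpec | None = None, clean: bool = True):
    """Run detection → NN → panels for all three modalities of one record.

    With ``clean`` (default) the ECG first passes the spike-removal and
    median-filter cleanup; EMD detrending is recipe-driven and applied
    separately when a recording needs it.  Returns ``{"full": {modality:
    panel}, "windowed": {modality: [panels]}, "nn": {modality: NNSeries}}``.
    The windowed entry is present only when ``windows`` is given.
    """
    ecg = clean_ecg(rec["ecg"]) if clean else rec["ecg"]
    r_beats = pan_tompkins(ecg)
    nn_by_mod: dict[str, NNSeries] = {}
    nn_by_mod["ecg"] = filter_nn(nn_from_beats(r_beats))
    for mod, chan in MODALITY_CHANNEL.items():
        ao = detect_ao(rec[chan], r_beats, modality=mod)
        nn_by_mod[mod] = filter_nn(nn_from_beats(ao))
    out = {"full": {m: panel(nn, min_beats=min_beats)
                    for m, nn in nn_by_mod.items()},
           "nn": nn_by_mod}
    if windows is not None:
        wmaps = {m: window_nn_map(nn, windows, duration=rec.duration,
                                  min_beats=min_beats)
                 for m, nn in nn_by_mod.items()}
        common = sorted(set.intersection(*(set(w) for w in wmaps.values())))
        out["windowed"] = {
            m: [panel(wmaps[m][k], min_beats=min_beats) for k in common]
            for m in wmaps}
    return out


def _aggregate(ref_panels: list[dict], test_panels: list[dict]) -> pd.DataFrame:
    """Per-index agreement table from paired panels."""
    rows = []
    for key in PANEL_KEYS:
        ref_vals = np.array([p[key] for p in ref_panels], dtype=float)
        test_vals = np.array([p[key] for p in test_panels], dtype=float)
        rels = []
        absd = []
        for r, t in zip(ref_vals, test_vals):
            if np.isfinite(r) and np.isfinite(t):
                absd.append(abs(t - r))
                if r != 0:
                    rels.append(abs(t - r) / abs(r))
        rels = np.array(rels)
        absd = np.array(absd)
        ok = np.isfinite(ref_vals) & np.isfinite(test_vals)
        if ok.sum() >= 3:
            rho, p = pearson(ref_vals[ok], test_vals[ok])
        else:
            rho, p = float("nan"), float("nan")
        rows.append({
            "index": key,
            "rel_err_mean": float(np.mean(rels)) if rels.size else float("nan"),
            "rel_err_sd": float(np.std(rels, ddof=1)) if rels.size > 1 else float("nan"),
            "abs_err_mean": float(np.mean(absd)) if absd.size else float("nan"),
            "pearson_rho": rho,
            "pearson_p": p,
            "strong": bool(rho > STRONG_RHO) if np.isfinite(rho) else False,
            "n_pairs": int(ok.sum()),
        })
    return pd.DataFrame(rows).set_index("index")


def compare_cohort(records: list[Record], spec: WindowSpec | None = None,
                   variant: str = "full",
                   min_beats: int = DEFAULT_MIN_BEATS) -> dict[str, pd.DataFrame]:
    """Cross-modality agreement over a cohort of records.

    ``variant="full"`` pairs one panel per record; ``variant="windowed"``
    pools every valid window of every record (windows are paired by
    position within each record).  Records failing validation are skipped
    with a warning.  Returns ``{"ecg_scg": table, "ecg_gcg": table}`` where
    each table has the 15 index rows and relative-error / correlation
    columns.
    """
    if variant not in ("full", "windowed"):
        raise ValueError("variant must be 'full' or 'windowed'")
    if variant == "windowed" and spec is None:
        spec = WindowSpec()
    panels: dict[str, list[dict]] = {"ecg": [], "scg": [], "gcg": []}
    for rec in records:
        findings = validate_record(rec)
        if findings:
            warnings.warn(
                f"skipping record {rec.subject_id!r}: {'; '.join(findings)}")
            continue
        res = analyze_record(rec, min_beats=min_beats,
                             windows=spec if variant == "windowed" else None)
        if variant == "full":
            for m in panels:
                panels[m].append(res["full"][m])
        else:
            # windows were already intersected by index inside analyze_record
            by_mod = res["windowed"]
            for m in panels:
                panels[m].extend(by_mod[m])
    return {
        "ecg_scg": _aggregate(panels["ecg"], panels["scg"]),
        "ecg_gcg": _aggregate(panels["ecg"], panels["gcg"]),
    }
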
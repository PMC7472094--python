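"""Poincaré-map (Lorenz plot) indices of nonlinear HRV.

The Poincaré map scatters each NN interval against its predecessor:
points (NN_i, NN_{i+1}).  An ellipse fitted along the identity line
summarizes the cloud: SD1 (width, short-term variability) is the RMS
distance of points from the identity line y = x; SD2 (length, long-term
variability) is the RMS distance from the perpendicular line
y = −x + 2·NN̄ through the cloud center.  Because the SD1 residuals are
taken about the identity line itself (no mean removal), SD1 = RMSSD/√2
exactly.  Derived quantities: SD1/SD2, the fitted-ellipse area
EA = π·SD1·SD2, the vector angular index VAI (mean absolute angular
deviation of the points from the 45° identity direction, as seen from the
origin) and the vector length index VLI (population standard deviation of
the point distances from the origin).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .beats import NNSeries


@dataclass
class PoincareIndices:
    sd1: float       # ms
    sd2: float       # ms
    sd_ratio: float  # SD1/SD2; NaN marks undefined (SD2 == 0)
    ea: float        # ms^2, ellipse area = pi * SD1 * SD2
    vai: float       # degrees, in [0, 45]
    vli: float       # ms


def poincare_points(nn: NNSeries) -> np.ndarray:
    """Scatter points (NN_i, NN_{i+1}); N intervals yield N−1 points."""
    x = nn.intervals
    if x.size < 2:
        raise ValueError("poincare_points requires at least 2 intervals")
    return np.column_stack([x[:-1], x[1:]])


def poincare_indices(nn: NNSeries, mean_removed_sd1: bool = False) -> PoincareIndices:
    """Compute SD1, SD2, SD1/SD2, EA, VAI and VLI.

    SD1 and SD2 are RMS distances about the identity line and its
    perpendicular through (NN̄, NN̄); with ``mean_removed_sd1`` the
    residuals are additionally centered before the RMS (a variant some
    toolboxes use, breaking the exact SD1–RMSSD/√2 identity).

    VAI averages |θ_i − 45°| with θ_i = atan2(NN_{i+1}, NN_i) in degrees —
    the angle of the ray from the origin to each scatter point.  VLI is the
    population (1/N) standard deviation of the point distances
    l_i = √(NN_i² + NN_{i+1}²) about their mean.
    """
    x = nn.intervals
    if x.size < 3:
        raise ValueError("poincare_indices requires at least 3 intervals")
    p1, p2 = x[:-1], x[1:]
    mean_nn = float(np.mean(x))

    d1 = (p2 - p1) / np.sqrt(2.0)                  # signed distance from y=x
    d2 = (p1 + p2 - 2 * mean_nn) / np.sqrt(2.0)    # from y=-x+2*mean
    if mean_removed_sd1:
        d1 = d1 - np.mean(d1)
        d2 = d2 - np.mean(d2)
    sd1 = float(np.sqrt(np.mean(d1 ** 2)))
    sd2 = float(np.sqrt(np.mean(d2 ** 2)))
    sd_ratio = sd1 / sd2 if sd2 > 0 else float("nan")
    ea = float(np.pi * sd1 * sd2)

    theta = np.degrees(np.arctan2(p2, p1))
    vai = float(np.mean(np.abs(theta - 45.0)))

    lengths = np.hypot(p1, p2)
    vli = float(np.sqrt(np.mean((lengths - np.mean(lengths)) ** 2)))
    return PoincareIndices(sd1=sd1, sd2=sd2, sd_ratio=sd_ratio, ea=ea,
                           vai=vai, vli=vli)


def plot_poincare(nn_by_modality: dict[str, NNSeries], path=None, ax=None):
    """Scatter-plot the Poincaré map for one or more modalities.

    Requires matplotlib (optional dependency).  Returns the axes.
    """
    import matplotlib
    if path is not None:
        matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    markers = {"ecg": "o", "scg": "*", "gcg": "."}
    for label, nn in nn_by_modality.items():
        pts = poincare_points(nn)
        ax.scatter(pts[:, 0], pts[:, 1], s=8, label=label,
                   marker=markers.get(label, "o"), alpha=0.6)
    lim = ax.get_xlim()
    ax.plot(lim, lim, "k--", lw=0.8)
    ax.set_xlabel("NN$_i$ [ms]")
    ax.set_ylabel("NN$_{i+1}$ [ms]")
    ax.legend()
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
    return ax
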
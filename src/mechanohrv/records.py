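"""Multichannel cardiac recordings: containers, CSV/text I/O, validation.

A :class:`Record` bundles synchronously acquired channels (ECG plus tri-axial
seismocardiogram and gyrocardiogram) sampled at a common rate.  The pipeline
requires the channels ``ecg``, ``scg_z`` (dorso-ventral acceleration) and
``gcg_y`` (head-to-foot angular velocity); the remaining axes are carried
along when present.  Axis convention: x lateral left→right, y head→foot,
z back→chest.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Channels every record must carry for the HRV agreement pipeline.
REQUIRED_CHANNELS = ("ecg", "scg_z", "gcg_y")

#: Full channel naming convention (one ECG lead, two tri-axial inertial sensors).
KNOWN_CHANNELS = (
    "ecg",
    "scg_x", "scg_y", "scg_z",
    "gcg_x", "gcg_y", "gcg_z",
)

DEFAULT_FS = 800.0


class RecordParseError(ValueError):
    """Raised when a recording file cannot be parsed; names the offending line."""


@dataclass
class Waveform:
    """One uniformly sampled channel.

    Parameters
    ----------
    samples : ndarray
        Sensor readings in arbitrary units; must be finite and non-empty.
    fs : float
        Sampling rate in Hz (> 0).
    label : str
        Channel name, e.g. ``"ecg"`` or ``"scg_z"``.
    t0 : float
        Start time in seconds.
    """

    samples: np.ndarray
    fs: float
    label: str = ""
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise ValueError("samples must be a non-empty 1-D array")
        if not self.fs > 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        # Non-finite samples are tolerated at construction so that
        # validate_record can report them; the pipeline rejects them there.

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Record length in seconds."""
        return self.samples.size / self.fs

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds."""
        return self.t0 + np.arange(self.samples.size) / self.fs

    def replace_samples(self, samples: np.ndarray) -> "Waveform":
        """New waveform with the same metadata and different samples."""
        return Waveform(np.asarray(samples, dtype=float), self.fs, self.label, self.t0)


@dataclass
class Record:
    """Synchronized multichannel recording from one subject."""

    channels: dict[str, Waveform] = field(default_factory=dict)
    subject_id: str = ""
    notes: str = ""

    def __getitem__(self, label: str) -> Waveform:
        return self.channels[label]

    def __contains__(self, label: str) -> bool:
        return label in self.channels

    @property
    def fs(self) -> float:
        return next(iter(self.channels.values())).fs

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.channels.values())))

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs


def read_record_text(path, schema: dict[int, str], fs: float = DEFAULT_FS,
                     subject_id: str = "") -> Record:
    """Load a whitespace-delimited numeric text recording.

    The deposited recordings are plain text with one sample per row and one
    column per channel; the column layout is not standardized, so a
    ``schema`` mapping column index (0-based) → channel label must be given
    together with the sampling rate.

    Raises
    ------
    RecordParseError
        Empty file, ragged rows or non-numeric cells (the message names the
        first offending line).
    """
    if not schema:
        raise ValueError("schema must map at least one column to a label")
    try:
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # empty file warns before failing
            data = np.loadtxt(path, ndmin=2)
    except Exception:
        _diagnose_text_file(path)
        raise  # unreachable unless the diagnosis finds nothing wrong
    if data.size == 0:
        raise RecordParseError(f"{path}: file contains no samples")
    ncol = data.shape[1]
    channels = {}
    for col, label in schema.items():
        if not 0 <= col < ncol:
            raise RecordParseError(
                f"{path}: schema column {col} out of range (file has {ncol} columns)")
        channels[label] = Waveform(data[:, col], fs=fs, label=label)
    return Record(channels=channels, subject_id=subject_id)


def _diagnose_text_file(path) -> None:
    """Re-scan a file np.loadtxt rejected to report the offending line."""
    width = None
    with open(path) as fh:
        n = 0
        for n, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            if width is None:
                width = len(parts)
            elif len(parts) != width:
                raise RecordParseError(
                    f"{path}: line {n}: expected {width} columns, found {len(parts)}")
            for cell in parts:
                try:
                    float(cell)
                except ValueError:
                    raise RecordParseError(
                        f"{path}: line {n}: non-numeric cell {cell!r}") from None
    if n == 0 or width is None:
        raise RecordParseError(f"{path}: file is empty")


def write_record_csv(rec: Record, path) -> None:
    """Write a record to the native CSV interchange format.

    Layout: ``# fs=<Hz>`` and ``# subject=<id>`` comment lines, a header row
    of channel labels, then one row per sample printed with 17 significant
    digits so that a read-back reproduces the float64 samples bitwise.
    """
    labels = list(rec.channels)
    data = np.column_stack([rec.channels[c].samples for c in labels])
    with open(path, "w") as fh:
        fh.write(f"# fs={rec.fs!r}\n")
        if rec.subject_id:
            fh.write(f"# subject={rec.subject_id}\n")
        fh.write(",".join(labels) + "\n")
        np.savetxt(fh, data, fmt="%.17g", delimiter=",")


def read_record_csv(path) -> Record:
    """Read a record written by :func:`write_record_csv`."""
    fs = None
    subject = ""
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            body = line[1:].strip()
            if body.startswith("fs="):
                fs = float(body[3:])
            elif body.startswith("subject="):
                subject = body[8:]
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        frame = pd.read_csv(fh, float_precision="round_trip")
    if fs is None:
        raise RecordParseError(f"{path}: missing '# fs=' header comment")
    if frame.empty:
        raise RecordParseError(f"{path}: no sample rows")
    channels = {c: Waveform(frame[c].to_numpy(dtype=float), fs=fs, label=c)
                for c in frame.columns}
    return Record(channels=channels, subject_id=subject)


def write_beats_csv(times_s: np.ndarray, flags, path, modality: str = "") -> None:
    """Beat annotations as two/three-column CSV (time_s, modality, flag)."""
    frame = pd.DataFrame({
        "time_s": np.asarray(times_s, dtype=float),
        "modality": modality,
        "flag": list(flags),
    })
    frame.to_csv(path, index=False)


def validate_record(rec: Record) -> list[str]:
    """Check the synchrony assumptions the pipeline relies on.

    Returns a list of human-readable findings; an empty list means the record
    is valid.  Never raises and never mutates the record.
    """
    findings: list[str] = []
    if not rec.channels:
        return ["record has no channels"]
    for label in REQUIRED_CHANNELS:
        if label not in rec.channels:
            findings.append(f"missing required channel {label!r}")
    ref_label = next(iter(rec.channels))
    ref = rec.channels[ref_label]
    for label, wf in rec.channels.items():
        if wf.fs != ref.fs:
            findings.append(
                f"channel {label!r} fs {wf.fs} differs from {ref_label!r} fs {ref.fs}")
        if len(wf) != len(ref):
            findings.append(
                f"channel {label!r} length {len(wf)} differs from "
                f"{ref_label!r} length {len(ref)}")
        bad = ~np.isfinite(wf.samples)
        if bad.any():
            findings.append(
                f"channel {label!r} has {int(bad.sum())} non-finite samples")
    return findings
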
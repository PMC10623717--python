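"""Reading and writing the external formats of the toolkit.

Two-channel abdominal recordings (BS = body-facing microphone, NS =
ambient-facing microphone) are plain PCM/float WAV. Event labels are
tab-separated seconds (Audacity label-track dialect accepted), hypnograms
are one 30-s stage label per line, and per-event feature tables are CSV.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.io import wavfile
from scipy.signal import resample_poly

from .intervals import IntervalSet

__all__ = [
    "Recording",
    "Hypnogram",
    "SLEEP_STAGES",
    "read_recording",
    "write_recording",
    "read_intervals",
    "write_intervals",
    "read_hypnogram",
    "write_hypnogram",
    "write_features",
    "read_features",
    "FEATURE_COLUMNS",
]

log = logging.getLogger(__name__)

#: Legal sleep-stage labels: wake, the three NREM stages, and REM.
SLEEP_STAGES = ("w", "N1", "N2", "N3", "REM")

FEATURE_COLUMNS = [
    "start_s",
    "end_s",
    "stage",
    "cv",
    "E0",
    "duration_ms",
    "FC",
    "ER_5_300",
    "ER_300_500",
    "ER_500_1000",
    "FD",
    "SampEn",
]


@dataclass
class Recording:
    """A pair of synchronized mono waveforms sharing one sample clock.

    ``bs`` is the bowel-sound channel, ``ns`` the ambient-noise channel.
    Amplitudes are dimensionless floats; PCM input is scaled to [-1, 1].
    """

    bs: np.ndarray
    ns: np.ndarray
    fs: float
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.bs = np.asarray(self.bs, dtype=np.float64)
        self.ns = np.asarray(self.ns, dtype=np.float64)
        if self.bs.ndim != 1 or self.ns.ndim != 1:
            raise ValueError("channels must be 1-D")
        if len(self.bs) != len(self.ns):
            raise ValueError("channel length mismatch")
        if not self.fs > 0:
            raise ValueError("fs must be positive")
        if not (np.isfinite(self.bs).all() and np.isfinite(self.ns).all()):
            raise ValueError("non-finite amplitude")

    @property
    def n_samples(self) -> int:
        return len(self.bs)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass(frozen=True)
class Hypnogram:
    """Sequence of fixed-length sleep-stage epochs (default 30 s)."""

    labels: tuple[str, ...]
    epoch_length_s: float = 30.0

    def __post_init__(self) -> None:
        if not self.labels:
            raise ValueError("empty hypnogram")
        if self.epoch_length_s <= 0:
            raise ValueError("epoch_length_s must be positive")
        bad = [lab for lab in self.labels if lab not in SLEEP_STAGES]
        if bad:
            raise ValueError(f"illegal sleep-stage label {bad[0]!r}")

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def duration_s(self) -> float:
        return len(self.labels) * self.epoch_length_s

    def epoch_of_sample(self, sample: int, fs: float) -> int:
        return int(sample / (self.epoch_length_s * fs))

    def stage_of_sample(self, sample: int, fs: float) -> str | None:
        """Stage label of the epoch containing ``sample``; None if beyond."""
        k = self.epoch_of_sample(sample, fs)
        if 0 <= k < len(self.labels):
            return self.labels[k]
        return None


def _to_float(x: np.ndarray) -> np.ndarray:
    """Scale integer PCM to [-1, 1]; pass float audio through."""
    if x.dtype == np.int16:
        return x.astype(np.float64) / 32768.0
    if x.dtype == np.int32:
        return x.astype(np.float64) / 2147483648.0
    if x.dtype == np.uint8:
        return (x.astype(np.float64) - 128.0) / 128.0
    if np.issubdtype(x.dtype, np.floating):
        return x.astype(np.float64)
    raise ValueError(f"unsupported WAV sample format {x.dtype}")


def read_recording(
    path_bs: str | Path,
    path_ns: str | Path | None = None,
    fs_expected: float | None = None,
    resample: bool = False,
) -> Recording:
    """Read a two-channel recording from one stereo or two mono WAV files.

    For a single stereo file channel 0 is the BS channel and channel 1 the
    NS channel. If no NS source exists the NS channel is all-zero (adaptive
    noise cancellation then degrades to a pass-through).
    """
    fs1, data = wavfile.read(str(path_bs))
    data = np.atleast_1d(data)
    if path_ns is None:
        if data.ndim == 2:
            if data.shape[1] < 2:
                raise ValueError("stereo file expected when path_ns is omitted")
            bs = _to_float(data[:, 0])
            ns = _to_float(data[:, 1])
        else:
            bs = _to_float(data)
            ns = np.zeros_like(bs)
            log.warning("no NS channel supplied; using silent reference")
    else:
        if data.ndim != 1:
            raise ValueError("BS file must be mono when a separate NS file is given")
        fs2, data2 = wavfile.read(str(path_ns))
        if fs2 != fs1:
            raise ValueError(f"sample-rate mismatch: {fs1} vs {fs2}")
        if len(data2) != len(data):
            raise ValueError("channel length mismatch")
        bs = _to_float(data)
        ns = _to_float(np.atleast_1d(data2))

    fs = float(fs1)
    if fs_expected is not None and fs != fs_expected:
        if not resample:
            raise ValueError(
                f"sample rate {fs} Hz != expected {fs_expected} Hz (set resample=True)"
            )
        up, down = int(fs_expected), int(fs)
        bs = resample_poly(bs, up, down)
        ns = resample_poly(ns, up, down)
        fs = float(fs_expected)
    return Recording(bs=bs, ns=ns, fs=fs)


def write_recording(rec: Recording, path_bs: str | Path, path_ns: str | Path | None = None) -> None:
    """Write a Recording as float32 WAV (stereo if only one path given)."""
    if path_ns is None:
        data = np.stack([rec.bs, rec.ns], axis=1).astype(np.float32)
        wavfile.write(str(path_bs), int(rec.fs), data)
    else:
        wavfile.write(str(path_bs), int(rec.fs), rec.bs.astype(np.float32))
        wavfile.write(str(path_ns), int(rec.fs), rec.ns.astype(np.float32))


def read_intervals(path: str | Path, fs: float) -> IntervalSet:
    """Read a label TSV of (start_s, end_s[, text]) rows into samples."""
    pairs: list[tuple[float, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                parts = line.split()
            try:
                a, b = float(parts[0]), float(parts[1])
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}: row {lineno}: cannot parse {line!r}") from exc
            if b <= a:
                raise ValueError(f"{path}: row {lineno}: end {b} <= start {a}")
            pairs.append((a, b))
    return IntervalSet.from_seconds(pairs, fs)


def write_intervals(iv: IntervalSet, path: str | Path, fs: float, label: str = "") -> None:
    with open(path, "w") as fh:
        for a, b in iv.to_seconds(fs):
            fh.write(f"{a:.6f}\t{b:.6f}\t{label}\n")


def read_hypnogram(path: str | Path, epoch_length_s: float = 30.0) -> Hypnogram:
    """Read a hypnogram TSV: one stage per line or (epoch_index, stage)."""
    labels: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            token = parts[-1]
            if token == "W":
                token = "w"
            labels.append(token)
    if not labels:
        raise ValueError("empty hypnogram")
    return Hypnogram(labels=tuple(labels), epoch_length_s=epoch_length_s)


def write_hypnogram(hyp: Hypnogram, path: str | Path) -> None:
    with open(path, "w") as fh:
        for lab in hyp.labels:
            fh.write(lab + "\n")


def write_features(records: Sequence, path: str | Path) -> None:
    """Write per-event feature records as CSV (header always present).

    Floats use repr-precision formatting, so a read-back round trip
    reproduces the values well beyond 9 significant digits.
    """
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(FEATURE_COLUMNS)
        for rec in records:
            row = []
            for col in FEATURE_COLUMNS:
                val = getattr(rec, col)
                if isinstance(val, float) and np.isnan(val):
                    row.append("")
                else:
                    row.append(repr(val) if isinstance(val, float) else val)
            writer.writerow(row)


def read_features(path: str | Path) -> list:
    from .features import FeatureRecord  # deferred: features imports audio_io

    out = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        for row in reader:
            kwargs = {}
            for col in FEATURE_COLUMNS:
                raw = row[col]
                if col == "stage":
                    kwargs[col] = raw
                else:
                    kwargs[col] = float(raw) if raw != "" else float("nan")
            out.append(FeatureRecord(**kwargs))
    return out
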
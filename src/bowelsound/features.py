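"""Per-event characteristic values (CVs) of detected bowel sounds.

Each event yields ten CVs: four time-domain (coefficient of variation of
the absolute amplitudes, energy E0, duration, and the per-epoch event rate
"frequency"), four frequency-domain (spectral centroid FC and the power
ratios in 5-300, 300-500 and 500-1000 Hz), and two nonlinear (Katz
fractal dimension and sample entropy). Undefined values on degenerate
segments are reported as NaN rather than raising.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import periodogram

from ._kernels import template_match_counts
from .audio_io import Hypnogram, Recording
from .intervals import IntervalSet

__all__ = [
    "FeatureRecord",
    "EntropyParams",
    "time_domain_cvs",
    "freq_domain_cvs",
    "katz_fd",
    "sample_entropy",
    "stage_ebs_frequency",
    "extract_all",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class FeatureRecord:
    """The ten characteristic values of one event plus its stage label."""

    start_s: float
    end_s: float
    stage: str
    cv: float
    E0: float
    duration_ms: float
    FC: float
    ER_5_300: float
    ER_300_500: float
    ER_500_1000: float
    FD: float
    SampEn: float


@dataclass(frozen=True)
class EntropyParams:
    """Sample-entropy parameters: pattern length m, tolerance r (absolute,
    or ``r_factor`` times the segment standard deviation when ``r`` is
    None), and time delay tau."""

    m: int = 2
    r: float | None = None
    r_factor: float = 0.2
    tau: int = 1

    def __post_init__(self) -> None:
        if self.m < 1 or self.tau < 1:
            raise ValueError("m >= 1 and tau >= 1 required")
        if self.r is not None and self.r <= 0:
            raise ValueError("r must be positive")
        if self.r is None and self.r_factor <= 0:
            raise ValueError("r_factor must be positive")


def time_domain_cvs(seg: np.ndarray, fs: float) -> tuple[float, float, float]:
    """Return (cv, E0, duration_ms).

    ``cv`` is std/mean of the absolute amplitudes (the raw audio is near
    zero-mean, so the signed ratio would be unstable); ``E0`` is the sum
    of squared amplitudes.
    """
    seg = np.asarray(seg, dtype=np.float64)
    if seg.size == 0:
        raise ValueError("empty segment")
    e0 = float(np.sum(seg**2))
    duration_ms = seg.size / fs * 1000.0
    a = np.abs(seg)
    mean = a.mean()
    cv = float(a.std() / mean) if mean > 0 else float("nan")
    return cv, e0, duration_ms


def freq_domain_cvs(seg: np.ndarray, fs: float) -> tuple[float, float, float, float]:
    """Return (FC, ER_5_300, ER_300_500, ER_500_1000).

    The power spectrum is a Hann-windowed periodogram zero-padded to the
    next power of two; FC is the spectral centroid and each ER is the
    power in a half-open band divided by the total power.
    """
    seg = np.asarray(seg, dtype=np.float64)
    if seg.size < 8:
        raise ValueError("segment too short for spectral features")
    if not seg.any():
        return (float("nan"),) * 4
    nfft = 1 << (seg.size - 1).bit_length()
    f, p = periodogram(seg, fs=fs, window="hann", nfft=nfft)
    total = p.sum()
    if total <= 0:
        return (float("nan"),) * 4
    fc = float((f * p).sum() / total)
    ers = []
    for lo, hi in ((5.0, 300.0), (300.0, 500.0), (500.0, 1000.0)):
        band = (f >= lo) & (f < hi)
        ers.append(float(p[band].sum() / total))
    return fc, ers[0], ers[1], ers[2]


def katz_fd(seg: np.ndarray, normalized: bool = False) -> float:
    """Katz fractal dimension of the waveform trace.

    With unit abscissa spacing, L is the path length sum of
    sqrt(1 + dx^2) and d the greatest distance from the first point;
    FD = log10(L) / log10(d). ``normalized=True`` uses the classical Katz
    form log10(n) / (log10(n) + log10(d/L)) with n = N - 1 steps. Returns
    NaN for constant traces or when log10(d) vanishes.
    """
    seg = np.asarray(seg, dtype=np.float64)
    if seg.size < 2:
        raise ValueError("need at least two points")
    dx = np.diff(seg)
    if not dx.any():
        return float("nan")  # constant trace: no meaningful dimension
    i = np.arange(1, seg.size, dtype=np.float64)
    d = float(np.sqrt(i**2 + (seg[1:] - seg[0]) ** 2).max())
    length = float(np.sqrt(1.0 + dx**2).sum())
    if normalized:
        n = seg.size - 1
        if length <= 0 or d <= 0:
            return float("nan")
        return float(np.log10(n) / (np.log10(n) + np.log10(d / length)))
    log_d = np.log10(d)
    if log_d == 0:
        return float("nan")
    return float(np.log10(length) / log_d)


def _match_frequency(x: np.ndarray, m: int, tau: int, r: float, n: int) -> float:
    """U^m(r): average per-template match frequency, self-matches excluded.

    Templates X_i of length m at delay tau are taken at i = 1..N - m*tau;
    each template's match count over j != i is divided by N - (m+1)*tau.
    """
    n_templates = n - m * tau
    if n_templates < 2:
        return float("nan")
    total = template_match_counts(x, m, tau, r, n_templates)
    denom = n - (m + 1) * tau
    if denom <= 0:
        return float("nan")
    return total / n_templates / denom


def sample_entropy(seg: np.ndarray, params: EntropyParams | None = None) -> float:
    """Sample entropy: -ln of the ratio of (m+1)- to m-template match
    frequencies at Chebyshev tolerance r, self-matches excluded.

    Returns NaN (flagged in the log) when no (m+1)-template pair matches,
    where the estimate diverges.
    """
    params = params or EntropyParams()
    seg = np.asarray(seg, dtype=np.float64)
    n = seg.size
    m, tau = params.m, params.tau
    if n <= (m + 1) * tau:
        raise ValueError("segment too short for the requested (m, tau)")
    r = params.r if params.r is not None else params.r_factor * float(seg.std())
    if r <= 0:
        return 0.0 if np.ptp(seg) == 0 else float("nan")
    u_m = _match_frequency(seg, m, tau, r, n)
    u_m1 = _match_frequency(seg, m + 1, tau, r, n)
    if not np.isfinite(u_m) or u_m <= 0:
        log.info("sample entropy undefined: no m-template matches")
        return float("nan")
    if not np.isfinite(u_m1) or u_m1 <= 0:
        log.info("sample entropy undefined: no (m+1)-template matches")
        return float("nan")
    return float(-np.log(u_m1 / u_m))


def stage_ebs_frequency(
    ebs: IntervalSet, hyp: Hypnogram, fs: float
) -> pd.DataFrame:
    """Per-epoch event rates with stage labels.

    Each event is assigned to the 30-s epoch containing its start sample;
    the per-epoch rate is the count divided by the epoch length in
    seconds. Events beyond the hypnogram extent are excluded (logged).
    The per-stage distribution of these per-epoch rates is what the
    "frequency" CV summarizes.
    """
    n_epochs = len(hyp)
    counts = np.zeros(n_epochs, dtype=np.int64)
    dropped = 0
    for a, _ in ebs:
        k = hyp.epoch_of_sample(a, fs)
        if 0 <= k < n_epochs:
            counts[k] += 1
        else:
            dropped += 1
    if dropped:
        log.info("%d events beyond hypnogram extent excluded from rates", dropped)
    return pd.DataFrame(
        {
            "epoch": np.arange(n_epochs),
            "stage": list(hyp.labels),
            "count": counts,
            "rate_per_s": counts / hyp.epoch_length_s,
        }
    )


def extract_all(
    rec: Recording,
    ebs: IntervalSet,
    hyp: Hypnogram | None = None,
    entropy_params: EntropyParams | None = None,
) -> list[FeatureRecord]:
    """Extract the per-segment CVs for every event.

    The stage label comes from the epoch containing the event's start
    sample ("unknown" beyond the hypnogram). Degenerate segments produce
    NaN fields, never exceptions.
    """
    entropy_params = entropy_params or EntropyParams()
    out: list[FeatureRecord] = []
    x = rec.bs
    for a, b in ebs:
        seg = x[a:b]
        cv, e0, duration_ms = time_domain_cvs(seg, rec.fs)
        try:
            fc, er1, er2, er3 = freq_domain_cvs(seg, rec.fs)
        except ValueError:
            fc = er1 = er2 = er3 = float("nan")
        fd = katz_fd(seg) if seg.size >= 2 else float("nan")
        try:
            sampen = sample_entropy(seg, entropy_params)
        except ValueError:
            sampen = float("nan")
        stage = "unknown"
        if hyp is not None:
            stage = hyp.stage_of_sample(a, rec.fs) or "unknown"
        out.append(
            FeatureRecord(
                start_s=a / rec.fs,
                end_s=b / rec.fs,
                stage=stage,
                cv=cv,
                E0=e0,
                duration_ms=duration_ms,
                FC=fc,
                ER_5_300=er1,
                ER_300_500=er2,
                ER_500_1000=er3,
                FD=fd,
                SampEn=sampen,
            )
        )
    return out
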
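"""Seeded synthetic two-channel overnight recordings with ground truth.

The generator emulates the statistical structure the detector assumes:

* sparse bowel-sound bursts on the BS channel — enveloped tones with a
  phase-locked second harmonic (bowel-sound clicks are asymmetric
  pressure transients, so their amplitude distribution is skewed — the
  non-Gaussian structure a third-order-cumulant detector keys on), with
  random phase, polarity and mild frequency jitter, tens to hundreds of
  ms long (log-normal durations, median near 230 ms), carriers mostly
  below 300 Hz;
* stationary pink ambient noise on the NS channel, bleeding into the BS
  channel through a short FIR room/body response (what the adaptive
  canceller removes);
* independent white sensor noise on each channel;
* rare turning-over events: long (1-5 s) high-amplitude broadband bursts
  dominating the NS channel, partially bleeding into the BS channel.

All randomness comes from one seed, split into independent streams for
event times, waveform parameters, ambient noise, sensor noise and
turnover events; fixing the seed fixes every byte of both channels, and
the noise floor is identical whether or not bursts are generated.

Ground-truth event intervals are the envelope supports, pre-merged under
the annotation rules (events closer than 100 ms become one label). Stage
modulation shifts per-epoch burst rate, amplitude and carrier so deeper
sleep has higher-energy, lower-frequency events.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np
from scipy import signal

from .audio_io import Hypnogram, Recording, SLEEP_STAGES
from .intervals import IntervalSet

__all__ = ["SynthConfig", "GroundTruth", "generate", "stage_modulate", "STAGE_EFFECTS"]

#: Per-stage (rate, amplitude, carrier) multipliers used by stage
#: modulation. Deeper sleep: fewer but higher-energy, lower-pitched
#: events; REM: sparsest. The ordering mirrors the observed stage trends
#: (event rate highest awake, energy highest in N3, centroid lowest in N3).
STAGE_EFFECTS: dict[str, tuple[float, float, float]] = {
    "w": (1.0, 1.0, 1.0),
    "N1": (0.9, 1.05, 0.95),
    "N2": (0.8, 0.9, 1.05),
    "N3": (0.7, 1.6, 0.7),
    "REM": (0.5, 0.95, 1.0),
}

_MERGE_GAP_S = 0.100  # annotation rule: sub-100-ms gaps are one event


@dataclass(frozen=True)
class SynthConfig:
    """Generator parameters.

    Durations are log-normal with median ``ebs_duration_ms_median``
    clipped to ``ebs_duration_ms_range``; carriers likewise, keeping most
    spectral mass below 300 Hz. ``ebs_snr_db`` is the burst-to-background
    rms ratio on the BS channel (energy SNR over the burst support).
    Turnover amplitudes are far above the ambient floor so the fixed
    artifact threshold separates them cleanly.
    """

    duration_s: float = 300.0
    fs: float = 8000.0
    ebs_rate_per_min: float = 20.0
    ebs_duration_ms_range: tuple[float, float] = (20.0, 600.0)
    ebs_duration_ms_median: float = 230.0
    ebs_duration_sigma: float = 0.6
    ebs_carrier_hz_range: tuple[float, float] = (80.0, 500.0)
    ebs_carrier_hz_median: float = 180.0
    ebs_carrier_sigma: float = 0.45
    ebs_snr_db: float = 15.0
    ebs_shape_harmonic: float = 0.5
    ambient_noise_rms: float = 0.01
    sensor_noise_rms: float = 0.002
    crosstalk_fir_length: int = 16
    crosstalk_gain: float = 1.0
    turnover_rate_per_hour: float = 6.0
    turnover_duration_s_range: tuple[float, float] = (1.0, 5.0)
    turnover_amplitude_range: tuple[float, float] = (6.0, 12.0)
    turnover_bleed_gain: float = 0.15
    stage_sequence: Hypnogram | None = None
    stage_modulated: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0 or self.fs <= 0:
            raise ValueError("duration_s and fs must be positive")
        for name in ("ebs_rate_per_min", "turnover_rate_per_hour"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in (
            "ebs_duration_ms_range",
            "ebs_carrier_hz_range",
            "turnover_duration_s_range",
            "turnover_amplitude_range",
        ):
            lo, hi = getattr(self, name)
            if not 0 < lo <= hi:
                raise ValueError(f"{name} must be an ordered positive range")
        if self.fs <= 2 * self.ebs_carrier_hz_range[1]:
            raise ValueError("fs must exceed twice the maximum carrier")


@dataclass
class GroundTruth:
    """Truth labels emitted alongside a synthetic recording."""

    ebs: IntervalSet
    turnover: IntervalSet
    hypnogram: Hypnogram
    events: list[dict[str, Any]] = field(default_factory=list)
    components: dict[str, np.ndarray] | None = None

    def ebs_in_turnover(self) -> list[bool]:
        return [self.turnover.overlaps(a, b) for a, b in self.ebs]


def stage_modulate(config: SynthConfig, hypnogram: Hypnogram | None) -> SynthConfig:
    """Attach a stage schedule to the config.

    With a hypnogram, per-epoch burst rate, amplitude and carrier follow
    the ``STAGE_EFFECTS`` multipliers; an empty/None hypnogram returns the
    config unchanged.
    """
    if hypnogram is None:
        return config
    if hypnogram.duration_s < config.duration_s:
        raise ValueError("hypnogram does not cover the configured duration")
    return replace(config, stage_sequence=hypnogram, stage_modulated=True)


def _auto_hypnogram(duration_s: float, epoch_s: float = 30.0) -> Hypnogram:
    """A plausible repeating stage pattern covering the duration."""
    cycle = ["w", "N1", "N2", "N2", "N3", "N3", "N2", "REM"]
    n_epochs = max(1, int(np.ceil(duration_s / epoch_s)))
    labels = tuple(cycle[i % len(cycle)] for i in range(n_epochs))
    return Hypnogram(labels=labels, epoch_length_s=epoch_s)


def _pink_noise(rng: np.random.Generator, n: int) -> np.ndarray:
    """Unit-rms 1/f noise via spectral shaping of white noise."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    scale = np.ones_like(f)
    scale[1:] = 1.0 / np.sqrt(f[1:])
    scale[0] = 0.0
    x = np.fft.irfft(spec * scale, n)
    return x / x.std()


def _lognormal_clipped(
    rng: np.random.Generator, median: float, sigma: float, lo: float, hi: float, size: int
) -> np.ndarray:
    draws = np.exp(np.log(median) + sigma * rng.standard_normal(size))
    return np.clip(draws, lo, hi)


def _stage_factors(cfg: SynthConfig, hyp: Hypnogram) -> np.ndarray:
    """(n_epochs, 3) array of (rate, amplitude, carrier) multipliers."""
    if cfg.stage_modulated:
        return np.array([STAGE_EFFECTS[s] for s in hyp.labels])
    return np.ones((len(hyp), 3))


def generate(
    config: SynthConfig, return_components: bool = False
) -> tuple[Recording, GroundTruth]:
    """Generate one synthetic two-channel recording with ground truth.

    With ``return_components=True`` the GroundTruth carries the additive
    BS-channel components (bursts, interference, sensor noise, turnover
    bleed) for diagnostics — e.g. measuring how well the adaptive
    canceller recovers the true interference.
    """
    cfg = config
    fs = cfg.fs
    n = int(round(cfg.duration_s * fs))
    hyp = cfg.stage_sequence or _auto_hypnogram(cfg.duration_s)
    if cfg.duration_s < hyp.epoch_length_s:
        raise ValueError("duration too short to hold one hypnogram epoch")

    ss = np.random.SeedSequence(cfg.seed)
    (s_events, s_wave, s_ambient, s_sensor, s_turn) = ss.spawn(5)
    rng_events = np.random.default_rng(s_events)
    rng_wave = np.random.default_rng(s_wave)
    rng_ambient = np.random.default_rng(s_ambient)
    rng_sensor = np.random.default_rng(s_sensor)
    rng_turn = np.random.default_rng(s_turn)

    factors = _stage_factors(cfg, hyp)
    epoch_len = hyp.epoch_length_s
    n_epochs_used = int(np.ceil(cfg.duration_s / epoch_len))

    # ---- event times first (reproducible truth independent of waveforms)
    starts: list[float] = []
    amp_factors: list[float] = []
    carrier_factors: list[float] = []
    base_rate_per_s = cfg.ebs_rate_per_min / 60.0
    for k in range(n_epochs_used):
        t0 = k * epoch_len
        t1 = min((k + 1) * epoch_len, cfg.duration_s)
        rate_f, amp_f, car_f = factors[min(k, len(factors) - 1)]
        lam = base_rate_per_s * rate_f * (t1 - t0)
        count = rng_events.poisson(lam)
        for t in np.sort(rng_events.uniform(t0, t1, size=count)):
            starts.append(float(t))
            amp_factors.append(float(amp_f))
            carrier_factors.append(float(car_f))

    n_events = len(starts)
    lo_ms, hi_ms = cfg.ebs_duration_ms_range
    durations_ms = _lognormal_clipped(
        rng_wave, cfg.ebs_duration_ms_median, cfg.ebs_duration_sigma, lo_ms, hi_ms, n_events
    )
    lo_hz, hi_hz = cfg.ebs_carrier_hz_range
    carriers = _lognormal_clipped(
        rng_wave, cfg.ebs_carrier_hz_median, cfg.ebs_carrier_sigma, lo_hz, hi_hz, n_events
    )
    carriers = np.clip(carriers * np.asarray(carrier_factors or [1.0])[: n_events], lo_hz, hi_hz)
    phases = rng_wave.uniform(0, 2 * np.pi, size=n_events)
    jitters = rng_wave.uniform(-0.05, 0.05, size=n_events)  # relative chirp
    polarities = rng_wave.choice([-1.0, 1.0], size=n_events)

    # ---- noise floor (independent streams; identical for any event draw)
    ambient = cfg.ambient_noise_rms * _pink_noise(rng_ambient, n)
    fir = rng_ambient.standard_normal(cfg.crosstalk_fir_length) * np.exp(
        -3.0 * np.arange(cfg.crosstalk_fir_length) / cfg.crosstalk_fir_length
    )
    fir *= cfg.crosstalk_gain / np.sqrt(np.sum(fir**2))
    interference = signal.lfilter(fir, [1.0], ambient)
    sensor_bs = cfg.sensor_noise_rms * rng_sensor.standard_normal(n)
    sensor_ns = cfg.sensor_noise_rms * rng_sensor.standard_normal(n)

    background_rms = float(
        np.sqrt((cfg.ambient_noise_rms * cfg.crosstalk_gain) ** 2 + cfg.sensor_noise_rms**2)
    )
    burst_rms = background_rms * 10 ** (cfg.ebs_snr_db / 20.0)

    # ---- burst synthesis
    bursts = np.zeros(n)
    events: list[dict[str, Any]] = []
    raw_intervals: list[tuple[int, int]] = []
    for i in range(n_events):
        a = int(round(starts[i] * fs))
        length = int(round(durations_ms[i] / 1000.0 * fs))
        length = max(length, 8)
        b = min(a + length, n)
        if b - a < 8:
            continue
        t = np.arange(b - a) / fs
        f_inst = carriers[i] * (1.0 + jitters[i] * t / t[-1] if t[-1] > 0 else 1.0)
        u = 2 * np.pi * f_inst * t + phases[i]
        # phase-locked second harmonic skews the amplitude distribution
        wave = polarities[i] * (np.sin(u) + cfg.ebs_shape_harmonic * np.cos(2 * u))
        env = signal.windows.tukey(b - a, alpha=0.5)
        burst = wave * env
        rms = burst.std()
        if rms > 0:
            burst *= burst_rms * amp_factors[i] / rms
        bursts[a:b] += burst
        raw_intervals.append((a, b))
        events.append(
            {
                "start": a,
                "end": b,
                "carrier_hz": float(carriers[i]),
                "amplitude": float(burst_rms * amp_factors[i]),
                "stage": hyp.stage_of_sample(a, fs) or "unknown",
            }
        )

    merge_gap = int(round(_MERGE_GAP_S * fs))
    ebs_truth = IntervalSet.from_pairs(raw_intervals).merge_within(merge_gap)

    # ---- turning-over events
    turnover_sig = np.zeros(n)
    turn_intervals: list[tuple[int, int]] = []
    lam_turn = cfg.turnover_rate_per_hour * cfg.duration_s / 3600.0
    n_turn = rng_turn.poisson(lam_turn)
    t_lo, t_hi = cfg.turnover_duration_s_range
    a_lo, a_hi = cfg.turnover_amplitude_range
    for t_start in np.sort(rng_turn.uniform(0, cfg.duration_s, size=n_turn)):
        length = int(round(rng_turn.uniform(t_lo, t_hi) * fs))
        a = int(round(t_start * fs))
        b = min(a + length, n)
        if b - a < int(0.5 * fs):
            continue
        amp = rng_turn.uniform(a_lo, a_hi)
        burst = rng_turn.standard_normal(b - a) * signal.windows.tukey(b - a, alpha=0.02)
        turnover_sig[a:b] += amp * burst
        turn_intervals.append((a, b))
    turnover_truth = IntervalSet.from_pairs(turn_intervals).merge_within(int(fs))

    bs = bursts + interference + sensor_bs + cfg.turnover_bleed_gain * turnover_sig
    ns = ambient + sensor_ns + turnover_sig

    rec = Recording(bs=bs, ns=ns, fs=fs)
    truth = GroundTruth(ebs=ebs_truth, turnover=turnover_truth, hypnogram=hyp, events=events)
    if return_components:
        truth.components = {
            "bursts": bursts,
            "interference": interference,
            "sensor_bs": sensor_bs,
            "turnover_bleed": cfg.turnover_bleed_gain * turnover_sig,
            "ambient": ambient,
        }
    return rec, truth
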
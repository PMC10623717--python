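"""End-to-end orchestration: denoise, calibrate, detect, clean, featurize.

``run_full`` reproduces the whole processing flow on one recording:
denoising, per-recording threshold calibration on a labeled window
(normally a ~30-min span of stage-N3 sleep), turning-over detection on
the ambient channel, whole-recording detection, artifact removal, CV
extraction and stage-wise statistics. Every stage logs counts and
thresholds so a per-recording summary can be emitted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .audio_io import Hypnogram, Recording
from .denoise import DenoiseConfig, denoise_pipeline
from .features import EntropyParams, FeatureRecord, extract_all, stage_ebs_frequency
from .hos import CalibrationResult, DetectorConfig, calibrate_threshold, detect
from .intervals import IntervalSet
from .stage_stats import StatsReport, summarize
from .turnover import TurnoverConfig, detect_turnover, remove_overlapping

__all__ = ["PipelineConfig", "PipelineResult", "run_full", "pick_calibration_window"]

log = logging.getLogger(__name__)

_CV_COLUMNS = [
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


@dataclass(frozen=True)
class PipelineConfig:
    denoise: DenoiseConfig = field(default_factory=DenoiseConfig)
    detector: DetectorConfig = field(default_factory=DetectorConfig)
    turnover: TurnoverConfig = field(default_factory=TurnoverConfig)
    entropy: EntropyParams = field(default_factory=EntropyParams)
    apply_turnover_removal: bool = True


@dataclass
class PipelineResult:
    ebs: IntervalSet
    records: list[FeatureRecord]
    reports: dict[str, StatsReport]
    calibration: CalibrationResult
    turnover: IntervalSet
    epoch_rates: pd.DataFrame | None
    denoised: Recording


def pick_calibration_window(
    hyp: Hypnogram, target_min: float = 30.0
) -> tuple[float, float]:
    """Longest contiguous N3 run as (start_s, end_s); warns if shorter
    than ``target_min`` minutes."""
    best = (0, 0)
    run_start = None
    for k, lab in enumerate(list(hyp.labels) + ["w"]):
        if lab == "N3" and run_start is None:
            run_start = k
        elif lab != "N3" and run_start is not None:
            if k - run_start > best[1] - best[0]:
                best = (run_start, k)
            run_start = None
    if best[1] == best[0]:
        raise ValueError("hypnogram contains no N3 epochs")
    start_s = best[0] * hyp.epoch_length_s
    end_s = best[1] * hyp.epoch_length_s
    if (end_s - start_s) / 60.0 < target_min:
        log.warning(
            "longest N3 run is %.1f min (< %.0f min target)",
            (end_s - start_s) / 60.0,
            target_min,
        )
    return start_s, end_s


def run_full(
    rec: Recording,
    calib_labels: IntervalSet,
    calib_window: tuple[float, float],
    hyp: Hypnogram | None,
    cfg: PipelineConfig | None = None,
) -> PipelineResult:
    """Run the complete flow on one recording.

    ``calib_labels`` are in absolute recording samples; ``calib_window``
    is (start_s, end_s) of the labeled calibration span.
    """
    cfg = cfg or PipelineConfig()
    if not calib_labels:
        raise ValueError("empty calibration labels")
    w0 = int(round(calib_window[0] * rec.fs))
    w1 = int(round(calib_window[1] * rec.fs))
    if not 0 <= w0 < w1 <= rec.n_samples:
        raise ValueError("calibration window outside recording")

    den = denoise_pipeline(rec, cfg.denoise)
    log.info("denoised %d samples at %.0f Hz", den.n_samples, den.fs)

    window_labels = calib_labels.intersect(IntervalSet.from_pairs([(w0, w1)]))
    if not window_labels:
        raise ValueError("empty calibration labels")
    local_labels = IntervalSet.from_pairs((a - w0, b - w0) for a, b in window_labels)
    calibration = calibrate_threshold(
        den.bs[w0:w1], den.fs, local_labels, cfg.detector
    )
    log.info(
        "calibrated threshold %.3g (portion %.3f, accuracy %.4f)",
        calibration.threshold,
        calibration.portion,
        calibration.evaluation.accuracy,
    )

    turnover_iv = detect_turnover(den.ns, den.fs, cfg.turnover, cfg.detector)
    log.info("found %d turning-over segments", len(turnover_iv))

    ebs = detect(den.bs, den.fs, calibration.threshold, cfg.detector)
    if cfg.apply_turnover_removal:
        ebs = remove_overlapping(ebs, turnover_iv)
    log.info("detected %d events after artifact removal", len(ebs))

    records = extract_all(den, ebs, hyp, cfg.entropy)
    epoch_rates = stage_ebs_frequency(ebs, hyp, den.fs) if hyp is not None else None

    reports: dict[str, StatsReport] = {}
    if hyp is not None and records:
        frame = pd.DataFrame([r.__dict__ for r in records])
        frame = frame[frame["stage"] != "unknown"]
        for col in _CV_COLUMNS:
            groups = {
                stage: sub[col].to_numpy()
                for stage, sub in frame.groupby("stage")
                if sub[col].notna().any()
            }
            if len(groups) >= 2:
                reports[col] = summarize(groups, col)
        if epoch_rates is not None and len(epoch_rates):
            rate_groups = {
                stage: sub["rate_per_s"].to_numpy()
                for stage, sub in epoch_rates.groupby("stage")
            }
            if len(rate_groups) >= 2:
                reports["frequency"] = summarize(rate_groups, "frequency")

    return PipelineResult(
        ebs=ebs,
        records=records,
        reports=reports,
        calibration=calibration,
        turnover=turnover_iv,
        epoch_rates=epoch_rates,
        denoised=den,
    )
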
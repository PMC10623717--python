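"""Movement-artifact (turning-over) detection on the ambient channel.

Turning over in bed produces long, high-energy broadband transients that
dominate the outward-facing microphone. They are found by thresholding the
same 3-ms third-order-cumulant series used for bowel-sound detection, but
on the bandpassed NS channel with fixed, conservative rules: threshold 50
(on the recorder's amplitude scale), runs separated by at most 1 s merge,
and runs shorter than 1 s are discarded. Bowel-sound detections that
overlap a turning-over segment are dropped whole.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .hos import DetectorConfig, hos_series
from .intervals import IntervalSet

__all__ = ["TurnoverConfig", "detect_turnover", "remove_overlapping"]


@dataclass(frozen=True)
class TurnoverConfig:
    """Turning-over detection parameters.

    The absolute threshold is meaningful on the recorder's amplitude
    scale; ``relative_mode`` instead derives the threshold as a multiple
    of a high quantile of the NS cumulant series, for recordings on other
    scales.
    """

    threshold: float = 50.0
    min_len_s: float = 1.0
    merge_gap_s: float = 1.0
    relative_mode: bool = False
    relative_quantile: float = 0.999
    relative_multiple: float = 10.0

    def __post_init__(self) -> None:
        if self.threshold <= 0 or self.min_len_s <= 0 or self.merge_gap_s <= 0:
            raise ValueError("threshold, min_len_s and merge_gap_s must be positive")


def detect_turnover(
    ns: np.ndarray,
    fs: float,
    cfg: TurnoverConfig | None = None,
    detector_cfg: DetectorConfig | None = None,
) -> IntervalSet:
    """Detect turning-over segments on the (bandpassed) NS channel."""
    cfg = cfg or TurnoverConfig()
    detector_cfg = detector_cfg or DetectorConfig()
    h = hos_series(ns, fs, detector_cfg)
    thr = cfg.threshold
    if cfg.relative_mode:
        thr = cfg.relative_multiple * float(np.quantile(h.values, cfg.relative_quantile))
    active = h.values > thr
    if not active.any():
        return IntervalSet()
    mm = h.window_samples
    runs = IntervalSet.from_pairs(
        (a * mm, b * mm) for a, b in IntervalSet.from_mask(active)
    )
    gap = int(round(cfg.merge_gap_s * fs))
    min_len = int(round(cfg.min_len_s * fs))
    return runs.merge_within(gap, inclusive=True).filter_min_length(min_len)


def remove_overlapping(ebs: IntervalSet, turnover: IntervalSet) -> IntervalSet:
    """Drop every bowel-sound interval overlapping any turnover interval.

    Removal is whole-event (no trimming); intervals only touching at a
    boundary do not overlap under the half-open convention.
    """
    kept = [(a, b) for a, b in ebs if not turnover.overlaps(a, b)]
    return IntervalSet.from_pairs(kept)
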
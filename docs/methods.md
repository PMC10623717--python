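# Methods

## Problem

Bowel sounds — short acoustic transients produced by intestinal
motility — can be recorded overnight from the abdominal surface with a
two-microphone recorder: a body-facing channel (BS) and an
ambient-facing channel (NS). This package implements the full analysis
chain for such recordings: denoising, detection of *effective bowel
sounds* (EBS; events longer than 10 ms, with sub-100-ms gaps merged),
rejection of turning-over movement artifacts, extraction of ten
per-event characteristic values (CVs), and nonparametric comparison of
those CVs across sleep stages defined by a 30-s-epoch hypnogram.

## Detector

The detector exploits the non-Gaussianity of bowel-sound transients.
The denoised BS channel is split into consecutive non-overlapping
windows of `MM = round(0.003 * fs)` samples (24 samples at 8 kHz). Each
window is mean-removed and the magnitude of its zero-lag third-order
cumulant — the third central moment — forms the series `H`. Gaussian
background noise has vanishing third-order cumulants, so `H` is near
zero between events and spikes on skewed transients. The zero-lag slice
is used because multi-lag cumulant estimates are unstable in a
24-sample window; the lag structure is isolated behind one function so
a lagged variant is a local change.

Segmentation thresholds `H` using its own amplitude histogram: with 512
equal-width bins on `[0, max(H)]`, the smallest bin whose cumulative
frequency reaches a portion `p` of all windows marks the top of the
background bulk, and **twice that bin's upper edge** is the detection
threshold. The doubling is applied to the H-value at the bin edge, not
to the bin ordinal — the ordinal reading would make the threshold
depend on the measurement unit. Supra-threshold windows are assembled
into events under the annotation rules (merge gaps < 100 ms, then drop
events < 10 ms).

The portion `p` is *calibrated per recording*: on a ~30-min manually
labeled window (chosen from quiet N3 sleep in practice), `p` is swept
over 0.900–0.999 in steps of 0.001 and the threshold maximizing
energy-based accuracy is kept (ties: higher sensitivity, then smaller
portion). Performance is scored on energy, not samples: the squared
signal is partitioned into TP/FP/FN/TN energy by intersecting detected
and labeled intervals, which de-emphasizes boundary disagreements and
low-energy misses. Accuracy = (E_TP+E_TN)/ΣE, sensitivity =
E_TP/(E_TP+E_FN), specificity = E_TN/(E_FP+E_TN).

A consequence of the `[0, max(H)]` histogram is that the threshold
resolution is `max(H)/256`: events whose peak `H` falls below that
cannot be recovered at any portion. This is inherent to the method and
is why heavy-tailed recordings benefit from the artifact handling
below.

## Denoising

Three length-preserving stages, each individually switchable:

1. **Bandpass 100–1000 Hz** — 4th-order Butterworth applied
   forward–backward (zero-phase, so burst timing is preserved for
   endpoint detection). The band retains bowel-sound energy (mostly
   below 300 Hz) while removing heart sounds and rumble.
2. **NLMS adaptive noise cancellation** — a 64-tap FIR driven by the
   bandpassed NS channel estimates the ambient interference that leaks
   into the BS channel through the room/body response; the estimate is
   subtracted. Normalized step 0.001, weights initialized to zero,
   regularization ε = 1e-8 on the reference power for numerical safety
   near silence. The NS channel is bandpassed before cancellation so
   both inputs live in the same band. With step 0.001 the convergence
   time constant is on the order of 10 s; performance checks therefore
   evaluate the estimate after convergence, on noise-dominated spans.
   Known limitation: dense high-SNR bursts inject weight noise into
   weakly excited directions of the reference spectrum, which can
   depress the estimate/interference correlation on some crosstalk
   responses; the residual stays ~30× below burst amplitude and does
   not measurably affect detection.
3. **Wavelet threshold denoising** — 6-level sym6 decomposition
   (symmetric extension), soft thresholding of detail coefficients with
   level-dependent thresholds from the Birgé–Massart sparsity schedule:
   at level *j* (finest = 1) the `M/(J+2-j)^α` largest coefficients are
   kept, `M` = length of the coarsest approximation. The approximation
   band is untouched. α controls sparsity and must be mild enough that
   the per-level keep fraction exceeds the duty cycle of genuine events
   (~10–15 % of a night); α = 1.5 satisfies this at the event-band
   levels (250–500 Hz keep ≈ 3 %, 125–250 Hz keep ≈ 10 %) while still
   zeroing most of the fine-scale noise floor. With α = 3 the
   threshold lands inside the event coefficient distribution and
   measurably shrinks weak bursts. Thresholds are computed per 30-s
   block so that a rare high-amplitude artifact inflates them only
   inside its own block.

Stage order is fixed (bandpass → ANC → wavelet).

## Turning-over rejection

Movement artifacts are detected on the bandpassed NS channel with the
same 3-ms cumulant series and fixed rules: threshold 50 (meaningful on
the recorder's amplitude scale; a relative quantile mode exists for
other scales), runs separated by ≤ 1 s merge, runs shorter than 1 s are
dropped. Every detected event overlapping a turning-over segment is
removed whole (no trimming). Because the artifact's onset/offset ramps
sit below threshold, detected artifact boundaries can be a few tens of
ms inside the true extent; events overlapping only that fringe may
survive.

## Characteristic values

Per event: time-domain `cv` (std/mean of the *absolute* amplitudes —
the signed ratio is unstable for near-zero-mean audio), energy
`E0 = Σx²`, duration in ms, and the per-epoch event rate ("frequency",
events/s per 30-s epoch, reported as a per-stage distribution);
frequency-domain spectral centroid `FC` and band power fractions
`ER_5_300`, `ER_300_500`, `ER_500_1000` from a Hann-windowed
periodogram zero-padded to the next power of two (the Hann window keeps
a pure tone ≥ 99 % inside its band even near a band edge, which a
boxcar does not); nonlinear Katz fractal dimension
`FD = log10(L)/log10(d)` with unit abscissa spacing (`L` path length,
`d` greatest distance from the first point; the classical
n-normalized Katz form is available behind a flag) and sample entropy
(m = 2, r = 0.2 × segment SD, τ = 1; template match frequencies with
self-matches excluded; an estimate with no (m+1)-matches is reported
as missing, never as infinity). Events are assigned the stage of the
epoch containing their start sample. Degenerate segments yield flagged
(NaN) fields, never exceptions.

## Stage statistics

CVs are heavily skewed, so groups are screened with a
Lilliefors-corrected Kolmogorov–Smirnov test, compared with the
Kruskal–Wallis H test (tie-corrected, χ² p with k−1 df), and followed
up with Dunn's z-tests on the pooled tie-corrected ranks, Bonferroni
multiplied by the number of stage pairs and capped at 1 (the SPSS
"pairwise comparisons" procedure; pairwise Mann–Whitney is available
behind a flag). Summaries are median and IQR with linear-interpolation
(type-7) quantiles. Event-level CVs are pooled across events; the rate
CV enters per epoch.

## Synthetic recordings

No overnight recordings are distributed, so the `synth` module
generates seeded two-channel recordings with ground truth, emulating
the statistical structure the detector assumes:

* **Bursts**: Tukey-enveloped tones with a phase-locked second harmonic
  (`sin u + 0.5 cos 2u`), random phase, polarity and ±5 % frequency
  jitter. The harmonic gives the waveform a genuinely skewed amplitude
  distribution — real bowel-sound clicks are asymmetric pressure
  transients, and a pure sinusoid would have a near-zero third-order
  cumulant over full cycles, contradicting the detector's premise.
  Durations are log-normal (median 230 ms, clipped to 20–600 ms),
  carriers log-normal (median 180 Hz, clipped to 80–500 Hz, most mass
  below 300 Hz), burst rms 15 dB above the BS-channel background by
  default. Arrivals are Poisson, 20/min by default.
* **Ambient noise**: stationary pink (1/f) noise on the NS channel,
  mixed into the BS channel through a random 16-tap decaying FIR
  (unit-energy by default) — the interference the canceller removes.
  Independent white sensor noise (rms 0.002) on each channel.
* **Turning-over events**: Poisson (6/hour), 1–5 s broadband noise
  bursts with amplitude 6–12 on the NS channel (placing their cumulant
  magnitudes well above the fixed threshold 50 while the ambient floor
  stays orders of magnitude below) and a 0.15 bleed into the BS
  channel.
* **Stage modulation** (optional): per-epoch multipliers on rate,
  amplitude and carrier reproduce the qualitative deep-sleep pattern —
  fewer but higher-energy, lower-pitched events in N3, sparsest in REM.

All randomness derives from one seed split into independent streams for
event times, waveform parameters, ambient, sensor and turnover noise;
truth labels are the envelope supports merged under the 100-ms rule,
and the noise floor is bit-identical whatever the event draw.

What the generator does **not** emulate: migrating-motor-complex
cycling, heart sounds (removed by the bandpass anyway), non-stationary
ambient noise, recorder clipping/quantization, and inter-subject
anatomical variation. Passing tests therefore show that the chain
recovers events of the assumed statistical shape under stationary
noise — not that it handles every pathology of real overnight audio.

## Problem sizes and numerical choices

Synthetic studies use 5-min calibration windows (10 seeds) and a 30-min
independent recording for recall, 20-min recordings for artifact
coverage, 40-s runs for the canceller check and 10-min stage-modulated
recordings (50 seeds) for the stage-effect rate; these sizes give
stable estimates of each quantity while keeping a full run in minutes.
Calibration recordings are generated without turning-over events,
matching practice: labeled windows are chosen from quiet sleep, and a
movement artifact inside one would dominate the energy metric.
Intervals are 0-based half-open sample indices; seconds appear only at
I/O boundaries and convert by round-half-even. Thresholding ties break
deterministically (accuracy, then sensitivity, then smaller portion).
The all-equal-H histogram degenerates to a single occupied bin and
yields twice that value. Metrics with empty denominators are NaN with
an explicit flag, and undefined feature values are NaN, never raised.
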
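# bowelsound

Detection and sleep-stage analysis of bowel sounds in long-term
two-channel abdominal audio recordings.

Intestinal motility can be monitored non-invasively overnight by
recording bowel sounds with an abdominal microphone (BS channel) paired
with an ambient-facing microphone (NS channel). This package implements
the full chain from raw audio to stage-wise statistics, for researchers
studying gut motility during sleep:

* **Denoising** — 100–1000 Hz zero-phase bandpass, NLMS adaptive noise
  cancellation against the ambient channel (64 taps, step 0.001), and
  sym6 6-level wavelet threshold denoising with Birgé–Massart
  level-dependent thresholds.
* **Detection** — a higher-order-statistics detector: the magnitude of
  the windowed zero-lag third-order cumulant
  `H[k] = |mean((x_k - x̄_k)³)|` over 3-ms windows (`MM = 0.003·fs`
  samples) is thresholded at twice the upper edge of the smallest
  histogram bin whose cumulative frequency reaches a portion
  `p ∈ [0.900, 0.999]` of all windows; `p` is calibrated per recording
  on a labeled window by maximizing the energy-based accuracy
  `(E_TP + E_TN)/ΣE`. Detections follow the annotation rules: events
  longer than 10 ms, gaps under 100 ms merged.
* **Artifact rejection** — turning-over movements are detected on the
  NS channel (same cumulant series; threshold 50, minimum length 1 s,
  merge gap 1 s) and overlapping detections are discarded.
* **Characteristic values** — per event: coefficient of variation,
  energy E0, duration, per-epoch event rate; spectral centroid FC and
  band power ratios ER₅₋₃₀₀, ER₃₀₀₋₅₀₀, ER₅₀₀₋₁₀₀₀; Katz fractal
  dimension `log10(L)/log10(d)` and sample entropy
  `−ln(U^{m+1}/U^m)`.
* **Statistics** — Kolmogorov–Smirnov (Lilliefors) normality screen,
  Kruskal–Wallis omnibus test, Dunn pairwise post-hoc with Bonferroni
  correction, median (IQR) summaries per sleep stage (w, N1, N2, N3,
  REM).
* **Synthetic recordings** — a seeded generator produces two-channel
  recordings with ground-truth event labels, movement artifacts and a
  hypnogram, for testing and benchmarking (no clinical recordings are
  distributed).

## Worked example

```python
import bowelsound as bs

# a seeded 5-min two-channel recording with ground-truth labels
cfg = bs.SynthConfig(duration_s=300.0, seed=3, turnover_rate_per_hour=0.0)
rec, truth = bs.generate(cfg)

den = bs.denoise_pipeline(rec)                      # bandpass -> ANC -> wavelet
res = bs.calibrate_threshold(den.bs, den.fs, truth.ebs)
print(f"portion {res.portion:.3f}  threshold {res.threshold:.3g}")
print(f"accuracy {res.evaluation.accuracy:.4f}  "
      f"sensitivity {res.evaluation.sensitivity:.4f}  "
      f"specificity {res.evaluation.specificity:.4f}")

events = bs.detect(den.bs, den.fs, res.threshold)
print(f"{len(events)} events detected")
```

Output:

```
portion 0.900  threshold 4.01e-06
accuracy 0.9788  sensitivity 0.9788  specificity 1.0000
87 events detected
```

The calibration swept the histogram portion over 0.900–0.999 and kept
the threshold with the highest energy-based accuracy: 97.9 % of signal
energy is classified correctly, 97.9 % of labeled event energy is
recovered, and essentially no background energy is flagged. The 87
detections (matching the 87 truth labels here; the residual energy
error comes from boundary samples) can then be passed to
`bs.extract_all` for the ten characteristic values and
`bs.summarize` for stage-wise statistics, or the whole chain can be run
with `bs.run_full`.

A command-line interface mirrors the library:

```bash
bowelsound synth --duration-s 300 --seed 3 --out-prefix rec
bowelsound calibrate rec_bs.wav rec_ebs.tsv --ns-wav rec_ns.wav --out-json thr.json
bowelsound detect rec_bs.wav thr.json --ns-wav rec_ns.wav --turnover --out-tsv det.tsv
bowelsound features rec_bs.wav det.tsv --hypnogram-tsv rec_hypnogram.tsv --out-csv cvs.csv
bowelsound stats cvs.csv --out-prefix report
```

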
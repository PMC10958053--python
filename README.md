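# fiberphot

Analysis of fiber-photometry recordings and behavioral time series:
isosbestic motion/bleaching correction and ΔF/F, robust calcium-transient
detection, peri-event z-score statistics with bootstrap significance
bands and cluster-duration permutation tests, lick-burst microstructure,
and spike-burst metrics — plus a synthetic session generator with full
ground truth so every stage is testable without animal data.

It is aimed at researchers quantifying bulk calcium dynamics of
genetically defined neuron populations (for instance D1- vs
D2-receptor-expressing striatal neurons) around behavioral events such
as cue onsets, feeding bouts, or wheel-running bouts.

## The method

A recording has a calcium-dependent channel (460/470 nm excitation) and
a calcium-independent isosbestic channel (405 nm) sharing motion and
bleaching artifacts.  Both are downsampled to the analysis rate (10 Hz)
by bin means; the isosbestic channel is scaled onto the signal channel
by least squares, and

ΔF/F = (F₄₆₀ − F̂₄₀₅) / F̂₄₀₅,  with F̂₄₀₅ = a·F₄₀₅ + b.

Calcium transients are peaks of the 0.1–2 Hz zero-phase Butterworth
band-passed ΔF/F exceeding median + 2·MAD, with prominence ≥ 1 MAD and
≥ 0.1 s spacing.  Around each behavioral event the trace is z-scored
per trial against an event-specific pre-event baseline,

z(t) = (ΔF/F(t) − μ_baseline) / σ_baseline,

and summarized per trial by AUC (trapezoid), mean z, peak z, and
transient rate.  Significance of a population response uses a trial
bootstrap (2000 resamples, 95% CI from the 2.5/97.5 percentiles,
expanded by √(n/(n−1)) against percentile-interval narrowness bias)
with intervals reported only where the CI excludes 0 for ≥ 1 s; group
comparisons use per-timepoint permutation tests (2000 partitions,
two-sided add-one p) under the same ≥ 1 s rule.  Lick bursts are runs
of interlick intervals < 250 ms; spike bursts open at an interspike
interval < 80 ms and close at ≥ 160 ms.

See `docs/methods.md` for assumptions, defaults, numerical conventions,
and known limitations.

## Worked example

```python
import numpy as np
import fiberphot as fp

# simulate a 10.5-min session: 12 feeding bouts, evoked response 0.4 dF/F
sched = tuple(("feeding", 60.0 + 45.0 * i) for i in range(12))
cfg = fp.SimConfig(duration_s=630.0, seed=42, event_schedule=sched,
                   evoked_amp={"feeding": 0.4})
rec, truth = fp.simulate_photometry(cfg)

corr = fp.correct_recording(rec, analysis_rate_hz=10.0)
print(f"slope={corr.slope:.3f} intercept={corr.intercept:.3f}")

ts = fp.detect_transients(fp.bandpass_filter(corr.dff))
print(f"{ts.n} transients, threshold={ts.threshold:.4f}")

ev = fp.EventSeries(np.array([t for _, t in sched]),
                    tuple(l for l, _ in sched))
pem = fp.extract_perievent(corr.dff, ev, "feeding", (-10.0, 10.0))
band = fp.bootstrap_band(pem, seed=1)
print("significant:", [(round(a, 1), round(b, 1))
                       for a, b in band.significant_intervals])

summ = fp.summarize_trials(pem, ts, windows=[(0.0, 2.0)])
print(summ[["auc", "mean_z", "peak_z", "transient_rate_hz"]].mean().round(2))
```

prints

```
slope=1.959 intercept=3.980
98 transients, threshold=0.0150
significant: [(0.0, 5.6)]
auc                  72.37
mean_z               35.21
peak_z               58.66
transient_rate_hz     0.50
dtype: float64
```

The fitted slope ≈ 2 recovers the simulated channel-gain ratio; the 98
detected transients match the ~0.2 Hz spontaneous rate plus the 12
evoked responses; the bootstrap band flags one sustained post-event
interval (0–5.6 s), covering the evoked kernel and its filter tail; and
the per-trial summaries over the 0–2 s window show a strong positive
response (the z-scores are large because the simulated baseline noise
is small).  `transient_rate_hz = 0.50` is the mean detected rate in
that window.

A command-line interface mirrors the library
(`fiberphot simulate|preprocess|detect|perievent|bootstrap|permtest|licks|spikes|run`),
each subcommand consuming the files the previous stage wrote; `run`
executes a YAML-configured pipeline end to end and writes a JSON
manifest with versions, seeds, parameters and input digests.

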
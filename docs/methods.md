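# Methods

`fiberphot` implements the analysis chain used to quantify bulk calcium
dynamics of genetically defined neuron populations (e.g. D1- vs
D2-receptor-expressing striatal neurons) recorded by fiber photometry
during behavior, together with lickometer and spike-train burst
metrics.  This note documents the models, the defaults and why they
were chosen, the numerical conventions, and what the synthetic-data
tests do and do not establish about real recordings.

## Signal model and isosbestic correction

A two-channel recording consists of a calcium-dependent channel
(460/470 nm excitation of GCaMP) and a calcium-independent isosbestic
channel (405 nm).  Both carry photobleaching and movement artifacts;
only the first carries calcium signal.  The correction assumes the
artifact parts of the two channels are affinely related:

1. both channels are downsampled to the analysis rate (default 10 Hz)
   by non-overlapping bin means with bin-center timestamps;
2. the isosbestic channel is scaled onto the calcium channel by
   ordinary least squares (one affine fit per session);
3. ΔF = signal − scaled isosbestic, and ΔF/F = ΔF / scaled isosbestic.

Bin-mean resampling was chosen over decimation or anti-aliased filtering
because it is deterministic and exactly checkable against a closed-form
oracle, and it is adequate at the large rate ratios involved (kHz-range
acquisition to 10 Hz analysis).  The source rate must be an integer
multiple of the target rate; non-uniform timestamps beyond a 1e-6
relative tolerance are a hard error, never silently interpolated.

Two quantitative properties of the OLS step worth knowing:

- **Attenuation bias.**  Noise in the isosbestic regressor biases the
  slope low (classic errors-in-variables), leaving a residual motion
  fraction ≈ σ²_noise,iso / (g²·σ²_motion) in ΔF/F, where g is the
  isosbestic motion gain.  With realistic gains this residue is a few
  percent of the artifact; it vanishes as the reference channel gets
  cleaner or the artifact larger.
- **Mean-signal absorption.**  A session-wide fit absorbs the session
  mean of the calcium component into the intercept, deflating ΔF/F by
  ≈ 1/(1 + mean ΔF/F).  For sparse events (e.g. 45 s inter-trial
  intervals) this is a ~2% effect; dense stimulation schedules inflate
  it.  Per-trial regression would avoid this but is out of scope; the
  session-wide fit matches the single scaling the analysis describes.

## Transient detection

ΔF/F is band-pass filtered with a 4th-order Butterworth (0.1–2 Hz
default) applied forward-backward (zero phase), so detected peak times
are not phase-shifted; edges are reflect-padded to suppress startup
transients.  Peaks are local maxima strictly above ``median + 2·MAD``
with prominence ≥ 1 MAD and pairwise spacing ≥ 0.1 s.  The MAD is the
raw median absolute deviation with **no** 1.4826 normal-consistency
factor (MATLAB ``mad(x,1)`` convention).  Threshold and MAD are
computed over the full analyzed segment, not per trial.

When two candidates violate the spacing rule the taller is kept; on
exact height ties the earlier.  (``scipy.signal.find_peaks`` orders
equal-height ties the other way, so the pruning is implemented
directly.)

Note that on a pure-noise trace the unscaled-MAD threshold sits at only
≈ 2.3σ, so the detector relies on genuine transients inflating the MAD;
precision degrades gracefully as transient amplitude approaches the
filtered noise floor (roughly below ~10× the filtered noise SD for the
default kernel).

The zero-phase band-pass shifts the apparent peak of a
rise-0.2 s/decay-1.0 s transient from +0.40 s (raw kernel) to ≈ +0.35 s
after the event; ground-truth matching in the tests measures this
offset on a clean pulse rather than assuming the raw kernel peak.

## Peri-event analysis

Trace segments around behavioral events are z-scored per trial against
a pre-event baseline: z = (ΔF/F − mean(baseline)) / SD(baseline).  The
SD uses the sample convention (n−1), configurable.  Baseline presets:
(−40, −30) s for room-entrance and feeding/running-period alignments,
(−8, −5) s for within-session feeding / stop-running / locked-wheel
events, (−2, −0.5) s for cue (CS) and lick alignments.  Baselines are
per trial, never pooled; trials whose window exceeds the trace are
dropped (counted in the output), trials with zero baseline SD are
excluded (counted), and a run fails only when no trial survives.
Overlapping trials are allowed and treated independently.

Per-trial summaries over analysis windows: AUC (trapezoid over seconds
by default; a plain sample-sum variant is also exposed since both
definitions are in circulation), mean z, peak (max) z, and the
calcium-transient rate over the trial's absolute window.  Sample
selection for AUC/mean/peak uses the closed interval [start, end] so
the trapezoid spans the full window duration (a constant z = 1 over a
2 s window integrates to exactly 2 z·s); event and transient *counting*
uses half-open [start, end) windows, as everywhere else in the package.

## Bootstrap bands and permutation tests

**Single group.**  Trials are resampled with replacement (default 2000
resamples) and a pointwise 95% CI is taken from the 2.5/97.5
percentiles of the bootstrap distribution of the mean.  Percentile
intervals are too narrow at small n, so both bounds are expanded about
the observed mean by √(n/(n−1)), where n is the trial count (events are
the resampling unit throughout; animal-level resampling is not
implemented).  Timepoints where the expanded CI excludes 0 for at least
1 s continuously are reported as significant intervals.

**Two groups.**  Per timepoint, the observed statistic is the
difference of group means; the null comes from random re-partitions of
the pooled trials into the original group sizes (default 2000), with
the Monte-Carlo add-one p-value p = (1 + #{|stat*| ≥ |stat|})/(n+1), so
p = 0 is unattainable.  Significance again requires p < α (0.05) for
≥ 1 s.  No other multiple-comparison correction is applied; the
duration criterion is the only cluster-level control.  Under the
spec'd null simulations the family-wise rate of reported intervals is
effectively zero at 10 Hz, because ten consecutive sub-α p-values are
vanishingly unlikely for exchangeable timepoints.

The duration rule reports maximal runs of k ≥ ceil(min_duration·rate)
samples as intervals of length k/rate; a 0.5 s run at 10 Hz is never
reported, a 1.0 s run always is.

## Synthetic sessions

The generator produces the two-channel model

    F_sig(t) = B_s(t)·(1 + dff(t)) + M(t) + ε_s(t)
    F_iso(t) = B_i(t) + g·M(t) + ε_i(t)

with per-channel exponential bleaching toward an asymptote B_c(t), a
shared Ornstein–Uhlenbeck motion artifact M(t) (exact discretization),
independent Gaussian noise, and a calcium component dff(t) built from a
difference-of-exponentials kernel normalized to unit peak (analytically
integrable, so oracles have closed forms).  Spontaneous transients are
a Poisson process thinned to a minimum separation (default 1 s): bulk
transients closer than the kernel width are not resolvable as distinct
peaks by any single-peak detector, so scoring detection against
un-thinned ground truth would conflate generator ambiguity with
detector error.  Event-locked responses add signed per-label amplitudes
at scheduled times.

Defaults: 180 s sessions at 100 Hz acquisition (an integer multiple of
the 10 Hz analysis rate; simulating at the hardware's kHz rates adds
cost without changing any tested property), baselines (100, 50)
fluorescence units, bleach amplitude 0.1 with τ = 120 s, motion SD 2
units with τ = 1 s, noise SD 0.5 units, spontaneous rate 0.2 Hz,
kernel rise 0.2 s / decay 1.0 s, transient amplitude 0.05 ΔF/F.  The
default isosbestic motion gain is the baseline ratio, which makes the
two channels' artifact parts exactly affinely related — the regime the
correction assumes; setting it independently degrades the correction
realistically.  At the default noise level the filtered transient SNR
is ≈ 17×, where detection is near-perfect; doubling the noise (≈ 8×)
already costs measurable precision (see above).

Lick trains are generated as bursts with within-burst intervals drawn
strictly below the 250 ms criterion and gaps strictly above it, so
segmentation recovers the drawn structure exactly.  Spike trains
superpose tonic Poisson firing with Poisson-rate burst episodes of
fixed intra-burst ISI (< 80 ms).

What the generator does **not** emulate: hemodynamic artifacts,
multi-fiber or spectral crosstalk, lock-in/modulated-carrier
acquisition, non-exponential (e.g. biphasic) bleaching, sensor
nonlinearity and saturation, and animal-to-animal variability (all
trials in a session are statistically exchangeable).  Passing tests
therefore establish correctness of the *analysis* under the stated
model, not robustness to every artifact of real recordings.

## Behavioral metrics

Lick bursts are maximal runs whose consecutive interlick intervals are
all strictly below 250 ms; a burst needs ≥ 2 licks (an isolated lick is
not a sequence; the minimum is configurable).  An interval exactly at
the threshold separates bursts.  Readouts: total licks, burst count,
licks per burst.

Spike bursts follow the classical dopamine-neuron convention: a burst
opens at the first of two spikes with ISI < 80 ms and extends while
ISIs stay < 160 ms.  The 160 ms offset is a deliberate design choice:
the onset rule alone does not define burst termination, and the
80/160 ms onset/offset pair is the standard convention in the VTA
literature.  Epoch metrics (defaults: 200 s epochs) are firing rate,
bursting rate, and mean spikes per burst (absent when no burst exists).
Counting spontaneously active cells per electrode track is a per-session
tally supplied by the experimenter, not an algorithm, and is not
modeled.

## Numerical conventions and degenerate inputs

- Time in seconds, t = 0 at recording start; windows half-open
  [start, end) except summary-window sample selection (closed, above).
- Sample SD (ddof = 1) for baselines; raw MAD for thresholds.
- All stochastic procedures draw from one `numpy` Generator per call,
  seeded explicitly; identical (config, seed) pairs are bit-identical.
  No global RNG state is touched.
- Degenerate inputs fail loudly: constant isosbestic regressor,
  non-positive scaled reference (ΔF/F undefined), zero-SD baselines
  (per-trial exclusion, error when all trials are excluded), empty
  masks, zero-duration windows, Nyquist-violating cutoffs, unsorted
  timestamp trains, non-uniform time axes.

## Problem sizes in the test suite

The property simulations use 300–900 s single-fiber sessions at 100 Hz,
500 replicate bootstrap-coverage simulations (n = 20 trials, 2000
resamples), 200 null permutation simulations (500 partitions), and 1000
random trains per burst-segmentation oracle check — sizes at which the
Monte-Carlo error of each estimate is several times smaller than the
margin to its acceptance bound, while the whole suite runs in well
under a minute on one core.
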
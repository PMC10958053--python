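"""Peri-event alignment, baseline z-scoring, and per-trial summaries.

Trace segments around behavioral events are z-scored against an
event-specific pre-event baseline:

    z[t] = (dff[t] - mean(baseline)) / sd(baseline)

with the mean and SD computed per trial over the baseline window.  The
SD uses the sample convention (n-1 denominator) by default; this is
configurable.  Standard baseline presets: (-40, -30) s for room-entrance
and feeding/running-period alignments, (-8, -5) s for within-session
feeding / stop-running / locked-wheel events, and (-2, -0.5) s for cue
(CS) and lick alignments in the conditioning paradigm.

Per-trial summaries over analysis windows are the area under the curve
(trapezoid over seconds, or a plain sample sum), the average z-score,
the peak z-score, and the calcium-transient rate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import AnalysisError, ValidationError
from .signals import PhotometryTrace
from .transients import TransientSet

logger = logging.getLogger(__name__)

#: baseline windows (seconds relative to the event) per event class
BASELINE_PRESETS: dict[str, tuple[float, float]] = {
    "feeding_room_entrance": (-40.0, -30.0),
    "feeding_period": (-40.0, -30.0),
    "running_room_entrance": (-40.0, -30.0),
    "running_period": (-40.0, -30.0),
    "feeding": (-8.0, -5.0),
    "stop_running": (-8.0, -5.0),
    "locked_wheel": (-8.0, -5.0),
    "CS": (-2.0, -0.5),
    "lick": (-2.0, -0.5),
}


@dataclass(frozen=True)
class EventSeries:
    """Labeled behavioral event timestamps."""

    times_s: np.ndarray
    labels: tuple

    def __post_init__(self):
        t = np.asarray(self.times_s, dtype=float)
        object.__setattr__(self, "times_s", t)
        object.__setattr__(self, "labels", tuple(str(x) for x in self.labels))
        if t.size != len(self.labels):
            raise ValidationError("times_s and labels must have equal length")
        if np.any(np.diff(t) < 0):
            raise ValidationError("event times must be sorted")

    def select(self, label: str) -> np.ndarray:
        """Times of all events carrying ``label``."""
        mask = np.array([lb == label for lb in self.labels], dtype=bool)
        return self.times_s[mask]

    @property
    def vocabulary(self) -> tuple:
        return tuple(sorted(set(self.labels)))


@dataclass(frozen=True)
class PeriEventMatrix:
    """Trials x timepoints z-scored responses around one event class.

    ``dff`` retains the un-normalized aligned segments; ``event_times_s``
    maps rows back to absolute session time (needed to count transients
    per trial).  ``n_dropped`` counts events whose window fell outside
    the trace, ``n_excluded`` trials removed for a zero-SD baseline.
    """

    z: np.ndarray
    rel_time_s: np.ndarray
    n_trials: int
    baseline_window: tuple[float, float]
    event_label: str
    rate_hz: float
    event_times_s: np.ndarray
    dff: np.ndarray | None = None
    n_dropped: int = 0
    n_excluded: int = 0
    sd_ddof: int = 1

    def __post_init__(self):
        if self.z.ndim != 2:
            raise ValidationError("z must be trials x timepoints")
        if self.z.shape != (self.n_trials, self.rel_time_s.size):
            raise ValidationError("z shape inconsistent with n_trials/rel_time_s")
        if self.n_trials < 1:
            raise ValidationError("peri-event matrix needs at least one trial")
        if not self.baseline_window[0] < self.baseline_window[1] <= 0:
            raise ValidationError("baseline window must strictly precede the event")

    def baseline_mask(self) -> np.ndarray:
        b0, b1 = self.baseline_window
        return (self.rel_time_s >= b0) & (self.rel_time_s < b1)


def extract_perievent(
    trace: PhotometryTrace,
    events: EventSeries,
    label: str,
    window: tuple[float, float],
    baseline: tuple[float, float] | None = None,
    sd_ddof: int = 1,
    keep_dff: bool = True,
) -> PeriEventMatrix:
    """Align a trace to all events of one class and z-score per trial.

    ``window`` is (pre_s, post_s) in seconds relative to the event
    (pre_s negative); samples with pre_s <= t_rel < post_s are taken.
    ``baseline`` defaults to the preset for ``label`` and must lie
    within the window and strictly before the event.  Trials whose
    window exceeds the trace bounds are dropped (counted); trials whose
    baseline SD is zero are excluded (counted).  All trials excluded is
    an error.
    """
    pre_s, post_s = window
    if not pre_s < post_s:
        raise AnalysisError("window must satisfy pre_s < post_s")
    if baseline is None:
        try:
            baseline = BASELINE_PRESETS[label]
        except KeyError:
            raise AnalysisError(
                f"no baseline preset for event label {label!r}; pass one explicitly"
            ) from None
    b0, b1 = baseline
    if not (b0 < b1 <= 0):
        raise AnalysisError("baseline must satisfy b0 < b1 <= 0")
    if b0 < pre_s:
        raise AnalysisError("baseline window must lie within the extraction window")

    rate = trace.rate_hz
    dt = 1.0 / rate
    k_pre = int(round(pre_s * rate))
    k_post = int(round(post_s * rate))
    rel_time = np.arange(k_pre, k_post) * dt
    if rel_time.size < 2:
        raise AnalysisError("window covers fewer than two samples")

    t0 = trace.time_s[0]
    n = len(trace)
    ev_times = events.select(label)
    if ev_times.size == 0:
        raise AnalysisError(f"no events with label {label!r}")

    rows, kept_times = [], []
    n_dropped = 0
    for te in ev_times:
        ie = int(round((te - t0) * rate))
        i0, i1 = ie + k_pre, ie + k_post
        if i0 < 0 or i1 > n:
            n_dropped += 1
            continue
        rows.append(trace.values[i0:i1])
        kept_times.append(te)
    if not rows:
        raise AnalysisError(
            f"all {ev_times.size} events of label {label!r} fall outside the trace"
        )
    if n_dropped:
        logger.warning("dropped %d/%d %r trials with incomplete window coverage",
                       n_dropped, ev_times.size, label)

    seg = np.asarray(rows)
    bmask = (rel_time >= b0) & (rel_time < b1)
    if np.count_nonzero(bmask) < 2:
        raise AnalysisError("baseline window covers fewer than two samples")
    bmean = seg[:, bmask].mean(axis=1)
    bsd = seg[:, bmask].std(axis=1, ddof=sd_ddof)

    ok = bsd > 0
    n_excluded = int(np.count_nonzero(~ok))
    if n_excluded:
        logger.warning("excluded %d %r trials with zero baseline SD", n_excluded, label)
    if not np.any(ok):
        raise AnalysisError(
            f"all trials of label {label!r} have zero baseline SD; cannot z-score"
        )
    seg = seg[ok]
    z = (seg - bmean[ok, None]) / bsd[ok, None]

    return PeriEventMatrix(
        z=z,
        rel_time_s=rel_time,
        n_trials=z.shape[0],
        baseline_window=(b0, b1),
        event_label=label,
        rate_hz=rate,
        event_times_s=np.asarray(kept_times)[ok],
        dff=seg if keep_dff else None,
        n_dropped=n_dropped,
        n_excluded=n_excluded,
        sd_ddof=sd_ddof,
    )


def summarize_trials(
    pem: PeriEventMatrix,
    transients: TransientSet | None = None,
    windows: list[tuple[float, float]] = ((0.0, 2.0),),
    auc_method: str = "trapezoid",
) -> pd.DataFrame:
    """Per-trial summaries over one or more analysis windows.

    For every trial and window returns the AUC, the mean z, the peak
    (max) z, and, when a :class:`TransientSet` is supplied, the
    transient rate over the trial's absolute window.  Sample selection
    for AUC/mean/peak is over the closed interval [start, end] so the
    trapezoid spans the full window duration; transient counting uses
    the half-open convention of :func:`transient_rate`.

    ``auc_method``: ``"trapezoid"`` integrates z over seconds (z*s);
    ``"sum"`` is the plain sum of the z samples in the window.
    """
    if auc_method not in ("trapezoid", "sum"):
        raise AnalysisError("auc_method must be 'trapezoid' or 'sum'")
    rel = pem.rel_time_s
    eps = 0.5 / pem.rate_hz
    records = []
    for w0, w1 in windows:
        if w1 <= w0:
            raise AnalysisError("summary window must have positive duration")
        if w0 < rel[0] - eps or w1 > rel[-1] + eps:
            raise AnalysisError(
                f"summary window ({w0}, {w1}) outside matrix span "
                f"({rel[0]:.3g}, {rel[-1]:.3g})"
            )
        mask = (rel >= w0 - 1e-9) & (rel <= w1 + 1e-9)
        x = rel[mask]
        for i in range(pem.n_trials):
            zi = pem.z[i, mask]
            if auc_method == "trapezoid":
                auc = float(np.trapezoid(zi, x))
            else:
                auc = float(zi.sum())
            rec = {
                "trial": i,
                "event_time_s": float(pem.event_times_s[i]),
                "window_start_s": w0,
                "window_end_s": w1,
                "auc": auc,
                "mean_z": float(zi.mean()),
                "peak_z": float(zi.max()),
            }
            if transients is not None:
                te = pem.event_times_s[i]
                rec["transient_rate_hz"] = transients.rate_in(te + w0, te + w1)
            records.append(rec)
    return pd.DataFrame.from_records(records)
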
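"""Lick-microstructure and spike-train burst metrics.

Lick bursts: maximal runs of licks whose consecutive interlick intervals
are all strictly below 250 ms; a burst needs at least 2 licks.  The
readouts are total licks, number of bursts, and licks per burst (a
standard hedonic-reactivity proxy).

Spike bursts (dopamine-neuron convention): a burst opens when two spikes
occur with an interspike interval strictly below 80 ms and extends while
subsequent ISIs stay below the offset criterion (default 160 ms).  Rate
metrics (basal firing rate, bursting rate, mean spikes per burst) are
computed over epochs, conventionally 200 s.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import AnalysisError

DEFAULT_ILI_THRESHOLD_S = 0.25
DEFAULT_ONSET_ISI_S = 0.08
DEFAULT_OFFSET_ISI_S = 0.16
DEFAULT_EPOCH_S = 200.0


def _check_sorted(t: np.ndarray, name: str) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if t.ndim != 1:
        raise AnalysisError(f"{name} must be one-dimensional")
    if np.any(np.diff(t) < 0):
        raise AnalysisError(f"{name} timestamps must be sorted")
    return t


@dataclass(frozen=True)
class BurstSet:
    """Segmentation of a timestamp train into bursts.

    ``burst_bounds`` holds (first_event_time, last_event_time) per burst;
    ``burst_slices`` the corresponding (start, stop) index ranges into
    the input train.
    """

    burst_bounds: tuple
    burst_sizes: np.ndarray
    n_events_total: int
    ili_threshold_s: float
    burst_slices: tuple = ()

    @property
    def n_bursts(self) -> int:
        return len(self.burst_bounds)

    @property
    def n_events_in_bursts(self) -> int:
        return int(self.burst_sizes.sum()) if self.burst_sizes.size else 0

    @property
    def mean_size(self) -> float | None:
        if self.n_bursts == 0:
            return None
        return float(self.burst_sizes.mean())


@dataclass(frozen=True)
class SpikeBurstStats:
    """Epoch firing metrics for one spike train."""

    firing_rate_hz: float
    bursting_rate_hz: float
    mean_spikes_per_burst: float | None
    n_spikes: int
    n_bursts: int
    epoch: tuple[float, float]
    onset_isi_s: float = DEFAULT_ONSET_ISI_S
    offset_isi_s: float = DEFAULT_OFFSET_ISI_S


def segment_lick_bursts(
    licks,
    ili_threshold_s: float = DEFAULT_ILI_THRESHOLD_S,
    min_burst_size: int = 2,
) -> BurstSet:
    """Segment a lick train into high-frequency bursts.

    Maximal runs in which every consecutive interlick interval is
    strictly below ``ili_threshold_s``; runs shorter than
    ``min_burst_size`` licks are not bursts.  An interval exactly equal
    to the threshold separates bursts.
    """
    t = _check_sorted(licks, "lick")
    if min_burst_size < 1:
        raise AnalysisError("min_burst_size must be >= 1")
    bounds, sizes, slices = [], [], []
    i = 0
    n = t.size
    while i < n:
        j = i
        while j + 1 < n and t[j + 1] - t[j] < ili_threshold_s:
            j += 1
        size = j - i + 1
        if size >= min_burst_size:
            bounds.append((float(t[i]), float(t[j])))
            sizes.append(size)
            slices.append((i, j + 1))
        i = j + 1
    return BurstSet(
        burst_bounds=tuple(bounds),
        burst_sizes=np.asarray(sizes, dtype=int),
        n_events_total=n,
        ili_threshold_s=ili_threshold_s,
        burst_slices=tuple(slices),
    )


def segment_spike_bursts(
    spikes,
    onset_isi_s: float = DEFAULT_ONSET_ISI_S,
    offset_isi_s: float = DEFAULT_OFFSET_ISI_S,
) -> BurstSet:
    """Segment a spike train into bursts.

    A burst opens at the first of two spikes with ISI < ``onset_isi_s``
    and extends while following ISIs are < ``offset_isi_s``; it closes
    at the first ISI >= ``offset_isi_s``.  Every burst has >= 2 spikes.
    """
    t = _check_sorted(spikes, "spike")
    if not onset_isi_s <= offset_isi_s:
        raise AnalysisError("offset_isi_s must be >= onset_isi_s")
    bounds, sizes, slices = [], [], []
    i = 0
    n = t.size
    while i < n - 1:
        if t[i + 1] - t[i] < onset_isi_s:
            j = i + 1
            while j + 1 < n and t[j + 1] - t[j] < offset_isi_s:
                j += 1
            bounds.append((float(t[i]), float(t[j])))
            sizes.append(j - i + 1)
            slices.append((i, j + 1))
            i = j + 1
        else:
            i += 1
    return BurstSet(
        burst_bounds=tuple(bounds),
        burst_sizes=np.asarray(sizes, dtype=int),
        n_events_total=n,
        ili_threshold_s=onset_isi_s,
        burst_slices=tuple(slices),
    )


def epoch_firing_metrics(
    spikes,
    epoch: tuple[float, float],
    onset_isi_s: float = DEFAULT_ONSET_ISI_S,
    offset_isi_s: float = DEFAULT_OFFSET_ISI_S,
) -> SpikeBurstStats:
    """Firing rate, bursting rate and mean spikes/burst over an epoch.

    The epoch window is half-open [start_s, end_s).  With no bursts the
    mean spikes per burst is reported as absent (None).
    """
    start_s, end_s = epoch
    if end_s <= start_s:
        raise AnalysisError("epoch must have positive duration")
    t = _check_sorted(spikes, "spike")
    dur = end_s - start_s
    in_epoch = t[(t >= start_s) & (t < end_s)]
    bursts = segment_spike_bursts(in_epoch, onset_isi_s, offset_isi_s)
    return SpikeBurstStats(
        firing_rate_hz=in_epoch.size / dur,
        bursting_rate_hz=bursts.n_bursts / dur,
        mean_spikes_per_burst=bursts.mean_size,
        n_spikes=int(in_epoch.size),
        n_bursts=bursts.n_bursts,
        epoch=(start_s, end_s),
        onset_isi_s=onset_isi_s,
        offset_isi_s=offset_isi_s,
    )
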
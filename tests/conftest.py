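"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately re-derive results from first principles
(exhaustive grouping, explicit normal equations, argmax scans) so they
stay independent of the library code paths they check.
"""

import numpy as np
import pytest

from fiberphot.perievent import PeriEventMatrix
from fiberphot.signals import PhotometryTrace


def make_trace(values, rate_hz=10.0, kind="dff", t0=0.0):
    values = np.asarray(values, dtype=float)
    t = t0 + np.arange(values.size) / rate_hz
    return PhotometryTrace(t, values, rate_hz, kind=kind)


def make_pem(z, rate_hz=10.0, rel_start=-2.0, baseline=(-2.0, -1.0)):
    z = np.asarray(z, dtype=float)
    n, T = z.shape
    rel = rel_start + np.arange(T) / rate_hz
    return PeriEventMatrix(
        z=z, rel_time_s=rel, n_trials=n, baseline_window=baseline,
        event_label="ev", rate_hz=rate_hz,
        event_times_s=100.0 + 50.0 * np.arange(n),
    )


# ---------------------------------------------------------------- oracles

def oracle_group_bursts(times, gap_threshold, min_size):
    """Brute-force segmentation: split wherever the gap is >= threshold."""
    times = np.asarray(times, dtype=float)
    groups, cur = [], []
    for t in times:
        if cur and t - cur[-1] >= gap_threshold:
            groups.append(cur)
            cur = []
        cur.append(t)
    if cur:
        groups.append(cur)
    return [g for g in groups if len(g) >= min_size]


def oracle_spike_bursts(times, onset, offset):
    """Brute-force spike-burst rule: open on ISI<onset, extend while ISI<offset."""
    times = list(np.asarray(times, dtype=float))
    bursts, i = [], 0
    while i < len(times) - 1:
        if times[i + 1] - times[i] < onset:
            burst = [times[i], times[i + 1]]
            j = i + 1
            while j + 1 < len(times) and times[j + 1] - times[j] < offset:
                burst.append(times[j + 1])
                j += 1
            bursts.append(burst)
            i = j + 1
        else:
            i += 1
    return bursts


def oracle_normal_equations(x, y):
    """Affine least squares from the explicit 2x2 normal equations."""
    n = x.size
    sx, sy, sxx, sxy = x.sum(), y.sum(), (x * x).sum(), (x * y).sum()
    det = n * sxx - sx * sx
    slope = (n * sxy - sx * sy) / det
    intercept = (sy * sxx - sx * sxy) / det
    return slope, intercept


def oracle_min_distance_peaks(times, heights, min_distance_s):
    """Exhaustive min-distance pruning: tallest first, earlier on ties."""
    order = sorted(range(len(times)), key=lambda i: (-heights[i], times[i]))
    kept = []
    for i in order:
        if all(abs(times[i] - times[j]) >= min_distance_s for j in kept):
            kept.append(i)
    return sorted(kept, key=lambda i: times[i])


def oracle_runs(mask, min_samples):
    """Exhaustive scan for maximal True runs of at least min_samples."""
    runs, i = [], 0
    n = len(mask)
    while i < n:
        if mask[i]:
            j = i
            while j + 1 < n and mask[j + 1]:
                j += 1
            if j - i + 1 >= min_samples:
                runs.append((i, j - i + 1))
            i = j + 1
        else:
            i += 1
    return runs


@pytest.fixture
def rng():
    return np.random.default_rng(20240321)
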
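"""Bootstrap significance bands and two-group permutation tests.

Single-group inference: trials are resampled with replacement (default
2000 resamples); a pointwise 95% CI is taken from the 2.5/97.5
percentiles of the bootstrap distribution of the mean and expanded about
the observed mean by sqrt(n/(n-1)) to correct the narrowness bias of
the percentile bootstrap at small n.  Timepoints where the expanded CI
excludes 0 (the pre-event baseline) for at least 1 s continuously are
reported as significant intervals.

Two-group inference: per-timepoint difference of group means against a
null built from random re-partitions of the pooled trials (default
2000), with the Monte-Carlo add-one p-value; the same >= 1 s duration
criterion gates reported intervals.  No other multiple-comparison
correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import AnalysisError
from .perievent import PeriEventMatrix

DEFAULT_N_BOOT = 2000
DEFAULT_N_PERM = 2000
DEFAULT_LEVEL = 0.95
DEFAULT_ALPHA = 0.05
DEFAULT_MIN_DURATION_S = 1.0


def narrowness_expansion(n: int) -> float:
    """CI expansion factor sqrt(n/(n-1)) for n resampled trials."""
    if n < 2:
        raise AnalysisError("expansion factor requires n >= 2")
    return float(np.sqrt(n / (n - 1)))


def find_significant_runs(
    mask: np.ndarray,
    rate_hz: float,
    min_duration_s: float = DEFAULT_MIN_DURATION_S,
    times: np.ndarray | None = None,
) -> list[tuple[float, float]]:
    """Maximal runs of True lasting at least ``min_duration_s``.

    A run of k samples at ``rate_hz`` lasts k/rate_hz seconds and is
    reported when k >= ceil(min_duration_s * rate_hz).  Intervals are
    returned as (start_s, end_s) with end = start + k/rate_hz; ``times``
    supplies the start coordinates (defaults to index/rate).
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.size == 0:
        raise AnalysisError("empty mask")
    if rate_hz <= 0:
        raise AnalysisError("rate_hz must be positive")
    min_samples = int(np.ceil(min_duration_s * rate_hz - 1e-9))
    dt = 1.0 / rate_hz
    if times is None:
        times = np.arange(mask.size) * dt

    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    starts, ends = edges[::2], edges[1::2]
    out = []
    for i0, i1 in zip(starts, ends):
        k = i1 - i0
        if k >= min_samples:
            out.append((float(times[i0]), float(times[i0] + k * dt)))
    return out


@dataclass(frozen=True)
class CiBand:
    """Per-timepoint bootstrap confidence band with significance intervals."""

    rel_time_s: np.ndarray
    mean_z: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    n_trials: int
    n_boot: int
    level: float
    expansion: float
    significant_intervals: list
    min_duration_s: float
    seed: int | None = None


@dataclass(frozen=True)
class PermResult:
    """Per-timepoint permutation p-values with significance intervals."""

    rel_time_s: np.ndarray
    observed: np.ndarray
    p: np.ndarray
    n_perm: int
    alpha: float
    significant_intervals: list
    min_duration_s: float
    statistic: str = "difference of group means"
    seed: int | None = None


def bootstrap_band(
    pem: PeriEventMatrix,
    n_boot: int = DEFAULT_N_BOOT,
    level: float = DEFAULT_LEVEL,
    min_duration_s: float = DEFAULT_MIN_DURATION_S,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> CiBand:
    """Bootstrap CI band for the trial-mean response.

    Trials (rows of ``pem.z``) are the resampling unit.  Both bounds are
    expanded symmetrically about the observed mean by sqrt(n/(n-1)).
    """
    z = pem.z
    n = pem.n_trials
    if n < 2:
        raise AnalysisError("bootstrap requires at least 2 trials")
    if not np.all(np.isfinite(z)):
        raise AnalysisError("non-finite z-scores")
    if rng is None:
        rng = np.random.default_rng(seed)

    q_lo = 100 * (1 - level) / 2
    q_hi = 100 - q_lo
    boot_means = np.empty((n_boot, z.shape[1]))
    # chunked gather keeps peak memory modest on long windows
    chunk = max(1, int(2e6 // max(n * z.shape[1], 1)))
    for s in range(0, n_boot, chunk):
        e = min(s + chunk, n_boot)
        idx = rng.integers(0, n, size=(e - s, n))
        boot_means[s:e] = z[idx].mean(axis=1)
    lower, upper = np.percentile(boot_means, [q_lo, q_hi], axis=0)

    mean_z = z.mean(axis=0)
    factor = narrowness_expansion(n)
    lower = mean_z + (lower - mean_z) * factor
    upper = mean_z + (upper - mean_z) * factor

    sig_mask = (lower > 0) | (upper < 0)
    intervals = find_significant_runs(sig_mask, pem.rate_hz, min_duration_s,
                                      times=pem.rel_time_s)
    return CiBand(
        rel_time_s=pem.rel_time_s,
        mean_z=mean_z,
        lower=lower,
        upper=upper,
        n_trials=n,
        n_boot=n_boot,
        level=level,
        expansion=factor,
        significant_intervals=intervals,
        min_duration_s=min_duration_s,
        seed=seed,
    )


def permutation_test(
    a: PeriEventMatrix,
    b: PeriEventMatrix,
    n_perm: int = DEFAULT_N_PERM,
    alpha: float = DEFAULT_ALPHA,
    min_duration_s: float = DEFAULT_MIN_DURATION_S,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> PermResult:
    """Two-sided per-timepoint permutation test of mean(a) - mean(b).

    The null re-partitions the pooled trials into groups of the original
    sizes; p = (1 + #{|stat_perm| >= |stat_obs|}) / (n_perm + 1), so the
    smallest attainable p is 1/(n_perm+1).
    """
    if a.rel_time_s.shape != b.rel_time_s.shape or not np.allclose(
        a.rel_time_s, b.rel_time_s
    ):
        raise AnalysisError("peri-event matrices must share the relative time grid")
    na, nb = a.n_trials, b.n_trials
    if na < 2 or nb < 2:
        raise AnalysisError("each group needs at least 2 trials")
    if rng is None:
        rng = np.random.default_rng(seed)

    pooled = np.vstack([a.z, b.z])
    obs = a.z.mean(axis=0) - b.z.mean(axis=0)
    abs_obs = np.abs(obs)

    exceed = np.zeros(pooled.shape[1], dtype=np.int64)
    total = pooled.sum(axis=0)
    for _ in range(n_perm):
        idx = rng.permutation(na + nb)[:na]
        mean_a = pooled[idx].sum(axis=0) / na
        mean_b = (total - mean_a * na) / nb
        exceed += np.abs(mean_a - mean_b) >= abs_obs - 1e-15
    p = (1.0 + exceed) / (n_perm + 1.0)

    intervals = find_significant_runs(p < alpha, a.rate_hz, min_duration_s,
                                      times=a.rel_time_s)
    return PermResult(
        rel_time_s=a.rel_time_s,
        observed=obs,
        p=p,
        n_perm=n_perm,
        alpha=alpha,
        significant_intervals=intervals,
        min_duration_s=min_duration_s,
        seed=seed,
    )
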
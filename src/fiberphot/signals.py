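"""Core time-series containers.

Two-channel raw recordings (calcium-dependent 460/470 nm signal plus the
405 nm isosbestic reference) and single uniform-rate traces.  Both are
thin, validated wrappers over numpy arrays; all downstream operations
accept and return these.

Conventions: time is in seconds with t=0 at recording start; sampling
must be uniform (relative tolerance 1e-6 on the step); windows are
half-open ``[start, end)`` unless an operation documents otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ValidationError

#: relative tolerance on sample-interval uniformity
UNIFORMITY_RTOL = 1e-6

# trace kinds, in pipeline order
TRACE_KINDS = ("raw", "scaled_iso", "dff", "filtered")


def _as_float_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValidationError(f"{name} must be one-dimensional, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValidationError(f"{name} contains non-finite samples")
    return arr


def check_uniform(time_s: np.ndarray, rtol: float = UNIFORMITY_RTOL) -> float:
    """Validate a strictly increasing, uniformly spaced time axis.

    Returns the sampling rate in Hz.
    """
    if time_s.size < 2:
        raise ValidationError("time axis needs at least two samples")
    dt = np.diff(time_s)
    if np.any(dt <= 0):
        raise ValidationError("time axis must be strictly increasing")
    step = float(np.median(dt))
    if np.any(np.abs(dt - step) > rtol * step):
        raise ValidationError(
            f"sampling is not uniform within relative tolerance {rtol:g}"
        )
    return 1.0 / step


@dataclass(frozen=True)
class PhotometryTrace:
    """A single uniform-rate series.

    ``kind`` tags the processing stage: ``raw`` fluorescence, the
    ``scaled_iso`` fitted reference, unitless ``dff`` (ΔF/F), or the
    band-pass ``filtered`` trace used for transient detection.
    """

    time_s: np.ndarray
    values: np.ndarray
    rate_hz: float
    kind: str = "raw"

    def __post_init__(self):
        object.__setattr__(self, "time_s", _as_float_array(self.time_s, "time_s"))
        object.__setattr__(self, "values", _as_float_array(self.values, "values"))
        if self.time_s.shape != self.values.shape:
            raise ValidationError("time_s and values must have equal length")
        if self.kind not in TRACE_KINDS:
            raise ValidationError(f"unknown trace kind {self.kind!r}")
        rate = check_uniform(self.time_s)
        if not np.isclose(rate, self.rate_hz, rtol=1e-4):
            raise ValidationError(
                f"declared rate {self.rate_hz} Hz inconsistent with "
                f"time axis ({rate:.6g} Hz)"
            )
        if self.rate_hz <= 0:
            raise ValidationError("rate_hz must be positive")

    def __len__(self) -> int:
        return self.values.size

    @property
    def duration_s(self) -> float:
        return len(self) / self.rate_hz

    def with_values(self, values: np.ndarray, kind: str | None = None) -> "PhotometryTrace":
        """Return a copy on the same grid with new samples (and optionally kind)."""
        return replace(self, values=np.asarray(values, dtype=float),
                       kind=self.kind if kind is None else kind)


@dataclass(frozen=True)
class RawRecording:
    """Time-aligned two-channel fluorescence at acquisition rate.

    ``f_signal`` is the calcium-dependent channel (460/470 nm excitation),
    ``f_iso`` the calcium-independent isosbestic channel (405 nm) that
    tracks motion and bleaching artifacts only.
    """

    time_s: np.ndarray
    f_signal: np.ndarray
    f_iso: np.ndarray
    acq_rate_hz: float = field(default=0.0)

    def __post_init__(self):
        object.__setattr__(self, "time_s", _as_float_array(self.time_s, "time_s"))
        object.__setattr__(self, "f_signal", _as_float_array(self.f_signal, "f_signal"))
        object.__setattr__(self, "f_iso", _as_float_array(self.f_iso, "f_iso"))
        if not (self.time_s.shape == self.f_signal.shape == self.f_iso.shape):
            raise ValidationError("time_s, f_signal and f_iso must have equal length")
        rate = check_uniform(self.time_s)
        if self.acq_rate_hz == 0.0:
            object.__setattr__(self, "acq_rate_hz", rate)
        elif not np.isclose(rate, self.acq_rate_hz, rtol=1e-4):
            raise ValidationError(
                f"declared acquisition rate {self.acq_rate_hz} Hz inconsistent "
                f"with time axis ({rate:.6g} Hz)"
            )

    def __len__(self) -> int:
        return self.time_s.size

    def channel(self, which: str) -> PhotometryTrace:
        """Extract one channel as a raw trace (``signal`` or ``iso``)."""
        if which == "signal":
            values = self.f_signal
        elif which == "iso":
            values = self.f_iso
        else:
            raise ValueError("which must be 'signal' or 'iso'")
        return PhotometryTrace(self.time_s, values, self.acq_rate_hz, kind="raw")
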
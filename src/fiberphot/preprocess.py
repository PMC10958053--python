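"""Motion and bleaching correction of two-channel photometry.

The correction follows the standard isosbestic strategy: downsample both
channels to the analysis rate, scale the 405 nm reference onto the
calcium channel with an ordinary least-squares affine fit, subtract to
obtain ΔF, and divide by the scaled reference to obtain ΔF/F.  Because
the isosbestic channel carries the same motion artifact and bleaching
trend but no calcium-dependent component, the quotient is (to first
order) free of both.

Resampling is by non-overlapping bin means with bin-center timestamps,
which is deterministic and exactly checkable; the source rate must be an
integer multiple of the target rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateRegressorError, ResamplingError, AnalysisError
from .signals import PhotometryTrace, RawRecording


def _decimation_factor(source_rate: float, target_rate: float) -> int:
    if target_rate <= 0:
        raise ResamplingError("target rate must be positive")
    if target_rate > source_rate * (1 + 1e-9):
        raise ResamplingError(
            f"cannot upsample from {source_rate:g} Hz to {target_rate:g} Hz"
        )
    ratio = source_rate / target_rate
    factor = int(round(ratio))
    if abs(ratio - factor) > 1e-6 * factor:
        raise ResamplingError(
            f"source rate {source_rate:g} Hz is not an integer multiple of "
            f"target rate {target_rate:g} Hz (ratio {ratio:.6g})"
        )
    return factor


def _bin_mean(x: np.ndarray, factor: int) -> np.ndarray:
    n_bins = x.size // factor
    return x[: n_bins * factor].reshape(n_bins, factor).mean(axis=1)


def resample_to_rate(rec, target_rate_hz: float):
    """Downsample a recording or trace to ``target_rate_hz`` by bin means.

    Each output sample is the arithmetic mean of its non-overlapping
    source bin; output timestamps are the bin centers (the mean of the
    source timestamps in the bin).  A trailing partial bin is dropped.
    The returned object has the same type as the input.
    """
    if isinstance(rec, RawRecording):
        factor = _decimation_factor(rec.acq_rate_hz, target_rate_hz)
        if factor == 1:
            return rec
        return RawRecording(
            time_s=_bin_mean(rec.time_s, factor),
            f_signal=_bin_mean(rec.f_signal, factor),
            f_iso=_bin_mean(rec.f_iso, factor),
            acq_rate_hz=target_rate_hz,
        )
    if isinstance(rec, PhotometryTrace):
        factor = _decimation_factor(rec.rate_hz, target_rate_hz)
        if factor == 1:
            return rec
        return PhotometryTrace(
            time_s=_bin_mean(rec.time_s, factor),
            values=_bin_mean(rec.values, factor),
            rate_hz=target_rate_hz,
            kind=rec.kind,
        )
    raise TypeError(f"cannot resample object of type {type(rec).__name__}")


def fit_isosbestic(signal: PhotometryTrace, iso: PhotometryTrace):
    """Least-squares affine scaling of the isosbestic channel.

    Finds slope a and intercept b minimizing ``sum((signal - (a*iso + b))**2)``
    and returns ``(scaled_iso, slope, intercept)`` where ``scaled_iso`` is
    the fitted reference on the same grid.

    Raises
    ------
    DegenerateRegressorError
        If the isosbestic channel has zero variance (the slope is then
        unidentifiable).
    AnalysisError
        If the two traces are not on the same grid.
    """
    if len(signal) != len(iso):
        raise AnalysisError("signal and iso must have equal length")
    if not np.isclose(signal.rate_hz, iso.rate_hz, rtol=1e-9):
        raise AnalysisError("signal and iso must share a sampling rate")
    x = iso.values
    y = signal.values
    if np.ptp(x) == 0.0:
        raise DegenerateRegressorError(
            "isosbestic channel is constant; affine scaling is unidentifiable"
        )
    # ordinary least squares via centered moments (numerically stable)
    xm = x.mean()
    ym = y.mean()
    xc = x - xm
    slope = float(np.dot(xc, y - ym) / np.dot(xc, xc))
    intercept = float(ym - slope * xm)
    scaled = signal.with_values(slope * x + intercept, kind="scaled_iso")
    return scaled, slope, intercept


def compute_dff(signal: PhotometryTrace, scaled_iso: PhotometryTrace) -> PhotometryTrace:
    """ΔF/F from the calcium channel and the fitted isosbestic reference.

    ``dff[t] = (signal[t] - scaled_iso[t]) / scaled_iso[t]``.  Every
    ``scaled_iso`` sample must be strictly positive; a non-positive
    denominator is an error, never silently clipped.
    """
    if len(signal) != len(scaled_iso):
        raise AnalysisError("signal and scaled_iso must have equal length")
    denom = scaled_iso.values
    if np.any(denom <= 0):
        raise AnalysisError(
            "scaled isosbestic trace has non-positive samples; "
            "ΔF/F is undefined (check the regression fit)"
        )
    dff = (signal.values - denom) / denom
    return signal.with_values(dff, kind="dff")


@dataclass(frozen=True)
class CorrectionResult:
    """Bundle of the full preprocessing chain on one recording."""

    dff: PhotometryTrace
    scaled_iso: PhotometryTrace
    slope: float
    intercept: float


def correct_recording(rec: RawRecording, analysis_rate_hz: float = 10.0) -> CorrectionResult:
    """Resample, fit the isosbestic reference, and compute ΔF/F.

    Convenience wrapper running the three preprocessing stages in order
    at the given analysis rate (default 10 Hz).
    """
    low = resample_to_rate(rec, analysis_rate_hz)
    sig = low.channel("signal")
    iso = low.channel("iso")
    scaled, slope, intercept = fit_isosbestic(sig, iso)
    dff = compute_dff(sig, scaled)
    return CorrectionResult(dff=dff, scaled_iso=scaled, slope=slope, intercept=intercept)
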
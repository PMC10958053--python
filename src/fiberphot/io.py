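"""Readers and writers for the package's text and HDF5 formats.

Recordings and traces travel as delimited text (comma or tab, sniffed
from the header line) with a ``time_s`` column; peri-event matrices as
HDF5 with a CSV export for small cases; statistical results as
delimited text plus a JSON sidecar carrying parameters, seeds, and
significant intervals.  Parse errors name the offending line.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .errors import ParseError
from .perievent import EventSeries, PeriEventMatrix
from .resampling import CiBand, PermResult
from .signals import PhotometryTrace, RawRecording
from .transients import TransientSet

RECORDING_COLUMNS = ("time_s", "f470", "f405")


def _read_table(path, required: tuple) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ParseError(f"{path}: file not found")
    with open(path) as fh:
        header = fh.readline()
    sep = "\t" if "\t" in header else ","
    try:
        df = pd.read_csv(path, sep=sep)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise ParseError(f"{path}: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing} (found {list(df.columns)})")
    for col in required:
        vals = pd.to_numeric(df[col], errors="coerce") if col != "label" else df[col]
        if col != "label":
            bad = np.flatnonzero(~np.isfinite(vals.to_numpy(dtype=float, na_value=np.nan)))
            if bad.size:
                # +2: one for the header, one for 1-based numbering
                raise ParseError(
                    f"{path}: non-finite or non-numeric value in column "
                    f"{col!r} at line {bad[0] + 2}"
                )
            df[col] = vals
    return df


def read_recording(path) -> RawRecording:
    """Read a two-channel recording (columns time_s, f470, f405)."""
    df = _read_table(path, RECORDING_COLUMNS)
    t = df["time_s"].to_numpy(dtype=float)
    bad = np.flatnonzero(np.diff(t) <= 0)
    if bad.size:
        raise ParseError(f"{path}: non-monotone time_s at line {bad[0] + 3}")
    return RawRecording(
        time_s=t,
        f_signal=df["f470"].to_numpy(dtype=float),
        f_iso=df["f405"].to_numpy(dtype=float),
    )


def write_recording(rec: RawRecording, path, sep: str = ",") -> None:
    df = pd.DataFrame({
        "time_s": rec.time_s, "f470": rec.f_signal, "f405": rec.f_iso,
    })
    df.to_csv(path, sep=sep, index=False, float_format="%.10g")


def write_trace(trace: PhotometryTrace, path, sep: str = ",",
                sidecar: dict | None = None) -> None:
    """Write a trace as time_s,value text; optional JSON sidecar."""
    pd.DataFrame({"time_s": trace.time_s, "value": trace.values}).to_csv(
        path, sep=sep, index=False, float_format="%.12g")
    if sidecar is not None:
        Path(path).with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def read_trace(path, rate_hz: float | None = None, kind: str = "dff") -> PhotometryTrace:
    df = _read_table(path, ("time_s", "value"))
    t = df["time_s"].to_numpy(dtype=float)
    if rate_hz is None:
        rate_hz = 1.0 / float(np.median(np.diff(t)))
    return PhotometryTrace(t, df["value"].to_numpy(dtype=float), rate_hz, kind=kind)


def read_events(path) -> EventSeries:
    """Read labeled events (columns time_s, label)."""
    df = _read_table(path, ("time_s", "label"))
    t = df["time_s"].to_numpy(dtype=float)
    order = np.argsort(t, kind="stable")
    return EventSeries(times_s=t[order],
                       labels=tuple(df["label"].astype(str).iloc[order]))


def write_events(events: EventSeries, path, sep: str = ",") -> None:
    pd.DataFrame({"time_s": events.times_s, "label": events.labels}).to_csv(
        path, sep=sep, index=False, float_format="%.10g")


def read_train(path) -> np.ndarray:
    """Read a single-column timestamp train (column time_s)."""
    df = _read_table(path, ("time_s",))
    t = df["time_s"].to_numpy(dtype=float)
    bad = np.flatnonzero(np.diff(t) < 0)
    if bad.size:
        raise ParseError(f"{path}: unsorted time_s at line {bad[0] + 3}")
    return t


def write_train(times, path) -> None:
    pd.DataFrame({"time_s": np.asarray(times, dtype=float)}).to_csv(
        path, index=False, float_format="%.10g")


def write_transients(ts: TransientSet, path) -> None:
    pd.DataFrame({"peak_time_s": ts.peak_times_s,
                  "peak_value": ts.peak_values}).to_csv(
        path, index=False, float_format="%.12g")
    meta = {"threshold": ts.threshold, "mad": ts.mad, "median": ts.median,
            "params": ts.params, "n": int(ts.n)}
    Path(path).with_suffix(".json").write_text(json.dumps(meta, indent=2))


def write_perievent(pem: PeriEventMatrix, path, csv_export: bool = False) -> None:
    """Write a peri-event matrix as HDF5 (optionally with a CSV export)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("z", data=pem.z)
        f.create_dataset("rel_time_s", data=pem.rel_time_s)
        f.create_dataset("event_times_s", data=pem.event_times_s)
        if pem.dff is not None:
            f.create_dataset("dff", data=pem.dff)
        f.attrs["event_label"] = pem.event_label
        f.attrs["baseline_window"] = pem.baseline_window
        f.attrs["rate_hz"] = pem.rate_hz
        f.attrs["n_trials"] = pem.n_trials
        f.attrs["n_dropped"] = pem.n_dropped
        f.attrs["n_excluded"] = pem.n_excluded
        f.attrs["sd_ddof"] = pem.sd_ddof
    if csv_export:
        df = pd.DataFrame(pem.z, columns=[f"{t:.4f}" for t in pem.rel_time_s])
        df.insert(0, "event_time_s", pem.event_times_s)
        df.to_csv(Path(path).with_suffix(".csv"), index=False)


def read_perievent(path) -> PeriEventMatrix:
    with h5py.File(path, "r") as f:
        return PeriEventMatrix(
            z=f["z"][()],
            rel_time_s=f["rel_time_s"][()],
            event_times_s=f["event_times_s"][()],
            dff=f["dff"][()] if "dff" in f else None,
            n_trials=int(f.attrs["n_trials"]),
            baseline_window=tuple(f.attrs["baseline_window"]),
            event_label=str(f.attrs["event_label"]),
            rate_hz=float(f.attrs["rate_hz"]),
            n_dropped=int(f.attrs["n_dropped"]),
            n_excluded=int(f.attrs["n_excluded"]),
            sd_ddof=int(f.attrs["sd_ddof"]),
        )


def write_ciband(band: CiBand, path) -> None:
    pd.DataFrame({"rel_time_s": band.rel_time_s, "mean": band.mean_z,
                  "lower": band.lower, "upper": band.upper}).to_csv(
        path, index=False, float_format="%.12g")
    meta = {
        "n_trials": band.n_trials, "n_boot": band.n_boot, "level": band.level,
        "expansion": band.expansion, "min_duration_s": band.min_duration_s,
        "seed": band.seed,
        "significant_intervals": [list(iv) for iv in band.significant_intervals],
    }
    Path(path).with_suffix(".json").write_text(json.dumps(meta, indent=2))


def write_permresult(res: PermResult, path) -> None:
    pd.DataFrame({"rel_time_s": res.rel_time_s, "observed": res.observed,
                  "p": res.p}).to_csv(path, index=False, float_format="%.12g")
    meta = {
        "n_perm": res.n_perm, "alpha": res.alpha, "statistic": res.statistic,
        "min_duration_s": res.min_duration_s, "seed": res.seed,
        "significant_intervals": [list(iv) for iv in res.significant_intervals],
    }
    Path(path).with_suffix(".json").write_text(json.dumps(meta, indent=2))


def file_digest(path) -> str:
    """SHA-256 of a file, for provenance manifests."""
    if not Path(path).exists():
        raise ParseError(f"{path}: file not found")
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
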
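"""Run configuration and end-to-end pipeline orchestration.

A run executes the analysis stages in order — resample, isosbestic
scaling, ΔF/F, band-pass filtering and transient detection, peri-event
extraction, bootstrap bands and (optionally) a two-group permutation
test — and leaves a JSON manifest recording the package version, the
full configuration, every seed, input digests and warning counts, so
any output file is traceable to config + seed.
"""

from __future__ import annotations

import contextlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .errors import ConfigError, FiberphotError
from . import io as fio
from .perievent import extract_perievent, summarize_trials
from .preprocess import correct_recording
from .resampling import bootstrap_band, permutation_test
from .synth import SimConfig, simulate_photometry
from .transients import bandpass_filter, detect_transients

logger = logging.getLogger(__name__)

_SECTION_KEYS = {
    "filter": {"low_hz", "high_hz", "order"},
    "detect": {"min_prominence_mads", "min_distance_s"},
    "perievent": {"labels", "window", "baselines", "sd_ddof"},
    "summary": {"windows", "auc_method"},
    "bootstrap": {"n_boot", "level", "min_duration_s"},
    "permutation": {"n_perm", "alpha", "min_duration_s", "compare"},
}
_TOP_KEYS = {"recording", "events", "output_dir", "analysis_rate_hz",
             "seed", "simulate"} | set(_SECTION_KEYS)


@dataclass(frozen=True)
class RunConfig:
    """Validated pipeline configuration (strict: unknown keys rejected)."""

    recording: str | None = None
    events: str | None = None
    output_dir: str = "fiberphot_out"
    analysis_rate_hz: float = 10.0
    seed: int = 0
    simulate: SimConfig | None = None
    filter: dict = field(default_factory=dict)
    detect: dict = field(default_factory=dict)
    perievent: dict = field(default_factory=dict)
    summary: dict = field(default_factory=dict)
    bootstrap: dict = field(default_factory=dict)
    permutation: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.recording is None and self.simulate is None:
            raise ConfigError("config needs either 'recording' or 'simulate'")
        for name in _SECTION_KEYS:
            section = getattr(self, name)
            unknown = set(section) - _SECTION_KEYS[name]
            if unknown:
                raise ConfigError(f"unknown keys in section {name!r}: {sorted(unknown)}")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        unknown = set(d) - _TOP_KEYS
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        if d.get("simulate") is not None:
            d["simulate"] = SimConfig.from_dict(d["simulate"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        out = {
            "recording": self.recording, "events": self.events,
            "output_dir": self.output_dir,
            "analysis_rate_hz": self.analysis_rate_hz, "seed": self.seed,
            "simulate": self.simulate.to_dict() if self.simulate else None,
        }
        for name in _SECTION_KEYS:
            out[name] = dict(getattr(self, name))
        return out


@contextlib.contextmanager
def _stage(name: str, manifest: dict):
    t0 = time.perf_counter()
    logger.info("[%s] start", name)
    manifest["stages"].setdefault(name, {})
    try:
        yield
    except FiberphotError as exc:
        raise FiberphotError(f"stage {name!r} failed: {exc}") from exc
    finally:
        manifest["stages"][name]["seconds"] = round(time.perf_counter() - t0, 4)


def run_pipeline(config: RunConfig, output_dir=None) -> dict:
    """Execute all configured stages; returns the manifest dict.

    Outputs are deterministic given config + seed.  The manifest is
    written to ``<output_dir>/manifest.json``.
    """
    out = Path(output_dir if output_dir is not None else config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "fiberphot", "version": __version__,
        "seed": config.seed, "config": config.to_dict(),
        "inputs": {}, "outputs": [], "stages": {}, "warnings": {},
    }

    events = None
    with _stage("input", manifest):
        if config.simulate is not None:
            rec, truth = simulate_photometry(config.simulate)
            fio.write_recording(rec, out / "recording.csv")
            (out / "ground_truth.json").write_text(json.dumps({
                "transient_times": truth.transient_times.tolist(),
                "evoked_response": {k: v.tolist()
                                    for k, v in truth.evoked_response.items()},
            }, indent=2))
            manifest["outputs"] += ["recording.csv", "ground_truth.json"]
            if config.simulate.event_schedule:
                from .perievent import EventSeries
                sched = sorted(config.simulate.event_schedule, key=lambda x: x[1])
                events = EventSeries(
                    times_s=np.array([t for _, t in sched]),
                    labels=tuple(lb for lb, _ in sched))
        else:
            manifest["inputs"]["recording"] = fio.file_digest(config.recording)
            rec = fio.read_recording(config.recording)
        if config.events is not None:
            manifest["inputs"]["events"] = fio.file_digest(config.events)
            events = fio.read_events(config.events)

    with _stage("preprocess", manifest):
        corr = correct_recording(rec, config.analysis_rate_hz)
        fio.write_trace(corr.dff, out / "dff.csv", sidecar={
            "slope": corr.slope, "intercept": corr.intercept,
            "analysis_rate_hz": config.analysis_rate_hz,
        })
        manifest["outputs"] += ["dff.csv", "dff.json"]

    with _stage("detect", manifest):
        filtered = bandpass_filter(corr.dff, **config.filter)
        transients = detect_transients(filtered, **config.detect)
        fio.write_trace(filtered, out / "filtered.csv")
        fio.write_transients(transients, out / "transients.csv")
        manifest["outputs"] += ["filtered.csv", "transients.csv", "transients.json"]
        manifest["stages"]["detect"]["n_transients"] = int(transients.n)

    pems = {}
    if events is not None and config.perievent.get("labels"):
        with _stage("perievent", manifest):
            window = tuple(config.perievent.get("window", (-10.0, 10.0)))
            baselines = config.perievent.get("baselines", {})
            sd_ddof = config.perievent.get("sd_ddof", 1)
            for label in config.perievent["labels"]:
                baseline = baselines.get(label)
                if baseline is not None:
                    baseline = tuple(baseline)
                pem = extract_perievent(corr.dff, events, label, window,
                                        baseline=baseline, sd_ddof=sd_ddof)
                pems[label] = pem
                fio.write_perievent(pem, out / f"perievent_{label}.h5")
                manifest["outputs"].append(f"perievent_{label}.h5")
                manifest["warnings"][f"{label}_dropped"] = pem.n_dropped
                manifest["warnings"][f"{label}_excluded"] = pem.n_excluded
                windows = [tuple(w) for w in config.summary.get("windows", [(0.0, 2.0)])]
                summ = summarize_trials(
                    pem, transients, windows=windows,
                    auc_method=config.summary.get("auc_method", "trapezoid"))
                summ.to_csv(out / f"summary_{label}.csv", index=False)
                manifest["outputs"].append(f"summary_{label}.csv")
            manifest["stages"]["perievent"]["auc_method"] = config.summary.get(
                "auc_method", "trapezoid")

    if pems:
        with _stage("bootstrap", manifest):
            for label, pem in pems.items():
                band = bootstrap_band(pem, seed=config.seed, **config.bootstrap)
                fio.write_ciband(band, out / f"ciband_{label}.csv")
                manifest["outputs"] += [f"ciband_{label}.csv", f"ciband_{label}.json"]

        compare = config.permutation.get("compare")
        if compare:
            with _stage("permtest", manifest):
                la, lb = compare
                if la not in pems or lb not in pems:
                    raise ConfigError(
                        f"permutation 'compare' labels {compare} must be analyzed "
                        "perievent labels")
                kwargs = {k: v for k, v in config.permutation.items()
                          if k != "compare"}
                res = permutation_test(pems[la], pems[lb], seed=config.seed, **kwargs)
                fio.write_permresult(res, out / f"permtest_{la}_vs_{lb}.csv")
                manifest["outputs"] += [f"permtest_{la}_vs_{lb}.csv",
                                        f"permtest_{la}_vs_{lb}.json"]

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
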
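"""Synthetic photometry sessions, lick trains, and spike trains.

Every downstream stage is tested against data generated here, with full
ground truth: the two-channel recording model is

    F_470(t) = B_s(t) * (1 + dff(t)) + M(t) + eps_s(t)
    F_405(t) = B_i(t) + g * M(t) + eps_i(t)

where B_c(t) is a per-channel exponential photobleaching curve toward an
asymptote, M(t) is an Ornstein-Uhlenbeck motion artifact shared across
channels with per-channel gain g, dff(t) is the true calcium component
in ΔF/F units (spontaneous Poisson transients plus event-locked
responses, both built from a difference-of-exponentials kernel
normalized to unit peak), and eps are independent white-noise terms.
The isosbestic channel carries no calcium component — exactly the
assumption the regression-based correction exploits.

By default the isosbestic motion gain is the ratio of channel baselines,
reflecting that additive artifacts scale with light throughput; with
equal bleach kinetics the two channels are then exactly affinely related
in their artifact parts, which is the regime the least-squares scaling
assumes.

All randomness flows from a single seeded generator per call; identical
(config, seed) pairs give bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .errors import ConfigError
from .signals import RawRecording

#: ISI below which two spikes open a burst (dopamine-neuron convention)
DEFAULT_BURST_ONSET_ISI_S = 0.08


def calcium_kernel(tau: np.ndarray, rise_s: float, decay_s: float) -> np.ndarray:
    """Difference-of-exponentials calcium kernel, unit peak, causal.

    k(t) = (exp(-t/decay) - exp(-t/rise)) / peak  for t >= 0, 0 before.
    """
    if not 0 < rise_s < decay_s:
        raise ConfigError("kernel requires 0 < rise_s < decay_s")
    tau = np.asarray(tau, dtype=float)
    tp = np.maximum(tau, 0.0)  # avoid overflow of exp at large negative lags
    k = np.where(tau >= 0, np.exp(-tp / decay_s) - np.exp(-tp / rise_s), 0.0)
    t_peak = kernel_peak_time(rise_s, decay_s)
    peak = np.exp(-t_peak / decay_s) - np.exp(-t_peak / rise_s)
    return k / peak


def kernel_peak_time(rise_s: float, decay_s: float) -> float:
    """Time of the kernel maximum (closed form)."""
    return rise_s * decay_s / (decay_s - rise_s) * np.log(decay_s / rise_s)


def kernel_integral(rise_s: float, decay_s: float) -> float:
    """Analytic integral of the unit-peak kernel over [0, inf)."""
    t_peak = kernel_peak_time(rise_s, decay_s)
    peak = np.exp(-t_peak / decay_s) - np.exp(-t_peak / rise_s)
    return (decay_s - rise_s) / peak


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulated photometry session.

    Amplitudes for ``transient_amp`` and ``evoked_amp`` are in ΔF/F
    units (signed for evoked responses); time constants in seconds;
    baselines and noise/motion scales in raw fluorescence units.
    Per-channel pairs are (signal, isosbestic).
    """

    duration_s: float = 180.0
    acq_rate_hz: float = 100.0
    bleach_tau_s: tuple[float, float] = (120.0, 120.0)
    bleach_amplitude: float = 0.1
    baseline_f: tuple[float, float] = (100.0, 50.0)
    motion_sd: float = 2.0
    motion_tau_s: float = 1.0
    noise_sd: float = 0.5
    spont_rate_hz: float = 0.2
    spont_min_gap_s: float = 1.0
    kernel_rise_s: float = 0.2
    kernel_decay_s: float = 1.0
    transient_amp: float = 0.05
    event_schedule: tuple = ()
    evoked_amp: dict = field(default_factory=dict)
    evoked_latency_s: float = 0.0
    iso_motion_gain: float | None = None
    seed: int = 0

    def __post_init__(self):
        scalars = {
            "duration_s": self.duration_s,
            "acq_rate_hz": self.acq_rate_hz,
            "motion_tau_s": self.motion_tau_s,
            "kernel_rise_s": self.kernel_rise_s,
            "kernel_decay_s": self.kernel_decay_s,
        }
        for name, v in scalars.items():
            if not np.isfinite(v) or v <= 0:
                raise ConfigError(f"{name} must be finite and positive, got {v!r}")
        for name, v in [("bleach_amplitude", self.bleach_amplitude),
                        ("motion_sd", self.motion_sd),
                        ("noise_sd", self.noise_sd),
                        ("spont_rate_hz", self.spont_rate_hz),
                        ("spont_min_gap_s", self.spont_min_gap_s),
                        ("transient_amp", self.transient_amp),
                        ("evoked_latency_s", self.evoked_latency_s)]:
            if not np.isfinite(v) or v < 0:
                raise ConfigError(f"{name} must be finite and >= 0, got {v!r}")
        if not 0 <= self.bleach_amplitude < 1:
            raise ConfigError("bleach_amplitude must be a fraction in [0, 1)")
        for tau in self.bleach_tau_s:
            if not np.isfinite(tau) or tau <= 0:
                raise ConfigError("bleach time constants must be positive")
        for b in self.baseline_f:
            if not np.isfinite(b) or b <= 0:
                raise ConfigError("channel baselines must be positive")
        if self.kernel_rise_s >= self.kernel_decay_s:
            raise ConfigError("kernel_rise_s must be < kernel_decay_s")
        for v in self.evoked_amp.values():
            if not np.isfinite(v):
                raise ConfigError("evoked amplitudes must be finite")
        for label, t in self.event_schedule:
            if not np.isfinite(t) or t < 0 or t >= self.duration_s:
                raise ConfigError(f"event {label!r} at {t!r} s outside the session")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["event_schedule"] = [[lb, float(t)] for lb, t in self.event_schedule]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown simulation keys: {sorted(unknown)}")
        d = dict(d)
        for key in ("bleach_tau_s", "baseline_f"):
            if key in d:
                d[key] = tuple(d[key])
        if "event_schedule" in d:
            d["event_schedule"] = tuple((str(lb), float(t)) for lb, t in d["event_schedule"])
        return cls(**d)


@dataclass(frozen=True)
class SimGroundTruth:
    """Everything the generator knows that an analyst would not.

    ``dff_true`` is the full injected calcium component in ΔF/F units;
    ``evoked_response`` maps each event label to its single-event
    response curve on ``rel_time_s``.
    """

    transient_times: np.ndarray
    dff_true: np.ndarray
    evoked_response: dict
    rel_time_s: np.ndarray
    motion_trace: np.ndarray
    bleach_signal: np.ndarray
    bleach_iso: np.ndarray


def _ou_process(n: int, dt: float, sd: float, tau: float,
                rng: np.random.Generator) -> np.ndarray:
    """Stationary Ornstein-Uhlenbeck path (exact discretization)."""
    if sd == 0:
        return np.zeros(n)
    rho = np.exp(-dt / tau)
    x = np.empty(n)
    innov = rng.standard_normal(n)
    x[0] = sd * innov[0]
    scale = sd * np.sqrt(1 - rho**2)
    for i in range(1, n):
        x[i] = rho * x[i - 1] + scale * innov[i]
    return x


def simulate_photometry(config: SimConfig):
    """Generate a two-channel recording with ground truth.

    Returns ``(RawRecording, SimGroundTruth)``.
    """
    rng = np.random.default_rng(config.seed)
    fs = config.acq_rate_hz
    dt = 1.0 / fs
    n = int(round(config.duration_s * fs))
    t = np.arange(n) * dt

    # per-channel bleaching toward an asymptote
    amp = config.bleach_amplitude
    b_sig = config.baseline_f[0] * ((1 - amp) + amp * np.exp(-t / config.bleach_tau_s[0]))
    b_iso = config.baseline_f[1] * ((1 - amp) + amp * np.exp(-t / config.bleach_tau_s[1]))

    motion = _ou_process(n, dt, config.motion_sd, config.motion_tau_s, rng)

    # spontaneous transients: Poisson process thinned to a minimum
    # separation (bulk transients closer than the kernel width are not
    # resolvable as distinct peaks, so ground truth enforces a dead time)
    n_spont = rng.poisson(config.spont_rate_hz * config.duration_s)
    raw_times = np.sort(rng.uniform(0.0, config.duration_s, size=n_spont))
    spont: list[float] = []
    for ts in raw_times:
        if not spont or ts - spont[-1] >= config.spont_min_gap_s:
            spont.append(float(ts))
    spont_times = np.asarray(spont)

    dff = np.zeros(n)
    for ts in spont_times:
        dff += config.transient_amp * calcium_kernel(
            t - ts, config.kernel_rise_s, config.kernel_decay_s
        )

    # event-locked responses; also record the single-event curve per label
    rel_time = np.arange(0.0, 10.0 * config.kernel_decay_s, dt)
    evoked_response: dict[str, np.ndarray] = {}
    for label, te in config.event_schedule:
        a = config.evoked_amp.get(label, 0.0)
        dff += a * calcium_kernel(
            t - te - config.evoked_latency_s,
            config.kernel_rise_s, config.kernel_decay_s,
        )
        if label not in evoked_response:
            evoked_response[label] = a * calcium_kernel(
                rel_time - config.evoked_latency_s,
                config.kernel_rise_s, config.kernel_decay_s,
            )

    noise_sig = config.noise_sd * rng.standard_normal(n)
    noise_iso = config.noise_sd * rng.standard_normal(n)

    gain = config.iso_motion_gain
    if gain is None:
        gain = config.baseline_f[1] / config.baseline_f[0]

    f_signal = b_sig * (1.0 + dff) + motion + noise_sig
    f_iso = b_iso + gain * motion + noise_iso

    rec = RawRecording(time_s=t, f_signal=f_signal, f_iso=f_iso, acq_rate_hz=fs)
    truth = SimGroundTruth(
        transient_times=spont_times,
        dff_true=dff,
        evoked_response=evoked_response,
        rel_time_s=rel_time,
        motion_trace=motion,
        bleach_signal=b_sig,
        bleach_iso=b_iso,
    )
    return rec, truth


def simulate_licks(
    n_bursts: int,
    licks_per_burst,
    intra_ili_s: float = 0.1,
    inter_burst_gap_s: float = 0.8,
    seed: int | None = None,
    t0: float = 0.0,
    ili_threshold_s: float = 0.25,
) -> np.ndarray:
    """Burst-structured lick train.

    ``licks_per_burst`` is an int (fixed size) or a sequence of per-burst
    sizes (each >= 2).  Within-burst intervals are drawn uniformly in
    [intra_ili_s/2, intra_ili_s] and between-burst gaps in
    [inter_burst_gap_s, 2*inter_burst_gap_s), so segmentation at the
    250 ms criterion recovers exactly the drawn bursts.
    """
    if n_bursts < 0:
        raise ConfigError("n_bursts must be >= 0")
    if not intra_ili_s < ili_threshold_s < inter_burst_gap_s:
        raise ConfigError(
            "need intra_ili_s < ili_threshold_s < inter_burst_gap_s "
            f"(got {intra_ili_s}, {ili_threshold_s}, {inter_burst_gap_s})"
        )
    rng = np.random.default_rng(seed)
    if np.isscalar(licks_per_burst):
        sizes = [int(licks_per_burst)] * n_bursts
    else:
        sizes = [int(s) for s in licks_per_burst]
        if len(sizes) != n_bursts:
            raise ConfigError("licks_per_burst length must equal n_bursts")
    if any(s < 2 for s in sizes):
        raise ConfigError("every burst needs at least 2 licks")

    times = []
    cursor = t0
    for k, size in enumerate(sizes):
        if k > 0:
            cursor += rng.uniform(inter_burst_gap_s, 2 * inter_burst_gap_s)
        for j in range(size):
            if j > 0:
                cursor += rng.uniform(intra_ili_s / 2, intra_ili_s)
            times.append(cursor)
    return np.asarray(times, dtype=float)


def simulate_spikes(
    duration_s: float,
    tonic_rate_hz: float,
    burst_rate_hz: float,
    spikes_per_burst: int = 3,
    intra_burst_isi_s: float = 0.04,
    seed: int | None = None,
):
    """Spike train with tonic Poisson firing plus Poisson burst episodes.

    Burst onsets follow a Poisson process at ``burst_rate_hz``; each
    burst emits ``spikes_per_burst`` spikes at ``intra_burst_isi_s``
    spacing (< 80 ms so the standard burst-onset rule fires).  Returns
    ``(times, burst_members)`` where ``burst_members`` is a list of the
    per-burst spike-time arrays (ground truth).
    """
    if duration_s <= 0:
        raise ConfigError("duration_s must be positive")
    if tonic_rate_hz < 0 or burst_rate_hz < 0:
        raise ConfigError("rates must be >= 0")
    if not 0 < intra_burst_isi_s < DEFAULT_BURST_ONSET_ISI_S:
        raise ConfigError(
            f"intra_burst_isi_s must be in (0, {DEFAULT_BURST_ONSET_ISI_S}) s"
        )
    if spikes_per_burst < 2:
        raise ConfigError("spikes_per_burst must be >= 2")
    rng = np.random.default_rng(seed)

    n_tonic = rng.poisson(tonic_rate_hz * duration_s)
    tonic = rng.uniform(0.0, duration_s, size=n_tonic)

    n_bursts = rng.poisson(burst_rate_hz * duration_s)
    burst_len = (spikes_per_burst - 1) * intra_burst_isi_s
    onsets = rng.uniform(0.0, max(duration_s - burst_len, 0.0), size=n_bursts)
    burst_members = [
        onset + np.arange(spikes_per_burst) * intra_burst_isi_s
        for onset in np.sort(onsets)
    ]

    parts = [tonic] + burst_members
    times = np.sort(np.concatenate(parts)) if parts else np.array([])
    # enforce strictly increasing timestamps (coincidences have measure
    # zero but break downstream sorting contracts)
    times = np.unique(times)
    return times, burst_members
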
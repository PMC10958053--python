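"""Ground-truth contracts of the synthetic session generator."""

import numpy as np
import pytest

from fiberphot import (
    EventSeries,
    SimConfig,
    bandpass_filter,
    calcium_kernel,
    correct_recording,
    detect_transients,
    extract_perievent,
    kernel_integral,
    kernel_peak_time,
    simulate_photometry,
)
from fiberphot.errors import ConfigError


class TestKernel:
    def test_unit_peak_and_causality(self):
        t = np.linspace(-2, 20, 20001)
        k = calcium_kernel(t, 0.2, 1.0)
        assert k[t < 0].max() == 0.0
        assert k.max() == pytest.approx(1.0, abs=1e-6)
        tp = kernel_peak_time(0.2, 1.0)
        assert t[np.argmax(k)] == pytest.approx(tp, abs=2e-3)

    def test_trapezoid_integral_matches_analytic(self):
        # generator invariant: numeric integral within 1% of closed form
        t = np.arange(0, 60, 0.01)
        k = calcium_kernel(t, 0.2, 1.0)
        num = np.trapezoid(k, t)
        assert num == pytest.approx(kernel_integral(0.2, 1.0), rel=0.01)

    def test_invalid_time_constants_rejected(self):
        with pytest.raises(ConfigError):
            calcium_kernel(np.arange(3.0), 1.0, 0.5)


class TestSimulatePhotometry:
    def test_no_signal_config_gives_pure_bleach_and_flat_dff(self):
        cfg = SimConfig(duration_s=60.0, seed=0, spont_rate_hz=0.0,
                        transient_amp=0.0, noise_sd=0.0, motion_sd=0.0)
        rec, truth = simulate_photometry(cfg)
        np.testing.assert_allclose(rec.f_signal, truth.bleach_signal, atol=1e-12)
        np.testing.assert_allclose(rec.f_iso, truth.bleach_iso, atol=1e-12)
        dff = correct_recording(rec, 10.0).dff.values
        assert np.max(np.abs(dff)) < 1e-6

    def test_bit_identical_under_same_seed(self):
        cfg = SimConfig(duration_s=30.0, seed=123,
                        event_schedule=(("A", 10.0),), evoked_amp={"A": 0.3})
        r1, t1 = simulate_photometry(cfg)
        r2, t2 = simulate_photometry(cfg)
        np.testing.assert_array_equal(r1.f_signal, r2.f_signal)
        np.testing.assert_array_equal(r1.f_iso, r2.f_iso)
        np.testing.assert_array_equal(t1.transient_times, t2.transient_times)

    def test_different_seeds_differ(self):
        r1, _ = simulate_photometry(SimConfig(duration_s=20.0, seed=1))
        r2, _ = simulate_photometry(SimConfig(duration_s=20.0, seed=2))
        assert not np.array_equal(r1.f_signal, r2.f_signal)

    def test_channel_residuals_share_motion_artifact(self):
        # noiseless: after bleach removal both channels are (scaled) motion
        cfg = SimConfig(duration_s=60.0, seed=3, spont_rate_hz=0.0,
                        transient_amp=0.0, noise_sd=0.0, motion_sd=2.0)
        rec, truth = simulate_photometry(cfg)
        res_sig = rec.f_signal - truth.bleach_signal
        res_iso = rec.f_iso - truth.bleach_iso
        r = np.corrcoef(res_sig, res_iso)[0, 1]
        assert r >= 0.99

    def test_evoked_peak_recovered_through_pipeline(self):
        # one noiseless evoked event of 0.5 dF/F: the peri-event pipeline
        # recovers the analytic kernel peak within 5%
        cfg = SimConfig(duration_s=120.0, seed=4, spont_rate_hz=0.0,
                        transient_amp=0.0, noise_sd=0.0, motion_sd=0.0,
                        event_schedule=(("A", 60.0),), evoked_amp={"A": 0.5})
        rec, truth = simulate_photometry(cfg)
        corr = correct_recording(rec, 10.0)
        ev = EventSeries(np.array([60.0]), ("A",))
        pem = extract_perievent(corr.dff, ev, "A", (-5.0, 8.0), baseline=(-4.0, -1.0))
        base = pem.dff[0, pem.baseline_mask()].mean()
        peak = pem.dff[0].max() - base
        assert peak == pytest.approx(0.5, rel=0.05)
        # and matches the injected ground-truth response curve (sampled at
        # the acquisition grid, so the exact peak may fall between samples)
        assert truth.evoked_response["A"].max() == pytest.approx(0.5, rel=1e-3)

    def test_spontaneous_times_within_session_and_spaced(self):
        cfg = SimConfig(duration_s=300.0, seed=5, spont_rate_hz=0.3)
        _, truth = simulate_photometry(cfg)
        t = truth.transient_times
        assert np.all((t >= 0) & (t < 300.0))
        assert np.all(np.diff(t) >= cfg.spont_min_gap_s)

    @pytest.mark.parametrize("bad", [
        dict(duration_s=0.0),
        dict(acq_rate_hz=-10.0),
        dict(noise_sd=-1.0),
        dict(bleach_amplitude=1.5),
        dict(kernel_rise_s=2.0, kernel_decay_s=1.0),
        dict(baseline_f=(0.0, 50.0)),
        dict(evoked_amp={"A": float("nan")}),
        dict(event_schedule=(("A", 1e9),)),
    ])
    def test_invalid_configs_rejected(self, bad):
        with pytest.raises(ConfigError):
            SimConfig(**bad)

    def test_config_roundtrips_through_dict(self):
        cfg = SimConfig(duration_s=45.0, seed=9,
                        event_schedule=(("A", 1.0), ("B", 2.0)),
                        evoked_amp={"A": 0.5, "B": -0.1})
        assert SimConfig.from_dict(cfg.to_dict()) == cfg

    def test_unknown_config_key_rejected(self):
        with pytest.raises(ConfigError):
            SimConfig.from_dict({"duration_s": 10.0, "bogus": 1})


class TestDetectionOnGroundTruth:
    def test_detection_recovers_known_transients(self):
        # default SNR (amp ~17x filtered noise SD): precision/recall high
        cfg = SimConfig(duration_s=300.0, seed=6)
        rec, truth = simulate_photometry(cfg)
        corr = correct_recording(rec, 10.0)
        ts = detect_transients(bandpass_filter(corr.dff))
        true = truth.transient_times
        det = ts.peak_times_s
        # expected peak lag of the filtered kernel (measured on a clean pulse)
        off = _filtered_peak_offset(cfg)
        matched = _greedy_match(true + off, det, tol=0.2)
        assert matched / max(true.size, 1) >= 0.9      # recall
        assert matched / max(det.size, 1) >= 0.9       # precision


def _filtered_peak_offset(cfg):
    clean = SimConfig(duration_s=60.0, seed=0, spont_rate_hz=0.0,
                      transient_amp=0.0, noise_sd=0.0, motion_sd=0.0,
                      event_schedule=(("A", 30.0),), evoked_amp={"A": 1.0},
                      kernel_rise_s=cfg.kernel_rise_s,
                      kernel_decay_s=cfg.kernel_decay_s)
    rec, _ = simulate_photometry(clean)
    f = bandpass_filter(correct_recording(rec, 10.0).dff)
    return float(f.time_s[np.argmax(f.values)] - 30.0)


def _greedy_match(expected, detected, tol):
    used = set()
    matched = 0
    for t in expected:
        best, best_d = None, tol
        for i, d in enumerate(detected):
            if i in used:
                continue
            dist = abs(d - t)
            if dist <= best_d:
                best, best_d = i, dist
        if best is not None:
            used.add(best)
            matched += 1
    return matched
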
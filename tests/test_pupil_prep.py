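"""Pupil trace cleaning, epoching, baseline correction and peak extraction."""

import numpy as np
import pandas as pd
import pytest

from dotcomp.pupil_prep import (
    EpochParams,
    PreprocessParams,
    PupilEpoch,
    epoch_phase,
    peak_pd,
    preprocess_trace,
)
from dotcomp.synthetic_data import PupilRecording

FS = 250.0
DT = 1000.0 / FS


def _recording(left, right=None, events=None):
    left = np.asarray(left, dtype=float)
    right = left.copy() if right is None else np.asarray(right, dtype=float)
    t = np.arange(len(left)) * DT
    ev = events if events is not None else pd.DataFrame(
        columns=["time_ms", "kind", "trial"])
    return PupilRecording(FS, t, left, right, ev)


def _events_for_trial(trial, cue_ms, rt_ms=700.0):
    stim = cue_ms + 1500.0
    resp = stim + rt_ms
    return [
        {"time_ms": cue_ms, "kind": "cue_on", "trial": trial},
        {"time_ms": stim, "kind": "stim_on", "trial": trial},
        {"time_ms": resp, "kind": "response", "trial": trial},
        {"time_ms": resp, "kind": "feedback_on", "trial": trial},
    ]


class TestPreprocess:
    def test_impulse_smoothing_gives_five_point_mean(self):
        y = np.zeros(101)
        y[50] = 1.0
        trace = preprocess_trace(_recording(y))
        np.testing.assert_allclose(trace.diameter[48:53], 0.2, atol=1e-12)
        assert np.allclose(trace.diameter[:46], 0.0)
        assert len(trace.diameter) == 101

    def test_equal_eyes_merge_to_either(self):
        y = np.sin(np.arange(500) / 30.0) + 4.0
        trace = preprocess_trace(_recording(y, y), PreprocessParams(smooth_points=1))
        np.testing.assert_allclose(trace.diameter, y)

    def test_one_eye_missing_uses_other(self):
        y = np.full(200, 4.0)
        left = y.copy()
        left[50:60] = np.nan
        trace = preprocess_trace(_recording(left, y))
        assert not trace.missing.any()
        np.testing.assert_allclose(trace.diameter, 4.0)

    def test_cubic_interpolation_recovers_smooth_signal(self):
        t = np.arange(2000) * DT
        y = 4.5 + 0.5 * np.sin(2 * np.pi * t / 2000.0)
        gappy = y.copy()
        gappy[1000:1050] = np.nan  # 200 ms gap
        trace = preprocess_trace(_recording(gappy))
        assert not trace.missing[1000:1050].any()
        assert np.max(np.abs(trace.diameter[1000:1050] - y[1000:1050])) < 0.01
        assert trace.log["n_interpolated"] == 50

    def test_long_gap_left_missing(self):
        y = np.full(1000, 4.0)
        y[300:600] = np.nan  # 1200 ms > small-blink threshold
        trace = preprocess_trace(_recording(y))
        assert trace.missing[300:600].all()
        assert np.isnan(trace.diameter[450])
        assert trace.log["n_missing_remaining"] == 300

    def test_all_missing_rejected(self):
        with pytest.raises(ValueError, match="missing everywhere"):
            preprocess_trace(_recording(np.full(100, np.nan)))


class TestEpochs:
    def test_constant_trace_epochs_are_zero(self):
        events = pd.DataFrame(_events_for_trial(1, 1000.0) + _events_for_trial(2, 7000.0))
        trace = preprocess_trace(_recording(np.full(4000, 4.2)))
        for phase in ("cue", "stimulus", "feedback"):
            epochs, report = epoch_phase(trace, events, phase)
            assert report["n_kept"] == 2
            for ep in epochs:
                np.testing.assert_allclose(ep.values, 0.0, atol=1e-12)

    def test_epoch_window_lengths(self):
        events = pd.DataFrame(_events_for_trial(1, 1000.0))
        trace = preprocess_trace(_recording(np.full(2500, 4.0)))
        for phase in ("cue", "stimulus", "feedback"):
            epochs, _ = epoch_phase(trace, events, phase)
            assert len(epochs) == 1
            assert len(epochs[0].values) == int(round(1500.0 / DT))
        stim, _ = epoch_phase(trace, events, "stimulus")
        assert stim[0].rel_time_ms[0] == pytest.approx(-1300.0)

    def test_baseline_window_mean_zero_after_correction(self):
        rng = np.random.default_rng(4)
        y = 4.0 + np.cumsum(rng.normal(0, 0.002, 3000))  # slow drift
        events = pd.DataFrame(_events_for_trial(1, 2000.0))
        trace = preprocess_trace(_recording(y))
        epochs, _ = epoch_phase(trace, events, "cue")
        ep = epochs[0]
        i0 = int(round((2000.0 - 200.0) / DT))
        i1 = int(round(2000.0 / DT))
        corrected_baseline = trace.diameter[i0:i1] - ep.baseline_mm
        assert abs(corrected_baseline.mean()) < 1e-9

    def test_out_of_bounds_epoch_discarded(self):
        events = pd.DataFrame(_events_for_trial(1, 100.0))  # baseline precedes start
        trace = preprocess_trace(_recording(np.full(1000, 4.0)))
        epochs, report = epoch_phase(trace, events, "cue")
        assert epochs == [] and report["n_discarded_bounds"] == 1

    def test_excessively_missing_epoch_discarded(self):
        y = np.full(2500, 4.0)
        y[300:460] = np.nan  # 640 ms gap -> stays missing, 42% of the cue epoch
        events = pd.DataFrame(_events_for_trial(1, 1000.0))
        trace = preprocess_trace(_recording(y))
        epochs, report = epoch_phase(trace, events, "cue",
                                     params=EpochParams(max_missing_frac=0.25))
        assert report["n_discarded_missing"] == 1
        # accounting: kept + discarded = input
        assert report["n_kept"] + report["n_discarded_missing"] + \
            report["n_discarded_bounds"] == report["n_input"]

    def test_trial_info_attached(self):
        events = pd.DataFrame(_events_for_trial(1, 1000.0))
        info = pd.DataFrame({"participant": ["p07"], "incentive": ["reward"],
                             "ratio": ["8:7"]}, index=pd.Index([1], name="trial"))
        trace = preprocess_trace(_recording(np.full(2500, 4.0)))
        epochs, _ = epoch_phase(trace, events, "feedback", trial_info=info)
        assert epochs[0].participant == "p07"
        assert epochs[0].incentive == "reward" and epochs[0].ratio == "8:7"


def _epoch(values, phase="stimulus", pid="p01", inc="reward", ratio="4:3", trial=1):
    values = np.asarray(values, dtype=float)
    return PupilEpoch(trial=trial, phase=phase,
                      rel_time_ms=np.arange(len(values)) * DT, values=values,
                      baseline_mm=4.0, missing_frac=0.0, participant=pid,
                      incentive=inc, ratio=ratio)


class TestPeaks:
    def test_flat_trace_peak_zero_both_definitions(self):
        eps = [_epoch(np.zeros(375), phase=ph, trial=i)
               for ph in ("cue", "stimulus") for i in range(12)]
        for ph in ("cue", "stimulus"):
            out = peak_pd(eps, ph)
            assert out["peak_mm"].item() == 0.0

    def test_cue_peak_is_range(self):
        shape = np.concatenate([np.linspace(0, -0.05, 100),
                                np.linspace(-0.05, 0.10, 275)])
        eps = [_epoch(shape, phase="cue", trial=i) for i in range(10)]
        out = peak_pd(eps, "cue")
        assert out["peak_mm"].item() == pytest.approx(0.15)

    def test_stimulus_peak_is_max(self):
        shape = np.concatenate([np.linspace(0, -0.05, 100),
                                np.linspace(-0.05, 0.10, 275)])
        eps = [_epoch(shape, trial=i) for i in range(10)]
        out = peak_pd(eps, "stimulus")
        assert out["peak_mm"].item() == pytest.approx(0.10)

    def test_minimum_trial_count_enforced(self):
        eps = [_epoch(np.ones(375), trial=i) for i in range(9)]
        out = peak_pd(eps, "stimulus")
        assert np.isnan(out["peak_mm"].item()) and not out["reliable"].item()
        out10 = peak_pd(eps + [_epoch(np.ones(375), trial=9)], "stimulus")
        assert out10["reliable"].item() and out10["n_trials"].item() == 10

    def test_condition_average_before_peak(self):
        """Averaging epochs first matters when peaks sit at different latencies."""
        a = np.zeros(375); a[100] = 1.0
        b = np.zeros(375); b[300] = 1.0
        eps = [_epoch(a if i % 2 else b, trial=i) for i in range(10)]
        out = peak_pd(eps, "stimulus")
        assert out["peak_mm"].item() == pytest.approx(0.5)

    def test_linearity_scaling(self):
        rng = np.random.default_rng(1)
        shape = np.abs(rng.normal(0, 0.1, 375))
        for ph in ("cue", "stimulus", "feedback"):
            eps1 = [_epoch(shape, phase=ph, trial=i) for i in range(10)]
            eps3 = [_epoch(3.0 * shape, phase=ph, trial=i) for i in range(10)]
            p1 = peak_pd(eps1, ph)["peak_mm"].item()
            p3 = peak_pd(eps3, ph)["peak_mm"].item()
            assert p3 == pytest.approx(3.0 * p1)
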
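"""Pupil preprocessing: eye merge, blink interpolation, smoothing, epoching,
baseline correction and phase-wise peak extraction.

The chain mirrors common pupillometry practice: average the two eyes
sample-wise (using the available eye when one is missing), replace small
blink gaps by cubic interpolation anchored on flanking samples, leave long
gaps missing, smooth with an unweighted 5-point moving average, cut
phase-locked epochs (cue and feedback: 0..1500 ms after onset; stimulus:
-1300..+200 ms around the button press), subtract the mean of the 200 ms
window before phase onset, and reduce each participant x condition to the
peak of the condition-mean trace.  Because the cue phase starts during the
recovery of the previous trial's response, its peak is defined as the range
(max - min) of the trace rather than the raw maximum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

from .synthetic_data import PupilRecording

PHASES = ("cue", "stimulus", "feedback")
#: epoch window (ms) relative to the anchor event, per phase
PHASE_WINDOWS = {"cue": (0.0, 1500.0), "stimulus": (-1300.0, 200.0), "feedback": (0.0, 1500.0)}
#: event used as the epoch anchor
PHASE_ANCHOR = {"cue": "cue_on", "stimulus": "response", "feedback": "feedback_on"}
#: event whose onset defines the baseline window (differs from the anchor
#: only in the response-locked stimulus phase)
PHASE_ONSET = {"cue": "cue_on", "stimulus": "stim_on", "feedback": "feedback_on"}


@dataclass(frozen=True)
class PreprocessParams:
    small_blink_max_ms: float = 500.0  # gaps up to this length are interpolated
    interp_flank_ms: float = 100.0  # anchor samples each side of a gap
    smooth_points: int = 5


@dataclass(frozen=True)
class EpochParams:
    baseline_ms: float = 200.0
    max_missing_frac: float = 0.25  # "excessive blinking" threshold per epoch
    max_gap_ms: float = 1000.0
    min_trials: int = 10


@dataclass
class CleanTrace:
    sampling_rate: float
    timestamps: np.ndarray  # ms
    diameter: np.ndarray  # mm, NaN where missing
    missing: np.ndarray  # bool
    log: dict = field(default_factory=dict)


@dataclass
class PupilEpoch:
    trial: int
    phase: str
    rel_time_ms: np.ndarray
    values: np.ndarray  # baseline-corrected, mm
    baseline_mm: float
    missing_frac: float
    participant: object = None
    incentive: str | None = None
    ratio: str | None = None


def _nan_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) index ranges of True runs."""
    padded = np.concatenate(([False], mask, [False]))
    diff = np.diff(padded.astype(int))
    starts = np.flatnonzero(diff == 1)
    stops = np.flatnonzero(diff == -1)
    return list(zip(starts, stops))


def _moving_average(y: np.ndarray, window: int) -> np.ndarray:
    """Unweighted moving average, NaN-aware, symmetric truncation at edges
    and around remaining gaps; positions that were missing stay NaN."""
    valid = np.isfinite(y)
    filled = np.where(valid, y, 0.0)
    kernel = np.ones(window)
    num = np.convolve(filled, kernel, mode="same")
    den = np.convolve(valid.astype(float), kernel, mode="same")
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / den
    out[~valid] = np.nan
    return out


def preprocess_trace(
    recording: PupilRecording, params: PreprocessParams | None = None
) -> CleanTrace:
    """Merge eyes, interpolate small blinks, smooth.  Length is preserved."""
    params = params or PreprocessParams()
    dt_ms = 1000.0 / recording.sampling_rate
    left, right = np.asarray(recording.left, float), np.asarray(recording.right, float)
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        merged = np.nanmean(np.vstack([left, right]), axis=0)
    missing = ~np.isfinite(merged)
    if missing.all():
        raise ValueError("both eyes missing everywhere; nothing to preprocess")

    n_missing_in = int(missing.sum())
    flank = max(2, int(round(params.interp_flank_ms / dt_ms)))
    n_interp = 0
    for start, stop in _nan_runs(missing):
        gap_ms = (stop - start) * dt_ms
        if gap_ms > params.small_blink_max_ms:
            continue
        lo = max(0, start - flank)
        hi = min(len(merged), stop + flank)
        idx = np.arange(lo, hi)
        anchor = idx[np.isfinite(merged[idx])]
        if anchor.size < 4:  # cubic needs four anchor points
            continue
        spline = CubicSpline(anchor, merged[anchor])
        gap_idx = np.arange(start, stop)
        merged[gap_idx] = spline(gap_idx)
        missing[gap_idx] = False
        n_interp += stop - start

    smoothed = _moving_average(merged, params.smooth_points)
    log = {
        "n_samples": len(merged),
        "n_missing_input": n_missing_in,
        "n_interpolated": n_interp,
        "n_missing_remaining": int(missing.sum()),
    }
    return CleanTrace(recording.sampling_rate, np.asarray(recording.timestamps, float),
                      smoothed, missing, log)


def epoch_phase(
    trace: CleanTrace,
    events: pd.DataFrame,
    phase: str,
    trial_info: pd.DataFrame | None = None,
    params: EpochParams | None = None,
) -> tuple[list[PupilEpoch], dict]:
    """Cut baseline-corrected epochs for one phase.

    ``events`` needs columns (time_ms, kind, trial).  ``trial_info``, if
    given, is indexed by trial and carries participant/incentive/ratio which
    are attached to each epoch.  Epochs exceeding the recording, with more
    than ``max_missing_frac`` missing samples, with any missing run longer
    than ``max_gap_ms``, or with a fully missing baseline window are
    discarded and counted in the returned report.
    """
    if phase not in PHASES:
        raise ValueError(f"unknown phase {phase!r}")
    params = params or EpochParams()
    dt_ms = 1000.0 / trace.sampling_rate
    w_lo, w_hi = PHASE_WINDOWS[phase]
    n_win = int(round((w_hi - w_lo) / dt_ms))
    n_base = int(round(params.baseline_ms / dt_ms))
    t0 = trace.timestamps[0]

    anchors = events[events["kind"] == PHASE_ANCHOR[phase]].set_index("trial")["time_ms"]
    onsets = events[events["kind"] == PHASE_ONSET[phase]].set_index("trial")["time_ms"]

    epochs: list[PupilEpoch] = []
    report = {"phase": phase, "n_input": len(anchors), "n_kept": 0,
              "n_discarded_bounds": 0, "n_discarded_missing": 0}
    rel_time = w_lo + np.arange(n_win) * dt_ms

    for trial, anchor_ms in anchors.items():
        if trial not in onsets.index:
            report["n_discarded_bounds"] += 1
            continue
        start = int(round((anchor_ms + w_lo - t0) / dt_ms))
        stop = start + n_win
        b_stop = int(round((onsets.loc[trial] - t0) / dt_ms))
        b_start = b_stop - n_base
        if start < 0 or b_start < 0 or stop > len(trace.diameter):
            report["n_discarded_bounds"] += 1
            continue
        seg = trace.diameter[start:stop]
        seg_missing = ~np.isfinite(seg)
        frac = float(seg_missing.mean())
        longest_gap = max((b - a for a, b in _nan_runs(seg_missing)), default=0) * dt_ms
        baseline_vals = trace.diameter[b_start:b_stop]
        if (
            frac > params.max_missing_frac
            or longest_gap > params.max_gap_ms
            or not np.isfinite(baseline_vals).any()
        ):
            report["n_discarded_missing"] += 1
            continue
        baseline = float(np.nanmean(baseline_vals))
        epoch = PupilEpoch(
            trial=int(trial), phase=phase, rel_time_ms=rel_time,
            values=seg - baseline, baseline_mm=baseline, missing_frac=frac,
        )
        if trial_info is not None and trial in trial_info.index:
            info = trial_info.loc[trial]
            epoch.participant = info.get("participant")
            epoch.incentive = info.get("incentive")
            epoch.ratio = info.get("ratio")
        epochs.append(epoch)
        report["n_kept"] += 1
    return epochs, report


def peak_pd(
    epochs: list[PupilEpoch], phase: str, min_trials: int = 10
) -> pd.DataFrame:
    """Phase-wise peak pupil dilation per participant x incentive x ratio.

    Epochs of a cell are averaged into one condition trace first; the peak is
    the maximum of that trace (stimulus, feedback) or its range, max - min
    (cue).  Cells with fewer than ``min_trials`` epochs report NaN and
    ``reliable = False``.
    """
    if phase not in PHASES:
        raise ValueError(f"unknown phase {phase!r}")
    groups: dict[tuple, list[PupilEpoch]] = {}
    for ep in epochs:
        if ep.phase != phase:
            continue
        groups.setdefault((ep.participant, ep.incentive, ep.ratio), []).append(ep)
    rows = []
    for (pid, inc, rlab), eps in sorted(groups.items(), key=lambda kv: str(kv[0])):
        n = len(eps)
        if n < min_trials:
            peak = np.nan
            reliable = False
        else:
            mean_trace = np.nanmean(np.vstack([ep.values for ep in eps]), axis=0)
            if phase == "cue":
                peak = float(np.nanmax(mean_trace) - np.nanmin(mean_trace))
            else:
                peak = float(np.nanmax(mean_trace))
            reliable = True
        rows.append({"participant": pid, "incentive": inc, "ratio": rlab,
                     "phase": phase, "peak_mm": peak, "n_trials": n,
                     "reliable": reliable})
    return pd.DataFrame(rows)
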
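"""Ground-truth generators: diffusion-process behaviour and pupil traces.

Behaviour is produced by a Wiener diffusion with absorbing boundaries
(Euler-Maruyama, absorb at first crossing): evidence starts at z (unbiased,
a/2), drifts at rate v with diffusion scale s, and a response is emitted when
it reaches 0 or a; non-decision time t_ER is added to the first-passage time.
With the upper boundary coding the correct response, the crossing probability
has the closed form 1/(1 + exp(-v*a/s^2)), which the tests use as an oracle.

Pupil traces are built additively: a constant baseline, one phasic kernel per
trial event (cue, stimulus, feedback) scaled by condition-dependent
amplitudes, white measurement noise per eye, and blink gaps marked missing.
The kernel is the Erlang-gamma pupil response function
h(t) = t^n * exp(-n*t/t_max), peak-normalized, with n = 10.1 and
t_max = 930 ms.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .task_design import INCENTIVES, RATIO_LABELS

PHASES = ("cue", "stimulus", "feedback")
EVENT_KINDS = ("cue_on", "stim_on", "response", "feedback_on")


@dataclass(frozen=True)
class DDMParams:
    """Diffusion parameters for one condition.

    v: drift rate (evidence/s), a: boundary separation, t_er: non-decision
    time (s), z: start point (defaults to a/2, unbiased), s: diffusion scale
    (0.1 by the EZ convention), sv: SD of trial-to-trial drift variability
    (0 = the pure model the EZ estimator assumes).
    """

    v: float
    a: float
    t_er: float
    z: float | None = None
    s: float = 0.1
    sv: float = 0.0

    def __post_init__(self) -> None:
        vals = (self.v, self.a, self.t_er, self.s, self.sv)
        if not all(np.isfinite(vals)):
            raise ValueError(f"non-finite diffusion parameters: {self}")
        if self.a <= 0:
            raise ValueError("boundary separation a must be positive")
        if self.t_er < 0:
            raise ValueError("non-decision time must be non-negative")
        if self.s <= 0:
            raise ValueError("diffusion scale s must be positive")
        if self.sv < 0:
            raise ValueError("drift variability sv must be non-negative")
        if self.z is not None and not (0 < self.z < self.a):
            raise ValueError("start point z must lie strictly between the boundaries")

    @property
    def start_point(self) -> float:
        return self.a / 2 if self.z is None else self.z


def _default_ddm() -> dict[tuple[str, str], DDMParams]:
    # Drift falls with difficulty; reward raises v, a and t_ER at every ratio.
    v_control = {"4:3": 0.32, "5:4": 0.26, "8:7": 0.16, "10:9": 0.12}
    table = {}
    for rlab in RATIO_LABELS:
        table[("control", rlab)] = DDMParams(v=v_control[rlab], a=0.11, t_er=0.30)
        table[("reward", rlab)] = DDMParams(v=v_control[rlab] + 0.04, a=0.13, t_er=0.33)
    return table


def _default_pupil() -> dict[tuple[str, str, str], float]:
    # mm of peak dilation per event; reward > control in every phase, and a
    # linear difficulty gradient in the stimulus and feedback phases.
    base = {"cue": {"reward": 0.25, "control": 0.10},
            "stimulus": {"reward": 0.30, "control": 0.18},
            "feedback": {"reward": 0.35, "control": 0.20}}
    difficulty_step = {"cue": 0.0, "stimulus": 0.01, "feedback": 0.015}
    table = {}
    for phase in PHASES:
        for inc in INCENTIVES:
            for level, rlab in enumerate(RATIO_LABELS):
                table[(inc, rlab, phase)] = base[phase][inc] + level * difficulty_step[phase]
    return table


@dataclass(frozen=True)
class ConditionEffectTable:
    """Ground-truth parameters per incentive x ratio cell.

    ``ddm`` maps (incentive, ratio label) to diffusion parameters and
    ``pupil_amplitude`` maps (incentive, ratio label, phase) to the peak
    dilation (mm) of the event kernel in that phase.
    """

    ddm: dict[tuple[str, str], DDMParams] = field(default_factory=_default_ddm)
    pupil_amplitude: dict[tuple[str, str, str], float] = field(default_factory=_default_pupil)

    def params_for(self, incentive: str, ratio: str) -> DDMParams:
        try:
            return self.ddm[(incentive, ratio)]
        except KeyError as exc:
            raise KeyError(f"no diffusion parameters for cell ({incentive}, {ratio})") from exc

    def amplitude_for(self, incentive: str, ratio: str, phase: str) -> float:
        try:
            return self.pupil_amplitude[(incentive, ratio, phase)]
        except KeyError as exc:
            raise KeyError(f"no pupil amplitude for ({incentive}, {ratio}, {phase})") from exc

    def with_no_effects(self) -> "ConditionEffectTable":
        """A null table: every cell inherits the control/4:3 parameters."""
        p0 = self.params_for("control", "4:3")
        a0 = {ph: self.amplitude_for("control", "4:3", ph) for ph in PHASES}
        return ConditionEffectTable(
            ddm={k: p0 for k in self.ddm},
            pupil_amplitude={(i, r, ph): a0[ph] for (i, r, ph) in self.pupil_amplitude},
        )


# ---------------------------------------------------------------------------
# Diffusion simulation
# ---------------------------------------------------------------------------

def simulate_ddm_trials(
    params: DDMParams,
    n: int,
    rng: np.random.Generator,
    dt: float = 5e-4,
    max_time: float = 10.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate ``n`` first-passage trials; returns (rt_s, upper_boundary).

    Euler-Maruyama with step ``dt`` seconds and absorption at the first
    crossing.  Because the path is only monitored at the grid points, the
    barriers are shifted inward by the Broadie-Glasserman continuity
    correction 0.5826 * s * sqrt(dt), which removes the O(sqrt(dt)) bias of
    discrete monitoring; the simulated moments then agree with the
    continuous-time closed forms.  Paths still unabsorbed at ``max_time``
    (astronomically rare for sane parameters) are forced to the nearer
    boundary.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if n < 0:
        raise ValueError("n must be non-negative")
    shift = 0.5826 * params.s * np.sqrt(dt)  # zeta(1/2)/sqrt(2*pi)
    hi = params.a - shift
    lo = shift
    if hi <= lo:
        raise ValueError("dt too coarse for this boundary separation")
    v = np.full(n, params.v)
    if params.sv > 0:
        v = rng.normal(params.v, params.sv, size=n)
    x = np.full(n, params.start_point)
    decision_t = np.full(n, np.nan)
    upper = np.zeros(n, dtype=bool)
    active = np.arange(n)
    sqdt = np.sqrt(dt)
    n_steps = int(np.ceil(max_time / dt))
    for step in range(1, n_steps + 1):
        if active.size == 0:
            break
        x[active] += v[active] * dt + params.s * sqdt * rng.standard_normal(active.size)
        xa = x[active]
        hit_up = xa >= hi
        hit_lo = xa <= lo
        done = hit_up | hit_lo
        if done.any():
            idx = active[done]
            decision_t[idx] = step * dt
            upper[idx] = hit_up[done]
            active = active[~done]
    if active.size:  # censored: assign by current position
        decision_t[active] = n_steps * dt
        upper[active] = x[active] > params.a / 2
    return decision_t + params.t_er, upper


def simulate_ddm_trial(
    params: DDMParams, rng: np.random.Generator, dt: float = 5e-4
) -> tuple[float, bool]:
    """Single-trial convenience wrapper around :func:`simulate_ddm_trials`."""
    rt, up = simulate_ddm_trials(params, 1, rng, dt=dt)
    return float(rt[0]), bool(up[0])


def simulate_behavior(
    schedule: pd.DataFrame,
    effects: ConditionEffectTable,
    rng: np.random.Generator,
    dt: float = 5e-4,
) -> pd.DataFrame:
    """Attach diffusion-generated responses to a trial schedule.

    Upper-boundary crossings code correct responses (v points towards the
    correct answer), so ``response`` equals ``larger_side`` on correct trials.
    RTs are returned in milliseconds.
    """
    out = schedule.copy()
    rt_ms = np.empty(len(out))
    correct = np.empty(len(out), dtype=bool)
    for (inc, rlab), idx in out.groupby(["incentive", "ratio"], sort=True).groups.items():
        params = effects.params_for(inc, rlab)
        rts, upper = simulate_ddm_trials(params, len(idx), rng, dt=dt)
        pos = out.index.get_indexer(idx)
        rt_ms[pos] = rts * 1000.0
        correct[pos] = upper
    out["rt_ms"] = rt_ms
    out["correct"] = correct
    other = np.where(out["larger_side"] == "left", "right", "left")
    out["response"] = np.where(correct, out["larger_side"], other)
    return out


# ---------------------------------------------------------------------------
# Pupil simulation
# ---------------------------------------------------------------------------

def pupil_response_function(
    t_ms: np.ndarray, shape: float = 10.1, t_max_ms: float = 930.0
) -> np.ndarray:
    """Peak-normalized Erlang-gamma kernel h(t) = t^n exp(-n t / t_max).

    Unit peak at ``t_max_ms``; zero for t < 0.
    """
    t = np.asarray(t_ms, dtype=float)
    out = np.zeros_like(t)
    pos = t > 0
    ratio = t[pos] / t_max_ms
    out[pos] = np.exp(shape * (np.log(ratio) + 1.0 - ratio))
    return out


@dataclass(frozen=True)
class PupilSimConfig:
    """Acquisition and noise model for the simulated recording."""

    sampling_rate: float = 250.0  # Hz
    baseline_mm: float = 4.5
    noise_sd_mm: float = 0.01
    blink_rate_hz: float = 0.05  # Poisson arrivals per second
    blink_dur_ms: tuple[float, float] = (80.0, 400.0)
    max_blink_fraction: float = 0.10  # cap on total samples lost to blinks
    pre_roll_ms: float = 1000.0  # recording lead-in before the first trial
    cue_duration_ms: float = 1500.0
    stim_window_ms: float = 3000.0
    feedback_duration_ms: float = 1500.0
    prf_shape: float = 10.1
    prf_t_max_ms: float = 930.0
    amp_subject_sd: float = 0.2  # lognormal sigma of per-participant gain
    amp_trial_sd: float = 0.15  # lognormal sigma of per-trial amplitude jitter

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")

    @property
    def trial_duration_ms(self) -> float:
        return self.cue_duration_ms + self.stim_window_ms + self.feedback_duration_ms


@dataclass
class PupilRecording:
    """One participant's continuous recording plus its event channel."""

    sampling_rate: float
    timestamps: np.ndarray  # ms, uniform
    left: np.ndarray  # mm, NaN = missing
    right: np.ndarray
    events: pd.DataFrame  # columns: time_ms, kind, trial


def _inject_blinks(
    n_samples: int, cfg: PupilSimConfig, rng: np.random.Generator
) -> np.ndarray:
    """Boolean missing mask from Poisson blink arrivals, capped in total."""
    dt_ms = 1000.0 / cfg.sampling_rate
    duration_s = n_samples * dt_ms / 1000.0
    n_blinks = rng.poisson(cfg.blink_rate_hz * duration_s)
    mask = np.zeros(n_samples, dtype=bool)
    budget = int(cfg.max_blink_fraction * n_samples)
    starts = np.sort(rng.uniform(0, n_samples, size=n_blinks)).astype(int)
    for start in starts:
        dur = rng.uniform(*cfg.blink_dur_ms)
        width = max(1, int(round(dur / dt_ms)))
        stop = min(n_samples, start + width)
        segment = mask[start:stop]
        if mask.sum() + (~segment).sum() > budget:
            break
        segment[:] = True
    return mask


def simulate_pupil(
    schedule: pd.DataFrame,
    behavior: pd.DataFrame,
    effects: ConditionEffectTable,
    config: PupilSimConfig | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[dict, pd.DataFrame]:
    """Simulate continuous recordings, one per participant in the schedule.

    Returns ``(recordings, truth)`` where ``recordings`` maps participant id
    to a :class:`PupilRecording` and ``truth`` lists the per-trial, per-phase
    kernel amplitudes actually injected (ground truth for recovery tests).
    """
    config = config or PupilSimConfig()
    rng = rng or np.random.default_rng()
    dt_ms = 1000.0 / config.sampling_rate
    recordings: dict = {}
    truth_rows = []
    phase_event = {"cue": "cue_on", "stimulus": "stim_on", "feedback": "feedback_on"}

    for pid, beh in behavior.groupby("participant", sort=True):
        beh = beh.sort_values(["block", "trial"]).reset_index(drop=True)
        n_trials = len(beh)
        total_ms = config.pre_roll_ms + n_trials * config.trial_duration_ms + 2000.0
        n_samples = int(round(total_ms / dt_ms))
        t_axis = np.arange(n_samples) * dt_ms
        signal = np.full(n_samples, config.baseline_mm)
        subject_gain = float(np.exp(rng.normal(0.0, config.amp_subject_sd)))

        kernel_len = int(round(4 * config.prf_t_max_ms / dt_ms))
        kernel_t = np.arange(kernel_len) * dt_ms
        kernel = pupil_response_function(kernel_t, config.prf_shape, config.prf_t_max_ms)

        event_rows = []
        for i, row in beh.iterrows():
            t0 = config.pre_roll_ms + i * config.trial_duration_ms
            cue_on = t0
            stim_on = t0 + config.cue_duration_ms
            rt = min(float(row["rt_ms"]), config.stim_window_ms)
            response = stim_on + rt
            feedback_on = response
            times = {"cue_on": cue_on, "stim_on": stim_on,
                     "response": response, "feedback_on": feedback_on}
            for kind in EVENT_KINDS:
                event_rows.append({"time_ms": times[kind], "kind": kind,
                                   "trial": int(row.name) + 1})
            for phase in PHASES:
                base_amp = effects.amplitude_for(row["incentive"], row["ratio"], phase)
                amp = base_amp * subject_gain
                if config.amp_trial_sd > 0 and amp > 0:
                    amp *= float(np.exp(rng.normal(0.0, config.amp_trial_sd)))
                onset = times[phase_event[phase]]
                start = int(round(onset / dt_ms))
                stop = min(n_samples, start + kernel_len)
                if stop > start and amp != 0.0:
                    signal[start:stop] += amp * kernel[: stop - start]
                truth_rows.append({"participant": pid, "trial": int(row.name) + 1,
                                   "incentive": row["incentive"], "ratio": row["ratio"],
                                   "phase": phase, "amplitude_mm": amp})

        left = signal + rng.normal(0.0, config.noise_sd_mm, n_samples)
        right = signal + rng.normal(0.0, config.noise_sd_mm, n_samples)
        blink = _inject_blinks(n_samples, config, rng)
        left[blink] = np.nan
        right[blink] = np.nan
        events = pd.DataFrame(event_rows)
        recordings[pid] = PupilRecording(config.sampling_rate, t_axis, left, right, events)

    return recordings, pd.DataFrame(truth_rows)


def noise_free_config(**overrides) -> PupilSimConfig:
    """A PupilSimConfig with noise, blinks and amplitude jitter disabled."""
    base = dict(noise_sd_mm=0.0, blink_rate_hz=0.0, amp_subject_sd=0.0, amp_trial_sd=0.0)
    base.update(overrides)
    return PupilSimConfig(**base)
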
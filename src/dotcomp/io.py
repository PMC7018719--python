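"""File formats, run configuration and the end-to-end pipeline.

All tables are comma-separated UTF-8 text with a header row and ``NA`` as
the missing marker.  A run writes every stage product plus a provenance
block (package version, seed, thresholds, retention accounting) into the
output directory, so any result can be traced back to its inputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .task_design import SessionConfig, generate_session, score_session
from .synthetic_data import (
    ConditionEffectTable,
    PupilRecording,
    PupilSimConfig,
    simulate_behavior,
    simulate_pupil,
)
from .behavior_prep import aggregate_condition, filter_outliers, filter_rt_window
from .ez_ddm import ez_estimate_table
from .pupil_prep import (
    PHASES,
    EpochParams,
    PreprocessParams,
    epoch_phase,
    peak_pd,
    preprocess_trace,
)
from . import stats_inference as si

TRIAL_COLUMNS = ("participant", "block", "trial", "incentive", "ratio",
                 "n_left", "n_right", "response", "correct", "rt_ms")
_CSV_KW = dict(na_rep="NA", index=False)


@dataclass
class RunConfig:
    """One pipeline run.  Thresholds default to the study's stated values."""

    seed: int = 0
    out_dir: str = "dotcomp_out"
    simulate: bool = True
    # design
    n_participants: int = 32
    blocks: int = 32
    trials_per_block: int = 24
    min_dots: int = 12
    max_dots: int = 32
    # behaviour preprocessing
    outlier_sd: float = 3.5
    rt_window_ms: tuple[float, float] = (250.0, 1500.0)
    # EZ
    ez_scale: float = 0.1
    # pupil acquisition + preprocessing
    sampling_rate: float = 250.0
    small_blink_max_ms: float = 500.0
    max_missing_frac: float = 0.25
    max_gap_ms: float = 1000.0
    min_trials_per_condition: int = 10
    # stats
    n_perm: int = 5000
    # inputs when simulate is False
    trials_path: str | None = None
    pupil_dir: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "rt_window_ms" in raw:
            raw["rt_window_ms"] = tuple(raw["rt_window_ms"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["rt_window_ms"] = list(self.rt_window_ms)
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_trials(path: str | Path) -> pd.DataFrame:
    """Read and validate a behavioural trial table."""
    df = pd.read_csv(path, na_values=["NA"])
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trial table {path} is missing required column(s): {missing}")
    bad_rt = df.index[pd.to_numeric(df["rt_ms"], errors="coerce").isna() & df["rt_ms"].notna()]
    if len(bad_rt):
        raise ValueError(f"non-numeric rt_ms at row(s) {list(bad_rt[:5])} of {path}")
    df["rt_ms"] = pd.to_numeric(df["rt_ms"])
    bad_inc = set(df["incentive"].dropna().unique()) - {"reward", "control"}
    if bad_inc:
        raise ValueError(f"invalid incentive value(s) {sorted(bad_inc)} in {path}")
    df["correct"] = df["correct"].astype(bool)
    return df


def write_trials(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, **_CSV_KW)


def write_pupil_recording(rec: PupilRecording, samples_path: str | Path,
                          events_path: str | Path) -> None:
    pd.DataFrame({"time_ms": rec.timestamps, "left_mm": rec.left,
                  "right_mm": rec.right}).to_csv(samples_path, **_CSV_KW)
    rec.events.to_csv(events_path, **_CSV_KW)


def read_pupil_recording(samples_path: str | Path, events_path: str | Path,
                         sampling_rate: float | None = None) -> PupilRecording:
    samples = pd.read_csv(samples_path, na_values=["NA"])
    for col in ("time_ms", "left_mm", "right_mm"):
        if col not in samples.columns:
            raise ValueError(f"pupil samples {samples_path} missing column {col!r}")
    events = pd.read_csv(events_path, na_values=["NA"])
    for col in ("time_ms", "kind", "trial"):
        if col not in events.columns:
            raise ValueError(f"pupil events {events_path} missing column {col!r}")
    t = samples["time_ms"].to_numpy(float)
    if sampling_rate is None:
        if len(t) < 2:
            raise ValueError("cannot infer sampling rate from fewer than 2 samples")
        sampling_rate = 1000.0 / float(np.median(np.diff(t)))
    return PupilRecording(sampling_rate, t, samples["left_mm"].to_numpy(float),
                          samples["right_mm"].to_numpy(float), events)


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

def _trial_info(behavior_one: pd.DataFrame) -> pd.DataFrame:
    """Map sequential trial ordinals (the event channel's ids) to conditions."""
    beh = behavior_one.sort_values(["block", "trial"]).reset_index(drop=True)
    info = beh[["participant", "incentive", "ratio"]].copy()
    info.index = pd.RangeIndex(1, len(beh) + 1, name="trial")
    return info


def _peaks_for_participant(rec, behavior_one, config) -> tuple[pd.DataFrame, list[dict], dict]:
    prep = PreprocessParams(small_blink_max_ms=config.small_blink_max_ms)
    epoch_params = EpochParams(max_missing_frac=config.max_missing_frac,
                               max_gap_ms=config.max_gap_ms,
                               min_trials=config.min_trials_per_condition)
    trace = preprocess_trace(rec, prep)
    info = _trial_info(behavior_one)
    peaks, reports = [], []
    for phase in PHASES:
        epochs, report = epoch_phase(trace, rec.events, phase, trial_info=info,
                                     params=epoch_params)
        report["participant"] = behavior_one["participant"].iloc[0]
        reports.append(report)
        peaks.append(peak_pd(epochs, phase, min_trials=config.min_trials_per_condition))
    return pd.concat(peaks, ignore_index=True), reports, trace.log


def _fit_all_effects(tables: dict[str, tuple[pd.DataFrame, str]]) -> pd.DataFrame:
    rows = []
    for measure, (table, dv) in tables.items():
        try:
            fit = si.fit_condition_lmm(table, dv, variance_components=False)
        except ValueError as exc:
            rows.append({"measure": measure, "term": "all", "F": np.nan, "df1": np.nan,
                         "df2": np.nan, "p": np.nan, "eta_p_sq": np.nan,
                         "method": f"skipped: {exc}"})
            continue
        for e in fit.effects:
            rows.append({"measure": measure, "term": e.term, "F": e.F, "df1": e.df1,
                         "df2": e.df2, "p": e.p, "eta_p_sq": e.eta_p_sq, "method": "lmm"})
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis and write all stage outputs.

    Stages: session/behaviour simulation (or file input), bonus scoring,
    outlier filtering, condition aggregation, EZ estimation, pupil
    preprocessing and peak extraction, mixed-model effects, reward
    modulation and its bonus correlation, and the text report.
    Deterministic given the config seed.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(config.seed)
    seeds = ss.spawn(3)
    effects_table = ConditionEffectTable()

    # --- stage 1-2: trials and behaviour -----------------------------------
    if config.simulate:
        session_cfg_base = dict(blocks=config.blocks,
                                trials_per_block=config.trials_per_block,
                                min_dots=config.min_dots, max_dots=config.max_dots)
        session_seeds = seeds[0].spawn(config.n_participants)
        schedules = [
            generate_session(f"p{i + 1:02d}",
                             SessionConfig(counterbalance_arm=i % 2, **session_cfg_base),
                             seed=session_seeds[i])
            for i in range(config.n_participants)
        ]
        schedule = pd.concat(schedules, ignore_index=True)
        behavior = simulate_behavior(schedule, effects_table,
                                     np.random.default_rng(seeds[1]))
    else:
        if not config.trials_path:
            raise ValueError("simulate is False but no trials_path given")
        behavior = read_trials(config.trials_path)
    write_trials(behavior, out_dir / "trials.csv")

    # --- stage 3: bonus ----------------------------------------------------
    bonus_rows = []
    for pid, grp in behavior.groupby("participant", sort=True):
        score = score_session(grp, grp["correct"].to_numpy())
        bonus_rows.append({"participant": pid, "final_points": score.final_points,
                           "level": score.final_level, "prize": score.prize})
    bonus = pd.DataFrame(bonus_rows)
    bonus.to_csv(out_dir / "bonus.csv", **_CSV_KW)

    # --- stage 4: behaviour preprocessing ----------------------------------
    kept, removal_report = filter_outliers(behavior, config.outlier_sd)
    removal_report.to_csv(out_dir / "removal_report.csv", **_CSV_KW)
    summaries = aggregate_condition(kept)
    summaries.to_csv(out_dir / "condition_summaries.csv", **_CSV_KW)

    # --- stage 5: EZ branch -------------------------------------------------
    ez_trials = filter_rt_window(kept, *config.rt_window_ms)
    ez_summaries = aggregate_condition(ez_trials)
    ez = ez_estimate_table(ez_summaries, s=config.ez_scale)
    ez.to_csv(out_dir / "ez_estimates.csv", **_CSV_KW)

    # --- stage 6: pupil -----------------------------------------------------
    pupil_cfg = PupilSimConfig(sampling_rate=config.sampling_rate)
    if config.simulate:
        recordings, _truth = simulate_pupil(behavior, behavior, effects_table,
                                            pupil_cfg, np.random.default_rng(seeds[2]))
    else:
        if not config.pupil_dir:
            raise ValueError("simulate is False but no pupil_dir given")
        pupil_dir = Path(config.pupil_dir)
        recordings = {}
        for pid in behavior["participant"].unique():
            recordings[pid] = read_pupil_recording(
                pupil_dir / f"samples_{pid}.csv", pupil_dir / f"events_{pid}.csv")
    peak_frames, retention_rows, clean_logs = [], [], {}
    for pid, rec in recordings.items():
        beh_one = behavior[behavior["participant"] == pid]
        if config.simulate:
            write_pupil_recording(rec, out_dir / f"samples_{pid}.csv",
                                  out_dir / f"events_{pid}.csv")
        pk, reports, log = _peaks_for_participant(rec, beh_one, config)
        peak_frames.append(pk)
        retention_rows.extend(reports)
        clean_logs[str(pid)] = log
    peaks = pd.concat(peak_frames, ignore_index=True)
    peaks.to_csv(out_dir / "pupil_peaks.csv", **_CSV_KW)
    retention = pd.DataFrame(retention_rows)
    retention.to_csv(out_dir / "pupil_retention.csv", **_CSV_KW)

    # --- stage 7: inference -------------------------------------------------
    summaries = summaries.assign(mrt_ms=summaries["mrt_s"] * 1000.0,
                                 accuracy_pct=summaries["pc"] * 100.0)
    stat_tables = {
        "rt_ms": (summaries, "mrt_ms"),
        "accuracy": (summaries, "accuracy_pct"),
        "v": (ez[ez["fit_ok"]], "v"),
        "a": (ez[ez["fit_ok"]], "a"),
        "t_er": (ez[ez["fit_ok"]], "t_er"),
    }
    for phase in PHASES:
        stat_tables[f"peak_pd_{phase}"] = (
            peaks[(peaks["phase"] == phase) & peaks["reliable"]], "peak_mm")
    effects = _fit_all_effects(stat_tables)
    effects.to_csv(out_dir / "effects.csv", **_CSV_KW)

    trend_rows = []
    for phase in ("stimulus", "feedback"):
        tab = peaks[(peaks["phase"] == phase) & peaks["reliable"]]
        try:
            tr = si.linear_trend_contrast(tab, "peak_mm")
            trend_rows.append({"phase": phase, "F": tr.F, "df1": tr.df1, "df2": tr.df2,
                               "p": tr.p, "eta_p_sq": tr.eta_p_sq,
                               "estimate": tr.estimate})
        except ValueError as exc:
            trend_rows.append({"phase": phase, "F": np.nan, "df1": np.nan,
                               "df2": np.nan, "p": np.nan, "eta_p_sq": np.nan,
                               "estimate": f"skipped: {exc}"})
    trends = pd.DataFrame(trend_rows)
    trends.to_csv(out_dir / "linear_trends.csv", **_CSV_KW)

    mod_rows = []
    for (pid, phase), grp in peaks[peaks["reliable"]].groupby(["participant", "phase"]):
        by_inc = grp.groupby("incentive")["peak_mm"].mean()
        if {"reward", "control"} <= set(by_inc.index):
            mod_rows.append({"participant": pid, "phase": phase,
                             "m": si.modulation_index(by_inc["reward"], by_inc["control"])})
    modulation = pd.DataFrame(mod_rows)
    modulation.to_csv(out_dir / "modulation.csv", **_CSV_KW)
    if len(modulation):
        correlations = si.spearman_bonus_correlation(
            modulation, bonus.set_index("participant")["level"])
    else:
        correlations = pd.DataFrame(
            columns=["phase", "rho", "p_one_tailed", "n", "flagged", "p_holm"])
    correlations.to_csv(out_dir / "bonus_correlations.csv", **_CSV_KW)

    provenance = {
        "package": "dotcomp",
        "version": __version__,
        "seed": config.seed,
        "config": json.loads(json.dumps(dataclasses.asdict(config), default=str)),
        "retention": {
            "behaviour_input": int(len(behavior)),
            "behaviour_kept": int(len(kept)),
            "behaviour_removed": int(len(behavior) - len(kept)),
            "ez_branch_kept": int(len(ez_trials)),
            "pupil_epochs": {k: int(v) for k, v in
                             retention[["n_input", "n_kept"]].sum().items()}
            if len(retention) else {},
        },
        "clean_logs": clean_logs,
    }
    def _jsonable(obj):
        if isinstance(obj, (np.integer, np.floating)):
            return obj.item()
        return str(obj)

    with open(out_dir / "provenance.json", "w", encoding="utf-8") as fh:
        json.dump(provenance, fh, indent=2, sort_keys=True, default=_jsonable)

    bundle = {
        "trials": behavior, "bonus": bonus, "removal_report": removal_report,
        "summaries": summaries, "ez": ez, "peaks": peaks, "retention": retention,
        "effects": effects, "trends": trends, "modulation": modulation,
        "correlations": correlations, "provenance": provenance,
    }
    report = write_report(bundle, out_dir / "report.txt")
    bundle["report"] = report
    return bundle


def _condition_table(df: pd.DataFrame, dv: str) -> str:
    if df.empty:
        return "  (no data)\n"
    pv = df.pivot_table(index="incentive", columns="ratio", values=dv, aggfunc="mean")
    pv = pv.reindex(index=["reward", "control"],
                    columns=["4:3", "5:4", "8:7", "10:9"])
    return pv.to_string(float_format=lambda x: f"{x:.4g}", na_rep="missing") + "\n"


def write_report(bundle: dict, path: str | Path | None = None) -> str:
    """Human-readable condition-mean tables and the effects summary."""
    lines = ["dotcomp run report", "=" * 60, ""]
    prov = bundle.get("provenance", {})
    lines.append(f"package version: {prov.get('version', '?')}  seed: {prov.get('seed', '?')}")
    lines.append("configuration:")
    for key, val in sorted(prov.get("config", {}).items()):
        lines.append(f"  {key}: {val}")
    lines.append("")
    lines.append("Condition means (rows: incentive, columns: ratio)")
    lines.append("-" * 60)
    summaries = bundle["summaries"]
    for title, frame, dv in [
        ("mean correct RT (ms)", summaries, "mrt_ms"),
        ("accuracy (%)", summaries, "accuracy_pct"),
        ("drift rate v", bundle["ez"][bundle["ez"]["fit_ok"]], "v"),
        ("boundary separation a", bundle["ez"][bundle["ez"]["fit_ok"]], "a"),
        ("non-decision time t_ER (s)", bundle["ez"][bundle["ez"]["fit_ok"]], "t_er"),
    ]:
        lines.append(f"\n{title}:")
        lines.append(_condition_table(frame, dv))
    for phase in PHASES:
        sub = bundle["peaks"]
        sub = sub[(sub["phase"] == phase) & sub["reliable"]]
        lines.append(f"\npeak pupil dilation, {phase} phase (mm):")
        lines.append(_condition_table(sub, "peak_mm"))
    lines.append("\nMixed-model effects")
    lines.append("-" * 60)
    lines.append(bundle["effects"].to_string(index=False, float_format=lambda x: f"{x:.4g}"))
    lines.append("\nLinear trend of Ratio on peak PD")
    lines.append(bundle["trends"].to_string(index=False, float_format=lambda x: f"{x:.4g}"))
    lines.append("\nReward modulation vs bonus level (Spearman)")
    lines.append(bundle["correlations"].to_string(index=False, float_format=lambda x: f"{x:.4g}"))
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text, encoding="utf-8")
    return text
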
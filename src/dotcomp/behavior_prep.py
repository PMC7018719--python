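"""Trial exclusion rules and per-condition aggregation of behaviour.

Two outlier rules run in order on the raw trial table, with statistics
computed once (no iterative re-filtering):

1. correct trials whose RT lies more than 3.5 SD from the participant's own
   mean correct RT are removed;
2. items (unique numerosity pairs including side) whose mean RT lies more
   than 3.5 SD from the sample mean of the items in the same incentive x
   ratio condition are removed.

A separate 250-1500 ms RT window (boundaries inclusive) is applied only on
the diffusion-model branch of the pipeline.  Aggregation yields, per
participant x incentive x ratio cell, the proportion correct Pc over all
kept trials and the mean (MRT) and unbiased variance (VRT) of correct-trial
RTs in seconds -- the three statistics the EZ estimator consumes.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

OUTLIER_SD = 3.5
RT_WINDOW_MS = (250.0, 1500.0)


def filter_outliers(
    trials: pd.DataFrame, sd_criterion: float = OUTLIER_SD
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply both outlier rules; returns (kept trials, removal report).

    The report has one row per rule plus a total, with counts and the
    fraction of the input removed.  Rules never double-count a trial: rule 2
    runs on the survivors of rule 1.
    """
    n_input = len(trials)
    trials = trials.copy()

    # Rule 1: participant-level RT deviation among correct trials.
    drop1 = np.zeros(n_input, dtype=bool)
    correct = trials["correct"].astype(bool).to_numpy()
    for pid, grp in trials.groupby("participant", sort=False):
        mask = grp["correct"].astype(bool)
        rts = grp.loc[mask, "rt_ms"]
        if len(rts) < 2:
            warnings.warn(
                f"participant {pid!r} has fewer than 2 correct trials; "
                "participant-level outlier rule skipped",
                stacklevel=2,
            )
            continue
        mean, sd = rts.mean(), rts.std(ddof=1)
        if sd == 0:
            continue
        bad = rts.index[np.abs(rts - mean) > sd_criterion * sd]
        drop1[trials.index.get_indexer(bad)] = True
    kept1 = trials.loc[~drop1]

    # Rule 2: item-level deviation from the condition sample mean.
    item_cols = ["n_left", "n_right"]
    drop2_idx: list = []
    for (_, _), grp in kept1.groupby(["incentive", "ratio"], sort=False):
        corr = grp[grp["correct"].astype(bool)]
        if corr.empty:
            continue
        item_means = corr.groupby(item_cols)["rt_ms"].mean()
        if len(item_means) < 2:
            continue
        mean, sd = item_means.mean(), item_means.std(ddof=1)
        if sd == 0:
            continue
        bad_items = item_means.index[np.abs(item_means - mean) > sd_criterion * sd]
        if len(bad_items):
            key = pd.MultiIndex.from_frame(grp[item_cols])
            drop2_idx.extend(grp.index[key.isin(bad_items)])
    kept = kept1.drop(index=drop2_idx)

    n_rule1 = int(drop1.sum())
    n_rule2 = len(drop2_idx)
    report = pd.DataFrame(
        {
            "rule": ["participant_rt", "item_condition_rt", "total"],
            "n_removed": [n_rule1, n_rule2, n_rule1 + n_rule2],
            "fraction": [
                n_rule1 / n_input if n_input else 0.0,
                n_rule2 / n_input if n_input else 0.0,
                (n_rule1 + n_rule2) / n_input if n_input else 0.0,
            ],
        }
    )
    return kept, report


def filter_rt_window(
    trials: pd.DataFrame,
    lo_ms: float = RT_WINDOW_MS[0],
    hi_ms: float = RT_WINDOW_MS[1],
) -> pd.DataFrame:
    """Keep trials with lo_ms <= RT <= hi_ms (boundaries inclusive)."""
    rt = trials["rt_ms"]
    return trials.loc[(rt >= lo_ms) & (rt <= hi_ms)]


def aggregate_condition(trials: pd.DataFrame) -> pd.DataFrame:
    """Per participant x incentive x ratio summaries (Pc, MRT, VRT, n).

    Pc is computed over all kept trials of the cell; MRT (s) and VRT (s^2,
    unbiased) over correct kept trials only.  Cells with fewer than two
    correct trials get NaN moments and ``flagged=True``.
    """
    rows = []
    for (pid, inc, rlab), grp in trials.groupby(
        ["participant", "incentive", "ratio"], sort=True
    ):
        correct = grp["correct"].astype(bool)
        rts_s = grp.loc[correct, "rt_ms"].to_numpy() / 1000.0
        n_correct = len(rts_s)
        mrt = float(np.mean(rts_s)) if n_correct >= 1 else np.nan
        vrt = float(np.var(rts_s, ddof=1)) if n_correct >= 2 else np.nan
        rows.append(
            {
                "participant": pid,
                "incentive": inc,
                "ratio": rlab,
                "pc": float(correct.mean()),
                "mrt_s": mrt,
                "vrt_s2": vrt,
                "n": len(grp),
                "n_correct": n_correct,
                "flagged": n_correct < 2,
            }
        )
    return pd.DataFrame(rows)
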
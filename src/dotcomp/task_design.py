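"""Session structure of the incentivized dot-comparison task.

The task is a two-alternative forced choice: on every trial two dot arrays are
shown and the participant picks the side with more dots.  Difficulty is set by
the numerosity ratio between the arrays (4:3 easiest ... 10:9 hardest) and
motivation by a coloured cue announcing whether the trial is rewarded
(correct: +3 points, error: -3 points) or a control trial (always 0 points).
Accumulated points map onto 15 bonus levels which in turn map onto 5 prizes.

This module generates balanced trial schedules for that design and scores the
bonus points; it knows nothing about responses beyond a correctness flag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

RATIO_LABELS = ("4:3", "5:4", "8:7", "10:9")
INCENTIVES = ("reward", "control")
SIDES = ("left", "right")
CUE_COLORS = ("pink", "blue")


@dataclass(frozen=True)
class RatioCondition:
    """One numerosity-ratio difficulty level (e.g. 4:3)."""

    label: str
    numerator: int
    denominator: int

    def __post_init__(self) -> None:
        if not (self.numerator > self.denominator >= 1):
            raise ValueError(f"ratio must satisfy numerator > denominator >= 1: {self}")
        if math.gcd(self.numerator, self.denominator) != 1:
            raise ValueError(f"ratio must be in lowest terms: {self}")
        if self.label != f"{self.numerator}:{self.denominator}":
            raise ValueError(f"label {self.label!r} does not match {self.numerator}:{self.denominator}")

    @classmethod
    def from_label(cls, label: str) -> "RatioCondition":
        try:
            num, den = (int(p) for p in label.split(":"))
        except ValueError as exc:
            raise ValueError(f"malformed ratio label {label!r}") from exc
        return cls(label, num, den)

    @property
    def value(self) -> float:
        return self.numerator / self.denominator


#: The four difficulty levels of the task, easiest first.
RATIO_CONDITIONS = tuple(RatioCondition.from_label(lab) for lab in RATIO_LABELS)


@dataclass(frozen=True)
class BonusScheme:
    """Point values and level structure of the bonus system."""

    points_correct_reward: int = 3
    points_error_reward: int = -3
    points_control: int = 0
    n_levels: int = 15
    n_prizes: int = 5


@dataclass(frozen=True)
class SessionConfig:
    """Design parameters of one session."""

    blocks: int = 32
    trials_per_block: int = 24
    min_dots: int = 12
    max_dots: int = 32
    counterbalance_arm: int = 0  # 0: pink cue = reward; 1: blue cue = reward

    def __post_init__(self) -> None:
        n_cells = len(INCENTIVES) * len(RATIO_CONDITIONS)
        if self.trials_per_block % n_cells != 0:
            raise ValueError(
                f"trials_per_block={self.trials_per_block} not divisible by the "
                f"{n_cells} incentive x ratio cells"
            )
        if self.counterbalance_arm not in (0, 1):
            raise ValueError("counterbalance_arm must be 0 or 1")
        if self.min_dots > self.max_dots or self.min_dots < 1:
            raise ValueError("invalid dot range")


def dot_pair_candidates(
    ratio: RatioCondition, min_dots: int = 12, max_dots: int = 32
) -> set[tuple[int, int]]:
    """All (smaller, larger) dot-count pairs realizing ``ratio`` exactly.

    Pairs are integer multiples k*(denominator, numerator) with both counts in
    ``[min_dots, max_dots]``.  The returned set is exhaustive; it may be empty.
    """
    if not isinstance(ratio, RatioCondition):
        raise TypeError("ratio must be a RatioCondition")
    if min_dots > max_dots:
        raise ValueError("min_dots must not exceed max_dots")
    k_lo = math.ceil(min_dots / ratio.denominator)
    k_hi = math.floor(max_dots / ratio.numerator)
    return {
        (k * ratio.denominator, k * ratio.numerator) for k in range(k_lo, k_hi + 1)
    }


def _cue_for(incentive: str, arm: int) -> str:
    reward_color = CUE_COLORS[arm]
    if incentive == "reward":
        return reward_color
    return CUE_COLORS[1 - arm]


def generate_session(
    participant_id: str | int,
    config: SessionConfig | None = None,
    seed: int | np.random.SeedSequence = 0,
) -> pd.DataFrame:
    """Generate one participant's full trial schedule.

    Every block holds equally many reward and control trials and every ratio
    appears equally often within each incentive; the side holding the larger
    array is counterbalanced (exactly half left) within every incentive x
    ratio cell over the session.  Trial order within a block is randomized.
    Deterministic given ``seed``.
    """
    config = config or SessionConfig()
    rng = np.random.default_rng(seed)
    per_cell_per_block = config.trials_per_block // (len(INCENTIVES) * len(RATIO_CONDITIONS))
    per_cell_total = per_cell_per_block * config.blocks

    candidates = {
        r.label: sorted(dot_pair_candidates(r, config.min_dots, config.max_dots))
        for r in RATIO_CONDITIONS
    }
    for lab, cand in candidates.items():
        if not cand:
            raise ValueError(f"no dot pairs available for ratio {lab} in the configured range")

    # Pre-draw a counterbalanced larger-side sequence per incentive x ratio cell.
    side_pool: dict[tuple[str, str], list[str]] = {}
    for inc in INCENTIVES:
        for r in RATIO_CONDITIONS:
            sides = np.array(
                ["left", "right"] * (per_cell_total // 2)
                + (["left"] if per_cell_total % 2 else [])
            )
            rng.shuffle(sides)
            side_pool[(inc, r.label)] = list(sides)

    rows = []
    for block in range(1, config.blocks + 1):
        block_cells = [
            (inc, r.label)
            for inc in INCENTIVES
            for r in RATIO_CONDITIONS
            for _ in range(per_cell_per_block)
        ]
        order = rng.permutation(len(block_cells))
        for t, idx in enumerate(order, start=1):
            inc, rlab = block_cells[idx]
            side = side_pool[(inc, rlab)].pop()
            cand = candidates[rlab]
            smaller, larger = cand[rng.integers(len(cand))]
            n_left, n_right = (larger, smaller) if side == "left" else (smaller, larger)
            rows.append(
                {
                    "participant": participant_id,
                    "block": block,
                    "trial": t,
                    "incentive": inc,
                    "ratio": rlab,
                    "larger_side": side,
                    "n_left": n_left,
                    "n_right": n_right,
                    "cue_color": _cue_for(inc, config.counterbalance_arm),
                }
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ScoreResult:
    """Outcome of scoring one session against a :class:`BonusScheme`."""

    trajectory: np.ndarray  # cumulative points after each trial
    final_points: int
    final_level: int
    prize: int


def max_attainable_points(n_reward_trials: int, scheme: BonusScheme) -> int:
    return n_reward_trials * scheme.points_correct_reward


def points_to_level(points: int, max_points: int, scheme: BonusScheme) -> int:
    """Map a points total onto a bonus level (1..n_levels).

    Levels are equal-width bins over [0, max_points]; totals below zero floor
    at level 1.  The mapping is non-decreasing in points.
    """
    if max_points <= 0:
        return 1
    width = max_points / scheme.n_levels
    level = 1 + int(max(points, 0) // width)
    return min(scheme.n_levels, level)


def level_to_prize(level: int, scheme: BonusScheme) -> int:
    """Map level 1..15 onto win option 1..5 (three levels per prize)."""
    per_prize = scheme.n_levels // scheme.n_prizes
    return min(scheme.n_prizes, 1 + (level - 1) // per_prize)


def score_session(
    trials: pd.DataFrame,
    outcomes: np.ndarray | pd.Series | list,
    scheme: BonusScheme | None = None,
) -> ScoreResult:
    """Score a session: only reward trials move the points total."""
    scheme = scheme or BonusScheme()
    outcomes = np.asarray(outcomes, dtype=bool)
    if len(outcomes) != len(trials):
        raise ValueError(
            f"outcomes length {len(outcomes)} does not match {len(trials)} trials"
        )
    is_reward = (trials["incentive"] == "reward").to_numpy()
    deltas = np.where(
        is_reward,
        np.where(outcomes, scheme.points_correct_reward, scheme.points_error_reward),
        scheme.points_control,
    )
    trajectory = np.cumsum(deltas)
    final_points = int(trajectory[-1]) if len(trajectory) else 0
    max_points = max_attainable_points(int(is_reward.sum()), scheme)
    level = points_to_level(final_points, max_points, scheme)
    return ScoreResult(trajectory, final_points, level, level_to_prize(level, scheme))
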
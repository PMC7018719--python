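import numpy as np
import pandas as pd
import pytest

from dotcomp.task_design import INCENTIVES, RATIO_LABELS


@pytest.fixture
def rng():
    return np.random.default_rng(20231107)


@pytest.fixture
def cell_table_factory():
    """Balanced participant x incentive x ratio tables with known effects."""

    def make(
        n_participants=32,
        incentive_effect=0.0,
        ratio_slope=0.0,
        subject_sd=1.0,
        noise_sd=1.0,
        seed=0,
    ):
        rng = np.random.default_rng(seed)
        rows = []
        for p in range(n_participants):
            intercept = rng.normal(0.0, subject_sd)
            for inc in INCENTIVES:
                for level, rlab in enumerate(RATIO_LABELS):
                    y = (
                        intercept
                        + (incentive_effect if inc == "reward" else 0.0)
                        + ratio_slope * level
                        + rng.normal(0.0, noise_sd)
                    )
                    rows.append(
                        {"participant": f"p{p:02d}", "incentive": inc,
                         "ratio": rlab, "y": y}
                    )
        return pd.DataFrame(rows)

    return make


@pytest.fixture
def simple_trials():
    """A tiny hand-built trial table covering two participants and two cells."""
    rows = []
    for pid in ("p01", "p02"):
        for i in range(10):
            rows.append(
                {"participant": pid, "block": 1, "trial": i + 1,
                 "incentive": "reward" if i % 2 else "control",
                 "ratio": "4:3", "larger_side": "left",
                 "n_left": 16, "n_right": 12, "cue_color": "pink",
                 "response": "left", "correct": True,
                 "rt_ms": 500.0 + 10 * i}
            )
    return pd.DataFrame(rows)
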
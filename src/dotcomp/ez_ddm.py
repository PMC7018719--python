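"""Closed-form EZ-diffusion estimation and its forward model.

The EZ method inverts three observed statistics of a two-choice cell --
proportion correct Pc, mean correct RT (MRT, s) and variance of correct RTs
(VRT, s^2) -- into the three central diffusion parameters: drift rate v,
boundary separation a and non-decision time t_ER.  With the logit
L = ln(Pc/(1-Pc)) and scale s (0.1 by convention):

    v    = sign(Pc - 1/2) * s * [ L*(Pc^2*L - Pc*L + Pc - 1/2) / VRT ]^(1/4)
    a    = s^2 * L / v
    MDT  = (a / 2v) * (1 - exp(-v a / s^2)) / (1 + exp(-v a / s^2))
    t_ER = MRT - MDT

The forward map (used as the estimator's own consistency check and as the
oracle for the simulator) is, with y = -v*a/s^2:

    Pc  = 1 / (1 + e^y)
    MRT = t_ER + (a / 2v) * (1 - e^y) / (1 + e^y)
    VRT = (a s^2 / 2 v^3) * (2 y e^y - e^{2y} + 1) / (e^y + 1)^2

Pc values at 0, 1/2 or 1 are undefined under the inversion and receive the
standard edge correction of half a trial.  A parametric-bootstrap skewness
band serves as the suitability diagnostic: real data whose correct-RT
skewness falls outside what the fitted pure-diffusion cell can produce are
flagged, the classic symptom of unmodelled drift variability (which biases
the drift rate downward).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic_data import DDMParams, simulate_ddm_trials

DEFAULT_SCALE = 0.1
_V_LIMIT = 1e-9  # |v*a/s^2| below this uses the analytic v->0 limits


@dataclass(frozen=True)
class EZEstimates:
    """Point estimates for one participant x condition cell."""

    v: float
    a: float
    t_er: float
    mdt: float  # mean decision time, s
    s: float


@dataclass
class EZDiagnostics:
    edge_corrected: bool = False
    underestimation_flag: bool | None = None
    skewness_observed: float | None = None
    skewness_predicted_range: tuple[float, float] | None = None


def ez_forward(
    v: float, a: float, t_er: float = 0.0, s: float = DEFAULT_SCALE
) -> tuple[float, float, float]:
    """Predicted (Pc, MRT, VRT) of a pure diffusion cell; v = 0 via limits."""
    if a <= 0:
        raise ValueError("boundary separation a must be positive")
    if s <= 0:
        raise ValueError("scale s must be positive")
    if not np.all(np.isfinite([v, a, t_er, s])):
        raise ValueError("non-finite parameters")
    x = v * a / s**2
    if abs(x) < _V_LIMIT:
        pc = 0.5
        mdt = a**2 / (4 * s**2)
        vrt = a**4 / (24 * s**4)
        return pc, t_er + mdt, vrt
    y = -x
    ey = np.exp(y)
    pc = 1.0 / (1.0 + ey)
    mdt = (a / (2 * v)) * (1 - ey) / (1 + ey)
    vrt = (a * s**2 / (2 * v**3)) * (2 * y * ey - np.exp(2 * y) + 1) / (ey + 1) ** 2
    return float(pc), float(t_er + mdt), float(vrt)


def edge_correct(pc: float, n: int) -> float:
    """Half-a-trial correction for Pc values the inversion cannot handle."""
    if n is None or n < 1:
        raise ValueError("edge correction needs the cell trial count n >= 1")
    if not 0 <= pc <= 1:
        raise ValueError(f"Pc must lie in [0, 1], got {pc}")
    if pc == 1.0:
        return 1.0 - 1.0 / (2 * n)
    if pc == 0.0:
        return 1.0 / (2 * n)
    if pc == 0.5:
        return 0.5 + 1.0 / (2 * n)
    return pc


def ez_estimate(
    pc: float,
    mrt: float,
    vrt: float,
    n: int | None = None,
    s: float = DEFAULT_SCALE,
) -> tuple[EZEstimates, EZDiagnostics]:
    """Invert (Pc, MRT, VRT) into (v, a, t_ER).

    ``n`` (trials entering Pc) enables the edge correction; without it an
    edge Pc raises.  The returned estimates reproduce the corrected inputs
    through :func:`ez_forward` to machine accuracy.
    """
    diag = EZDiagnostics()
    if vrt is None or not np.isfinite(vrt) or vrt <= 0:
        raise ValueError(f"VRT must be positive and finite, got {vrt}")
    if not np.isfinite(mrt):
        raise ValueError("MRT must be finite")
    if pc in (0.0, 0.5, 1.0):
        if n is None:
            raise ValueError(
                f"Pc = {pc} is undefined under the EZ inversion; supply n for edge correction"
            )
        pc = edge_correct(pc, n)
        diag.edge_corrected = True
    if not 0 < pc < 1 or pc == 0.5:
        raise ValueError(f"Pc = {pc} remains at an edge after correction")

    L = np.log(pc / (1 - pc))
    inner = L * (pc**2 * L - pc * L + pc - 0.5) / vrt
    v = float(np.sign(pc - 0.5) * s * inner**0.25)
    a = float(s**2 * L / v)
    x = v * a / s**2
    mdt = float((a / (2 * v)) * (1 - np.exp(-x)) / (1 + np.exp(-x)))
    t_er = float(mrt - mdt)
    return EZEstimates(v=v, a=a, t_er=t_er, mdt=mdt, s=s), diag


def ez_estimate_table(summaries: pd.DataFrame, s: float = DEFAULT_SCALE) -> pd.DataFrame:
    """Vector version over a condition-summary table from behavior_prep.

    One output row per input cell; cells flagged as having too few correct
    trials propagate NaN estimates with ``fit_ok = False``.
    """
    rows = []
    for _, cell in summaries.iterrows():
        base = {
            "participant": cell["participant"],
            "incentive": cell["incentive"],
            "ratio": cell["ratio"],
            "n": cell["n"],
            "pc": cell["pc"],
            "mrt_s": cell["mrt_s"],
            "vrt_s2": cell["vrt_s2"],
        }
        try:
            est, diag = ez_estimate(
                cell["pc"], cell["mrt_s"], cell["vrt_s2"], n=int(cell["n"]), s=s
            )
            base.update(
                v=est.v, a=est.a, t_er=est.t_er, mdt=est.mdt, s=s,
                edge_corrected=diag.edge_corrected, fit_ok=True,
            )
        except (ValueError, ZeroDivisionError):
            base.update(
                v=np.nan, a=np.nan, t_er=np.nan, mdt=np.nan, s=s,
                edge_corrected=False, fit_ok=False,
            )
        rows.append(base)
    return pd.DataFrame(rows)


def suitability_check(
    correct_rts_s: np.ndarray,
    estimates: EZEstimates,
    n_trials: int,
    rng: np.random.Generator,
    n_boot: int = 200,
    band: tuple[float, float] = (2.5, 97.5),
    edge_corrected: bool = False,
) -> EZDiagnostics:
    """Parametric-bootstrap skewness diagnostic for one cell.

    Simulates ``n_boot`` cells of ``n_trials`` trials from the fitted pure
    diffusion and compares the observed correct-RT skewness against the
    central ``band`` percentiles of the simulated skewness distribution.
    Falling outside flags likely drift-rate underestimation.
    """
    correct_rts_s = np.asarray(correct_rts_s, dtype=float)
    if correct_rts_s.size < 2:
        raise ValueError("suitability check needs at least 2 correct trials")
    obs = float(stats.skew(correct_rts_s, bias=False))
    params = DDMParams(v=estimates.v, a=estimates.a, t_er=max(estimates.t_er, 0.0),
                       s=estimates.s)
    # one batched simulation, then split into bootstrap cells
    rts, upper = simulate_ddm_trials(params, n_boot * n_trials, rng)
    rts = rts.reshape(n_boot, n_trials)
    corr_mask = upper.reshape(n_boot, n_trials) if estimates.v >= 0 \
        else ~upper.reshape(n_boot, n_trials)
    sims = np.empty(n_boot)
    for b in range(n_boot):
        corr = rts[b][corr_mask[b]]
        sims[b] = stats.skew(corr, bias=False) if corr.size >= 2 else np.nan
    lo, hi = np.nanpercentile(sims, band)
    return EZDiagnostics(
        edge_corrected=edge_corrected,
        underestimation_flag=bool(obs < lo or obs > hi),
        skewness_observed=obs,
        skewness_predicted_range=(float(lo), float(hi)),
    )
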
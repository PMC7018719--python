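"""Inferential layer: mixed-model F-tests with partial eta squared,
Holm-corrected post-hocs, linear trend contrasts, a within-participant
permutation fallback, the reward-modulation index, rank correlation with the
bonus level, and the repeated-measures power computation.

Design: every dependent variable arrives as one row per participant x
incentive x ratio (32 x 2 x 4 = 256 rows at study scale).  The model is a
linear mixed-effects model with a participant random intercept fitted by
maximum likelihood; F-tests for the within-subject terms use the containment
denominator df, N - n_participants - 7 = 217 for the full design.  On a
balanced complete design those F statistics coincide with the projection
ANOVA that treats participants as fixed blocks, which is how they are
computed here (exactly F-distributed under the null); the ML variance
components are reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .task_design import INCENTIVES, RATIO_LABELS

TERMS = ("Incentive", "Ratio", "Incentive x Ratio")
#: linear polynomial contrast over the 4 ordered ratio levels (easy -> hard)
LINEAR_WEIGHTS = np.array([-3.0, -1.0, 1.0, 3.0])


@dataclass(frozen=True)
class EffectResult:
    term: str
    F: float
    df1: int
    df2: int
    p: float
    eta_p_sq: float


@dataclass
class ConditionModelFit:
    dv: str
    effects: list[EffectResult]
    variance_components: dict = field(default_factory=dict)
    residuals: np.ndarray | None = None
    method: str = "lmm"


def partial_eta_sq(F: float, df1: int, df2: int) -> float:
    """Partial eta squared from an F statistic and its df pair."""
    if F < 0 or df1 < 1 or df2 < 1:
        raise ValueError("need F >= 0 and df >= 1")
    return F * df1 / (F * df1 + df2)


def _cell_array(table: pd.DataFrame, dv: str) -> tuple[np.ndarray, list]:
    """Pivot to y[participant, incentive, ratio]; raises if not complete."""
    pv = table.pivot_table(index="participant", columns=["incentive", "ratio"],
                           values=dv, aggfunc="mean")
    expected = [(i, r) for i in INCENTIVES for r in RATIO_LABELS]
    if pv.isna().any().any() or set(pv.columns) != set(expected):
        raise ValueError("design not balanced/complete")
    pv = pv.reindex(columns=pd.MultiIndex.from_tuples(expected))
    y = pv.to_numpy().reshape(len(pv), len(INCENTIVES), len(RATIO_LABELS))
    return y, list(pv.index)


def _anova_sums(y: np.ndarray) -> dict:
    """Balanced three-way (subject blocks x incentive x ratio) decomposition."""
    n_s, n_i, n_r = y.shape
    grand = y.mean()
    m_s = y.mean(axis=(1, 2))
    m_i = y.mean(axis=(0, 2))
    m_r = y.mean(axis=(0, 1))
    m_ir = y.mean(axis=0)
    ss_s = n_i * n_r * np.sum((m_s - grand) ** 2)
    ss_i = n_s * n_r * np.sum((m_i - grand) ** 2)
    ss_r = n_s * n_i * np.sum((m_r - grand) ** 2)
    ss_ir = n_s * np.sum((m_ir - m_i[:, None] - m_r[None, :] + grand) ** 2)
    ss_tot = np.sum((y - grand) ** 2)
    ss_res = ss_tot - ss_s - ss_i - ss_r - ss_ir
    # containment residual df: N - 1 - (n_s - 1) - (n_i - 1) - (n_r - 1)
    # - (n_i - 1)(n_r - 1)  ->  217 for the 32 x 2 x 4 design
    df_res = n_s * n_i * n_r - n_s - (n_i - 1) - (n_r - 1) - (n_i - 1) * (n_r - 1)
    return {
        "ss": {"Incentive": ss_i, "Ratio": ss_r, "Incentive x Ratio": ss_ir,
               "subject": ss_s, "resid": ss_res, "total": ss_tot},
        "df": {"Incentive": n_i - 1, "Ratio": n_r - 1,
               "Incentive x Ratio": (n_i - 1) * (n_r - 1), "resid": df_res},
    }


def _containment_f(y: np.ndarray) -> list[EffectResult]:
    dec = _anova_sums(y)
    ms_res = dec["ss"]["resid"] / dec["df"]["resid"]
    out = []
    for term in TERMS:
        df1, df2 = dec["df"][term], dec["df"]["resid"]
        F = float((dec["ss"][term] / df1) / ms_res) if ms_res > 0 else np.inf
        p = float(stats.f.sf(F, df1, df2))
        out.append(EffectResult(term, F, df1, df2, p, partial_eta_sq(F, df1, df2)))
    return out


def _residuals(y: np.ndarray) -> np.ndarray:
    """Residuals of the containment model (subject + both factors + interaction)."""
    m_s = y.mean(axis=(1, 2), keepdims=True)
    m_ir = y.mean(axis=0, keepdims=True)
    grand = y.mean()
    return (y - m_s - m_ir + grand).ravel()


def fit_condition_lmm(
    table: pd.DataFrame, dv: str, variance_components: bool = True
) -> ConditionModelFit:
    """Incentive/Ratio/interaction F-tests with containment df and eta_p^2.

    The table must hold one row per participant x incentive x ratio with the
    dependent variable in column ``dv`` and at least two participants.
    """
    if table["participant"].nunique() < 2:
        raise ValueError("need at least 2 participants")
    y, _ = _cell_array(table, dv)
    effects = _containment_f(y)
    vc: dict = {}
    if variance_components:
        try:
            import statsmodels.formula.api as smf

            data = table[["participant", "incentive", "ratio", dv]].dropna().copy()
            data.columns = ["participant", "incentive", "ratio", "y"]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                md = smf.mixedlm("y ~ C(incentive) * C(ratio)", data,
                                 groups=data["participant"])
                fit = md.fit(reml=False)
            vc = {"participant_var": float(fit.cov_re.iloc[0, 0]),
                  "residual_var": float(fit.scale),
                  "loglik": float(fit.llf)}
        except Exception as exc:  # variance components are auxiliary output
            vc = {"error": str(exc)}
    return ConditionModelFit(dv=dv, effects=effects, variance_components=vc,
                             residuals=_residuals(y), method="lmm")


@dataclass(frozen=True)
class TrendResult:
    F: float
    df1: int
    df2: int
    p: float
    eta_p_sq: float
    estimate: float  # signed contrast value; > 0 means dv rises with difficulty
    ss_linear: float
    ss_ratio: float


def linear_trend_contrast(table: pd.DataFrame, dv: str) -> TrendResult:
    """Linear polynomial contrast of the Ratio main effect.

    Weights (-3, -1, 1, 3) over the ordered ratio levels 4:3 -> 10:9, tested
    against the residual of a one-way ``dv ~ ratio`` analysis (df2 = N - 4).
    """
    if not set(table["ratio"]) <= set(RATIO_LABELS):
        raise ValueError(f"ratio labels must be among {RATIO_LABELS}")
    groups = [table.loc[table["ratio"] == r, dv].dropna().to_numpy() for r in RATIO_LABELS]
    sizes = np.array([g.size for g in groups])
    if (sizes < 1).any():
        raise ValueError("every ratio level needs at least one observation")
    if sizes.min() != sizes.max():
        raise ValueError("unbalanced ratio levels are not supported")
    n_per = sizes[0]
    means = np.array([g.mean() for g in groups])
    y_all = np.concatenate(groups)
    grand = y_all.mean()
    ss_ratio = n_per * np.sum((means - grand) ** 2)
    ss_total = np.sum((y_all - grand) ** 2)
    ss_res = ss_total - ss_ratio
    df2 = y_all.size - len(RATIO_LABELS)
    contrast = float(LINEAR_WEIGHTS @ means)
    ss_lin = contrast**2 / (np.sum(LINEAR_WEIGHTS**2) / n_per)
    ms_res = ss_res / df2 if df2 > 0 else 0.0
    F = float(ss_lin / ms_res) if ms_res > 0 else np.inf
    p = float(stats.f.sf(F, 1, df2))
    eta = partial_eta_sq(F, 1, df2) if np.isfinite(F) else 1.0
    return TrendResult(F, 1, df2, p, eta, contrast, float(ss_lin), float(ss_ratio))


def posthoc_pairwise(
    table: pd.DataFrame,
    dv: str,
    factor: str,
    alternative: str = "two-sided",
) -> pd.DataFrame:
    """Paired t-tests between all level pairs of ``factor``, Holm-adjusted.

    Observations are paired by participant (cell means are averaged over any
    other factor first).  ``alternative`` follows scipy ('two-sided',
    'greater', 'less'); directional tests are one-tailed.
    """
    cell = table.groupby(["participant", factor], sort=True)[dv].mean().unstack(factor)
    levels = [l for l in (RATIO_LABELS if factor == "ratio" else INCENTIVES)
              if l in cell.columns]
    rows = []
    for i, la in enumerate(levels):
        for lb in levels[i + 1:]:
            paired = cell[[la, lb]].dropna()
            if len(paired) < 2:
                rows.append({"level_a": la, "level_b": lb, "t": np.nan, "df": np.nan,
                             "p_raw": np.nan, "skipped": True})
                continue
            diffs = (paired[la] - paired[lb]).to_numpy()
            if np.std(diffs, ddof=1) == 0.0 and diffs.mean() == 0.0:
                # identical groups: no evidence against the null
                t, p = 0.0, 1.0 if alternative == "two-sided" else 0.5
            else:
                t, p = stats.ttest_rel(paired[la], paired[lb], alternative=alternative)
            rows.append({"level_a": la, "level_b": lb, "t": float(t),
                         "df": len(paired) - 1, "p_raw": float(p), "skipped": False})
    out = pd.DataFrame(rows)
    out["p_holm"] = holm_adjust(out["p_raw"].to_numpy())
    return out


def holm_adjust(p_values: np.ndarray) -> np.ndarray:
    """Holm step-down adjustment; NaNs pass through untouched."""
    p = np.asarray(p_values, dtype=float)
    out = np.full_like(p, np.nan)
    valid = np.flatnonzero(np.isfinite(p))
    m = valid.size
    if m == 0:
        return out
    order = valid[np.argsort(p[valid])]
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[rank] = min(1.0, running)
    out[order] = adj
    return out


def _within_participant_permutations(flat: np.ndarray, rng, n_perm: int):
    """Yield ``n_perm`` arrays with each row's values shuffled in place of
    one another; rows never exchange values (the exchangeability unit is the
    condition label within a participant)."""
    n_s, n_c = flat.shape
    for _ in range(n_perm):
        yield np.stack([flat[s][rng.permutation(n_c)] for s in range(n_s)])


@dataclass
class PermutationResult:
    p_values: dict
    observed_F: dict
    n_perm: int
    shapiro_w: float
    shapiro_p: float
    residuals_normal: bool


def permutation_fallback(
    table: pd.DataFrame,
    dv: str,
    n_perm: int = 5000,
    seed: int | np.random.Generator = 0,
) -> PermutationResult:
    """Within-participant label-permutation p-values for all three terms.

    Condition labels (the 8 incentive x ratio cells) are shuffled within each
    participant, preserving every participant's multiset of values;
    p = (1 + #{F_perm >= F_obs}) / (1 + n_perm).  A Shapiro-Wilk test on the
    containment-model residuals is reported so callers can decide when the
    fallback is needed.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    y, _ = _cell_array(table, dv)
    n_s, n_i, n_r = y.shape
    obs = {e.term: e.F for e in _containment_f(y)}
    resid = _residuals(y)
    sw = stats.shapiro(resid)
    count = {t: 0 for t in TERMS}
    for perm in _within_participant_permutations(y.reshape(n_s, n_i * n_r),
                                                 rng, n_perm):
        perm_F = _containment_f(perm.reshape(n_s, n_i, n_r))
        for e in perm_F:
            if e.F >= obs[e.term]:
                count[e.term] += 1
    p = {t: (1 + count[t]) / (1 + n_perm) for t in TERMS}
    return PermutationResult(p_values=p, observed_F=obs, n_perm=n_perm,
                             shapiro_w=float(sw.statistic), shapiro_p=float(sw.pvalue),
                             residuals_normal=bool(sw.pvalue > 0.05))


def modulation_index(peak_reward, peak_control):
    """Relative reward modulation: (r - c) / ((r + c) / 2).

    Zero in the absence of a reward effect, antisymmetric under swapping the
    arguments, bounded in (-2, 2) when both peaks are positive.  A zero
    denominator yields NaN.
    """
    r = np.asarray(peak_reward, dtype=float)
    c = np.asarray(peak_control, dtype=float)
    denom = (r + c) / 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        m = np.where(denom == 0, np.nan, (r - c) / denom)
    if m.ndim == 0:
        return float(m)
    return m


def spearman_bonus_correlation(
    modulation: pd.DataFrame, bonus_level: pd.Series
) -> pd.DataFrame:
    """Per-phase Spearman rho between reward modulation and bonus level.

    ``modulation`` holds (participant, phase, m); ``bonus_level`` maps
    participant to the achieved win option (1..5).  One-tailed p for a
    positive association (average-rank ties), Holm-adjusted over the phases.
    """
    rows = []
    for phase, grp in modulation.groupby("phase", sort=True):
        merged = grp.set_index("participant")["m"].to_frame().join(
            bonus_level.rename("level"), how="inner").dropna()
        if len(merged) < 4:
            rows.append({"phase": phase, "rho": np.nan, "p_one_tailed": np.nan,
                         "n": len(merged), "flagged": True})
            continue
        if merged["m"].nunique() == 1 or merged["level"].nunique() == 1:
            rows.append({"phase": phase, "rho": np.nan, "p_one_tailed": np.nan,
                         "n": len(merged), "flagged": True})
            continue
        res = stats.spearmanr(merged["m"], merged["level"], alternative="greater")
        rows.append({"phase": phase, "rho": float(res.statistic),
                     "p_one_tailed": float(res.pvalue), "n": len(merged),
                     "flagged": False})
    out = pd.DataFrame(rows)
    out["p_holm"] = holm_adjust(out["p_one_tailed"].to_numpy())
    return out


@dataclass(frozen=True)
class PowerSpec:
    """Inputs of the repeated-measures power computation."""

    f: float = 0.70  # Cohen's f for the within factor
    m: int = 2  # number of measurements
    rho: float = 0.0  # correlation among measurements
    alpha: float = 0.05
    target_power: float = 0.95

    def __post_init__(self) -> None:
        if self.f <= 0 or self.m < 2:
            raise ValueError("need f > 0 and m >= 2")
        if not 0 <= self.rho < 1:
            raise ValueError("need 0 <= rho < 1")
        if not (0 < self.alpha < 1 and 0 < self.target_power < 1):
            raise ValueError("alpha and target_power must lie in (0, 1)")


def repeated_measures_power(n: int, spec: PowerSpec) -> float:
    """Power of the within-factor F-test at sample size ``n``.

    Noncentral F with df1 = m - 1, df2 = (n - 1)(m - 1) and noncentrality
    lambda = f^2 * n * m / (1 + (m - 1) * rho).
    """
    df1 = spec.m - 1
    df2 = (n - 1) * (spec.m - 1)
    if df2 < 1:
        return 0.0
    lam = spec.f**2 * n * spec.m / (1 + (spec.m - 1) * spec.rho)
    crit = stats.f.ppf(1 - spec.alpha, df1, df2)
    return float(stats.ncf.sf(crit, df1, df2, lam))


def required_sample_size(spec: PowerSpec | None = None, n_max: int = 10**6, **kwargs) -> int:
    """Smallest n whose repeated-measures power reaches the target."""
    spec = spec or PowerSpec(**kwargs)
    for n in range(2, n_max + 1):
        if repeated_measures_power(n, spec) >= spec.target_power:
            return n
    raise ValueError(f"target power {spec.target_power} not attainable below n = {n_max}")
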
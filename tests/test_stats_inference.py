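"""Mixed-model F-tests, effect sizes, post-hocs, permutations, power."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dotcomp.stats_inference import (
    PowerSpec,
    fit_condition_lmm,
    holm_adjust,
    linear_trend_contrast,
    modulation_index,
    partial_eta_sq,
    permutation_fallback,
    posthoc_pairwise,
    repeated_measures_power,
    required_sample_size,
    spearman_bonus_correlation,
)


class TestPartialEtaSq:
    def test_printed_value_scale(self):
        assert partial_eta_sq(117.00, 1, 217) == pytest.approx(0.3503, abs=1e-4)
        assert partial_eta_sq(0.0, 1, 217) == 0.0

    @settings(max_examples=50, deadline=None)
    @given(F=st.floats(min_value=0, max_value=1e4),
           df1=st.integers(1, 10), df2=st.integers(1, 500))
    def test_bounded_and_monotone(self, F, df1, df2):
        eta = partial_eta_sq(F, df1, df2)
        assert 0.0 <= eta < 1.0
        assert partial_eta_sq(F + 1.0, df1, df2) > eta


class TestConditionModel:
    def test_full_design_df_pair(self, cell_table_factory):
        fit = fit_condition_lmm(cell_table_factory(32), "y")
        dfs = {e.term: (e.df1, e.df2) for e in fit.effects}
        assert dfs["Incentive"] == (1, 217)
        assert dfs["Ratio"] == (3, 217)
        assert dfs["Incentive x Ratio"] == (3, 217)
        assert {"participant_var", "residual_var"} <= set(fit.variance_components)

    def test_variance_components_recovered(self, cell_table_factory):
        tab = cell_table_factory(40, subject_sd=2.0, noise_sd=0.5, seed=3)
        fit = fit_condition_lmm(tab, "y")
        assert fit.variance_components["participant_var"] == pytest.approx(4.0, rel=0.5)
        assert fit.variance_components["residual_var"] == pytest.approx(0.25, rel=0.3)

    def test_detects_injected_incentive_effect(self, cell_table_factory):
        tab = cell_table_factory(32, incentive_effect=1.0, noise_sd=1.0, seed=5)
        fit = fit_condition_lmm(tab, "y", variance_components=False)
        eff = {e.term: e for e in fit.effects}
        assert eff["Incentive"].p < 0.05
        assert eff["Incentive"].eta_p_sq == pytest.approx(
            partial_eta_sq(eff["Incentive"].F, 1, 217))

    def test_requires_two_participants(self, cell_table_factory):
        with pytest.raises(ValueError, match="2 participants"):
            fit_condition_lmm(cell_table_factory(1), "y")


class TestLinearTrend:
    def test_pure_linear_means_capture_all_ratio_ss(self, cell_table_factory):
        tab = cell_table_factory(8, ratio_slope=1.0, subject_sd=0.0, noise_sd=0.0)
        tr = linear_trend_contrast(tab, "y")
        assert tr.ss_linear == pytest.approx(tr.ss_ratio)
        assert tr.estimate > 0

    def test_detects_noisy_linear_trend(self, cell_table_factory):
        hits = 0
        for seed in range(20):
            tab = cell_table_factory(32, ratio_slope=0.3, subject_sd=0.5,
                                     noise_sd=0.5, seed=100 + seed)
            tr = linear_trend_contrast(tab, "y")
            hits += (tr.p < 0.05) and (tr.estimate > 0)
        assert hits >= 18  # > 90% of replicates

    def test_unknown_ratio_levels_rejected(self, cell_table_factory):
        tab = cell_table_factory(4)
        tab.loc[0, "ratio"] = "2:1"
        with pytest.raises(ValueError, match="ratio labels"):
            linear_trend_contrast(tab, "y")


class TestHolm:
    def test_worked_example(self):
        np.testing.assert_allclose(holm_adjust(np.array([0.01, 0.02, 0.03])),
                                   [0.03, 0.04, 0.04])

    def test_single_comparison_unchanged(self):
        np.testing.assert_allclose(holm_adjust(np.array([0.2])), [0.2])

    @settings(max_examples=80, deadline=None)
    @given(ps=st.lists(st.floats(min_value=1e-9, max_value=1.0), min_size=1,
                       max_size=8))
    def test_adjusted_never_below_raw_and_monotone(self, ps):
        p = np.array(ps)
        adj = holm_adjust(p)
        assert (adj >= p - 1e-15).all() and (adj <= 1.0).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-15).all()


class TestPosthoc:
    def test_identical_groups_null(self, cell_table_factory):
        tab = cell_table_factory(10, seed=2)
        # make both incentive levels identical per participant
        piv = tab.pivot_table(index=["participant", "ratio"], columns="incentive",
                              values="y").reset_index()
        piv["control"] = piv["reward"]
        long = piv.melt(id_vars=["participant", "ratio"], var_name="incentive",
                        value_name="y")
        out = posthoc_pairwise(long, "y", "incentive")
        assert out["t"].item() == pytest.approx(0.0, abs=1e-12)
        assert out["p_raw"].item() == pytest.approx(1.0)

    def test_directional_alternative_and_holm_family(self, cell_table_factory):
        tab = cell_table_factory(20, ratio_slope=0.8, noise_sd=0.3, seed=9)
        out = posthoc_pairwise(tab, "y", "ratio", alternative="less")
        assert len(out) == 6  # 4 choose 2
        assert (out["p_holm"] >= out["p_raw"] - 1e-15).all()
        # easiest vs hardest has the strongest (negative-direction) evidence
        row = out[(out["level_a"] == "4:3") & (out["level_b"] == "10:9")]
        assert row["p_holm"].item() < 0.01


class TestPermutation:
    def test_agrees_with_parametric_on_gaussian_data(self, cell_table_factory):
        tab = cell_table_factory(32, incentive_effect=0.25, seed=11)
        fit = fit_condition_lmm(tab, "y", variance_components=False)
        res = permutation_fallback(tab, "y", n_perm=5000, seed=1)
        for e in fit.effects:
            assert res.p_values[e.term] == pytest.approx(e.p, abs=0.02)
        assert res.residuals_normal  # Gaussian generator

    def test_shuffling_preserves_participant_multisets(self):
        """Every permutation rearranges values within a participant only."""
        from dotcomp.stats_inference import _within_participant_permutations

        rng = np.random.default_rng(0)
        flat = rng.normal(size=(6, 8))
        seen_different = False
        for perm in _within_participant_permutations(flat, rng, 50):
            for s in range(6):
                assert sorted(perm[s]) == sorted(flat[s])
            seen_different |= not np.array_equal(perm, flat)
        assert seen_different

    def test_minimum_permutations_enforced(self, cell_table_factory):
        with pytest.raises(ValueError, match="at least 100"):
            permutation_fallback(cell_table_factory(4), "y", n_perm=10)


class TestModulation:
    def test_worked_examples(self):
        assert modulation_index(3.0, 1.0) == pytest.approx(1.0)
        assert modulation_index(2.5, 2.5) == 0.0
        assert np.isnan(modulation_index(1.0, -1.0))

    @settings(max_examples=50, deadline=None)
    @given(r=st.floats(min_value=0.01, max_value=5.0),
           c=st.floats(min_value=0.01, max_value=5.0))
    def test_antisymmetric_and_bounded(self, r, c):
        m = modulation_index(r, c)
        assert modulation_index(c, r) == pytest.approx(-m, rel=1e-9)
        assert -2.0 < m < 2.0


class TestSpearman:
    def _frame(self, ms):
        return pd.DataFrame({"participant": [f"p{i}" for i in range(len(ms))],
                             "phase": "cue", "m": ms})

    def test_monotone_and_antimonotone(self):
        levels = pd.Series([1, 2, 3, 4, 5],
                           index=[f"p{i}" for i in range(5)])
        up = spearman_bonus_correlation(self._frame([0.1, 0.2, 0.3, 0.4, 0.5]), levels)
        assert up["rho"].item() == pytest.approx(1.0)
        assert up["p_one_tailed"].item() < 0.05
        down = spearman_bonus_correlation(self._frame([0.5, 0.4, 0.3, 0.2, 0.1]), levels)
        assert down["rho"].item() == pytest.approx(-1.0)
        assert down["p_one_tailed"].item() > 0.95

    def test_constant_vector_flagged(self):
        levels = pd.Series([1, 2, 3, 4, 5], index=[f"p{i}" for i in range(5)])
        out = spearman_bonus_correlation(self._frame([0.2] * 5), levels)
        assert out["flagged"].item() and np.isnan(out["rho"].item())

    def test_holm_over_phases(self):
        levels = pd.Series([1, 2, 3, 4, 5], index=[f"p{i}" for i in range(5)])
        frames = []
        for phase in ("cue", "stimulus", "feedback"):
            f = self._frame([0.1, 0.2, 0.3, 0.4, 0.5])
            f["phase"] = phase
            frames.append(f)
        out = spearman_bonus_correlation(pd.concat(frames), levels)
        assert len(out) == 3
        assert (out["p_holm"] >= out["p_one_tailed"] - 1e-15).all()


class TestPower:
    def test_monotone_in_effect_size_and_target(self):
        n_ref = required_sample_size(PowerSpec(f=0.70))
        assert required_sample_size(PowerSpec(f=1.0)) <= n_ref
        assert required_sample_size(PowerSpec(f=0.70, target_power=0.50)) <= n_ref

    def test_power_increases_with_n(self):
        spec = PowerSpec(f=0.5)
        powers = [repeated_measures_power(n, spec) for n in range(4, 40, 4)]
        assert all(np.diff(powers) > 0)

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            PowerSpec(f=0.0)
        with pytest.raises(ValueError):
            PowerSpec(rho=1.0)
        with pytest.raises(ValueError):
            PowerSpec(alpha=0.0)
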
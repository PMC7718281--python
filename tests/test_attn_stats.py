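"""AMI arithmetic, its invariances, and the group-level statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

import attnmod as am
from attnmod import attn_stats


class TestComputeAMI:
    @pytest.mark.parametrize("constant", [0.0, 0.1, 0.2, 0.4])
    @pytest.mark.parametrize("level", [0.05, 0.5, 2.0])
    def test_equal_amplitudes_give_exactly_one(self, constant, level):
        """No modulation <=> AMI = 1, for any constant and overall level."""
        assert attn_stats.compute_ami(level, level, level, level, constant) == 1.0

    def test_worked_example(self):
        # (0.3+0.2) / mean(0.5, 0.3, 0.3, 0.3) = 0.5 / 0.35
        assert attn_stats.compute_ami(0.3, 0.1, 0.1, 0.1, 0.2) == pytest.approx(0.5 / 0.35)

    def test_scale_invariant_at_zero_constant(self):
        a = attn_stats.compute_ami(0.4, 0.2, 0.3, 0.1, 0.0)
        b = attn_stats.compute_ami(4.0, 2.0, 3.0, 1.0, 0.0)
        assert a == pytest.approx(b)

    def test_ami_approaches_one_monotonically_as_constant_grows(self):
        constants = [0.0, 0.5, 1.0, 5.0, 50.0]
        vals = [attn_stats.compute_ami(0.6, 0.2, 0.2, 0.2, c) for c in constants]
        gaps = np.abs(np.asarray(vals) - 1.0)
        assert np.all(np.diff(gaps) < 0)

    def test_nonpositive_denominator_rejected_with_guidance(self):
        with pytest.raises(ValueError, match="constant"):
            attn_stats.compute_ami(-0.5, -0.5, -0.5, -0.5, 0.2)

    @given(
        amps=st.tuples(*[st.floats(-0.15, 2.0) for _ in range(4)]),
        constant=st.floats(0.2, 1.0),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_numerator_rotation_conserves_sum_of_four(self, amps, constant):
        """Sum over the four numerator choices is exactly 4."""
        total = sum(
            attn_stats.compute_ami(*amps, constant, numerator=num)
            for num in attn_stats.NUMERATOR_CONDITIONS
        )
        assert total == pytest.approx(4.0, abs=1e-12)


class TestAmiTable:
    def test_table_structure_and_values(self, amplitude_table_flat):
        table = attn_stats.ami_table(amplitude_table_flat, constant=0.2)
        assert len(table) == 5 * 6 * 2 * 2
        # flat construction: Vc = 0.7, Ic = 0.5, Vi = Ii = 0.25 (+ participant bump)
        assert (table["Vc"] > table["Ic"]).all()
        assert (table["ami_valid"] > table["ami_invalid"]).all()
        assert (table["ami_diff"] > 0).all()
        assert (table["constant_used"] == 0.2).all()

    def test_ipsilateral_terms_average_epochs_by_default(self, amplitude_table_flat):
        mod = amplitude_table_flat.copy()
        # make ipsilateral valid betas epoch-dependent
        mask = (mod["laterality"] == "ipsilateral") & (mod["cue_epoch"] == "post")
        mod.loc[mask, "beta_psc"] += 0.1
        default = attn_stats.ami_table(mod)
        specific = attn_stats.ami_table(mod, ipsi_epoch_specific=True)
        assert not np.allclose(default["Vi"], specific["Vi"])
        pre = default[default["cue_epoch"] == "pre"]["Vi"].to_numpy()
        post = default[default["cue_epoch"] == "post"]["Vi"].to_numpy()
        np.testing.assert_allclose(pre, post)  # shared epoch-averaged term


class TestAmiVsOne:
    def test_null_case(self):
        df = pd.DataFrame(
            {"participant": ["a", "b", "c"], "ami_valid": [1.0, 1.0, 1.0]}
        )
        res = attn_stats.ami_vs_one_test(df)
        assert res.degenerate  # zero spread is reported, not an infinite t

    def test_matches_closed_form(self):
        means = [1.1, 1.2, 1.15, 1.25, 1.3]
        df = pd.DataFrame({"participant": list("abcde"), "ami_valid": means})
        res = attn_stats.ami_vs_one_test(df)
        m, s = np.mean(means), np.std(means, ddof=1)
        t_expected = (m - 1) / (s / np.sqrt(5))
        assert res.t == pytest.approx(t_expected, abs=1e-10)
        assert res.cohens_d == pytest.approx((m - 1) / s, abs=1e-10)
        assert res.df == 4
        assert res.p == pytest.approx(2 * sps.t.sf(t_expected, 4), abs=1e-10)

    def test_requires_two_participants(self):
        df = pd.DataFrame({"participant": ["a"], "ami_valid": [1.2]})
        with pytest.raises(ValueError):
            attn_stats.ami_vs_one_test(df)


class TestPerRoiTests:
    def test_equal_valid_invalid_gives_half(self, amplitude_table_flat):
        table = attn_stats.ami_table(amplitude_table_flat)
        table["ami_invalid"] = table["ami_valid"]
        res = attn_stats.per_roi_validity_tests(table)
        assert np.allclose(res["p"], 0.5)

    def test_unpaired_data_rejected(self, amplitude_table_flat):
        table = attn_stats.ami_table(amplitude_table_flat)
        dup = pd.concat([table, table.iloc[:1]], ignore_index=True)
        with pytest.raises(ValueError, match="unpaired"):
            attn_stats.per_roi_validity_tests(dup)

    def test_flat_positive_effect_detected_everywhere(self, amplitude_table_flat):
        table = attn_stats.ami_table(amplitude_table_flat)
        res = attn_stats.per_roi_validity_tests(table)
        assert (res["p"] < 0.05).all()

    def test_holm_correction_is_monotone(self, amplitude_table_flat):
        table = attn_stats.ami_table(amplitude_table_flat)
        res = attn_stats.per_roi_validity_tests(table, correction="holm")
        assert (res["p_corrected"] >= res["p"] - 1e-15).all()

    def test_type_one_error_rate_under_null(self):
        """Null AMI differences reject at ~ the nominal 5% level."""
        rng = np.random.default_rng(6)
        n_reps, hits, cells = 300, 0, 0
        for _ in range(n_reps):
            df = pd.DataFrame(
                {
                    "participant": np.repeat([f"P{i}" for i in range(5)], 6),
                    "attention_type": "exogenous",
                    "cue_epoch": "post",
                    "roi": list(am.ROIS) * 5,
                    "ami_valid": 1 + 0.1 * rng.standard_normal(30),
                    "ami_invalid": 1 + 0.1 * rng.standard_normal(30),
                }
            )
            res = attn_stats.per_roi_validity_tests(df)
            hits += (res["p"] < 0.05).sum()
            cells += len(res)
        rate = hits / cells
        assert rate == pytest.approx(0.05, abs=0.02)


class TestHierarchyRegression:
    def _table(self, diffs):
        rows = []
        for roi, d in zip(am.ROIS, diffs):
            rows.append(
                {
                    "participant": "P1",
                    "roi": roi,
                    "hierarchy_rank": am.HIERARCHY_RANK[roi],
                    "attention_type": "endogenous",
                    "cue_epoch": "pre",
                    "ami_diff": d,
                }
            )
        return pd.DataFrame(rows)

    def test_perfect_line_gives_r2_one(self):
        res = attn_stats.hierarchy_regression(
            self._table([0.1 * r for r in range(1, 7)]), "endogenous", "pre"
        )
        assert res.r2 == pytest.approx(1.0)
        assert res.slope == pytest.approx(0.1)
        assert res.p < 1e-20

    def test_constant_differences_give_zero_slope(self):
        res = attn_stats.hierarchy_regression(
            self._table([0.2] * 6), "endogenous", "pre"
        )
        assert res.slope == pytest.approx(0.0)
        assert res.r2 == pytest.approx(0.0)

    def test_matches_independent_least_squares_oracle(self):
        diffs = [0.01, 0.02, 0.03, 0.05, 0.06, 0.08]
        res = attn_stats.hierarchy_regression(self._table(diffs), "endogenous", "pre")
        oracle = sps.linregress(np.arange(1, 7), diffs)
        assert res.slope == pytest.approx(oracle.slope, abs=1e-10)
        assert res.intercept == pytest.approx(oracle.intercept, abs=1e-10)
        assert res.r2 == pytest.approx(oracle.rvalue**2, abs=1e-10)
        assert res.F == pytest.approx(
            oracle.rvalue**2 / (1 - oracle.rvalue**2) * 4, rel=1e-9
        )
        assert res.p == pytest.approx(oracle.pvalue, abs=1e-10)
        assert res.df == (1, 4)

    def test_too_few_rois_rejected(self):
        table = self._table([0.1] * 6)
        with pytest.raises(ValueError, match="3 ROIs"):
            attn_stats.hierarchy_regression(
                table[table["hierarchy_rank"] <= 2], "endogenous", "pre"
            )


class TestLateralityAnova:
    def test_contralateral_boost_detected(self, amplitude_table_flat):
        res = attn_stats.laterality_anova(amplitude_table_flat, "endogenous")
        res = res.set_index("effect")
        assert res.loc["laterality", "p"] < 1e-6

    def test_incomplete_cells_named(self, amplitude_table_flat):
        broken = amplitude_table_flat[
            ~(
                (amplitude_table_flat["participant"] == "P2")
                & (amplitude_table_flat["roi"] == "hV4")
                & (amplitude_table_flat["laterality"] == "ipsilateral")
            )
        ]
        with pytest.raises(ValueError, match="P2"):
            attn_stats.laterality_anova(broken, "endogenous")


def _mixed_input(slope_endo=0.1, slope_exo=0.0, noise_sd=0.0, seed=0,
                 intercept=0.0, n_participants=5):
    rng = np.random.default_rng(seed)
    rows = []
    for p in range(n_participants):
        for attention, s in (("endogenous", slope_endo), ("exogenous", slope_exo)):
            for roi in am.ROIS:
                rank = am.HIERARCHY_RANK[roi]
                rows.append(
                    {
                        "participant": f"P{p}",
                        "roi": roi,
                        "hierarchy_rank": rank,
                        "attention_type": attention,
                        "cue_epoch": "pre",
                        "ami_diff": intercept + s * rank + noise_sd * rng.standard_normal(),
                    }
                )
    return pd.DataFrame(rows)


class TestMixedModel:
    def test_noiseless_fixed_effects_closed_form(self):
        """With zero random variance the interaction equals the slope difference
        and the rank effect the mean slope, under +/- 1/2 attention coding."""
        df = _mixed_input(slope_endo=0.1, slope_exo=0.02)
        res = attn_stats.fit_mixed_model(df, "pre")
        assert res.estimates["rank_x_attention"] == pytest.approx(0.08, abs=1e-6)
        assert res.estimates["rank"] == pytest.approx(0.06, abs=1e-6)
        assert res.singular  # zero variance is flagged, not hidden

    def test_interaction_detected_with_noise(self):
        df = _mixed_input(slope_endo=0.1, slope_exo=0.0, noise_sd=0.02, seed=3)
        res = attn_stats.fit_mixed_model(df, "pre")
        assert res.lrt_p["rank_x_attention"] < 0.05
        assert res.lrt_p["rank"] < 0.05
        assert res.df_t == 56

    def test_flat_regime_shows_intercept_only(self):
        df = _mixed_input(
            slope_endo=0.0, slope_exo=0.0, intercept=0.2, noise_sd=0.02, seed=4
        )
        res = attn_stats.fit_mixed_model(df, "pre")
        assert res.lrt_p["intercept"] < 1e-6
        # rank and interaction estimates are noise-level, far below the intercept
        assert abs(res.estimates["rank"]) < 0.02
        assert abs(res.estimates["rank_x_attention"]) < 0.02
        assert res.estimates["intercept"] == pytest.approx(0.2, abs=0.05)

    def test_missing_cells_rejected(self):
        df = _mixed_input().iloc[:-1]
        with pytest.raises(ValueError, match="observations"):
            attn_stats.fit_mixed_model(df, "pre")


class TestSensitivity:
    def test_flat_effect_pattern_is_constant_invariant(self, amplitude_table_flat):
        res = attn_stats.ami_sensitivity(amplitude_table_flat, constants=[0.1, 0.2, 0.4])
        assert res["pattern_invariant"].all()
        # a flat (rank-independent) effect never yields a significant slope by design
        assert len(res) == 3 * 4
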
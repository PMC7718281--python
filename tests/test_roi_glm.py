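"""Preprocessing filters, ROI averaging, design structure and OLS recovery."""

import numpy as np
import pandas as pd
import pytest

import attnmod as am
from attnmod import bold_synth, roi_glm


def _wrap(data, tr=1.75, n_discard=8):
    meta = pd.DataFrame(
        {"roi": ["V1"] * data.shape[0], "hemisphere": "left", "responsive": True}
    )
    return bold_synth.VoxelTimeSeries(
        data=data, tr=tr, run_id="test", n_discard=n_discard, voxel_meta=meta
    )


class TestPreprocess:
    def test_discard_arithmetic(self):
        ts = _wrap(100 + np.random.default_rng(0).normal(0, 1, (2, 160)))
        out = am.preprocess_run(ts)
        assert out.n_timepoints == 152
        assert out.units == "psc"

    def test_linear_ramp_removed(self):
        ramp = 100 + np.linspace(0, 5, 160)[None, :]
        out = am.preprocess_run(_wrap(np.repeat(ramp, 3, axis=0)))
        np.testing.assert_allclose(out.data, 0.0, atol=1e-10)

    def test_slow_oscillation_attenuated(self):
        """Power at 0.001 Hz drops by >= 90% through the 0.01 Hz high-pass."""
        t = np.arange(600) * 1.75
        slow = np.sin(2 * np.pi * 0.001 * t)
        ts = _wrap(100.0 * (1 + slow[None, :] / 100.0), n_discard=0)
        out = am.preprocess_run(ts, n_discard=0)
        power_in = np.sum(slow**2)
        assert np.sum(out.data[0] ** 2) < 0.1 * power_in

    def test_passband_signal_survives(self):
        t = np.arange(600) * 1.75
        fast = np.sin(2 * np.pi * 0.05 * t)  # well above cutoff
        ts = _wrap(100.0 * (1 + fast[None, :] / 100.0), n_discard=0)
        out = am.preprocess_run(ts, n_discard=0)
        assert np.sum(out.data[0] ** 2) > 0.9 * np.sum(fast**2)

    def test_too_short_run_rejected(self):
        with pytest.raises(ValueError, match="volumes"):
            am.preprocess_run(_wrap(np.ones((1, 20)) * 100))


class TestRoiAverage:
    def test_identical_voxels_equal_any_single(self):
        x = np.random.default_rng(1).normal(0, 1, 50)
        ts = _wrap(np.tile(x, (4, 1)), n_discard=0)
        avg = roi_glm.average_roi_timecourse(ts, None, "V1", "left")
        np.testing.assert_allclose(avg, x, atol=1e-12)

    def test_opposite_signals_cancel(self):
        x = np.random.default_rng(2).normal(0, 1, 50)
        ts = _wrap(np.vstack([x, -x]), n_discard=0)
        avg = roi_glm.average_roi_timecourse(ts, None, "V1", "left")
        np.testing.assert_allclose(avg, 0.0, atol=1e-12)

    def test_absent_roi_rejected(self):
        ts = _wrap(np.ones((2, 50)), n_discard=0)
        with pytest.raises(ValueError, match="hV4"):
            roi_glm.average_roi_timecourse(ts, None, "hV4", "left")

    def test_empty_selection_falls_back_with_warning(self):
        ts = _wrap(np.ones((2, 50)), n_discard=0)
        fits = pd.DataFrame({"amplitude": [1, 1], "phase": [5.0, 5.0], "coherence": [0.9, 0.9]})
        sel = am.select_voxels(fits, ts.voxel_meta)
        with pytest.warns(UserWarning, match="averaging all"):
            avg = roi_glm.average_roi_timecourse(ts, sel, "V1", "left")
        np.testing.assert_allclose(avg, 1.0)

    def test_selection_restriction_improves_contrast_to_noise(self, small_session):
        """Averaging only responsive voxels beats averaging the whole ROI."""
        gt = am.make_ground_truth("endogenous", "flat", "flat")
        noise = am.NoiseParams(0.0, 0.0, 0.8)
        run = am.simulate_attention_run(
            small_session.runs[0], small_session, gt, noise, seed=8,
            n_voxels_per_roi=20, responsive_frac=0.5, voxel_gain_sd=0.0,
        )
        pre = am.preprocess_run(run, baseline=100.0)
        truth_mask = run.voxel_meta["responsive"]
        fits = pd.DataFrame(
            {
                "amplitude": 1.0,
                "phase": np.where(truth_mask, 1.5, 5.0),
                "coherence": np.where(truth_mask, 0.9, 0.9),
            }
        )
        sel = am.select_voxels(fits, run.voxel_meta)
        design = am.build_design_matrix(small_session, [small_session.runs[0]])
        y_sel = roi_glm.average_roi_timecourse(pre, sel, "V1", "right")
        y_all = roi_glm.average_roi_timecourse(pre, None, "V1", "right")
        fit_sel = am.estimate_amplitudes(y_sel, design)
        fit_all = am.estimate_amplitudes(y_all, design)
        snr_sel = fit_sel.betas["left_valid_pre"] / np.sqrt(fit_sel.sigma2)
        snr_all = fit_all.betas["left_valid_pre"] / np.sqrt(fit_all.sigma2)
        assert snr_sel > snr_all


class TestDesignMatrix:
    def test_twelve_task_regressors(self, small_session):
        d = am.build_design_matrix(small_session)
        assert len(d.task_names) == 12
        assert set(bold_synth.GLM_REGRESSORS) == set(d.task_names)
        assert d.matrix.shape[1] == 12 + small_session.n_runs

    def test_no_exclusions_flags_eye_movement_column(self, small_session):
        d = am.build_design_matrix(small_session)  # no trial excluded
        assert "eye_movement" in d.empty_columns
        assert not np.any(d.column("eye_movement"))

    def test_full_column_rank(self, small_session):
        d = am.build_design_matrix(small_session)
        keep = [i for i, n in enumerate(d.names) if n not in d.empty_columns]
        X = d.matrix[:, keep]
        assert np.linalg.matrix_rank(X) == X.shape[1]

    def test_correct_only_moves_incorrect_trials(self, small_session, observer):
        sim = am.simulate_responses(small_session, observer, tilt=0.5, seed=2)
        d = am.build_design_matrix(sim, correct_only=True)
        assert "incorrect" in d.task_names
        assert np.any(np.abs(d.column("incorrect")) > 0)

    def test_blank_regressor_carries_response_cue_activity(self, small_session):
        """Dropping the blank regressor shifts condition betas when blank
        trials evoke a response."""
        gt = am.make_ground_truth("endogenous", "flat", "flat", blank_amp=0.6)
        run = am.simulate_attention_run(
            small_session.runs[0], small_session, gt, am.NoiseParams(0, 0, 0),
            seed=4, n_voxels_per_roi=2, responsive_frac=1.0, voxel_gain_sd=0.0,
        )
        pre = am.preprocess_run(run, baseline=100.0)
        d = am.build_design_matrix(small_session, [small_session.runs[0]])
        y = roi_glm.average_roi_timecourse(pre, None, "V1", "left")
        full = am.estimate_amplitudes(y, d)
        blank_idx = d.names.index("blank")
        reduced = roi_glm.DesignMatrix(
            matrix=np.delete(d.matrix, blank_idx, axis=1),
            names=[n for n in d.names if n != "blank"],
            task_names=[n for n in d.task_names if n != "blank"],
            run_index=d.run_index,
            empty_columns=d.empty_columns,
        )
        crippled = am.estimate_amplitudes(y, reduced)
        assert abs(crippled.betas["left_valid_pre"] - full.betas["left_valid_pre"]) > 1e-4


class TestEstimation:
    def test_noiseless_recovery_exact(self, small_session, noiseless_run):
        run, gt = noiseless_run
        pre = am.preprocess_run(run, baseline=100.0)
        table = am.condition_amplitude_table(
            "P01", small_session, [pre], None, correct_only=False
        )
        for row in table.itertuples():
            true = gt.amplitude(
                row.roi, row.hemisphere, f"{row.cue_side}_{row.validity}_{row.cue_epoch}"
            )
            assert row.beta_psc == pytest.approx(true, abs=1e-6)

    def test_doubling_amplitudes_doubles_betas(self, small_session):
        gt1 = am.make_ground_truth("endogenous", "flat", "flat")
        gt2 = am.make_ground_truth(
            "endogenous", "flat", "flat",
            base_contra=1.6, base_ipsi=0.8, flat_level=0.3,
            cue_only_amp=0.6, blank_amp=0.2, slope=0.1,
        )
        common = dict(n_voxels_per_roi=2, responsive_frac=1.0, voxel_gain_sd=0.0)
        r1 = am.simulate_attention_run(
            small_session.runs[0], small_session, gt1, am.NoiseParams(0, 0, 0), 1, **common
        )
        r2 = am.simulate_attention_run(
            small_session.runs[0], small_session, gt2, am.NoiseParams(0, 0, 0), 1, **common
        )
        d = am.build_design_matrix(small_session, [small_session.runs[0]])
        y1 = am.preprocess_run(r1, baseline=100.0).data[0]
        y2 = am.preprocess_run(r2, baseline=100.0).data[0]
        f1 = am.estimate_amplitudes(y1, d)
        f2 = am.estimate_amplitudes(y2, d)
        for name in f1.betas:
            if name in d.task_names and name not in d.empty_columns:
                assert f2.betas[name] == pytest.approx(2 * f1.betas[name], abs=1e-8)

    def test_white_noise_beta_variance_matches_closed_form(self, small_session):
        """Empirical beta covariance matches sigma^2 (X'X)^-1 over replicates."""
        d = am.build_design_matrix(small_session, [small_session.runs[0]])
        keep = [i for i, n in enumerate(d.names) if n not in d.empty_columns]
        X = d.matrix[:, keep]
        names = [d.names[i] for i in keep]
        sigma = 0.7
        rng = np.random.default_rng(12)
        j = names.index("left_valid_pre")
        expected_var = sigma**2 * np.linalg.inv(X.T @ X)[j, j]
        n_rep = 600
        betas = np.empty(n_rep)
        for r in range(n_rep):
            y = sigma * rng.standard_normal(X.shape[0])
            betas[r] = np.linalg.lstsq(X, y, rcond=None)[0][j]
        assert betas.mean() == pytest.approx(0.0, abs=4 * np.sqrt(expected_var / n_rep))
        assert betas.var() == pytest.approx(expected_var, rel=0.25)

    def test_rank_deficiency_names_columns(self, small_session):
        d = am.build_design_matrix(small_session)
        dup = roi_glm.DesignMatrix(
            matrix=np.hstack([d.matrix, d.matrix[:, [0]]]),
            names=d.names + ["dup"],
            task_names=d.task_names + ["dup"],
            run_index=d.run_index,
            empty_columns=d.empty_columns,
        )
        with pytest.raises(ValueError, match="rank deficient"):
            am.estimate_amplitudes(np.zeros(d.matrix.shape[0]), dup)

    def test_betas_invariant_to_run_order(self, small_session):
        gt = am.make_ground_truth("endogenous", "increasing", "flat")
        runs = [
            am.simulate_attention_run(
                small_session.runs[r], small_session, gt, am.NoiseParams(0, 0, 0),
                seed=30 + r, n_voxels_per_roi=2, responsive_frac=1.0, voxel_gain_sd=0.0,
            )
            for r in range(2)
        ]
        pre = [am.preprocess_run(r, baseline=100.0) for r in runs]
        fwd = am.condition_amplitude_table(
            "P", small_session, pre, None, correct_only=False
        )
        swapped = am.generate_session("endogenous", 2, 40, seed=7)
        swapped.runs = [small_session.runs[1], small_session.runs[0]]
        rev = am.condition_amplitude_table(
            "P", swapped, pre[::-1], None, correct_only=False
        )
        merged = fwd.merge(
            rev, on=["roi", "hemisphere", "cue_side", "validity", "cue_epoch"],
            suffixes=("_f", "_r"),
        )
        np.testing.assert_allclose(
            merged["beta_psc_f"], merged["beta_psc_r"], atol=1e-8
        )


class TestLaterality:
    def test_recoding_rule(self):
        df = pd.DataFrame(
            {"cue_side": ["left", "left", "right", "right"],
             "hemisphere": ["left", "right", "left", "right"]}
        )
        out = roi_glm.recode_laterality(df)
        assert list(out["laterality"]) == [
            "ipsilateral", "contralateral", "contralateral", "ipsilateral"
        ]

    def test_recoding_is_involution(self):
        df = pd.DataFrame({"cue_side": ["left", "right"], "hemisphere": ["left", "left"]})
        once = roi_glm.recode_laterality(df)
        twice = roi_glm.recode_laterality(once)
        assert list(once["laterality"]) == list(twice["laterality"])
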
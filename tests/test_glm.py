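"""GLM stage: canonical HRF shape, design-matrix construction, OLS
estimation, contrast inference and its frequentist calibration."""

import numpy as np
import pytest
from scipy import stats as sps

from readnet import (
    RoiTimeSeriesSet,
    build_design_matrix,
    canonical_hrf,
    contrast_t,
    fit_glm,
    group_activation_ttest,
)
from readnet.glm import convolved_regressor, dct_highpass_basis, global_signal_regressor


class TestCanonicalHrf:
    def test_zero_at_onset(self):
        assert canonical_hrf(2.0)[0] == 0.0

    def test_peaks_near_five_seconds(self):
        dt = 0.1
        h = canonical_hrf(dt)
        assert abs(np.argmax(h) * dt - 5.0) <= dt

    def test_undershoot_between_10_and_30_seconds(self):
        dt = 0.1
        h = canonical_hrf(dt)
        t = np.arange(h.size) * dt
        window = h[(t > 10) & (t < 30)]
        assert window.min() < 0

    def test_peak_normalized(self):
        assert canonical_hrf(0.5).max() == pytest.approx(1.0)

    @pytest.mark.parametrize("tr_s,duration_s", [(0.0, 32.0), (2.0, 16.0)])
    def test_invalid_inputs(self, tr_s, duration_s):
        with pytest.raises(ValueError):
            canonical_hrf(tr_s, duration_s)

    def test_matches_reference_spm_shape(self):
        # independent cross-check against nilearn's SPM HRF: same
        # double-gamma parameterization, evaluated on nilearn's own grid
        # (it samples linspace(0, 32, n) rather than arange steps; their
        # ratio is rounded to 0.167, hence the loose tolerance)
        nilearn = pytest.importorskip("nilearn.glm.first_level.hemodynamic_models")
        from readnet.glm import _gamma_pdf

        ref = nilearn.spm_hrf(0.5, oversampling=1)
        # nilearn evaluates on linspace(0, 32, n) shifted by loc=dt and
        # rounds the undershoot ratio to 0.167
        t = np.linspace(0, 32, ref.size) - 0.5
        ours = _gamma_pdf(t, 6, 1) - _gamma_pdf(t, 16, 1) / 6
        assert np.abs(ours / ours.max() - ref / ref.max()).max() < 1e-3
        assert np.argmax(ours) == np.argmax(ref)


class TestDesignMatrix:
    def test_default_columns(self, schedule):
        # analyzed duration 158 s -> K = floor(316/128) = 2 drift columns
        design = build_design_matrix(schedule)
        assert design.names == ("task", "instruction", "dct_1", "dct_2", "intercept")
        assert design.matrix.shape == (79, 5)

    def test_infinite_cutoff_drops_drift_columns(self, schedule):
        design = build_design_matrix(schedule, hp_cutoff_s=np.inf)
        assert design.names == ("task", "instruction", "intercept")

    def test_dct_column_count_rule(self):
        assert dct_highpass_basis(79, 2.0, 128.0).shape == (79, 2)
        assert dct_highpass_basis(79, 2.0, 64.0).shape == (79, 4)

    def test_nuisance_columns_appended(self, schedule, rng):
        design = build_design_matrix(
            schedule, nuisance=rng.standard_normal((79, 2)), nuisance_names=("m1", "m2")
        )
        assert design.names[2:4] == ("m1", "m2")

    def test_nuisance_row_mismatch_rejected(self, schedule, rng):
        with pytest.raises(ValueError, match="nuisance"):
            build_design_matrix(schedule, nuisance=rng.standard_normal((40, 2)))

    def test_collinear_columns_named(self, schedule):
        dup = convolved_regressor(schedule, "task")
        with pytest.raises(ValueError, match="nuisance_1"):
            build_design_matrix(schedule, nuisance=dup[:, None])

    def test_highpass_attenuation_profile(self, schedule):
        # slow drifts project almost entirely onto the DCT set; task-band
        # fluctuations pass nearly untouched
        design = build_design_matrix(schedule)
        drift_cols = [design.column("dct_1"), design.column("dct_2"),
                      design.column("intercept")]
        x = np.column_stack(drift_cols)
        proj = x @ np.linalg.pinv(x)
        t = np.arange(79) * 2.0

        def attenuation(period):
            # cosine-phase probe: the DCT drift set is cosine-phase by
            # construction, so this measures its intended stop/pass bands
            sig = np.cos(2 * np.pi * t / period)
            removed = proj @ sig
            return np.linalg.norm(removed) / np.linalg.norm(sig)

        assert attenuation(316.0) >= 0.90
        assert attenuation(200.0) >= 0.90
        assert attenuation(64.0) < 0.10
        assert attenuation(40.0) < 0.10


def _ts(data, schedule, labels=None):
    labels = labels or tuple(f"ROI_{i + 1:03d}" for i in range(data.shape[0]))
    return RoiTimeSeriesSet(
        subject_id="s1",
        group="good",
        session="phonological",
        data=data,
        tr_s=schedule.tr_s,
        roi_labels=labels,
    )


class TestFitAndContrast:
    def test_exact_recovery_of_generating_betas(self, schedule, rng):
        design = build_design_matrix(schedule)
        beta_true = rng.standard_normal((5, 4))
        data = (design.matrix @ beta_true).T
        fit = fit_glm(_ts(data, schedule), design)
        assert np.abs(fit.betas - beta_true).max() < 1e-8
        assert np.all(fit.residual_variance < 1e-16)
        assert fit.dof_resid == 79 - 5

    def test_residuals_orthogonal_to_design(self, schedule, rng):
        design = build_design_matrix(schedule)
        data = rng.standard_normal((6, 79))
        fit = fit_glm(_ts(data, schedule), design)
        resid = data.T - design.matrix @ fit.betas
        assert np.abs(design.matrix.T @ resid).max() < 1e-6

    def test_white_noise_task_beta_centred_on_zero(self, schedule, rng):
        # 1000 replicate "ROIs" fitted in one call
        design = build_design_matrix(schedule)
        data = rng.standard_normal((1000, 79))
        fit = fit_glm(_ts(data, schedule), design)
        task_betas = fit.betas[design.names.index("task")]
        assert abs(task_betas.mean()) < 3 * task_betas.std() / np.sqrt(1000)

    def test_single_roi_input(self, schedule, rng):
        design = build_design_matrix(schedule)
        fit = fit_glm(_ts(rng.standard_normal((1, 79)), schedule), design)
        assert fit.betas.shape == (5, 1)

    def test_zero_contrast_gives_zero_t(self, schedule, rng):
        design = build_design_matrix(schedule)
        fit = fit_glm(_ts(rng.standard_normal((3, 79)), schedule), design)
        res = contrast_t(fit, design, np.zeros(5))
        assert np.all(res["effect"] == 0) and np.all(res["t"] == 0)

    def test_noiseless_positive_effect_flagged_infinite(self, schedule):
        design = build_design_matrix(schedule)
        data = (design.matrix @ np.array([[2.0], [0], [0], [0], [0]])).T
        fit = fit_glm(_ts(data, schedule), design)
        with pytest.warns(UserWarning, match="zero residual variance"):
            res = contrast_t(fit, design, {"task": 1.0})
        assert np.isposinf(res["t"].iloc[0])
        assert res["p"].iloc[0] == 0.0
        assert bool(res["zero_variance"].iloc[0])

    def test_t_invariant_under_data_rescaling(self, schedule, rng):
        design = build_design_matrix(schedule)
        data = rng.standard_normal((5, 79)) + 0.5 * design.column("task")
        t1 = contrast_t(fit_glm(_ts(data, schedule), design), design, {"task": 1.0})["t"]
        t2 = contrast_t(
            fit_glm(_ts(data * 37.5, schedule), design), design, {"task": 1.0}
        )["t"]
        assert np.allclose(t1, t2, atol=1e-10)

    def test_null_type_i_rate_near_nominal(self, schedule, rng):
        # 1000 independent null ROIs: |t| should clear the 97.5% Student
        # quantile about 5% of the time
        design = build_design_matrix(schedule)
        data = rng.standard_normal((1000, 79))
        fit = fit_glm(_ts(data, schedule), design)
        res = contrast_t(fit, design, {"task": 1.0})
        crit = sps.t.ppf(0.975, fit.dof_resid)
        rate = np.mean(np.abs(res["t"]) > crit)
        assert 0.03 <= rate <= 0.07


class TestGroupActivation:
    def test_identical_groups_all_zero(self, rng):
        effects = rng.standard_normal((4, 10))
        table = group_activation_ttest(effects, effects.copy())
        assert np.all(table["t"] == 0)
        assert np.all(table["df"] == 6)

    def test_df_is_thirty_for_sixteen_per_group(self, rng):
        table = group_activation_ttest(
            rng.standard_normal((16, 5)), rng.standard_normal((16, 5))
        )
        assert np.all(table["df"] == 30)

    def test_unequal_roi_sets_rejected(self, rng):
        with pytest.raises(ValueError, match="ROI sets"):
            group_activation_ttest(
                rng.standard_normal((4, 10)), rng.standard_normal((4, 9))
            )

    def test_injected_effect_has_largest_t(self, rng):
        # effect in ROI 3 of group A; detection = max |t| lands there
        hits = 0
        for _ in range(200):
            a = rng.standard_normal((16, 20))
            a[:, 3] += 2.0
            b = rng.standard_normal((16, 20))
            table = group_activation_ttest(a, b)
            hits += int(np.argmax(np.abs(table["t"])) == 3)
        assert hits >= 190


def test_global_signal_regressor_is_centred_roi_mean(schedule, rng):
    ts = _ts(rng.standard_normal((5, 79)) + 3.0, schedule)
    g = global_signal_regressor(ts)
    assert g.shape == (79,)
    assert abs(g.mean()) < 1e-12
    assert np.allclose(g, ts.data.mean(axis=0) - ts.data.mean())


def test_no_residual_dof_rejected(rng):
    from readnet import make_block_design
    from readnet.glm import DesignMatrix

    sched = make_block_design()
    # as many regressors as volumes: zero residual degrees of freedom
    x = rng.standard_normal((79, 79))
    design = DesignMatrix(x, tuple(f"c{i}" for i in range(79)), 2.0)
    with pytest.raises(ValueError, match="degrees of freedom"):
        fit_glm(_ts(rng.standard_normal((2, 79)), sched), design)
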
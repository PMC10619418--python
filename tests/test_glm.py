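import dataclasses
import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sp_stats

from rovebold.annotate import annotate_run
from rovebold.bold import NoiseSpec, RegionEffectSpec, generate_dataset
from rovebold.experiment import ExperimentConfig, simulate_subject, subject_first_level
from rovebold.glm import (
    build_design_matrix,
    conjunction_global_null,
    fit_glm,
    linear_ramp_weights,
    multiple_comparison_adjust,
    permutation_max_t,
    repeated_measures_anova,
    second_level,
    t_contrast,
    train_length_contrast,
)
from rovebold.markov import MODALITIES
from rovebold.sequences import sample_run

N_VOL, TR = 125, 1.5


@pytest.fixture()
def c1_events(matrices):
    run = sample_run(matrices["C1"], 100, np.random.default_rng(0))
    return annotate_run(run)


@pytest.fixture()
def quiet_config():
    cfg = ExperimentConfig.small()
    cfg.noise = NoiseSpec(rho=0.0, sigma=0.0, drift_order=0, drift_amplitude=0.0)
    return cfg


class TestBuildDesignMatrix:
    def test_rows_equal_volumes_times_runs(self, c1_events):
        d = build_design_matrix([c1_events, c1_events], n_volumes=N_VOL)
        assert d.matrix.shape[0] == 2 * N_VOL

    def test_modulator_column_count(self, c1_events):
        d = build_design_matrix([c1_events], n_volumes=N_VOL, drift_order=2)
        assert len(d.task_names) == 1 + 9
        assert len(d.names) == 10 + 3  # + intercept + 2 drift columns

    def test_motion_columns_pass_through(self, c1_events):
        rng = np.random.default_rng(0)
        d = build_design_matrix(
            [c1_events], n_volumes=N_VOL, motion=[rng.normal(size=(N_VOL, 6))]
        )
        assert sum("motion" in n for n in d.names) == 6

    def test_c3_only_predictability_errors(self, matrices):
        run = sample_run(matrices["C3"], 100, np.random.default_rng(1))
        ev = annotate_run(run)
        with pytest.raises(ValueError, match="predictability"):
            build_design_matrix([ev], n_volumes=N_VOL)

    def test_c3_only_drop_path(self, matrices):
        run = sample_run(matrices["C3"], 100, np.random.default_rng(1))
        ev = annotate_run(run)
        with pytest.warns(UserWarning, match="predictability"):
            d = build_design_matrix([ev], n_volumes=N_VOL, on_empty="drop")
        assert not any("predictability" in n for n in d.task_names)

    def test_duplicate_column_rank_error(self, c1_events):
        d = build_design_matrix([c1_events], n_volumes=N_VOL)
        from rovebold.glm import _check_rank

        X = np.column_stack([d.matrix, d.matrix[:, 0]])
        with pytest.raises(ValueError, match="rank deficient"):
            _check_rank(X, d.names + ["dup_onset"])


class TestFitGLM:
    def test_matches_closed_form_oracle(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(20, 5))
        Y = rng.normal(size=(20, 3))
        from rovebold.glm import DesignMatrix

        d = DesignMatrix(X, [f"c{i}" for i in range(5)], [], [slice(0, 20)])
        res = fit_glm([Y.T], d, whitening="none")
        beta_oracle = np.linalg.solve(X.T @ X, X.T @ Y)
        assert np.allclose(res.betas.T, beta_oracle, atol=1e-10)

    def test_residuals_orthogonal_to_design(self, c1_events):
        rng = np.random.default_rng(2)
        d = build_design_matrix([c1_events], n_volumes=N_VOL)
        Y = (d.matrix @ rng.normal(size=(d.matrix.shape[1], 4))
             + rng.normal(size=(N_VOL, 4)))
        res = fit_glm([Y.T], d, whitening="none")
        resid = Y - d.matrix @ res.betas.T
        rel = np.abs(d.matrix.T @ resid).max() / (np.abs(Y).max() * N_VOL)
        assert rel < 1e-8

    def test_df_rows_minus_columns(self, c1_events):
        d = build_design_matrix([c1_events], n_volumes=N_VOL)
        Y = np.random.default_rng(0).normal(size=(2, N_VOL))
        res = fit_glm([Y], d)
        assert res.df == N_VOL - d.matrix.shape[1]

    def test_noiseless_recovery_modulator(self, quiet_config):
        ds = simulate_subject(quiet_config, 42)
        res, _ = subject_first_level(ds, quiet_config, variant="modulator")
        checks = {
            ("mismatch_A", "aud_l"): 1.0,
            ("mismatch_S", "som_l"): 1.0,
            ("intensity_V", "vis_r"): 1.0,
            ("predictability_A", "ips_r"): 1.0,
            ("mismatch_A", "null_1"): 0.0,
        }
        for (col, region), true in checks.items():
            est = res.beta(col)[ds.region_names.index(region)]
            assert est == pytest.approx(true, abs=1e-6)

    def test_noiseless_recovery_trainbins(self, quiet_config):
        specs = [RegionEffectSpec(name="slope", trainlength_slope=0.5),
                 RegionEffectSpec(name="null")]
        ds = simulate_subject(quiet_config, 7, specs=specs)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            d = build_design_matrix(ds.events, variant="trainbins",
                                    n_volumes=ds.n_volumes, on_empty="drop")
        res = fit_glm(ds, d, whitening="none")
        from rovebold.annotate import TRAIN_BINS

        for k, b in enumerate(TRAIN_BINS):
            for m in MODALITIES:
                name = f"dev_{m.name}_{b}"
                if name in res.names:
                    est = res.beta(name)[0]
                    assert est == pytest.approx((k - 2.5) * 0.5, abs=1e-6)

    def test_nonfinite_data_rejected(self, c1_events):
        d = build_design_matrix([c1_events], n_volumes=N_VOL)
        Y = np.full((1, N_VOL), np.nan)
        with pytest.raises(ValueError, match="finite"):
            fit_glm([Y], d)

    def test_ar1_whitening_estimates_rho(self, c1_events):
        d = build_design_matrix([c1_events], n_volumes=N_VOL)
        rng = np.random.default_rng(3)
        from rovebold.bold import ar1_noise

        Y = np.vstack([ar1_noise(N_VOL, NoiseSpec(rho=0.5, sigma=1.0), rng)
                       for _ in range(30)])
        res = fit_glm([Y], d, whitening="ar1")
        assert res.rho[0] == pytest.approx(0.5, abs=0.1)

    def test_nuisance_invariance(self, c1_events):
        # adding a nuisance column orthogonal to task regressors leaves the
        # task contrast estimates unchanged
        rng = np.random.default_rng(4)
        d = build_design_matrix([c1_events], n_volumes=N_VOL)
        Y = d.matrix @ rng.normal(size=(d.matrix.shape[1], 2)) + rng.normal(
            size=(N_VOL, 2)
        )
        res = fit_glm([Y.T], d, whitening="none")
        extra = rng.normal(size=N_VOL)
        Q, _ = np.linalg.qr(d.matrix)
        extra = extra - Q @ (Q.T @ extra)  # orthogonalize against the design
        from rovebold.glm import DesignMatrix

        d2 = DesignMatrix(
            np.column_stack([d.matrix, extra]), d.names + ["extra"],
            d.task_names, d.run_slices,
        )
        res2 = fit_glm([Y.T], d2, whitening="none")
        c1 = t_contrast(res, {"mismatch_A": 1.0})
        c2 = t_contrast(res2, {"mismatch_A": 1.0})
        assert np.allclose(c1.estimate, c2.estimate, atol=1e-8)


class TestTContrast:
    def test_zero_weights(self, c1_events):
        d = build_design_matrix([c1_events], n_volumes=N_VOL)
        Y = np.random.default_rng(0).normal(size=(2, N_VOL))
        res = fit_glm([Y], d, whitening="none")
        c = t_contrast(res, np.zeros(len(res.names)))
        assert np.all(c.estimate == 0) and np.all(c.t == 0)

    def test_matches_textbook_slope_t(self):
        # fixed small instance: y on [intercept, x]; compare with linregress
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        y = np.array([1.1, 1.9, 3.2, 3.9, 5.2, 5.8])
        X = np.column_stack([np.ones(6), x])
        from rovebold.glm import DesignMatrix

        d = DesignMatrix(X, ["intercept", "x"], [], [slice(0, 6)])
        res = fit_glm([y[None, :]], d, whitening="none")
        c = t_contrast(res, {"x": 1.0})
        lr = sp_stats.linregress(x, y)
        assert c.estimate[0] == pytest.approx(lr.slope, abs=1e-12)
        assert c.t[0] == pytest.approx(lr.slope / lr.stderr, abs=1e-10)
        assert c.p[0] == pytest.approx(lr.pvalue, abs=1e-12)

    def test_first_level_type_one_rate(self, matrices):
        """Deviants>Standards on null regions: rejection rate ~ alpha."""
        alpha, n_sim, n_null = 0.05, 250, 8
        rng = np.random.default_rng(2024)
        run = sample_run(matrices["C1"], 100, rng)
        ev = annotate_run(run)
        d = build_design_matrix([ev], n_volumes=N_VOL)
        specs = [RegionEffectSpec(name=f"null_{i}") for i in range(n_null)]
        rejections = 0
        for _ in range(n_sim):
            ds = generate_dataset([ev], specs, NoiseSpec(rho=0.3), rng,
                                  n_volumes=N_VOL)
            res = fit_glm(ds, d, whitening="ar1")
            c = t_contrast(res, {"mismatch_A": 1.0})
            rejections += int((c.p < alpha).sum())
        n_tests = n_sim * n_null
        rate = rejections / n_tests
        ci = 1.96 * np.sqrt(alpha * (1 - alpha) / n_tests)
        assert abs(rate - alpha) < ci + 1e-9


class TestTrainLengthContrast:
    def test_ramp_weights_sum_to_zero(self):
        assert linear_ramp_weights(6).sum() == 0.0

    def test_equal_bin_estimates_zero_contrast(self, quiet_config):
        # exact: identical per-bin betas annihilate the sum-zero ramp
        specs = [RegionEffectSpec(name="flat")]
        ds = simulate_subject(quiet_config, 3, specs=specs)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            d = build_design_matrix(ds.events, variant="trainbins",
                                    n_volumes=ds.n_volumes, on_empty="drop")
            res = fit_glm(ds, d, whitening="none")
        res.betas = np.full_like(res.betas, 3.7)  # force equal bin estimates
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            c = train_length_contrast(res, "A")
        assert c.estimate[0] == pytest.approx(0.0, abs=1e-12)

    def test_missing_bin_renormalizes_with_warning(self, quiet_config):
        specs = [RegionEffectSpec(name="slope", trainlength_slope=0.5)]
        cfg = quiet_config
        from rovebold.experiment import SessionLayout

        cfg.layout = SessionLayout(n_runs=1, n_trials=60, n_volumes=75, n_catch=2)
        ds = simulate_subject(cfg, 5, specs=specs)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            d = build_design_matrix(ds.events, variant="trainbins",
                                    n_volumes=ds.n_volumes, on_empty="drop")
            res = fit_glm(ds, d, whitening="none")
        with pytest.warns(UserWarning, match="renormalized"):
            c = train_length_contrast(res, "A")
        assert np.isfinite(c.estimate[0])

    def test_positive_slope_recovered(self, small_config):
        """Injected positive train slope -> positive contrast in most subjects."""
        n_pos, n_sub = 0, 12
        specs = [RegionEffectSpec(name="slope", baseline_response=1.0,
                                  mismatch_effect=1.0, trainlength_slope=0.4)]
        for s in range(n_sub):
            ds = simulate_subject(small_config, 100 + s, specs=specs)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                d = build_design_matrix(ds.events, variant="trainbins",
                                        n_volumes=ds.n_volumes, on_empty="drop")
                res = fit_glm(ds, d)
                c = train_length_contrast(res, "A")
            n_pos += int(c.estimate[0] > 0)
        assert n_pos >= int(0.9 * n_sub)


class TestSecondLevel:
    def test_matches_hand_formula(self):
        v = np.array([1.2, 0.8, 1.0, 1.4, 0.6])
        res = second_level(v[:, None])
        mean, sd = v.mean(), v.std(ddof=1)
        t_hand = mean / (sd / np.sqrt(5))
        assert res.t[0] == pytest.approx(t_hand, abs=1e-12)
        t_sp, p_sp = sp_stats.ttest_1samp(v, 0.0)
        assert res.t[0] == pytest.approx(t_sp, abs=1e-12)
        assert res.p[0] == pytest.approx(p_sp, abs=1e-12)

    def test_identical_estimates_degenerate(self):
        res = second_level(np.full((4, 1), 2.0))
        assert np.isinf(res.t[0]) and res.degenerate[0]
        assert np.isnan(res.p[0])

    def test_too_few_subjects(self):
        with pytest.raises(ValueError):
            second_level(np.array([[1.0]]))

    def test_group_type_one_rate(self):
        alpha, n_sim, n_sub = 0.05, 2000, 12
        rng = np.random.default_rng(7)
        rejections = 0
        for _ in range(n_sim):
            res = second_level(rng.normal(size=(n_sub, 1)))
            rejections += int(res.p[0] < alpha)
        rate = rejections / n_sim
        ci = 1.96 * np.sqrt(alpha * (1 - alpha) / n_sim)
        assert abs(rate - alpha) < ci

    def test_repeated_measures_anova_null(self):
        rng = np.random.default_rng(8)
        out = repeated_measures_anova(rng.normal(size=(10, 3, 200)))
        assert ((out["p"] < 0.05).mean()) == pytest.approx(0.05, abs=0.05)


class TestConjunction:
    def _contrast_from_t(self, t, df=20):
        from rovebold.glm import ContrastResult, _p_from_t

        t = np.asarray(t, dtype=float)
        return ContrastResult(t, np.ones_like(t), t, _p_from_t(t, df, "greater"),
                              df, "greater")

    def test_identical_maps_min_equals_map(self):
        t = np.array([2.0, -1.0, 0.5])
        conj = conjunction_global_null([self._contrast_from_t(t)] * 3)
        assert np.array_equal(conj.min_t, t)

    def test_min_of_components(self):
        conj = conjunction_global_null(
            [self._contrast_from_t([3.0]), self._contrast_from_t([1.0])]
        )
        assert conj.min_t[0] == 1.0

    def test_monotone_in_components(self):
        base = [self._contrast_from_t([2.0]), self._contrast_from_t([3.0])]
        more = base + [self._contrast_from_t([1.5])]
        assert conjunction_global_null(more).min_t[0] <= conjunction_global_null(base).min_t[0]

    def test_mismatched_df_rejected(self):
        with pytest.raises(ValueError, match="df"):
            conjunction_global_null(
                [self._contrast_from_t([1.0], df=10), self._contrast_from_t([1.0], df=20)]
            )

    def test_conjnull_p_geq_component_p(self):
        comps = [self._contrast_from_t([1.0]), self._contrast_from_t([2.5])]
        conj = conjunction_global_null(comps)
        for c in comps:
            assert conj.p_conjnull[0] >= c.p[0] - 1e-15

    def test_global_null_calibration(self):
        alpha, n_sim, n_sub, k = 0.05, 2000, 10, 3
        rng = np.random.default_rng(9)
        rejections = 0
        for _ in range(n_sim):
            comps = [second_level(rng.normal(size=(n_sub, 1)), alternative="greater")
                     for _ in range(k)]
            conj = conjunction_global_null(comps)
            rejections += int(conj.p[0] < alpha)
        rate = rejections / n_sim
        ci = 1.96 * np.sqrt(alpha * (1 - alpha) / n_sim)
        assert abs(rate - alpha) < ci


class TestMultipleComparisons:
    def test_single_test_unchanged(self):
        assert multiple_comparison_adjust(np.array([0.03]))[0] == pytest.approx(0.03)

    def test_bonferroni_arithmetic(self):
        out = multiple_comparison_adjust(np.array([0.01] * 20))
        assert np.allclose(out, 0.2)

    def test_capped_at_one(self):
        out = multiple_comparison_adjust(np.array([0.9, 0.001]), m=20)
        assert out[0] == 1.0

    def test_permutation_and_bonferroni_agree_in_ordering(self):
        # max-T permutation p is a monotone function of |t|, so its ordering
        # matches the (uncapped) Bonferroni ordering on independent null data
        rng = np.random.default_rng(10)
        est = rng.normal(size=(15, 8))
        t = second_level(est)
        p_perm = permutation_max_t(est, n_perm=500, rng=rng)
        order = np.argsort(-np.abs(t.t))
        assert np.all(np.diff(p_perm[order]) >= 0)
        order_bonf = np.argsort(t.p[order])
        assert np.all(np.diff(order_bonf) >= 0)
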
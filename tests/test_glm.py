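import numpy as np
import pytest

from midbrainfb.design import build_mid_design as mid_trials
from midbrainfb.glm import (GLMError, RankError, DesignMatrix,
                            build_block_design, build_linear_time_design,
                            build_mid_design, build_ppi_design,
                            build_td_design, fit_ols, imagine_minus_rest,
                            run_contrast)
from midbrainfb.preprocess import pca_nuisance
from midbrainfb.simulate import hrf_kernel
import pandas as pd


def slow_convolve(signal, kernel):
    """Double-loop discrete convolution oracle."""
    out = np.zeros(len(signal))
    for t in range(len(signal)):
        for k in range(len(kernel)):
            if t - k >= 0:
                out[t] += signal[t - k] * kernel[k]
    return out


class TestBlockDesign:
    def test_has_exactly_fifteen_columns(self, default_run, nuisance_190):
        dm = build_block_design(default_run, nuisance_190)
        assert len(dm.columns) == 15

    def test_boxcars_match_convolution_oracle(self, default_run, nuisance_190):
        dm = build_block_design(default_run, nuisance_190)
        kernel = hrf_kernel(default_run.tr)
        box = np.zeros(default_run.n_volumes)
        for blk in default_run.condition_blocks("IMAGINE_REWARD"):
            box[int(blk.onset / 2): int(blk.end / 2)] = 1.0
        assert np.allclose(dm.frame["imagine"].to_numpy(),
                           slow_convolve(box, kernel), atol=1e-10)

    def test_reproducible_bit_identical(self, default_run, nuisance_190):
        a = build_block_design(default_run, nuisance_190)
        b = build_block_design(default_run, nuisance_190)
        assert a.frame.equals(b.frame)

    def test_duplicate_columns_rejected(self, rng):
        frame = pd.DataFrame(rng.normal(size=(10, 2)), columns=["a", "a"])
        with pytest.raises(GLMError):
            DesignMatrix(frame)

    def test_nuisance_length_mismatch_rejected(self, default_run, rng):
        short = pca_nuisance(rng.normal(size=(30, 100)) + 100,
                             motion=rng.normal(size=(6, 100)))
        with pytest.raises(GLMError):
            build_block_design(default_run, short)


class TestTDDesign:
    def test_constant_series_zeroes_modulators(self, default_run, nuisance_190):
        dm = build_td_design(default_run, np.full(190, 5.0), nuisance_190)
        assert np.allclose(dm.frame["imagine_td"], 0.0)
        assert np.allclose(dm.frame["rest_td"], 0.0)

    def test_linear_ramp_centers_to_zero(self, default_run, nuisance_190):
        ramp = np.arange(190, dtype=float) * 0.5
        dm = build_td_design(default_run, ramp, nuisance_190)
        # backward difference of a ramp is constant, hence zero after
        # within-condition mean-centering
        assert np.allclose(dm.frame["imagine_td"], 0.0, atol=1e-10)

    def test_modulator_scales_with_series(self, default_run, nuisance_190, rng):
        series = rng.normal(100, 2, 190)
        a = build_td_design(default_run, series, nuisance_190)
        b = build_td_design(default_run, 3.0 * series, nuisance_190)
        assert np.allclose(b.frame["imagine_td"], 3.0 * a.frame["imagine_td"],
                           atol=1e-9)


class TestLinearTimeDesign:
    def test_increase_and_decrease_are_negatives(self, default_run, nuisance_190):
        inc = build_linear_time_design(default_run, "increase", nuisance_190)
        dec = build_linear_time_design(default_run, "decrease", nuisance_190)
        assert np.allclose(inc.frame["linear_mod"],
                           -dec.frame["linear_mod"], atol=1e-10)

    def test_centered_modulator_ignores_flat_task_signal(self, default_run,
                                                         nuisance_190):
        # mean-centering makes the modulator orthogonal to a constant task
        # amplitude: a trend-free signal must load 0 on it
        dm = build_linear_time_design(default_run, "increase", nuisance_190)
        y = dm.frame["task_events"].to_numpy()
        fit = fit_ols(dm, y)
        assert fit.beta("linear_mod") == pytest.approx(0.0, abs=1e-10)
        assert fit.beta("task_events") == pytest.approx(1.0, abs=1e-10)

    def test_recovers_linear_trend_sign(self, default_run, nuisance_190, rng):
        # Monte-Carlo sign recovery: signal whose amplitude ramps up should
        # load positively on the increasing modulator
        dm = build_linear_time_design(default_run, "increase", nuisance_190)
        hits = 0
        n_rep = 100
        for _ in range(n_rep):
            y = (dm.frame["linear_mod"].to_numpy() * 0.8
                 + dm.frame["task_events"].to_numpy()
                 + rng.normal(0, 1.0, 190))
            fit = fit_ols(dm, y)
            hits += fit.beta("linear_mod") > 0
        assert hits / n_rep >= 0.95

    def test_unknown_direction_rejected(self, default_run, nuisance_190):
        with pytest.raises(GLMError):
            build_linear_time_design(default_run, "sideways", nuisance_190)


class TestMIDDesignMatrix:
    def _nuisance(self, n, rng):
        return pca_nuisance(rng.normal(size=(30, n)) + 100,
                            motion=rng.normal(0, 0.05, size=(6, n)))

    def test_equal_magnitudes_zero_modulator(self, rng):
        trials = mid_trials(seed=1)
        fixed = [t.__class__(cue_type=t.cue_type,
                             magnitude=0.3 if t.cue_type != "none" else 0.0,
                             cue_onset=t.cue_onset, delay=t.delay)
                 for t in trials]
        n = 400
        dm = build_mid_design(fixed, n, 2.0, self._nuisance(n, rng))
        assert np.allclose(dm.frame["mod_small"], 0.0)
        assert np.allclose(dm.frame["mod_large"], 0.0)

    def test_no_reward_cue_carries_no_modulator(self, rng):
        n = 400
        dm = build_mid_design(mid_trials(seed=1), n, 2.0,
                              self._nuisance(n, rng))
        assert "mod_none" not in dm.columns
        assert {"cue_large", "cue_small", "cue_none"} <= set(dm.columns)

    def test_trial_outside_run_rejected(self, rng):
        n = 40
        with pytest.raises(GLMError):
            build_mid_design(mid_trials(seed=1), n, 2.0,
                             self._nuisance(n, rng))


class TestPPIDesign:
    def test_zero_seed_zeroes_interactions(self, default_run, nuisance_190):
        dm = build_ppi_design(np.zeros(190), default_run, nuisance_190)
        assert np.allclose(dm.frame["ppi_imagine"], 0.0)
        assert np.allclose(dm.frame["ppi_rest"], 0.0)

    def test_null_interaction_t_centered_on_zero(self, default_run,
                                                 nuisance_190, rng):
        ts = []
        for _ in range(60):
            seed_series = rng.normal(0, 1, 190)
            y = rng.normal(100, 2, 190)
            dm = build_ppi_design(seed_series, default_run, nuisance_190)
            fit = fit_ols(dm, y)
            ts.append(run_contrast(fit, {"ppi_imagine": 1.0,
                                         "ppi_rest": -1.0})["t"])
        ts = np.array(ts)
        assert abs(ts.mean()) < 3.0 / np.sqrt(ts.size) * ts.std(ddof=1) + 0.5


class TestFitOLS:
    def test_exact_fit_single_regressor(self):
        x = np.linspace(0, 1, 30)
        dm = DesignMatrix(pd.DataFrame({"x": x}))
        fit = fit_ols(dm, 2.0 * x, add_intercept=False)
        assert fit.beta("x") == pytest.approx(2.0, abs=1e-10)
        assert fit.residual_variance == pytest.approx(0.0, abs=1e-16)

    def test_matches_normal_equations_oracle(self, rng):
        for _ in range(20):
            n, p = 40, 5
            x = rng.normal(size=(n, p))
            y = rng.normal(size=n)
            dm = DesignMatrix(pd.DataFrame(x, columns=[f"c{i}" for i in range(p)]))
            fit = fit_ols(dm, y, add_intercept=False)
            oracle = np.linalg.solve(x.T @ x, x.T @ y)
            assert np.allclose(fit.betas.to_numpy(), oracle, rtol=1e-8)

    def test_duplicated_regressor_raises_rank_error(self, rng):
        x = rng.normal(size=30)
        dm = DesignMatrix(pd.DataFrame({"a": x, "b": x}))
        with pytest.raises(RankError):
            fit_ols(dm, rng.normal(size=30), add_intercept=False)

    def test_dof_accounts_for_intercept(self, rng):
        dm = DesignMatrix(pd.DataFrame({"x": rng.normal(size=50)}))
        fit = fit_ols(dm, rng.normal(size=50))
        assert fit.dof == 48

    def test_prewhitening_keeps_betas_close(self, default_run, nuisance_190, rng):
        dm = build_block_design(default_run, nuisance_190)
        y = dm.frame["imagine"].to_numpy() * 1.5 + rng.normal(0, 1, 190)
        plain = fit_ols(dm, y)
        white = fit_ols(dm, y, prewhiten=True)
        assert white.beta("imagine") == pytest.approx(plain.beta("imagine"),
                                                      abs=0.3)


class TestContrasts:
    @pytest.fixture()
    def simple_fit(self, rng):
        x = rng.normal(size=(60, 3))
        dm = DesignMatrix(pd.DataFrame(x, columns=["a", "b", "c"]))
        y = x @ np.array([1.0, 1.0, 0.5]) + rng.normal(0, 0.5, 60)
        return fit_ols(dm, y, add_intercept=False)

    def test_zero_weights_zero_contrast(self, simple_fit):
        res = run_contrast(simple_fit, {"a": 0.0})
        assert res["estimate"] == 0.0 and res["t"] == 0.0

    def test_difference_of_equal_betas_near_zero(self, simple_fit):
        res = run_contrast(simple_fit, {"a": 1.0, "b": -1.0})
        direct = simple_fit.beta("a") - simple_fit.beta("b")
        assert res["estimate"] == pytest.approx(direct, abs=1e-12)

    def test_matches_dot_product_oracle(self, simple_fit, rng):
        w = rng.normal(size=3)
        res = run_contrast(simple_fit, dict(zip(["a", "b", "c"], w)))
        assert res["estimate"] == pytest.approx(
            float(w @ simple_fit.betas.to_numpy()), abs=1e-12)

    def test_unknown_column_rejected(self, simple_fit):
        with pytest.raises(GLMError):
            run_contrast(simple_fit, {"nope": 1.0})

    def test_orthogonal_nuisance_leaves_contrast_stable(self, default_run,
                                                        nuisance_190, rng):
        dm = build_block_design(default_run, nuisance_190)
        y = dm.frame["imagine"].to_numpy() - dm.frame["rest"].to_numpy() \
            + rng.normal(0, 1.0, 190)
        base = imagine_minus_rest(fit_ols(dm, y))["estimate"]
        extra = dm.frame.copy()
        col = rng.normal(0, 1, 190)
        # orthogonalize the new column against design and signal
        x = np.column_stack([extra.to_numpy(), y, np.ones_like(y)])
        col = col - x @ np.linalg.lstsq(x, col, rcond=None)[0]
        extra["junk"] = col
        aug = fit_ols(DesignMatrix(extra), y)
        assert imagine_minus_rest(aug)["estimate"] == pytest.approx(base,
                                                                    abs=1e-8)
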
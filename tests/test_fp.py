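"""Fractional-polynomial fitting, centile arithmetic and their invariants."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import trunkdate as td
from trunkdate.fp import fp_design


def normal_equations_fit(x, y, powers):
    """Independent OLS oracle: explicit design + numpy solve."""
    cols = [np.ones_like(x)]
    prev = None
    for p in powers:
        if prev is not None and p == prev:
            cols.append(cols[-1] * np.log(x))
        else:
            cols.append(np.log(x) if p == 0 else x**p)
        prev = p
    X = np.column_stack(cols)
    return np.linalg.solve(X.T @ X, X.T @ y)


class TestFitMean:
    def test_exact_linear_data_reproduced_to_machine_precision(self):
        x = np.arange(1.0, 51.0)
        y = 2.0 + 3.0 * x
        model = td.fit_fp_mean(x, y)
        assert np.allclose(model.predict(x), y, atol=1e-9)
        resid = y - model.predict(x)
        assert float(resid @ resid) < 1e-16

    @pytest.mark.parametrize("powers", [(0.0, 1.0), (-2.0,), (2.0, 2.0), (0.5, 3.0)])
    def test_fixed_powers_match_normal_equations_oracle(self, powers):
        rng = np.random.default_rng(7)
        x = np.linspace(2.0, 40.0, 20)
        y = 1.0 + 0.3 * np.log(x) + 0.01 * x + rng.normal(0, 0.1, x.size)
        model = td.fit_fp_mean(x, y, powers=powers)
        beta = normal_equations_fit(x, y, powers)
        assert model.intercept == pytest.approx(beta[0], abs=1e-10)
        assert np.asarray(model.coefficients) == pytest.approx(beta[1:], abs=1e-10)

    def test_repeated_power_design_is_xp_times_log(self):
        x = np.array([1.5, 2.0, 5.0])
        design = fp_design(x, (2.0, 2.0))
        assert np.allclose(design[:, 0], x**2)
        assert np.allclose(design[:, 1], x**2 * np.log(x))
        # repeated log power: ln x then (ln x)^2
        design0 = fp_design(x, (0.0, 0.0))
        assert np.allclose(design0[:, 1], np.log(x) ** 2)

    def test_power_search_recovers_generating_powers(self, verburg_sim):
        model = td.fit_fp_mean(
            verburg_sim.crl, verburg_sim.ga, outcome_log=True,
            covariate_name="crl_mm",
        )
        assert model.powers == (0.0, 1.0)
        # medians close to the generating curve across the fitted span
        grid = np.arange(5.0, 111.0, 5.0)
        fitted = np.exp(model.predict(grid))
        assert np.max(np.abs(fitted - td.VERBURG.median(grid)) * 7) < 0.2

    def test_rejects_nonpositive_covariate_and_degenerate_design(self):
        y = np.arange(10.0) + 1
        with pytest.raises(td.InvalidInputError):
            td.fit_fp_mean(np.arange(-5.0, 5.0), y)
        with pytest.raises(td.DegenerateDesignError):
            td.fit_fp_mean(np.full(10, 3.0), y, powers=(0.0, 1.0))


class TestFitSD:
    def test_homoscedastic_residuals_give_flat_curve(self):
        rng = np.random.default_rng(12)
        x = np.repeat(np.arange(5.0, 105.0, 5.0), 400)
        r = rng.normal(0, 0.04, x.size)
        sd = td.fit_fp_sd(x, r)
        grid = np.linspace(5, 100, 20)
        assert np.all(np.abs(sd.predict(grid) - 0.04) < 0.003)

    def test_heteroscedastic_slope_recovered(self):
        rng = np.random.default_rng(99)
        xs = np.arange(10.0, 60.0, 10.0)
        x = np.repeat(xs, 5000)
        r = rng.normal(0, 0.02 + 0.001 * x)
        sd = td.fit_fp_sd(x, r, powers=(1.0,))
        slope = sd.coefficients[0]
        # SE of the slope of the scaled |r| regression, computed from the
        # half-normal residual variance around the true SD line
        resid_sd = np.sqrt(np.pi / 2 - 1) * (0.02 + 0.001 * x)
        X = np.column_stack([np.ones_like(x), x])
        se = np.sqrt(np.mean(resid_sd**2) * np.linalg.inv(X.T @ X)[1, 1])
        assert abs(slope - 0.001) < 3 * se

    def test_nonpositive_fixed_sd_curve_raises(self):
        # residuals growing in x forced through a decreasing shape dip
        # below zero inside the range: not a usable SD curve
        x = np.linspace(1.0, 50.0, 100)
        r = 0.002 * x
        with pytest.raises(td.InvalidSDError):
            td.fit_fp_sd(x, r, powers=(-2.0,))

    def test_search_avoids_nonpositive_candidates(self):
        x = np.linspace(1.0, 50.0, 100)
        r = 0.002 * x
        sd = td.fit_fp_sd(x, r)
        assert np.all(sd.predict(np.linspace(1.0, 50.0, 201)) > 0)


class TestCentiles:
    def test_verburg_median_matches_printed_table(self):
        model = td.VERBURG.to_model()
        assert td.predict_centile(model, 50.0, td.MEDIAN)[0] == pytest.approx(
            11.670, abs=5e-4
        )
        assert td.predict_centile(model, 100.0, td.MEDIAN)[0] == pytest.approx(
            14.942, abs=5e-4
        )

    @pytest.mark.parametrize("K", [1.880794, 1.88])
    def test_verburg_outer_centiles_match_printed_row_under_either_K(self, K):
        model = td.VERBURG.to_model()
        lo = td.predict_centile(model, 50.0, td.CentileSpec(0.03, -K))[0]
        hi = td.predict_centile(model, 50.0, td.CentileSpec(0.97, K))[0]
        assert round(lo, 2) == 10.70
        assert round(hi, 2) == 12.72

    def test_median_of_log_model_is_exp_mean(self):
        model = td.VERBURG.to_model()
        x = np.array([10.0, 42.0, 97.0])
        assert np.allclose(
            td.predict_centile(model, x, td.MEDIAN), np.exp(model.mean.predict(x))
        )

    def test_log_scale_centile_symmetry_is_exact(self):
        model = td.VERBURG.to_model()
        x = np.linspace(6, 105, 50)
        c3 = td.predict_centile(model, x, td.CENTILE_3)
        c50 = td.predict_centile(model, x, td.MEDIAN)
        c97 = td.predict_centile(model, x, td.CENTILE_97)
        assert np.allclose(np.log(c97) - np.log(c50), np.log(c50) - np.log(c3))

    @given(
        st.floats(min_value=-3, max_value=3),
        st.floats(min_value=-3, max_value=3),
        st.floats(min_value=6, max_value=105),
    )
    def test_centile_monotone_in_K(self, k1, k2, x):
        if abs(k1 - k2) < 1e-9:
            return
        k1, k2 = sorted((k1, k2))
        model = td.VERBURG.to_model()
        lo = td.predict_centile(model, x, td.CentileSpec(0.5, k1))[0]
        hi = td.predict_centile(model, x, td.CentileSpec(0.5, k2))[0]
        assert lo < hi


class TestZScores:
    def test_point_on_median_curve_scores_zero(self):
        model = td.VERBURG.to_model()
        crl = np.array([30.0, 60.0])
        z = td.zscores(model, crl, td.VERBURG.median(crl))
        assert np.allclose(z, 0.0, atol=1e-12)

    def test_point_on_97th_curve_scores_K(self):
        model = td.VERBURG.to_model()
        crl = np.array([25.0])
        z = td.zscores(model, crl, td.VERBURG.centile(crl, td.CENTILE_97))
        assert z[0] == pytest.approx(td.CENTILE_97.K, abs=1e-9)

    def test_self_simulated_zscores_are_standard_normal(self):
        obs = td.simulate_from_dating(td.VERBURG, np.arange(10.0, 110.0), 100, seed=5)
        z = td.zscores(td.VERBURG.to_model(), obs.crl, obs.ga)
        n = z.size
        assert abs(z.mean()) < 3 / np.sqrt(n)
        assert abs(z.std(ddof=1) - 1) < 3 / np.sqrt(2 * n)


class TestSerialisation:
    def test_model_json_roundtrip(self, tmp_path):
        model = td.VERBURG.to_model()
        path = tmp_path / "m.json"
        model.save(path)
        back = td.MeanSDModel.load(path)
        assert back.mean == model.mean
        assert back.sd == model.sd
        x = np.linspace(6, 100, 7)
        assert np.allclose(back.predict_centile(x), model.predict_centile(x))
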
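"""Truncation-handling strategies: collapse cases, inversion, SD recovery."""

import numpy as np
import pytest
from scipy.optimize import brentq

import trunkdate as td
from trunkdate.approaches import Approach1Config, Approach3Config


class TestPipelineCollapse:
    def test_no_truncation_no_augmentation_equals_direct_fit(self, verburg_sim):
        """With nothing to correct, Approaches 1-2 are the plain dating fit."""
        direct = td.fit_dating_model(verburg_sim)
        cfg1 = Approach1Config(
            augment_low_days=(),
            restrict_crl=(
                float(verburg_sim.crl.min()),
                float(verburg_sim.crl.max()),
            ),
        )
        a1 = td.run_approach1(verburg_sim, cfg1, seed=0)
        cfg2 = td.Approach2Config(augment_low_days=(), augment_high_days=())
        a2 = td.run_approach2(verburg_sim, cfg2, seed=0)
        for fitted in (a1, a2):
            assert fitted.mean.powers == direct.mean.powers
            assert fitted.mean.intercept == pytest.approx(direct.mean.intercept)
            assert np.asarray(fitted.mean.coefficients) == pytest.approx(
                np.asarray(direct.mean.coefficients)
            )


class TestApproach1:
    def test_recovers_generating_median_at_interior_crl(self):
        """Generator-as-oracle: truth known, interior prediction must track it."""
        eq = td.DatingEquation(1.5, 0.002, 0.23, 0.03)
        obs = td.simulate_from_dating(eq, seed=77)
        trunc = td.truncate(obs, td.TruncationWindow())
        model = td.run_approach1(trunc, seed=78)
        fitted = model.predict_centile(40.0, td.MEDIAN)[0]
        # interior CRL, inside the restriction: Monte-Carlo scale ~0.01 wk
        assert abs(fitted - eq.median(40.0)[0]) * 7 < 0.3

    def test_fit_range_records_the_restriction(self, approach1_fit):
        model, fitset = approach1_fit
        lo, hi = model.fit_range
        assert lo >= 20.0 and hi <= 65.0
        assert fitset.crl.min() >= 20.0 and fitset.crl.max() <= 65.0

    def test_empty_restriction_raises(self, truncated):
        cfg = Approach1Config(restrict_crl=(200.0, 300.0))
        with pytest.raises(td.InsufficientDataError):
            td.run_approach1(truncated, cfg, seed=1)


class TestApproach3:
    def test_exact_centile_coordinates_invert_to_the_generating_model(self):
        """Noise-free inversion is an identity up to FP approximation error."""
        ga_grid = np.arange(63.0, 120.0) / 7.0
        coords = []
        for spec in (td.CENTILE_3, td.MEDIAN, td.CENTILE_97):
            crl = np.array(
                [
                    brentq(
                        lambda c, g=g: td.VERBURG.centile(c, spec)[0] - g, 1.0, 400.0
                    )
                    for g in ga_grid
                ]
            )
            coords.append((crl, ga_grid))
        model = td.fit_dating_from_coordinates(coords)
        grid = np.arange(10.0, 101.0, 5.0)
        diff_days = (
            td.VERBURG.median(grid) - model.predict_centile(grid, td.MEDIAN)
        ) * 7
        assert np.max(np.abs(diff_days)) < 0.05
        sd_grid = model.sd.predict(np.arange(20.0, 91.0, 5.0))
        assert np.allclose(sd_grid, 0.04590, rtol=0.02)

    def test_full_run_recovers_generating_sd_scale(self, approach3_model):
        sd_vals = approach3_model.sd.predict(np.arange(20.0, 91.0, 5.0))
        assert np.all(np.abs(sd_vals - 0.04590) / 0.04590 < 0.15)

    def test_sd_recovery_matches_outer_regressions(self, truncated):
        """Averaged half-spread SD tracks the SD implied by the outer fits."""
        size = td.fit_size_model(truncated)
        cfg = Approach3Config()
        ga = np.asarray(cfg.ga_eval_days, dtype=float) / 7.0
        fits = {}
        for level in cfg.centile_levels:
            crl = size.predict_centile(ga, td.CentileSpec(level))
            fits[level] = td.fit_fp_mean(
                crl, ga, outcome_log=True, covariate_name="crl_mm"
            )
        grid = np.arange(25.0, 96.0, 5.0)
        direct = (fits[0.03].predict(grid) - fits[0.97].predict(grid)) / (
            2 * td.CENTILE_3.K
        )
        model = td.run_approach3(truncated, cfg)
        recovered = model.sd.predict(grid)
        assert np.max(np.abs(recovered - direct) / direct) < 0.02

    def test_nonmonotone_coordinates_rejected(self):
        ga = np.linspace(9.0, 14.0, 20)
        bad = np.concatenate([np.linspace(20, 50, 10), np.linspace(49, 30, 10)])
        good = np.linspace(20, 80, 20)
        with pytest.raises(td.InversionInvalidError):
            td.fit_dating_from_coordinates([(bad, ga), (good, ga), (good + 5, ga)])


class TestRecoverSD:
    def test_exact_lognormal_centiles_give_constant_sigma(self):
        crl = np.arange(10.0, 101.0, 5.0)
        sigma, K = 0.0459, td.CENTILE_97.K
        c50 = td.VERBURG.median(crl)
        sd = td.recover_sd_from_centiles(
            crl, c50 * np.exp(-K * sigma), c50, c50 * np.exp(K * sigma), K=K
        )
        assert np.allclose(sd.predict(crl), sigma, atol=1e-12)

    def test_ordering_violation_raises(self):
        crl = np.arange(10.0, 101.0, 5.0)
        c50 = td.VERBURG.median(crl)
        with pytest.raises(td.InvalidCentilesError):
            td.recover_sd_from_centiles(crl, c50, c50 * 0.9, c50 * 1.1)


class TestInvariants:
    def test_all_approaches_give_increasing_median_ga(
        self, approach1_fit, approach2_model, approach3_model
    ):
        grid = np.arange(10.0, 101.0, 1.0)
        for model in (approach1_fit[0], approach2_model, approach3_model):
            med = model.predict_centile(grid, td.MEDIAN)
            assert np.all(np.diff(med) > 0)

    def test_reruns_with_same_seed_are_identical(self, truncated):
        a = td.run_approach1(truncated, seed=5)
        b = td.run_approach1(truncated, seed=5)
        assert a.mean == b.mean and a.sd == b.sd


class TestSensitivity:
    def test_single_cutoff_reproduces_base_run(self, truncated):
        base = Approach1Config(sensitivity_cutoffs=(20.0,))
        table = td.sensitivity_lower_cutoff(truncated, base, td.VERBURG, seed=9)
        model = td.run_approach1(truncated, base, seed=9)
        comp = td.compare_to_reference(model, td.VERBURG, np.arange(20.0, 101.0, 5.0))
        max_abs, mean = td.agreement_summary(comp, (20.0, 100.0), "median")
        assert len(table) == 1
        assert table.loc[0, "cutoff_mm"] == 20.0
        assert table.loc[0, "max_abs_diff_days"] == pytest.approx(max_abs)
        assert table.loc[0, "mean_diff_days"] == pytest.approx(mean)

    def test_reports_one_row_per_cutoff(self, truncated):
        cfg = Approach1Config()
        table = td.sensitivity_lower_cutoff(truncated, cfg, td.VERBURG, seed=9)
        assert list(table["cutoff_mm"]) == [10.0, 15.0, 20.0]
        assert (table["max_abs_diff_days"] >= 0).all()
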
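import dataclasses
import warnings

import numpy as np
import pytest
from scipy.stats import chi2, multivariate_normal

from polycat.calibrate import (
    CalibrationError,
    FitResult,
    PipelineConfig,
    _bvn_cdf,
    calibration_pipeline,
    detect_reversals,
    fit_gpcm,
    fit_pcm,
    item_fit_g2,
    likelihood_ratio_test,
    polychoric_correlation,
    unidimensionality_screen,
)
from polycat.item_bank import ItemBank, ItemParameters, ResponseMatrix
from polycat.simulate import simulate_responses
from conftest import two_group_matrix


@pytest.fixture(scope="module")
def recovery_fit(recovery_bank):
    thetas = np.random.default_rng(101).normal(0, 1, 1000)
    rm = simulate_responses(recovery_bank, thetas, 201)
    return rm, fit_gpcm(rm)


class TestFitGpcm:
    def test_parameter_recovery(self, recovery_bank, recovery_fit):
        _, fit = recovery_fit
        true_a = np.array([it.slope for it in recovery_bank])
        est_a = np.array([fit.bank[it.item_id].slope for it in recovery_bank])
        assert np.sqrt(np.mean((true_a - est_a) ** 2)) < 0.15
        true_b = np.concatenate([it.step_difficulties for it in recovery_bank])
        est_b = np.concatenate([fit.bank[it.item_id].step_difficulties for it in recovery_bank])
        assert np.sqrt(np.mean((true_b - est_b) ** 2)) < 0.2

    def test_marginal_likelihood_monotone(self, recovery_fit):
        _, fit = recovery_fit
        path = np.array(fit.loglik_path)
        assert np.all(np.diff(path) > -1e-6)

    def test_parameter_count_and_se(self, recovery_fit):
        _, fit = recovery_fit
        # 10 items: 6 dichotomous (1 step) + 4 trichotomous (2 steps) + 10 slopes
        assert fit.n_parameters == 6 + 8 + 10
        assert fit.converged and np.isfinite(fit.deviance)
        assert len(fit.standard_errors) == fit.n_parameters
        assert all(se > 0 for se in fit.standard_errors.values())

    def test_duplicated_respondents_sufficiency(self, recovery_bank):
        thetas = np.random.default_rng(5).normal(0, 1, 300)
        rm = simulate_responses(recovery_bank, thetas, 6)
        doubled = ResponseMatrix(
            respondent_ids=[f"P{i}" for i in range(600)],
            item_ids=rm.item_ids,
            values=np.vstack([rm.values, rm.values]),
        )
        f1 = fit_gpcm(rm)
        f2 = fit_gpcm(doubled)
        a1 = np.array([it.slope for it in f1.bank])
        a2 = np.array([it.slope for it in f2.bank])
        np.testing.assert_allclose(a1, a2, atol=5e-3)
        assert f2.deviance == pytest.approx(2 * f1.deviance, rel=1e-4)

    def test_degenerate_item_rejected(self):
        values = np.zeros((50, 2), dtype=int)
        values[:, 1] = np.random.default_rng(0).integers(0, 2, 50)
        rm = ResponseMatrix([f"P{i}" for i in range(50)], ["DEAD", "OK"], values)
        with pytest.raises(CalibrationError, match="DEAD"):
            fit_gpcm(rm)

    def test_too_few_items_rejected(self):
        rm = ResponseMatrix(["P1", "P2"], ["I1"], [[0], [1]])
        with pytest.raises(CalibrationError):
            fit_gpcm(rm)


class TestFitPcm:
    def test_common_slope_recovery(self):
        items = [
            ItemParameters(f"I{j}", 1.4, (b,), 2)
            for j, b in enumerate(np.linspace(-1.5, 1.5, 8))
        ]
        bank = ItemBank(items)
        thetas = np.random.default_rng(8).normal(0, 1, 1000)
        rm = simulate_responses(bank, thetas, 9)
        fit = fit_pcm(rm)
        assert abs(fit.bank.items[0].slope - 1.4) < 0.1
        slopes = {it.slope for it in fit.bank}
        assert len(slopes) == 1  # one shared slope

    def test_nested_in_gpcm(self, recovery_fit):
        rm, g_fit = recovery_fit
        p_fit = fit_pcm(rm)
        assert p_fit.deviance >= g_fit.deviance
        assert g_fit.n_parameters - p_fit.n_parameters == len(g_fit.bank) - 1


class TestLikelihoodRatio:
    def fake_fit(self, deviance, n_parameters, k_items):
        bank = ItemBank(
            [ItemParameters(f"I{j}", 1.0, (0.0,), 2) for j in range(k_items)]
        )
        return FitResult(
            bank=bank, standard_errors={}, deviance=deviance,
            n_parameters=n_parameters, converged=True, n_iterations=1,
        )

    def test_df_for_67_items(self):
        k = 67
        gpcm = self.fake_fit(1000.0, k + k, k)      # k steps + k slopes
        pcm = self.fake_fit(1242.972, k + 1, k)
        res = likelihood_ratio_test(gpcm, pcm)
        assert res.df == 66
        assert res.chi_square == pytest.approx(242.972)
        assert res.p_value < 0.001

    def test_identical_deviances(self):
        gpcm = self.fake_fit(500.0, 20, 10)
        pcm = self.fake_fit(500.0, 11, 10)
        res = likelihood_ratio_test(gpcm, pcm)
        assert res.chi_square == 0.0 and res.p_value == 1.0

    def test_negative_chi_square_signals_failure(self):
        gpcm = self.fake_fit(500.0, 20, 10)
        pcm = self.fake_fit(400.0, 11, 10)
        with pytest.raises(CalibrationError):
            likelihood_ratio_test(gpcm, pcm)


class TestItemFit:
    def test_type_one_rate_within_binomial_bounds(self, recovery_fit):
        """Data simulated from the fitted model itself -> ~nominal flag rate."""
        rm, fit = recovery_fit
        rng = np.random.default_rng(31)
        flags, total = 0, 0
        for rep in range(5):
            thetas = rng.normal(0, 1, 1000)
            rm_rep = simulate_responses(fit.bank, thetas, int(rng.integers(2**31)))
            refit = fit_gpcm(rm_rep)
            results = item_fit_g2(refit, rm_rep)
            flags += sum(r.p_value < 0.05 for r in results)
            total += len(results)
        # binomial(50, 0.05) central 99% interval: [0, 7]
        assert flags <= 7

    def test_misspecified_item_flagged(self, recovery_bank):
        thetas = np.random.default_rng(17).normal(0, 1, 1000)
        rm = simulate_responses(recovery_bank, thetas, 18)
        fit = fit_gpcm(rm)
        items = list(fit.bank.items)
        items[3] = dataclasses.replace(items[3], slope=0.5)  # truth is ~2.1
        bad = dataclasses.replace(fit, bank=ItemBank(items, name="bad"))
        results = item_fit_g2(bad, rm)
        assert results[3].p_value < 1e-6

    def test_group_bookkeeping(self, recovery_fit):
        rm, fit = recovery_fit
        for r in item_fit_g2(fit, rm):
            assert 2 <= r.n_groups_used <= 10
            assert r.g2 >= 0
            m = fit.bank[r.item_id].max_category
            assert r.df == r.n_groups_used * m - (m + 1)


class TestReversals:
    def test_flagging(self):
        bank = ItemBank(
            [
                ItemParameters("REV", 1.0, (0.5, 0.2), 3),
                ItemParameters("OK", 1.0, (0.2, 0.5), 3),
                ItemParameters("DICH", 1.0, (0.1,), 2),
            ]
        )
        assert detect_reversals(bank) == ["REV"]

    def test_dichotomous_never_flagged(self):
        bank = ItemBank([ItemParameters(f"I{j}", 1.0, (0.0,), 2) for j in range(5)])
        assert detect_reversals(bank) == []


class TestUnidimensionality:
    def test_bvn_cdf_matches_scipy(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            h, k = rng.uniform(-2.5, 2.5, 2)
            rho = rng.uniform(-0.95, 0.95)
            ref = multivariate_normal(cov=[[1, rho], [rho, 1]]).cdf([h, k])
            assert abs(_bvn_cdf(h, k, rho) - ref) < 1e-10

    def test_polychoric_recovers_latent_correlation(self):
        rng = np.random.default_rng(1)
        z = rng.multivariate_normal([0, 0], [[1, 0.6], [0.6, 1]], 4000)
        x = np.digitize(z[:, 0], [-0.5, 0.7])
        y = np.digitize(z[:, 1], [-0.3, 0.9])
        assert polychoric_correlation(x, y) == pytest.approx(0.6, abs=0.05)

    def test_duplicate_items_near_unit_correlation(self):
        rng = np.random.default_rng(2)
        x = rng.integers(0, 3, 800)
        assert polychoric_correlation(x, x.copy()) > 0.98

    def test_one_factor_data_clean(self, small_study):
        bank, _, rm = small_study
        res = unidimensionality_screen(rm)
        assert res.flagged_items == []
        assert res.eigenvalue_ratio > 3
        assert np.allclose(np.diag(res.polychoric_matrix), 1.0)

    def test_noise_item_flagged(self, small_study):
        bank, _, rm = small_study
        noise = np.random.default_rng(8).integers(0, 3, rm.n_respondents)
        rm2 = ResponseMatrix(
            rm.respondent_ids, rm.item_ids + ["NOISE"],
            np.column_stack([rm.values, noise]),
        )
        res = unidimensionality_screen(rm2)
        assert res.flagged_items == ["NOISE"]

    def test_single_category_item_excluded(self, small_study):
        bank, _, rm = small_study
        dead = np.zeros(rm.n_respondents, dtype=int)
        rm2 = ResponseMatrix(
            rm.respondent_ids, rm.item_ids + ["DEAD"],
            np.column_stack([rm.values, dead]),
        )
        with pytest.warns(RuntimeWarning, match="DEAD"):
            res = unidimensionality_screen(rm2)
        assert res.excluded_items == ["DEAD"]


class TestPipeline:
    def test_clean_study_drops_nothing(self, screen_bank, small_study):
        _, _, rm = small_study
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            final, report = calibration_pipeline(rm)
        dropped = [d for st in report["stages"] for d in st.get("items_dropped", [])]
        assert dropped == []
        assert len(final) == len(screen_bank)
        true_a = np.array([it.slope for it in screen_bank])
        est_a = np.array([final[it.item_id].slope for it in screen_bank])
        assert np.corrcoef(true_a, est_a)[0, 1] > 0.9

    def test_planted_defects_dropped(self, screen_bank):
        items_b = list(screen_bank.items)
        it = items_b[5]   # central, high-slope item
        items_b[5] = dataclasses.replace(
            it, step_difficulties=tuple(np.asarray(it.step_difficulties) + 0.8)
        )
        bank_b = ItemBank(items_b, "shifted")
        rm = two_group_matrix(screen_bank, bank_b, 300, seed=3)
        noise = np.random.default_rng(3).integers(0, 3, rm.n_respondents)
        rm = ResponseMatrix(
            rm.respondent_ids, rm.item_ids + ["NZ"],
            np.column_stack([rm.values, noise]), groups=rm.groups,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            final, report = calibration_pipeline(rm)
        dropped = sorted(
            d["item_id"] for st in report["stages"] for d in st.get("items_dropped", [])
        )
        assert dropped == [it.item_id, "NZ"]

    def test_stage_order_fixed(self, small_study):
        _, _, rm = small_study
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, report = calibration_pipeline(rm)
        assert [s["stage"] for s in report["stages"]] == [
            "min_responses", "unidimensionality", "model_comparison",
            "item_fit", "reversals", "dif", "final_fit",
        ]
        assert report["model"] in ("GPCM", "PCM")

    def test_group_specific_items_thresholded(self, screen_bank, small_study):
        _, _, rm = small_study
        sparse = np.full(rm.n_respondents, -1, dtype=int)
        sparse[:10] = np.random.default_rng(1).integers(0, 2, 10)
        rm2 = ResponseMatrix(
            rm.respondent_ids, rm.item_ids + ["FEM1"],
            np.column_stack([rm.values, sparse]),
        )
        cfg = PipelineConfig(group_specific={"FEM1": "female"})
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            final, report = calibration_pipeline(rm2, cfg)
        stage1 = report["stages"][0]
        assert any(d["item_id"] == "FEM1" for d in stage1["items_dropped"])
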
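import math
from dataclasses import replace

import numpy as np
import pytest

import ssie
from ssie.fit import (
    FitError,
    FitResult,
    LRModel,
    SSiEModel,
    compare_models,
    cumulative_consumption,
    fit_lr_baseline,
    fit_mle,
    information_criteria,
    loglik,
    predict_mean,
    profiled_sigma,
)
from ssie.greenlab import RecurrenceModel
from ssie.lir import LIRSpec

from conftest import make_ssie_dataset


class TestCumulativeConsumption:
    def test_prefix_sums(self):
        assert cumulative_consumption([1.0, 2.0, 3.0]) == pytest.approx([0.0, 1.0, 3.0])

    def test_offset_only(self):
        assert cumulative_consumption([1.0], c0=0.4) == pytest.approx([0.4])

    def test_telescoping(self):
        w = np.array([0.5, 1.2, 0.8, 2.0])
        sw = cumulative_consumption(w, c0=0.3)
        assert sw[-1] + w[-1] == pytest.approx(0.3 + w.sum())

    def test_negative_entries_rejected(self):
        with pytest.raises(FitError):
            cumulative_consumption([1.0, -0.1])


class TestPredictMean:
    def exp_model(self, **kw):
        return SSiEModel(theta1=0.005, lir=LIRSpec("exp", {"k": 0.5}), sigma=0.1, **kw)

    def test_zero_history_gives_zero_mean(self):
        e = np.full(5, 300.0)
        mean = predict_mean(self.exp_model(), e, np.zeros(5))
        assert mean[0] == 0.0

    def test_saturated_history_gives_ceiling(self):
        e = np.array([250.0, 300.0])
        mean = predict_mean(self.exp_model(), e, np.array([1e6, 0.0]))
        assert mean[1] == pytest.approx(0.005 * 300.0)

    def test_mean_linear_in_radiation(self):
        e = np.linspace(100, 400, 8)
        w = np.linspace(0.2, 1.5, 8)
        m1 = predict_mean(self.exp_model(), e, w)
        m2 = predict_mean(self.exp_model(), 3.0 * e, w)
        assert m2 == pytest.approx(3.0 * m1)

    def test_recurrence_mean_bounded_by_ceiling(self):
        model = RecurrenceModel(theta1=0.005, theta2=0.5, r_source="parametric", a=0.0, t_max=10)
        e = np.full(10, 300.0)
        w = np.linspace(0.5, 2.0, 10)
        mean = predict_mean(model, e, w)
        assert np.all(mean >= 0.0) and np.all(mean <= 0.005 * e + 1e-12)
        assert mean[0] == 0.0  # empty history

    def test_misaligned_series_rejected(self):
        with pytest.raises(FitError):
            predict_mean(self.exp_model(), np.ones(4), np.ones(5))


class TestLoglik:
    def test_zero_residual_closed_form(self):
        # 10 points, sigma = 0.2: loglik = -5 ln(2 pi 0.04)
        e = np.full(10, 200.0)
        model = SSiEModel(theta1=1.0, lir=LIRSpec("exp", {"k": 1.0}), sigma=0.2, sw_offset=1e9)
        w = predict_mean(model, e, np.zeros(10))
        assert loglik(model, e, w) == pytest.approx(-5.0 * math.log(2 * math.pi * 0.04))

    def test_profiled_sigma_maximizes(self):
        rng = np.random.default_rng(0)
        e = np.full(20, 300.0)
        w = rng.uniform(0.5, 1.5, 20)
        model = SSiEModel(theta1=0.004, lir=LIRSpec("exp", {"k": 0.3}), sigma=1.0)
        resid = w - predict_mean(model, e, w)
        sig_hat = math.sqrt(float(resid @ resid) / 20)
        ll_hat = loglik(replace(model, sigma=sig_hat), e, w)
        for s in (0.5 * sig_hat, 2.0 * sig_hat):
            assert loglik(replace(model, sigma=s), e, w) < ll_hat
        # concentrated-likelihood identity round-trips
        assert profiled_sigma(ll_hat, 20) == pytest.approx(sig_hat, rel=1e-12)

    def test_scale_compensation_between_theta1_and_radiation(self):
        rng = np.random.default_rng(1)
        e = rng.uniform(200, 350, 15)
        w = rng.uniform(0.3, 1.8, 15)
        m1 = SSiEModel(theta1=0.006, lir=LIRSpec("exp", {"k": 0.2}), sigma=0.2)
        m2 = replace(m1, theta1=0.006 / 3.0)
        assert loglik(m1, e, w) == pytest.approx(loglik(m2, 3.0 * e, w), rel=1e-12)


class TestInformationCriteria:
    def test_aicc_penalty_identity(self):
        ll, k, n = 12.0, 4, 53
        aicc, _ = information_criteria(ll, k, n)
        assert aicc - (-2 * ll + 2 * k) == pytest.approx(2 * k * (k + 1) / (n - k - 1))

    def test_undefined_for_tiny_samples(self):
        with pytest.raises(FitError):
            information_criteria(0.0, 4, 5)


class TestFitMLE:
    def test_single_seed_exponential_recovery(self, cycle_radiation):
        truth = {"theta1": 0.005, "k": 0.13}
        w = make_ssie_dataset("exp", truth, cycle_radiation, seed=2024, sigma=0.05)
        fr = fit_mle("exp", cycle_radiation, w, n_starts=100, seed=9)
        assert fr.estimates["theta1"] == pytest.approx(0.005, rel=0.10)
        assert fr.estimates["k"] == pytest.approx(0.13, rel=0.10)
        assert fr.estimates["sigma"] == pytest.approx(0.05, rel=0.15)
        assert fr.rmse == pytest.approx(fr.estimates["sigma"])  # MLE identity
        # FitResult criteria match the closed formulas
        aicc, bic = information_criteria(fr.loglik, fr.k, fr.n)
        assert (fr.aicc, fr.bic) == pytest.approx((aicc, bic))

    def test_repeat_call_is_bit_identical(self, daily_dataset):
        e, w = daily_dataset
        a = fit_mle("exp", e, w, n_starts=20, seed=5, c0=0.4)
        b = fit_mle("exp", e, w, n_starts=20, seed=5, c0=0.4)
        assert a.estimates == b.estimates and a.loglik == b.loglik

    def test_more_starts_never_hurt(self, daily_dataset):
        e, w = daily_dataset
        one = fit_mle("gamma", e, w, n_starts=1, seed=12, c0=0.4)
        many = fit_mle("gamma", e, w, n_starts=40, seed=12, c0=0.4)
        assert many.loglik >= one.loglik - 1e-9

    def test_exponential_matches_unit_order_mittag_leffler(self, cycle_radiation):
        # the Mittag-Leffler family at tail order 1 embeds the exponential
        # family exactly, so both searches reach the same maximized likelihood
        e = cycle_radiation[:120]
        w = make_ssie_dataset("mlf", {"theta1": 0.005, "k": 0.13, "a_ml": 1.0}, e, seed=4, sigma=0.05)
        fr_exp = fit_mle("exp", e, w, n_starts=40, seed=6)
        fr_mlf = fit_mle(
            "mlf", e, w, n_starts=12, seed=6, bounds={"a_ml": (1.0 - 1e-12, 1.0)}
        )
        assert fr_exp.loglik == pytest.approx(fr_mlf.loglik, abs=1e-3)

    def test_recovery_improves_with_sample_size_and_lower_noise(self, cycle_radiation):
        truth = {"theta1": 0.005, "k": 0.13}

        def median_k_err(n, sigma):
            errs = []
            for s in range(3):
                w = make_ssie_dataset("exp", truth, cycle_radiation[:n], seed=100 + s, sigma=sigma)
                fr = fit_mle("exp", cycle_radiation[:n], w, n_starts=30, seed=s)
                errs.append(abs(fr.estimates["k"] - truth["k"]) / truth["k"])
            return float(np.median(errs))

        assert median_k_err(200, 0.05) <= median_k_err(60, 0.05) + 1e-9
        assert median_k_err(200, 0.05) <= median_k_err(200, 0.4) + 1e-9

    def test_insufficient_data_rejected(self):
        with pytest.raises(FitError):
            fit_mle("gamma", np.ones(4), np.ones(4), n_starts=2, seed=0)

    def test_unknown_family_rejected(self):
        with pytest.raises(FitError):
            fit_mle("weibull", np.ones(20), np.ones(20))

    def test_recurrence_families_fit(self, daily_dataset):
        e, w = daily_dataset
        fr = fit_mle("exp-rate", e, w, n_starts=25, seed=3)
        assert fr.k == 4 and fr.n == len(w) - 1
        assert np.isfinite(fr.loglik)


class TestLRBaseline:
    def test_noiseless_coefficients_recovered_exactly(self):
        rng = np.random.default_rng(3)
        e = rng.uniform(150, 350, 40)
        w = np.zeros(40)
        for t in range(1, 40):
            w[t] = 0.5 + 0.9 * w[t - 1] + 0.002 * e[t]
        fr = fit_lr_baseline(e, w)
        assert fr.estimates["b0"] == pytest.approx(0.5, abs=1e-9)
        assert fr.estimates["b1"] == pytest.approx(0.9, abs=1e-9)
        assert fr.estimates["b2"] == pytest.approx(0.002, abs=1e-9)

    def test_54_day_series_yields_53_regression_rows(self, daily_dataset):
        e, w = daily_dataset
        fr = fit_lr_baseline(e, w)
        assert fr.n == 53
        assert 0.0 <= fr.estimates["r_squared"] <= 1.0

    def test_collinear_design_rejected(self):
        e = np.full(20, 300.0)  # constant radiation duplicates the intercept
        w = np.linspace(0.5, 1.5, 20)
        with pytest.raises(FitError):
            fit_lr_baseline(e, w)


def _dummy_fit(family, ll, k, n=53):
    aicc, bic = information_criteria(ll, k, n)
    model = LRModel(b0=0.0, b1=0.0, b2=0.0, sigma=1.0)
    return FitResult(
        model=model, family=family, estimates={}, loglik=ll, k=k, n=n,
        rmse=1.0, aicc=aicc, bic=bic,
    )


class TestCompareModels:
    def test_fewer_parameters_win_ties(self):
        table = compare_models([_dummy_fit("a", 10.0, 4), _dummy_fit("b", 10.0, 3)])
        assert list(table["family"]) == ["b", "a"]

    def test_single_fit(self):
        table = compare_models([_dummy_fit("only", 5.0, 3)])
        assert len(table) == 1

    def test_input_order_irrelevant(self):
        fits = [_dummy_fit("a", 10.0, 4), _dummy_fit("b", 12.0, 4), _dummy_fit("c", 8.0, 3)]
        t1 = compare_models(fits)
        t2 = compare_models(fits[::-1])
        assert list(t1["family"]) == list(t2["family"])

    def test_mixed_sample_sizes_rejected(self):
        with pytest.raises(FitError):
            compare_models([_dummy_fit("a", 10.0, 4, n=53), _dummy_fit("b", 10.0, 4, n=54)])
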
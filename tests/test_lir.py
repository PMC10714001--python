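import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import special as sp
from scipy.integrate import quad

from ssie.lir import (
    LIRError,
    LIRSpec,
    MLConvergenceError,
    lir,
    mittag_leffler,
    mittag_leffler_series,
)

# Reference values computed with 60-digit arithmetic on the defining series.
_ML_REFERENCE = [
    (0.1, -0.5, 0.65432446028800193),
    (0.1, -3.0, 0.23855934978253856),
    (0.25, -1.7, 0.33411339744289772),
    (0.35, -6.0, 0.11102465524239703),
    (0.5, -0.25, 0.77034654773099674),
    (0.5, -4.0, 0.13699945762506139),
    (0.5, -12.0, 0.046854221014893763),
    (0.6, -2.5, 0.1909167074011698),
    (0.7, -9.0, 0.040531197267350683),
    (0.75, -0.8, 0.46272669723112535),
    (0.8, -20.0, 0.011617250451432778),
    (0.9, -1.3, 0.28811228644540738),
    (0.9, -15.0, 0.0079286024323444471),
    (0.95, -25.0, 0.0022247079107317236),
    (0.99, -3.3, 0.040566964228294564),
    (0.999, -7.0, 0.0011226152328407223),
    (0.3, 1.5, 158.07887059078353),
    (0.8, 0.9, 2.8945423030318847),
]


class TestMittagLeffler:
    @pytest.mark.parametrize("a", [0.05, 0.3, 0.5, 0.8, 1.0])
    def test_value_at_zero_is_one(self, a):
        assert mittag_leffler(0.0, a) == pytest.approx(1.0, abs=1e-14)

    def test_order_one_reduces_to_exponential(self):
        x = np.array([-5.0, -1.0, 0.0, 1.0])
        assert mittag_leffler(x, 1.0) == pytest.approx(np.exp(x), rel=1e-14)

    def test_half_order_matches_scaled_erfc(self):
        # E_{1/2}(-x) = e^(x^2) erfc(x) on the nonpositive-argument range
        x = np.array([0.0, 0.2, 1.0, 3.0, 8.0, 20.0])
        got = mittag_leffler(-x, 0.5)
        assert got == pytest.approx(sp.erfcx(x), rel=1e-10)

    @pytest.mark.parametrize("a,x,expected", _ML_REFERENCE)
    def test_against_high_precision_references(self, a, x, expected):
        assert mittag_leffler(x, a) == pytest.approx(expected, rel=1e-9)

    @pytest.mark.parametrize("a", [0.4, 0.6, 0.8, 1.0])
    def test_agrees_with_series_oracle_on_small_arguments(self, a):
        x = np.linspace(-2.0, 2.0, 21)
        assert mittag_leffler(x, a) == pytest.approx(
            mittag_leffler_series(x, a), rel=1e-10
        )

    def test_continuous_at_order_one(self):
        # E_a(x) -> e^x as a -> 1; the residual difference at a = 1 - 1e-6
        # is of order 1e-6 * x^2, well inside the 1e-3 band checked here
        x = np.array([-3.0, -1.0, -0.3])
        assert mittag_leffler(x, 1.0 - 1e-6) == pytest.approx(np.exp(x), rel=1e-3)

    @pytest.mark.parametrize("a", [0.0, -0.3, 1.2])
    def test_order_outside_unit_interval_rejected(self, a):
        with pytest.raises(LIRError):
            mittag_leffler(-1.0, a)

    def test_large_positive_argument_rejected(self):
        with pytest.raises(LIRError):
            mittag_leffler(5.0, 0.5)

    def test_series_refuses_arguments_beyond_its_accuracy(self):
        with pytest.raises(MLConvergenceError):
            mittag_leffler_series(-30.0, 0.5)

    def test_completely_monotone_on_negative_axis(self):
        for a in (0.3, 0.7, 0.95):
            t = np.geomspace(1e-3, 50.0, 60)
            vals = mittag_leffler(-t, a)
            assert np.all(np.diff(vals) < 0)
            assert np.all((vals > 0) & (vals <= 1.0))


def density_quad_cdf(family, params, sw):
    """Independent oracle: adaptive quadrature of the family's density."""
    if family == "exp":
        f = lambda s: params["k"] * math.exp(-params["k"] * s)
    elif family == "gamma":
        k, a = params["k"], params["a_gamma"]
        f = lambda s: k**a / sp.gamma(a) * s ** (a - 1) * math.exp(-k * s)
    elif family == "lognorm":
        mu, sd = params["mu_log"], params["sigma_log"]
        f = lambda s: math.exp(-((math.log(s) - mu) ** 2) / (2 * sd**2)) / (
            s * sd * math.sqrt(2 * math.pi)
        )
    elif family == "pareto":
        th, eta = params["theta"], params["eta"]
        f = lambda s: th * eta**th / s ** (th + 1) if s > eta else 0.0
        val, _ = quad(f, eta, max(sw, eta), limit=200)
        return val
    val, _ = quad(f, 0.0, sw, limit=200, points=None)
    return val


class TestLIRFamilies:
    def test_exp_half_life(self):
        spec = LIRSpec("exp", {"k": 1.0})
        assert spec.cdf(math.log(2.0)) == pytest.approx(0.5, rel=1e-12)

    def test_mlf_order_one_equals_exponential_family(self):
        k = 0.13
        sw = np.linspace(0.0, 60.0, 31)
        mlf = LIRSpec("mlf", {"k": k, "a_ml": 1.0})
        exp = LIRSpec("exp", {"k": k})
        assert mlf.cdf(sw) == pytest.approx(exp.cdf(sw), abs=1e-12)

    def test_gamma_matches_quadrature_oracle(self):
        spec = LIRSpec("gamma", {"k": 0.01, "a_gamma": 0.386})
        got = spec.cdf(50.0)
        assert got == pytest.approx(density_quad_cdf("gamma", spec.params, 50.0), abs=1e-8)

    def test_gamma_shape_one_equals_exponential(self):
        sw = np.linspace(0.0, 40.0, 23)
        g = LIRSpec("gamma", {"k": 0.2, "a_gamma": 1.0})
        e = LIRSpec("exp", {"k": 0.2})
        assert g.cdf(sw) == pytest.approx(e.cdf(sw), abs=1e-10)

    def test_lognorm_median(self):
        spec = LIRSpec("lognorm", {"mu_log": 1.7, "sigma_log": 0.9})
        assert spec.cdf(math.exp(1.7)) == pytest.approx(0.5, rel=1e-12)

    def test_pareto_closed_form(self):
        spec = LIRSpec("pareto", {"theta": 1.0, "eta": 0.4})
        assert spec.cdf(0.8) == pytest.approx(0.5, rel=1e-12)
        assert spec.cdf(0.4) == 0.0
        assert spec.cdf(0.1) == 0.0

    def test_negative_consumption_rejected(self):
        with pytest.raises(LIRError):
            LIRSpec("exp", {"k": 1.0}).cdf(-0.5)

    @pytest.mark.parametrize(
        "family,params",
        [
            ("exp", {"k": -1.0}),
            ("gamma", {"k": 0.1, "a_gamma": 0.0}),
            ("mlf", {"k": 0.1, "a_ml": 1.5}),
            ("lognorm", {"mu_log": 0.0, "sigma_log": -0.1}),
            ("pareto", {"theta": 0.0, "eta": 0.4}),
            ("exp", {"rate": 1.0}),
            ("nope", {}),
        ],
    )
    def test_invalid_specs_rejected(self, family, params):
        with pytest.raises(LIRError):
            LIRSpec(family, params)

    @settings(derandomize=True, max_examples=30)
    @given(
        family=st.sampled_from(["exp", "gamma", "mlf", "lognorm", "pareto"]),
        u1=st.floats(0.05, 0.95),
        u2=st.floats(0.05, 0.95),
    )
    def test_every_family_is_a_cdf(self, family, u1, u2):
        params = {
            "exp": {"k": 0.01 + u1},
            "gamma": {"k": 0.01 + u1, "a_gamma": 0.2 + 3 * u2},
            "mlf": {"k": 0.01 + u1, "a_ml": 0.05 + 0.95 * u2},
            "lognorm": {"mu_log": 4 * (u1 - 0.5), "sigma_log": 0.2 + 2 * u2},
            "pareto": {"theta": 0.3 + 3 * u1, "eta": 0.05 + u2},
        }[family]
        spec = LIRSpec(family, params)
        sw = np.linspace(0.0, 80.0, 40)
        vals = spec.cdf(sw)
        assert np.all(np.diff(vals) >= -1e-12)  # nondecreasing
        assert np.all((vals >= 0.0) & (vals <= 1.0))
        assert lir(spec, 1e9) > 0.9  # right limit approaches one

    def test_serialization_roundtrip(self):
        spec = LIRSpec("gamma", {"k": 0.02, "a_gamma": 0.5})
        assert LIRSpec.from_dict(spec.to_dict()) == spec
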
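"""Estimation and model comparison for water-consumption models.

All stochastic models share the observation structure
W_c(t) ~ N(mean_t, sigma^2) with independent homoskedastic Gaussian errors:

* SSiE:        mean_t = theta1 * E(t) * F_X(SW_c(t^-))
* recurrence:  mean_t = theta1 * E(t) * (1 - exp(-theta2 * sum_{n<t} r(n) W_c(n)))
* LR baseline: mean_t = b0 + b1 W_c(t-1) + b2 E(t)   (ordinary least squares)

The noise level sigma is always profiled analytically (sigma_hat^2 = RSS/n),
so the numerical search runs over the mean parameters only; sigma still
counts as an estimated parameter in the information criteria.  Maximum
likelihood uses bounded L-BFGS-B from many uniformly drawn starting points,
keeping the best optimum (deterministic for a given seed).
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import statsmodels.api as sm
from scipy.optimize import minimize

from .greenlab import RecurrenceModel, r_coefficients
from .lir import FAMILIES, LIRSpec

__all__ = [
    "FitError",
    "SSiEModel",
    "LRModel",
    "FitResult",
    "MODEL_FAMILIES",
    "cumulative_consumption",
    "predict_mean",
    "loglik",
    "profiled_sigma",
    "fit_mle",
    "information_criteria",
    "fit_lr_baseline",
    "compare_models",
    "default_bounds",
]


class FitError(ValueError):
    """Invalid estimation inputs or a failed estimation."""


@dataclass(frozen=True)
class SSiEModel:
    """Stochastic Segmentation of input Energy model.

    theta1 (L per radiation unit) absorbs RUE * S_p * mu0 together with the
    greenhouse transmission of radiation; ``lir`` is the CDF family giving
    the light interception ratio at the cumulated consumption; ``sw_offset``
    is the consumption accumulated before the first observation (c0, liters).
    """

    theta1: float
    lir: LIRSpec
    sigma: float = 0.1
    sw_offset: float = 0.0

    def __post_init__(self) -> None:
        if self.theta1 <= 0:
            raise FitError("theta1 must be > 0")
        if self.sigma <= 0:
            raise FitError("sigma must be > 0")
        if self.sw_offset < 0:
            raise FitError("sw_offset (c0) must be >= 0")


@dataclass(frozen=True)
class LRModel:
    """First-order autoregressive baseline with radiation as exogenous input."""

    b0: float
    b1: float
    b2: float
    sigma: float

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise FitError("sigma must be > 0")


AnyModel = Union[SSiEModel, RecurrenceModel, LRModel]


@dataclass(frozen=True)
class FitResult:
    """Outcome of one maximum-likelihood (or OLS) fit."""

    model: AnyModel
    family: str
    estimates: dict
    loglik: float
    k: int
    n: int
    rmse: float
    aicc: float
    bic: float
    n_starts: int = 1
    seed: Optional[int] = None
    converged_starts: int = 1
    bounds: Optional[dict] = None

    def to_dict(self) -> dict:
        d = {
            "family": self.family,
            "estimates": dict(self.estimates),
            "loglik": self.loglik,
            "k": self.k,
            "n": self.n,
            "rmse": self.rmse,
            "aicc": self.aicc,
            "bic": self.bic,
            "n_starts": self.n_starts,
            "seed": self.seed,
            "converged_starts": self.converged_starts,
        }
        if self.bounds is not None:
            digest = hashlib.sha256(
                json.dumps(self.bounds, sort_keys=True).encode()
            ).hexdigest()[:12]
            d["bounds_digest"] = digest
        return d


def cumulative_consumption(w: Sequence[float], c0: float = 0.0) -> np.ndarray:
    """SW_c(t^-): consumption cumulated strictly before each index, plus c0."""
    w = np.asarray(w, dtype=float)
    if np.any(w < 0) or not np.all(np.isfinite(w)):
        raise FitError("consumption series must be finite and >= 0")
    if c0 < 0:
        raise FitError("c0 must be >= 0")
    out = np.empty_like(w)
    out[0] = c0
    np.cumsum(w[:-1], out=out[1:])
    out[1:] += c0
    return out


def predict_mean(
    model: Union[SSiEModel, RecurrenceModel],
    e: Sequence[float],
    w_history: Sequence[float],
) -> np.ndarray:
    """Model mean consumption for each time, driven by the observed history.

    ``w_history`` supplies W_c(1..T) used only through its strict past at
    each index, so the mean at index t never depends on w_history[t:].
    """
    e = np.asarray(e, dtype=float)
    w_history = np.asarray(w_history, dtype=float)
    if e.shape != w_history.shape:
        raise FitError(
            f"series misaligned: radiation has {e.shape}, history {w_history.shape}"
        )
    if isinstance(model, SSiEModel):
        sw = cumulative_consumption(w_history, model.sw_offset)
        return model.theta1 * e * model.lir.cdf(sw)
    if isinstance(model, RecurrenceModel):
        r = model.r(len(w_history))
        weighted = np.concatenate(([0.0], np.cumsum(r[: len(w_history) - 1] * w_history[:-1])))
        return model.theta1 * e * (-np.expm1(-model.theta2 * weighted))
    raise FitError(f"cannot predict with model type {type(model).__name__}")


def _gauss_loglik(resid: np.ndarray, sigma: float) -> float:
    n = resid.size
    return float(-0.5 * n * math.log(2.0 * math.pi * sigma**2) - 0.5 * np.sum(resid**2) / sigma**2)


def profiled_sigma(loglik_value: float, n: int) -> float:
    """Invert the concentrated log-likelihood l = -(n/2)(1 + ln(2 pi s^2))."""
    return math.sqrt(math.exp(-2.0 * loglik_value / n - 1.0) / (2.0 * math.pi))


def loglik(model: AnyModel, e: Sequence[float], w: Sequence[float]) -> float:
    """Gaussian log-likelihood of the observed series under the model."""
    e = np.asarray(e, dtype=float)
    w = np.asarray(w, dtype=float)
    if isinstance(model, LRModel):
        mean = model.b0 + model.b1 * w[:-1] + model.b2 * e[1:]
        return _gauss_loglik(w[1:] - mean, model.sigma)
    mean = predict_mean(model, e, w)
    if not np.all(np.isfinite(mean)):
        t_bad = int(np.argmax(~np.isfinite(mean)))
        raise FitError(f"non-finite model mean at index {t_bad}")
    return _gauss_loglik(w - mean, model.sigma)


def information_criteria(loglik_value: float, k: int, n: int) -> tuple[float, float]:
    """(AICc, BIC) from a maximized log-likelihood with k parameters, n points."""
    if n <= k + 1:
        raise FitError(f"AICc undefined for n={n} <= k+1={k + 1}")
    aicc = -2.0 * loglik_value + 2.0 * k + 2.0 * k * (k + 1.0) / (n - k - 1.0)
    bic = -2.0 * loglik_value + k * math.log(n)
    return aicc, bic


# free mean-parameters per fitted family (sigma is profiled, not searched)
MODEL_FAMILIES: dict[str, tuple[str, ...]] = {
    "exp": ("theta1", "k"),
    "gamma": ("theta1", "k", "a_gamma"),
    "mlf": ("theta1", "k", "a_ml"),
    "lognorm": ("theta1", "mu_log", "sigma_log"),
    "pareto": ("theta1", "theta", "eta"),
    "greenlab-exp": ("theta1", "theta2"),
    "exp-rate": ("theta1", "theta2", "a"),
}

_THETA1_BOUNDS = (1e-6, 10.0)
_THETA2_BOUNDS = (1e-6, 10.0)
_RATE_EXP_BOUNDS = (-0.99, 5.0)


def default_bounds(family: str) -> dict[str, tuple[float, float]]:
    """Default optimization box for a model family (config-overridable)."""
    if family not in MODEL_FAMILIES:
        raise FitError(f"unknown family {family!r}; choose from {sorted(MODEL_FAMILIES)}")
    bounds = {"theta1": _THETA1_BOUNDS}
    if family in FAMILIES:
        bounds.update(FAMILIES[family]["bounds"])
    else:
        bounds["theta2"] = _THETA2_BOUNDS
        if family == "exp-rate":
            bounds["a"] = _RATE_EXP_BOUNDS
    return bounds


def _build_model(family: str, values: dict, sigma: float, c0: float) -> AnyModel:
    if family in FAMILIES:
        lir_params = {k: v for k, v in values.items() if k != "theta1" and not k.startswith("_")}
        return SSiEModel(
            theta1=values["theta1"],
            lir=LIRSpec(family, lir_params),
            sigma=sigma,
            sw_offset=c0,
        )
    if family == "greenlab-exp":
        return RecurrenceModel(
            theta1=values["theta1"], theta2=values["theta2"], sigma=sigma, r_source="greenlab"
        )
    return RecurrenceModel(
        theta1=values["theta1"],
        theta2=values["theta2"],
        sigma=sigma,
        r_source="parametric",
        a=values["a"],
        t_max=values["_t_max"],
    )


def fit_mle(
    family: str,
    e: Sequence[float],
    w: Sequence[float],
    n_starts: int = 1000,
    bounds: Optional[dict] = None,
    seed: Optional[int] = None,
    c0: float = 0.0,
    drop_first: Optional[bool] = None,
) -> FitResult:
    """Multi-start bounded maximum-likelihood fit of one model family.

    Starting points are drawn uniformly inside the bounds box with a seeded
    generator; each start runs L-BFGS-B on the sigma-profiled negative
    log-likelihood and the best optimum is kept.  When ``drop_first`` is
    unset, the first observation enters the likelihood only if c0 > 0 gives
    it a usable pre-observation history (it always contributes to SW).
    Returns a :class:`FitResult` whose k counts sigma as estimated.
    """
    if family not in MODEL_FAMILIES:
        raise FitError(f"unknown family {family!r}; choose from {sorted(MODEL_FAMILIES)}")
    e = np.asarray(e, dtype=float)
    w = np.asarray(w, dtype=float)
    if e.shape != w.shape or e.ndim != 1:
        raise FitError("radiation and consumption series must be aligned 1-d arrays")
    if np.any(~np.isfinite(w)):
        raise FitError("consumption series must be complete (no gaps) for the likelihood")
    if n_starts < 1:
        raise FitError("n_starts must be >= 1")

    names = MODEL_FAMILIES[family]
    box = default_bounds(family)
    if bounds:
        box.update(bounds)
    lo = np.array([box[p][0] for p in names])
    hi = np.array([box[p][1] for p in names])

    if drop_first is None:
        # the first point has no usable history unless an SSiE offset c0 > 0
        # gives it one; recurrence families always start from empty history
        drop_first = (c0 == 0.0) or (family not in FAMILIES)
    fit_slice = slice(1, None) if drop_first else slice(None)
    n = w[fit_slice].size
    k = len(names) + 1  # + sigma
    if n <= k + 1:
        raise FitError(f"insufficient data: n={n} <= k+1={k + 1}")

    if family in FAMILIES:
        sw = cumulative_consumption(w, c0)
        cdf = FAMILIES[family]["cdf"]

        def mean_fn(values: np.ndarray) -> np.ndarray:
            params = dict(zip(names[1:], values[1:]))
            return values[0] * e * cdf(sw, params)

    else:
        r = r_coefficients("greenlab", len(w)) if family == "greenlab-exp" else None
        t_grid = np.arange(1.0, len(w) + 1)
        w_past = w[:-1]

        def mean_fn(values: np.ndarray) -> np.ndarray:
            if family == "greenlab-exp":
                rr = r
            else:
                i_a = len(w) ** (values[2] + 1.0) / (values[2] + 1.0)
                rr = t_grid ** values[2] / i_a
            weighted = np.concatenate(([0.0], np.cumsum(rr[:-1] * w_past)))
            return values[0] * e * (-np.expm1(-values[1] * weighted))

    w_fit = w[fit_slice]

    def objective(values: np.ndarray) -> float:
        try:
            resid = w_fit - mean_fn(values)[fit_slice]
        except (ArithmeticError, ValueError):
            return 1e10
        rss = float(resid @ resid)
        if not math.isfinite(rss):
            return 1e10
        # floor keeps the concentrated likelihood finite on noiseless data
        rss = max(rss, n * 1e-24)
        return 0.5 * n * (1.0 + math.log(2.0 * math.pi * rss / n))

    rng = np.random.default_rng(seed)
    starts = lo + (hi - lo) * rng.uniform(size=(n_starts, len(names)))
    best = None
    converged = 0
    for x0 in starts:
        res = minimize(
            objective,
            x0,
            method="L-BFGS-B",
            bounds=list(zip(lo, hi)),
            options={"maxiter": 200},
        )
        if not np.all(np.isfinite(res.x)) or res.fun >= 1e10:
            continue
        converged += 1
        if best is None or res.fun < best.fun:
            best = res
    if best is None:
        raise FitError(
            f"all {n_starts} starts failed for family {family!r} "
            f"(n={n}, bounds={box})"
        )

    values = dict(zip(names, (float(v) for v in best.x)))
    resid = w_fit - mean_fn(best.x)[fit_slice]
    rss = max(float(resid @ resid), n * 1e-24)
    sigma_hat = math.sqrt(rss / n)
    ll = -0.5 * n * (1.0 + math.log(2.0 * math.pi * rss / n))
    aicc, bic = information_criteria(ll, k, n)
    build_values = dict(values, _t_max=len(w))
    model = _build_model(family, build_values, sigma_hat, c0)
    estimates = dict(values, sigma=sigma_hat)
    return FitResult(
        model=model,
        family=family,
        estimates=estimates,
        loglik=ll,
        k=k,
        n=n,
        rmse=sigma_hat,
        aicc=aicc,
        bic=bic,
        n_starts=n_starts,
        seed=seed,
        converged_starts=converged,
        bounds={p: list(box[p]) for p in names},
    )


def fit_lr_baseline(e: Sequence[float], w: Sequence[float]) -> FitResult:
    """OLS fit of W_c(t) = b0 + b1 W_c(t-1) + b2 E(t), rows t >= 2.

    The reported log-likelihood uses the profiled (divide-by-n) noise
    variance so it is directly comparable with the MLE fits; k counts
    (b0, b1, b2, sigma).
    """
    e = np.asarray(e, dtype=float)
    w = np.asarray(w, dtype=float)
    if e.shape != w.shape or w.size < 5:
        raise FitError("need aligned series with at least 4 usable regression rows")
    y = w[1:]
    X = sm.add_constant(np.column_stack([w[:-1], e[1:]]), has_constant="add")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise FitError("collinear design: the regression matrix is rank-deficient")
    ols = sm.OLS(y, X).fit()
    n = y.size
    resid = ols.resid
    rss = float(resid @ resid)
    sigma_hat = math.sqrt(rss / n)
    ll = -0.5 * n * (1.0 + math.log(2.0 * math.pi * rss / n))
    k = 4
    aicc, bic = information_criteria(ll, k, n)
    model = LRModel(
        b0=float(ols.params[0]), b1=float(ols.params[1]), b2=float(ols.params[2]), sigma=sigma_hat
    )
    estimates = {
        "b0": model.b0,
        "b1": model.b1,
        "b2": model.b2,
        "sigma": sigma_hat,
        "r_squared": float(ols.rsquared),
    }
    return FitResult(
        model=model,
        family="lr",
        estimates=estimates,
        loglik=ll,
        k=k,
        n=n,
        rmse=sigma_hat,
        aicc=aicc,
        bic=bic,
    )


def compare_models(fits: Sequence[FitResult], criterion: str = "bic"):
    """Rank fitted models by an information criterion (ascending).

    All fits must be on the same number of observations; ties are broken by
    fewer parameters, then family name.  Returns a pandas DataFrame in the
    layout (family, loglik, rmse, k, bic, aicc).
    """
    import pandas as pd

    if criterion not in ("bic", "aicc"):
        raise FitError("criterion must be 'bic' or 'aicc'")
    if not fits:
        raise FitError("no fits to compare")
    ns = {f.n for f in fits}
    if len(ns) > 1:
        raise FitError(f"fits are not comparable: observation counts differ {sorted(ns)}")
    rows = sorted(fits, key=lambda f: (getattr(f, criterion), f.k, f.family))
    return pd.DataFrame(
        {
            "family": [f.family for f in rows],
            "loglik": [f.loglik for f in rows],
            "rmse": [f.rmse for f in rows],
            "k": [f.k for f in rows],
            "bic": [f.bic for f in rows],
            "aicc": [f.aicc for f in rows],
        }
    )
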
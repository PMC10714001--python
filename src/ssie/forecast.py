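"""Expanding-window one-day-ahead forecasting with per-step refitting.

The protocol mirrors operational greenhouse use: train on the first 55% of
the daily series, predict the next day's water consumption from that day's
radiation and the observed consumption history, then append the true
observation and repeat to the end of the series.  Predictive quality is
summarized by the root mean square prediction error (RMSPE).  The radiation
of the day being predicted can optionally be perturbed with N(0, sd^2) noise
(floored at zero) to emulate imperfect radiation forecasts; training always
uses the recorded radiation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .fit import FitError, fit_mle, predict_mean

__all__ = ["ForecastError", "ForecastResult", "rmspe", "perturb_radiation", "expanding_forecast"]


class ForecastError(ValueError):
    """Invalid forecasting inputs or a failed per-step estimation."""


@dataclass
class ForecastResult:
    """One-step-ahead predictions over the evaluation window."""

    predictions: np.ndarray
    actuals: np.ndarray
    rmspe: float
    setting: str
    family: str
    train_size: int
    step_estimates: list[dict]
    seed: Optional[int] = None

    @property
    def m(self) -> int:
        return self.predictions.size

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "setting": self.setting,
            "train_size": self.train_size,
            "m": self.m,
            "rmspe": self.rmspe,
            "seed": self.seed,
            "steps": [
                {"y": float(y), "y_hat": float(p), "estimates": est}
                for y, p, est in zip(self.actuals, self.predictions, self.step_estimates)
            ],
        }


def rmspe(y: Sequence[float], y_hat: Sequence[float]) -> float:
    """Root mean square prediction error sqrt(mean((y - y_hat)^2))."""
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.size == 0 or y.shape != y_hat.shape:
        raise ForecastError("prediction and observation vectors must be nonempty and aligned")
    return float(np.sqrt(np.mean((y - y_hat) ** 2)))


def perturb_radiation(e, sd: float, rng: np.random.Generator) -> np.ndarray:
    """Radiation plus N(0, sd^2) noise, floored at zero (sd = 0 is identity)."""
    if sd < 0:
        raise ForecastError("noise sd must be >= 0")
    e = np.asarray(e, dtype=float)
    if sd == 0:
        return e.copy()
    return np.maximum(e + rng.normal(0.0, sd, size=e.shape), 0.0)


def initial_train_size(length: int, split_fraction: float) -> int:
    """Round-half-up day count for the initial training window."""
    return int(math.floor(split_fraction * length + 0.5))


def expanding_forecast(
    e: Sequence[float],
    w: Sequence[float],
    family: str,
    split_fraction: float = 0.55,
    n_starts: int = 1000,
    seed: Optional[int] = None,
    e_noise_sd: float = 0.0,
    c0: float = 0.0,
    bounds: Optional[dict] = None,
    clamp_negative: bool = False,
) -> ForecastResult:
    """Sequential expanding-window one-step-ahead forecast with refitting.

    At each step the model is refitted by multi-start MLE on the current
    window; the next day's mean is evaluated with that day's radiation
    (perturbed when ``e_noise_sd`` > 0; the training window always uses the
    recorded values) and the observed consumption history; the true
    observation is then appended.  Per-step fit seeds and noise draws derive
    from ``seed`` through a SeedSequence, so the whole procedure is
    reproducible end-to-end and ``e_noise_sd = 0`` reproduces the
    fixed-covariate setting bit-exactly.
    """
    e = np.asarray(e, dtype=float)
    w = np.asarray(w, dtype=float)
    if e.shape != w.shape or e.ndim != 1:
        raise ForecastError("radiation and consumption series must be aligned 1-d arrays")
    n_total = w.size
    n_train = initial_train_size(n_total, split_fraction)
    if n_train < 6 or n_train >= n_total:
        raise ForecastError(
            f"split {split_fraction} leaves an unusable training window "
            f"({n_train} of {n_total} days)"
        )

    ss = np.random.SeedSequence(seed)
    child_seeds = ss.spawn(n_total - n_train)
    preds = np.empty(n_total - n_train)
    step_estimates: list[dict] = []
    for j, t_end in enumerate(range(n_train, n_total)):
        step_ss = child_seeds[j]
        fit_seed = int(step_ss.generate_state(1)[0] % (2**31))
        try:
            fr = fit_mle(
                family,
                e[:t_end],
                w[:t_end],
                n_starts=n_starts,
                bounds=bounds,
                seed=fit_seed,
                c0=c0,
            )
        except FitError as exc:
            raise ForecastError(f"estimation failed at forecast step {j + 1}: {exc}") from exc
        e_next = e[t_end]
        if e_noise_sd > 0:
            rng = np.random.default_rng(step_ss.spawn(1)[0])
            e_next = float(perturb_radiation(np.array([e_next]), e_noise_sd, rng)[0])
        mean = predict_mean(fr.model, np.append(e[:t_end], e_next), np.append(w[:t_end], 0.0))
        y_hat = float(mean[-1])
        if clamp_negative:
            y_hat = max(y_hat, 0.0)
        preds[j] = y_hat
        step_estimates.append(
            {"step": j + 1, "train_end": t_end, "seed": fit_seed, "e_used": float(e_next), **fr.estimates}
        )

    actuals = w[n_train:]
    return ForecastResult(
        predictions=preds,
        actuals=actuals.copy(),
        rmspe=rmspe(actuals, preds),
        setting="fixed-E" if e_noise_sd == 0 else f"noisy-E({e_noise_sd:g})",
        family=family,
        train_size=n_train,
        step_estimates=step_estimates,
        seed=seed,
    )
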
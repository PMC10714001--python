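"""Light Interception Ratio (LIR) models.

The LIR at time t is modelled as the CDF of a positive random variable X
evaluated at the cumulated water consumption prior to t:
LIR(t) = F_X(SW_c(t^-)).  Five distribution families are supported --
exponential (the Beer-Lambert law), gamma, Mittag-Leffler (the fractional
Beer-Lambert law), log-normal and Pareto -- each parameterized as a
:class:`LIRSpec`.

The Mittag-Leffler function E_a(x) = sum_j x^j / Gamma(j a + 1) has no
implementation in the scientific Python stack, so one is provided here for
the argument range reached from LIR evaluation (a in (0, 1], x <= 0, plus a
small positive range for cross-checks).  Three branches are used: the Taylor
series for small |x|, an optimally-truncated asymptotic expansion for large
|x|, and, in between, Gauss-Legendre quadrature of the spectral (completely
monotone) representation

    E_a(-t) = (sin a pi / pi) * int_0^inf  e^{-r t} r^{a-1}
              / (r^{2a} + 2 r^a cos a pi + 1) dr,   0 < a < 1, t > 0,

rewritten with y = r^a so the integrand is bounded, with the kernel's
near-pole at y = -cos(a pi) (which sharpens as a -> 1) resolved by
width-scaled quadrature panels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy import special as sp

__all__ = [
    "LIRError",
    "MLConvergenceError",
    "LIRSpec",
    "FAMILIES",
    "mittag_leffler",
    "mittag_leffler_series",
    "lir",
]


class LIRError(ValueError):
    """Invalid LIR specification or evaluation domain."""


class MLConvergenceError(ArithmeticError):
    """The Mittag-Leffler evaluation could not reach the accuracy target."""


# ---------------------------------------------------------------------------
# Mittag-Leffler function
# ---------------------------------------------------------------------------

_SERIES_TMAX = 1.0       # |x| bound for the Taylor branch
_SERIES_XPOS_MAX = 2.0   # largest positive x served (series only)
_ASYMP_BASE = 35.0       # asymptotic branch for t >= 35**a  (error ~ e^-35)
_QUAD_ORDER = 48


def mittag_leffler_series(x, a: float, tol: float = 1e-17, max_terms: int = 8000):
    """Direct Taylor evaluation sum_j x^j / Gamma(a j + 1) with a tail bound.

    Serves as the independent small-argument oracle.  Terms are computed in
    log space (sign * exp(j ln|x| - ln Gamma(a j + 1))) and accumulated until
    they fall below ``tol`` while decreasing; a convergence failure is raised
    when the truncation-plus-roundoff bound exceeds ~1e-12 of the result,
    rather than returning a silently inaccurate value.
    """
    if not 0.0 < a <= 1.0:
        raise LIRError(f"Mittag-Leffler order must be in (0, 1], got {a}")
    x = np.atleast_1d(np.asarray(x, dtype=float))
    out = np.ones_like(x)
    absum = np.ones_like(x)
    last_abs = np.full_like(x, np.inf)
    done = np.zeros(x.shape, dtype=bool)
    nz = x != 0.0
    log_ax = np.where(nz, np.log(np.abs(np.where(nz, x, 1.0))), -np.inf)
    sgn = np.sign(x)
    decreasing_runs = np.zeros(x.shape, dtype=int)
    converged = False
    with np.errstate(over="ignore", invalid="ignore"):
        for j in range(1, max_terms + 1):
            mag = np.exp(j * log_ax - sp.gammaln(a * j + 1.0))
            term = np.where(done, 0.0, sgn**j * mag)
            out += term
            absum += np.abs(term)
            decreasing_runs = np.where(np.abs(term) < last_abs, decreasing_runs + 1, 0)
            last_abs = np.where(done, last_abs, np.abs(term))
            done |= (np.abs(term) < tol) & (decreasing_runs >= 3)
            done |= ~nz
            if done.all():
                converged = True
                break
    if not converged:
        raise MLConvergenceError("Taylor series did not converge within the term budget")
    bound = 2.0 * last_abs * (~(np.abs(last_abs) == np.inf)) + absum * 1e-16
    bad = ~np.isfinite(out) | (bound > 1e-12 * np.maximum(np.abs(out), 1e-300))
    if bad.any():
        raise MLConvergenceError(
            "Taylor series accuracy bound not met (argument too large for the series branch)"
        )
    return out


def _ml_series_fast(x: np.ndarray, a: float, n_terms: int = 64) -> np.ndarray:
    """Fixed-length vectorized Taylor sum for |x| <= 1 and a >= 0.35.

    The tail beyond 64 terms is below 1/Gamma(0.35*64 + 1) ~ 1e-21, so the
    fixed truncation is exact to double precision on this range.
    """
    j = np.arange(n_terms + 1)
    coeff = sp.rgamma(a * j + 1.0)
    return np.polynomial.polynomial.polyval(x, coeff)


def _ml_asymptotic(t: np.ndarray, a: float) -> np.ndarray:
    """E_a(-t) ~ sum_{k>=1} (-1)^(k-1) t^-k / Gamma(1 - k a), optimally truncated.

    Via the reflection formula, 1/Gamma(1 - k a) = Gamma(k a) sin(pi k a)/pi,
    so each term is written pole-free and the truncation point is chosen at
    the minimum of the smooth envelope t^-k Gamma(k a)/pi (the raw magnitudes
    oscillate through the Gamma zeros).  The envelope minimum, ~e^(-t^(1/a)),
    also bounds the remainder.
    """
    kmax = 130
    k = np.arange(1.0, kmax + 1)
    log_env = sp.gammaln(k * a) - math.log(math.pi)  # k-dependent part sans t
    logt = np.log(t)[:, None]
    env = -k[None, :] * logt + log_env[None, :]
    k_opt = np.argmin(env, axis=1)
    keep = k[None, :] <= k[k_opt][:, None]
    terms = (
        (-1.0) ** (k[None, :] - 1.0)
        * np.exp(env)
        * np.sin(math.pi * k * a)[None, :]
    )
    out = np.sum(np.where(keep, terms, 0.0), axis=1)
    rem = np.exp(np.min(env, axis=1))
    if np.any(rem > 1e-11 * np.abs(out)):
        raise MLConvergenceError("asymptotic branch could not reach the accuracy target")
    return out


@lru_cache(maxsize=8)
def _leggauss(order: int):
    return np.polynomial.legendre.leggauss(order)


def _ml_spectral_sharp(t: np.ndarray, a: float) -> np.ndarray:
    """Spectral quadrature for small orders (a < 0.35, kernel pole-free).

    With small a the factor e^{-(t y)^(1/a)} is a near-step at y = 1/t, so the
    integral is computed in the scaled variable z = t y whose nodes are shared
    across all t: below z_lo the exponential factor is 1 to machine precision
    and the kernel integrates in closed form (arctangent); the transition
    region [z_lo, z_hi] is covered by composite Gauss-Legendre in log z.
    """
    c = -math.cos(math.pi * a)
    w = math.sin(math.pi * a)
    u_lo = -32.0 * a          # z_lo: (z)^(1/a) = e^-32
    u_hi = math.log(45.0) * a  # z_hi: (z)^(1/a) = 45
    n_seg = max(4, int(math.ceil((u_hi - u_lo) / 0.7)))
    gx, gw = _leggauss(_QUAD_ORDER)
    edges = np.linspace(u_lo, u_hi, n_seg + 1)
    mid = 0.5 * (edges[1:] + edges[:-1])
    half = 0.5 * (edges[1:] - edges[:-1])
    u = (mid[:, None] + half[:, None] * gx[None, :]).ravel()
    wu = (half[:, None] * gw[None, :]).ravel()
    z = np.exp(u)
    ez = np.exp(-(z ** (1.0 / a)))  # shared across t
    y = z[None, :] / t[:, None]
    kern = 1.0 / ((y - c) ** 2 + w**2)
    tail = (ez * wu * z)[None, :] * kern / t[:, None]
    head = (1.0 / w) * (
        np.arctan((np.exp(u_lo) / t - c) / w) - math.atan(-c / w)
    )
    return (w / (math.pi * a)) * (head + tail.sum(axis=1))


def _ml_spectral(t: np.ndarray, a: float) -> np.ndarray:
    """Middle-range E_a(-t) by quadrature of the spectral representation.

    Composite Gauss-Legendre in y with two merged gradings: geometric
    segments from 0 resolve the e^{-(t y)^(1/a)} decay layer, and, for
    a > 1/2, panels scaled to the Lorentzian half-width w = sin(a pi) resolve
    the kernel peak at y = -cos(a pi).
    """
    if a < 0.35:
        return _ml_spectral_sharp(t, a)
    c = -math.cos(math.pi * a)
    w = math.sin(math.pi * a)
    t_min = float(np.min(t))
    y_max = 45.0**a / t_min  # (t y)^(1/a) = 45 cutoff (e^-45) for the smallest t

    edges = {0.0, y_max}
    b = min(0.01, 0.3 * 45.0**a / float(np.max(t)))
    while b < y_max:
        edges.add(b)
        b *= 3.0
    if c > 0:
        # panels at +-{0.25, 0.5, 1, 2, ...} half-widths, extended by factor 4
        # until they leave the integration range, so the kernel's algebraic
        # tails stay resolved even when w is tiny (a close to 1)
        m = 0.25
        ms = [0.0]
        while c - m * w > 0.0 or c + m * w < y_max:
            ms.extend((-m, m))
            m *= 2.0 if m < 8.0 else 4.0
            if m * w > 10.0 * max(y_max, 1.0):
                break
        for m in ms:
            e = c + m * w
            if 0.0 < e < y_max:
                edges.add(e)
    edges = sorted(edges)

    gx, gw = _leggauss(_QUAD_ORDER)
    ed = np.asarray(edges)
    mid = 0.5 * (ed[1:] + ed[:-1])
    half = 0.5 * (ed[1:] - ed[:-1])
    y = (mid[:, None] + half[:, None] * gx[None, :]).ravel()
    kern = w / (math.pi * a) / ((y - c) ** 2 + w**2)
    wt = (half[:, None] * gw[None, :]).ravel() * kern  # includes prefactor
    arg = np.minimum(np.outer(t, y) ** (1.0 / a), 700.0)
    return np.exp(-arg) @ wt


def mittag_leffler(x, a: float):
    """Mittag-Leffler function E_a(x) for order a in (0, 1].

    Guaranteed for nonpositive arguments (the range reached from LIR
    evaluation, x = -(k sw)^a) at better than 1e-10 relative accuracy;
    positive arguments are served by the Taylor branch up to x = 2 and
    rejected beyond (for a = 1 the function is exp(x) for any x).  Returns a
    scalar for scalar input.
    """
    if not 0.0 < a <= 1.0:
        raise LIRError(f"Mittag-Leffler order must be in (0, 1], got {a}")
    x_arr = np.atleast_1d(np.asarray(x, dtype=float))
    if not np.all(np.isfinite(x_arr)):
        raise LIRError("Mittag-Leffler argument must be finite")
    if a == 1.0:
        out = np.exp(x_arr)
        return out[0] if np.isscalar(x) or np.ndim(x) == 0 else out
    if np.any(x_arr > _SERIES_XPOS_MAX):
        raise LIRError(
            f"positive arguments beyond {_SERIES_XPOS_MAX} are outside the supported range"
        )

    out = np.empty_like(x_arr)
    t = -x_arr
    if a >= 0.35:
        # the optimally-truncated asymptotic expansion needs ~35/a terms, so
        # it is practical only for a >= 0.35, and it omits a beyond-all-orders
        # e^-t contribution that becomes significant as a -> 1, so very high
        # orders stay on the (exact) spectral representation
        small = np.abs(x_arr) <= _SERIES_TMAX
        pos = x_arr > _SERIES_TMAX  # positive arguments up to the series cap
        large = (t >= _ASYMP_BASE**a) & ~pos if a <= 0.999 else np.zeros_like(t, bool)
        mid = ~small & ~large & ~pos
        if small.any():
            out[small] = _ml_series_fast(x_arr[small], a)
        if pos.any():
            out[pos] = mittag_leffler_series(x_arr[pos], a)
        if large.any():
            out[large] = _ml_asymptotic(t[large], a)
        if mid.any():
            out[mid] = _ml_spectral(t[mid], a)
    else:
        # small orders: the scaled spectral scheme is uniformly accurate for
        # every t > 0; the series handles only nonnegative arguments
        pos = t <= 0.0
        if pos.any():
            out[pos] = mittag_leffler_series(x_arr[pos], a)
        if (~pos).any():
            out[~pos] = _ml_spectral_sharp(t[~pos], a)
    return out[0] if np.isscalar(x) or np.ndim(x) == 0 else out


# ---------------------------------------------------------------------------
# LIR families
# ---------------------------------------------------------------------------

def _exp_cdf(sw, p):
    return -np.expm1(-p["k"] * sw)


def _gamma_cdf(sw, p):
    return sp.gammainc(p["a_gamma"], p["k"] * sw)


def _mlf_cdf(sw, p):
    arg = -((p["k"] * sw) ** p["a_ml"])
    return 1.0 - mittag_leffler(arg, p["a_ml"])


def _lognorm_cdf(sw, p):
    sw = np.asarray(sw, dtype=float)
    out = np.zeros_like(sw)
    pos = sw > 0
    z = (np.log(sw[pos]) - p["mu_log"]) / (p["sigma_log"] * math.sqrt(2.0))
    out[pos] = 0.5 * sp.erfc(-z)
    return out


def _pareto_cdf(sw, p):
    sw = np.asarray(sw, dtype=float)
    out = np.zeros_like(sw)
    over = sw > p["eta"]
    out[over] = 1.0 - (p["eta"] / sw[over]) ** p["theta"]
    return out


def _positive(name):
    return lambda v: v > 0 or f"{name} must be > 0"


# family registry: parameter names, validation, default optimization bounds
FAMILIES: dict[str, dict] = {
    "exp": {
        "params": ("k",),
        "bounds": {"k": (1e-6, 10.0)},
        "cdf": _exp_cdf,
    },
    "gamma": {
        "params": ("k", "a_gamma"),
        "bounds": {"k": (1e-6, 10.0), "a_gamma": (0.01, 20.0)},
        "cdf": _gamma_cdf,
    },
    "mlf": {
        "params": ("k", "a_ml"),
        "bounds": {"k": (1e-6, 10.0), "a_ml": (0.01, 1.0)},
        "cdf": _mlf_cdf,
    },
    "lognorm": {
        "params": ("mu_log", "sigma_log"),
        "bounds": {"mu_log": (-5.0, 10.0), "sigma_log": (1e-3, 20.0)},
        "cdf": _lognorm_cdf,
    },
    "pareto": {
        "params": ("theta", "eta"),
        "bounds": {"theta": (1e-8, 50.0), "eta": (1e-3, 5.0)},
        "cdf": _pareto_cdf,
    },
}


def _validate_params(family: str, params: dict) -> None:
    spec = FAMILIES[family]
    missing = set(spec["params"]) - set(params)
    extra = set(params) - set(spec["params"])
    if missing or extra:
        raise LIRError(
            f"family {family!r} takes parameters {spec['params']}, got {tuple(params)}"
        )
    for name, v in params.items():
        if not np.isfinite(v):
            raise LIRError(f"{family}: {name} must be finite")
    if family in ("exp", "gamma", "mlf") and params["k"] <= 0:
        raise LIRError(f"{family}: rate k must be > 0")
    if family == "gamma" and params["a_gamma"] <= 0:
        raise LIRError("gamma: shape a_gamma must be > 0")
    if family == "mlf" and not 0.0 < params["a_ml"] <= 1.0:
        raise LIRError("mlf: tail parameter a_ml must be in (0, 1]")
    if family == "lognorm" and params["sigma_log"] <= 0:
        raise LIRError("lognorm: sigma_log must be > 0")
    if family == "pareto" and (params["theta"] <= 0 or params["eta"] <= 0):
        raise LIRError("pareto: theta and eta must be > 0")


@dataclass(frozen=True)
class LIRSpec:
    """One CDF family plus its parameters, evaluating LIR(t) = F_X(SW_c(t^-)).

    Families and parameters: ``exp`` (rate k), ``gamma`` (rate k, shape
    a_gamma), ``mlf`` (rate k, tail a_ml in (0,1]), ``lognorm`` (mu_log,
    sigma_log) and ``pareto`` (shape theta, scale eta; the CDF is 0 at or
    below eta so the spec remains a valid distribution function).
    """

    family: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise LIRError(
                f"unknown family {self.family!r}; choose from {sorted(FAMILIES)}"
            )
        _validate_params(self.family, self.params)
        object.__setattr__(self, "params", dict(self.params))

    @property
    def n_params(self) -> int:
        return len(FAMILIES[self.family]["params"])

    def cdf(self, sw):
        """F_X evaluated at cumulative consumption sw >= 0 (liters)."""
        sw_arr = np.atleast_1d(np.asarray(sw, dtype=float))
        if np.any(sw_arr < 0) or not np.all(np.isfinite(sw_arr)):
            raise LIRError("cumulative consumption must be finite and >= 0")
        out = np.asarray(FAMILIES[self.family]["cdf"](sw_arr, self.params), dtype=float)
        out = np.clip(out, 0.0, 1.0)
        return float(out[0]) if np.ndim(sw) == 0 else out

    def to_dict(self) -> dict:
        return {"family": self.family, **self.params}

    @classmethod
    def from_dict(cls, d: dict) -> "LIRSpec":
        d = dict(d)
        return cls(family=d.pop("family"), params=d)


def lir(spec: LIRSpec, sw):
    """Evaluate the Light Interception Ratio F_X(sw) for a given family spec."""
    return spec.cdf(sw)
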
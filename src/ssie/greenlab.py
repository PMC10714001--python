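"""Simplified GreenLab tomato simulator.

The plant is an automaton producing one phytomer (blade + petiole + internode)
per Cycle of Development (CD); after eight vegetative phytomers a fruit truss
of three fruits appears on every third phytomer.  Each organ draws biomass
from a common pool proportionally to its sink strength p_o times a
discretized-beta demand profile f_o over its expansion span T_o.  Biomass
production per cycle follows a Beer-Lambert interception law driven by the
photosynthetically active leaf surface.

Two parameterizations are supported: the full four-organ model
(:class:`GreenLabParams`) and the two-compartment simplification
(:class:`Comp1Params`) that merges petiole, internode and fruit into a single
"body" sink; the latter is used for identifiability experiments and emits an
expected water-consumption series ``mu0 * Q(t)``.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from functools import lru_cache
from typing import Callable, Optional, Sequence, Union

import numpy as np
import pandas as pd

__all__ = [
    "GreenLabError",
    "load_params",
    "GreenLabParams",
    "Comp1Params",
    "RecurrenceModel",
    "OrganCohort",
    "PlantState",
    "Trajectory",
    "scaled_beta_shapes",
    "sink_profile",
    "phytomer_schedule",
    "sink_value",
    "total_demand",
    "production",
    "simulate",
    "r_coefficients",
]


class GreenLabError(ValueError):
    """Invalid parameters, inputs or states of the plant simulator."""


def load_params(path, kind: str = "greenlab"):
    """Read a flat key/value parameter file (YAML or JSON) into a params object.

    ``kind`` selects :class:`GreenLabParams` ("greenlab") or
    :class:`Comp1Params` ("comp1"); unknown keys are reported.
    """
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cls = {"greenlab": GreenLabParams, "comp1": Comp1Params}.get(kind)
    if cls is None:
        raise GreenLabError(f"unknown parameter kind {kind!r}")
    valid = {f.name for f in fields(cls)}
    unknown = set(raw) - valid
    if unknown:
        raise GreenLabError(f"unknown parameter keys {sorted(unknown)} for {cls.__name__}")
    return cls(**raw)


def scaled_beta_shapes(b_param: float) -> tuple[float, float]:
    """Map a single sink-variation parameter B in (0,1) to beta shapes.

    The convention (a, b) = (5B, 5(1-B)) keeps the tomato shape constraint
    a + b = 5 for any B.  Alternative mappings can be supplied through the
    ``beta_mapping`` hook of the parameter objects.
    """
    if not 0.0 < b_param < 1.0:
        raise GreenLabError(f"sink-variation parameter must be in (0,1), got {b_param}")
    return 5.0 * b_param, 5.0 * (1.0 - b_param)


@dataclass(frozen=True)
class GreenLabParams:
    """Four-organ GreenLab tomato parameters.

    Defaults are the published tomato values: sink strengths p_o, single
    sink-variation parameters B_o (mapped to beta shapes with a_o + b_o = 5),
    expansion durations T_o in CDs, projection surface S_p (cm^2), extinction
    coefficient k, radiation use efficiency and a two-day phyllochron.  SLA
    (cm^2 of blade surface per g) and the seed biomass Q0 (g) are simulator
    choices, not published values; allocation fractions are invariant to both.
    """

    p_b: float = 1.0
    p_p: float = 1.09
    p_e: float = 0.93
    p_f: float = 61.3
    B_b: float = 0.43
    B_p: float = 0.45
    B_e: float = 0.38
    B_f: float = 0.36
    T_b: int = 10
    T_p: int = 10
    T_e: int = 8
    T_f: int = 15
    S_p: float = 5047.0
    k: float = 0.8
    rue: float = 0.05
    sla: float = 150.0
    q0: float = 0.2
    phyllochron: int = 2
    n_vegetative: int = 8
    truss_period: int = 3
    fruits_per_truss: int = 3
    beta_mapping: Callable[[float], tuple[float, float]] = scaled_beta_shapes

    def __post_init__(self) -> None:
        for name in ("p_b", "p_p", "p_e", "p_f", "S_p", "k", "rue", "sla"):
            if getattr(self, name) <= 0:
                raise GreenLabError(f"{name} must be > 0")
        for name in ("T_b", "T_p", "T_e", "T_f"):
            if getattr(self, name) < 1:
                raise GreenLabError(f"{name} must be >= 1 CD")
        for name in ("B_b", "B_p", "B_e", "B_f"):
            if not 0.0 < getattr(self, name) < 1.0:
                raise GreenLabError(f"{name} must be in (0,1)")
        if self.q0 < 0:
            raise GreenLabError("q0 must be >= 0")

    def organ_specs(self) -> dict[str, tuple[float, float, float, int]]:
        """Per organ type: (sink strength, beta shape a, beta shape b, duration)."""
        out = {}
        for organ, p, B, T in (
            ("blade", self.p_b, self.B_b, self.T_b),
            ("petiole", self.p_p, self.B_p, self.T_p),
            ("internode", self.p_e, self.B_e, self.T_e),
            ("fruit", self.p_f, self.B_f, self.T_f),
        ):
            a, b = self.beta_mapping(B)
            out[organ] = (p, a, b, T)
        return out


@dataclass(frozen=True)
class Comp1Params:
    """Two-compartment (blade/body) simplification with observation model.

    Blade beta shapes (a_b, b_b) and the body sink (p_body, a_body, b_body)
    are given directly, each pair constrained to a + b = 5.  ``mu0`` (L/g)
    converts produced biomass into expected daily water consumption and
    ``sigma`` (L) is the homoskedastic Gaussian observation noise.  The body
    expansion duration defaults to the longest merged organ span (15 CDs).
    """

    a_b: float = 2.15
    b_b: float = 2.85
    p_body: float = 3.0
    a_body: float = 2.25
    b_body: float = 2.75
    T_b: int = 10
    T_body: int = 15
    S_p: float = 5047.0
    k: float = 0.8
    rue: float = 0.05
    sla: float = 150.0
    q0: float = 0.2
    mu0: float = 2.0e-5
    sigma: float = 0.1
    p_b: float = 1.0
    phyllochron: int = 2

    def __post_init__(self) -> None:
        for pair in (("a_b", "b_b"), ("a_body", "b_body")):
            a, b = getattr(self, pair[0]), getattr(self, pair[1])
            if a <= 0 or b <= 0:
                raise GreenLabError(f"beta shapes {pair} must be positive")
            if abs(a + b - 5.0) > 1e-9:
                raise GreenLabError(f"shape constraint {pair[0]}+{pair[1]}=5 violated: {a}+{b}")
        for name in ("p_b", "p_body", "S_p", "k", "rue", "sla", "mu0", "sigma"):
            if getattr(self, name) <= 0:
                raise GreenLabError(f"{name} must be > 0")
        if self.q0 < 0:
            raise GreenLabError("q0 must be >= 0")

    def organ_specs(self) -> dict[str, tuple[float, float, float, int]]:
        return {
            "blade": (self.p_b, self.a_b, self.b_b, self.T_b),
            "body": (self.p_body, self.a_body, self.b_body, self.T_body),
        }


@dataclass(frozen=True)
class RecurrenceModel:
    """Water-consumption recurrence model driven by green-biomass coefficients.

    Predicted mean: theta1 * E(t) * (1 - exp(-theta2 * sum_{n<t} r(n) W_c(n))),
    where r(n) is the proportion of green (blade) to totally produced biomass.
    ``r_source`` is either "greenlab" (r extracted from a reference simulation
    at published tomato values) or "parametric" with r(t) = t^a / I(a),
    I(a) = t_max^(a+1) / (a+1).
    """

    theta1: float
    theta2: float
    sigma: float = 0.1
    r_source: str = "greenlab"
    a: Optional[float] = None
    t_max: Optional[int] = None

    def __post_init__(self) -> None:
        if self.theta1 <= 0 or self.theta2 <= 0:
            raise GreenLabError("theta1 and theta2 must be > 0")
        if self.r_source not in ("greenlab", "parametric"):
            raise GreenLabError(f"unknown r_source {self.r_source!r}")
        if self.r_source == "parametric":
            if self.a is None or self.t_max is None:
                raise GreenLabError("parametric r requires exponent a and horizon t_max")
            if self.a <= -1:
                raise GreenLabError("parametric exponent must satisfy a > -1")

    def r(self, t_max: int) -> np.ndarray:
        if self.r_source == "parametric":
            return r_coefficients("parametric", t_max=self.t_max or t_max, a=self.a)[:t_max]
        return r_coefficients("greenlab", t_max=t_max)


@dataclass(frozen=True)
class OrganCohort:
    """Organs of one type born on the same cycle (same chronological age)."""

    organ_type: str
    birth_cycle: int
    count: int

    def __post_init__(self) -> None:
        if self.count < 1:
            raise GreenLabError("cohort count must be >= 1")


@dataclass
class PlantState:
    """Simulator state after a given cycle."""

    cycle: int
    q: float
    blade_mass: float
    body_mass: float
    s_l: float
    blade_fraction: float


@dataclass
class Trajectory:
    """Per-cycle simulation output (arrays indexed by cycle 1..n)."""

    cycles: np.ndarray
    q: np.ndarray
    blade_mass: np.ndarray
    body_mass: np.ndarray
    s_l: np.ndarray
    blade_fraction: np.ndarray
    green_ratio: np.ndarray
    expected_wc: Optional[np.ndarray]
    q0: float

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "cycle": self.cycles,
                "Q": self.q,
                "blade_mass": self.blade_mass,
                "body_mass": self.body_mass,
                "s_l": self.s_l,
                "blade_fraction": self.blade_fraction,
            }
        )
        if self.expected_wc is not None:
            df["expected_wc"] = self.expected_wc
        return df


def sink_profile(a: float, b: float, duration: int) -> np.ndarray:
    """Discretized beta demand profile over ages 0..duration-1, summing to 1.

    The beta kernel x^(a-1) (1-x)^(b-1) is evaluated at the age-bin midpoints
    (j + 0.5)/T and normalized; normalization makes the shape-mapping choice
    affect only the profile's shape, never the organ's lifetime demand.
    """
    if duration < 1:
        raise GreenLabError("duration must be >= 1")
    x = (np.arange(duration) + 0.5) / duration
    f = x ** (a - 1.0) * (1.0 - x) ** (b - 1.0)
    return f / f.sum()


Params = Union[GreenLabParams, Comp1Params]


@lru_cache(maxsize=64)
def _profiles_cached(key) -> dict[str, tuple[float, np.ndarray]]:
    specs = dict(key)
    return {o: (p, sink_profile(a, b, T)) for o, (p, a, b, T) in specs.items()}


def _profiles(params: Params) -> dict[str, tuple[float, np.ndarray]]:
    specs = params.organ_specs()
    key = tuple(sorted((o, v) for o, v in specs.items()))
    try:
        return _profiles_cached(key)
    except TypeError:  # unhashable custom mapping output; compute directly
        return {o: (p, sink_profile(a, b, T)) for o, (p, a, b, T) in specs.items()}


def _truss_phytomers(params, upto: int) -> list[int]:
    """Truss-bearing phytomer indices <= upto (first on n_vegetative+1)."""
    first = getattr(params, "n_vegetative", 8) + 1
    period = getattr(params, "truss_period", 3)
    return list(range(first, upto + 1, period))


def phytomer_schedule(cycle: int, params: Params) -> list[OrganCohort]:
    """Organ cohorts present at ``cycle`` (one phytomer appears per cycle).

    Phytomer i is born on cycle i.  Every phytomer carries one blade, one
    petiole and one internode (one blade and one body organ for the
    compartmental model); truss-bearing phytomers additionally carry
    ``fruits_per_truss`` fruits whose expansion clock starts at the phytomer's
    birth cycle (flowers and fruits are not distinguished).
    """
    if cycle < 0:
        raise GreenLabError("cycle must be >= 0")
    cohorts: list[OrganCohort] = []
    veg_types = (
        ("blade", "petiole", "internode")
        if isinstance(params, GreenLabParams)
        else ("blade", "body")
    )
    for i in range(1, cycle + 1):
        for organ in veg_types:
            cohorts.append(OrganCohort(organ, birth_cycle=i, count=1))
    if isinstance(params, GreenLabParams):
        for i in _truss_phytomers(params, cycle):
            cohorts.append(OrganCohort("fruit", birth_cycle=i, count=params.fruits_per_truss))
    return cohorts


def sink_value(organ_type: str, age: int, params: Params) -> float:
    """Demand p_o * f_o(age) of one organ; zero once the organ is expanded."""
    profiles = _profiles(params)
    if organ_type not in profiles:
        raise GreenLabError(f"unknown organ type {organ_type!r} for {type(params).__name__}")
    if age < 0 or int(age) != age:
        raise GreenLabError(f"age must be a nonnegative integer, got {age}")
    p, prof = profiles[organ_type]
    if age >= prof.size:
        return 0.0
    return float(p * prof[age])


def total_demand(cohorts: Sequence[OrganCohort], cycle: int, params: Params) -> float:
    """Total demand D(t) = sum over cohorts of count * p_o * f_o(age)."""
    d = 0.0
    for c in cohorts:
        age = cycle - c.birth_cycle
        if age >= 0:
            d += c.count * sink_value(c.organ_type, age, params)
    return d


def production(e_cd: float, s_l: float, params: Params) -> float:
    """Beer-Lambert biomass production E * RUE * S_p * (1 - exp(-k s_l / S_p))."""
    if e_cd < 0 or s_l < 0:
        raise GreenLabError("radiation and leaf surface must be nonnegative")
    return e_cd * params.rue * params.S_p * (1.0 - np.exp(-params.k * s_l / params.S_p))


def _demand_arrays(params: Params, n_cycles: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized per-cycle demands via birth-profile convolution.

    Returns (blade demand, body demand, total demand) for cycles 1..n_cycles,
    where "body" aggregates every non-blade organ.
    """
    profiles = _profiles(params)
    births = {o: np.zeros(n_cycles) for o in profiles}
    veg = [o for o in profiles if o != "fruit"]
    for o in veg:
        births[o][:] = 1.0  # phytomer t is born on cycle t (index t-1)
    if "fruit" in profiles:
        for i in _truss_phytomers(params, n_cycles):
            births["fruit"][i - 1] = params.fruits_per_truss
    d_blade = np.zeros(n_cycles)
    d_total = np.zeros(n_cycles)
    for o, (p, prof) in profiles.items():
        d_o = p * np.convolve(births[o], prof)[:n_cycles]
        d_total += d_o
        if o == "blade":
            d_blade = d_o
    return d_blade, d_total - d_blade, d_total


def simulate(params: Params, e_series: Sequence[float]) -> Trajectory:
    """Run the deterministic growth recursion over a per-cycle radiation series.

    At cycle t, the biomass Q(t-1) produced on the previous cycle is shared
    among all expanding organs proportionally to demand; the blade compartment
    then defines the active leaf surface s_l = SLA * blade mass, and the new
    production Q(t) follows the Beer-Lambert law with input e_series[t-1].
    With :class:`Comp1Params`, the trajectory also carries the noiseless
    expected consumption ``mu0 * Q(t)``.
    """
    e = np.asarray(e_series, dtype=float)
    if e.ndim != 1 or e.size < 1:
        raise GreenLabError("e_series must be a nonempty 1-d sequence")
    if np.any(e < 0) or not np.all(np.isfinite(e)):
        raise GreenLabError("radiation inputs must be finite and nonnegative")
    n = e.size
    d_blade, d_body, d_total = _demand_arrays(params, n)

    q = np.zeros(n)
    blade_mass = np.zeros(n)
    body_mass = np.zeros(n)
    s_l = np.zeros(n)
    bf = np.zeros(n)
    green_ratio = np.zeros(n)
    k_over_sp = params.k / params.S_p
    scale = params.rue * params.S_p

    q_prev = params.q0
    blade = 0.0
    body = 0.0
    produced = params.q0
    for t in range(n):
        if d_total[t] <= 0:
            if q_prev > 0:
                raise GreenLabError(f"dead plant: zero demand at cycle {t + 1} with biomass to allocate")
            frac = 0.0
        else:
            frac = d_blade[t] / d_total[t]
        blade += frac * q_prev
        body += (1.0 - frac) * q_prev
        sl = params.sla * blade
        qt = e[t] * scale * (1.0 - np.exp(-k_over_sp * sl))
        if not np.isfinite(qt):
            raise GreenLabError(f"numerical failure at cycle {t + 1}: non-finite production")
        produced += qt
        q[t], blade_mass[t], body_mass[t], s_l[t], bf[t] = qt, blade, body, sl, frac
        green_ratio[t] = blade / produced if produced > 0 else 0.0
        q_prev = qt

    expected_wc = None
    if isinstance(params, Comp1Params):
        expected_wc = params.mu0 * q
    return Trajectory(
        cycles=np.arange(1, n + 1),
        q=q,
        blade_mass=blade_mass,
        body_mass=body_mass,
        s_l=s_l,
        blade_fraction=bf,
        green_ratio=green_ratio,
        expected_wc=expected_wc,
        q0=params.q0,
    )


_REFERENCE_E = 574.0  # two days of ~287 W/m^2 average radiation per cycle


def r_coefficients(
    source: str,
    t_max: int,
    a: Optional[float] = None,
    params: Optional[GreenLabParams] = None,
    e_ref: float = _REFERENCE_E,
) -> np.ndarray:
    """Green-biomass proportion coefficients r(1..t_max) for the recurrence model.

    ``parametric``: r(t) = t^a / I(a) with I(a) = t_max^(a+1)/(a+1), the
    continuous normalization over (0, t_max].  ``greenlab``: the cumulative
    proportion of green (blade) to totally produced biomass from a reference
    simulation at the published tomato values under constant radiation.
    """
    if t_max < 1:
        raise GreenLabError("t_max must be >= 1")
    if source == "parametric":
        if a is None:
            raise GreenLabError("parametric r requires the exponent a")
        if a <= -1:
            raise GreenLabError(f"divergent normalization: need a > -1, got {a}")
        t = np.arange(1, t_max + 1, dtype=float)
        i_a = t_max ** (a + 1.0) / (a + 1.0)
        return t**a / i_a
    if source == "greenlab":
        ref = params or GreenLabParams()
        traj = simulate(ref, np.full(t_max, e_ref))
        return traj.green_ratio.copy()
    raise GreenLabError(f"unknown r source {source!r}")
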
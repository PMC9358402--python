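"""Gland-mass model of the hypothalamic-pituitary-thyroid (HPT) axis.

The classical HPT negative-feedback cascade (TRH -> TSH -> free T4, with
thyroid hormone inhibiting the upper tiers) is extended by two slow
variables: the functional mass ``T`` of the thyroid (thyrocytes) and the
functional mass ``P`` of the pituitary thyrotrophs.  TSH acts as a growth
factor for the thyroid, while thyroid hormone suppresses thyrotroph growth.
The five ordinary differential equations are

    dTRH/dt = b_trh * u / TH               - a_trh * TRH
    dTSH/dt = b_tsh * P * TRH / TH         - a_tsh * TSH
    dTH/dt  = b_th  * T * f(TSH + Ab) + b30 - a_th * TH
    dT/dt   = T * (b_t * f(TSH + Ab) * (1 - k_t * T) - a_t)
    dP/dt   = P * (b_p * (1 - k_p * P) / TH - a_p)

with ``f`` the TSH-receptor regulation function (linear by default),
``Ab`` a TSH-receptor-activating antibody level in TSH-equivalent units
(Graves' disease), ``b30`` an external levothyroxine source, and ``1/k_t``,
``1/k_p`` the gland carrying capacities.  When the capacities do not bind,
the two mass equations implement integral feedback: the only steady state
with non-zero masses pins TSH = f^{-1}(a_t/b_t) and TH = b_p/a_p,
independently of every fast-timescale parameter.

Units: time in days, TH in pmol/L (a free-T4 proxy), TSH in mIU/L, TRH and
the gland masses dimensionless with healthy value 1.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

logger = logging.getLogger("thyraxis")

DAY = 1.0
HOUR = 1.0 / 24.0
MINUTE = 1.0 / 1440.0

#: relative TH floor used inside the RHS to guard the 1/TH terms
TH_FLOOR_REL = 1e-9


class SingularStateError(ValueError):
    """Raised when a state with TH <= 0 is handed to the RHS."""


class InfeasibleCalibrationError(ValueError):
    """Raised when a carrying capacity is at or below the requested set-point mass."""


class DomainError(ValueError):
    """Raised for arguments outside an operation's mathematical domain."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SetPoint:
    """Healthy steady-state targets the production rates are calibrated to."""

    th_set: float = 15.0  # pmol/L free T4
    tsh_set: float = 1.5  # mIU/L
    t_set: float = 1.0  # thyroid functional mass
    p_set: float = 1.0  # thyrotroph functional mass
    trh_set: float = 1.0  # TRH in arbitrary units, normalised to 1

    def __post_init__(self) -> None:
        if min(self.th_set, self.tsh_set, self.t_set, self.p_set, self.trh_set) <= 0:
            raise DomainError("set point values must all be positive")


@dataclass
class AxisState:
    """The five dynamical variables at one time point."""

    trh: float
    tsh: float
    th: float
    t_mass: float
    p_mass: float

    def as_array(self) -> np.ndarray:
        return np.array([self.trh, self.tsh, self.th, self.t_mass, self.p_mass], float)

    @classmethod
    def from_array(cls, y: np.ndarray) -> "AxisState":
        return cls(*(float(v) for v in y))

    def validate(self, require_positive_th: bool = True) -> None:
        y = self.as_array()
        if np.any(y < 0):
            raise DomainError(f"negative state component: {self}")
        if require_positive_th and self.th <= 0:
            raise SingularStateError("state with TH <= 0 is invalid for RHS evaluation")


FIELD_NAMES = ("trh", "tsh", "th", "t_mass", "p_mass")


@dataclass(frozen=True)
class ModelParameters:
    """All rate constants, capacities and external inputs of the model.

    Removal rates are per day; ``b_*`` production rates carry the units
    needed to balance their equation at the calibrated set point.
    """

    # removal / turnover rates (1/day)
    a_trh: float
    a_tsh: float
    a_th: float
    a_t: float
    a_p: float
    # production rates (calibrated)
    b_trh: float
    b_tsh: float
    b_th: float
    b_t: float
    b_p: float
    # inverse carrying capacities (1/mass)
    k_t: float = 0.0
    k_p: float = 0.0
    # external inputs
    u: float = 1.0  # hypothalamic input, baseline 1
    ab: float = 0.0  # activating antibody, TSH-equivalent mIU/L
    b_30: float = 0.0  # levothyroxine source, pmol/L/day
    # Michaelis constants (TRH-test variant of the TSH equation)
    k_trh: float = 1.0  # TRH stimulation half-saturation (TRH units)
    k_t4: float = 15.0  # TH suppression half-saturation (pmol/L)
    # regulation function
    f_variant: str = "linear"  # or "saturating"
    f_km: float = 6.0  # Michaelis constant of the saturating variant (mIU/L)
    # TH-suppression kernel of the TSH equation: "inverse" (1/TH) or
    # "michaelis" (k_t4/(k_t4+TH)); the analytic layer assumes "inverse"
    th_suppression: str = "inverse"
    # the set point the production rates were calibrated against
    setpoint: SetPoint = field(default_factory=SetPoint)

    def __post_init__(self) -> None:
        for name in ("a_trh", "a_tsh", "a_th", "a_t", "a_p",
                     "b_trh", "b_tsh", "b_th", "b_t", "b_p"):
            if getattr(self, name) <= 0:
                raise DomainError(f"rate {name} must be positive")
        for name in ("k_t", "k_p", "ab", "b_30", "u"):
            if getattr(self, name) < 0:
                raise DomainError(f"{name} must be non-negative")

    @property
    def th_floor(self) -> float:
        return TH_FLOOR_REL * self.setpoint.th_set

    def replace(self, **changes) -> "ModelParameters":
        return dataclasses.replace(self, **changes)

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["setpoint"] = dataclasses.asdict(self.setpoint)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParameters":
        d = dict(d)
        sp = d.pop("setpoint", None)
        if sp is not None:
            d["setpoint"] = SetPoint(**sp)
        return cls(**d)


#: units of each parameter, recorded alongside serialized parameter sets
PARAMETER_UNITS = {
    "a_trh": "1/day", "a_tsh": "1/day", "a_th": "1/day", "a_t": "1/day", "a_p": "1/day",
    "b_trh": "TRH*pmol/L/day", "b_tsh": "mIU/L*pmol/L/(TRH*mass)/day",
    "b_th": "pmol/L/(mass*f)/day", "b_t": "1/(f*day)", "b_p": "pmol/L/day",
    "k_t": "1/mass", "k_p": "1/mass", "u": "dimensionless",
    "ab": "mIU/L (TSH-equivalent)", "b_30": "pmol/L/day",
    "k_trh": "TRH units", "k_t4": "pmol/L", "f_km": "mIU/L",
}


@dataclass(frozen=True)
class ScaledParameters:
    """Dimensionless groups governing the reduced slow (T, P) system.

    ``K_T = k_t*T0`` and ``K_P = k_p*P0`` with ``T0``, ``P0`` the
    capacity-free steady-state masses; ``AB = Ab*b_t/a_t``;
    ``B30 = b30*a_p/(a_th*b_p)``; ``KX2 = k_t4/TH0`` (0 for the 1/TH kernel).
    The gland turnover rates are carried along for stability analysis.
    """

    K_T: float = 0.0
    K_P: float = 0.0
    AB: float = 0.0
    B30: float = 0.0
    KX2: float = 0.0
    a_t: float = 1.0 / 30.0
    a_p: float = 1.0 / 30.0

    def __post_init__(self) -> None:
        for name in ("K_T", "K_P", "AB", "B30", "KX2"):
            if getattr(self, name) < 0:
                raise DomainError(f"{name} must be non-negative")

    def replace(self, **changes) -> "ScaledParameters":
        return dataclasses.replace(self, **changes)


# ---------------------------------------------------------------------------
# regulation function
# ---------------------------------------------------------------------------


def regulation_function(tsh_effective, variant: str = "linear", km: float | None = None):
    """TSH-receptor activation multiplier f(.).

    ``linear`` returns its argument (the form every analytic result assumes);
    ``saturating`` returns the Michaelis-Menten form x/(1 + x/km), bounded by
    ``km``.  Both are monotone non-decreasing and vanish at 0.
    """
    x = np.asarray(tsh_effective, float)
    if np.any(x < 0):
        raise DomainError("regulation function argument must be >= 0")
    if variant == "linear":
        out = x
    elif variant == "saturating":
        if km is None or km <= 0:
            raise DomainError("saturating variant requires a positive Michaelis constant")
        out = x / (1.0 + x / km)
    else:
        raise DomainError(f"unknown regulation-function variant {variant!r}")
    return out if out.ndim else float(out)


def regulation_inverse(y: float, variant: str = "linear", km: float | None = None) -> float:
    """Inverse of the regulation function (used for the pinned steady TSH)."""
    if y < 0:
        raise DomainError("regulation function is non-negative")
    if variant == "linear":
        return y
    if variant == "saturating":
        if y >= km:
            raise DomainError("value above the saturating bound has no preimage")
        return y / (1.0 - y / km)
    raise DomainError(f"unknown regulation-function variant {variant!r}")


def _f(params: ModelParameters, tsh_effective):
    return regulation_function(tsh_effective, params.f_variant, params.f_km)


def _supp(params: ModelParameters, th):
    """TH-suppression kernel of the TSH secretion term."""
    if params.th_suppression == "inverse":
        return 1.0 / th
    if params.th_suppression == "michaelis":
        return params.k_t4 / (params.k_t4 + th)
    raise DomainError(f"unknown TH-suppression kernel {params.th_suppression!r}")


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------


def calibrate_production_rates(
    setpoint: SetPoint = SetPoint(),
    *,
    a_trh: float,
    a_tsh: float,
    a_th: float,
    a_t: float,
    a_p: float,
    k_t: float = 0.0,
    k_p: float = 0.0,
    u: float = 1.0,
    f_variant: str = "linear",
    f_km: float = 6.0,
    th_suppression: str = "inverse",
    **extra,
) -> ModelParameters:
    """Solve the five production rates so the set point is a fixed point.

    The healthy state (with ``ab = b_30 = 0``) must zero every equation:
    ``b_t`` and ``b_p`` come from the mass equations, ``b_th``, ``b_tsh`` and
    ``b_trh`` from the hormone equations with TRH normalised to ``trh_set``.
    """
    if k_t * setpoint.t_set >= 1.0:
        raise InfeasibleCalibrationError(
            "thyroid carrying capacity 1/k_t must exceed the set-point mass")
    if k_p * setpoint.p_set >= 1.0:
        raise InfeasibleCalibrationError(
            "thyrotroph carrying capacity 1/k_p must exceed the set-point mass")
    if u <= 0:
        raise DomainError("hypothalamic input u must be positive")
    fs = regulation_function(setpoint.tsh_set, f_variant, f_km)
    b_t = a_t / (fs * (1.0 - k_t * setpoint.t_set))
    b_p = a_p * setpoint.th_set / (1.0 - k_p * setpoint.p_set)
    b_th = a_th * setpoint.th_set / (setpoint.t_set * fs)
    b_trh = a_trh * setpoint.trh_set * setpoint.th_set / u
    params = ModelParameters(
        a_trh=a_trh, a_tsh=a_tsh, a_th=a_th, a_t=a_t, a_p=a_p,
        b_trh=b_trh, b_tsh=1.0, b_th=b_th, b_t=b_t, b_p=b_p,
        k_t=k_t, k_p=k_p, u=u, f_variant=f_variant, f_km=f_km,
        th_suppression=th_suppression, setpoint=setpoint, **extra)
    b_tsh = a_tsh * setpoint.tsh_set / (
        setpoint.p_set * setpoint.trh_set * _supp(params, setpoint.th_set))
    return params.replace(b_tsh=b_tsh)


def default_parameters(
    setpoint: SetPoint = SetPoint(),
    *,
    k_t: float = 0.0,
    k_p: float = 0.0,
    u: float = 1.0,
    half_life_convention: str = "reciprocal",
    **extra,
) -> ModelParameters:
    """Literature calibration: removal rates from the stated half-lives
    (TRH 6 min, TSH 1 h, T4 7 d, gland turnover 30 d), production rates
    solved against the healthy set point; no perturbation (ab = b_30 = 0).

    ``half_life_convention`` is ``"reciprocal"`` (a = 1/t_half, the default,
    which reproduces the reference simulations) or ``"log2"`` (a = ln2/t_half).
    """
    if half_life_convention == "reciprocal":
        c = 1.0
    elif half_life_convention == "log2":
        c = math.log(2.0)
    else:
        raise DomainError("half_life_convention must be 'reciprocal' or 'log2'")
    return calibrate_production_rates(
        setpoint,
        a_trh=c / (6 * MINUTE),
        a_tsh=c / (1 * HOUR),
        a_th=c / (7 * DAY),
        a_t=c / (30 * DAY),
        a_p=c / (30 * DAY),
        k_t=k_t, k_p=k_p, u=u, **extra)


def set_point_state(params: ModelParameters) -> AxisState:
    sp = params.setpoint
    return AxisState(sp.trh_set, sp.tsh_set, sp.th_set, sp.t_set, sp.p_set)


# ---------------------------------------------------------------------------
# right-hand side
# ---------------------------------------------------------------------------


def rhs_array(y: np.ndarray, params: ModelParameters,
              mass_frozen: bool = False) -> np.ndarray:
    """Vectorised RHS on a raw state array; TH is clamped at a small floor
    inside the 1/TH terms (thyroidectomy can drive TH transiently very low)."""
    trh, tsh, th, t_mass, p_mass = y
    th_div = max(th, params.th_floor)
    tsh_eff = max(tsh, 0.0) + params.ab
    fval = _f(params, tsh_eff)
    d_th = params.b_th * t_mass * fval + params.b_30 - params.a_th * th
    d_tsh = params.b_tsh * p_mass * trh * _supp(params, th_div) - params.a_tsh * tsh
    d_trh = params.b_trh * params.u / th_div - params.a_trh * trh
    if mass_frozen:
        d_t = 0.0
        d_p = 0.0
    else:
        d_t = t_mass * (params.b_t * fval * (1.0 - params.k_t * t_mass) - params.a_t)
        d_p = p_mass * (params.b_p * (1.0 - params.k_p * p_mass) / th_div - params.a_p)
    return np.array([d_trh, d_tsh, d_th, d_t, d_p])


def rhs(state: AxisState, params: ModelParameters) -> np.ndarray:
    """d(TRH, TSH, TH, T, P)/dt at ``state``.  Raises for TH <= 0."""
    if state.th <= 0:
        raise SingularStateError("RHS undefined for TH <= 0 (division by TH)")
    state.validate()
    return rhs_array(state.as_array(), params)


def jacobian(state: AxisState, params: ModelParameters,
             eps: float = 1e-7) -> np.ndarray:
    """Finite-difference Jacobian of the full 5-D system (central differences,
    step relative to each component's scale)."""
    y0 = state.as_array()
    scale = np.maximum(np.abs(y0), 1e-3)
    J = np.empty((5, 5))
    for j in range(5):
        h = eps * scale[j]
        yp, ym = y0.copy(), y0.copy()
        yp[j] += h
        ym[j] -= h
        J[:, j] = (rhs_array(yp, params) - rhs_array(ym, params)) / (2 * h)
    return J


# ---------------------------------------------------------------------------
# dimensionless scaling
# ---------------------------------------------------------------------------


def capacity_free_steady_state(params: ModelParameters) -> AxisState:
    """Steady state of the integral-feedback core (capacities, antibody and
    external T4 all ignored): TSH0 = f^{-1}(a_t/b_t), TH0 = b_p/a_p, with the
    masses solved from the hormone balances."""
    tsh0 = regulation_inverse(params.a_t / params.b_t, params.f_variant, params.f_km)
    th0 = params.b_p / params.a_p
    trh0 = params.b_trh * params.u / (params.a_trh * th0)
    t0 = params.a_th * th0 / (params.b_th * _f(params, tsh0))
    p0 = params.a_tsh * tsh0 / (params.b_tsh * trh0 * _supp(params, th0))
    return AxisState(trh0, tsh0, th0, t0, p0)


def scale_parameters(params: ModelParameters) -> ScaledParameters:
    """Dimensionless groups of the slow subsystem.

    ``AB = ab*b_t/a_t`` and ``B30 = b_30*a_p/(a_th*b_p)`` are the printed
    closed-form groups; ``K_T`` and ``K_P`` are the capacities measured in
    units of the capacity-free steady masses.
    """
    free = capacity_free_steady_state(params)
    kx2 = params.k_t4 / free.th if params.th_suppression == "michaelis" else 0.0
    return ScaledParameters(
        K_T=params.k_t * free.t_mass,
        K_P=params.k_p * free.p_mass,
        AB=params.ab * params.b_t / params.a_t,
        B30=params.b_30 * params.a_p / (params.a_th * params.b_p),
        KX2=kx2,
        a_t=params.a_t,
        a_p=params.a_p,
    )


def capacities_from_scaled(K_T: float, K_P: float,
                           setpoint: SetPoint = SetPoint()) -> tuple[float, float]:
    """Raw (k_t, k_p) whose *calibrated* model has the requested scaled
    capacities.  Under set-point calibration with unit masses,
    K_T = x/((1-x)(1-y)) and K_P = y(1-x)/(1-y)^2 with x = k_t*t_set,
    y = k_p*p_set; the pair is solved numerically (exact closed forms are
    used to seed and for the single-capacity cases).
    """
    if K_T < 0 or K_P < 0:
        raise DomainError("scaled capacities must be non-negative")

    def resid(z):
        x, y = z
        return [x / ((1 - x) * (1 - y)) - K_T, y * (1 - x) / (1 - y) ** 2 - K_P]

    # closed-form single-capacity seeds
    x0 = K_T / (1.0 + K_T)
    if K_P == 0:
        y0 = 0.0
    else:
        y0 = ((2 * K_P + 1) - math.sqrt(4 * K_P + 1)) / (2 * K_P)
    if K_T == 0 or K_P == 0:
        x, y = x0, y0
    else:
        sol = optimize.root(resid, [x0, y0], method="hybr")
        if max(abs(r) for r in resid(sol.x)) > 1e-10:
            raise RuntimeError(f"capacity inversion failed: {sol.message}")
        x, y = sol.x
    if not (0 <= x < 1 and 0 <= y < 1):
        raise InfeasibleCalibrationError("no admissible capacities for these scaled values")
    return x / setpoint.t_set, y / setpoint.p_set


def nondimensionalized_parameters(params: ModelParameters) -> tuple[ModelParameters, np.ndarray]:
    """Equivalent parameter set whose set point is (1, 1, 1, 1, 1), plus the
    state scale vector: simulating the unit-set-point system and multiplying
    by the scale reproduces the dimensional trajectory."""
    sp = params.setpoint
    scale = np.array([sp.trh_set, sp.tsh_set, sp.th_set, sp.t_set, sp.p_set])
    unit = calibrate_production_rates(
        SetPoint(1.0, 1.0, 1.0, 1.0, 1.0),
        a_trh=params.a_trh, a_tsh=params.a_tsh, a_th=params.a_th,
        a_t=params.a_t, a_p=params.a_p,
        k_t=params.k_t * sp.t_set, k_p=params.k_p * sp.p_set, u=params.u,
        f_variant=params.f_variant, f_km=params.f_km / sp.tsh_set,
        th_suppression=params.th_suppression,
        ab=params.ab / sp.tsh_set, b_30=params.b_30 / sp.th_set,
        k_trh=params.k_trh / sp.trh_set, k_t4=params.k_t4 / sp.th_set,
    )
    return unit, scale
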
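"""Slow/fast reduction of the gland-mass HPT model.

The hormones (minutes-to-days turnover) equilibrate much faster than the
gland masses (a month), so the slow dynamics live on the (T, P) plane with
the hormones at quasi-steady state (QSS).  This module provides the QSS
solver, the two slow nullclines, fixed points and their stability, the
antibody threshold of the transcritical bifurcation, the analytic piecewise
TSH(T4) curve, clinical region classification, and parameter sweeps.

The scaled slow system (linear regulation function) is

    dt/dtau = a_t * t * [(tsh + AB)(1 - K_T t) - 1]
    dp/dtau = a_p * p * [(1 - K_P p)/th - 1]

with scaled QSS hormones solving

    th  = t (tsh + AB) + B30
    tsh = p (1 + KX2) / (th (KX2 + th))       (KX2 = 0 -> tsh = p/th^2)

so in the unperturbed case th = (t p)^(1/3).  All scaled quantities are in
units of the capacity-free steady state.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .hpt_model import (
    AxisState,
    DomainError,
    ModelParameters,
    ScaledParameters,
    capacity_free_steady_state,
    jacobian,
    regulation_function,
    regulation_inverse,
    rhs_array,
    scale_parameters,
    _supp,
)

logger = logging.getLogger("thyraxis")

_RESID_TOL = 1e-8


class NoPositiveRootError(ValueError):
    """QSS hormone system has no positive TH root for the given masses."""


# ---------------------------------------------------------------------------
# quasi-steady-state hormones
# ---------------------------------------------------------------------------


@dataclass
class QssHormones:
    """Fast-variable steady state at fixed gland masses."""

    trh: float
    tsh: float
    th: float
    degenerate: bool = False

    def __iter__(self):
        return iter((self.trh, self.tsh, self.th))


def _qss_tsh_of_th(th: float, p_mass: float, params: ModelParameters) -> float:
    """TSH at fast QSS for an imposed TH (TRH itself at QSS)."""
    trh = params.b_trh * params.u / (params.a_trh * th)
    return params.b_tsh * p_mass * trh * _supp(params, th) / params.a_tsh


def qss_hormones(t_mass: float, p_mass: float, params: ModelParameters) -> QssHormones:
    """Solve Eqs (1)-(3) steady state at fixed masses.

    With a linear regulation function and no antibody/external T4 the closed
    form is TH^3 = (b_th/a_th) * T * C * P with C = b_tsh*b_trh*u/(a_tsh*a_trh)
    (scaled: th = (t p)^(1/3)); the general case is solved by bracketed 1-D
    root-finding in TH.  A degenerate input (no TH source at all) returns the
    floor state flagged ``degenerate``.
    """
    if t_mass < 0 or p_mass < 0:
        raise DomainError("gland masses must be non-negative")
    simple = (params.f_variant == "linear" and params.ab == 0.0
              and params.b_30 == 0.0 and params.th_suppression == "inverse")
    C = params.b_tsh * params.b_trh * params.u / (params.a_tsh * params.a_trh)
    if t_mass * p_mass == 0.0 and params.b_30 == 0.0 and (
            t_mass == 0.0 or params.ab == 0.0):
        th = params.th_floor
        tsh = _qss_tsh_of_th(th, p_mass, params) if p_mass > 0 else 0.0
        trh = params.b_trh * params.u / (params.a_trh * th)
        return QssHormones(trh, tsh, th, degenerate=True)
    if simple:
        th = (params.b_th * t_mass * C * p_mass / params.a_th) ** (1.0 / 3.0)
    else:
        def g(log_th):
            th_ = math.exp(log_th)
            tsh_ = _qss_tsh_of_th(th_, p_mass, params)
            f = regulation_function(tsh_ + params.ab, params.f_variant, params.f_km)
            return params.b_th * t_mass * f + params.b_30 - params.a_th * th_

        sp = params.setpoint
        lo, hi = math.log(1e-9 * sp.th_set), math.log(1e6 * sp.th_set)
        if g(lo) < 0:  # pragma: no cover - production + source at tiny TH is positive
            raise NoPositiveRootError("no positive TH root")
        while g(hi) > 0:
            hi += math.log(10.0)
        th = math.exp(optimize.brentq(g, lo, hi, xtol=1e-15, rtol=1e-14))
    tsh = _qss_tsh_of_th(th, p_mass, params)
    trh = params.b_trh * params.u / (params.a_trh * th)
    return QssHormones(trh, tsh, th)


def fast_relation_exponent(params: ModelParameters,
                           th_pair: tuple[float, float] | None = None,
                           t_mass: float | None = None,
                           p_mass: float | None = None) -> float:
    """Magnitude of the log-log slope of the fast-timescale TSH(TH) relation
    at fixed gland masses (TH imposed as demand, TRH and TSH at QSS).

    With the 1/TH kernels of the TSH and TRH equations this is exactly 2;
    a saturating (Michaelis-Menten) TH suppression flattens it below 2.
    If ``th_pair`` holds two distinct TH values the two-point finite
    difference |d ln TSH / d ln TH| is returned, otherwise the analytic
    derivative at the set point (the degenerate equal pair falls back to the
    analytic route as well).
    """
    p_mass = params.setpoint.p_set if p_mass is None else p_mass
    if th_pair is not None and not math.isclose(th_pair[0], th_pair[1]):
        th1, th2 = th_pair
        if min(th1, th2) <= 0:
            raise DomainError("TH values must be positive")
        tsh1 = _qss_tsh_of_th(th1, p_mass, params)
        tsh2 = _qss_tsh_of_th(th2, p_mass, params)
        return abs(math.log(tsh2 / tsh1) / math.log(th2 / th1))
    th = params.setpoint.th_set
    if params.th_suppression == "inverse":
        return 2.0
    return 1.0 + th / (params.k_t4 + th)


# ---------------------------------------------------------------------------
# scaled slow subsystem
# ---------------------------------------------------------------------------


def scaled_qss(t: float, p: float, scaled: ScaledParameters) -> tuple[float, float]:
    """Scaled (th, tsh) at QSS for scaled masses (t, p)."""
    AB, B30, KX2 = scaled.AB, scaled.B30, scaled.KX2

    def tsh_of(th):
        return p * (1.0 + KX2) / (th * (KX2 + th))

    if t == 0.0 and B30 == 0.0:
        return 0.0, math.inf if p > 0 else 0.0
    if p == 0.0:
        th = t * AB + B30
        return th, 0.0
    if AB == 0.0 and B30 == 0.0 and KX2 == 0.0:
        th = (t * p) ** (1.0 / 3.0)
        return th, p / th**2

    def g(log_th):
        th = math.exp(log_th)
        return t * (tsh_of(th) + AB) + B30 - th

    lo, hi = math.log(1e-12), math.log(1e6)
    while g(hi) > 0:
        hi += math.log(10.0)
    th = math.exp(optimize.brentq(g, lo, hi, xtol=1e-15, rtol=1e-14))
    return th, tsh_of(th)


def slow_residuals(t: float, p: float, scaled: ScaledParameters) -> tuple[float, float]:
    """Growth-balance residuals of the two slow equations (zero on the
    respective nullcline): r_T = (tsh+AB)(1-K_T t) - 1, r_P = (1-K_P p)/th - 1."""
    th, tsh = scaled_qss(t, p, scaled)
    r_t = (tsh + scaled.AB) * (1.0 - scaled.K_T * t) - 1.0
    r_p = (1.0 - scaled.K_P * p) / th - 1.0
    return r_t, r_p


def slow_vector_field(t: float, p: float, scaled: ScaledParameters) -> np.ndarray:
    r_t, r_p = slow_residuals(t, p, scaled)
    return np.array([scaled.a_t * t * r_t, scaled.a_p * p * r_p])


def slow_jacobian(t: float, p: float, scaled: ScaledParameters,
                  eps: float = 1e-7) -> np.ndarray:
    J = np.empty((2, 2))
    for j, (dt_, dp_) in enumerate([(1.0, 0.0), (0.0, 1.0)]):
        h = eps * max(abs(t) if j == 0 else abs(p), 1e-3)
        fp = slow_vector_field(t + h * dt_, p + h * dp_, scaled)
        fm = slow_vector_field(t - h * dt_, p - h * dp_, scaled)
        J[:, j] = (fp - fm) / (2 * h)
    return J


# ---------------------------------------------------------------------------
# nullclines
# ---------------------------------------------------------------------------


@dataclass
class NullclineSamples:
    """Paired samples of one slow nullcline in scaled mass units."""

    which: str  # "thyroid" (dT/dt = 0) or "pituitary" (dP/dt = 0)
    t_values: np.ndarray
    p_values: np.ndarray
    scaled_params: ScaledParameters


def nullcline_thyroid(t_grid, scaled: ScaledParameters,
                      method: str = "numeric") -> NullclineSamples:
    """dT/dt = 0 branch with T > 0.

    In the unperturbed case (AB = B30 = KX2 = 0) the closed form is
    p = t^2/(1 - K_T t)^3; the numeric route root-finds the slow residual
    with hormones at QSS and is valid for any perturbation.
    """
    t_grid = np.atleast_1d(np.asarray(t_grid, float))
    if scaled.K_T > 0 and np.any(t_grid >= 1.0 / scaled.K_T):
        raise DomainError("t grid must lie below the scaled capacity 1/K_T")
    if np.any(t_grid <= 0):
        raise DomainError("t grid must be positive (T = 0 is the trivial branch)")
    if method == "closed":
        if scaled.AB or scaled.B30 or scaled.KX2:
            raise DomainError("closed form only valid for AB = B30 = KX2 = 0")
        p = t_grid**2 / (1.0 - scaled.K_T * t_grid) ** 3
        return NullclineSamples("thyroid", t_grid, p, scaled)
    p_out = np.empty_like(t_grid)
    for i, t in enumerate(t_grid):
        tsh_req = 1.0 / (1.0 - scaled.K_T * t) - scaled.AB
        if tsh_req <= 0:
            p_out[i] = 0.0  # antibody alone sustains growth; nullcline hits p = 0
            continue

        def r(log_p, t=t):
            return slow_residuals(t, math.exp(log_p), scaled)[0]

        lo, hi = math.log(1e-10), math.log(1e8)
        p_out[i] = math.exp(optimize.brentq(r, lo, hi, xtol=1e-14, rtol=1e-14))
    return NullclineSamples("thyroid", t_grid, p_out, scaled)


def nullcline_pituitary(p_grid, scaled: ScaledParameters,
                        method: str = "numeric") -> NullclineSamples:
    """dP/dt = 0 branch with P > 0; closed form t = (1 - K_P p)^3/p in the
    unperturbed case."""
    p_grid = np.atleast_1d(np.asarray(p_grid, float))
    if np.any(p_grid <= 0):
        raise DomainError("p grid must be positive (P = 0 is the trivial branch)")
    if scaled.K_P > 0 and np.any(p_grid >= 1.0 / scaled.K_P):
        raise DomainError("p grid must lie below the scaled capacity 1/K_P")
    if method == "closed":
        if scaled.AB or scaled.B30 or scaled.KX2:
            raise DomainError("closed form only valid for AB = B30 = KX2 = 0")
        t = (1.0 - scaled.K_P * p_grid) ** 3 / p_grid
        return NullclineSamples("pituitary", t, p_grid, scaled)
    t_out = np.empty_like(p_grid)
    for i, p in enumerate(p_grid):
        th_req = 1.0 - scaled.K_P * p  # growth balance pins scaled th
        if th_req <= scaled.B30:
            t_out[i] = 0.0
            continue

        def r(log_t, p=p):
            return slow_residuals(math.exp(log_t), p, scaled)[1]

        lo, hi = math.log(1e-10), math.log(1e8)
        # residual decreases in t (more thyroid -> more TH -> less P growth)
        t_out[i] = math.exp(optimize.brentq(r, lo, hi, xtol=1e-14, rtol=1e-14))
    return NullclineSamples("pituitary", t_out, p_grid, scaled)


# ---------------------------------------------------------------------------
# fixed points and the Graves bifurcation
# ---------------------------------------------------------------------------


@dataclass
class FixedPoint:
    """Fixed point of the slow subsystem (scaled units, hormones at QSS)."""

    state: AxisState  # scaled state: trh, tsh, th, t, p all relative to capacity-free values
    stable: bool
    eigenvalues: np.ndarray
    branch: str = "interior"  # interior | p_zero | t_zero
    residual: float = 0.0


def _make_fixed_point(t: float, p: float, scaled: ScaledParameters,
                      branch: str) -> FixedPoint:
    th, tsh = scaled_qss(t, p, scaled)
    trh = 1.0 / th if th > 0 else math.inf
    if branch == "interior":
        J = slow_jacobian(t, p, scaled)
        eig = np.linalg.eigvals(J)
        resid = float(np.max(np.abs(slow_vector_field(t, p, scaled))))
    else:
        # along the boundary the off-branch eigenvalue is the growth rate of
        # the zero component; the on-branch eigenvalue is the 1-D derivative
        r_t, r_p = slow_residuals(t, p, scaled)
        if branch == "p_zero":
            lam_off = scaled.a_p * r_p
            h = 1e-7 * max(t, 1e-3)
            lam_on = (slow_vector_field(t + h, p, scaled)[0]
                      - slow_vector_field(t - h, p, scaled)[0]) / (2 * h)
            resid = abs(scaled.a_t * t * r_t)
        else:
            lam_off = scaled.a_t * r_t
            h = 1e-7 * max(p, 1e-3)
            lam_on = (slow_vector_field(t, p + h, scaled)[1]
                      - slow_vector_field(t, p - h, scaled)[1]) / (2 * h)
            resid = abs(scaled.a_p * p * r_p)
        eig = np.array([lam_on, lam_off])
    stable = bool(np.max(eig.real) < 0)
    state = AxisState(trh=trh, tsh=tsh, th=th, t_mass=t, p_mass=p)
    return FixedPoint(state, stable, eig, branch, resid)


def fixed_points(scaled: ScaledParameters) -> list[FixedPoint]:
    """All intersections of the slow nullclines plus the boundary branches.

    Interior points are found by multi-start 2-D root-finding in log masses;
    the P = 0 branch exists for AB > 1 (finite only with K_T > 0) and the
    T = 0 branch for 0 < B30 < 1 with K_P > 0.  Stability comes from the
    slow-subsystem Jacobian; the interior/boundary stability exchange at
    AB = 1 + K_T is the transcritical bifurcation of Graves' disease.
    """
    found: list[FixedPoint] = []

    def resid(z):
        t, p = math.exp(z[0]), math.exp(z[1])
        return slow_residuals(t, p, scaled)

    t_max = 1.0 / scaled.K_T if scaled.K_T > 0 else 10.0
    p_max = 1.0 / scaled.K_P if scaled.K_P > 0 else 10.0
    seeds = [(0.0, 0.0)]
    for ft in (0.05, 0.3, 0.7, 0.95):
        for fp_ in (0.05, 0.3, 0.7, 0.95):
            seeds.append((math.log(ft * t_max), math.log(fp_ * p_max)))
    for z0 in seeds:
        sol = optimize.root(resid, z0, method="hybr", tol=1e-13)
        if not sol.success:
            continue
        t, p = math.exp(sol.x[0]), math.exp(sol.x[1])
        if scaled.K_T > 0 and t >= 1.0 / scaled.K_T:
            continue
        if scaled.K_P > 0 and p >= 1.0 / scaled.K_P:
            continue
        if max(abs(r) for r in slow_residuals(t, p, scaled)) > _RESID_TOL:
            continue
        if any(fp0.branch == "interior"
               and abs(math.log(t / fp0.state.t_mass)) < 1e-6
               and abs(math.log(p / fp0.state.p_mass)) < 1e-6 for fp0 in found):
            continue
        found.append(_make_fixed_point(t, p, scaled, "interior"))
    # P = 0 branch: thyroid growth balanced by the antibody alone
    if scaled.AB > 1.0 and scaled.K_T > 0:
        t_star = (scaled.AB - 1.0) / (scaled.AB * scaled.K_T)
        found.append(_make_fixed_point(t_star, 0.0, scaled, "p_zero"))
    # T = 0 branch: external T4 sustains the hormones without a thyroid
    if 0.0 < scaled.B30 < 1.0 and scaled.K_P > 0:
        p_star = (1.0 - scaled.B30) / scaled.K_P
        found.append(_make_fixed_point(0.0, p_star, scaled, "t_zero"))
    return found


def transcritical_ab(scaled: ScaledParameters) -> float:
    """Scaled antibody level at which the interior and P = 0 branches
    exchange stability: AB = 1 + K_T."""
    return 1.0 + scaled.K_T


def graves_threshold(params: ModelParameters) -> float:
    """Dimensional antibody threshold for clinical Graves' disease,
    a_t/b_t + b_p*a_th*k_t/(a_p*b_th) in TSH-equivalent mIU/L; the thyrotroph
    mass collapses to zero above it (scaled form AB > 1 + K_T)."""
    if params.f_variant != "linear":
        raise DomainError("threshold formula assumes the linear regulation function")
    thr = (params.a_t / params.b_t
           + params.b_p * params.a_th * params.k_t / (params.a_p * params.b_th))
    scaled = scale_parameters(params)
    scaled_thr = thr * params.b_t / params.a_t
    if not math.isclose(scaled_thr, 1.0 + scaled.K_T, rel_tol=1e-10):
        raise AssertionError("scaled threshold inconsistent with 1 + K_T")
    return thr


# ---------------------------------------------------------------------------
# the analytic TSH(T4) curve
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TshT4Curve:
    """Piecewise-rational steady-state TSH as a function of free T4:

        TSH(T4) = A (1 - T4/B) / T4^2   for 0 < T4 <= B,  else 0

    with A = b_trh*b_tsh*u/(a_trh*a_tsh*k_p) and B = b_p/a_p.  The curve is
    independent of every thyroid-side parameter (b_th, a_th, b_t, a_t, k_t)
    and of the antibody level, which is why steady states of Hashimoto's,
    Graves' and iodine-deficiency sweeps all fall on one curve; pituitary
    parameters and the hypothalamic input u move the curve itself.
    """

    alpha: float  # A, mIU/L * (pmol/L)^2
    beta_inv: float  # B, pmol/L (TH zero-crossing)

    def __call__(self, t4):
        t4 = np.asarray(t4, float)
        if np.any(t4 <= 0):
            raise DomainError("T4 must be positive")
        val = np.where(t4 <= self.beta_inv,
                       self.alpha * (1.0 - t4 / self.beta_inv) / t4**2, 0.0)
        return val if val.ndim else float(val)


def tsh_of_t4_curve(params: ModelParameters) -> TshT4Curve:
    if params.k_p <= 0:
        raise DomainError("the TSH(T4) curve requires a finite pituitary "
                          "carrying capacity (k_p > 0)")
    A = params.b_trh * params.b_tsh * params.u / (params.a_trh * params.a_tsh * params.k_p)
    B = params.b_p / params.a_p
    return TshT4Curve(alpha=A, beta_inv=B)


def curve_from_setpoint(tsh0: float = 1.5, t40: float = 15.0,
                        capacity_fold: float = 5.0) -> TshT4Curve:
    """Non-parameterised form of the curve in terms of the capacity-free set
    point: alpha = TSH0*T40^2/(P0*k_p), beta = 1/T40, with the pituitary
    capacity expressed as a fold of the healthy mass (1/k_p = fold*P0)."""
    if capacity_fold <= 1:
        raise DomainError("capacity must exceed the healthy mass")
    return TshT4Curve(alpha=tsh0 * t40**2 * capacity_fold, beta_inv=t40)


def curve_residual(curve: TshT4Curve, th: float, tsh: float) -> float:
    """Relative TSH residual of a steady state against the curve."""
    pred = curve(th)
    return abs(tsh - pred) / max(abs(tsh), 1e-300)


# ---------------------------------------------------------------------------
# full-model steady state
# ---------------------------------------------------------------------------


@dataclass
class SteadyState:
    state: AxisState  # dimensional
    branch: str
    converged: bool
    residual: float


def steady_state(params: ModelParameters) -> SteadyState:
    """Stable steady state of the full five-variable model (dimensional).

    Solved on the QSS-reduced slow plane: above the Graves threshold
    (AB > 1 + K_T) the thyrotroph branch P = 0 is returned exactly; when the
    thyroid cannot persist (e.g. levothyroxine replacement with elevated
    thyrocyte removal) the T = 0 branch is returned; otherwise the interior
    point is located by 2-D root-finding seeded from the set point.
    """
    free = capacity_free_steady_state(params)
    scaled = scale_parameters(params)
    linear = params.f_variant == "linear"

    def dimensional(t_scaled, p_scaled):
        T = t_scaled * free.t_mass
        P = p_scaled * free.p_mass
        h = qss_hormones(T, P, params)
        return AxisState(h.trh, h.tsh, h.th, T, P)

    if linear and scaled.AB > transcritical_ab(scaled) * (1 + 1e-12):
        if scaled.K_T <= 0:
            return SteadyState(dimensional(1.0, 1.0), "unbounded", False, math.inf)
        t_star = (scaled.AB - 1.0) / (scaled.AB * scaled.K_T)
        st = dimensional(t_star, 0.0)
        st.tsh = 0.0
        resid = float(np.max(np.abs(rhs_array(st.as_array(), params))))
        return SteadyState(st, "p_zero", True, resid)

    # interior branch
    def resid2(z):
        return slow_residuals(math.exp(z[0]), math.exp(z[1]), scaled)

    best = None
    for z0 in [(0.0, 0.0), (-1.0, 1.0), (1.0, -1.0), (-2.0, 0.5), (0.5, -2.0)]:
        sol = optimize.root(resid2, z0, method="hybr", tol=1e-13)
        if sol.success and max(abs(r) for r in resid2(sol.x)) < _RESID_TOL:
            t_s, p_s = math.exp(sol.x[0]), math.exp(sol.x[1])
            if scaled.K_T > 0 and t_s >= 1.0 / scaled.K_T:
                continue
            if scaled.K_P > 0 and p_s >= 1.0 / scaled.K_P:
                continue
            J = slow_jacobian(t_s, p_s, scaled)
            if np.max(np.linalg.eigvals(J).real) < 0:
                best = (t_s, p_s)
                break
    if best is not None:
        st = dimensional(*best)
        resid = float(np.max(np.abs(rhs_array(st.as_array(), params))))
        return SteadyState(st, "interior", True, resid)

    # T = 0 branch (external T4 carries the axis)
    if params.b_30 > 0:
        th = params.b_30 / params.a_th
        if params.k_p > 0:
            P = (1.0 - th * params.a_p / params.b_p) / params.k_p
        else:
            P = params.setpoint.p_set if math.isclose(
                th, params.b_p / params.a_p, rel_tol=1e-9) else -1.0
        if P > 0:
            trh = params.b_trh * params.u / (params.a_trh * th)
            tsh = params.b_tsh * P * trh * _supp(params, th) / params.a_tsh
            st = AxisState(trh, tsh, th, 0.0, P)
            resid = float(np.max(np.abs(rhs_array(st.as_array(), params))))
            return SteadyState(st, "t_zero", resid < 1e-6, resid)
    return SteadyState(dimensional(1.0, 1.0), "not_converged", False, math.inf)


# ---------------------------------------------------------------------------
# clinical region classification and sweeps
# ---------------------------------------------------------------------------

#: default laboratory reference ranges: TSH 0.5-5 mIU/L, free T4 10-20 pmol/L
DEFAULT_THRESHOLDS = {"tsh": (0.5, 5.0), "t4": (10.0, 20.0)}


@dataclass(frozen=True)
class RegionLabel:
    tsh_class: str  # hypo | normal | hyper
    t4_class: str
    composite: str


def _band(x: float, lo: float, hi: float) -> str:
    return "hypo" if x < lo else ("hyper" if x > hi else "normal")


def classify_region(t_mass: float, p_mass: float, params: ModelParameters,
                    thresholds: dict | None = None) -> RegionLabel:
    """Clinical state implied by the QSS hormones at given gland masses.

    Composite classes follow the usual diagnostic logic: abnormal TSH with
    normal T4 is subclinical; abnormal T4 is clinical (hypo/hyper by the T4
    side) unless TSH is normal, which is flagged normo-TSH/abnormal-T4.
    """
    thr = thresholds or DEFAULT_THRESHOLDS
    h = qss_hormones(t_mass, p_mass, params)
    tsh_class = _band(h.tsh, *thr["tsh"])
    t4_class = _band(h.th, *thr["t4"])
    if t4_class == "normal":
        if tsh_class == "normal":
            composite = "euthyroid"
        else:
            # high TSH compensates a failing thyroid: subclinical hypothyroid
            composite = "subclinical-hypo" if tsh_class == "hyper" else "subclinical-hyper"
    elif tsh_class == "normal":
        composite = "normo-TSH/abnormal-T4"
    else:
        composite = "clinical-hypo" if t4_class == "hypo" else "clinical-hyper"
    return RegionLabel(tsh_class, t4_class, composite)


def sweep(parameter: str, values, params: ModelParameters,
          relative: bool = False, thresholds: dict | None = None) -> pd.DataFrame:
    """Steady states and clinical labels over a 1-D parameter sweep.

    ``relative=True`` multiplies the calibrated baseline value instead of
    setting absolute values (the convention of the staging sweeps, e.g.
    a_t in {1, 2, 5, 15} x basal).
    """
    if parameter not in {f.name for f in dataclasses.fields(ModelParameters)}:
        raise DomainError(f"unknown parameter {parameter!r}")
    base = getattr(params, parameter)
    rows = []
    for v in values:
        val = base * v if relative else v
        p = params.replace(**{parameter: val})
        ss = steady_state(p)
        h = ss.state
        if ss.converged:
            label = classify_region(h.t_mass, h.p_mass, p, thresholds)
            composite = label.composite
        else:
            composite = "not-converged"
        mult = v if relative else (val / base if base != 0 else math.nan)
        rows.append({parameter: val, "multiplier": mult,
                     "th": h.th, "tsh": h.tsh, "t_mass": h.t_mass,
                     "p_mass": h.p_mass, "branch": ss.branch,
                     "converged": ss.converged, "region": composite})
    return pd.DataFrame(rows)
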
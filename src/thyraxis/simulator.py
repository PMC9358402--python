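"""Event-scheduled integration of the gland-mass HPT model and the named
disease/treatment scenarios (Hashimoto's thyroiditis, Graves' disease,
iodine deficiency, thyroidectomy) plus the TRH stimulation test.

Integration is piecewise: the solver restarts at every scheduled parameter
change so discontinuities are placed exactly.  A ``mass_frozen`` run
integrates only the three hormone equations with the gland masses pinned —
the constant-mass comparison model, which shows no compensation and no
hysteresis.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.integrate import solve_ivp

from . import axis_analysis
from .hpt_model import (
    AxisState,
    DomainError,
    MINUTE,
    ModelParameters,
    SetPoint,
    capacities_from_scaled,
    default_parameters,
    rhs_array,
    set_point_state,
    _supp,
)

logger = logging.getLogger("thyraxis")


class IntegrationError(RuntimeError):
    pass


class NoCrossingError(ValueError):
    pass


# ---------------------------------------------------------------------------
# schedules and trajectories
# ---------------------------------------------------------------------------


@dataclass
class EventSchedule:
    """Ordered (time, parameter, value) overrides applied during integration."""

    events: list[tuple[float, str, float]] = field(default_factory=list)
    horizon: float = 100.0

    def __post_init__(self) -> None:
        valid = {f.name for f in dataclasses.fields(ModelParameters)} - {"setpoint"}
        times = [e[0] for e in self.events]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise DomainError("event times must be strictly increasing")
        if times and (times[0] < 0 or times[-1] > self.horizon):
            raise DomainError("event times must lie within [0, horizon]")
        for _, name, _ in self.events:
            if name not in valid:
                raise DomainError(f"unknown parameter {name!r} in event schedule")

    def to_dict(self) -> dict:
        return {"events": [list(e) for e in self.events], "horizon": self.horizon}


def ramp_events(name: str, t0: float, t1: float, v0: float, v1: float,
                n_steps: int = 10) -> list[tuple[float, str, float]]:
    """Staircase approximation of a linear ramp of one parameter."""
    ts = np.linspace(t0, t1, n_steps + 1)
    vs = np.linspace(v0, v1, n_steps + 1)
    return [(float(t), name, float(v)) for t, v in zip(ts[1:], vs[1:])]


@dataclass
class Trajectory:
    """Time series of the axis state under an event schedule."""

    times: np.ndarray  # days
    states: np.ndarray  # (n, 5): trh, tsh, th, t_mass, p_mass
    params_active: list[tuple[float, ModelParameters]]
    mass_frozen: bool = False
    meta: dict = field(default_factory=dict)

    @property
    def trh(self):
        return self.states[:, 0]

    @property
    def tsh(self):
        return self.states[:, 1]

    @property
    def th(self):
        return self.states[:, 2]

    @property
    def t_mass(self):
        return self.states[:, 3]

    @property
    def p_mass(self):
        return self.states[:, 4]

    def state_at(self, t: float) -> AxisState:
        """Linear interpolation of the state at time t."""
        if not (self.times[0] <= t <= self.times[-1]):
            raise DomainError(f"time {t} outside trajectory range")
        y = np.array([np.interp(t, self.times, self.states[:, j]) for j in range(5)])
        return AxisState.from_array(y)

    def terminal_state(self) -> AxisState:
        return AxisState.from_array(self.states[-1])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time_days": self.times, "trh": self.trh, "tsh": self.tsh,
             "th": self.th, "t_mass": self.t_mass, "p_mass": self.p_mass})

    def to_csv(self, path, schedule: EventSchedule | None = None) -> None:
        """Write the trajectory as CSV plus a JSON sidecar of the schedule."""
        path = Path(path)
        self.to_frame().to_csv(path, index=False, float_format="%.17g")
        sidecar = {"mass_frozen": self.mass_frozen, "meta":
                   {k: v for k, v in self.meta.items() if isinstance(v, (int, float, str, bool))}}
        if schedule is not None:
            sidecar["schedule"] = schedule.to_dict()
        path.with_suffix(".schedule.json").write_text(json.dumps(sidecar, indent=1))

    @staticmethod
    def concatenate(first: "Trajectory", second: "Trajectory") -> "Trajectory":
        if not math.isclose(first.times[-1], second.times[0]):
            raise DomainError("trajectories are not contiguous")
        return Trajectory(
            times=np.concatenate([first.times, second.times[1:]]),
            states=np.vstack([first.states, second.states[1:]]),
            params_active=first.params_active + second.params_active,
            mass_frozen=first.mass_frozen and second.mass_frozen,
            meta={"segments": [first.meta, second.meta]})


# ---------------------------------------------------------------------------
# integrator
# ---------------------------------------------------------------------------


def integrate(
    initial: AxisState,
    params: ModelParameters,
    schedule: EventSchedule | None = None,
    *,
    t0: float = 0.0,
    dt_out: float = 0.25,
    method: str = "LSODA",
    rtol: float = 1e-9,
    atol: np.ndarray | float | None = None,
    mass_frozen: bool = False,
) -> Trajectory:
    """Integrate the model under an event schedule.

    The stiff-capable solver restarts at each event time; output is on a
    uniform grid of spacing ``dt_out`` (event times included exactly).
    ``mass_frozen`` pins T and P (the constant-mass comparison model).
    """
    initial.validate()
    if schedule is None:
        schedule = EventSchedule(events=[], horizon=100.0)
    sp = params.setpoint
    if atol is None:
        atol = 1e-12 * np.array([sp.trh_set, sp.tsh_set, sp.th_set, sp.t_set, sp.p_set])
    breakpoints = [0.0] + [e[0] for e in schedule.events if 0.0 < e[0] < schedule.horizon]
    breakpoints.append(schedule.horizon)
    # deduplicate (an event exactly at 0 modifies the first segment)
    seg_edges = sorted(set(breakpoints))
    current = params
    for etime, name, value in schedule.events:
        if etime == 0.0:
            current = current.replace(**{name: value})
    event_map: dict[float, list[tuple[str, float]]] = {}
    for etime, name, value in schedule.events:
        if etime > 0.0:
            event_map.setdefault(etime, []).append((name, value))

    times_all: list[np.ndarray] = []
    states_all: list[np.ndarray] = []
    params_active: list[tuple[float, ModelParameters]] = [(seg_edges[0] + t0, current)]
    y = initial.as_array()
    floor_hits = 0
    for a, b in zip(seg_edges[:-1], seg_edges[1:]):
        for name, value in event_map.get(a, []):
            current = current.replace(**{name: value})
            params_active.append((a + t0, current))
        n = max(2, int(round((b - a) / dt_out)) + 1)
        t_eval = np.linspace(a, b, n)
        p_seg = current

        def fun(t, yv):
            nonlocal floor_hits
            if yv[2] < p_seg.th_floor:
                floor_hits += 1
            return rhs_array(yv, p_seg, mass_frozen=mass_frozen)

        sol = solve_ivp(fun, (a, b), y, method=method, t_eval=t_eval,
                        rtol=rtol, atol=atol, dense_output=False)
        if not sol.success:
            raise IntegrationError(
                f"solver failed on segment [{a}, {b}] day: {sol.message}")
        y = sol.y[:, -1]
        if times_all:
            times_all.append(sol.t[1:])
            states_all.append(sol.y.T[1:])
        else:
            times_all.append(sol.t)
            states_all.append(sol.y.T)
    if floor_hits:
        logger.warning("TH floor engaged %d times during integration", floor_hits)
    times = np.concatenate(times_all) + t0
    states = np.vstack(states_all)
    drate = np.max(np.abs(rhs_array(states[-1], current)) /
                   np.array([sp.trh_set, sp.tsh_set, sp.th_set, sp.t_set, sp.p_set]))
    return Trajectory(times, states, params_active, mass_frozen,
                      meta={"floor_hits": floor_hits,
                            "terminal_rate_scaled": float(drate),
                            "converged": bool(drate < 1e-8)})


# ---------------------------------------------------------------------------
# disease / treatment scenarios
# ---------------------------------------------------------------------------


def _hashimoto_params(base: ModelParameters | None) -> ModelParameters:
    """Methods convention: thyroid far from capacity (k_t = 0), pituitary
    capacity at the scaled value K_P = 1."""
    if base is not None:
        return base
    _, k_p = capacities_from_scaled(0.0, 1.0)
    return default_parameters(k_t=0.0, k_p=k_p)


def _graves_params(base: ModelParameters | None) -> ModelParameters:
    """Methods convention: K_T = 1, pituitary far from capacity (k_p = 0)."""
    if base is not None:
        return base
    k_t, _ = capacities_from_scaled(1.0, 0.0)
    return default_parameters(k_t=k_t, k_p=0.0)


def calibrate_levothyroxine(params: ModelParameters) -> float:
    """External-T4 source b_30 whose steady state restores the healthy free-T4
    set point under the (possibly diseased) parameters, found by root-finding
    on the steady-state map."""
    target = params.setpoint.th_set

    def g(b30):
        ss = axis_analysis.steady_state(params.replace(b_30=b30))
        return ss.state.th - target

    hi = 2.0 * params.a_th * target
    if g(0.0) >= 0:
        return 0.0
    return float(optimize.brentq(g, 0.0, hi, xtol=1e-12, rtol=1e-12))


def calibrate_bth_treatment(params: ModelParameters) -> float:
    """Antithyroid-treatment b_th whose steady state restores the healthy TSH
    set point (antibody already cleared), by root-finding on the steady-state
    map.  With the antibody at zero this lands on the basal b_th."""
    target = params.setpoint.tsh_set

    def g(log_fct):
        p = params.replace(b_th=params.b_th * math.exp(log_fct))
        return axis_analysis.steady_state(p).state.tsh - target

    lo, hi = math.log(0.05), math.log(4.0)
    if g(lo) * g(hi) > 0:
        return params.b_th
    return params.b_th * math.exp(optimize.brentq(g, lo, hi, xtol=1e-12, rtol=1e-12))


def scenario_hashimoto(
    params: ModelParameters | None = None,
    severity_multiplier: float = 5.0,
    disease_days: float = 200.0,
    treatment_days: float = 100.0,
    *,
    dt_out: float = 0.1,
) -> tuple[Trajectory, Trajectory]:
    """Autoimmune thyrocyte destruction (a_t raised ``severity_multiplier``-fold)
    followed by levothyroxine replacement calibrated to restore the original
    hormone set point.  Returns (disease, treatment) trajectories; treatment
    times continue from the disease phase."""
    if severity_multiplier < 1:
        raise DomainError("severity multiplier must be >= 1")
    params = _hashimoto_params(params)
    diseased = params.replace(a_t=params.a_t * severity_multiplier)
    disease = integrate(set_point_state(params), diseased,
                        EventSchedule([], disease_days), dt_out=dt_out)
    b30 = calibrate_levothyroxine(diseased) if severity_multiplier > 1 else 0.0
    treated = diseased.replace(b_30=b30)
    treatment = integrate(disease.terminal_state(), treated,
                          EventSchedule([], treatment_days),
                          t0=disease_days, dt_out=dt_out)
    return disease, treatment


def scenario_graves(
    params: ModelParameters | None = None,
    ab_level: float = 5.0,
    disease_days: float = 100.0,
    treatment_days: float = 500.0,
    *,
    dt_out: float = 0.1,
) -> tuple[Trajectory, Trajectory]:
    """TSH-receptor-activating antibodies at ``ab_level`` (units of the
    set-point TSH) for the disease phase; treatment clears the antibody and
    root-finds the antithyroid b_th restoring the original set point."""
    if ab_level < 0:
        raise DomainError("antibody level must be >= 0")
    params = _graves_params(params)
    diseased = params.replace(ab=ab_level * params.setpoint.tsh_set)
    disease = integrate(set_point_state(params), diseased,
                        EventSchedule([], disease_days), dt_out=dt_out)
    cleared = diseased.replace(ab=0.0)
    bth = calibrate_bth_treatment(cleared) if ab_level > 0 else params.b_th
    treated = cleared.replace(b_th=bth)
    treatment = integrate(disease.terminal_state(), treated,
                          EventSchedule([], treatment_days),
                          t0=disease_days, dt_out=dt_out)
    return disease, treatment


def scenario_iodine_step(
    params: ModelParameters | None = None,
    bth_fraction: float = 0.5,
    with_capacity: bool = False,
    horizon: float = 1000.0,
    *,
    dt_out: float = 0.25,
) -> tuple[Trajectory, Trajectory]:
    """Step reduction of the per-thyrocyte secretion rate b_th (iodine
    deficiency).  Returns (full-model, frozen-mass) trajectories; with
    ``with_capacity`` the literature gland capacities (5.5x thyroid, 5.3x
    pituitary) limit the compensation."""
    if not 0 < bth_fraction <= 1:
        raise DomainError("b_th fraction must be in (0, 1]")
    if params is None:
        if with_capacity:
            params = default_parameters(k_t=1 / 5.5, k_p=1 / 5.3)
        else:
            params = default_parameters()
    stepped = params.replace(b_th=params.b_th * bth_fraction)
    start = set_point_state(params)
    sched = EventSchedule([], horizon)
    full = integrate(start, stepped, sched, dt_out=dt_out)
    frozen = integrate(start, stepped, sched, dt_out=dt_out, mass_frozen=True)
    return full, frozen


def scenario_thyroidectomy(
    params: ModelParameters | None = None,
    residual_fraction: float = 0.0,
    horizon: float = 60.0,
    *,
    dt_out: float = 0.02,
) -> Trajectory:
    """Surgical removal of the thyroid at t = 0: the thyroid mass is set to
    ``residual_fraction`` with regrowth disabled, after which free T4 decays
    on its one-week timescale while TSH and the thyrotroph mass climb toward
    the pituitary carrying capacity."""
    if not 0 <= residual_fraction < 1:
        if residual_fraction == 1.0:
            pass  # unchanged gland, trivial control case
        else:
            raise DomainError("residual fraction must be in [0, 1]")
    if params is None:
        _, k_p = capacities_from_scaled(0.0, 1.0)
        params = default_parameters(k_t=0.0, k_p=k_p)
    start = set_point_state(params)
    start.t_mass = residual_fraction * params.setpoint.t_set
    # b_t -> 0 disables regrowth; keep the parameter positive for validation
    post = params.replace(b_t=1e-300 if residual_fraction < 1 else params.b_t)
    if residual_fraction >= 1:
        post = params
    return integrate(start, post, EventSchedule([], horizon), dt_out=dt_out)


# ---------------------------------------------------------------------------
# TRH stimulation test
# ---------------------------------------------------------------------------


@dataclass
class TrhTestRecord:
    """Basal and TRH-stimulated TSH, with the true thyrotroph mass when the
    record comes from simulation."""

    tsh_basal: float
    tsh_stimulated: float
    delta_t: float  # minutes
    t4_basal: float
    p_true: float | None = None

    def __post_init__(self) -> None:
        if self.delta_t <= 0:
            raise DomainError("delta_t must be positive")


def b_tsh_mm(params: ModelParameters) -> float:
    """Maximal TSH secretion rate per thyrotroph of the Michaelis-Menten TSH
    equation, fixed by basal consistency at the healthy set point (the scale
    convention shared with the mass estimator)."""
    sp = params.setpoint
    return (params.a_tsh * sp.tsh_set
            * (1.0 + params.k_trh / sp.trh_set)
            * (1.0 + sp.th_set / params.k_t4) / sp.p_set)


def trh_stimulation_test(
    params: ModelParameters,
    state: AxisState,
    delta_t_minutes: float = 30.0,
    trh_bolus: float = 1000.0,
) -> TrhTestRecord:
    """Simulate a TRH stimulation test at the given axis state.

    TSH secretion follows the Michaelis-Menten variant
    dTSH/dt = bTSH * P * TRH/(TRH+kTRH) * kT4/(kT4+T4) - aTSH * TSH.
    The bolus (``trh_bolus`` in units of the healthy TRH) saturates the TRH
    term; T4, TRH and P are effectively constant on the minutes timescale.
    """
    state.validate()
    if delta_t_minutes <= 0:
        raise DomainError("delta_t must be positive")
    b = b_tsh_mm(params)
    t4 = state.th
    trh_b = params.b_trh * params.u / (params.a_trh * t4)  # TRH at QSS
    supp = params.k_t4 / (params.k_t4 + t4)
    s_basal = b * state.p_mass * trh_b / (trh_b + params.k_trh) * supp
    tsh_basal = s_basal / params.a_tsh
    s_bolus = b * state.p_mass * trh_bolus / (trh_bolus + params.k_trh) * supp
    dt_days = delta_t_minutes * MINUTE

    sol = solve_ivp(lambda t, y: [s_bolus - params.a_tsh * y[0]],
                    (0.0, dt_days), [tsh_basal], rtol=1e-11, atol=1e-13)
    if not sol.success:  # pragma: no cover
        raise IntegrationError(sol.message)
    return TrhTestRecord(tsh_basal=float(tsh_basal),
                         tsh_stimulated=float(sol.y[0, -1]),
                         delta_t=delta_t_minutes, t4_basal=float(t4),
                         p_true=float(state.p_mass))


# ---------------------------------------------------------------------------
# hysteresis diagnostics
# ---------------------------------------------------------------------------


def hysteresis_loop_area(disease: Trajectory, recovery: Trajectory,
                         log_tsh: bool = True) -> float:
    """Unsigned shoelace area of the closed disease+recovery loop in the
    (TH, log10 TSH) plane.  The constant-mass model collapses onto a single
    TSH(TH) curve (zero area); the full model encloses a positive loop."""
    th = np.concatenate([disease.th, recovery.th])
    tsh = np.concatenate([disease.tsh, recovery.tsh])
    y = np.log10(np.maximum(tsh, 1e-12)) if log_tsh else tsh
    x = th
    return float(abs(0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)))


def crossing_values(traj: Trajectory, t4_level: float,
                    which: str = "first") -> dict:
    """Interpolated TSH, P and time where the trajectory's TH crosses
    ``t4_level`` (``which`` in {first, last})."""
    th = traj.th
    s = np.sign(th - t4_level)
    idx = np.where(np.diff(s) != 0)[0]
    if len(idx) == 0:
        raise NoCrossingError(f"trajectory never crosses T4 = {t4_level}")
    i = idx[0] if which == "first" else idx[-1]
    w = (t4_level - th[i]) / (th[i + 1] - th[i])
    return {
        "time": float(traj.times[i] + w * (traj.times[i + 1] - traj.times[i])),
        "tsh": float(traj.tsh[i] + w * (traj.tsh[i + 1] - traj.tsh[i])),
        "p_mass": float(traj.p_mass[i] + w * (traj.p_mass[i + 1] - traj.p_mass[i])),
    }


def relaxation_time(times: np.ndarray, values: np.ndarray) -> float:
    """1/e relaxation time of a monotone-trending signal: the first time the
    excursion from the initial value covers a (1 - 1/e) fraction of the total
    excursion to the within-horizon extremum."""
    v0 = values[0]
    extreme = values[np.argmax(np.abs(values - v0))]
    target = v0 + (1.0 - 1.0 / math.e) * (extreme - v0)
    s = np.sign(values - target)
    idx = np.where(np.diff(s) != 0)[0]
    if len(idx) == 0:
        raise NoCrossingError("signal never covers 1 - 1/e of its excursion")
    i = idx[0]
    w = (target - values[i]) / (values[i + 1] - values[i])
    return float(times[i] + w * (times[i + 1] - times[i]) - times[0])
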
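"""Synthetic longitudinal lab-test cohorts and the population-level
hysteresis binning pipeline.

The generator emulates the structure of large HMO electronic-health-record
extracts used to study thyroid-disease hysteresis: per-patient paired
same-day TSH and free-T4 tests at sparse random dates, a diagnosis date
(the first test crossing a TSH threshold), a first-medication-purchase date,
and pre-/post-treatment labeling with a 90-day lookback window.  Each
patient carries an individual hormone set point and progresses through a
ramped disease (Hashimoto: rising thyrocyte removal; Graves: rising
receptor-activating antibody) simulated with the gland-mass model, then a
treatment phase (levothyroxine titration, or antibody clearance).

The binning pipeline reproduces the population analysis: semi-equal-sized
(quantile) TSH bins with mean FT4 +/- SEM per bin and range filters, plus
ordinary least-squares log-linear TSH-FT4 slopes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .hpt_model import (
    DomainError,
    ModelParameters,
    SetPoint,
    capacities_from_scaled,
    default_parameters,
    set_point_state,
)
from .simulator import EventSchedule, Trajectory, integrate, ramp_events

logger = logging.getLogger("thyraxis")

EPOCH = pd.Timestamp("2015-01-01")


@dataclass
class CohortConfig:
    """Study-design knobs of the synthetic cohort.

    Defaults mirror the modeled disease scenarios (fivefold severity) with
    assay noise and set-point spread at values typical for TSH/FT4
    laboratory data (multiplicative lognormal, 10% TSH / 5% FT4; 10%
    inter-individual set-point CV).
    """

    n_patients: int = 200
    disease: str = "hashimoto"  # or "graves"
    severity_mean: float = 5.0  # x a_t (Hashimoto) or x tsh_set as Ab (Graves)
    severity_cv: float = 0.3
    setpoint_cv: float = 0.10
    tsh_noise_cv: float = 0.10
    ft4_noise_cv: float = 0.05
    tests_per_year: float = 8.0
    diagnosis_tsh_threshold: float | None = None  # default by disease
    ramp_days: float = 200.0
    titration_days: float = 21.0
    med_offset_days: tuple[float, float] = (-30.0, 30.0)
    horizon_days: float = 600.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients <= 0:
            raise DomainError("n_patients must be positive")
        if self.disease not in ("hashimoto", "graves"):
            raise DomainError("disease must be 'hashimoto' or 'graves'")
        for cv in (self.severity_cv, self.setpoint_cv,
                   self.tsh_noise_cv, self.ft4_noise_cv):
            if cv < 0:
                raise DomainError("coefficients of variation must be >= 0")
        if self.diagnosis_tsh_threshold is None:
            self.diagnosis_tsh_threshold = 6.0 if self.disease == "hashimoto" else 0.3


LAB_COLUMNS = ["patient_id", "date", "tsh", "ft4",
               "diagnosis_date", "first_med_date", "phase"]


def _lognormal_factor(rng: np.random.Generator, cv: float, size=None):
    """Multiplicative lognormal noise with unit mean and the given CV."""
    if cv == 0:
        return np.ones(size) if size is not None else 1.0
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return np.exp(rng.normal(-0.5 * sigma * sigma, sigma, size=size))


def _patient_params(config: CohortConfig, rng: np.random.Generator) -> ModelParameters:
    f_th = _lognormal_factor(rng, config.setpoint_cv)
    f_tsh = _lognormal_factor(rng, config.setpoint_cv)
    sp = SetPoint(th_set=15.0 * f_th, tsh_set=1.5 * f_tsh)
    if config.disease == "hashimoto":
        _, k_p = capacities_from_scaled(0.0, 1.0, sp)
        return default_parameters(sp, k_t=0.0, k_p=k_p)
    k_t, _ = capacities_from_scaled(1.0, 0.0, sp)
    return default_parameters(sp, k_t=k_t, k_p=0.0)


def _simulate_patient(config: CohortConfig, params: ModelParameters,
                      severity: float, rng: np.random.Generator):
    """Disease trajectory, test dates, diagnosis and (re-simulated)
    treatment trajectory for one patient."""
    horizon = config.horizon_days
    if config.disease == "hashimoto":
        ramp = ramp_events("a_t", 0.0, config.ramp_days,
                           params.a_t, severity * params.a_t, n_steps=10)
    else:
        ramp = ramp_events("ab", 0.0, config.ramp_days,
                           0.0, severity * params.setpoint.tsh_set, n_steps=10)
    disease = integrate(set_point_state(params), params,
                        EventSchedule(ramp, horizon), dt_out=1.0, rtol=1e-7)

    n_tests = rng.poisson(config.tests_per_year * horizon / 365.25)
    dates = np.sort(rng.uniform(0.0, horizon, size=max(n_tests, 2)))

    # evaluate true values on the untreated course, diagnose at the first
    # noisy test crossing the threshold
    tsh_noise = _lognormal_factor(rng, config.tsh_noise_cv, len(dates))
    ft4_noise = _lognormal_factor(rng, config.ft4_noise_cv, len(dates))
    tsh_true = np.interp(dates, disease.times, disease.tsh)
    ft4_true = np.interp(dates, disease.times, disease.th)
    tsh_obs = tsh_true * tsh_noise
    thr = config.diagnosis_tsh_threshold
    crossed = tsh_obs > thr if config.disease == "hashimoto" else tsh_obs < thr
    diag_idx = int(np.argmax(crossed)) if crossed.any() else None
    if diag_idx is None:
        return disease, None, dates, tsh_obs, ft4_true * ft4_noise, None, None

    diag_day = float(dates[diag_idx])
    med_day = diag_day + float(rng.uniform(*config.med_offset_days))
    med_day = min(max(med_day, 0.0), horizon - 1.0)
    start_day = min(diag_day, med_day) if med_day >= diag_day - 90.0 else diag_day
    start_day = max(start_day, 1e-6)

    # treatment phase re-simulated from the disease state at start_day,
    # on a clock relative to the treatment start
    start_state = disease.state_at(start_day)
    active = _params_at(disease, start_day)
    treat_horizon = max(horizon - start_day, config.titration_days + 1.0)
    if config.disease == "hashimoto":
        b30_full = active.a_th * params.setpoint.th_set
        titr = ramp_events("b_30", 0.0, config.titration_days,
                           0.0, b30_full, n_steps=6)
        titr = [(t, n, v) for t, n, v in titr if t <= treat_horizon]
        sched = EventSchedule(titr, treat_horizon)
        treat_params = active
    else:
        sched = EventSchedule([], treat_horizon)
        treat_params = active.replace(ab=0.0)
    treatment = integrate(start_state, treat_params, sched,
                          t0=0.0, dt_out=1.0, rtol=1e-7)
    # treatment trajectory times are relative to start_day
    post = dates >= start_day
    tsh_true[post] = np.interp(dates[post] - start_day, treatment.times, treatment.tsh)
    ft4_true[post] = np.interp(dates[post] - start_day, treatment.times, treatment.th)
    tsh_obs = tsh_true * tsh_noise
    ft4_obs = ft4_true * ft4_noise
    return disease, treatment, dates, tsh_obs, ft4_obs, diag_day, med_day


def _params_at(traj: Trajectory, day: float) -> ModelParameters:
    params = traj.params_active[0][1]
    for t, p in traj.params_active:
        if t <= day:
            params = p
    return params


def generate_cohort(config: CohortConfig) -> pd.DataFrame:
    """Simulate the cohort and return the lab-test table.

    Columns: patient_id, date (ISO), tsh (mIU/L), ft4 (pmol/L),
    diagnosis_date, first_med_date, phase (pre | post | unassigned).
    Bit-reproducible for a fixed config (single seeded generator).
    """
    rng = np.random.default_rng(config.seed)
    rows = []
    for pid in range(config.n_patients):
        params = _patient_params(config, rng)
        severity = config.severity_mean * _lognormal_factor(rng, config.severity_cv)
        severity = max(severity, 1.0)
        (_, _, dates, tsh_obs, ft4_obs,
         diag_day, med_day) = _simulate_patient(config, params, severity, rng)
        diag_date = EPOCH + pd.Timedelta(days=round(diag_day)) if diag_day is not None else pd.NaT
        med_date = EPOCH + pd.Timedelta(days=round(med_day)) if med_day is not None else pd.NaT
        for d, tsh, ft4 in zip(dates, tsh_obs, ft4_obs):
            rows.append({"patient_id": pid,
                         "date": EPOCH + pd.Timedelta(days=round(float(d))),
                         "tsh": float(tsh), "ft4": float(ft4),
                         "diagnosis_date": diag_date,
                         "first_med_date": med_date,
                         "phase": "unassigned"})
    table = pd.DataFrame(rows, columns=LAB_COLUMNS)
    return split_pre_post(table)


def split_pre_post(table: pd.DataFrame, window_days: float = 90.0) -> pd.DataFrame:
    """Assign each test to the pre- or post-treatment phase.

    Treatment onset is the earliest of the diagnosis date and the first
    medication purchase, the latter counting only if it falls within
    ``window_days`` before diagnosis (or after it).  A patient with no
    treatment events was never treated, so all their tests are ``pre``;
    rows whose own test date is missing are flagged ``unassigned``.
    Idempotent.
    """
    out = table.copy()
    diag = pd.to_datetime(out["diagnosis_date"])
    med = pd.to_datetime(out["first_med_date"])
    onset = diag.copy()
    med_counts = med.notna() & diag.notna() & (
        med >= diag - pd.to_timedelta(window_days, unit="D"))
    onset[med_counts] = np.minimum(diag[med_counts], med[med_counts])
    onset[diag.isna() & med.notna()] = med[diag.isna() & med.notna()]
    dates = pd.to_datetime(out["date"])
    phase = np.where(dates.isna(), "unassigned",
                     np.where(onset.isna() | (dates < onset), "pre", "post"))
    out["phase"] = phase
    return out


@dataclass
class BinnedCurve:
    """Per-TSH-bin FT4 summary of one phase of the cohort."""

    bins: pd.DataFrame  # columns: tsh_lo, tsh_hi, tsh_mid, n, ft4, ft4_sem
    phase: str
    statistic: str
    filters: dict = field(default_factory=dict)

    def to_csv(self, path) -> None:
        self.bins.to_csv(path, index=False, float_format="%.17g")


def bin_mean_ft4_by_tsh(
    table: pd.DataFrame,
    phase: str | None = None,
    tsh_filter: tuple[float | None, float | None] | None = None,
    n_bins: int = 10,
    statistic: str = "mean",
) -> BinnedCurve:
    """Semi-equal-sized (quantile) TSH bins with the mean (or median) FT4 and
    its standard error per bin.

    The population curves use TSH > 0.5 for the Hashimoto (normal/hypo)
    range and TSH < 5 for the Graves (normal/hyper) range; pass these as
    ``tsh_filter = (0.5, None)`` / ``(None, 5.0)``.  Tied discrete TSH
    values collapse bins (reduced bin count with a warning).
    """
    df = table
    if phase is not None:
        df = df[df["phase"] == phase]
    lo, hi = tsh_filter if tsh_filter is not None else (None, None)
    if lo is not None:
        df = df[df["tsh"] > lo]
    if hi is not None:
        df = df[df["tsh"] < hi]
    if df.empty:
        raise DomainError("no tests left after filtering")
    if statistic not in ("mean", "median"):
        raise DomainError("statistic must be 'mean' or 'median'")
    try:
        cats, edges = pd.qcut(df["tsh"], q=n_bins, retbins=True, duplicates="drop")
    except ValueError as err:
        raise DomainError(f"cannot form bins: {err}") from None
    if len(edges) - 1 < n_bins:
        logger.warning("tied TSH values reduced the bin count to %d", len(edges) - 1)
    grp = df.groupby(cats, observed=True)
    agg = grp["ft4"].agg(["count", "mean", "median", "std"])
    stat = agg["mean"] if statistic == "mean" else agg["median"]
    bins = pd.DataFrame({
        "tsh_lo": [iv.left for iv in agg.index],
        "tsh_hi": [iv.right for iv in agg.index],
        "tsh_mid": grp["tsh"].mean().to_numpy(),
        "n": agg["count"].to_numpy(),
        "ft4": stat.to_numpy(),
        "ft4_sem": (agg["std"] / np.sqrt(agg["count"])).to_numpy(),
    }).reset_index(drop=True)
    return BinnedCurve(bins=bins, phase=phase or "all", statistic=statistic,
                       filters={"tsh_gt": lo, "tsh_lt": hi, "n_bins": n_bins})


def loglinear_slope(
    table: pd.DataFrame,
    tsh_range: tuple[float | None, float | None] | None = None,
    log_base: float = 10.0,
) -> tuple[float, float]:
    """Ordinary least-squares slope of log(TSH) against FT4 (per pmol/L),
    with its standard error.  log10 by convention of the clinical
    literature's "log-linear TSH/T4 relation"; configurable."""
    df = table
    lo, hi = tsh_range if tsh_range is not None else (None, None)
    if lo is not None:
        df = df[df["tsh"] > lo]
    if hi is not None:
        df = df[df["tsh"] < hi]
    if len(df) < 3:
        raise DomainError("need at least 3 tests in range for a slope")
    if float(np.ptp(df["ft4"].to_numpy())) <= 0:
        raise DomainError("degenerate FT4 spread")
    y = np.log(df["tsh"].to_numpy()) / math.log(log_base)
    X = sm.add_constant(df["ft4"].to_numpy())
    fit = sm.OLS(y, X).fit()
    return float(fit.params[1]), float(fit.bse[1])
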
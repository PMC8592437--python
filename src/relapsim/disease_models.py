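"""Mechanistic ODE models of AML and CML remission kinetics.

AML: four ODEs for healthy (H) and leukemic (L) stem cells, each switching
between a quiescent state Q (shared niche capacity ``K_Q``) and an active
state A (shared capacity ``K_A``).  Active cells proliferate (``p_i``),
differentiate out of the stem-cell pool (``d_i``) and are killed by cyclic
chemotherapy with rate ``c`` while a cycle is running.  Quiescent cells are
chemo-protected; the healthy population persists mainly through its quiescent
reservoir, which is what lets the leukemic fraction fall by several orders of
magnitude during induction/consolidation cycles.

CML: three ODEs for quiescent (X) and active (Y) leukemic stem cells and an
immune effector population (Z).  Y grows logistically (``p_Y``, ``K_Y``), is
killed by TKI with rate ``e_TKI`` times the current relative dose, and by
immune cells at rate ``m*Y*Z``.  Immune cells are produced at ``r_Z``, decay
at ``a`` and are recruited through an immune window ``p_Z*Z*Y/(K_Z + Y^2)``
that peaks at intermediate leukemia levels ``Y = sqrt(K_Z)``.

The observable in both cases is the leukemic burden in percent, analysed on a
log10 scale as in clinical NPM1-mut/ABL and BCR-ABL1/ABL1 monitoring.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from . import _integrate

__all__ = [
    "MONTH_DAYS", "BURDEN_FLOOR_PCT", "AML_RELAPSE_THRESHOLD_PCT",
    "CML_RECURRENCE_THRESHOLD_PCT", "AML_HORIZON_MONTHS", "CML_POST_STOP_MONTHS",
    "AMLParameters", "CMLParameters", "TreatmentSchedule", "Trajectory",
    "SimulationError", "NoRemissionError",
    "aml_rhs", "cml_rhs", "simulate", "burden", "label_relapse",
]

MONTH_DAYS = 30.44
BURDEN_FLOOR_PCT = 1e-6
AML_RELAPSE_THRESHOLD_PCT = 1.0
CML_RECURRENCE_THRESHOLD_PCT = 0.1
AML_HORIZON_MONTHS = 24.0
CML_POST_STOP_MONTHS = 120.0
# minimum contiguous time above threshold that counts as CML molecular recurrence
CML_RECURRENCE_SPAN_MONTHS = 1.0

# Diagnosis-state convention (fractions of the carrying capacities).  The AML
# parameter set carries no initial conditions, so every simulated patient
# starts from the same newly diagnosed configuration: the quiescent niche is
# split between healthy and leukemic cells while the active niche is almost
# fully occupied by the leukemic clone.
AML_IC_FRACTIONS = (0.5, 0.05, 0.5, 0.90)  # (Q_H/K_Q, A_H/K_A, Q_L/K_Q, A_L/K_A)


class SimulationError(RuntimeError):
    """Numerical integration failed (blow-up or step underflow)."""


class NoRemissionError(ValueError):
    """AML trajectory never fell below the remission threshold."""


@dataclass(frozen=True)
class AMLParameters:
    """11 named rates/capacities; two are patient-specific by default."""

    t_QA_H: float  # healthy activation, 1/day
    t_AQ_H: float  # healthy deactivation, 1/day
    p_H: float     # healthy proliferation, 1/day
    d_H: float     # healthy differentiation, 1/day
    t_QA_L: float  # leukemic activation, 1/day (free by default)
    t_AQ_L: float  # leukemic deactivation, 1/day
    p_L: float     # leukemic proliferation, 1/day (free by default)
    d_L: float     # leukemic differentiation, 1/day
    K_Q: float     # quiescent niche capacity, cells
    K_A: float     # active niche capacity, cells
    c: float       # chemotherapy kill rate, 1/day
    free_names: tuple[str, ...] = ("p_L", "t_QA_L")

    RATE_NAMES = ("t_QA_H", "t_AQ_H", "p_H", "d_H", "t_QA_L", "t_AQ_L",
                  "p_L", "d_L", "K_Q", "K_A", "c")

    def __post_init__(self):
        for name in self.RATE_NAMES:
            if getattr(self, name) < 0:
                raise ValueError(f"AML parameter {name} must be >= 0")
        if self.K_Q <= 0 or self.K_A <= 0:
            raise ValueError("carrying capacities must be > 0")
        unknown = set(self.free_names) - set(self.RATE_NAMES)
        if unknown:
            raise ValueError(f"unknown free parameter(s): {sorted(unknown)}")

    def as_vector(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in self.RATE_NAMES])

    def with_values(self, **kwargs) -> "AMLParameters":
        return replace(self, **kwargs)

    def initial_state(self) -> np.ndarray:
        fQH, fAH, fQL, fAL = AML_IC_FRACTIONS
        return np.array([fQH * self.K_Q, fAH * self.K_A,
                         fQL * self.K_Q, fAL * self.K_A])


@dataclass(frozen=True)
class CMLParameters:
    """10 rates/constants plus 3 initial counts; seven patient-specific by default."""

    p_XY: float   # quiescent -> active transition, 1/month (free)
    p_YX: float   # active -> quiescent transition, 1/month (free)
    p_Y: float    # max proliferation of active cells, 1/month
    K_Y: float    # carrying capacity of active cells, cells
    e_TKI: float  # TKI kill rate at full dose, 1/month (free)
    m: float      # immune kill coefficient, 1/(cell*month) (free)
    p_Z: float    # immune recruitment coefficient, cells/month (free)
    K_Z: float    # immune-window saturation constant, cells^2 (free)
    r_Z: float    # immune production, cells/month
    a: float      # immune decay, 1/month
    X0: float     # initial quiescent leukemic cells
    Y0: float     # initial active leukemic cells
    Z0: float     # initial immune cells (free)
    free_names: tuple[str, ...] = ("p_XY", "p_YX", "e_TKI", "m", "p_Z", "K_Z", "Z0")

    RATE_NAMES = ("p_XY", "p_YX", "p_Y", "K_Y", "e_TKI", "m", "p_Z", "K_Z", "r_Z", "a")
    IC_NAMES = ("X0", "Y0", "Z0")

    def __post_init__(self):
        for name in self.RATE_NAMES + self.IC_NAMES:
            if getattr(self, name) < 0:
                raise ValueError(f"CML parameter {name} must be >= 0")
        if self.K_Y <= 0 or self.K_Z <= 0:
            raise ValueError("K_Y and K_Z must be > 0")
        unknown = set(self.free_names) - set(self.RATE_NAMES + self.IC_NAMES)
        if unknown:
            raise ValueError(f"unknown free parameter(s): {sorted(unknown)}")

    def as_vector(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in self.RATE_NAMES])

    def with_values(self, **kwargs) -> "CMLParameters":
        return replace(self, **kwargs)

    def initial_state(self) -> np.ndarray:
        return np.array([self.X0, self.Y0, self.Z0])


@dataclass(frozen=True)
class TreatmentSchedule:
    """Chemotherapy cycles (AML, days) or TKI dose breakpoints (CML, months).

    AML: ``cycles`` is a time-ordered tuple of non-overlapping ``(start, end)``
    day intervals with the kill rate active on ``[start, end)``.

    CML: full dose from 0 until ``half_dose_start`` (if set), half dose until
    ``t_stop``, zero dose afterwards.
    """

    disease: str  # "AML" | "CML"
    cycles: tuple[tuple[float, float], ...] = ()
    t_stop: float | None = None           # months
    half_dose_start: float | None = None  # months; must end exactly at t_stop

    def __post_init__(self):
        if self.disease not in ("AML", "CML"):
            raise ValueError("disease must be 'AML' or 'CML'")
        if self.disease == "AML":
            prev_end = -math.inf
            for s, e in self.cycles:
                if e <= s or s < prev_end:
                    raise ValueError("cycles must be time-ordered and non-overlapping")
                prev_end = e
        else:
            if self.t_stop is None or self.t_stop <= 0:
                raise ValueError("CML schedule requires t_stop > 0")
            if self.half_dose_start is not None and not (
                    0 < self.half_dose_start < self.t_stop):
                raise ValueError("half-dose interval must end at t_stop")

    @property
    def treatment_end_day(self) -> float:
        """Last chemotherapy day (AML only)."""
        if self.disease != "AML" or not self.cycles:
            raise ValueError("treatment_end_day is defined for AML schedules")
        return self.cycles[-1][1]

    def dose(self, t: float) -> float:
        """Relative dose at time t (days for AML, months for CML)."""
        if self.disease == "AML":
            for s, e in self.cycles:
                if s <= t < e:
                    return 1.0
            return 0.0
        if t >= self.t_stop:
            return 0.0
        if self.half_dose_start is not None and t >= self.half_dose_start:
            return 0.5
        return 1.0

    def segments(self, t_end: float) -> tuple[np.ndarray, np.ndarray]:
        """Breakpoints and per-segment dose covering [0, t_end]."""
        pts = [0.0]
        if self.disease == "AML":
            for s, e in self.cycles:
                if s < t_end:
                    pts.extend([s, min(e, t_end)])
        else:
            if self.half_dose_start is not None and self.half_dose_start < t_end:
                pts.append(self.half_dose_start)
            if self.t_stop < t_end:
                pts.append(self.t_stop)
        pts.append(t_end)
        pts = np.unique(np.array(pts, dtype=float))
        mid = 0.5 * (pts[:-1] + pts[1:])
        dose = np.array([self.dose(t) for t in mid])
        return pts, dose


@dataclass
class Trajectory:
    """Time-stamped leukemic-burden series for one patient and one variant."""

    patient_id: str
    disease: str
    variant: str  # D | DN | SN | AP | AS
    times: np.ndarray     # months, strictly increasing
    values: np.ndarray    # percent, > 0
    censored: np.ndarray  # True where value was below LOD and set to LOD

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.censored = np.asarray(self.censored, dtype=bool)
        if not (len(self.times) == len(self.values) == len(self.censored)):
            raise ValueError("times, values and censored must have equal length")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.values <= 0):
            raise ValueError("burden values must be > 0")

    def __len__(self):
        return len(self.times)

    def log10_values(self) -> np.ndarray:
        return np.log10(np.maximum(self.values, BURDEN_FLOOR_PCT))


def aml_rhs(state, t, params: AMLParameters, schedule: TreatmentSchedule) -> np.ndarray:
    """Derivative of (Q_H, A_H, Q_L, A_L) at time ``t`` (days)."""
    state = np.asarray(state, dtype=float)
    if not np.all(np.isfinite(state)):
        raise SimulationError("non-finite AML state (simulation blow-up)")
    out = np.empty(4)
    _integrate._rhs.py_func(0, state, params.as_vector(), schedule.dose(t), out)
    return out


def cml_rhs(state, t, params: CMLParameters, schedule: TreatmentSchedule) -> np.ndarray:
    """Derivative of (X, Y, Z) at time ``t`` (months)."""
    state = np.asarray(state, dtype=float)
    if not np.all(np.isfinite(state)):
        raise SimulationError("non-finite CML state (simulation blow-up)")
    out = np.empty(3)
    _integrate._rhs.py_func(1, state, params.as_vector(), schedule.dose(t), out)
    return out


def burden(state, disease: str, params) -> float:
    """Leukemic burden in percent, floored at ``BURDEN_FLOOR_PCT``."""
    state = np.asarray(state, dtype=float)
    if disease == "AML":
        total = state.sum()
        if total <= 0:
            raise ValueError("all-zero AML state has no defined burden")
        b = 100.0 * (state[2] + state[3]) / total
    else:
        b = 100.0 * state[1] / params.K_Y
    return max(b, BURDEN_FLOOR_PCT)


def _burden_series(states: np.ndarray, disease: str, params) -> np.ndarray:
    if disease == "AML":
        totals = states.sum(axis=1)
        if np.any(totals <= 0):
            raise ValueError("all-zero AML state has no defined burden")
        b = 100.0 * (states[:, 2] + states[:, 3]) / totals
    else:
        b = 100.0 * states[:, 1] / params.K_Y
    return np.maximum(b, BURDEN_FLOOR_PCT)


def simulate(params, schedule: TreatmentSchedule, grid,
             patient_id: str = "", rtol: float = 1e-6,
             method: str = "rk45") -> Trajectory:
    """Forward-simulate and evaluate the burden observable on ``grid`` (months).

    ``method='rk45'`` uses the jitted adaptive Dormand-Prince driver;
    ``method='lsoda'`` uses scipy's stiff-capable LSODA as a reference path.
    """
    grid = np.asarray(grid, dtype=float)
    if len(grid) == 0 or (len(grid) > 1 and not np.all(np.diff(grid) > 0)):
        raise ValueError("grid must be non-empty and strictly increasing")
    disease = schedule.disease
    if disease == "AML":
        horizon = AML_HORIZON_MONTHS
    else:
        horizon = schedule.t_stop + CML_POST_STOP_MONTHS
    if grid[-1] > horizon + 1e-9 or grid[0] < 0:
        raise ValueError(
            f"grid must lie within [0, {horizon}] months for {disease}")

    if disease == "AML":
        model, y0 = 0, params.initial_state()
        t_eval = grid * MONTH_DAYS
        atol = 1e-3
    else:
        model, y0 = 1, params.initial_state()
        t_eval = grid.copy()
        atol = 1e-3
    seg_t, seg_dose = schedule.segments(float(t_eval[-1]))

    if method == "rk45":
        states, status = _integrate.integrate(
            model, y0, params.as_vector(), seg_t, seg_dose, t_eval, rtol, atol)
        if status != _integrate.OK:
            raise SimulationError(
                f"integration failed (status {status}) for {disease} "
                f"params {params}")
    elif method == "lsoda":
        states = _simulate_lsoda(model, y0, params, seg_t, seg_dose, t_eval,
                                 rtol, atol)
    else:
        raise ValueError(f"unknown method {method!r}")

    values = _burden_series(states, disease, params)
    return Trajectory(patient_id=patient_id, disease=disease, variant="D",
                      times=grid, values=values,
                      censored=np.zeros(len(grid), dtype=bool))


def _simulate_lsoda(model, y0, params, seg_t, seg_dose, t_eval, rtol, atol):
    from scipy.integrate import solve_ivp

    pvec = params.as_vector()
    out = np.empty((len(t_eval), len(y0)))
    y = np.asarray(y0, dtype=float)
    iev = 0
    for i in range(len(seg_t) - 1):
        t0, t1, dose = seg_t[i], seg_t[i + 1], seg_dose[i]
        if t1 <= t0:
            continue
        while iev < len(t_eval) and t_eval[iev] <= t0 + 1e-9:
            out[iev] = y
            iev += 1
        sub = [t for t in t_eval[iev:] if t < t1 - 1e-9]

        def f(t, yy):
            d = np.empty(len(yy))
            _integrate._rhs.py_func(model, yy, pvec, dose, d)
            return d

        # evaluate interior output points and always integrate through to the
        # segment end so the hand-off state is exact
        sol = solve_ivp(f, (t0, t1), y, method="LSODA", t_eval=sub + [t1],
                        rtol=rtol, atol=atol)
        if not sol.success:
            raise SimulationError(f"LSODA failed: {sol.message}")
        for j in range(len(sub)):
            out[iev] = sol.y[:, j]
            iev += 1
        y = sol.y[:, -1]
    while iev < len(t_eval):
        out[iev] = y
        iev += 1
    return out


def label_relapse(dense: Trajectory, disease: str,
                  schedule: TreatmentSchedule) -> bool:
    """Ground-truth relapse/recurrence label from the dense noise-free course.

    AML: relapse iff the burden, after first dropping below 1%, exceeds 1% at
    any grid point within 24 months of treatment start.  CML: molecular
    recurrence iff the burden stays above 0.1% for a contiguous span of at
    least one month within ten years after cessation.
    """
    t, v = dense.times, dense.values
    if disease == "AML":
        below = np.nonzero(v < AML_RELAPSE_THRESHOLD_PCT)[0]
        if len(below) == 0:
            raise NoRemissionError(
                "AML trajectory never fell below 1%; exclude patient upstream")
        first = below[0]
        in_horizon = t <= AML_HORIZON_MONTHS + 1e-9
        return bool(np.any(v[first + 1:][in_horizon[first + 1:]]
                           > AML_RELAPSE_THRESHOLD_PCT))
    t_stop = schedule.t_stop
    sel = (t > t_stop + 1e-9) & (t <= t_stop + CML_POST_STOP_MONTHS + 1e-9)
    tt, vv = t[sel], v[sel]
    above = vv > CML_RECURRENCE_THRESHOLD_PCT
    run_start = None
    for i in range(len(tt)):
        if above[i]:
            if run_start is None:
                run_start = tt[i]
            if tt[i] - run_start >= CML_RECURRENCE_SPAN_MONTHS - 1e-9:
                return True
        else:
            run_start = None
    return False
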
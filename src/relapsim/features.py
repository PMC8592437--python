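"""Hand-crafted kinetic features of remission time courses for the GLM.

AML (five features, S-shaped sawtooth of cyclic chemotherapy): the overall
elimination slope ``alpha`` during treatment, the lowest measured burden
after treatment ``n``, and from a segmented regression with breakpoints at
the chemotherapy cycle boundaries the burden at diagnosis ``y0``, the common
decreasing in-cycle slope ``a`` and the common increasing between-cycle
slope ``b``.

CML (seven features): the bi-phasic TKI response is approximated by a
continuous two-segment straight line on the log10 axis (intercepts/slopes
``A``/``alpha`` and ``B``/``beta``, the breakpoint chosen by exhaustive
search over interior measurement times), the root-mean-square deviation of
that fit ``sigma``, the cessation time and the last measured value before
cessation (or before dose reduction).  For the AS dose-reduction scheme the
half-dose year adds the response slope ``gamma``, its intercept ``C``, the
deviation ``sigma_half`` and the last measured value before cessation.

All fits work on log10 burden with censored values entered at the detection
limit; slopes are per month.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .disease_models import Trajectory, TreatmentSchedule, MONTH_DAYS

logger = logging.getLogger(__name__)

__all__ = ["AMLFeatures", "CMLFeatures", "aml_features", "cml_features",
           "feature_matrix", "AML_FEATURE_NAMES", "CML_FEATURE_NAMES",
           "CML_AS_FEATURE_NAMES", "FeaturizationError"]

AML_FEATURE_NAMES = ("alpha", "n", "y0", "a", "b")
CML_FEATURE_NAMES = ("A", "alpha", "B", "beta", "sigma", "t_stop", "last_value")
CML_AS_FEATURE_NAMES = CML_FEATURE_NAMES + ("gamma", "C", "sigma_half",
                                            "last_pre_stop")


class FeaturizationError(ValueError):
    pass


@dataclass(frozen=True)
class AMLFeatures:
    alpha: float  # elimination slope over the treatment phase, log10 %/month
    n: float      # lowest measured log10 burden after treatment
    y0: float     # fitted log10 burden at diagnosis (t = 0)
    a: float      # in-cycle slope, log10 %/month
    b: float      # between-cycle slope, log10 %/month

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, f) for f in AML_FEATURE_NAMES])


@dataclass(frozen=True)
class CMLFeatures:
    A: float
    alpha: float
    B: float
    beta: float
    sigma: float
    t_stop: float
    last_value: float
    gamma: float | None = None
    C: float | None = None
    sigma_half: float | None = None
    last_pre_stop: float | None = None

    def as_array(self, with_as: bool = False) -> np.ndarray:
        names = CML_AS_FEATURE_NAMES if with_as else CML_FEATURE_NAMES
        return np.array([getattr(self, f) for f in names], dtype=float)


def _cycle_time_split(times_months: np.ndarray,
                      schedule: TreatmentSchedule) -> tuple[np.ndarray, np.ndarray]:
    """Cumulative in-cycle and off-cycle months elapsed at each time point."""
    cyc = [(s / MONTH_DAYS, e / MONTH_DAYS) for s, e in schedule.cycles]
    g = np.zeros_like(times_months)
    for i, t in enumerate(times_months):
        acc = 0.0
        for s, e in cyc:
            acc += max(0.0, min(t, e) - s) if t > s else 0.0
        g[i] = acc
    h = times_months - g
    return g, h


def aml_features(inp: Trajectory, schedule: TreatmentSchedule) -> AMLFeatures:
    if len(inp) < 3:
        raise FeaturizationError("insufficient data for segmented regression "
                                 f"({len(inp)} points)")
    t = inp.times
    y = inp.log10_values()
    # segmented regression: y = y0 + a * (in-cycle time) + b * (off-cycle time)
    g, h = _cycle_time_split(t, schedule)
    X = np.column_stack([np.ones_like(t), g, h])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    y0, a, b = coef
    # elimination slope: plain OLS over the treatment phase (dashed line)
    t_end = schedule.treatment_end_day / MONTH_DAYS
    sel = t <= t_end + 1e-9
    if sel.sum() < 2:
        sel = np.ones_like(sel)
    alpha = np.polyfit(t[sel], y[sel], 1)[0]
    post = t > t_end + 1e-9
    n = float(y[post].min()) if post.any() else float(y.min())
    return AMLFeatures(alpha=float(alpha), n=n, y0=float(y0), a=float(a),
                       b=float(b))


def _two_segment_fit(t: np.ndarray, y: np.ndarray):
    """Continuous two-segment least-squares line; exhaustive breakpoint search.

    Returns (A, alpha, beta, tau, rmse); the breakpoint tau is chosen among
    interior measurement times minimizing the SSE, with at least two points
    on each side.
    """
    best = None
    for i in range(1, len(t) - 2):
        tau = t[i]
        X = np.column_stack([np.ones_like(t), t, np.maximum(0.0, t - tau)])
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ coef
        sse = float(resid @ resid)
        if best is None or sse < best[0] - 1e-15:
            best = (sse, coef, tau)
    sse, coef, tau = best
    A, alpha, dbeta = coef
    return float(A), float(alpha), float(alpha + dbeta), float(tau), \
        float(np.sqrt(sse / len(t)))


def cml_features(inp: Trajectory, schedule: TreatmentSchedule,
                 variant: str = "AP") -> CMLFeatures:
    t_stop = float(schedule.t_stop)
    t = inp.times
    y = inp.log10_values()
    if np.all(inp.censored):
        raise FeaturizationError("all points censored")
    is_as = variant == "AS"
    fit_end = t_stop - 12.0 if is_as else t_stop
    # AS: the bi-linear fit covers only the full-dose phase
    sel = t < fit_end - 1e-9 if is_as else t <= fit_end + 1e-9
    if sel.sum() < 4:
        raise FeaturizationError(
            f"need >= 4 points before {'half dose' if is_as else 'cessation'}, "
            f"got {int(sel.sum())}")
    A, alpha, beta, tau, sigma = _two_segment_fit(t[sel], y[sel])
    B = A + (alpha - beta) * tau  # intercept of the second-segment line
    last_value = float(y[sel][-1])
    kw = {}
    if is_as:
        half = (t >= fit_end - 1e-9) & (t <= t_stop + 1e-9)
        if half.sum() < 2:
            raise FeaturizationError("need >= 2 half-dose points for AS features")
        th, yh = t[half] - fit_end, y[half]
        gamma, C = np.polyfit(th, yh, 1)
        resid = yh - (gamma * th + C)
        kw = dict(gamma=float(gamma), C=float(C),
                  sigma_half=float(np.sqrt(np.mean(resid ** 2))),
                  last_pre_stop=float(y[t <= t_stop + 1e-9][-1]))
    return CMLFeatures(A=A, alpha=alpha, B=B, beta=beta, sigma=sigma,
                       t_stop=t_stop, last_value=last_value, **kw)


def feature_matrix(inputs: list[Trajectory],
                   schedules: list[TreatmentSchedule],
                   labels, disease: str, variant: str = "AP",
                   max_failure_frac: float = 0.05):
    """Featurize a cohort; returns (X DataFrame, y, kept indices).

    Patients whose series cannot be featurized are dropped with a logged
    warning; more than ``max_failure_frac`` failures raises, as that signals
    a mis-configured generator rather than occasional short series.
    """
    labels = np.asarray(labels)
    rows, kept = [], []
    for i, (inp, sch) in enumerate(zip(inputs, schedules)):
        try:
            if disease == "AML":
                rows.append(aml_features(inp, sch).as_array())
            else:
                rows.append(cml_features(inp, sch, variant)
                            .as_array(with_as=(variant == "AS")))
            kept.append(i)
        except FeaturizationError as exc:
            logger.warning("dropping %s: %s", inp.patient_id, exc)
    n_failed = len(inputs) - len(kept)
    if n_failed > max_failure_frac * len(inputs):
        raise FeaturizationError(
            f"{n_failed}/{len(inputs)} patients failed featurization")
    if disease == "AML":
        cols = AML_FEATURE_NAMES
    else:
        cols = CML_AS_FEATURE_NAMES if variant == "AS" else CML_FEATURE_NAMES
    X = pd.DataFrame(np.array(rows), columns=list(cols),
                     index=[inputs[i].patient_id for i in kept])
    return X, labels[kept], np.array(kept)
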
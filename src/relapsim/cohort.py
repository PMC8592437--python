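"""Virtual patient cohorts: parameter sampling, treatment schedules, simulation.

This module is the synthetic stand-in for fitting the mechanistic models to a
clinical cohort: patient-specific parameters are resampled from the reference
tables in :mod:`relapsim.priors` (AML: row resampling with multiplicative
log-normal jitter; CML: a Gaussian copula that preserves the tables' marginal
distributions and mutual rank correlations), chemotherapy schedules and TKI
cessation times are drawn from generative models of the clinical protocols,
and every patient is forward-simulated on a dense grid (weekly for AML,
monthly for CML) to obtain the ground-truth course and relapse label.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import brentq, fsolve

from . import priors
from .disease_models import (
    AMLParameters, CMLParameters, TreatmentSchedule, Trajectory,
    MONTH_DAYS, AML_HORIZON_MONTHS, CML_POST_STOP_MONTHS,
    simulate, label_relapse, NoRemissionError,
)

__all__ = [
    "ParameterPrior", "PatientRecord", "CohortConfig", "CessationSampler",
    "default_prior", "sample_parameters", "sample_schedule", "generate_cohort",
    "aml_dense_grid", "cml_dense_grid", "cohort_to_trajectory_frame",
    "save_cohort", "load_cohort",
]

AML_INPUT_WINDOW_MONTHS = 9.0


@dataclass
class ParameterPrior:
    """Base free-parameter table plus resampling settings for one disease."""

    disease: str
    free_names: tuple[str, ...]
    base_table: np.ndarray           # (n_rows, n_free)
    jitter_sd: float = 0.05          # SD of log-normal multiplicative jitter (AML)
    rank_corr: np.ndarray | None = None  # target Spearman matrix (CML)

    def __post_init__(self):
        self.base_table = np.asarray(self.base_table, dtype=float)
        if self.base_table.ndim != 2 or self.base_table.shape[0] == 0:
            raise ValueError("base table must be a non-empty 2-D array")
        if self.jitter_sd < 0:
            raise ValueError("jitter SD must be >= 0")
        if self.disease == "CML" and self.rank_corr is None:
            self.rank_corr = pd.DataFrame(self.base_table).corr("spearman").to_numpy()
        if self.rank_corr is not None:
            R = self.rank_corr
            if not np.allclose(R, R.T) or not np.allclose(np.diag(R), 1.0):
                raise ValueError("rank correlation matrix must be symmetric "
                                 "with unit diagonal")
            if np.min(np.linalg.eigvalsh(R)) < -1e-8:
                raise ValueError("rank correlation matrix must be PSD")


def default_prior(disease: str) -> ParameterPrior:
    if disease == "AML":
        return ParameterPrior("AML", priors.AML_FREE, priors.AML_BASE.copy())
    return ParameterPrior("CML", priors.CML_FREE, priors.CML_BASE.copy())


@dataclass
class PatientRecord:
    id: str
    disease: str
    parameters: AMLParameters | CMLParameters
    schedule: TreatmentSchedule
    dense: Trajectory | None
    relapse: bool | None
    excluded: bool = False

    def __post_init__(self):
        if (self.relapse is None) != self.excluded:
            raise ValueError("label must be present exactly when not excluded")


@dataclass
class CohortConfig:
    disease: str
    n_patients: int
    seed: int
    jitter_sd: float = 0.05
    cessation_mean: float = 92.0     # months
    cessation_sd: float = 28.2       # months
    cessation_min: float = 24.0      # months
    max_attempt_factor: int = 10

    def __post_init__(self):
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if self.disease not in ("AML", "CML"):
            raise ValueError("disease must be 'AML' or 'CML'")


class CessationSampler:
    """Truncated-normal sampler of TKI cessation times.

    The pre-truncation location/scale are calibrated so the *realized*
    (post-truncation) mean and SD match the targets; truncating at 24 months
    otherwise shrinks the SD slightly below its nominal value.
    """

    def __init__(self, mean: float = 92.0, sd: float = 28.2,
                 lower: float = 24.0):
        self.mean, self.sd, self.lower = mean, sd, lower

        def moments(x):
            mu0, sig0 = x
            a = (self.lower - mu0) / sig0
            m, v = stats.truncnorm.stats(a, np.inf, loc=mu0, scale=sig0,
                                         moments="mv")
            return [m - self.mean, np.sqrt(v) - self.sd]

        sol = fsolve(moments, x0=[mean, sd], full_output=False)
        self.mu0, self.sigma0 = float(sol[0]), float(sol[1])
        self._a = (lower - self.mu0) / self.sigma0

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return stats.truncnorm.rvs(self._a, np.inf, loc=self.mu0,
                                   scale=self.sigma0, size=n, random_state=rng)


def sample_parameters(prior: ParameterPrior, n: int, seed: int):
    """Draw ``n`` patient-specific parameter sets from the prior.

    AML: rows are drawn with replacement and each free parameter is
    multiplied by ``exp(N(0, jitter_sd^2))`` so no two draws coincide.
    CML: free parameters are drawn from a Gaussian copula whose marginals
    are the (interpolated) empirical distributions of the base-table columns
    and whose rank correlations match the prior's Spearman matrix.
    """
    rng = np.random.default_rng(seed)
    if prior.disease == "AML":
        rows = rng.integers(0, prior.base_table.shape[0], size=n)
        jit = np.exp(rng.normal(0.0, prior.jitter_sd,
                                size=(n, prior.base_table.shape[1])))
        vals = prior.base_table[rows] * jit
        return [priors.default_aml_parameters(*v) for v in vals]

    # Gaussian copula: Spearman -> Pearson on the latent normal scale
    R = 2.0 * np.sin(np.pi * prior.rank_corr / 6.0)
    w, V = np.linalg.eigh(R)
    R = (V * np.maximum(w, 1e-10)) @ V.T  # clip to PSD
    d = np.sqrt(np.diag(R))
    R = R / np.outer(d, d)
    L = np.linalg.cholesky(R)
    z = rng.standard_normal((n, R.shape[0])) @ L.T
    u = stats.norm.cdf(z)
    out = np.empty_like(u)
    for j in range(u.shape[1]):
        out[:, j] = np.quantile(prior.base_table[:, j], u[:, j],
                                method="linear")
    return [priors.default_cml_parameters(**dict(zip(prior.free_names, v)))
            for v in out]


def sample_schedule(disease: str, seed=None, rng: np.random.Generator = None,
                    cessation: CessationSampler | None = None) -> TreatmentSchedule:
    """Draw a treatment schedule.

    AML: 3-5 one-week chemotherapy cycles, starts spaced 33-38 days apart,
    the first cycle starting at day 0 (treatment ends before month 6).
    CML: continuous full-dose TKI until a cessation time drawn from the
    truncated-normal sampler; the half-dose pre-cessation year is added only
    by the AS transform.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if disease == "AML":
        k = int(rng.integers(3, 6))
        gaps = rng.integers(33, 39, size=k - 1)
        starts = np.concatenate([[0.0], np.cumsum(gaps)]).astype(float)
        return TreatmentSchedule(disease="AML",
                                 cycles=tuple((s, s + 7.0) for s in starts))
    if cessation is None:
        cessation = CessationSampler()
    t_stop = float(cessation.sample(1, rng)[0])
    return TreatmentSchedule(disease="CML", t_stop=t_stop)


def aml_dense_grid() -> np.ndarray:
    """Weekly measurement grid in months, from day 7 to month 24."""
    days = np.arange(7.0, AML_HORIZON_MONTHS * MONTH_DAYS + 1e-9, 7.0)
    return days / MONTH_DAYS


def cml_dense_grid(t_stop: float) -> np.ndarray:
    """Monthly grid from diagnosis to ten years past cessation.

    A measurement is also taken at the cessation visit itself (``t_stop``),
    the last point of the prediction input window.
    """
    g = np.arange(0.0, t_stop + CML_POST_STOP_MONTHS + 1e-9, 1.0)
    if np.min(np.abs(g - t_stop)) > 1e-6:
        g = np.sort(np.append(g, t_stop))
    return g


def _aml_remitted(traj: Trajectory) -> bool:
    win = traj.times <= AML_INPUT_WINDOW_MONTHS + 1e-9
    return bool(traj.values[win].min() < 1.0)


def generate_cohort(config: CohortConfig) -> list[PatientRecord]:
    """Simulate a labeled dense cohort; AML non-remitters are resampled."""
    ss = np.random.SeedSequence(config.seed)
    s_param, s_sched = ss.spawn(2)
    rng_sched = np.random.default_rng(s_sched)
    prior = default_prior(config.disease)
    prior.jitter_sd = config.jitter_sd
    cess = (CessationSampler(config.cessation_mean, config.cessation_sd,
                             config.cessation_min)
            if config.disease == "CML" else None)

    records: list[PatientRecord] = []
    attempts = 0
    max_attempts = config.max_attempt_factor * config.n_patients
    batch = config.n_patients
    param_seed = int(s_param.generate_state(1)[0] % (2 ** 31))
    while len(records) < config.n_patients:
        if attempts >= max_attempts:
            raise RuntimeError(
                f"cohort generation exceeded {max_attempts} attempts; "
                "the prior produces too few remissions")
        params_list = sample_parameters(prior, batch, param_seed)
        param_seed = (param_seed * 48271 + 1) % (2 ** 31)
        for params in params_list:
            if len(records) >= config.n_patients:
                break
            attempts += 1
            sched = sample_schedule(config.disease, rng=rng_sched,
                                    cessation=cess)
            pid = f"{config.disease}-{config.seed}-{attempts:05d}"
            if config.disease == "AML":
                grid = aml_dense_grid()
            else:
                grid = cml_dense_grid(sched.t_stop)
            dense = simulate(params, sched, grid, patient_id=pid)
            if config.disease == "AML" and not _aml_remitted(dense):
                continue
            label = label_relapse(dense, config.disease, sched)
            records.append(PatientRecord(id=pid, disease=config.disease,
                                         parameters=params, schedule=sched,
                                         dense=dense, relapse=label))
        batch = max(8, config.n_patients - len(records))
    return records


# ---------------------------------------------------------------------------
# serialization: trajectory CSV + patient JSON-lines sidecar
# ---------------------------------------------------------------------------

def trajectory_frame(trajs: list[Trajectory]) -> pd.DataFrame:
    rows = []
    for tr in trajs:
        for t, v, c in zip(tr.times, tr.values, tr.censored):
            rows.append((tr.patient_id, tr.disease, tr.variant, t, v, int(c)))
    return pd.DataFrame(rows, columns=["patient_id", "disease", "variant",
                                       "time_months", "burden_pct", "censored"])


def cohort_to_trajectory_frame(records: list[PatientRecord]) -> pd.DataFrame:
    return trajectory_frame([r.dense for r in records])


def _schedule_to_dict(s: TreatmentSchedule) -> dict:
    return {"disease": s.disease, "cycles": [list(c) for c in s.cycles],
            "t_stop": s.t_stop, "half_dose_start": s.half_dose_start}


def _schedule_from_dict(d: dict) -> TreatmentSchedule:
    return TreatmentSchedule(disease=d["disease"],
                             cycles=tuple(tuple(c) for c in d["cycles"]),
                             t_stop=d["t_stop"],
                             half_dose_start=d["half_dose_start"])


def save_cohort(records: list[PatientRecord], out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort_to_trajectory_frame(records).to_csv(out / "trajectories.csv",
                                               index=False, float_format="%.10g")
    with open(out / "patients.jsonl", "w") as fh:
        for r in records:
            pdict = {n: getattr(r.parameters, n)
                     for n in (r.parameters.RATE_NAMES
                               + getattr(r.parameters, "IC_NAMES", ()))}
            fh.write(json.dumps({
                "id": r.id, "disease": r.disease, "parameters": pdict,
                "free_names": list(r.parameters.free_names),
                "schedule": _schedule_to_dict(r.schedule),
                "relapse": r.relapse, "excluded": r.excluded}) + "\n")


def load_cohort(in_dir) -> list[PatientRecord]:
    out = Path(in_dir)
    df = pd.read_csv(out / "trajectories.csv")
    trajs = {}
    for pid, g in df.groupby("patient_id", sort=False):
        trajs[pid] = Trajectory(
            patient_id=pid, disease=g.disease.iloc[0], variant=g.variant.iloc[0],
            times=g.time_months.to_numpy(), values=g.burden_pct.to_numpy(),
            censored=g.censored.to_numpy().astype(bool))
    records = []
    with open(out / "patients.jsonl") as fh:
        for line in fh:
            d = json.loads(line)
            cls = AMLParameters if d["disease"] == "AML" else CMLParameters
            params = cls(**d["parameters"],
                         free_names=tuple(d["free_names"]))
            records.append(PatientRecord(
                id=d["id"], disease=d["disease"], parameters=params,
                schedule=_schedule_from_dict(d["schedule"]),
                dense=trajs.get(d["id"]), relapse=d["relapse"],
                excluded=d["excluded"]))
    return records
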
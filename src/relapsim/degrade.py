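"""Data-quality ladder D -> DN -> SN -> AP and the improved AS schemes.

Starting from the dense noise-free course (D), measurements are degraded to
mimic clinical molecular monitoring: multiplicative log-normal measurement
noise (DN), thinning to clinical measurement frequency (SN) and censoring at
a lower detection limit (AP).  The AS schemes keep the clinical measurement
*count* but redistribute information: for AML, measurements are taken at the
end of every chemotherapy cycle and every six weeks thereafter until month
nine; for CML, the TKI dose is halved during the final year before cessation
with monthly measurements during that perturbation period.

Ground-truth labels are always computed on D and are invariant under every
transform here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .cohort import PatientRecord, AML_INPUT_WINDOW_MONTHS
from .disease_models import (
    Trajectory, TreatmentSchedule, MONTH_DAYS, simulate,
    CML_POST_STOP_MONTHS,
)

logger = logging.getLogger(__name__)

__all__ = [
    "DegradeConfig", "CountDistribution", "add_noise", "sparsify",
    "apply_detection_limit", "as_scheme", "split_windows", "make_variants",
]

DEFAULT_NOISE_SD = {"AML": 0.3, "CML": 0.35}   # dex on the log10 axis
DEFAULT_LOD_PCT = {"AML": 0.01, "CML": 0.01}   # detection limit, percent


@dataclass(frozen=True)
class CountDistribution:
    """Per-patient in-window measurement-count distribution."""

    values: tuple[int, ...]
    weights: tuple[float, ...]

    def __post_init__(self):
        if len(self.values) != len(self.weights):
            raise ValueError("values and weights must match")
        if min(self.values) < 2:
            raise ValueError("sparsity counts must be >= 2")
        if abs(sum(self.weights) - 1.0) > 1e-9:
            raise ValueError("weights must sum to 1")

    def sample(self, rng: np.random.Generator) -> int:
        return int(rng.choice(self.values, p=self.weights))


# AML clinical follow-up holds a handful of marrow/molecular assessments in
# the first nine months (population median 4); CML monitoring is roughly
# quarterly over the years of TKI therapy (population median 25 in-window).
DEFAULT_COUNT_DIST = {
    "AML": CountDistribution((3, 4, 5, 6), (0.25, 0.35, 0.20, 0.20)),
    "CML": CountDistribution(tuple(range(19, 32)), (1.0 / 13,) * 13),
}


@dataclass
class DegradeConfig:
    disease: str
    noise_sd: float = None
    count_dist: CountDistribution = None
    lod: float = None
    # AML AS: measure on the first day of each cycle (default) or at cycle
    # ends.  First-day sampling hits the uncensored inter-cycle rebound peaks
    # that carry the regrowth signal; end-of-cycle sampling hits the nadirs,
    # which are frequently below the detection limit.
    as_first_day: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.noise_sd is None:
            self.noise_sd = DEFAULT_NOISE_SD[self.disease]
        if self.count_dist is None:
            self.count_dist = DEFAULT_COUNT_DIST[self.disease]
        if self.lod is None:
            self.lod = DEFAULT_LOD_PCT[self.disease]
        if self.noise_sd < 0:
            raise ValueError("noise SD must be >= 0")
        if self.lod <= 0:
            raise ValueError("detection limit must be > 0")


def _window_end(disease: str, schedule: TreatmentSchedule) -> float:
    return (AML_INPUT_WINDOW_MONTHS if disease == "AML"
            else float(schedule.t_stop))


def add_noise(traj: Trajectory, sd: float, seed) -> Trajectory:
    """Multiplicative log-normal measurement noise on every point (DN)."""
    if sd < 0:
        raise ValueError("noise SD must be >= 0")
    rng = np.random.default_rng(seed)
    noisy = 10.0 ** (np.log10(traj.values) + rng.normal(0.0, sd, len(traj)))
    return Trajectory(patient_id=traj.patient_id, disease=traj.disease,
                      variant="DN", times=traj.times.copy(), values=noisy,
                      censored=traj.censored.copy())


def sparsify(traj: Trajectory, count_dist: CountDistribution, seed,
             window_end: float) -> Trajectory:
    """Thin to clinical measurement frequency (SN).

    The first and last points of the input window are always retained and the
    remaining in-window measurements are drawn uniformly without replacement.
    Post-window points are kept on a sparse grid of comparable spacing so the
    label horizon remains realistically sampled.
    """
    rng = np.random.default_rng(seed)
    t = traj.times
    in_win = np.nonzero(t <= window_end + 1e-9)[0]
    post = np.nonzero(t > window_end + 1e-9)[0]
    n_req = count_dist.sample(rng)
    if n_req >= len(in_win):
        logger.warning("requested %d points but only %d available in window "
                       "for %s; keeping all", n_req, len(in_win),
                       traj.patient_id)
        keep_win = in_win
        n_kept = len(in_win)
    else:
        interior = in_win[1:-1]
        picked = rng.choice(interior, size=n_req - 2, replace=False)
        keep_win = np.sort(np.concatenate([[in_win[0]], picked, [in_win[-1]]]))
        n_kept = n_req
    keep = keep_win
    if len(post) > 0:
        window_span = t[in_win[-1]] - t[in_win[0]]
        spacing = window_span / max(n_kept - 1, 1)
        grid_step = np.median(np.diff(t[post])) if len(post) > 1 else spacing
        stride = max(1, int(round(spacing / max(grid_step, 1e-9))))
        keep = np.concatenate([keep_win, post[::stride]])
    keep = np.unique(keep)
    return Trajectory(patient_id=traj.patient_id, disease=traj.disease,
                      variant="SN", times=t[keep], values=traj.values[keep],
                      censored=traj.censored[keep])


def apply_detection_limit(traj: Trajectory, lod: float) -> Trajectory:
    """Censor values below the assay detection limit at the limit (AP)."""
    if lod <= 0:
        raise ValueError("detection limit must be > 0")
    below = traj.values < lod
    values = np.where(below, lod, traj.values)
    return Trajectory(patient_id=traj.patient_id, disease=traj.disease,
                      variant="AP", times=traj.times.copy(), values=values,
                      censored=traj.censored | below)


def _aml_as_times_months(schedule: TreatmentSchedule,
                         first_day: bool = False) -> np.ndarray:
    """AS-AML measurement days: one per cycle plus six-weekly follow-up."""
    if first_day:
        cycle_days = [s for s, _ in schedule.cycles]
    else:
        cycle_days = [e for _, e in schedule.cycles]
    end = schedule.treatment_end_day
    horizon_day = AML_INPUT_WINDOW_MONTHS * MONTH_DAYS
    t = end + 42.0
    follow = []
    while t <= horizon_day + 1e-9:
        follow.append(t)
        t += 42.0
    days = np.array(sorted(set(cycle_days + follow)))
    return days / MONTH_DAYS


def as_scheme(patient: PatientRecord, cfg: DegradeConfig,
              ap: Trajectory | None = None, seed=None) -> Trajectory:
    """Improved-scheme trajectory (AS) for one patient.

    AML: the dense model course is read out at the AS measurement times and
    then degraded exactly like AP data (noise + detection limit).  CML: the
    course is re-simulated with half TKI dose during the final year before
    cessation; measurement times are the patient's AP times before the
    half-dose year plus monthly points during it.
    """
    if seed is None:
        seed = cfg.seed
    sch = patient.schedule
    if patient.disease == "AML":
        times = _aml_as_times_months(sch, cfg.as_first_day)
        dense = simulate(patient.parameters, sch, times,
                         patient_id=patient.id)
    else:
        t_stop = sch.t_stop
        if t_stop < 12.0:
            raise ValueError("half-dose window undefined for t_stop < 12 months")
        half_start = t_stop - 12.0
        sch_half = TreatmentSchedule(disease="CML", t_stop=t_stop,
                                     half_dose_start=half_start)
        if ap is None:
            ap = make_variants([patient], cfg)["AP"][0]
        pre = ap.times[ap.times < half_start - 1e-9]
        during = np.arange(half_start, t_stop + 1e-9, 1.0)
        times = np.unique(np.concatenate([pre, during, [t_stop]]))
        dense = simulate(patient.parameters, sch_half, times,
                         patient_id=patient.id)
    noisy = add_noise(dense, cfg.noise_sd, seed)
    out = apply_detection_limit(noisy, cfg.lod)
    return Trajectory(patient_id=patient.id, disease=patient.disease,
                      variant="AS", times=out.times, values=out.values,
                      censored=out.censored)


def as_schedule(record: PatientRecord) -> TreatmentSchedule:
    """The treatment schedule actually administered under the AS scheme.

    AML keeps its chemotherapy schedule; CML runs half dose during the final
    year before cessation, which any predictor aware of the protocol (in
    particular the mechanistic fitter) must be told about.
    """
    sch = record.schedule
    if record.disease == "AML":
        return sch
    return TreatmentSchedule(disease="CML", t_stop=sch.t_stop,
                             half_dose_start=sch.t_stop - 12.0)


def split_windows(traj: Trajectory, disease: str,
                  schedule: TreatmentSchedule):
    """Split a trajectory into the prediction input window and the horizon.

    AML: input is everything up to nine months after treatment start, the
    relapse horizon is the following 15 months.  CML: input is everything up
    to TKI cessation, the horizon is the ten years thereafter.
    """
    wend = _window_end(disease, schedule)
    sel = traj.times <= wend + 1e-9
    if not np.any(sel):
        raise ValueError(f"empty input window for {traj.patient_id}")
    inp = Trajectory(patient_id=traj.patient_id, disease=disease,
                     variant=traj.variant, times=traj.times[sel],
                     values=traj.values[sel], censored=traj.censored[sel])
    horizon = ((wend, 24.0) if disease == "AML"
               else (wend, wend + CML_POST_STOP_MONTHS))
    return inp, horizon


def make_variants(records: list[PatientRecord], cfg: DegradeConfig,
                  variants=("DN", "SN", "AP", "AS")) -> dict[str, list[Trajectory]]:
    """Materialize degraded variants for a cohort, deterministically seeded.

    Per-patient seeds are spawned from ``cfg.seed`` by patient index, so each
    patient's ladder is internally consistent (SN thins DN, AP censors SN)
    and independent of cohort ordering length.
    """
    ss = np.random.SeedSequence(cfg.seed)
    out: dict[str, list[Trajectory]] = {v: [] for v in variants}
    need_ladder = any(v in variants for v in ("DN", "SN", "AP", "AS"))
    for i, rec in enumerate(records):
        child = np.random.SeedSequence(entropy=cfg.seed, spawn_key=(i,))
        s_noise, s_sparse, s_as = child.generate_state(3) % (2 ** 31)
        if not need_ladder:
            continue
        dn = add_noise(rec.dense, cfg.noise_sd, s_noise)
        sn = sparsify(dn, cfg.count_dist, s_sparse,
                      _window_end(rec.disease, rec.schedule))
        ap = apply_detection_limit(sn, cfg.lod)
        if "DN" in out:
            out["DN"].append(dn)
        if "SN" in out:
            out["SN"].append(sn)
        if "AP" in out:
            out["AP"].append(ap)
        if "AS" in out:
            out["AS"].append(as_scheme(rec, cfg, ap=ap, seed=s_as))
    if "D" in variants:
        out["D"] = [rec.dense for rec in records]
    return out
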
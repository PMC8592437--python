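"""The three relapse predictors behind one estimator interface.

* :class:`MechanisticClassifier` (MM) refits the generative ODE model's
  patient-specific parameters to each input series (sum of squared residuals
  on the log10 axis; SLSQP multistart for the two AML parameters, a genetic
  algorithm with gradient polish for the seven CML parameters), simulates the
  fitted model through the prediction horizon and reads off the relapse label.
* :class:`FeatureLogisticClassifier` (GLM) is a ridge-stabilised logistic
  regression on the hand-crafted kinetic features of :mod:`relapsim.features`.
* :class:`SequenceLSTMClassifier` (NN) is a bidirectional LSTM trained
  end-to-end on the raw (scaled) time courses, with multiple independently
  seeded training runs of which the one with the highest inner-validation
  accuracy is kept.

All three are scikit-learn style estimators operating on lists of
:class:`PatientInput` and are interchangeable in the evaluator.
"""

from __future__ import annotations

import logging
import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import train_test_split
from sklearn.preprocessing import StandardScaler

from . import priors
from ._lstm import BiLSTMNet, reverse_within_length
from .cohort import aml_dense_grid, cml_dense_grid, AML_INPUT_WINDOW_MONTHS
from .degrade import DEFAULT_LOD_PCT
from .disease_models import (
    Trajectory, TreatmentSchedule, simulate, label_relapse,
    SimulationError, NoRemissionError, BURDEN_FLOOR_PCT,
)
from .features import feature_matrix, FeaturizationError

logger = logging.getLogger(__name__)

__all__ = [
    "PatientInput", "Prediction", "FitResult", "fit_mechanistic",
    "predict_mm", "MechanisticClassifier", "FeatureLogisticClassifier",
    "SequenceLSTMClassifier", "encode_sequences",
]


@dataclass
class PatientInput:
    """Input-window series plus treatment context for one patient."""

    id: str
    disease: str
    variant: str
    times: np.ndarray
    values: np.ndarray
    censored: np.ndarray
    schedule: TreatmentSchedule
    lod: float

    @property
    def window_end(self) -> float:
        return (AML_INPUT_WINDOW_MONTHS if self.disease == "AML"
                else float(self.schedule.t_stop))

    def as_trajectory(self) -> Trajectory:
        return Trajectory(patient_id=self.id, disease=self.disease,
                          variant=self.variant, times=self.times,
                          values=self.values, censored=self.censored)


def make_patient_inputs(records, input_trajs, variant, lod=None):
    out = []
    for rec, tr in zip(records, input_trajs):
        out.append(PatientInput(
            id=rec.id, disease=rec.disease, variant=variant,
            times=tr.times, values=tr.values, censored=tr.censored,
            schedule=rec.schedule,
            lod=lod if lod is not None else DEFAULT_LOD_PCT[rec.disease]))
    return out


@dataclass
class Prediction:
    patient_id: str
    method: str          # MM | GLM | NN
    label: bool
    score: float         # probability for GLM/NN; 0/1 for MM

    def __post_init__(self):
        if not 0.0 <= self.score <= 1.0:
            raise ValueError("score must lie in [0, 1]")


@dataclass
class FitResult:
    params: object
    objective: float
    converged: bool
    restarts_used: int
    n_iter: int


def _free_bounds(disease: str, free_names) -> np.ndarray:
    table = (priors.AML_FREE_BOUNDS if disease == "AML"
             else priors.CML_FREE_BOUNDS)
    return np.log10(np.array([table[n] for n in free_names]))


def _objective_factory(inp: PatientInput, base_params):
    """SSQ of log10 residuals; censored points penalise only simulated
    values above the detection limit (one-sided)."""
    free = base_params.free_names
    obs_log = np.log10(np.maximum(inp.values, BURDEN_FLOOR_PCT))
    log_lod = np.log10(inp.lod)
    cens = inp.censored

    def obj(theta_log10):
        vals = 10.0 ** np.asarray(theta_log10)
        try:
            p = base_params.with_values(**dict(zip(free, vals)))
            tr = simulate(p, inp.schedule, inp.times)
        except (SimulationError, ValueError):
            return 1e6
        sim_log = np.log10(tr.values)
        r = sim_log - obs_log
        r[cens] = np.maximum(0.0, sim_log[cens] - log_lod)
        return float(r @ r)

    return obj


def _fit_aml(inp, base_params, bounds_log, seed, n_restarts):
    rng = np.random.default_rng(seed)
    obj = _objective_factory(inp, base_params)
    starts = np.log10(
        priors.AML_BASE[rng.integers(0, len(priors.AML_BASE), n_restarts)])
    best = None
    n_iter = 0
    any_conv = False
    for x0 in starts:
        res = minimize(obj, x0, method="SLSQP",
                       bounds=list(map(tuple, bounds_log)),
                       options={"maxiter": 200, "ftol": 1e-10})
        n_iter += res.nit
        any_conv = any_conv or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    return best, any_conv, n_iter, n_restarts


def _fit_cml_ga(inp, base_params, bounds_log, seed, population, generations):
    """Generational GA (tournament selection, uniform crossover, Gaussian
    mutation) in normalised log10 space, followed by local polish."""
    rng = np.random.default_rng(seed)
    obj = _objective_factory(inp, base_params)
    lo, hi = bounds_log[:, 0], bounds_log[:, 1]
    span = hi - lo

    def denorm(u):
        return lo + np.clip(u, 0.0, 1.0) * span

    d = len(lo)
    pop = rng.uniform(0, 1, size=(population, d))
    # seed part of the population from the reference table
    n_seed = min(len(priors.CML_BASE), population // 3)
    idx = rng.integers(0, len(priors.CML_BASE), n_seed)
    pop[:n_seed] = np.clip(
        (np.log10(priors.CML_BASE[idx]) - lo) / span, 0.0, 1.0)
    fit = np.array([obj(denorm(u)) for u in pop])
    n_eval = population
    for _ in range(generations):
        order = np.argsort(fit)
        elite = pop[order[:2]].copy()
        new = [elite[0], elite[1]]
        while len(new) < population:
            # tournament selection, k = 3
            cand = rng.integers(0, population, (2, 3))
            p1 = pop[cand[0][np.argmin(fit[cand[0]])]]
            p2 = pop[cand[1][np.argmin(fit[cand[1]])]]
            mask = rng.random(d) < 0.5
            child = np.where(mask, p1, p2)
            mut = rng.random(d) < 0.3
            child = child + mut * rng.normal(0.0, 0.12, d)
            new.append(np.clip(child, 0.0, 1.0))
        pop = np.array(new)
        fit = np.array([obj(denorm(u)) for u in pop])
        n_eval += population
    ibest = int(np.argmin(fit))
    x0 = denorm(pop[ibest])
    res = minimize(obj, x0, method="L-BFGS-B",
                   bounds=list(map(tuple, bounds_log)),
                   options={"maxiter": 100})
    from types import SimpleNamespace
    if res.fun <= fit[ibest]:
        out = SimpleNamespace(x=res.x, fun=float(res.fun))
        conv = bool(res.success)
    else:
        out = SimpleNamespace(x=x0, fun=float(fit[ibest]))
        conv = False
    return out, conv, n_eval + res.nit, 1


def fit_mechanistic(inp: PatientInput, seed=0, n_restarts: int = 5,
                    ga_population: int = 50, ga_generations: int = 40,
                    base_params=None) -> FitResult:
    """Refit the patient-specific model parameters to an input series."""
    if base_params is None:
        base_params = (priors.default_aml_parameters(*priors.AML_BASE[0])
                       if inp.disease == "AML"
                       else priors.default_cml_parameters(
                           **dict(zip(priors.CML_FREE, priors.CML_BASE[0]))))
    n_min = 2 if inp.disease == "AML" else 4
    if len(inp.times) < n_min:
        raise ValueError(f"need >= {n_min} points to fit {inp.disease}")
    bounds_log = _free_bounds(inp.disease, base_params.free_names)
    if inp.disease == "AML":
        res, conv, n_iter, restarts = _fit_aml(inp, base_params, bounds_log,
                                               seed, n_restarts)
    else:
        res, conv, n_iter, restarts = _fit_cml_ga(
            inp, base_params, bounds_log, seed, ga_population, ga_generations)
    vals = 10.0 ** np.asarray(res.x)
    fitted = base_params.with_values(
        **dict(zip(base_params.free_names, vals)))
    return FitResult(params=fitted, objective=float(res.fun), converged=conv,
                     restarts_used=restarts, n_iter=int(n_iter))


def predict_mm(inp: PatientInput, fit: FitResult | None = None,
               seed=0, **fit_kwargs) -> Prediction:
    """Forward-simulate the fitted model over the horizon and label it."""
    if fit is None:
        fit = fit_mechanistic(inp, seed=seed, **fit_kwargs)
    sch = inp.schedule
    grid = (aml_dense_grid() if inp.disease == "AML"
            else cml_dense_grid(sch.t_stop))
    dense = simulate(fit.params, sch, grid, patient_id=inp.id)
    try:
        label = label_relapse(dense, inp.disease, sch)
    except NoRemissionError:
        # the fitted course never remits: treat as an (early) relapse course
        label = True
    return Prediction(patient_id=inp.id, method="MM", label=bool(label),
                      score=float(label))


class MechanisticClassifier(BaseEstimator, ClassifierMixin):
    """Per-patient mechanistic refitting; requires no training data."""

    method_tag = "MM"

    def __init__(self, n_restarts=5, ga_population=50, ga_generations=40,
                 random_state=0):
        self.n_restarts = n_restarts
        self.ga_population = ga_population
        self.ga_generations = ga_generations
        self.random_state = random_state

    def fit(self, X, y=None):
        self.classes_ = np.array([False, True])
        self.n_features_in_ = 1
        return self

    def _predict_one(self, inp: PatientInput, idx: int) -> Prediction:
        # stable per-patient seed (string hash randomisation would break
        # run-to-run determinism)
        seed = (zlib.crc32(f"{self.random_state}|{inp.id}".encode())
                % (2 ** 31))
        fit = fit_mechanistic(inp, seed=seed, n_restarts=self.n_restarts,
                              ga_population=self.ga_population,
                              ga_generations=self.ga_generations)
        return predict_mm(inp, fit)

    def predictions(self, X) -> list[Prediction]:
        return [self._predict_one(inp, i) for i, inp in enumerate(X)]

    def predict(self, X):
        return np.array([p.label for p in self.predictions(X)])

    def predict_proba(self, X):
        lab = self.predict(X).astype(float)
        return np.column_stack([1 - lab, lab])


class FeatureLogisticClassifier(BaseEstimator, ClassifierMixin):
    """Logistic regression on explicit kinetic features.

    Features are z-scored with training-fold statistics; a small ridge
    penalty keeps the fit defined under perfect separation.  Constant
    feature columns are dropped with a warning.
    """

    method_tag = "GLM"

    def __init__(self, disease="AML", variant="AP", ridge=1e-4):
        self.disease = disease
        self.variant = variant
        self.ridge = ridge

    def _featurize(self, X, labels=None):
        y = np.zeros(len(X)) if labels is None else labels
        F, yk, kept = feature_matrix(
            [i.as_trajectory() for i in X], [i.schedule for i in X], y,
            self.disease, self.variant,
            max_failure_frac=1.0 if labels is None else 0.05)
        return F, yk, kept

    def fit(self, X, y):
        y = np.asarray(y).astype(bool)
        if len(np.unique(y)) < 2:
            raise ValueError("training labels must contain both classes")
        F, yk, _ = self._featurize(X, y)
        var = F.to_numpy().var(axis=0)
        self.keep_cols_ = var > 1e-12
        if not self.keep_cols_.all():
            dropped = [c for c, k in zip(F.columns, self.keep_cols_) if not k]
            warnings.warn(f"dropping constant feature column(s): {dropped}")
        A = F.to_numpy()[:, self.keep_cols_]
        self.scaler_ = StandardScaler().fit(A)
        self.clf_ = LogisticRegression(C=1.0 / self.ridge, solver="lbfgs",
                                       max_iter=5000)
        self.clf_.fit(self.scaler_.transform(A), yk)
        self.classes_ = np.array([False, True])
        self.majority_ = bool(np.mean(yk) >= 0.5)
        return self

    def predict_proba(self, X):
        F, _, kept = self._featurize(X)
        probs = np.full(len(X), 0.5 + (0.0001 if self.majority_ else -0.0001))
        if len(kept):
            A = F.to_numpy()[:, self.keep_cols_]
            probs[kept] = self.clf_.predict_proba(
                self.scaler_.transform(A))[:, 1]
        return np.column_stack([1 - probs, probs])

    def predict(self, X):
        return self.predict_proba(X)[:, 1] >= 0.5

    def predictions(self, X) -> list[Prediction]:
        p = self.predict_proba(X)[:, 1]
        return [Prediction(patient_id=inp.id, method="GLM",
                           label=bool(pi >= 0.5), score=float(pi))
                for inp, pi in zip(X, p)]


def encode_sequences(inputs: list[PatientInput], scale: tuple | None = None):
    """Encode input series as padded (B, T, 3) tensors plus a mask.

    Channels per time point: time scaled by the patient's window length,
    log10 burden mapped to [-1, 1] by the training-fold min/max, and the
    censoring flag.  Sequences are front-aligned; the mask marks real points.
    """
    if any(len(i.times) == 0 for i in inputs):
        raise ValueError("empty input series cannot be encoded")
    logs = [np.log10(np.maximum(i.values, BURDEN_FLOOR_PCT)) for i in inputs]
    if scale is None:
        allv = np.concatenate(logs)
        lo, hi = float(allv.min()), float(allv.max())
        if hi - lo < 1e-9:
            hi = lo + 1.0
        scale = (lo, hi)
    lo, hi = scale
    T = max(len(i.times) for i in inputs)
    X = np.zeros((len(inputs), T, 3))
    mask = np.zeros((len(inputs), T))
    for b, (inp, lv) in enumerate(zip(inputs, logs)):
        L = len(inp.times)
        X[b, :L, 0] = inp.times / max(inp.window_end, 1e-9)
        X[b, :L, 1] = 2.0 * (lv - lo) / (hi - lo) - 1.0
        X[b, :L, 2] = inp.censored.astype(float)
        mask[b, :L] = 1.0
    return X, mask, scale


class SequenceLSTMClassifier(BaseEstimator, ClassifierMixin):
    """Bidirectional LSTM sequence classifier with restart selection.

    ``restarts`` independently seeded training runs are performed on the
    same split and the run with the highest validation accuracy is kept
    (ties favour the earlier run); if the validation subset happens to be
    single-class, selection falls back to validation loss with a warning.
    """

    method_tag = "NN"

    def __init__(self, hidden=32, head=(16,), epochs=100, patience=10,
                 batch_size=32, lr=1e-3, restarts=10, val_fraction=0.1,
                 random_state=0):
        self.hidden = hidden
        self.head = head
        self.epochs = epochs
        self.patience = patience
        self.batch_size = batch_size
        self.lr = lr
        self.restarts = restarts
        self.val_fraction = val_fraction
        self.random_state = random_state

    def _train_once(self, Xtr, mtr, ytr, Xva, mva, yva, seed):
        net = BiLSTMNet(Xtr.shape[2], hidden=self.hidden,
                        head=tuple(self.head), seed=seed)
        update = net.make_adam(lr=self.lr)
        rng = np.random.default_rng(seed)
        n = len(ytr)
        best = (-1.0, np.inf, net.get_weights())  # (val acc, val loss, weights)
        stale = 0
        for _ in range(self.epochs):
            order = rng.permutation(n)
            for s in range(0, n, self.batch_size):
                idx = order[s:s + self.batch_size]
                _, grads, _ = net.loss_and_grads(Xtr[idx], mtr[idx], ytr[idx])
                update(grads)
            pva = net.predict_proba(Xva, mva)
            acc = float(np.mean((pva >= 0.5) == (yva >= 0.5)))
            eps = 1e-12
            vloss = float(-np.mean(yva * np.log(pva + eps)
                                   + (1 - yva) * np.log(1 - pva + eps)))
            if acc > best[0] + 1e-12 or (acc >= best[0] - 1e-12
                                         and vloss < best[1] - 1e-12):
                best = (acc, vloss, net.get_weights())
                stale = 0
            else:
                stale += 1
                if stale >= self.patience:
                    break
        net.set_weights(best[2])
        return net, best[0], best[1]

    def fit(self, X, y):
        y = np.asarray(y).astype(float)
        Xt, mask, self.scale_ = encode_sequences(X)
        strat = y if 0 < y.mean() < 1 else None
        idx = np.arange(len(y))
        tr_idx, va_idx = train_test_split(
            idx, test_size=self.val_fraction, random_state=self.random_state,
            stratify=strat)
        Xtr, mtr, ytr = Xt[tr_idx], mask[tr_idx], y[tr_idx]
        Xva, mva, yva = Xt[va_idx], mask[va_idx], y[va_idx]
        single_class_val = len(np.unique(yva)) < 2
        if single_class_val:
            warnings.warn("validation subset is single-class; selecting "
                          "restarts by validation loss")
        runs = []
        for r in range(self.restarts):
            seed = (self.random_state * 7919 + r) % (2 ** 31)
            runs.append(self._train_once(Xtr, mtr, ytr, Xva, mva, yva, seed))
        if single_class_val:
            sel = int(np.argmin([r[2] for r in runs]))
        else:
            accs = np.array([r[1] for r in runs])
            sel = int(np.argmax(accs))  # argmax takes the first maximum
        self.net_ = runs[sel][0]
        self.selected_run_ = sel
        self.val_accuracy_ = runs[sel][1]
        self.classes_ = np.array([False, True])
        return self

    def predict_proba(self, X):
        Xt, mask, _ = encode_sequences(X, scale=self.scale_)
        p = self.net_.predict_proba(Xt, mask)
        return np.column_stack([1 - p, p])

    def predict(self, X):
        return self.predict_proba(X)[:, 1] >= 0.5

    def predictions(self, X) -> list[Prediction]:
        p = self.predict_proba(X)[:, 1]
        return [Prediction(patient_id=inp.id, method="NN",
                           label=bool(pi >= 0.5), score=float(pi))
                for inp, pi in zip(X, p)]
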
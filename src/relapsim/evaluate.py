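"""Cross-validated benchmark over the disease x variant x method grid.

Every method is evaluated on the identical stratified 10-fold test splits;
the feature-based and sequence classifiers are trained on the complementary
folds (the sequence classifier carves a stratified inner-validation subset
out of its training fold for restart selection and early stopping), while
the mechanistic predictor needs no training and is fit per patient on that
patient's degraded input series.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .cohort import PatientRecord
from .degrade import DegradeConfig, make_variants, split_windows, as_schedule
from .predict import (
    PatientInput, make_patient_inputs, MechanisticClassifier,
    FeatureLogisticClassifier, SequenceLSTMClassifier,
)

logger = logging.getLogger(__name__)

__all__ = ["EvalConfig", "EvalReport", "kfold_split", "accuracy",
           "run_experiment"]


def kfold_split(n: int, k: int, seed, labels) -> list[np.ndarray]:
    """Stratified k-fold test-index sets (disjoint, sizes differing by <= 1).

    Falls back to unstratified splitting with a warning when a class has
    fewer than ``k`` members.
    """
    if n < k:
        raise ValueError(f"need at least k={k} samples, got {n}")
    labels = np.asarray(labels).astype(int)
    counts = np.bincount(labels, minlength=2)
    idx = np.arange(n)
    if counts.min() < k:
        logger.warning("class with < %d members; unstratified folds", k)
        rng = np.random.default_rng(seed)
        perm = rng.permutation(n)
        return [np.sort(f) for f in np.array_split(perm, k)]
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [np.sort(test) for _, test in skf.split(idx, labels)]


def accuracy(tp: int, tn: int, fp: int, fn: int) -> float:
    """(TP + TN) / (TP + FP + TN + FN)."""
    total = tp + tn + fp + fn
    if min(tp, tn, fp, fn) < 0:
        raise ValueError("confusion counts must be >= 0")
    if total == 0:
        raise ValueError("cannot compute accuracy of zero predictions")
    return (tp + tn) / total


@dataclass
class EvalConfig:
    k: int = 10
    seed: int = 0
    degrade: DegradeConfig | None = None
    methods: tuple[str, ...] = ("MM", "GLM", "NN")
    variants: tuple[str, ...] = ("D", "DN", "SN", "AP", "AS")
    mm_kwargs: dict = field(default_factory=dict)
    nn_kwargs: dict = field(default_factory=dict)
    glm_kwargs: dict = field(default_factory=dict)
    max_method_failure_frac: float = 0.05


@dataclass
class Cell:
    fold_acc: list[float]
    confusion: list[tuple[int, int, int, int]]  # (TP, TN, FP, FN) per fold

    @property
    def mean(self) -> float:
        return float(np.mean(self.fold_acc))

    @property
    def sd(self) -> float:
        return float(np.std(self.fold_acc, ddof=1))


@dataclass
class EvalReport:
    disease: str
    n: int
    seed: int
    cells: dict = field(default_factory=dict)   # (variant, method) -> Cell
    timings: dict = field(default_factory=dict)

    def mean_accuracy(self, variant: str, method: str) -> float:
        return self.cells[(variant, method)].mean

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (variant, method), cell in self.cells.items():
            for fold, (acc, conf) in enumerate(zip(cell.fold_acc,
                                                   cell.confusion)):
                rows.append((self.disease, variant, method, fold, acc, *conf))
        return pd.DataFrame(rows, columns=["disease", "variant", "method",
                                           "fold", "accuracy", "TP", "TN",
                                           "FP", "FN"])

    def summary_frame(self) -> pd.DataFrame:
        rows = [(self.disease, v, m, c.mean, c.sd)
                for (v, m), c in self.cells.items()]
        return pd.DataFrame(rows, columns=["disease", "variant", "method",
                                           "mean_accuracy", "sd_accuracy"])

    def to_json(self) -> str:
        payload = {
            "disease": self.disease, "n": self.n, "seed": self.seed,
            "cells": {f"{v}|{m}": {"fold_acc": c.fold_acc,
                                   "confusion": [list(x) for x in c.confusion]}
                      for (v, m), c in self.cells.items()},
            "timings": self.timings,
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "EvalReport":
        d = json.loads(text)
        rep = cls(disease=d["disease"], n=d["n"], seed=d["seed"],
                  timings=d.get("timings", {}))
        for key, c in d["cells"].items():
            v, m = key.split("|")
            rep.cells[(v, m)] = Cell(fold_acc=c["fold_acc"],
                                     confusion=[tuple(x) for x in
                                                c["confusion"]])
        return rep


def _confusion(pred: np.ndarray, truth: np.ndarray):
    pred = np.asarray(pred).astype(bool)
    truth = np.asarray(truth).astype(bool)
    tp = int(np.sum(pred & truth))
    tn = int(np.sum(~pred & ~truth))
    fp = int(np.sum(pred & ~truth))
    fn = int(np.sum(~pred & truth))
    return tp, tn, fp, fn


def _make_estimator(method: str, disease: str, variant: str, fold_seed: int,
                    cfg: EvalConfig):
    if method == "MM":
        return MechanisticClassifier(random_state=cfg.seed, **cfg.mm_kwargs)
    if method == "GLM":
        return FeatureLogisticClassifier(disease=disease, variant=variant,
                                         **cfg.glm_kwargs)
    if method == "NN":
        return SequenceLSTMClassifier(random_state=fold_seed,
                                      **cfg.nn_kwargs)
    raise ValueError(f"unknown method {method!r}")


def run_experiment(records: list[PatientRecord], cfg: EvalConfig) -> EvalReport:
    """Run the full variant x method grid under k-fold cross-validation."""
    if not records:
        raise ValueError("empty cohort")
    disease = records[0].disease
    degrade_cfg = cfg.degrade or DegradeConfig(disease, seed=cfg.seed)
    labels = np.array([r.relapse for r in records])
    if labels.sum() in (0, len(labels)):
        raise ValueError("cohort labels are degenerate")
    n = len(records)
    folds = kfold_split(n, cfg.k, cfg.seed, labels)
    trajs = make_variants(records, degrade_cfg, variants=cfg.variants)
    report = EvalReport(disease=disease, n=n, seed=cfg.seed)

    for variant in cfg.variants:
        inputs = make_patient_inputs(
            records,
            [split_windows(t, disease, r.schedule)[0]
             for t, r in zip(trajs[variant], records)],
            variant, lod=degrade_cfg.lod)
        if variant == "AS":
            # predictors must see the schedule actually administered
            # (half-dose pre-cessation year for CML)
            for inp, rec in zip(inputs, records):
                inp.schedule = as_schedule(rec)
        for method in cfg.methods:
            t0 = time.time()
            if method == "MM":
                # MM needs no training: fit every patient once, slice folds
                est = _make_estimator("MM", disease, variant, cfg.seed, cfg)
                est.fit(inputs)
                pred_all = est.predict(inputs)
                fold_preds = [pred_all[f] for f in folds]
            else:
                fold_preds = []
                for fi, test_idx in enumerate(folds):
                    train_idx = np.setdiff1d(np.arange(n), test_idx)
                    est = _make_estimator(method, disease, variant,
                                          (cfg.seed * 1000 + fi) % (2 ** 31),
                                          cfg)
                    est.fit([inputs[i] for i in train_idx], labels[train_idx])
                    fold_preds.append(
                        est.predict([inputs[i] for i in test_idx]))
            cell = Cell(fold_acc=[], confusion=[])
            for test_idx, pred in zip(folds, fold_preds):
                tp, tn, fp, fn = _confusion(pred, labels[test_idx])
                cell.confusion.append((tp, tn, fp, fn))
                cell.fold_acc.append(accuracy(tp, tn, fp, fn))
            report.cells[(variant, method)] = cell
            report.timings[f"{variant}|{method}"] = time.time() - t0
            logger.info("%s %s %s: %.3f +/- %.3f (%.1fs)", disease, variant,
                        method, cell.mean, cell.sd,
                        report.timings[f"{variant}|{method}"])
    return report
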
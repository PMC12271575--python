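"""Cross-validated training protocol and classification metrics.

Folds are stratified on the IS label; each fold's training portion is
balanced by randomly downsampling controls to the case count, and every
control excluded from training joins that fold's evaluation pool. AUROC is
the Mann-Whitney pair statistic (ties count 1/2) with optional stratified
bootstrap confidence intervals.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold

from .genodata import DISEASES
from .model import BackboneConfig, MetaGenoModel, TrainConfig, fit

logger = logging.getLogger(__name__)


@dataclass
class FoldPlan:
    k: int
    seed: int
    assignments: np.ndarray          # validation-fold index per sample
    train_indices: list              # balanced training indices per fold
    eval_indices: list               # validation fold + excluded controls
    val_indices: list                # validation fold only

    def validate(self, is_labels: np.ndarray) -> None:
        n = len(self.assignments)
        all_val = np.concatenate(self.val_indices)
        assert len(all_val) == n and len(np.unique(all_val)) == n, \
            "validation folds must partition the cohort"
        for tr in self.train_indices:
            y = is_labels[tr]
            assert (y == 1).sum() == (y == 0).sum(), \
                "training folds must be case/control balanced"


def make_fold_plan(is_labels: np.ndarray, k: int = 5, seed: int = 0) -> FoldPlan:
    """Stratified k-fold plan with balanced training folds.

    Training uses all cases of the fold's 80% plus an equal-sized random
    control subset; excluded controls are evaluated with that fold's model.
    """
    y = np.asarray(is_labels).astype(int)
    n_cases = int((y == 1).sum())
    n_controls = int((y == 0).sum())
    if n_cases < k or n_controls < k:
        raise ValueError(f"need at least {k} cases and controls for {k} folds")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    assignments = np.empty(len(y), dtype=int)
    train_indices, eval_indices, val_indices = [], [], []
    for fold, (tr, va) in enumerate(skf.split(np.zeros(len(y)), y)):
        assignments[va] = fold
        cases = tr[y[tr] == 1]
        controls = tr[y[tr] == 0]
        rng = np.random.default_rng(seed * 1000 + fold)
        sampled = rng.choice(controls, size=len(cases), replace=False)
        excluded = np.setdiff1d(controls, sampled)
        train = np.sort(np.concatenate([cases, sampled]))
        train_indices.append(train)
        eval_indices.append(np.sort(np.concatenate([va, excluded])))
        val_indices.append(np.sort(va))
    plan = FoldPlan(k=k, seed=seed, assignments=assignments,
                    train_indices=train_indices, eval_indices=eval_indices,
                    val_indices=val_indices)
    plan.validate(y)
    return plan


def auroc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mann-Whitney AUROC; tied scores count half a concordant pair."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n1 = int(labels.sum())
    n0 = len(labels) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("auroc needs both classes present")
    ranks = stats.rankdata(scores)
    return float((ranks[labels == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def auroc_ci(scores: np.ndarray, labels: np.ndarray, n_boot: int = 1000,
             seed: int = 0, alpha: float = 0.05) -> tuple:
    """(auroc, lo, hi) with a stratified percentile bootstrap CI."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    point = auroc(scores, labels)
    rng = np.random.default_rng(seed)
    cases = np.where(labels == 1)[0]
    controls = np.where(labels == 0)[0]
    vals = np.empty(n_boot)
    for b in range(n_boot):
        ci = rng.choice(cases, size=len(cases), replace=True)
        co = rng.choice(controls, size=len(controls), replace=True)
        idx = np.concatenate([ci, co])
        vals[b] = auroc(scores[idx], labels[idx])
    lo, hi = np.quantile(vals, [alpha / 2, 1 - alpha / 2])
    return point, float(lo), float(hi)


def precision_recall_f1(scores: np.ndarray, labels: np.ndarray,
                        threshold: float = 0.5) -> tuple:
    """Confusion-matrix precision, recall and F1 at the given threshold."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if labels.min() == labels.max():
        raise ValueError("both classes must be present")
    pred = (scores >= threshold).astype(int)
    tp = int(((pred == 1) & (labels == 1)).sum())
    fp = int(((pred == 1) & (labels == 0)).sum())
    fn = int(((pred == 0) & (labels == 1)).sum())
    if tp + fp == 0:
        warnings.warn("no predicted positives; precision reported as 0")
        precision = 0.0
    else:
        precision = tp / (tp + fp)
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall else 0.0)
    return precision, recall, f1


@dataclass
class ExperimentConfig:
    """Everything needed to train and evaluate one cross-validated run."""

    d: int = 8
    mode: str = "chromosome_wise"
    missing_policy: str = "state"
    backbone: BackboneConfig = field(default_factory=BackboneConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    k: int = 5
    seed: int = 0
    positional: bool = True


@dataclass
class ExperimentResult:
    metrics: pd.DataFrame        # tidy: fold, task, auroc, precision, recall, f1
    oof_scores: np.ndarray       # out-of-fold IS risk score per sample
    oof_fold: np.ndarray         # which fold's model produced each score
    models: list                 # one trained model per fold

    def mean_auroc(self, task: str = "IS") -> float:
        sub = self.metrics[self.metrics.task == task]
        return float(sub.auroc.mean())


def run_experiment(states: np.ndarray, labels: np.ndarray, groups,
                   config: ExperimentConfig,
                   plan: Optional[FoldPlan] = None) -> ExperimentResult:
    """Train one model per fold and evaluate all six tasks out of fold.

    Out-of-fold IS scores come exclusively from the model of the fold in
    which a sample sits in the validation set, so no model ever scores a
    sample it was trained on.
    """
    labels = np.asarray(labels)
    y_is = labels[:, 0]
    if plan is None:
        plan = make_fold_plan(y_is, k=config.k, seed=config.seed)
    V = 4 if config.missing_policy == "state" else 3
    rows = []
    oof = np.full(len(states), np.nan)
    oof_fold = np.full(len(states), -1, dtype=int)
    models = []
    for fold in range(plan.k):
        tr = plan.train_indices[fold]
        ev = plan.eval_indices[fold]
        model = MetaGenoModel(groups, d=config.d, V=V, mode=config.mode,
                              backbone=config.backbone,
                              seed=config.seed * 100 + fold,
                              positional=config.positional)
        fit(model, states[tr], labels[tr],
            TrainConfig(lr=config.train.lr, batch_size=config.train.batch_size,
                        epochs=config.train.epochs,
                        seed=config.seed * 100 + fold,
                        task_weights=config.train.task_weights))
        assert not np.intersect1d(tr, plan.val_indices[fold]).size, \
            "fold leakage: training overlaps validation"
        preds = model.predict(states[ev])
        for ti, task in enumerate(DISEASES):
            if config.train.task_weights[ti] == 0:
                continue
            yt = labels[ev, ti]
            if yt.min() == yt.max():
                logger.warning("fold %d task %s single-class; skipped", fold, task)
                continue
            p, r, f1 = precision_recall_f1(preds.probs[:, ti], yt)
            rows.append({"fold": fold, "task": task,
                         "auroc": auroc(preds.probs[:, ti], yt),
                         "precision": p, "recall": r, "f1": f1})
        va = plan.val_indices[fold]
        oof[va] = preds.probs[np.searchsorted(ev, va), 0]
        oof_fold[va] = fold
        models.append(model)
    return ExperimentResult(pd.DataFrame(rows), oof, oof_fold, models)
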
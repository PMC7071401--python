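"""Repeated 80/20 split evaluation with a logistic-regression comparator.

Out-of-sample performance is assessed on several independent random
stratified train (80%) / test (20%) splits.  Within every training split
the whole preprocessing chain is refit — Spearman screening of the DBM
regions against the raw year-t score, median imputation, min–max scaling —
so no held-out information leaks into the model.  Both the stacked sparse
autoencoder and a hand-rolled Newton–Raphson (IRLS) logistic regression are
evaluated on identical splits, reporting accuracy, sensitivity and
specificity (positive class = the impaired category).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit as sigmoid

from .cohort import CohortTable, OutcomeLabels
from .feature_selection import ScreenResult, select_features
from .preprocessing import (ScalerParams, exclude_incomplete, fit_scaler,
                            impute_median, scale_matrix)
from . import sparse_autoencoder as sae


# ----------------------------------------------------------------------
# split plans


@dataclass
class SplitPlan:
    """Recipe for repeated random train/test splits."""

    n_splits: int = 5
    train_fraction: float = 0.8
    stratified: bool = True
    seed: int = 0
    splits: list[tuple[list, list]] = field(default_factory=list)


def make_splits(subject_ids, labels, plan: SplitPlan) -> SplitPlan:
    """Populate *plan* with deterministic random splits.

    Each test set holds ``round((1 - train_fraction) * n)`` subjects; in
    stratified mode class proportions are preserved to within one subject.
    Splits whose training half lacks a class are redrawn (at most 20
    attempts each).
    """
    subject_ids = np.asarray(subject_ids)
    y = np.asarray(labels)
    n = len(subject_ids)
    if n < 5:
        raise ValueError("need at least 5 subjects to split")
    if len(np.unique(y)) < 2:
        raise ValueError("both outcome classes must be present")
    n_test = int(round((1 - plan.train_fraction) * n))
    rng = np.random.default_rng(plan.seed)
    splits = []
    for _ in range(plan.n_splits):
        for _attempt in range(20):
            test_idx = _draw_test(rng, y, n, n_test, plan.stratified)
            train_mask = np.ones(n, bool)
            train_mask[test_idx] = False
            if len(np.unique(y[train_mask])) == 2:
                break
        splits.append((list(subject_ids[train_mask]), list(subject_ids[test_idx])))
    out = replace(plan)
    out.splits = splits
    return out


def _draw_test(rng, y, n, n_test, stratified):
    if not stratified:
        return rng.permutation(n)[:n_test]
    test_idx = []
    classes, counts = np.unique(y, return_counts=True)
    # largest-remainder apportionment of the test quota across classes
    quota = counts * n_test / n
    base = np.floor(quota).astype(int)
    rem = n_test - base.sum()
    order = np.argsort(-(quota - base))
    base[order[:rem]] += 1
    for cls, k in zip(classes, base):
        members = np.flatnonzero(y == cls)
        test_idx.extend(rng.permutation(members)[:k])
    return np.array(sorted(test_idx))


# ----------------------------------------------------------------------
# logistic regression (IRLS)


@dataclass
class LogisticModel:
    coef: np.ndarray
    intercept: float
    n_iter: int
    converged: bool


def train_logistic_regression(X, y, l2: float = 0.0, max_iter: int = 100,
                              tol: float = 1e-8) -> LogisticModel:
    """Fit binary logistic regression by Newton–Raphson (IRLS).

    Minimises the cross-entropy with an optional ridge penalty
    ``l2/2 * ||coef||^2`` (intercept unpenalised).  Iterations are capped at
    *max_iter* so perfectly separable data terminate; with ``l2 = 0`` and
    no separation, non-convergence raises a diagnostic.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    if len(np.unique(y)) < 2:
        raise ValueError("labels contain a single class")
    n, d = X.shape
    Xb = np.hstack([np.ones((n, 1)), X])
    w = np.zeros(d + 1)
    pen = np.full(d + 1, l2); pen[0] = 0.0
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        p = sigmoid(Xb @ w)
        grad = Xb.T @ (p - y) / n + pen * w
        if np.linalg.norm(grad) < tol:
            converged = True
            break
        s = np.clip(p * (1 - p), 1e-10, None)
        H = (Xb * s[:, None]).T @ Xb / n + np.diag(pen) + 1e-12 * np.eye(d + 1)
        w = w - np.linalg.solve(H, grad)
    separable = np.all((sigmoid(Xb @ w) > 0.5) == (y == 1)) and np.abs(w).max() > 10
    if not converged and not separable and l2 == 0:
        raise RuntimeError(f"IRLS failed to converge in {max_iter} iterations")
    return LogisticModel(w[1:], float(w[0]), it, converged)


def lr_predict_proba(model: LogisticModel, X) -> np.ndarray:
    """Subject x 2 probability matrix, columns (class 0, class 1)."""
    p1 = sigmoid(np.asarray(X, float) @ model.coef + model.intercept)
    return np.column_stack([1 - p1, p1])


# ----------------------------------------------------------------------
# metrics


def confusion_metrics(y_true, y_pred, positive_class: int = 1) -> dict:
    """Accuracy, sensitivity, specificity and confusion counts.

    *y_pred* may be hard labels or an (n, 2) probability matrix, in which
    case the prediction is argmax with probability ties going to the
    positive class.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.size == 0:
        raise ValueError("empty input")
    if y_pred.ndim == 2:
        pos_col = 1 if positive_class == 1 else 0
        y_pred = np.where(y_pred[:, pos_col] >= 0.5, positive_class, 1 - positive_class)
    if y_pred.shape != y_true.shape:
        raise ValueError("prediction and truth are misaligned")
    pos = y_true == positive_class
    hit = y_pred == y_true
    tp = int(np.sum(pos & hit)); fn = int(np.sum(pos & ~hit))
    tn = int(np.sum(~pos & hit)); fp = int(np.sum(~pos & ~hit))
    return {
        "TP": tp, "TN": tn, "FP": fp, "FN": fn,
        "accuracy": (tp + tn) / len(y_true),
        "sensitivity": tp / (tp + fn) if tp + fn else np.nan,
        "specificity": tn / (tn + fp) if tn + fp else np.nan,
    }


# ----------------------------------------------------------------------
# the fitted pipeline object


@dataclass
class ModelSpec:
    """Which model(s) to fit and with what settings."""

    kind: str = "autoencoder"  # "autoencoder" | "logistic"
    hidden_sizes: tuple[int, ...] = (20, 10)
    hyper_kwargs: dict = field(default_factory=dict)
    pretrain_iters: int = 150
    softmax_iters: int = 150
    finetune_iters: int = 300
    lr_ridge: float = 1e-3
    screen_alpha: float = 0.05
    screen_dbm_only: bool = True
    include_controls: bool = False


@dataclass
class FittedModel:
    """A trained classifier plus the frozen preprocessing needed to apply it
    to raw cohort tables (feature list, training medians, scaler)."""

    kind: str
    classifier: object
    feature_names: list[str]
    medians: pd.Series
    scaler: ScalerParams
    screen_results: list[ScreenResult]
    modality: str
    year: int

    def design_matrix(self, table: CohortTable) -> np.ndarray:
        vals = table.values[self.feature_names].fillna(self.medians[self.feature_names])
        return scale_matrix(vals, self.scaler)

    def predict_proba(self, table: CohortTable) -> np.ndarray:
        X = self.design_matrix(table)
        if self.kind == "logistic":
            return lr_predict_proba(self.classifier, X)
        return sae.predict_proba(self.classifier, X)


def fit_prognostic_model(
    table: CohortTable,
    outcomes: OutcomeLabels,
    year: int,
    modality: str,
    spec: ModelSpec,
    train_ids=None,
    seed: int = 0,
) -> FittedModel:
    """Fit the full chain (screen -> impute -> scale -> classify) on the
    given training subjects (default: all patients after exclusion)."""
    work = exclude_incomplete(table)
    if not spec.include_controls:
        work = work.subset(work.patient_ids)
    if train_ids is None:
        train_ids = work.subject_ids
    train_ids = [s for s in train_ids if s in work.subject_ids]

    train_tab = work.subset(train_ids)
    target = outcomes.raw_scores[modality].loc[train_ids, year].to_numpy(float)
    labels = outcomes.categories[modality].loc[train_ids, year].to_numpy(int)

    candidates = work.dbm_columns if spec.screen_dbm_only else list(work.values.columns)
    train_imp = impute_median(train_tab, train_ids)
    results = select_features(train_imp, target, candidates, alpha=spec.screen_alpha)
    selected_dbm = [r.feature for r in results if r.selected]
    if spec.screen_dbm_only:
        non_dbm = [c for c in work.values.columns if c not in work.dbm_columns]
        feature_names = selected_dbm + non_dbm
    else:
        feature_names = selected_dbm
    if not feature_names:  # degenerate screen: fall back to every candidate
        feature_names = list(candidates)

    medians = train_imp.values.median(axis=0)
    scaler = fit_scaler(train_imp, train_ids, mode="minmax")
    X = scale_matrix(train_imp.values[feature_names], scaler)

    if spec.kind == "logistic":
        clf = train_logistic_regression(X, labels, l2=spec.lr_ridge)
    else:
        clf = sae.train_stacked_classifier(
            X, labels,
            hidden_sizes=spec.hidden_sizes,
            hyper_kwargs=dict(spec.hyper_kwargs),
            pretrain_iters=spec.pretrain_iters,
            softmax_iters=spec.softmax_iters,
            finetune_iters=spec.finetune_iters,
            seed=seed,
        )
    return FittedModel(spec.kind, clf, feature_names, medians, scaler, results, modality, year)


# ----------------------------------------------------------------------
# evaluation


@dataclass
class MetricReport:
    """Per-split and mean metrics for one (year, modality, model)."""

    model: str
    modality: str
    year: int
    per_split: list[dict]
    fitted: list[FittedModel] = field(default_factory=list)

    def mean(self, key: str) -> float:
        return float(np.nanmean([m[key] for m in self.per_split]))

    def summary(self) -> dict:
        return {k: self.mean(k) for k in ("accuracy", "sensitivity", "specificity")}

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.per_split)
        df.insert(0, "split", range(len(df)))
        df.insert(0, "year", self.year)
        df.insert(0, "modality", self.modality)
        df.insert(0, "model", self.model)
        return df

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps({
            "model": self.model, "modality": self.modality, "year": self.year,
            "per_split": self.per_split, "mean": self.summary(),
        }, indent=1))


def evaluate_pipeline(
    table: CohortTable,
    outcomes: OutcomeLabels,
    year: int,
    modality: str,
    spec: ModelSpec,
    plan: SplitPlan | None = None,
    keep_models: bool = False,
) -> MetricReport:
    """Repeated-split out-of-sample evaluation of one model spec.

    Screening, imputation and scaling are refit inside every training
    split.  Pass the same *plan* to different specs to compare models on
    identical splits.
    """
    plan = plan or SplitPlan()
    work = exclude_incomplete(table)
    if not spec.include_controls:
        work = work.subset(work.patient_ids)
    ids = work.subject_ids
    y_all = outcomes.categories[modality].loc[ids, year]
    if not plan.splits:
        plan = make_splits(ids, y_all.to_numpy(int), plan)

    per_split = []
    fitted_models = []
    for si, (train_ids, test_ids) in enumerate(plan.splits):
        fitted = fit_prognostic_model(table, outcomes, year, modality, spec,
                                      train_ids=train_ids, seed=plan.seed * 100 + si)
        proba = fitted.predict_proba(work.subset(test_ids))
        y_test = y_all.loc[test_ids].to_numpy(int)
        m = confusion_metrics(y_test, proba)
        m["n_test"] = len(test_ids)
        per_split.append(m)
        if keep_models:
            fitted_models.append(fitted)
    return MetricReport(spec.kind, modality, year, per_split, fitted=fitted_models)


def compare_models(table, outcomes, year, modality, plan: SplitPlan | None = None,
                   ae_spec: ModelSpec | None = None, lr_spec: ModelSpec | None = None,
                   keep_models: bool = False) -> dict[str, MetricReport]:
    """Autoencoder vs logistic regression on identical splits."""
    ae_spec = ae_spec or ModelSpec(kind="autoencoder")
    lr_spec = lr_spec or replace(ae_spec, kind="logistic")
    plan = plan or SplitPlan()
    work = exclude_incomplete(table)
    if not ae_spec.include_controls:
        work = work.subset(work.patient_ids)
    if not plan.splits:
        labels = outcomes.categories[modality].loc[work.subject_ids, year].to_numpy(int)
        plan = make_splits(work.subject_ids, labels, plan)
    return {
        "autoencoder": evaluate_pipeline(table, outcomes, year, modality, ae_spec, plan, keep_models),
        "logistic": evaluate_pipeline(table, outcomes, year, modality, lr_spec, plan, keep_models),
    }
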
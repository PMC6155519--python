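"""Preictal/interictal labeling, feature selection, cost-sensitive SVM
classification and the two evaluation protocols.

Windows are labeled from seizure annotations: ictal if they overlap a
seizure, preictal if they lie entirely inside the 15 minutes before an
onset, interictal only when at least 50 minutes from every onset and
offset; everything else (boundary-straddling and postictal buffer
windows) is excluded.  Features are chosen by stepwise regression on the
training rows, and a cost-sensitive RBF-SVM — the minority preictal
class weighted by the interictal/preictal count ratio — is tuned by
class-weighted five-fold cross-validation over a log grid of (C, gamma).

Two protocols are provided: a stratified 80/20 holdout (experiment 1)
and, for patients with at least three seizures, a chronological double
cross-validation that trains on earlier seizure blocks and tests on the
next unseen one (experiment 2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.svm import SVC

from .features import FEATURE_NAMES
from .records import SeizureAnnotation, check_annotations

__all__ = [
    "PREICTAL_SPAN_S",
    "INTERICTAL_MARGIN_S",
    "SelectionResult",
    "CSVMModel",
    "ConfusionCounts",
    "PerformanceReport",
    "PipelineConfig",
    "label_windows",
    "stepwise_select",
    "train_csvm",
    "confusion",
    "evaluate",
    "prediction_time",
    "experiment1_holdout",
    "experiment2_double_cv",
]

PREICTAL_SPAN_S = 15 * 60.0
INTERICTAL_MARGIN_S = 50 * 60.0


@dataclass
class PipelineConfig:
    p_enter: float = 0.05
    p_exit: float = 0.10
    c_grid: tuple[float, ...] = tuple(2.0 ** np.arange(-5, 16, 2))
    gamma_grid: tuple[float, ...] = tuple(2.0 ** np.arange(-15, 4, 2))
    cv_folds: int = 5
    test_fraction: float = 0.2
    preictal_span_s: float = PREICTAL_SPAN_S
    interictal_margin_s: float = INTERICTAL_MARGIN_S


def label_windows(features: pd.DataFrame,
                  annotations: Sequence[SeizureAnnotation],
                  config: PipelineConfig | None = None) -> pd.DataFrame:
    """Attach a state label to every feature window.

    Expects ``start_s``/``end_s`` columns; adds ``label`` and, for
    preictal windows, ``seizure_index`` (which annotation they precede).
    """
    cfg = config or PipelineConfig()
    anns = check_annotations(annotations)
    out = features.copy()
    labels = []
    seizure_idx = []
    for s, e in zip(out["start_s"], out["end_s"]):
        label, sk = "interictal", -1
        for k, a in enumerate(anns):
            if s < a.offset_s and e > a.onset_s:
                label, sk = "ictal", k
                break
            if a.onset_s - cfg.preictal_span_s <= s and e <= a.onset_s:
                label, sk = "preictal", k
                break
        if label == "interictal":
            for a in anns:
                if not (e <= a.onset_s - cfg.interictal_margin_s
                        or s >= a.offset_s + cfg.interictal_margin_s):
                    label = "excluded"
                    break
        labels.append(label)
        seizure_idx.append(sk)
    out["label"] = labels
    out["seizure_index"] = seizure_idx
    return out


@dataclass
class SelectionResult:
    selected: list[str]
    trace: list[tuple[str, str, float]] = field(default_factory=list)
    p_enter: float = 0.05
    p_exit: float = 0.10


def _ols_sse(X: np.ndarray, y: np.ndarray) -> float:
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ coef
    return float(r @ r)


def _partial_f_pvalue(X_small: np.ndarray, X_big: np.ndarray,
                      y: np.ndarray) -> float:
    """p-value of the F-test comparing nested linear models."""
    n = y.size
    sse_s = _ols_sse(X_small, y)
    sse_b = _ols_sse(X_big, y)
    df_b = n - X_big.shape[1]
    if df_b <= 0:
        return 1.0
    num = max(sse_s - sse_b, 0.0)
    den = sse_b / df_b
    if den <= 0:
        return 0.0 if num > 0 else 1.0
    return float(stats.f.sf(num / den, 1, df_b))


def stepwise_select(X: np.ndarray, y: np.ndarray,
                    feature_names: Sequence[str] | None = None,
                    p_enter: float = 0.05, p_exit: float = 0.10,
                    max_steps: int = 200) -> SelectionResult:
    """Forward-backward stepwise regression on a 0/1 response.

    Starting from an intercept-only multilinear model, the out-of-model
    term with the smallest partial-F p-value below ``p_enter`` is added,
    then any in-model term whose p-value exceeds ``p_exit`` is removed
    (largest first), until no step changes the model.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    names = list(feature_names) if feature_names is not None \
        else [f"x{j}" for j in range(p)]
    if len(set(names)) != p:
        raise ValueError("feature names must be unique")
    # standardize; constant columns are unusable and dropped
    mu, sd = X.mean(axis=0), X.std(axis=0)
    usable = sd > 0
    if not usable.all():
        warnings.warn("dropping constant feature columns: "
                      + ", ".join(np.array(names)[~usable]))
    Z = np.zeros_like(X)
    Z[:, usable] = (X[:, usable] - mu[usable]) / sd[usable]

    ones = np.ones((n, 1))
    selected: list[int] = []
    trace: list[tuple[str, str, float]] = []

    def design(idx: list[int]) -> np.ndarray:
        return np.hstack([ones] + [Z[:, [j]] for j in idx])

    for _ in range(max_steps):
        changed = False
        # entry step
        X_cur = design(selected)
        best_j, best_p = -1, 1.0
        for j in range(p):
            if not usable[j] or j in selected:
                continue
            pv = _partial_f_pvalue(X_cur, design(selected + [j]), y)
            if pv < best_p:
                best_j, best_p = j, pv
        if best_j >= 0 and best_p < p_enter:
            selected.append(best_j)
            trace.append(("add", names[best_j], best_p))
            changed = True
        # removal step
        while len(selected) > 0:
            X_cur = design(selected)
            pvals = [_partial_f_pvalue(design([k for k in selected if k != j]),
                                       X_cur, y) for j in selected]
            worst = int(np.argmax(pvals))
            if pvals[worst] > p_exit:
                j = selected.pop(worst)
                trace.append(("remove", names[j], pvals[worst]))
                changed = True
            else:
                break
        if not changed:
            break

    return SelectionResult(selected=[names[j] for j in selected],
                           trace=trace, p_enter=p_enter, p_exit=p_exit)


@dataclass
class CSVMModel:
    """Trained cost-sensitive RBF-SVM with its preprocessing state."""

    svc: SVC
    scaler_mean: np.ndarray
    scaler_sd: np.ndarray
    selected: list[str]
    C: float
    gamma: float
    class_weight: dict
    cv_loss: float

    def transform(self, features: pd.DataFrame) -> np.ndarray:
        X = features[self.selected].to_numpy(dtype=float)
        return (X - self.scaler_mean) / self.scaler_sd

    def predict(self, features: pd.DataFrame) -> np.ndarray:
        return self.svc.predict(self.transform(features))

    def decision_function(self, features: pd.DataFrame) -> np.ndarray:
        return self.svc.decision_function(self.transform(features))


def _weighted_cv_loss(X: np.ndarray, y: np.ndarray, C: float, gamma: float,
                      class_weight: dict, folds: int, seed: int) -> float:
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    num = den = 0.0
    for tr, te in skf.split(X, y):
        clf = SVC(C=C, gamma=gamma, kernel="rbf", class_weight=class_weight)
        clf.fit(X[tr], y[tr])
        pred = clf.predict(X[te])
        w = np.where(y[te] == 1, class_weight[1], class_weight[0])
        num += float(np.sum(w * (pred != y[te])))
        den += float(np.sum(w))
    return num / den if den else 1.0


def train_csvm(features: pd.DataFrame, y: np.ndarray,
               selected: Sequence[str], seed: int = 0,
               config: PipelineConfig | None = None) -> CSVMModel:
    """Fit the cost-sensitive RBF-SVM with grid-searched (C, gamma).

    The preictal class weight is the interictal/preictal training-count
    ratio; (C, gamma) minimize the class-weighted stratified five-fold
    cross-validation misclassification loss.
    """
    cfg = config or PipelineConfig()
    selected = list(selected)
    if not selected:
        raise ValueError("empty selected-feature set")
    y = np.asarray(y, dtype=int)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("training data must contain both classes")
    n_inter = int(np.sum(y == 0))
    n_pre = int(np.sum(y == 1))
    class_weight = {0: 1.0, 1: n_inter / n_pre}

    X = features[selected].to_numpy(dtype=float)
    mean, sd = X.mean(axis=0), X.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    Z = (X - mean) / sd

    folds = min(cfg.cv_folds, n_pre, n_inter)
    best = (np.inf, None, None)
    if folds >= 2:
        for C in cfg.c_grid:
            for gamma in cfg.gamma_grid:
                loss = _weighted_cv_loss(Z, y, C, gamma, class_weight,
                                         folds, seed)
                if loss < best[0]:
                    best = (loss, C, gamma)
    if best[1] is None:
        best = (np.nan, 1.0, 1.0 / len(selected))

    loss, C, gamma = best
    svc = SVC(C=C, gamma=gamma, kernel="rbf", class_weight=class_weight)
    svc.fit(Z, y)
    return CSVMModel(svc=svc, scaler_mean=mean, scaler_sd=sd,
                     selected=selected, C=float(C), gamma=float(gamma),
                     class_weight=class_weight, cv_loss=float(loss))


@dataclass
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int
    interictal_hours: float = 0.0


@dataclass
class PerformanceReport:
    sensitivity: float
    specificity: float
    accuracy: float
    fp_per_hour: float
    counts: ConfusionCounts | None = None
    prediction_times_min: list[float | None] = field(default_factory=list)
    meta: dict = field(default_factory=dict)


def confusion(y_true: np.ndarray, y_pred: np.ndarray,
              interictal_hours: float = 0.0) -> ConfusionCounts:
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    return ConfusionCounts(
        TP=int(np.sum((y_true == 1) & (y_pred == 1))),
        TN=int(np.sum((y_true == 0) & (y_pred == 0))),
        FP=int(np.sum((y_true == 0) & (y_pred == 1))),
        FN=int(np.sum((y_true == 1) & (y_pred == 0))),
        interictal_hours=interictal_hours,
    )


def evaluate(counts: ConfusionCounts) -> PerformanceReport:
    """Sens/Spec/Acc (percent) and FP per interictal hour; NaN when undefined."""
    tp, tn, fp, fn = counts.TP, counts.TN, counts.FP, counts.FN
    sens = 100.0 * tp / (tp + fn) if tp + fn else float("nan")
    spec = 100.0 * tn / (tn + fp) if tn + fp else float("nan")
    total = tp + tn + fp + fn
    acc = 100.0 * (tp + tn) / total if total else float("nan")
    fph = fp / counts.interictal_hours if counts.interictal_hours > 0 \
        else float("nan")
    return PerformanceReport(sensitivity=sens, specificity=spec,
                             accuracy=acc, fp_per_hour=fph, counts=counts)


def prediction_time(windows: pd.DataFrame, predictions: np.ndarray,
                    onset_s: float,
                    preictal_span_s: float = PREICTAL_SPAN_S) -> float | None:
    """Minutes between the earliest preictal-classified window and onset.

    Only windows truly inside the 15-min pre-onset span count; earlier
    alarms are false positives, not predictions.  None if the seizure is
    missed.
    """
    in_span = ((windows["start_s"] >= onset_s - preictal_span_s)
               & (windows["end_s"] <= onset_s))
    hit = in_span.to_numpy() & (np.asarray(predictions) == 1)
    if not hit.any():
        return None
    first_end = float(windows.loc[hit, "end_s"].min())
    return (onset_s - first_end) / 60.0


def _union_hours(spans: pd.DataFrame) -> float:
    """Total unique time (hours) covered by possibly overlapping windows."""
    if len(spans) == 0:
        return 0.0
    iv = sorted(zip(spans["start_s"], spans["end_s"]))
    total, cur_s, cur_e = 0.0, iv[0][0], iv[0][1]
    for s, e in iv[1:]:
        if s > cur_e:
            total += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    total += cur_e - cur_s
    return total / 3600.0


def _usable(labeled: pd.DataFrame) -> pd.DataFrame:
    rows = labeled[labeled["label"].isin(("preictal", "interictal"))]
    if "valid" in rows:
        rows = rows[rows["valid"]]
    return rows


def _fit_on(train: pd.DataFrame, seed: int,
            cfg: PipelineConfig) -> tuple[CSVMModel, SelectionResult]:
    y_tr = (train["label"] == "preictal").to_numpy(dtype=int)
    X_tr = train[list(FEATURE_NAMES)].to_numpy(dtype=float)
    sel = stepwise_select(X_tr, y_tr, FEATURE_NAMES,
                          p_enter=cfg.p_enter, p_exit=cfg.p_exit)
    if not sel.selected:
        # no feature passed entry; fall back to the single best candidate
        pvals = [_partial_f_pvalue(np.ones((len(y_tr), 1)),
                                   np.column_stack([np.ones(len(y_tr)),
                                                    X_tr[:, j]]), y_tr)
                 for j in range(X_tr.shape[1])]
        sel.selected = [FEATURE_NAMES[int(np.argmin(pvals))]]
    model = train_csvm(train, y_tr, sel.selected, seed=seed, config=cfg)
    return model, sel


def _score_on(model: CSVMModel, test: pd.DataFrame) -> PerformanceReport:
    y_te = (test["label"] == "preictal").to_numpy(dtype=int)
    pred = model.predict(test)
    hours = _union_hours(test[test["label"] == "interictal"])
    return evaluate(confusion(y_te, pred, interictal_hours=hours))


def experiment1_holdout(labeled: pd.DataFrame, seed: int = 0,
                        config: PipelineConfig | None = None
                        ) -> PerformanceReport:
    """Stratified 80/20 holdout on one patient's windows.

    Feature selection, scaling and the (C, gamma) search all run on the
    80% training split only; metrics and FP/h come from the 20% test
    split.
    """
    cfg = config or PipelineConfig()
    rows = _usable(labeled)
    y = (rows["label"] == "preictal").to_numpy(dtype=int)
    if np.sum(y == 1) < 2 or np.sum(y == 0) < 5:
        raise ValueError("too few preictal/interictal windows for a "
                         "stratified holdout")
    idx_tr, idx_te = train_test_split(np.arange(len(rows)),
                                      test_size=cfg.test_fraction,
                                      random_state=seed, stratify=y)
    train, test = rows.iloc[idx_tr], rows.iloc[idx_te]
    model, sel = _fit_on(train, seed, cfg)
    report = _score_on(model, test)
    report.meta = {"protocol": "experiment1", "seed": seed,
                   "selected_features": sel.selected,
                   "C": model.C, "gamma": model.gamma,
                   "class_weight": model.class_weight}
    return report


def experiment2_double_cv(labeled: pd.DataFrame,
                          annotations: Sequence[SeizureAnnotation],
                          seed: int = 0,
                          config: PipelineConfig | None = None
                          ) -> tuple[list[PerformanceReport],
                                     PerformanceReport]:
    """Chronological double cross-validation over seizure blocks.

    The recording is split into N blocks, one per seizure, at seizure
    offsets; block k holds its share of interictal data plus the 15-min
    preictal span of seizure k.  For k = 3..N the model (selection,
    scaler, hyperparameters) is fitted on blocks 1..k-1 and tested on
    block k, so training always precedes testing in time.  Returns the
    per-block reports and their average.
    """
    cfg = config or PipelineConfig()
    anns = check_annotations(annotations)
    n_seiz = len(anns)
    if n_seiz < 3:
        raise ValueError("double cross-validation needs at least 3 seizures "
                         "(two blocks for training)")
    rows = _usable(labeled)
    # block index: first annotation whose offset the window does not pass
    offsets = np.array([a.offset_s for a in anns])
    ends = rows["end_s"].to_numpy()
    block = np.searchsorted(offsets, ends, side="left")
    block = np.minimum(block, n_seiz - 1)

    reports: list[PerformanceReport] = []
    for k in range(2, n_seiz):
        train = rows[block < k]
        test = rows[block == k]
        if (train["label"] == "preictal").sum() < 2 or len(test) == 0:
            warnings.warn(f"block {k + 1}: insufficient data; skipped")
            continue
        model, sel = _fit_on(train, seed, cfg)
        report = _score_on(model, test)
        pt = prediction_time(test, model.predict(test), anns[k].onset_s,
                             cfg.preictal_span_s)
        report.prediction_times_min = [pt]
        report.meta = {"protocol": "experiment2", "block": k + 1,
                       "seed": seed, "selected_features": sel.selected,
                       "C": model.C, "gamma": model.gamma}
        reports.append(report)

    def _mean(vals):
        vals = [v for v in vals if v is not None and np.isfinite(v)]
        return float(np.mean(vals)) if vals else float("nan")

    avg = PerformanceReport(
        sensitivity=_mean([r.sensitivity for r in reports]),
        specificity=_mean([r.specificity for r in reports]),
        accuracy=_mean([r.accuracy for r in reports]),
        fp_per_hour=_mean([r.fp_per_hour for r in reports]),
        prediction_times_min=[pt for r in reports
                              for pt in r.prediction_times_min],
        meta={"protocol": "experiment2-average", "n_folds": len(reports)},
    )
    return reports, avg
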
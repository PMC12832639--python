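"""Classifier training, evaluation, calibration, decision curves and
sample-size planning.

Five model families are compared — random forest (RF), RBF support
vector machine (SVM), gradient-boosted trees (XGB), L2 logistic
regression (LR) and a decision tree (DT) — each tuned by repeated
stratified 10-fold cross-validation over a small grid, selecting the
highest mean ROC AUC (ties favour the simpler / more regularised
configuration, which is listed first in each grid).

The positive class (impaired) is encoded 1 and all probabilities are
positive-class probabilities.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import (RepeatedStratifiedKFold,
                                     train_test_split)
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from xgboost import XGBClassifier

from .recording import FEATURE_COLUMNS, OUTCOME_COLUMN

#: Classification threshold of the deployed clinical tool.
DEPLOYED_THRESHOLD = 0.4883

MODEL_FAMILIES = ("RF", "SVM", "XGB", "LR", "DT")


@dataclass(frozen=True)
class SplitSpec:
    """Hold-out split: 70% training / 30% test, stratified by outcome."""

    test_fraction: float = 0.3
    seed: int = 0
    stratified: bool = True

    def __post_init__(self):
        if not 0 < self.test_fraction < 1:
            raise ValueError("test fraction must be in (0, 1)")


def split_standardize(table: pd.DataFrame, spec: SplitSpec = SplitSpec(),
                      feature_cols=FEATURE_COLUMNS):
    """Stratified train/test split with train-only standardization.

    Per-feature mean/SD are computed on the training partition only and
    applied to both partitions (leakage guard).  Returns
    ``(train, test, scaler)`` with standardized feature columns.
    """
    feature_cols = list(feature_cols)
    y = table[OUTCOME_COLUMN]
    if y.value_counts().min() < 2:
        raise ValueError("need at least 2 subjects per class")
    train, test = train_test_split(
        table, test_size=spec.test_fraction, random_state=spec.seed,
        stratify=y if spec.stratified else None)
    for part, name in ((train, "training"), (test, "test")):
        if part[OUTCOME_COLUMN].nunique() < 2:
            raise ValueError(f"a class is absent from the {name} partition")
    scaler = StandardScaler().fit(train[feature_cols])
    train = train.copy()
    test = test.copy()
    train[feature_cols] = scaler.transform(train[feature_cols])
    test[feature_cols] = scaler.transform(test[feature_cols])
    return train, test, scaler


def _model_grids(seed: int):
    """Ordered (family, estimator, grid) triples.  Grid entries are
    listed simplest / most regularised first so argmax tie-breaking
    prefers them.  The RF grid contains the fixed reference
    configuration (50 trees, min_samples_split=10, unlimited depth,
    random_state=42)."""
    rf_grid = [dict(n_estimators=n, min_samples_split=s)
               for n in (50, 100, 200) for s in (10, 5, 2)]
    svm_grid = [dict(C=c, gamma=g)
                for c in (0.1, 1.0, 10.0) for g in ("scale", 0.01, 0.1)]
    xgb_grid = [dict(n_estimators=n, max_depth=d, learning_rate=lr)
                for n in (50, 200) for d in (2, 3, 4)
                for lr in (0.05, 0.1, 0.3)]
    lr_grid = [dict(C=c) for c in (0.01, 0.1, 1.0, 10.0, 100.0)]
    dt_grid = [dict(max_depth=d) for d in range(2, 9)]
    return {
        "RF": (RandomForestClassifier(max_depth=None, random_state=42,
                                      n_jobs=1), rf_grid),
        "SVM": (SVC(kernel="rbf", probability=True, random_state=seed),
                svm_grid),
        "XGB": (XGBClassifier(eval_metric="logloss", tree_method="hist",
                              n_jobs=1, random_state=seed), xgb_grid),
        "LR": (LogisticRegression(max_iter=5000), lr_grid),
        "DT": (DecisionTreeClassifier(random_state=seed), dt_grid),
    }


def _cv_auc(estimator, X, y, cv) -> np.ndarray:
    aucs = []
    for tr, te in cv.split(X, y):
        m = clone(estimator)
        m.fit(X[tr], y[tr])
        aucs.append(roc_auc_score(y[te], m.predict_proba(X[te])[:, 1]))
    return np.array(aucs)


@dataclass
class TrainedModel:
    name: str
    model: object
    best_params: dict
    cv_auc_mean: float
    cv_auc_sd: float
    feature_names: list


def train_models(train: pd.DataFrame, feature_cols, folds: int = 10,
                 seed: int = 0, n_repeats: int = 5,
                 families=MODEL_FAMILIES) -> dict:
    """Grid-search the five families with repeated stratified K-fold CV
    maximising mean AUC; refit each winner on the full training set."""
    feature_cols = list(feature_cols)
    X = train[feature_cols].to_numpy(dtype=np.float64)
    y = train[OUTCOME_COLUMN].to_numpy(dtype=np.int64)
    folds = min(folds, int(np.bincount(y).min()))
    if folds < 2:
        raise ValueError("too few subjects per class for cross-validation")
    cv = RepeatedStratifiedKFold(n_splits=folds, n_repeats=n_repeats,
                                 random_state=seed)
    out = {}
    for name, (base, grid) in _model_grids(seed).items():
        if name not in families:
            continue
        best = None
        for params in grid:
            aucs = _cv_auc(clone(base).set_params(**params), X, y, cv)
            if best is None or aucs.mean() > best[0]:
                best = (aucs.mean(), aucs.std(ddof=0), params)
        mean_auc, sd_auc, params = best
        final = clone(base).set_params(**params)
        final.fit(train[feature_cols], y)     # DataFrame keeps feature names
        out[name] = TrainedModel(name=name, model=final, best_params=params,
                                 cv_auc_mean=float(mean_auc),
                                 cv_auc_sd=float(sd_auc),
                                 feature_names=feature_cols)
    return out


def confusion_counts(y_true, y_pred):
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    tp = int(np.sum((y_pred == 1) & (y_true == 1)))
    tn = int(np.sum((y_pred == 0) & (y_true == 0)))
    fp = int(np.sum((y_pred == 1) & (y_true == 0)))
    fn = int(np.sum((y_pred == 0) & (y_true == 1)))
    return tp, fp, tn, fn


def metrics_from_counts(tp, fp, tn, fn) -> dict:
    def safe(num, den):
        return num / den if den else 0.0
    sens = safe(tp, tp + fn)
    spec = safe(tn, tn + fp)
    ppv = safe(tp, tp + fp)
    npv = safe(tn, tn + fn)
    return {
        "accuracy": safe(tp + tn, tp + fp + tn + fn),
        "sensitivity": sens, "specificity": spec,
        "ppv": ppv, "npv": npv,
        "f1": safe(2 * ppv * sens, ppv + sens) if (ppv + sens) else 0.0,
    }


def evaluate(probs, y, threshold: float = 0.5) -> dict:
    """Threshold-based metrics plus AUC and Brier score.

    Classification is positive when probability exceeds ``threshold``.
    Raises on a single-class test set (AUC undefined).
    """
    probs = np.asarray(probs, dtype=float)
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("AUC undefined: test set contains a single class")
    pred = (probs > threshold).astype(int)
    block = metrics_from_counts(*confusion_counts(y, pred))
    block["auc"] = float(roc_auc_score(y, probs))
    block["brier"] = float(np.mean((probs - y) ** 2))
    block["threshold"] = float(threshold)
    return block


def _reliability_curve(probs, y, bins):
    edges = np.linspace(0.0, 1.0, bins + 1)
    idx = np.clip(np.digitize(probs, edges[1:-1]), 0, bins - 1)
    rows = []
    for b in range(bins):
        sel = idx == b
        if not sel.any():
            continue
        rows.append((sel.mean(), float(probs[sel].mean()),
                     float(np.mean(y[sel]))))
    return rows          # (weight, mean predicted, observed rate)


def calibration_analysis(probs, y, bins: int = 10, boot: int = 200,
                         seed: int = 0, refit=None, X=None) -> dict:
    """Equal-width-bin calibration summary.

    ECE is the bin-weighted mean absolute gap between mean predicted
    probability and observed event rate; MCE is the maximum gap (so
    ECE <= MCE always).  If ``refit`` (a callable ``refit(X_boot,
    y_boot) -> probs on X``) and ``X`` are given, a bias-corrected
    reliability curve is added by refitting on bootstrap resamples,
    evaluating on the original sample and averaging the curves.
    """
    probs = np.asarray(probs, dtype=float)
    y = np.asarray(y, dtype=int)
    if probs.min() < 0 or probs.max() > 1:
        raise ValueError("probabilities must lie in [0, 1]")
    curve = _reliability_curve(probs, y, bins)
    gaps = np.array([abs(p - o) for _, p, o in curve])
    weights = np.array([w for w, _, _ in curve])
    result = {
        "ece": float(np.sum(weights * gaps)),
        "mce": float(gaps.max()) if gaps.size else 0.0,
        "curve": [(p, o) for _, p, o in curve],
    }
    if refit is not None:
        if X is None:
            raise ValueError("bias-corrected curve needs the design matrix X")
        rng = np.random.default_rng(seed)
        n = len(y)
        grid = np.linspace(0.05, 0.95, bins)
        acc = np.zeros(bins)
        n_ok = 0
        for _ in range(boot):
            idx = rng.integers(0, n, n)
            if len(np.unique(y[idx])) < 2:
                continue
            pb = np.clip(refit(X[idx], y[idx]), 0.0, 1.0)
            rows = _reliability_curve(pb, y, bins)
            if len(rows) < 2:
                continue
            xs = [p for _, p, _ in rows]
            os_ = [o for _, _, o in rows]
            acc += np.interp(grid, xs, os_)
            n_ok += 1
        if n_ok:
            result["bias_corrected_curve"] = list(
                zip(grid.tolist(), (acc / n_ok).tolist()))
    return result


def decision_curve(probs, y, thresholds=None) -> pd.DataFrame:
    """Decision-curve analysis.

    Net benefit at threshold probability pt is TP/n - (FP/n)*pt/(1-pt)
    when calling positive at probability >= pt; treat-all uses the same
    formula with everyone positive, treat-none is identically 0.
    """
    probs = np.asarray(probs, dtype=float)
    y = np.asarray(y, dtype=int)
    if thresholds is None:
        thresholds = np.arange(0.01, 1.0, 0.01)
    thresholds = np.asarray(thresholds, dtype=float)
    if np.any(thresholds >= 1.0) or np.any(thresholds <= 0.0):
        raise ValueError("thresholds must lie strictly inside (0, 1)")
    n = len(y)
    prevalence = y.mean()
    rows = []
    for pt in thresholds:
        pred = probs >= pt
        tp = np.sum(pred & (y == 1)) / n
        fp = np.sum(pred & (y == 0)) / n
        odds = pt / (1.0 - pt)
        rows.append({
            "threshold": pt,
            "net_benefit": tp - fp * odds,
            "treat_all": prevalence - (1.0 - prevalence) * odds,
            "treat_none": 0.0,
        })
    return pd.DataFrame(rows)


def bootstrap_ci(metric_fn, y, probs, B: int = 1000, seed: int = 0,
                 level: float = 0.95, max_redraws: int = 100):
    """Percentile bootstrap interval for ``metric_fn(y, probs)``.

    Subjects are resampled with replacement; resamples on which the
    metric is undefined (single class) are redrawn, with the count
    reported.
    """
    if B < 100:
        raise ValueError("use at least 100 bootstrap resamples")
    y = np.asarray(y)
    probs = np.asarray(probs, dtype=float)
    rng = np.random.default_rng(seed)
    n = len(y)
    values = np.empty(B)
    redraws = 0
    for b in range(B):
        for _ in range(max_redraws):
            idx = rng.integers(0, n, n)
            try:
                values[b] = metric_fn(y[idx], probs[idx])
                break
            except ValueError:
                redraws += 1
        else:
            raise RuntimeError("metric undefined on every redrawn resample")
    lo, hi = np.percentile(values, [(1 - level) / 2 * 100,
                                    (1 + level) / 2 * 100])
    return float(lo), float(hi), redraws


def optimal_threshold(probs, y) -> float:
    """Probability threshold maximising Youden's J (sens + spec - 1).

    Youden's J is piecewise constant between consecutive distinct
    probabilities, so candidate thresholds are the midpoints of those
    gaps: a perfectly separating gap returns its midpoint.  Ties pick
    the lowest threshold.
    """
    probs = np.asarray(probs, dtype=float)
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes required")
    uniq = np.unique(probs)
    if uniq.size == 1:
        return float(uniq[0])
    candidates = (uniq[:-1] + uniq[1:]) / 2.0
    best_j, best_t = -np.inf, candidates[0]
    for t in candidates:
        pred = (probs > t).astype(int)
        tp, fp, tn, fn = confusion_counts(y, pred)
        j = (tp / (tp + fn) if tp + fn else 0.0) + \
            (tn / (tn + fp) if tn + fp else 0.0) - 1.0
        if j > best_j + 1e-12:
            best_j, best_t = j, t
    return float(best_t)


def epv_min_sample_size(n_vars: int, epv: float, incidence: float) -> int:
    """Minimum total sample size under the events-per-variable rule:
    ceil(n_vars * epv / (1 - incidence))."""
    if n_vars < 1:
        raise ValueError("need at least one variable")
    if epv <= 0:
        raise ValueError("EPV must be positive")
    if not 0 <= incidence < 1:
        raise ValueError("incidence must lie in [0, 1)")
    return math.ceil(n_vars * epv / (1.0 - incidence))


def effective_epv(events: int, n_vars: int) -> float:
    """Achieved events-per-variable ratio, rounded to one decimal for
    display."""
    if n_vars < 1:
        raise ValueError("need at least one variable")
    return round(events / n_vars, 1)


def model_report(trained: dict, test: pd.DataFrame, feature_cols,
                 threshold: float = 0.5, bootstrap_B: int = 1000,
                 calibration_bins: int = 10, seed: int = 0) -> dict:
    """Full evaluation block for every trained family: hold-out metrics,
    bootstrap CIs for AUC/accuracy, calibration, decision curve and the
    Youden-optimal threshold."""
    feature_cols = list(feature_cols)
    y = test[OUTCOME_COLUMN].to_numpy(dtype=np.int64)
    report = {}
    for name, tm in trained.items():
        probs = tm.model.predict_proba(test[feature_cols])[:, 1]
        block = evaluate(probs, y, threshold=threshold)
        block["cv_auc_mean"] = tm.cv_auc_mean
        block["cv_auc_sd"] = tm.cv_auc_sd
        block["best_params"] = tm.best_params
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            auc_lo, auc_hi, _ = bootstrap_ci(
                lambda yy, pp: roc_auc_score(yy, pp), y, probs,
                B=bootstrap_B, seed=seed)
            acc_lo, acc_hi, _ = bootstrap_ci(
                lambda yy, pp: np.mean((pp > threshold) == yy), y, probs,
                B=bootstrap_B, seed=seed)
        block["auc_ci95"] = [auc_lo, auc_hi]
        block["accuracy_ci95"] = [acc_lo, acc_hi]
        cal = calibration_analysis(probs, y, bins=calibration_bins)
        block["ece"], block["mce"] = cal["ece"], cal["mce"]
        block["calibration_curve"] = cal["curve"]
        dca = decision_curve(probs, y)
        block["decision_curve"] = dca.to_dict(orient="list")
        block["optimal_threshold"] = optimal_threshold(probs, y)
        report[name] = block
    return report
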
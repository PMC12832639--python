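"""Three-method consensus feature selection.

The selection stage runs (1) L1-penalised logistic regression with a
10-fold cross-validated deviance path, (2) random-forest impurity
importance ranking and (3) the Boruta shadow-feature procedure, then
keeps the intersection of the three retained sets.  Features that
survive all three filters form the consensus used by the modelling
stage.  The whole stage is a pure function of (table, seed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import binom
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import log_loss
from sklearn.model_selection import StratifiedKFold

from .recording import FEATURE_COLUMNS, OUTCOME_COLUMN


def _design(table: pd.DataFrame, feature_cols):
    feature_cols = list(feature_cols)
    X = table[feature_cols].to_numpy(dtype=np.float64)
    y = table[OUTCOME_COLUMN].to_numpy(dtype=np.int64)
    if len(np.unique(y)) < 2:
        raise ValueError("outcome must contain both classes")
    mu, sd = X.mean(axis=0), X.std(axis=0, ddof=0)
    sd_safe = np.where(sd > 0, sd, 1.0)
    return (X - mu) / sd_safe, y, feature_cols


@dataclass
class LassoResult:
    lasso_min: list
    lasso_1se: list
    lambdas: np.ndarray
    mean_deviance: np.ndarray
    se_deviance: np.ndarray
    lambda_min: float
    lambda_1se: float


def lasso_select(table: pd.DataFrame, feature_cols=FEATURE_COLUMNS,
                 folds: int = 10, seed: int = 0,
                 n_lambdas: int = 50) -> LassoResult:
    """L1 logistic path with cross-validated binomial deviance.

    Returns the nonzero-coefficient feature sets at the deviance-minimum
    penalty (``lasso_min``) and at the largest penalty within one
    standard error of the minimum (``lasso_1se``); the 1-SE penalty is
    always at least the minimum-deviance penalty.
    """
    X, y, feature_cols = _design(table, feature_cols)
    n = X.shape[0]
    lam_max = np.max(np.abs(X.T @ (y - y.mean()))) / n
    lambdas = np.geomspace(lam_max, lam_max * 1e-3, n_lambdas)

    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    dev = np.zeros((folds, n_lambdas))
    for i, (tr, te) in enumerate(cv.split(X, y)):
        for j, lam in enumerate(lambdas):
            model = LogisticRegression(
                l1_ratio=1, C=1.0 / (n * lam), solver="liblinear",
                max_iter=2000)
            model.fit(X[tr], y[tr])
            p = model.predict_proba(X[te])[:, 1]
            dev[i, j] = 2.0 * log_loss(y[te], p, labels=[0, 1])
    mean_dev = dev.mean(axis=0)
    se_dev = dev.std(axis=0, ddof=1) / np.sqrt(folds)

    j_min = int(np.argmin(mean_dev))
    cutoff = mean_dev[j_min] + se_dev[j_min]
    # lambdas are descending, so the largest qualifying penalty is the
    # first index with mean deviance under the 1-SE cutoff.
    j_1se = int(np.flatnonzero(mean_dev <= cutoff)[0])

    def refit_nonzero(lam):
        model = LogisticRegression(
            l1_ratio=1, C=1.0 / (n * lam), solver="liblinear",
            max_iter=2000)
        model.fit(X, y)
        keep = np.abs(model.coef_[0]) > 1e-10
        return [feature_cols[i] for i in np.flatnonzero(keep)]

    return LassoResult(
        lasso_min=refit_nonzero(lambdas[j_min]),
        lasso_1se=refit_nonzero(lambdas[j_1se]),
        lambdas=lambdas, mean_deviance=mean_dev, se_deviance=se_dev,
        lambda_min=float(lambdas[j_min]), lambda_1se=float(lambdas[j_1se]))


@dataclass
class RFImportanceResult:
    ranking: list                       # all features, descending importance
    importances: dict                   # feature -> impurity importance
    retained: list                      # above-mean importance, top-10 cap


def rf_importance(table: pd.DataFrame, feature_cols=FEATURE_COLUMNS,
                  seed: int = 0, n_estimators: int = 500,
                  top_cap: int = 10) -> RFImportanceResult:
    """Impurity-based random-forest importance ranking.

    Retains features whose importance exceeds the mean importance,
    capped at the ``top_cap`` highest-ranked.  Deterministic for a
    given seed.
    """
    X, y, feature_cols = _design(table, feature_cols)
    forest = RandomForestClassifier(
        n_estimators=n_estimators, random_state=seed, n_jobs=1)
    forest.fit(X, y)
    imp = forest.feature_importances_
    order = np.argsort(-imp, kind="stable")
    ranking = [feature_cols[i] for i in order]
    threshold = imp.mean()
    retained = [feature_cols[i] for i in order
                if imp[i] > threshold][:top_cap]
    return RFImportanceResult(
        ranking=ranking,
        importances={feature_cols[i]: float(imp[i]) for i in order},
        retained=retained)


@dataclass
class BorutaResult:
    confirmed: list
    tentative: list
    rejected: list
    n_iterations: int


def boruta_select(table: pd.DataFrame, feature_cols=FEATURE_COLUMNS,
                  max_iter: int = 100, alpha: float = 0.05,
                  seed: int = 0, n_estimators: int = 100) -> BorutaResult:
    """Boruta all-relevant selection with shadow features.

    Each iteration appends an independently shuffled copy of every
    undecided feature, fits a seeded random forest, and scores a "hit"
    for features beating the best shadow importance.  Accumulated hits
    are tested against Binomial(trials, 1/2) one-sided in each
    direction at level ``alpha`` with Bonferroni correction across the
    currently undecided features; significant winners are confirmed,
    significant losers rejected, and the loop continues on the rest
    until every feature is decided or ``max_iter`` is reached
    (leftovers are tentative).
    """
    X, y, feature_cols = _design(table, feature_cols)
    rng = np.random.default_rng(seed)
    undecided = list(range(len(feature_cols)))
    hits = np.zeros(len(feature_cols), dtype=int)
    trials = np.zeros(len(feature_cols), dtype=int)
    confirmed, rejected = [], []

    iteration = 0
    while undecided and iteration < max_iter:
        iteration += 1
        Xu = X[:, undecided]
        shadows = Xu.copy()
        for j in range(shadows.shape[1]):
            rng.shuffle(shadows[:, j])
        forest = RandomForestClassifier(
            n_estimators=n_estimators, n_jobs=1,
            random_state=int(rng.integers(0, 2 ** 31)))
        forest.fit(np.hstack([Xu, shadows]), y)
        imp = forest.feature_importances_
        real, shadow = imp[:Xu.shape[1]], imp[Xu.shape[1]:]
        threshold = shadow.max()
        for pos, f in enumerate(undecided):
            trials[f] += 1
            if real[pos] > threshold:
                hits[f] += 1
        bonferroni = alpha / len(undecided)
        still = []
        for f in undecided:
            p_hi = binom.sf(hits[f] - 1, trials[f], 0.5)   # at least this many
            p_lo = binom.cdf(hits[f], trials[f], 0.5)      # at most this many
            if p_hi < bonferroni:
                confirmed.append(f)
            elif p_lo < bonferroni:
                rejected.append(f)
            else:
                still.append(f)
        undecided = still

    return BorutaResult(
        confirmed=[feature_cols[f] for f in sorted(confirmed)],
        tentative=[feature_cols[f] for f in undecided],
        rejected=[feature_cols[f] for f in sorted(rejected)],
        n_iterations=iteration)


@dataclass
class SelectionResult:
    """All per-method retained sets plus their consensus intersection."""

    lasso: LassoResult
    rf: RFImportanceResult
    boruta: BorutaResult
    consensus: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "lasso_min": self.lasso.lasso_min,
            "lasso_1se": self.lasso.lasso_1se,
            "lambda_min": self.lasso.lambda_min,
            "lambda_1se": self.lasso.lambda_1se,
            "lambda_path": self.lasso.lambdas.tolist(),
            "cv_mean_deviance": self.lasso.mean_deviance.tolist(),
            "rf_ranking": self.rf.ranking,
            "rf_retained": self.rf.retained,
            "boruta_confirmed": self.boruta.confirmed,
            "boruta_tentative": self.boruta.tentative,
            "boruta_rejected": self.boruta.rejected,
            "consensus": self.consensus,
        }


def consensus(lasso_set, rf_result: RFImportanceResult,
              boruta_confirmed) -> list:
    """Intersection of the three retained sets, in random-forest
    importance rank order.  An empty intersection triggers a warning
    and returns an empty list (the caller decides how to proceed)."""
    inter = set(lasso_set) & set(rf_result.retained) & set(boruta_confirmed)
    ordered = [f for f in rf_result.ranking if f in inter]
    if not ordered:
        warnings.warn("consensus feature set is empty", stacklevel=2)
    return ordered


def run_selection(table: pd.DataFrame, feature_cols=FEATURE_COLUMNS,
                  seed: int = 0, folds: int = 10,
                  boruta_max_iter: int = 100) -> SelectionResult:
    """The full consensus stage.  The LASSO arm of the intersection uses
    the deviance-minimum set (the 1-SE set is reported alongside)."""
    lasso = lasso_select(table, feature_cols, folds=folds, seed=seed)
    rf = rf_importance(table, feature_cols, seed=seed)
    boruta = boruta_select(table, feature_cols, max_iter=boruta_max_iter,
                           seed=seed)
    cons = consensus(lasso.lasso_min, rf, boruta.confirmed)
    return SelectionResult(lasso=lasso, rf=rf, boruta=boruta, consensus=cons)
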
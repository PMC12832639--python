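"""Per-subject Shapley attribution and the single-subject prediction
interface.

Shapley values are computed on the probability scale with an
interventional value function: v(S) is the model's mean positive-class
probability over a background sample with the subject's values
substituted on the coalition S.  For up to 12 features all 2^d
coalitions are enumerated, giving the exact Shapley value; beyond that
a seeded permutation-sampling estimate is used.  Both routes satisfy
the additivity identity base_value + sum(contributions) = model output
exactly (up to floating-point summation), because every permutation's
marginal contributions telescope.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from math import factorial

import numpy as np
import pandas as pd

from .model import DEPLOYED_THRESHOLD


def _positive_probability(model, X: pd.DataFrame) -> np.ndarray:
    return model.predict_proba(X)[:, 1]


def _check_schema(model, feature_names):
    trained = getattr(model, "feature_names_in_", None)
    if trained is not None and list(trained) != list(feature_names):
        missing = sorted(set(trained) - set(feature_names))
        extra = sorted(set(feature_names) - set(trained))
        raise ValueError(
            "feature names do not match the training schema: "
            f"missing {missing}, unexpected {extra}")


@dataclass
class ShapExplanation:
    """Additive per-feature attributions for a cohort of subjects."""

    base_value: float                  # expected model output (background)
    contributions: np.ndarray          # (n_subjects, n_features), signed
    feature_values: pd.DataFrame
    feature_names: list
    model_output: np.ndarray           # per-subject probability

    @property
    def ranking(self) -> list:
        """Features ordered by mean absolute contribution (descending)."""
        mean_abs = np.abs(self.contributions).mean(axis=0)
        order = np.argsort(-mean_abs, kind="stable")
        return [self.feature_names[i] for i in order]

    def additivity_gap(self) -> np.ndarray:
        return self.model_output - (self.base_value
                                    + self.contributions.sum(axis=1))


def _exact_shapley_row(predict, x: np.ndarray, background: np.ndarray):
    """Exact Shapley values by coalition enumeration.

    Builds every coalition's hybrid background matrix once and batches
    a single predict call.
    """
    d = x.size
    n_bg = background.shape[0]
    n_masks = 2 ** d
    big = np.repeat(background, n_masks, axis=0)
    for m in range(n_masks):
        rows = slice(m, None, n_masks)
        for j in range(d):
            if m >> j & 1:
                big[rows, j] = x[j]
    v = predict(big).reshape(n_bg, n_masks).mean(axis=0)

    phi = np.zeros(d)
    for size in range(d):
        w = factorial(size) * factorial(d - size - 1) / factorial(d)
        for subset in combinations(range(d), size):
            m = sum(1 << j for j in subset)
            for j in range(d):
                if j in subset:
                    continue
                phi[j] += w * (v[m | (1 << j)] - v[m])
    return phi, v[0], v[-1]


def _sampled_shapley_row(predict, x: np.ndarray, background: np.ndarray,
                         n_permutations: int, rng):
    """Permutation-sampling Shapley estimate (additive by telescoping)."""
    d = x.size
    n_bg = background.shape[0]
    phi = np.zeros(d)
    base = predict(background).mean()
    for _ in range(n_permutations):
        perm = rng.permutation(d)
        current = background.copy()
        prev = base
        for j in perm:
            current[:, j] = x[j]
            val = predict(current).mean()
            phi[j] += val - prev
            prev = val
    phi /= n_permutations
    full = predict(np.tile(x, (1, 1)))[0]
    return phi, base, full


def shap_explain(model, features: pd.DataFrame, background=None,
                 max_exact: int = 12, n_permutations: int = 200,
                 max_background: int = 100,
                 seed: int = 0) -> ShapExplanation:
    """Shapley attribution of the model's probability output for every
    row of ``features``.

    ``background`` (default: the cohort itself, subsampled to
    ``max_background`` rows) defines the reference distribution; the
    base value is the mean predicted probability over it.
    """
    feature_names = list(features.columns)
    _check_schema(model, feature_names)
    X = features.to_numpy(dtype=np.float64)
    bg = X if background is None else np.asarray(background, dtype=np.float64)
    rng = np.random.default_rng(seed)
    if bg.shape[0] > max_background:
        bg = bg[rng.choice(bg.shape[0], max_background, replace=False)]

    def predict(arr):
        return _positive_probability(
            model, pd.DataFrame(arr, columns=feature_names))

    d = X.shape[1]
    contribs = np.empty_like(X)
    outputs = np.empty(X.shape[0])
    base = None
    for i in range(X.shape[0]):
        if d <= max_exact:
            phi, v0, v_full = _exact_shapley_row(predict, X[i], bg)
        else:
            phi, v0, v_full = _sampled_shapley_row(
                predict, X[i], bg, n_permutations, rng)
        contribs[i] = phi
        outputs[i] = v_full
        base = v0 if base is None else base
    return ShapExplanation(base_value=float(base), contributions=contribs,
                           feature_values=features,
                           feature_names=feature_names,
                           model_output=outputs)


CLINICAL_DISCLAIMER = (
    "Research use only: this risk estimate supports, and does not "
    "replace, clinical judgement and formal neuropsychological "
    "assessment.")


@dataclass
class PredictionResult:
    probability: float
    predicted_class: str               # "PSCI" or "non-PSCI"
    threshold: float
    base_value: float
    contributions: dict                # feature -> signed contribution
    risk_increasing: dict              # positive contributions
    risk_decreasing: dict              # negative contributions
    disclaimer: str = CLINICAL_DISCLAIMER

    def to_dict(self) -> dict:
        return {
            "probability": self.probability,
            "class": self.predicted_class,
            "threshold": self.threshold,
            "base_value": self.base_value,
            "contributions": self.contributions,
            "risk_increasing": self.risk_increasing,
            "risk_decreasing": self.risk_decreasing,
            "disclaimer": self.disclaimer,
        }


def predict_subject(model, feature_values: dict, background,
                    threshold: float = DEPLOYED_THRESHOLD,
                    seed: int = 0) -> PredictionResult:
    """Single-subject risk prediction with force-plot attributions.

    ``feature_values`` must supply every feature of the training
    schema (missing ones raise, naming them); unknown extras are
    ignored with a warning.  The predicted class is positive when the
    probability strictly exceeds ``threshold``.
    """
    trained = list(getattr(model, "feature_names_in_", []))
    if not trained:
        raise ValueError("model lacks a feature-name schema; fit it on a "
                         "DataFrame")
    missing = [f for f in trained if f not in feature_values]
    if missing:
        raise ValueError(f"missing required features: {missing}")
    extra = [f for f in feature_values if f not in trained]
    if extra:
        warnings.warn(f"ignoring features outside the model schema: {extra}",
                      stacklevel=2)
    for f in trained:
        if not np.isfinite(feature_values[f]):
            raise ValueError(f"feature {f!r} is not finite")

    row = pd.DataFrame([{f: float(feature_values[f]) for f in trained}])
    expl = shap_explain(model, row, background=background, seed=seed)
    prob = float(expl.model_output[0])
    contribs = dict(zip(trained, expl.contributions[0].tolist()))
    return PredictionResult(
        probability=prob,
        predicted_class="PSCI" if prob > threshold else "non-PSCI",
        threshold=float(threshold),
        base_value=expl.base_value,
        contributions=contribs,
        risk_increasing={f: c for f, c in contribs.items() if c > 0},
        risk_decreasing={f: c for f, c in contribs.items() if c < 0},
    )
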
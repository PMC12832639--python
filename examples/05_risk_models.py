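"""End-to-end risk modelling on a synthetic cohort.

Simulates a strong-effect cohort, extracts the 26 candidate
predictors, trains the five classifier families with repeated
cross-validated grid search, and reports hold-out discrimination,
calibration and decision-curve summaries.
"""

import warnings

import eegrisk as er
from eegrisk.model import SplitSpec, model_report, split_standardize, \
    train_models
from eegrisk.pipeline import extract_features

spec = er.strong_effect_cohort_spec(n_per_group=(20, 20), duration_s=40.0,
                                    fs=250.0, seed=0)
recordings, metadata = er.simulate_cohort(spec)
table = extract_features(recordings, metadata, candidate_counts=(2, 2, 2, 2))

features = list(er.FEATURE_COLUMNS)
train, test, _ = split_standardize(table, SplitSpec(seed=0),
                                   feature_cols=features)
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    trained = train_models(train, features, seed=0, n_repeats=2)
    report = model_report(trained, test, features, bootstrap_B=200, seed=0)

print(f"{'model':6s} {'acc':>5s} {'auc':>5s} {'brier':>6s} "
      f"{'sens':>5s} {'spec':>5s} {'ece':>5s} {'mce':>5s}")
for name, b in report.items():
    print(f"{name:6s} {b['accuracy']:5.2f} {b['auc']:5.2f} "
          f"{b['brier']:6.3f} {b['sensitivity']:5.2f} "
          f"{b['specificity']:5.2f} {b['ece']:5.2f} {b['mce']:5.2f}")

best = max(report, key=lambda k: report[k]["auc"])
b = report[best]
print(f"\nbest by hold-out AUC: {best} "
      f"(AUC {b['auc']:.2f}, 95% CI {b['auc_ci95'][0]:.2f}-"
      f"{b['auc_ci95'][1]:.2f}; Youden threshold "
      f"{b['optimal_threshold']:.3f})")
print("net benefit exceeding both treat-all and treat-none across mid "
      "thresholds indicates clinical usefulness of acting on the model.")
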
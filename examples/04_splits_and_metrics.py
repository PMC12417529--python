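"""Cohort split arithmetic and imbalance-aware metrics.

Reproduces the published 4:1 stratified split of the 149 pMCI / 363
sMCI cohort, carves stratified five-fold cross-validation folds from
the training half, and shows why balanced accuracy is preferred over
plain accuracy under class imbalance.
"""

from trilightnet import (
    compute_metrics,
    confusion_from_predictions,
    make_cv_folds,
    stratified_split,
)

labels = {f"p{i}": 1 for i in range(149)} | {f"s{i}": 0 for i in range(363)}
plan = stratified_split(labels, test_fraction=0.2, seed=0)
test_pos = sum(labels[i] for i in plan.test_ids)
train_pos = sum(labels[i] for i in plan.train_ids)
print(f"test:  {test_pos} pMCI / {len(plan.test_ids) - test_pos} sMCI")
print(f"train: {train_pos} pMCI / {len(plan.train_ids) - train_pos} sMCI")

folds = make_cv_folds({i: labels[i] for i in plan.train_ids}, k=5, seed=1)
sizes = [len(folds.fold_ids(f)) for f in range(1, 6)]
print(f"five-fold sizes over the 409 training subjects: {sizes}")

# an all-majority predictor looks accurate but is clinically useless
probs = [0.0] * len(plan.test_ids)
ys = [labels[i] for i in plan.test_ids]
report = compute_metrics(confusion_from_predictions(probs, ys), probs, ys)
print(f"all-sMCI predictor on the test split: accuracy={report.accuracy:.3f} "
      f"but balanced accuracy={report.balanced_accuracy:.3f}")
print("Accuracy 0.709 comes entirely from the majority class; balanced "
      "accuracy 0.5 exposes that no converter is ever detected.")
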
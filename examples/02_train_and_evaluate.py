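"""Train the test-preset network on synthetic data and score it.

Generates a 60-subject cohort with strong class effects, holds out a
third (stratified), trains TriLightNet for 8 epochs and prints the
held-out metrics.  On this easy planted-signal task the balanced
accuracy should approach 1.0 within a few epochs.
"""

import numpy as np

from trilightnet import (
    EffectSpec,
    ModelConfig,
    TrainConfig,
    compute_metrics,
    confusion_from_predictions,
    gen_cohort,
    stratified_split,
)
from trilightnet.synthetic import cohort_to_dataset
from trilightnet.train import evaluate, train_one_fold

cohort = gen_cohort(n_pos=18, n_neg=42, spec=EffectSpec(), seed=3)
split = stratified_split(cohort.labels(), test_fraction=1 / 3, seed=14)
data = cohort_to_dataset(cohort, split.train_ids)

cfg = TrainConfig(epochs=8, batch_size=8, lr=1e-3, seed=3)
model, history = train_one_fold(
    data, data.index_of(split.train_ids), None, ModelConfig(), cfg
)
print("training loss by epoch:", [round(v, 4) for v in history["train_loss"]])

probs, labels = evaluate(model, data, data.index_of(split.test_ids))
report = compute_metrics(confusion_from_predictions(probs, labels), probs, labels)
print(f"held-out ({len(labels)} subjects): "
      f"balanced accuracy={report.balanced_accuracy:.3f} "
      f"AUROC={report.auroc:.3f} F1={report.f1:.3f}")
print("A falling focal loss plus near-perfect held-out separation shows the "
      "network recovered the planted imaging + clinical class signal.")
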
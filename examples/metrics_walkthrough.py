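"""The evaluation metrics on a small hand-checkable example.

Scores ten samples over three classes, prints the confusion matrix, the
per-class and macro precision/recall/F1, and the rank-based one-vs-rest AUC.
The AUC here is the Mann-Whitney statistic: the probability that a randomly
chosen positive outranks a randomly chosen negative, ties counting 1/2.
"""

import numpy as np

from gcanet.metrics import auc_rank, full_report

rng = np.random.default_rng(0)
y_true = np.array([0, 0, 0, 1, 1, 1, 1, 2, 2, 2])
logits = rng.normal(size=(10, 3)) + 2.0 * np.eye(3)[y_true]  # informative scores
proba = np.exp(logits) / np.exp(logits).sum(axis=1, keepdims=True)

report = full_report(proba, y_true, labels=[0, 1, 2])
print("confusion matrix (rows true, cols predicted):")
print(report.confusion.counts)
print(f"accuracy {report.accuracy:.2f}")
print(f"macro P/R/F1: {report.macro_precision:.3f} / "
      f"{report.macro_recall:.3f} / {report.macro_f1:.3f}")
print(f"macro one-vs-rest AUC: {report.macro_auc:.3f}")

scores = np.array([0.1, 0.4, 0.35, 0.8])
labels = np.array([0, 0, 1, 1])
print(f"worked binary AUC example: {auc_rank(scores, labels):.2f} "
      "(3 of 4 positive-negative pairs correctly ranked)")
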
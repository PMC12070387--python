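"""Confusion-matrix metrics and ROC/AUC on a toy evaluation.

accuracy = (TP+TN)/total, precision = TP/(TP+FP), recall = TP/(TP+FN),
F1 = harmonic mean of precision and recall; AUC is the area under the
tie-grouped ROC curve, identical to the Mann-Whitney concordance.
"""

import numpy as np

from twintower.metrics import confusion_counts, compute_metrics, f1_score, roc_auc

labels = np.array([1, 1, 1, 1, 0, 0, 0, 0, 1, 0])
scores = np.array([0.9, 0.8, 0.75, 0.6, 0.55, 0.4, 0.3, 0.2, 0.45, 0.65])

counts = confusion_counts(labels, (scores >= 0.5).astype(int))
print(f"TP={counts.tp} TN={counts.tn} FP={counts.fp} FN={counts.fn}")

report = compute_metrics(counts)
print(
    f"accuracy {report.accuracy:.3f}  precision {report.precision:.3f}  "
    f"recall {report.recall:.3f}  F1 {report.f1:.3f}"
)

curve = roc_auc(labels, scores)
print(f"AUC {curve.auc:.3f} over {len(curve.points)} ROC points from (0,0) to (1,1)")

# a precision/recall pair alone determines F1:
print(f"f1_score(0.933, 0.875) = {f1_score(0.933, 0.875):.3f}  (harmonic mean)")
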
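"""Evaluation metrics and confidence-interval arithmetic.

Computes the six binary-classification metrics from a confusion matrix and
shows the SEM / 95% CI arithmetic for a measured precision, including the
difference between quoting an SEM directly and recomputing it from the
binomial formula sqrt(p(1-p)/N).
"""

from pidsan import class_weights, confusion_and_metrics, sem_ci

# a classifier that got 9/10 positives and 8/10 negatives right
y_true = [1] * 10 + [0] * 10
y_pred = [1] * 9 + [0] + [1] * 2 + [0] * 8
rep = confusion_and_metrics(y_true, y_pred, positive_label=1)
print(f"TP={rep.tp} FN={rep.fn} FP={rep.fp} TN={rep.tn}")
print(f"accuracy {rep.accuracy:.3f}  sensitivity {rep.sensitivity:.3f}  "
      f"specificity {rep.specificity:.3f}  precision {rep.precision:.3f}")
print(f"F-measure {rep.f_measure:.3f}  G-mean {rep.g_mean:.3f}")

# 95% CI for a precision of 0.895 measured on 2,131 test samples
res = sem_ci(0.895, n=2131, z=1.96)
print(f"\nprecision 0.895, N=2131: SEM {res.sem:.5f}, "
      f"95% CI [{res.lower:.3f}, {res.upper:.3f}]")

# inverse-frequency class weights for a nearly balanced two-class dataset
w = class_weights((5531, 5530))
print(f"class weights for counts (5531, 5530): ({w[0]:.7f}, {w[1]:.7f})")
# A weight barely above/below 1 — the dataset is almost balanced, but the
# weighting still nudges the loss toward the slightly rarer class.
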
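"""The evaluation metric suite on a hand-checkable toy example.

Shows the confusion-based metrics and the trapezoid-rule ROC/AUC, including
the pairwise-concordance interpretation of the area.
"""

from ictalnet import confusion, metrics, roc_auc

predictions = [1, 1, 1, 0, 0, 1]
labels = [1, 1, 1, 0, 0, 0]
c = confusion(predictions, labels)
print(f"TP={c.tp} FP={c.fp} TN={c.tn} FN={c.fn}")
for name, value in metrics(c).items():
    print(f"  {name}: {value:.4f}")
# accuracy 5/6, sensitivity 1.0 (no missed seizures), specificity 2/3

scores = [0.1, 0.4, 0.35, 0.8]
labels = [0, 0, 1, 1]
curve, auc = roc_auc(scores, labels)
print("ROC points (FPR, TPR):",
      [(float(x), float(y)) for x, y in zip(curve.fpr, curve.tpr)])
print(f"AUC = {auc}")
# 0.75: three of the four positive-negative score pairs are ordered correctly
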
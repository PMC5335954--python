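"""Metric arithmetic on a published-style per-activity confusion table.

Given raw decision counts, the four binary metrics follow directly:
sensitivity TP/(TP+FN), specificity TN/(FP+TN), precision TP/(TP+FP),
accuracy (TP+TN)/total, all in percent, falls positive.
"""

from fallphase import compute_metrics
from fallphase.evaluation import ConfusionCounts

# stoop falls: 375 detected, 5 missed, over five CV rounds
stoop = compute_metrics(ConfusionCounts(tp=375, fn=5, fp=0, tn=0))
print(f"stoop sensitivity:       {stoop.sensitivity:.2f} %  (375 of 380 falls detected)")

# lie-on-the-bed (normal): 137 rejected, 8 false alarms
lie = compute_metrics(ConfusionCounts(tn=137, fp=8, tp=0, fn=0))
print(f"lie (normal) specificity: {lie.specificity:.2f} %  (8 of 145 ADLs raised an alarm)")

# pooled totals of a full five-round evaluation
overall = compute_metrics(ConfusionCounts(tp=2370, fn=5, fp=23, tn=1797))
print(f"overall: sensitivity {overall.sensitivity:.2f} %, specificity {overall.specificity:.2f} %, "
      f"precision {overall.precision:.2f} %, accuracy {overall.accuracy:.2f} %")
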
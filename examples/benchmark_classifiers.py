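"""Benchmark the eight classifiers on one shared stratified 80:20 split.

Prints a per-method table of train/test accuracy (percent), precision,
recall, F1 and AUC — the package's analogue of a published classifier
comparison — plus the ROC endpoints of the best method.
"""

from alleracc import ClassifierSpec, SyntheticParams, generate_dataset, load_e_descriptor_table
from alleracc.evaluation import benchmark
from alleracc.models import CLASSIFIER_KINDS

dataset = generate_dataset(SyntheticParams(n_per_class=300, seed=5))
specs = [ClassifierSpec(kind=k, seed=5) for k in CLASSIFIER_KINDS]
report = benchmark(dataset, specs, load_e_descriptor_table(), ratio=0.8, seed=5)

print(report.to_text())
fpr, tpr = report.roc_points["fpr"], report.roc_points["tpr"]
print(f"best-method ROC: {len(fpr)} points from "
      f"({fpr[0]:.0f},{tpr[0]:.0f}) to ({fpr[-1]:.0f},{tpr[-1]:.0f})")
# AUC near 1 means the method ranks almost every allergen above every
# non-allergen on held-out data; 0.5 would be chance
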
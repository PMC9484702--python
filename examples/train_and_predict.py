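"""Train one classifier on synthetic data, persist it, and score new sequences.

Scores are allergen-class probabilities; a score >= 0.5 calls the sequence
an allergen (ties deliberately go to allergen — conservative for a safety
screen).
"""

import tempfile
from pathlib import Path

from alleracc import (ClassifierSpec, SyntheticParams, featurize_dataset,
                      generate_dataset, load_e_descriptor_table, load_model,
                      predict_proba, save_model, train)

table = load_e_descriptor_table()
train_set = generate_dataset(SyntheticParams(n_per_class=300, seed=1))
features = featurize_dataset(train_set, table)

model = train(ClassifierSpec(kind="extra_trees", seed=1), features)
print(f"trained extra_trees on {model.training_meta['n_samples']} sequences, "
      f"training accuracy {model.training_meta['training_accuracy']:.3f}")

with tempfile.TemporaryDirectory() as tmp:
    save_model(model, Path(tmp) / "model")
    reloaded = load_model(Path(tmp) / "model")

# fresh sequences from the same generating process, different seed
new_set = generate_dataset(SyntheticParams(n_per_class=5, seed=99))
new_features = featurize_dataset(new_set, table)
scores = predict_proba(reloaded, new_features)
for rec_id, truth, score in zip(new_features.ids, new_features.labels, scores):
    call = "allergen" if score >= 0.5 else "non_allergen"
    print(f"{rec_id}: score {score:.3f} -> {call} (truth: {truth})")
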
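"""Train the hybrid model and its no-quantum ablation, then evaluate.

Runs the whole pipeline on a small phantom study: the hybrid route sends
the five SVD features through the variational circuit before the dense
head; the traditional route passes them straight through. Both share every
other stage, seed and split, so the comparison isolates the quantum layer.
"""

import tempfile

from qlung.config import merge_config
from qlung.pipeline import (evaluate_model, generate_phantom_dataset,
                            train_from_manifest)

config = merge_config({
    "seed": 5,
    "data": {"n_subjects": 80},
    "train": {"epochs": 12},
})

with tempfile.TemporaryDirectory() as out:
    manifest = generate_phantom_dataset(config, out)
    for mode in ("hybrid", "traditional"):
        model, history, features = train_from_manifest(manifest, out, config,
                                                       mode=mode)
        result = evaluate_model(model, features, positive_class="malignant",
                                subjects=model.split["test"])
        final = history.iloc[-1]
        report = result["report"]
        print(f"\n=== {mode} (quantum params: {model.n_quantum_params}) ===")
        print(f"final training accuracy: {final.accuracy_pct:.2f}%  "
              f"loss: {final.loss_pct:.2f}%")
        print("test-split confusion matrix (rows true, cols predicted):")
        print(result["confusion_matrix"].to_string())
        print(f"test accuracy {report.accuracy:.2f}%  "
              f"sensitivity {report.sensitivity:.2f}%  "
              f"specificity {report.specificity:.2f}%  "
              f"MCC {report.mcc:.3f}  AUC {report.auc}")

# Training accuracy/loss are percentages (loss normalized by ln 3 so a
# uniform guesser scores 100%). The binary metrics collapse the 3x3 matrix
# one-vs-rest with malignant as the positive class.
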
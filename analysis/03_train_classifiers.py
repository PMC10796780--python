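"""Train and evaluate one classifier per condition x hemifield.

Epochs each run, averages per cell, splits subjects 80/20 with matched
test pairs, trains the slim 3D residual network with per-batch
augmentation, and reports held-out metrics.  Checkpoints go to scratch/
for the downstream relevance driver.
"""

import json
import sys
from pathlib import Path

import numpy as np

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import HYPERPARAMS, RESULTS, SCRATCH, SEED, load_cohort  # noqa: E402

from hrfprobe.classifier import (GROUP_LABELS, evaluate, predict_subjects,  # noqa: E402
                                 split_datasets, subject_cell_epochs,
                                 train_cell_model)
from hrfprobe.events import CONDITIONS, HEMIFIELDS  # noqa: E402
from hrfprobe.nn import save_network  # noqa: E402


def main() -> None:
    runs, schedules, metadata, _ = load_cohort()
    table, groups = subject_cell_epochs(runs, schedules)
    train_ids, test_ids = split_datasets(metadata, 0.2, rng_seed=SEED)
    labels = np.array([GROUP_LABELS[groups[s]] for s in test_ids])
    print(f"{len(train_ids)} training / {len(test_ids)} matched test "
          f"subjects")

    model_dir = SCRATCH / "models"
    model_dir.mkdir(parents=True, exist_ok=True)
    metrics = {}
    split = {"train": train_ids, "test": test_ids}
    for condition in CONDITIONS:
        for hemifield in HEMIFIELDS:
            model_id = f"{condition}_{hemifield}"
            net = train_cell_model(table, groups, train_ids, condition,
                                   hemifield, HYPERPARAMS, rng_seed=SEED)
            save_network(net, model_dir / f"{model_id}.npz")
            probs = predict_subjects(net, table, test_ids, condition,
                                     hemifield)
            metrics[model_id] = evaluate(probs, labels).to_dict()
            print(f"{model_id:16s} AUC {metrics[model_id]['auc']:.3f}  "
                  f"accuracy {metrics[model_id]['accuracy']:.3f}  "
                  f"F1 {metrics[model_id]['f1']:.3f}")

    RESULTS.mkdir(exist_ok=True)
    (RESULTS / "classifier_metrics.json").write_text(
        json.dumps(metrics, indent=2))
    (RESULTS / "split.json").write_text(json.dumps(split, indent=2))


if __name__ == "__main__":
    main()
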
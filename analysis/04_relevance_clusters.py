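"""Explain the trained classifiers and derive cluster ROIs.

Computes a deep-Taylor relevance heatmap for every test subject and
model, compares the per-group average patterns, aggregates all maps into
a global average, and converts it into ROIs by percentile thresholding,
morphological opening, connected-component labeling, and the 20-voxel
size filter.  Requires driver 03's checkpoints (retrains if absent).
"""

import json
import sys
from pathlib import Path

import numpy as np

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import HYPERPARAMS, RESULTS, SCRATCH, SEED, load_cohort  # noqa: E402

from hrfprobe.classifier import averaged_input, subject_cell_epochs, train_cell_model  # noqa: E402
from hrfprobe.clustering import (cluster_stats, label_clusters,  # noqa: E402
                                 morphological_open, threshold_map)
from hrfprobe.events import CONDITIONS, HEMIFIELDS  # noqa: E402
from hrfprobe.nn import load_network  # noqa: E402
from hrfprobe.relevance import (aggregate_heatmaps, dtd_heatmap,  # noqa: E402
                                group_average_comparison)


def main() -> None:
    runs, schedules, metadata, truth = load_cohort()
    table, groups = subject_cell_epochs(runs, schedules)
    test_ids = json.loads((RESULTS / "split.json").read_text())["test"] \
        if (RESULTS / "split.json").exists() else list(groups)[:4]

    maps = []
    for condition in CONDITIONS:
        for hemifield in HEMIFIELDS:
            model_id = f"{condition}_{hemifield}"
            ckpt = SCRATCH / "models" / f"{model_id}.npz"
            if ckpt.exists():
                net = load_network(ckpt)
            else:
                train_ids = [s for s in groups if s not in set(test_ids)]
                net = train_cell_model(table, groups, train_ids,
                                       condition, hemifield, HYPERPARAMS,
                                       rng_seed=SEED)
            for sid in test_ids:
                x = averaged_input(table[(sid, condition, hemifield)])
                maps.append(dtd_heatmap(net, x, subject_id=sid,
                                        model_id=model_id))

    by_group = {"control": [], "patient": []}
    for m in maps:
        by_group[groups[m.subject_id]].append(m)
    _, corr = group_average_comparison(by_group)
    print(f"{len(maps)} heatmaps; control vs patient average-pattern "
          f"correlation r = {corr:.3f}")

    avg = aggregate_heatmaps(maps, normalize_each=True)
    mask = morphological_open(threshold_map(avg, "percentile", 95.0))
    clusters = label_clusters(mask, connectivity=26, min_size=20)
    stats = cluster_stats(clusters, avg)
    RESULTS.mkdir(exist_ok=True)
    stats.to_csv(RESULTS / "clusters.csv", index=False)
    np.save(SCRATCH / "cluster_labels.npy", clusters.label_volume)
    np.save(SCRATCH / "avg_relevance.npy", avg)
    (RESULTS / "relevance_summary.json").write_text(json.dumps({
        "n_heatmaps": len(maps),
        "group_pattern_correlation": corr,
        "n_clusters": int(clusters.n_clusters),
    }, indent=2))

    inside = np.zeros(avg.shape, dtype=bool)
    for region in truth["activation"].regions:
        inside |= region.mask
    print(f"relevance inside ground-truth active regions is "
          f"{avg[inside].mean() / avg[~inside].mean():.1f}x the outside "
          f"mean")
    print(f"{clusters.n_clusters} cluster(s) after opening and 20-voxel "
          f"size filter:")
    if clusters.n_clusters:
        print(stats.to_string(index=False))


if __name__ == "__main__":
    main()
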
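"""Published benchmark figures for pre-miRNA identification methods.

These are the reported per-dataset example counts and evaluation
metrics for the standard *human*, *cross-species* and *new* benchmark
collections (positives from miRBase, negatives from coding exons and
non-miRNA ncRNAs), for this cascaded CNN-BLSTM classifier and the four
methods it is usually compared against. They serve as inputs to the
comparison arithmetic in :mod:`clpmi.metrics` — none of them is
computed by this package.

Metric column order everywhere: SE, SP, PPV, F-score, g-mean, AUROC,
AUPR; ``None`` marks a value not reported for that method.
"""

from __future__ import annotations

METRIC_NAMES = ("SE", "SP", "PPV", "F_score", "g_mean", "AUROC", "AUPR")

#: (positives, negatives) per benchmark dataset
DATASET_COUNTS: dict[str, tuple[int, int]] = {
    "cross-species": (1677, 8266),
    "human": (863, 7422),
    "new": (690, 8246),
    "new22": (690, 8246),
}

#: datasets pooled for the overall positive/negative totals; new22 reuses
#: the new negatives and positives and is excluded from the pooled count
POOLED_DATASETS = ("cross-species", "human", "new")


def _rows(table):
    return {method: dict(zip(METRIC_NAMES, vals)) for method, vals in table.items()}


HUMAN_CV = _rows({
    "miRBoost": (0.803, 0.988, 0.887, 0.843, 0.891, None, None),
    "microPred": (0.763, 0.989, 0.888, 0.820, 0.869, 0.974, 0.890),
    "deepMiRGene": (0.799, 0.988, 0.885, 0.839, 0.888, 0.984, 0.915),
    "DCNN fixed-sized": (0.878, 0.978, 0.827, 0.849, 0.926, 0.984, 0.915),
    "DCNN variable-sized": (0.835, 0.985, 0.868, 0.851, 0.907, 0.985, 0.922),
    "Proposed": (0.989, 0.935, 0.992, 0.991, 0.962, 0.962, 0.854),
})

HUMAN_TEST = _rows({
    "miRBoost": (0.884, 0.969, 0.768, 0.822, 0.925, None, None),
    "microPred": (0.779, 0.988, 0.882, 0.827, 0.877, 0.980, 0.892),
    "deepMiRGene": (0.822, 0.992, 0.919, 0.868, 0.903, 0.981, 0.918),
    "DCNN fixed-sized": (0.930, 0.984, 0.870, 0.899, 0.957, 0.983, 0.946),
    "DCNN variable-sized": (0.884, 0.991, 0.916, 0.899, 0.936, 0.986, 0.934),
    "Proposed": (0.968, 0.895, 0.988, 0.978, 0.931, 0.972, 0.807),
})

CROSS_SPECIES_CV = _rows({
    "miRBoost": (0.861, 0.977, 0.884, 0.872, 0.917, None, None),
    "microPred": (0.825, 0.975, 0.875, 0.848, 0.897, 0.970, 0.873),
    "deepMiRGene": (0.886, 0.982, 0.911, 0.898, 0.933, 0.985, 0.927),
    "DCNN fixed-sized": (0.903, 0.978, 0.894, 0.898, 0.940, 0.985, 0.936),
    "DCNN variable-sized": (0.881, 0.981, 0.906, 0.893, 0.930, 0.983, 0.936),
    "Proposed": (0.995, 0.950, 0.990, 0.992, 0.972, 0.972, 0.933),
})

CROSS_SPECIES_TEST = _rows({
    "miRBoost": (0.856, 0.844, 0.526, 0.651, 0.850, None, None),
    "microPred": (0.814, 0.985, 0.919, 0.863, 0.896, 0.963, 0.906),
    "deepMiRGene": (0.900, 0.983, 0.913, 0.906, 0.940, 0.984, 0.955),
    "DCNN fixed-sized": (0.904, 0.982, 0.910, 0.907, 0.942, 0.983, 0.951),
    "DCNN variable-sized": (0.880, 0.988, 0.936, 0.907, 0.933, 0.985, 0.950),
    "Proposed": (0.977, 0.910, 0.982, 0.979, 0.943, 0.958, 0.877),
})

NEW_TEST = _rows({
    "miRBoost": (0.921, 0.936, 0.609, 0.733, 0.928, None, None),
    "microPred": (0.728, 0.970, 0.672, 0.699, 0.840, 0.940, 0.756),
    "deepMiRGene": (0.917, 0.964, 0.682, 0.782, 0.941, 0.981, 0.808),
    "DCNN fixed-sized": (0.917, 0.967, 0.696, 0.792, 0.942, 0.979, 0.864),
    "DCNN variable-sized": (0.859, 0.981, 0.779, 0.817, 0.918, 0.979, 0.818),
    "Proposed": (0.970, 0.907, 0.992, 0.981, 0.938, 0.939, 0.746),
})

#: every benchmark table carrying a row for this method
PROPOSED_ROWS: dict[str, dict[str, float]] = {
    "human_cv": HUMAN_CV["Proposed"],
    "human_test": HUMAN_TEST["Proposed"],
    "cross_species_cv": CROSS_SPECIES_CV["Proposed"],
    "cross_species_test": CROSS_SPECIES_TEST["Proposed"],
    "new_test": NEW_TEST["Proposed"],
}


def best_competitor(table: dict[str, dict], metric: str) -> float:
    """Best reported value of a metric among the comparison methods."""
    vals = [
        row[metric]
        for method, row in table.items()
        if method != "Proposed" and row[metric] is not None
    ]
    return max(vals)


def pooled_counts() -> tuple[int, int]:
    """Total positives and negatives across the pooled benchmark datasets."""
    pos = sum(DATASET_COUNTS[d][0] for d in POOLED_DATASETS)
    neg = sum(DATASET_COUNTS[d][1] for d in POOLED_DATASETS)
    return pos, neg
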
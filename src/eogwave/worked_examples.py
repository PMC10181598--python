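"""Published per-feature confusion counts used as worked examples.

The study this pipeline replicates reports, for each of the 18 windowed
features (9 per EOG channel), averaged one-vs-rest confusion counts
(TP / TN / FP / FN, real-valued) together with the derived sensitivity,
specificity, accuracy and precision percentages.  The counts are opaque
inputs here: they demonstrate :func:`eogwave.evaluation.derived_metrics`
on real published numbers and let the derivation be checked against the
printed percentages.

Not every printed row is internally consistent (some printed percentages
cannot be produced from the row's own counts by the standard formulas);
``CONSISTENT_ROWS`` lists those whose sensitivity, specificity and
precision all re-derive to within 0.02.
"""

from __future__ import annotations

from .evaluation import ConfusionCounts, MetricRow, derived_metrics

__all__ = [
    "FEATURE_CONFUSION_COUNTS",
    "PRINTED_METRICS",
    "CONSISTENT_ROWS",
    "rederive_metrics",
]

#: feature name -> (TP, TN, FP, FN); H = horizontal channel, V = vertical.
FEATURE_CONFUSION_COUNTS: dict[str, ConfusionCounts] = {
    "RMSH": ConfusionCounts(1, 36.78, 0, 1.8841),
    "AMPH": ConfusionCounts(1, 83.5, 0.36, 3.423),
    "VarianceH": ConfusionCounts(1, 76.66, 1.22, 2.30405),
    "AverageH": ConfusionCounts(1, 79.72, 0.051, 1.966),
    "MedianH": ConfusionCounts(1, 79.39, 1.151, 0.8329),
    "CovarianceH": ConfusionCounts(1, 16.05, 2.5, 0.6645),
    "MaxH": ConfusionCounts(1, 76.30, 2.93, 0.1949),
    "PspectrumH": ConfusionCounts(1, 80.36, 0.0062, 1.09084),
    "PowerH": ConfusionCounts(1, 82.80, 1.937, 0.0296),
    "RMSV": ConfusionCounts(1, 81.87, 0.3183, 0.9022),
    "AMPV": ConfusionCounts(1, 75.76, 0.103, 2.7607),
    "VarianceV": ConfusionCounts(1, 77.28, 0.95497, 1.65257),
    "AverageV": ConfusionCounts(1, 82.59, 0.7812, 1.166),
    "MedianV": ConfusionCounts(1, 79.43, 0.0759, 0.468),
    "CovarianceV": ConfusionCounts(1, 77.77, 1.89397, 0.71257),
    "MaxV": ConfusionCounts(1, 73.95, 2.9454, 0.071),
    "PspectrumV": ConfusionCounts(1, 83.03, 0.952127, 0.033),
    "PowerV": ConfusionCounts(1, 81.72, 1.1841, 0),
}

#: Printed (sensitivity, specificity, precision) percentages per feature.
PRINTED_METRICS: dict[str, tuple[float, float, float]] = {
    "RMSH": (34.72, 100.0, 100.0),
    "AMPH": (22.60, 99.57, 73.52),
    "VarianceH": (30.26, 98.43, 45.04),
    "AverageH": (33.78, 99.93, 95.14),
    "MedianH": (54.64, 98.57, 39.84),
    "CovarianceH": (60.24, 86.52, 28.57),
    "MaxH": (83.68, 96.30, 25.44),
    "PspectrumH": (47.84, 99.99, 34.12),
    "PowerH": (98.03, 97.72, 34.12),
    "RMSV": (52.63, 99.62, 45.87),
    "AMPV": (26.59, 99.86, 90.66),
    "VarianceV": (37.73, 98.78, 51.28),
    "AverageV": (46.16, 99.06, 56.14),
    "MedianV": (68.11, 99.90, 34.55),
    "CovarianceV": (58.47, 97.62, 34.60),
    "MaxV": (93.37, 96.16, 25.34),
    "PspectrumV": (96.8054, 98.86, 51.28),
    "PowerV": (45.87, 98.57, 45.87),
}

#: Rows whose printed sensitivity, specificity AND precision all re-derive
#: from their own counts to within 0.02.
CONSISTENT_ROWS: tuple[str, ...] = ("AMPH", "VarianceH", "AMPV", "MaxV")


def rederive_metrics(feature: str) -> MetricRow:
    """Derive the metric percentages of one published feature row from its
    confusion counts."""
    return derived_metrics(FEATURE_CONFUSION_COUNTS[feature])
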
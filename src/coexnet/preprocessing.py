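"""QC filtering of features and samples before network construction.

Two independent rules remove features: low total expression (summed
expression across samples below a threshold) and sparsity (fraction of
entries that are missing or <= 0 above a threshold). Outlier samples are
removed by hierarchically clustering samples (Euclidean distance,
average linkage), cutting the tree at a user-chosen height, and keeping
only the largest resulting cluster.

Default thresholds (min_total_expression=1, max_missing_fraction=0.5,
sample cut disabled unless a height is given) are package choices; pick
them to match the scale of your data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from coexnet.core_data import ExpressionDataset

logger = logging.getLogger(__name__)


@dataclass
class QCReport:
    """Record of what a QC step removed and the thresholds it used."""

    n_features_removed_low_expression: int = 0
    n_features_removed_sparse: int = 0
    removed_sample_ids: list[str] = field(default_factory=list)
    thresholds_used: dict[str, float] = field(default_factory=dict)

    def summary(self) -> str:
        lines = [
            f"features removed (low expression): {self.n_features_removed_low_expression}",
            f"features removed (sparse): {self.n_features_removed_sparse}",
            f"samples removed: {len(self.removed_sample_ids)}",
        ]
        if self.removed_sample_ids:
            lines.append("removed sample ids: " + ", ".join(self.removed_sample_ids))
        if self.thresholds_used:
            lines.append(
                "thresholds: " + ", ".join(f"{k}={v}" for k, v in self.thresholds_used.items())
            )
        return "\n".join(lines)


def filter_features(
    ds: ExpressionDataset,
    min_total_expression: float = 1.0,
    max_missing_fraction: float = 0.5,
) -> tuple[ExpressionDataset, QCReport]:
    """Remove lowly expressed and overly sparse features.

    A feature is removed when its summed expression across samples
    (missing values ignored) is below ``min_total_expression``, or when
    the fraction of its entries that are missing or <= 0 exceeds
    ``max_missing_fraction``. Both rules are applied to the input
    dataset, so filtering is idempotent.
    """
    if not np.isfinite(min_total_expression):
        raise ValueError("min_total_expression must be finite")
    if not 0.0 <= max_missing_fraction <= 1.0:
        raise ValueError("max_missing_fraction must be in [0, 1]")

    mat = ds.matrix
    totals = mat.sum(axis=0, skipna=True)
    low = totals < min_total_expression
    sparse_frac = ((mat.isna()) | (mat <= 0)).mean(axis=0)
    sparse = sparse_frac > max_missing_fraction

    keep = ~(low | sparse)
    if not keep.any():
        raise ValueError(
            "all features would be removed; relax min_total_expression "
            "and/or max_missing_fraction"
        )
    report = QCReport(
        n_features_removed_low_expression=int(low.sum()),
        n_features_removed_sparse=int(sparse.sum()),
        thresholds_used={
            "min_total_expression": float(min_total_expression),
            "max_missing_fraction": float(max_missing_fraction),
        },
    )
    kept = ds.subset(features=mat.columns[keep].tolist())
    logger.info(
        "filter_features: kept %d/%d features (%d low-expression, %d sparse)",
        kept.n_features, ds.n_features, report.n_features_removed_low_expression,
        report.n_features_removed_sparse,
    )
    return kept, report


def sample_dendrogram(ds: ExpressionDataset) -> np.ndarray:
    """Average-linkage merge tree over samples (Euclidean on rows)."""
    ds.require_complete("sample clustering")
    return linkage(pdist(ds.values, metric="euclidean"), method="average")


def detect_outlier_samples(
    ds: ExpressionDataset,
    cut_height: float,
) -> tuple[ExpressionDataset, QCReport]:
    """Drop outlier samples via hierarchical clustering of sample profiles.

    Samples are clustered with Euclidean distance and average linkage;
    the dendrogram is cut at ``cut_height`` and only the largest
    resulting cluster is kept. A tie for the largest cluster is an
    error: silently discarding an arbitrary half of the data is not
    acceptable QC, so the caller must pick a different cut height.
    """
    if cut_height <= 0:
        raise ValueError("cut_height must be positive")
    if ds.n_samples < 3:
        raise ValueError(f"need at least 3 samples for outlier detection, have {ds.n_samples}")
    Z = sample_dendrogram(ds)
    labels = fcluster(Z, t=cut_height, criterion="distance")
    sizes = np.bincount(labels)[1:]  # labels are 1-based
    largest = sizes.max()
    winners = np.flatnonzero(sizes == largest) + 1
    if len(winners) > 1:
        raise ValueError(
            f"cut_height={cut_height} produces {len(winners)} equally large "
            f"clusters of {largest} samples; choose a different cut_height"
        )
    keep_mask = labels == winners[0]
    removed = [sid for sid, k in zip(ds.sample_ids, keep_mask) if not k]
    report = QCReport(
        removed_sample_ids=removed,
        thresholds_used={"cut_height": float(cut_height)},
    )
    if removed:
        logger.info("detect_outlier_samples: removed %d samples: %s", len(removed), removed)
    kept = ds.subset(samples=[sid for sid, k in zip(ds.sample_ids, keep_mask) if k])
    return kept, report
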
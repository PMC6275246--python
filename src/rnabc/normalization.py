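"""Target-distribution quantile normalization onto the microarray scale.

RNA-Seq abundances and microarray intensities live on incompatible scales; a
classifier trained on log2 RMA intensities cannot consume TPM directly. The
fix used here is rank-based: each sample's values are replaced, rank for
rank, by the quantiles of a fixed *target distribution* — the per-probe mean
intensity of the training cohort, sorted. Because the mapping is monotone,
the transform preserves each sample's internal ordering exactly while placing
it on the training intensity scale.

Quantile convention: the value of rank r out of R maps to the target's
empirical quantile at probability (r - 0.5)/R, linearly interpolated over the
sorted target values (and clamped at the extremes). When a column has R equal
to the target length and no ties, its sorted output equals the target values
exactly. Ties receive the mean of the target values their ordinal ranks would
have mapped to.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .matrix import ExpressionMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TargetDistribution:
    """Sorted reference values (one per probe set) and their provenance size."""

    sorted_values: np.ndarray
    source_n_samples: int

    def __post_init__(self) -> None:
        values = np.asarray(self.sorted_values, dtype=float)
        if values.ndim != 1 or values.size == 0:
            raise ValueError("target distribution must be a non-empty 1-D vector")
        if not np.isfinite(values).all():
            raise ValueError("target distribution contains non-finite values")
        if (np.diff(values) < 0).any():
            raise ValueError("target distribution must be sorted ascending")
        object.__setattr__(self, "sorted_values", values)

    def __len__(self) -> int:
        return self.sorted_values.size


def log2_plus_one(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """log2(x + 1) transform for raw TPM/FPKM matrices."""
    if matrix.scale_tag not in ("tpm", "fpkm"):
        raise ValueError(
            f"log2_plus_one expects tpm or fpkm input, got {matrix.scale_tag!r}"
        )
    values = matrix.values
    if (values < 0).any():
        raise ValueError("negative abundance values cannot be log-transformed")
    return matrix.with_values(np.log2(values + 1.0), "log2_intensity")


def target_distribution_from_training(training: ExpressionMatrix) -> TargetDistribution:
    """Sorted per-probe mean intensity of the training cohort."""
    if training.scale_tag != "log2_intensity":
        raise ValueError("training matrix must carry log2 intensities")
    if training.shape[1] < 1:
        raise ValueError("training matrix needs at least one sample")
    means = training.values.mean(axis=1)
    return TargetDistribution(np.sort(means), training.shape[1])


def _normalize_column(col: np.ndarray, target: TargetDistribution) -> np.ndarray:
    r = col.size
    length = len(target)
    order = np.argsort(col, kind="stable")
    probs = (np.arange(1, r + 1) - 0.5) / r
    grid = (np.arange(1, length + 1) - 0.5) / length
    mapped = np.interp(probs, grid, target.sorted_values)
    # tie rule: tied ranks share the mean of the values they would map to
    sorted_col = col[order]
    new_group = np.empty(r, dtype=bool)
    new_group[0] = True
    np.not_equal(sorted_col[1:], sorted_col[:-1], out=new_group[1:])
    group = np.cumsum(new_group) - 1
    sums = np.bincount(group, weights=mapped)
    cnts = np.bincount(group)
    mapped = (sums / cnts)[group]
    out = np.empty(r)
    out[order] = mapped
    return out


def quantile_normalize_to_target(
    matrix: ExpressionMatrix, target: TargetDistribution
) -> ExpressionMatrix:
    """Quantile-normalize every column independently to the target distribution."""
    if matrix.shape[0] == 0 or matrix.shape[1] == 0:
        raise ValueError("cannot quantile-normalize an empty matrix")
    if matrix.shape[1] == 1:
        warnings.warn(
            "single-sample quantile normalization: distribution matching against "
            "the full training cohort is unreliable for lone samples; submit "
            "samples in batches where possible",
            stacklevel=2,
        )
    values = matrix.values
    out = np.empty_like(values, dtype=float)
    for j in range(values.shape[1]):
        out[:, j] = _normalize_column(values[:, j], target)
    return matrix.with_values(out, "normalized")
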
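"""Fixed-rotation PCA projection and cross-platform concordance metrics.

The PCA is fit once on the training cohort; new samples are centered and
scaled with the *training* statistics and multiplied by the frozen rotation,
so repeated runs with different test sets leave the training scores — and the
plot — unchanged. Component signs are fixed deterministically (the largest-
magnitude loading of each component is made positive) because eigen-solvers
are sign-ambiguous.

Concordance between a microarray profile and its paired RNA-Seq profile is
summarized by the R-squared of an ordinary least-squares fit, Spearman's rank
correlation, and a per-sample comparison of subtype calls into
perfect_match / confidence_mismatch / class_mismatch.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .classifier import SubtypeCall
from .matrix import ExpressionMatrix


@dataclass
class PcaModel:
    feature_ids: tuple[str, ...]
    center: np.ndarray
    scale: np.ndarray
    rotation: np.ndarray  # features x components
    explained_variance: np.ndarray

    def __post_init__(self) -> None:
        if (self.scale <= 0).any():
            raise ValueError("feature scale must be strictly positive")


def fit_pca(training: ExpressionMatrix, scale_features: bool = True) -> PcaModel:
    """PCA of the training samples (rows = features, columns = samples).

    Features with zero variance are dropped (with a warning) when scaling is
    on; at least three samples are required.
    """
    n_samples = training.shape[1]
    if n_samples < 3:
        raise ValueError("PCA requires at least three training samples")
    x = training.values.T  # samples x features
    feature_ids = np.asarray(training.row_ids)
    sd = x.std(axis=0, ddof=1)
    if scale_features:
        keep = sd > 0
        if not keep.all():
            warnings.warn(
                f"dropping {int((~keep).sum())} zero-variance feature(s) before "
                "scaled PCA",
                stacklevel=2,
            )
        x = x[:, keep]
        feature_ids = feature_ids[keep]
        sd = sd[keep]
        scale = sd
    else:
        scale = np.ones(x.shape[1])
    center = x.mean(axis=0)
    xs = (x - center) / scale
    _, s, vt = np.linalg.svd(xs, full_matrices=False)
    rotation = vt.T
    # deterministic sign: largest-magnitude loading of each component positive
    for j in range(rotation.shape[1]):
        i = int(np.argmax(np.abs(rotation[:, j])))
        if rotation[i, j] < 0:
            rotation[:, j] = -rotation[:, j]
    explained = s**2 / (n_samples - 1)
    return PcaModel(tuple(feature_ids), center, scale, rotation, explained)


def project_samples(matrix: ExpressionMatrix, model: PcaModel,
                    n_components: int = 2) -> pd.DataFrame:
    """Scores of new samples in the frozen training PC space."""
    missing = [f for f in model.feature_ids if f not in matrix.frame.index]
    if missing:
        raise KeyError(
            f"{len(missing)} PCA feature(s) missing from matrix, e.g. {missing[:5]}"
        )
    n_components = min(n_components, model.rotation.shape[1])
    x = matrix.frame.loc[list(model.feature_ids)].to_numpy().T
    scores = ((x - model.center) / model.scale) @ model.rotation[:, :n_components]
    return pd.DataFrame(
        scores,
        index=list(matrix.col_ids),
        columns=[f"PC{i + 1}" for i in range(n_components)],
    )


def r_squared(x: np.ndarray, y: np.ndarray) -> float:
    """R^2 of the ordinary least-squares regression of y on x."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need equal-length vectors with at least 3 entries")
    if np.std(y) == 0:
        raise ValueError("R^2 undefined for zero-variance response")
    result = stats.linregress(x, y)
    return float(result.rvalue**2)


def spearman_rho(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman rank correlation (mid-ranks for ties)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need equal-length vectors with at least 3 entries")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("spearman undefined for constant input")
    rho = stats.spearmanr(x, y).statistic
    return float(rho)


def compare_calls(call_a: SubtypeCall, call_b: SubtypeCall) -> str:
    """perfect_match / confidence_mismatch / class_mismatch for a call pair.

    A perfect match agrees on subtype and confidence (and on the mixed set
    when mixed). Pairs that agree on the assigned subtype — or where one
    call's mixed set contains the other's assignment — differ only in
    confidence; anything else is a class mismatch.
    """
    if call_a.sample_id != call_b.sample_id:
        raise ValueError(
            f"sample IDs differ: {call_a.sample_id!r} vs {call_b.sample_id!r}"
        )
    same_subtype = call_a.assigned_subtype == call_b.assigned_subtype
    if same_subtype and call_a.confidence == call_b.confidence:
        if call_a.confidence != "mixed" or call_a.mixed_set == call_b.mixed_set:
            return "perfect_match"
    if (
        same_subtype
        or call_b.assigned_subtype in call_a.mixed_set
        or call_a.assigned_subtype in call_b.mixed_set
    ):
        return "confidence_mismatch"
    return "class_mismatch"


@dataclass
class ConcordanceReport:
    r2: float
    spearman: float
    call_comparison: dict[str, str]
    per_sample_spearman: dict[str, float] = field(default_factory=dict)

    @property
    def counts(self) -> dict[str, int]:
        out = {"perfect_match": 0, "confidence_mismatch": 0, "class_mismatch": 0}
        for cat in self.call_comparison.values():
            out[cat] += 1
        return out

    @property
    def match_fraction(self) -> float:
        n = len(self.call_comparison)
        return self.counts["perfect_match"] / n if n else float("nan")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": list(self.call_comparison),
                "category": list(self.call_comparison.values()),
                "spearman": [
                    self.per_sample_spearman.get(s, np.nan)
                    for s in self.call_comparison
                ],
            }
        )


def concordance_report(
    matrix_a: ExpressionMatrix,
    matrix_b: ExpressionMatrix,
    calls_a: list[SubtypeCall],
    calls_b: list[SubtypeCall],
) -> ConcordanceReport:
    """Pooled R^2/Spearman over all probes and samples plus per-call categories.

    The two matrices must be row-aligned and hold the same samples (columns
    may be ordered differently); calls are matched by sample ID.
    """
    if matrix_a.row_ids != matrix_b.row_ids:
        raise ValueError("matrices must share row IDs in the same order")
    if set(matrix_a.col_ids) != set(matrix_b.col_ids):
        raise ValueError("matrices must hold the same samples")
    b_aligned = matrix_b.frame[list(matrix_a.col_ids)]
    flat_a = matrix_a.values.ravel()
    flat_b = b_aligned.to_numpy().ravel()
    per_sample = {
        col: spearman_rho(matrix_a.frame[col].to_numpy(), b_aligned[col].to_numpy())
        for col in matrix_a.col_ids
    }
    by_id_a = {c.sample_id: c for c in calls_a}
    by_id_b = {c.sample_id: c for c in calls_b}
    if set(by_id_a) != set(by_id_b):
        raise ValueError("call lists cover different samples")
    comparison = {s: compare_calls(by_id_a[s], by_id_b[s]) for s in by_id_a}
    return ConcordanceReport(
        r2=r_squared(flat_a, flat_b),
        spearman=spearman_rho(flat_a, flat_b),
        call_comparison=comparison,
        per_sample_spearman=per_sample,
    )


def pca_plot(train_scores: pd.DataFrame, train_labels: list[str],
             test_scores: pd.DataFrame | None = None, path: str | None = None):
    """PC1-PC2 scatter of training samples (circles) and test samples (triangles)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    labels_arr = np.asarray(train_labels)
    for subtype in sorted(set(train_labels)):
        mask = labels_arr == subtype
        ax.scatter(train_scores.iloc[mask, 0], train_scores.iloc[mask, 1],
                   s=18, alpha=0.6, label=subtype)
    if test_scores is not None:
        ax.scatter(test_scores.iloc[:, 0], test_scores.iloc[:, 1],
                   marker="^", s=40, c="black", label="test")
    ax.set_xlabel("PC1")
    ax.set_ylabel("PC2")
    ax.legend(fontsize=7)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
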
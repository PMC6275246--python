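"""Distance-to-centroid molecular subtyping with confidence scoring.

The classifier mirrors the six-class CITBCMST scheme (basL, lumA, lumB, lumC,
mApo, normL): each subtype is represented by the mean vector of its training
samples over the signature probe sets, and a new sample is assigned to the
subtype with the closest centroid. Two distances are supported:

* ``dlda`` — the diagonal linear discriminant analysis statistic with uniform
  class priors, i.e. the variance-weighted squared Euclidean distance
  d(x, k) = sum_g (x_g - mu_kg)^2 / s2_g with s2_g the pooled within-class
  variance of feature g;
* ``pearson`` — 1 minus the Pearson correlation with the centroid.

Each call carries a confidence label. If the sample sits within t of more
than one centroid — t being the 10th percentile of the pairwise centroid
distances in training — the call is *mixed* and lists the near-tied subtypes.
Otherwise the call is *core* unless the distance to the winning centroid
exceeds an outlier threshold built from the training samples' distances to
their own centroid (median and raw MAD, scaled by the multiplier n defined as
the largest (max - med)/mad over the subtypes), in which case it is
*outlier*. Two readings of the outlier rule are selectable:
``med_plus_n_mad`` (default; d > med_k + n * mad_k, under which the most
extreme training sample sits exactly on its subtype's threshold) and
``n_mad`` (d > n * mad_k, the literal multiplier-only reading).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix

logger = logging.getLogger(__name__)

MODEL_FORMAT_VERSION = "rnabc-subtype-model-1"
OUTLIER_RULES = ("med_plus_n_mad", "n_mad")
_VAR_FLOOR = 1e-8


@dataclass
class SubtypeModel:
    subtypes: tuple[str, ...]
    signature_ids: tuple[str, ...]
    centroids: np.ndarray  # subtypes x features
    pooled_var: np.ndarray  # features
    distance_method: str
    mixed_threshold: float
    med: np.ndarray  # per subtype
    mad: np.ndarray  # per subtype, raw (no 1.4826 constant)
    outlier_multiplier: float
    outlier_rule: str = "med_plus_n_mad"

    def outlier_threshold(self, k: int) -> float:
        if self.outlier_rule == "med_plus_n_mad":
            return float(self.med[k] + self.outlier_multiplier * self.mad[k])
        return float(self.outlier_multiplier * self.mad[k])

    def to_json(self, path: str | Path) -> None:
        payload = {
            "format_version": MODEL_FORMAT_VERSION,
            "subtypes": list(self.subtypes),
            "signature_ids": list(self.signature_ids),
            "centroids": self.centroids.tolist(),
            "pooled_var": self.pooled_var.tolist(),
            "distance_method": self.distance_method,
            "mixed_threshold": self.mixed_threshold,
            "med": self.med.tolist(),
            "mad": self.mad.tolist(),
            "outlier_multiplier": self.outlier_multiplier,
            "outlier_rule": self.outlier_rule,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "SubtypeModel":
        payload = json.loads(Path(path).read_text())
        if payload.get("format_version") != MODEL_FORMAT_VERSION:
            raise ValueError(f"unsupported model format {payload.get('format_version')!r}")
        return cls(
            subtypes=tuple(payload["subtypes"]),
            signature_ids=tuple(payload["signature_ids"]),
            centroids=np.asarray(payload["centroids"], dtype=float),
            pooled_var=np.asarray(payload["pooled_var"], dtype=float),
            distance_method=payload["distance_method"],
            mixed_threshold=float(payload["mixed_threshold"]),
            med=np.asarray(payload["med"], dtype=float),
            mad=np.asarray(payload["mad"], dtype=float),
            outlier_multiplier=float(payload["outlier_multiplier"]),
            outlier_rule=payload["outlier_rule"],
        )


@dataclass
class SubtypeCall:
    sample_id: str
    assigned_subtype: str
    confidence: str  # core | mixed | outlier
    mixed_set: tuple[str, ...]
    distances: np.ndarray
    subtypes: tuple[str, ...]

    @property
    def label(self) -> str:
        """Human-readable rendering, e.g. 'lumA/lumB mixed' or 'basL'."""
        if self.confidence == "mixed":
            return "/".join(self.mixed_set) + " mixed"
        return self.assigned_subtype


def dlda_distance(x: np.ndarray, k: int, model: SubtypeModel) -> float:
    """Variance-weighted squared distance of x to centroid k."""
    x = np.asarray(x, dtype=float)
    if x.shape != (len(model.signature_ids),):
        raise ValueError(
            f"feature vector length {x.size} != signature size {len(model.signature_ids)}"
        )
    s2 = np.maximum(model.pooled_var, _VAR_FLOOR)
    diff = x - model.centroids[k]
    return float(np.sum(diff * diff / s2))


def pearson_distance(x: np.ndarray, centroid: np.ndarray) -> float:
    """1 - Pearson correlation; range [0, 2]."""
    x = np.asarray(x, dtype=float)
    centroid = np.asarray(centroid, dtype=float)
    if x.shape != centroid.shape or x.size < 3:
        raise ValueError("vectors must share a length of at least 3")
    if np.std(x) == 0 or np.std(centroid) == 0:
        raise ValueError("pearson distance undefined for zero-variance input")
    r = float(np.corrcoef(x, centroid)[0, 1])
    return 1.0 - r


def _all_distances(x: np.ndarray, model: SubtypeModel) -> np.ndarray:
    if model.distance_method == "dlda":
        return np.array([dlda_distance(x, k, model) for k in range(len(model.subtypes))])
    return np.array([pearson_distance(x, model.centroids[k])
                     for k in range(len(model.subtypes))])


def train_subtype_model(
    training: ExpressionMatrix,
    labels: list[str],
    signature_ids: list[str],
    distance_method: str = "dlda",
    outlier_rule: str = "med_plus_n_mad",
) -> SubtypeModel:
    """Fit centroids, the mixed threshold t, and the outlier statistics.

    Subtypes are ordered alphabetically (which reproduces the canonical
    basL..normL ordering for the six-class instance). Every subtype needs at
    least two training samples; a subtype with zero MAD is excluded from the
    max defining the multiplier n, with a warning.
    """
    if distance_method not in ("dlda", "pearson"):
        raise ValueError(f"unknown distance method {distance_method!r}")
    if outlier_rule not in OUTLIER_RULES:
        raise ValueError(f"outlier_rule must be one of {OUTLIER_RULES}")
    if len(labels) != training.shape[1]:
        raise ValueError("one label per training sample is required")
    sig = training.subset_rows(signature_ids)
    x = sig.values.T  # samples x features
    labels_arr = np.asarray([str(b) for b in labels])
    subtypes = tuple(sorted({str(x) for x in labels_arr}))

    centroids = np.empty((len(subtypes), x.shape[1]))
    within_ss = np.zeros(x.shape[1])
    for k, s in enumerate(subtypes):
        members = x[labels_arr == s]
        if members.shape[0] < 2:
            raise ValueError(f"subtype {s!r} has fewer than two training samples")
        centroids[k] = members.mean(axis=0)
        within_ss += ((members - centroids[k]) ** 2).sum(axis=0)
    pooled_var = np.maximum(within_ss / (x.shape[0] - len(subtypes)), _VAR_FLOOR)

    model = SubtypeModel(
        subtypes=subtypes,
        signature_ids=tuple(signature_ids),
        centroids=centroids,
        pooled_var=pooled_var,
        distance_method=distance_method,
        mixed_threshold=np.nan,
        med=np.zeros(len(subtypes)),
        mad=np.zeros(len(subtypes)),
        outlier_multiplier=0.0,
        outlier_rule=outlier_rule,
    )

    pairwise = [
        _all_distances(centroids[a], model)[b]
        for a in range(len(subtypes))
        for b in range(a + 1, len(subtypes))
    ]
    model.mixed_threshold = float(np.quantile(pairwise, 0.10))

    ratios = []
    for k, s in enumerate(subtypes):
        members = x[labels_arr == s]
        dists = np.array([_all_distances(m, model)[k] for m in members])
        med = float(np.median(dists))
        mad = float(np.median(np.abs(dists - med)))
        model.med[k] = med
        model.mad[k] = mad
        if mad > 0:
            ratios.append((dists.max() - med) / mad)
        else:
            warnings.warn(
                f"subtype {s!r} has zero MAD of training distances; excluded from "
                "the outlier multiplier",
                stacklevel=2,
            )
    model.outlier_multiplier = float(max(ratios)) if ratios else 0.0
    if not ratios:
        warnings.warn("all subtypes degenerate; outlier multiplier set to 0",
                      stacklevel=2)
    return model


def classify_sample(x: np.ndarray, model: SubtypeModel,
                    sample_id: str = "sample") -> SubtypeCall:
    """Assign the nearest centroid and a core/mixed/outlier confidence label."""
    distances = _all_distances(np.asarray(x, dtype=float), model)
    k_star = int(np.argmin(distances))
    ties = np.flatnonzero(distances == distances[k_star])
    if ties.size > 1:
        logger.info(
            "sample %s: exact distance tie between %s; keeping first in model order",
            sample_id, [model.subtypes[t] for t in ties],
        )
    near = distances - distances[k_star] < model.mixed_threshold
    mixed_set = tuple(model.subtypes[k] for k in np.flatnonzero(near))
    if len(mixed_set) >= 2:
        confidence = "mixed"
    elif distances[k_star] > model.outlier_threshold(k_star):
        confidence = "outlier"
        mixed_set = (model.subtypes[k_star],)
    else:
        confidence = "core"
        mixed_set = (model.subtypes[k_star],)
    return SubtypeCall(
        sample_id=sample_id,
        assigned_subtype=model.subtypes[k_star],
        confidence=confidence,
        mixed_set=mixed_set,
        distances=distances,
        subtypes=model.subtypes,
    )


def classify_matrix(matrix: ExpressionMatrix, model: SubtypeModel) -> list[SubtypeCall]:
    """Classify every column; rows are subset to the signature in model order."""
    missing = [g for g in model.signature_ids if g not in matrix.frame.index]
    if missing:
        raise KeyError(
            f"{len(missing)} signature feature(s) missing from matrix, "
            f"e.g. {missing[:5]}"
        )
    sig = matrix.frame.loc[list(model.signature_ids)]
    return [
        classify_sample(sig[col].to_numpy(), model, sample_id=str(col))
        for col in sig.columns
    ]


def calls_to_frame(calls: list[SubtypeCall]) -> pd.DataFrame:
    """Tabular view of calls: one row per sample plus per-subtype distances."""
    if not calls:
        return pd.DataFrame(
            columns=["sample_id", "subtype", "confidence", "mixed_set"]
        )
    subtypes = calls[0].subtypes
    rows = []
    for c in calls:
        row = {
            "sample_id": c.sample_id,
            "subtype": c.assigned_subtype,
            "confidence": c.confidence,
            "mixed_set": "/".join(c.mixed_set),
        }
        row.update({f"dist_{s}": d for s, d in zip(subtypes, c.distances)})
        rows.append(row)
    return pd.DataFrame(rows)
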
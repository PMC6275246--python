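"""Equivalence-class read assignment and EM abundance estimation.

A read is *compatible* with a target when every one of its k-mers that is
present in the index occurs in that target; the set of compatible targets is
the read's equivalence class. Reads are never base-aligned. Class counts feed
a standard mixture-model EM: a read from class C is generated by target t in C
with probability proportional to alpha_t / length_t, where alpha_t is the
(unknown) fraction of reads originating from t. The EM maximizes

    L(alpha) = sum_C n_C * log( sum_{t in C} alpha_t / l_t ),  sum alpha = 1,

which is concave, and abundances are reported as transcripts per million:
TPM_t = 1e6 * (alpha_t/l_t) / sum_u (alpha_u/l_u).
"""

from __future__ import annotations

import gzip
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from . import _kmers
from .probe_reference import KmerIndex

logger = logging.getLogger(__name__)


@dataclass
class ReadSet:
    """Single- or paired-end reads held in memory.

    ``mate2`` is None for single-end data; when present it must parallel
    ``mate1`` record for record.
    """

    ids: list[str]
    mate1: list[str]
    mate2: list[str] | None = None

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.mate1):
            raise ValueError("ids and mate1 must have equal length")
        if self.mate2 is not None and len(self.mate2) != len(self.mate1):
            raise ValueError("paired ReadSet requires a mate2 for every record")

    @property
    def paired(self) -> bool:
        return self.mate2 is not None

    def __len__(self) -> int:
        return len(self.mate1)

    @classmethod
    def from_fastq(cls, path1: str | Path, path2: str | Path | None = None) -> "ReadSet":
        ids, seqs1 = _read_fastq(path1)
        if path2 is None:
            return cls(ids, seqs1)
        ids2, seqs2 = _read_fastq(path2)
        if len(ids2) != len(ids):
            raise ValueError("mate FASTQ files have different record counts")
        return cls(ids, seqs1, seqs2)

    def write_fastq(self, path1: str | Path, path2: str | Path | None = None) -> None:
        _write_fastq(path1, self.ids, self.mate1)
        if self.paired:
            if path2 is None:
                raise ValueError("paired ReadSet needs two output paths")
            _write_fastq(path2, self.ids, self.mate2)


def _read_fastq(path: str | Path) -> tuple[list[str], list[str]]:
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    ids: list[str] = []
    seqs: list[str] = []
    with opener(path, "rt") as fh:
        for title, seq, _qual in FastqGeneralIterator(fh):
            ids.append(title.split()[0])
            seqs.append(seq.upper())
    return ids, seqs


def _write_fastq(path: str | Path, ids: list[str], seqs: list[str]) -> None:
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as fh:
        for rid, seq in zip(ids, seqs):
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")


@dataclass
class EqClassCounts:
    """Read tallies per equivalence class (sorted tuples of target ordinals)."""

    classes: dict[tuple[int, ...], int]
    n_assigned: int
    n_unassigned: int
    n_too_short: int = 0

    def __post_init__(self) -> None:
        if sum(self.classes.values()) != self.n_assigned:
            raise ValueError("class counts do not sum to n_assigned")
        for cls_tuple in self.classes:
            if not cls_tuple or list(cls_tuple) != sorted(cls_tuple):
                raise ValueError(f"class tuple must be non-empty and sorted: {cls_tuple}")


@dataclass
class AbundanceTable:
    """Per-target abundance: TPM, expected counts, and the EM trace."""

    target_ids: tuple[str, ...]
    lengths: np.ndarray
    tpm: np.ndarray
    est_counts: np.ndarray
    n_iterations: int
    loglik_trace: np.ndarray = field(default_factory=lambda: np.empty(0))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "probe_set_id": list(self.target_ids),
                "length": self.lengths.astype(int),
                "est_counts": self.est_counts,
                "tpm": self.tpm,
            }
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")


def _mate_class(codes: np.ndarray, index: KmerIndex) -> tuple[int, ...] | None | str:
    """Equivalence class of one mate.

    Returns a sorted tuple of target ordinals, None when the mate carries no
    k-mer present in the index (uninformative), or "empty" when its index-hit
    k-mers have an empty target intersection (incompatible).
    """
    lookup = index.targets_for_code
    seen: set[tuple[int, ...]] = set()
    for code in codes:
        hit = lookup(int(code))
        if hit is not None:
            seen.add(hit)
    if not seen:
        return None
    it = iter(seen)
    result = set(next(it))
    for tup in it:
        result.intersection_update(tup)
        if not result:
            return "empty"
    return tuple(sorted(result))


def assign_read(mate1: str, mate2: str | None,
                index: KmerIndex) -> tuple[int, ...] | None:
    """Equivalence class for one read (pair), or None if unassigned.

    Per mate, target sets of index-present k-mers are intersected (absent
    k-mers are skipped — they are treated as sequencing noise, not
    contradictions). The pair's class is the intersection of the mates'
    informative classes; one informative mate decides alone.
    """
    vals = _kmers.encode_batch([m for m in (mate1, mate2) if m is not None])
    encoder = _kmers.forward_codes if index.stranded else _kmers.canonical_codes
    codes, valid = encoder(vals, index.k)
    classes = []
    for row in range(vals.shape[0]):
        classes.append(_mate_class(codes[row][valid[row]], index))
    return _combine_mates(classes)


def _combine_mates(classes: list) -> tuple[int, ...] | None:
    informative = [c for c in classes if c is not None]
    if not informative:
        return None
    if "empty" in informative:
        return None
    result = set(informative[0])
    for c in informative[1:]:
        result.intersection_update(c)
    if not result:
        return None
    return tuple(sorted(result))


def count_equivalence_classes(reads: ReadSet, index: KmerIndex) -> EqClassCounts:
    """Tally equivalence classes over a whole ReadSet (deterministic)."""
    n = len(reads)
    if n == 0:
        return EqClassCounts({}, 0, 0)
    encoder = _kmers.forward_codes if index.stranded else _kmers.canonical_codes
    mate_arrays = [reads.mate1] + ([reads.mate2] if reads.paired else [])
    per_mate: list[tuple[np.ndarray, np.ndarray]] = []
    for seqs in mate_arrays:
        vals = _kmers.encode_batch(seqs)
        per_mate.append(encoder(vals, index.k))

    counts: dict[tuple[int, ...], int] = {}
    n_unassigned = 0
    n_too_short = 0
    k = index.k
    for i in range(n):
        too_short = all(len(seqs[i]) < k for seqs in mate_arrays)
        mates = []
        for codes, valid in per_mate:
            row_codes = codes[i][valid[i]] if codes.shape[1] else codes[i][:0]
            mates.append(_mate_class(row_codes, index))
        cls = _combine_mates(mates)
        if cls is None:
            n_unassigned += 1
            if too_short:
                n_too_short += 1
        else:
            counts[cls] = counts.get(cls, 0) + 1
    n_assigned = n - n_unassigned
    if n_too_short:
        logger.info("%d read(s) shorter than k=%d were unassigned", n_too_short, k)
    return EqClassCounts(counts, n_assigned, n_unassigned, n_too_short)


def em_estimate(
    counts: EqClassCounts,
    lengths: np.ndarray,
    target_ids: tuple[str, ...] | None = None,
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> AbundanceTable:
    """EM abundance estimation over equivalence-class counts.

    ``lengths`` is indexed by target ordinal (the same ordinals used in the
    class tuples). Iteration stops when the maximum relative change of any
    non-negligible alpha falls below ``tol``. Targets absent from every class
    end at zero TPM; with no assigned reads an all-zero table is returned.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    lengths = np.asarray(lengths, dtype=float)
    n_targets = lengths.size
    if target_ids is None:
        target_ids = tuple(f"t{i}" for i in range(n_targets))
    if counts.n_assigned == 0:
        warnings.warn("no assigned reads; returning all-zero abundances", stacklevel=2)
        zeros = np.zeros(n_targets)
        return AbundanceTable(target_ids, lengths, zeros, zeros.copy(), 0)

    class_tuples = list(counts.classes)
    for tup in class_tuples:
        if max(tup) >= n_targets:
            raise ValueError(f"class references unknown target ordinal {max(tup)}")
    n_c = np.array([counts.classes[t] for t in class_tuples], dtype=float)
    keep = n_c > 0
    class_tuples = [t for t, k_ in zip(class_tuples, keep) if k_]
    n_c = n_c[keep]

    members = np.concatenate([np.asarray(t, dtype=np.int64) for t in class_tuples])
    class_of_member = np.concatenate(
        [np.full(len(t), i, dtype=np.int64) for i, t in enumerate(class_tuples)]
    )
    n_classes = len(class_tuples)
    n_reads = float(n_c.sum())

    alpha = np.full(n_targets, 1.0 / n_targets)
    loglik: list[float] = []
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        w = alpha / lengths
        denom = np.bincount(class_of_member, weights=w[members], minlength=n_classes)
        loglik.append(float(np.dot(n_c, np.log(denom))))
        frac = w[members] / denom[class_of_member] * n_c[class_of_member]
        expected = np.bincount(members, weights=frac, minlength=n_targets)
        new_alpha = expected / n_reads
        active = new_alpha > 1e-12
        rel = np.abs(new_alpha[active] - alpha[active]) / np.maximum(
            new_alpha[active], 1e-12
        )
        alpha = new_alpha
        if rel.size == 0 or rel.max() < tol:
            break

    rate = alpha / lengths
    total_rate = rate.sum()
    tpm = 1e6 * rate / total_rate if total_rate > 0 else np.zeros_like(rate)
    est_counts = alpha * counts.n_assigned
    return AbundanceTable(
        target_ids, lengths, tpm, est_counts, n_iter, np.asarray(loglik)
    )


def quantify(reads: ReadSet, index: KmerIndex, tol: float = 1e-8,
             max_iter: int = 1000) -> AbundanceTable:
    """Convenience wrapper: count equivalence classes, run the EM, name rows."""
    counts = count_equivalence_classes(reads, index)
    return em_estimate(
        counts, index.target_lengths, target_ids=index.target_ids,
        tol=tol, max_iter=max_iter,
    )
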
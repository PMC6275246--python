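"""Probe-set target sequences and the k-mer index used for pseudoalignment.

A probe set on an Affymetrix-style expression array is summarized from probes
that were all selected from one *target sequence* (a transcript region).
Quantifying RNA-Seq reads directly against these target sequences puts
sequencing-based abundances on the same feature space as the array, probe set
by probe set. This module loads the target-sequence FASTA, strips the AFFX
spike-in/control probe sets, and builds the exact-k-mer index that the
pseudoaligner matches reads against.
"""

from __future__ import annotations

import gzip
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
from Bio import SeqIO

from . import _kmers

logger = logging.getLogger(__name__)

_VALID_CHARS = frozenset("ACGTN")

INDEX_FORMAT_VERSION = "rnabc-kmer-index-1"


class ReferenceError(ValueError):
    """Raised for malformed or inconsistent target-sequence input."""


@dataclass(frozen=True)
class ProbeTargetSet:
    """Ordered mapping of probe-set IDs to nucleotide target sequences.

    Entry order is preserved and defines the row order of every downstream
    expression matrix.
    """

    entries: dict[str, str]

    def __post_init__(self) -> None:
        for pid, seq in self.entries.items():
            if not seq:
                raise ReferenceError(f"empty sequence for probe set {pid!r}")
            bad = set(seq) - _VALID_CHARS
            if bad:
                raise ReferenceError(
                    f"probe set {pid!r} contains invalid characters: {sorted(bad)}"
                )

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[str]:
        return iter(self.entries)

    def __getitem__(self, probe_set_id: str) -> str:
        return self.entries[probe_set_id]

    def __contains__(self, probe_set_id: str) -> bool:
        return probe_set_id in self.entries

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(self.entries)

    @property
    def lengths(self) -> np.ndarray:
        return np.array([len(s) for s in self.entries.values()], dtype=np.int64)

    def write_fasta(self, path: str | Path) -> None:
        path = Path(path)
        opener = gzip.open if path.suffix == ".gz" else open
        with opener(path, "wt") as fh:
            for pid, seq in self.entries.items():
                fh.write(f">{pid}\n")
                for i in range(0, len(seq), 70):
                    fh.write(seq[i : i + 70] + "\n")


def _normalize_sequence(raw: str, probe_set_id: str) -> str:
    seq = raw.upper().replace("U", "T")
    bad = set(seq) - _VALID_CHARS
    if bad:
        raise ReferenceError(
            f"record {probe_set_id!r}: invalid sequence characters {sorted(bad)}"
        )
    if not seq:
        raise ReferenceError(f"record {probe_set_id!r}: empty sequence")
    return seq


def load_target_fasta(path: str | Path) -> ProbeTargetSet:
    """Load probe-set target sequences from a (possibly gzipped) FASTA file.

    The probe-set ID is the first whitespace-delimited token of each header;
    sequences are uppercased and U is converted to T so RNA-alphabet files
    work. Duplicate IDs, empty files and malformed records are hard errors.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    is_gz = path.suffix == ".gz"
    opener = gzip.open if is_gz else open
    entries: dict[str, str] = {}
    with opener(path, "rt") as fh:
        try:
            for record in SeqIO.parse(fh, "fasta"):
                pid = record.id
                if pid in entries:
                    raise ReferenceError(f"duplicate probe set ID {pid!r} in {path}")
                entries[pid] = _normalize_sequence(str(record.seq), pid)
        except ValueError as exc:  # biopython's malformed-record signal
            if isinstance(exc, ReferenceError):
                raise
            raise ReferenceError(f"malformed FASTA record in {path}: {exc}") from exc
    if not entries:
        raise ReferenceError(f"no FASTA records found in {path}")
    return ProbeTargetSet(entries)


CONTROL_PREFIX = "AFFX"


def remove_control_probesets(targets: ProbeTargetSet) -> ProbeTargetSet:
    """Drop every AFFX spike-in/control probe set, preserving order."""
    kept = {pid: seq for pid, seq in targets.entries.items()
            if not pid.startswith(CONTROL_PREFIX)}
    n_removed = len(targets) - len(kept)
    if n_removed:
        logger.info("removed %d AFFX control probe sets", n_removed)
    if not kept:
        warnings.warn("all probe sets were AFFX controls; result is empty",
                      stacklevel=2)
    return ProbeTargetSet(kept)


@dataclass
class KmerIndex:
    """Canonical k-mer -> target index over a ProbeTargetSet.

    ``_code_to_targets`` maps the 2-bit canonical k-mer code to the sorted
    tuple of target ordinals containing it. In stranded mode only sense-strand
    k-mers are keyed (no canonicalization).
    """

    k: int
    target_ids: tuple[str, ...]
    target_lengths: np.ndarray
    stranded: bool = False
    _code_to_targets: dict[int, tuple[int, ...]] = field(default_factory=dict, repr=False)

    @property
    def n_kmers(self) -> int:
        return len(self._code_to_targets)

    def targets_for_code(self, code: int) -> tuple[int, ...] | None:
        return self._code_to_targets.get(code)

    def targets_for_kmer(self, kmer: str) -> tuple[str, ...]:
        """Probe-set IDs containing the given k-mer (either strand unless stranded)."""
        if len(kmer) != self.k:
            raise ValueError(f"expected a {self.k}-mer, got length {len(kmer)}")
        code = _kmers.encode_kmer(kmer)
        if not self.stranded:
            code = min(code, _kmers.revcomp_code(code, self.k))
        hit = self._code_to_targets.get(code, ())
        return tuple(self.target_ids[i] for i in hit)

    def kmer_to_targets(self) -> dict[str, tuple[str, ...]]:
        """Materialize the full index as strings (intended for small indexes)."""
        return {
            _kmers.decode_kmer(code, self.k): tuple(self.target_ids[i] for i in tids)
            for code, tids in sorted(self._code_to_targets.items())
        }

    def save(self, path: str | Path) -> None:
        """Serialize to JSON-lines: a header record, then one record per k-mer."""
        path = Path(path)
        with open(path, "w") as fh:
            header = {
                "format_version": INDEX_FORMAT_VERSION,
                "k": self.k,
                "stranded": self.stranded,
                "target_ids": list(self.target_ids),
                "target_lengths": [int(x) for x in self.target_lengths],
            }
            fh.write(json.dumps(header) + "\n")
            for code in sorted(self._code_to_targets):
                fh.write(json.dumps([code, list(self._code_to_targets[code])]) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "KmerIndex":
        with open(path) as fh:
            header = json.loads(fh.readline())
            if header.get("format_version") != INDEX_FORMAT_VERSION:
                raise ReferenceError(
                    f"unsupported index format {header.get('format_version')!r}"
                )
            mapping = {}
            for line in fh:
                code, tids = json.loads(line)
                mapping[int(code)] = tuple(tids)
        return cls(
            k=header["k"],
            target_ids=tuple(header["target_ids"]),
            target_lengths=np.asarray(header["target_lengths"], dtype=np.int64),
            stranded=header["stranded"],
            _code_to_targets=mapping,
        )


def build_kmer_index(targets: ProbeTargetSet, k: int = 31,
                     stranded: bool = False) -> KmerIndex:
    """Index every A/C/G/T k-window of every target.

    k must be odd and within [11, 63] (odd so a k-mer can never equal its own
    reverse complement, which keeps canonicalization unambiguous). Windows
    containing N are skipped; targets shorter than k are recorded in the index
    (so they keep a matrix row) but are unindexable, with a warning.
    """
    if k % 2 == 0 or not (11 <= k <= 63):
        raise ValueError(f"k must be odd and in [11, 63], got {k}")
    lengths = targets.lengths
    if len(targets) == 0 or not (lengths >= k).any():
        raise ReferenceError(f"no target of length >= k={k} to index")
    n_short = int((lengths < k).sum())
    if n_short:
        warnings.warn(
            f"{n_short} target(s) shorter than k={k} are unindexable", stacklevel=2
        )

    code_chunks: list[np.ndarray] = []
    tid_chunks: list[np.ndarray] = []
    encoder = _kmers.forward_codes if stranded else _kmers.canonical_codes
    for tid, seq in enumerate(targets.entries.values()):
        if len(seq) < k:
            continue
        vals = _kmers.encode_batch([seq])
        codes, valid = encoder(vals, k)
        codes = codes[valid]
        if codes.size:
            code_chunks.append(np.unique(codes))
            tid_chunks.append(np.full(code_chunks[-1].size, tid, dtype=np.int32))

    mapping: dict[int, tuple[int, ...]] = {}
    if code_chunks:
        all_codes = np.concatenate(code_chunks)
        all_tids = np.concatenate(tid_chunks)
        order = np.lexsort((all_tids, all_codes))
        all_codes, all_tids = all_codes[order], all_tids[order]
        uniq, starts = np.unique(all_codes, return_index=True)
        bounds = np.append(starts, all_codes.size)
        for i, code in enumerate(uniq):
            mapping[int(code)] = tuple(
                int(t) for t in all_tids[bounds[i] : bounds[i + 1]]
            )
    return KmerIndex(
        k=k,
        target_ids=targets.ids,
        target_lengths=lengths,
        stranded=stranded,
        _code_to_targets=mapping,
    )
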
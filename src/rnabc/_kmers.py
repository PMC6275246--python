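"""Shared 2-bit k-mer encoding used by the index builder and the pseudoaligner.

Nucleotides are packed two bits per base (A=0, C=1, G=2, T=3); any other
character (N, padding) is marked invalid and every window touching it is
dropped. Canonical form is the lexicographic minimum of a k-mer code and the
code of its reverse complement, so both strands collapse to one key.
"""

from __future__ import annotations

import numpy as np

_LUT = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _LUT[_b] = _i

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def encode_batch(seqs: list[str]) -> np.ndarray:
    """Pack sequences into an (n, L_max) uint8 matrix of 2-bit codes.

    Shorter sequences are right-padded with the invalid marker 255, so padded
    positions can never contribute a window.
    """
    n = len(seqs)
    width = max((len(s) for s in seqs), default=0)
    out = np.full((n, width), 255, dtype=np.uint8)
    for i, s in enumerate(seqs):
        raw = np.frombuffer(s.encode("ascii"), dtype=np.uint8)
        out[i, : len(raw)] = _LUT[raw]
    return out


def canonical_codes(vals: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Canonical k-mer codes for every window of every row of ``vals``.

    Returns ``(codes, valid)`` with shape (n, L-k+1); windows containing an
    invalid base have ``valid`` False (their code entry is meaningless).
    """
    n, length = vals.shape
    w = length - k + 1
    if w <= 0:
        return (np.empty((n, 0), dtype=np.uint64), np.empty((n, 0), dtype=bool))
    fwd = np.zeros((n, w), dtype=np.uint64)
    rev = np.zeros((n, w), dtype=np.uint64)
    for i in range(k):
        col = (vals[:, i : i + w] & 3).astype(np.uint64)
        fwd = (fwd << np.uint64(2)) | col
        rev |= (np.uint64(3) - col) << np.uint64(2 * i)
    invalid = (vals == 255).astype(np.int32)
    cum = np.zeros((n, length + 1), dtype=np.int32)
    np.cumsum(invalid, axis=1, out=cum[:, 1:])
    valid = (cum[:, k:] - cum[:, :-k]) == 0
    return np.minimum(fwd, rev), valid


def forward_codes(vals: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Sense-strand (non-canonical) window codes; same contract as above."""
    n, length = vals.shape
    w = length - k + 1
    if w <= 0:
        return (np.empty((n, 0), dtype=np.uint64), np.empty((n, 0), dtype=bool))
    fwd = np.zeros((n, w), dtype=np.uint64)
    for i in range(k):
        fwd = (fwd << np.uint64(2)) | (vals[:, i : i + w] & 3).astype(np.uint64)
    invalid = (vals == 255).astype(np.int32)
    cum = np.zeros((n, length + 1), dtype=np.int32)
    np.cumsum(invalid, axis=1, out=cum[:, 1:])
    valid = (cum[:, k:] - cum[:, :-k]) == 0
    return fwd, valid


def encode_kmer(kmer: str) -> int:
    """2-bit code of a single k-mer (must be pure A/C/G/T)."""
    vals = _LUT[np.frombuffer(kmer.upper().encode("ascii"), dtype=np.uint8)]
    if (vals == 255).any():
        raise ValueError(f"k-mer contains non-ACGT characters: {kmer!r}")
    code = 0
    for v in vals:
        code = (code << 2) | int(v)
    return code


def decode_kmer(code: int, k: int) -> str:
    out = bytearray(k)
    for i in range(k - 1, -1, -1):
        out[i] = _BASES[code & 3]
        code >>= 2
    return out.decode("ascii")


def canonical_kmer(kmer: str) -> str:
    code = encode_kmer(kmer)
    rc = revcomp_code(code, len(kmer))
    return decode_kmer(min(code, rc), len(kmer))


def revcomp_code(code: int, k: int) -> int:
    rc = 0
    for _ in range(k):
        rc = (rc << 2) | (3 - (code & 3))
        code >>= 2
    return rc


_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (N self-complements)."""
    return seq.translate(_COMP)[::-1]
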
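"""Small sequence helpers shared across modules."""

from __future__ import annotations

import numpy as np

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

# 2-bit encoding used by the vectorised kmer path (A=0, C=1, G=2, T=3).
_ENC = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENC[_b] = _i
    _ENC[_b + 32] = _i


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-safe)."""
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode ACGT to uint8 0..3; other characters become 255."""
    return _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


_DEC = np.frombuffer(b"ACGT", dtype=np.uint8)


def decode(arr: np.ndarray) -> str:
    return _DEC[arr].tobytes().decode("ascii")


def canonical_kmer_counts(seq: str, k: int) -> dict:
    """Count canonical kmers (lexicographic min of kmer and reverse complement).

    Kmers overlapping non-ACGT characters are skipped.  For k <= 31 a
    vectorised 2-bit integer path is used; the returned dict maps the kmer
    *string* to its count either way.
    """
    if len(seq) < k:
        return {}
    if k <= 31:
        return _canonical_counts_fast(seq, k)
    counts: dict[str, int] = {}
    s = seq.upper()
    for i in range(len(s) - k + 1):
        kmer = s[i : i + k]
        if any(c not in "ACGT" for c in kmer):
            continue
        canon = min(kmer, revcomp(kmer))
        counts[canon] = counts.get(canon, 0) + 1
    return counts


def canonical_kmer_ints(seq: str, k: int) -> dict:
    """Like :func:`canonical_kmer_counts` but with 2-bit-packed integer
    keys (k <= 31 only); much faster for genome-scale input."""
    if k > 31:
        raise ValueError("integer kmers support k <= 31 only")
    if len(seq) < k:
        return {}
    vals, cnts = _canonical_arrays(seq, k)
    return dict(zip(vals.tolist(), cnts.tolist()))


def kmer_string(v: int, k: int) -> str:
    return _int_to_kmer(v, k)


def _canonical_arrays(seq: str, k: int):
    enc = encode(seq)
    valid = enc != 255
    enc = np.where(valid, enc, 0).astype(np.uint64)
    n = len(enc) - k + 1
    powers = (np.uint64(4) ** np.arange(k - 1, -1, -1, dtype=np.uint64)).astype(np.uint64)
    win = np.lib.stride_tricks.sliding_window_view(enc, k)
    fwd = (win * powers).sum(axis=1, dtype=np.uint64)
    rc_enc = (np.uint64(3) - enc)[::-1]
    rc_win = np.lib.stride_tricks.sliding_window_view(rc_enc, k)
    rev = (rc_win * powers).sum(axis=1, dtype=np.uint64)[::-1]
    canon = np.minimum(fwd, rev)
    # windows touching an invalid base are dropped
    ok = np.lib.stride_tricks.sliding_window_view(valid, k).all(axis=1)
    canon = canon[ok[:n]]
    return np.unique(canon, return_counts=True)


def _canonical_counts_fast(seq: str, k: int) -> dict:
    vals, cnts = _canonical_arrays(seq, k)
    return {_int_to_kmer(int(v), k): int(c) for v, c in zip(vals, cnts)}


def _int_to_kmer(v: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append("ACGT"[v & 3])
        v >>= 2
    return "".join(reversed(out))
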
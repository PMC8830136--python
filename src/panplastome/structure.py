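"""Quadripartite plastome architecture: detection and normalization.

Plastomes carry two inverted-repeat copies (IRa/IRb) separating a large
and a small single-copy region.  The IR pair is found directly from
sequence (maximal pair of disjoint reverse-complementary intervals,
seed-and-extend on the doubled sequence so origin-crossing repeats are
caught) or from read-coverage evidence (the IR shows roughly doubled
depth relative to single-copy regions).  Because the SSC occurs in two
orientations in vivo, a fixed convention (lexicographically smaller of
the SSC and its reverse complement) canonicalises samples before
comparison.
"""

from __future__ import annotations

import warnings
from typing import Optional, Sequence

import numpy as np

from ._util import revcomp
from .types import AnnotatedPlastome, GeneFeature, Interval, QuadripartitePartition

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


class NoInvertedRepeatWarning(UserWarning):
    pass


def detect_quadripartite(sequence: str, min_ir_len: int = 500,
                         mismatch_tol: float = 0.0) -> QuadripartitePartition:
    """Find the maximal inverted-repeat pair and label LSC/SSC.

    Seeds are exact kmer matches between the sequence and its reverse
    complement, grouped by anti-diagonal and extended greedily; with
    ``mismatch_tol > 0`` extension tolerates isolated mismatches up to
    that fraction of the repeat length (flanked by matches, so exact
    repeats are still recovered exactly).  If no repeat of at least
    ``min_ir_len`` exists, the whole molecule is returned as LSC with a
    warning.
    """
    seq = sequence.upper()
    L = len(seq)
    if L < 4 * min_ir_len:
        raise ValueError(f"sequence length {L} < 4*min_ir_len")
    best = _find_best_ir(seq, min_ir_len, mismatch_tol)
    if best is None:
        warnings.warn("no inverted repeat found; returning single-copy-only partition",
                      NoInvertedRepeatWarning)
        return QuadripartitePartition(lsc=Interval(0, L), ssc=None, ira=None, irb=None)
    (a, b, m) = best  # starts (mod L) and shared length
    # single-copy gaps between the two repeat copies on the circle
    gap1 = _gap(a + m, b, L)  # between end of first copy and start of second
    gap2 = _gap(b + m, a, L)
    if gap1[1] >= gap2[1]:
        lsc, ssc = gap1, gap2
        ira_start, irb_start = b, a  # IRa follows the LSC
    else:
        lsc, ssc = gap2, gap1
        ira_start, irb_start = a, b
    # IRa is the copy immediately after the LSC end
    if (lsc[0] + lsc[1]) % L == irb_start % L:
        ira_start, irb_start = irb_start, ira_start
    return QuadripartitePartition(
        lsc=_interval(lsc[0], lsc[1], L),
        ssc=_interval(ssc[0], ssc[1], L) if ssc[1] > 0 else None,
        ira=_interval(ira_start, m, L),
        irb=_interval(irb_start, m, L),
    )


def _interval(start: int, length: int, L: int) -> Interval:
    return Interval(start % L, start % L + length)


def _gap(start: int, end: int, L: int) -> tuple[int, int]:
    """(start, length) of the circular gap [start, end)."""
    return (start % L, (end - start) % L)


def _find_best_ir(seq: str, min_ir_len: int, tol: float):
    L = len(seq)
    k = min(31, min_ir_len)
    doubled = seq + seq[: k - 1]
    index: dict[str, list[int]] = {}
    for i in range(L):
        index.setdefault(doubled[i : i + k], []).append(i)
    rc = revcomp(seq)
    rc_doubled = rc + rc[: k - 1]
    diagonals: dict[int, tuple[int, int]] = {}
    for jr in range(L):
        kmer = rc_doubled[jr : jr + k]
        for i in index.get(kmer, ()):
            # rc position jr corresponds to forward start j of the partner kmer
            j = (L - jr - k) % L
            if i == j:
                continue
            d = (i + j) % L
            if d not in diagonals or i < diagonals[d][0]:
                diagonals[d] = (i, j)
    best = None
    for i, j in diagonals.values():
        ext = _extend(seq, i, j, k, tol)
        if ext is None:
            continue
        a, b, m = ext
        if m < min_ir_len:
            continue
        if not _disjoint(a, b, m, L):
            continue
        key = (m, -min(a, b))
        if best is None or key > best[0]:
            best = (key, (a, b, m))
    return None if best is None else best[1]


def _disjoint(a: int, b: int, m: int, L: int) -> bool:
    if 2 * m > L:
        return False
    return _gap(a + m, b, L)[1] + _gap(b + m, a, L)[1] + 2 * m == L


def _extend(seq: str, i: int, j: int, k: int, tol: float):
    """Greedy bidirectional extension of an inverted seed pair.

    The pair is (i .. i+k) on the forward strand matching the reverse
    complement of (j .. j+k).  Returns (start_a, start_b, length) with
    start_a canonically the smaller start, or None when the copies
    collide during extension.
    """
    L = len(seq)

    def comp_match(p, q):
        return _COMP.get(seq[p % L]) == seq[q % L]

    a_lo, a_hi = i, i + k  # [a_lo, a_hi)
    b_lo, b_hi = j, j + k
    mismatches = 0

    def budget():
        return tol * (a_hi - a_lo)

    # grow a to the right, b to the left
    while a_hi - a_lo < L // 2:
        if comp_match(a_hi, b_lo - 1):
            a_hi += 1
            b_lo -= 1
        elif tol > 0 and mismatches + 1 <= budget() and comp_match(a_hi + 1, b_lo - 2):
            mismatches += 1
            a_hi += 2
            b_lo -= 2
        else:
            break
    # grow a to the left, b to the right
    while a_hi - a_lo < L // 2:
        if comp_match(a_lo - 1, b_hi):
            a_lo -= 1
            b_hi += 1
        elif tol > 0 and mismatches + 1 <= budget() and comp_match(a_lo - 2, b_hi + 1):
            mismatches += 1
            a_lo -= 2
            b_hi += 2
        else:
            break
    m = a_hi - a_lo
    a, b = a_lo % L, b_lo % L
    if a > b:
        a, b = b, a
    return (a, b, m)


# ------------------------------------------------------------------ coverage

def detect_ir_by_coverage(track: Sequence[float], factor_low: float = 1.5,
                          factor_high: float = 2.5) -> Optional[Interval]:
    """Maximal contiguous (circular) interval with ~doubled depth.

    The single-copy depth is first estimated from the track, IR
    candidate positions (depth ratio within [factor_low, factor_high])
    are masked out, and the mean re-estimated once from the remaining
    positions; the returned interval is the longest circular run of
    positions whose depth ratio against the re-estimated single-copy mean
    lies in the window.  A flat track yields None.
    """
    depth = np.asarray(track, dtype=float)
    if depth.size == 0:
        raise ValueError("empty coverage track")
    # the IR occupies less than half the molecule, so the median is a
    # robust first estimate of single-copy depth
    sc = float(np.median(depth))
    if sc == 0:
        return None
    mask = (depth >= factor_low * sc) & (depth <= factor_high * sc)
    outside = depth[~mask]
    if outside.size:
        sc = outside.mean()
    mask = (depth >= factor_low * sc) & (depth <= factor_high * sc)
    if not mask.any():
        return None
    if mask.all():
        return None  # indistinguishable from a flat doubled track
    return _longest_circular_run(mask)


def _longest_circular_run(mask: np.ndarray) -> Optional[Interval]:
    L = mask.size
    doubled = np.concatenate([mask, mask])
    best_start, best_len = None, 0
    run_start = None
    for p in range(2 * L):
        if doubled[p]:
            if run_start is None:
                run_start = p
            run_len = min(p - run_start + 1, L)
            if run_len > best_len and run_start < L:
                best_start, best_len = run_start, run_len
        else:
            run_start = None
    if best_start is None:
        return None
    return Interval(best_start, best_start + best_len)


# ------------------------------------------------------------------ orientation

def normalize_orientation(plastome: AnnotatedPlastome) -> AnnotatedPlastome:
    """Flip the SSC to the canonical orientation if needed (idempotent).

    Canonical = the lexicographically smaller of the SSC sequence and its
    reverse complement.  Features wholly inside the SSC are remapped;
    a feature straddling an SSC boundary is an error.
    """
    part = plastome.partition
    if part is None:
        raise ValueError(f"{plastome.sample_id}: partition required")
    if part.ssc is None:
        return plastome
    L = len(plastome.sequence)
    ssc = part.ssc
    if ssc.wraps(L):
        raise ValueError("normalize_orientation expects a linearization where "
                         "the SSC does not cross the origin")
    ssc_seq = ssc.extract(plastome.sequence)
    rc = revcomp(ssc_seq)
    if ssc_seq <= rc:
        if part.orientation_flag == "canonical":
            return plastome
        return plastome.with_(partition=QuadripartitePartition(
            part.lsc, part.ssc, part.ira, part.irb, "canonical"))
    new_seq = plastome.sequence[: ssc.start] + rc + plastome.sequence[ssc.end :]
    new_feats = []
    for f in plastome.features:
        inside = ssc.start <= f.start and f.end <= ssc.end
        outside = f.end <= ssc.start or f.start >= ssc.end
        if inside:
            new_feats.append(GeneFeature(
                name=f.name,
                start=ssc.start + (ssc.end - f.end),
                end=ssc.start + (ssc.end - f.start),
                strand="-" if f.strand == "+" else "+",
                kind=f.kind,
            ))
        elif outside:
            new_feats.append(f)
        else:
            raise ValueError(f"feature {f.name} straddles an SSC boundary")
    return AnnotatedPlastome(
        sample_id=plastome.sample_id,
        sequence=new_seq,
        features=new_feats,
        partition=QuadripartitePartition(part.lsc, part.ssc, part.ira, part.irb,
                                         "canonical"),
    )
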
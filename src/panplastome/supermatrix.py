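"""Trimming, concatenation, codon partitioning, diagnostic-set selection
and a neighbor-joining stand-in tree.

The supermatrix is the concatenation of per-region trimmed alignments over
a shared taxon set, with a partition map recording which columns came from
which region and summary statistics (sites, site patterns, gap fraction,
invariant fraction) recomputable from the content.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
from skbio import DistanceMatrix
from skbio.tree import nj as _skbio_nj

from .alignstats import GAP, RegionAlignment, percent_identity
from .types import RegionKey

_GAP_B = ord(GAP)
_N_B = ord("N")


# ------------------------------------------------------------------ trimming

def trim_alignment(aln: RegionAlignment, gap_keep: float = 0.8,
                   min_similarity: float = 0.001) -> RegionAlignment:
    """Column filter in the spirit of trimAl's -gt/-st thresholds.

    A column is kept iff its non-gap fraction is >= ``gap_keep`` and its
    similarity — the frequency of the majority non-gap residue among
    non-gap residues — is >= ``min_similarity``.  An empty result is
    allowed.
    """
    m = aln.matrix()
    keep = _trim_mask(m, gap_keep, min_similarity)
    rows = {s: "".join(np.array(list(seq))[keep]) for s, seq in aln.rows.items()}
    return RegionAlignment(aln.key, rows)


def _trim_mask(m: np.ndarray, gap_keep: float, min_similarity: float) -> np.ndarray:
    n_rows = m.shape[0]
    nongap = m != _GAP_B
    frac = nongap.sum(axis=0) / n_rows
    keep = frac >= gap_keep
    sim = np.zeros(m.shape[1])
    for col in np.nonzero(keep)[0]:
        residues = m[nongap[:, col], col]
        if len(residues) == 0:
            continue
        _, counts = np.unique(residues, return_counts=True)
        sim[col] = counts.max() / len(residues)
    return keep & (sim >= min_similarity)


# ------------------------------------------------------------------ matrix

@dataclass
class SuperMatrix:
    sample_ids: list[str]
    rows: dict[str, str]
    partition_map: list[tuple[RegionKey, int, int]]  # key, start, end (half-open)

    @property
    def n_sites(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0

    def matrix(self) -> np.ndarray:
        return np.frombuffer(
            "".join(self.rows[s] for s in self.sample_ids).encode("ascii"),
            dtype=np.uint8,
        ).reshape(len(self.sample_ids), self.n_sites)

    def summary(self) -> dict:
        m = self.matrix()
        n_sites = m.shape[1]
        if n_sites == 0:
            return {"n_sites": 0, "n_site_patterns": 0,
                    "gap_fraction": 0.0, "invariant_fraction": 0.0}
        patterns = len({tuple(m[:, c]) for c in range(n_sites)})
        gap_fraction = float((m == _GAP_B).mean())
        informative = (m != _GAP_B) & (m != _N_B)
        invariant = 0
        for c in range(n_sites):
            residues = m[informative[:, c], c]
            if len(residues) and len(np.unique(residues)) == 1:
                invariant += 1
        return {
            "n_sites": int(n_sites),
            "n_site_patterns": int(patterns),
            "gap_fraction": gap_fraction,
            "invariant_fraction": invariant / n_sites,
        }


def concatenate(alignments: Sequence[RegionAlignment]) -> SuperMatrix:
    """Append alignments column-wise in the given (plastome) order."""
    if not alignments:
        raise ValueError("nothing to concatenate")
    sample_ids = sorted(alignments[0].rows)
    for aln in alignments:
        missing = set(sample_ids) ^ set(aln.rows)
        if missing:
            raise ValueError(f"{aln.key}: sample-set mismatch, differing ids {sorted(missing)}")
    parts: dict[str, list[str]] = {s: [] for s in sample_ids}
    partition_map = []
    offset = 0
    for aln in alignments:
        for s in sample_ids:
            parts[s].append(aln.rows[s])
        partition_map.append((aln.key, offset, offset + aln.length))
        offset += aln.length
    return SuperMatrix(sample_ids, {s: "".join(v) for s, v in parts.items()}, partition_map)


# ------------------------------------------------------------------ codon matrices

def build_matrices(alignments: Mapping[RegionKey, RegionAlignment],
                   cds_names: set[str],
                   gap_keep: float = 0.8,
                   min_similarity: float = 0.001) -> dict[str, SuperMatrix]:
    """Build the five classic partitioned matrices.

    (I) all gene regions, (II) all intergenic regions, (III) complete
    coding sequences with the first and last codon (start/stop) removed,
    (IV) first+second codon positions and (V) third positions of (III).
    (I)/(II) are trimmed; the codon matrices keep codon-faithful columns
    untrimmed.  A CDS whose column count after start/stop removal is not a
    multiple of three is excluded with a warning.
    """
    keys = list(alignments)
    genic = [trim_alignment(alignments[k], gap_keep, min_similarity)
             for k in keys if k.kind == "genic"]
    intergenic = [trim_alignment(alignments[k], gap_keep, min_similarity)
                  for k in keys if k.kind == "intergenic"]

    cds_alns, m4, m5 = [], [], []
    for k in keys:
        if k.kind != "genic" or k.name not in cds_names:
            continue
        aln = alignments[k]
        if aln.length <= 6:
            warnings.warn(f"{k}: too short after start/stop removal; excluded")
            continue
        core = RegionAlignment(k, {s: seq[3:-3] for s, seq in aln.rows.items()})
        if core.length % 3 != 0:
            warnings.warn(f"{k}: length not divisible by 3 after start/stop removal; excluded")
            continue
        cds_alns.append(core)
        idx = np.arange(core.length)
        keep12 = idx % 3 != 2
        m4.append(RegionAlignment(k, {
            s: "".join(np.array(list(seq))[keep12]) for s, seq in core.rows.items()}))
        m5.append(RegionAlignment(k, {
            s: "".join(np.array(list(seq))[~keep12]) for s, seq in core.rows.items()}))

    out = {}
    for name, alns in [("I", genic), ("II", intergenic), ("III", cds_alns),
                       ("IV", m4), ("V", m5)]:
        out[name] = concatenate(alns) if alns else None
    return out


# ------------------------------------------------------------------ diagnostic set

@dataclass
class DiagnosticSelection:
    selected: list[RegionKey]  # in selection order (ascending identity)
    separated: bool
    unseparated_pairs: list[tuple[str, str]]


def select_diagnostic_regions(alignments: Mapping[RegionKey, RegionAlignment],
                              identities: Optional[Mapping[RegionKey, float]] = None,
                              ) -> DiagnosticSelection:
    """Smallest identity-ordered prefix of regions separating all samples.

    Regions are sorted by ascending alignment identity (most variable
    first) and added one by one; a sample pair is separated once some
    column in the selected regions shows differing non-gap, non-N
    residues for the two samples.  Selection stops when every pair is
    separated; if that never happens the full list is returned together
    with the still-unseparated pairs.
    """
    keys = list(alignments)
    if identities is None:
        identities = {k: percent_identity(alignments[k]) for k in keys}
    order = sorted(keys, key=lambda k: (identities[k], str(k)))
    samples = sorted(alignments[order[0]].rows)
    pairs = {(a, b) for i, a in enumerate(samples) for b in samples[i + 1:]}

    selected: list[RegionKey] = []
    remaining = set(pairs)
    for key in order:
        selected.append(key)
        aln = alignments[key]
        for (a, b) in list(remaining):
            if _pair_separated(aln.rows[a], aln.rows[b]):
                remaining.discard((a, b))
        if not remaining:
            return DiagnosticSelection(selected, True, [])
    return DiagnosticSelection(selected, False, sorted(remaining))


def _pair_separated(sa: str, sb: str) -> bool:
    for x, y in zip(sa, sb):
        if x != y and x not in "-N" and y not in "-N":
            return True
    return False


# ------------------------------------------------------------------ NJ tree

def p_distance_matrix(matrix: SuperMatrix) -> DistanceMatrix:
    """Pairwise p-distances ignoring columns with a gap or N in either row."""
    ids = matrix.sample_ids
    m = matrix.matrix()
    informative = (m != _GAP_B) & (m != _N_B)
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = informative[i] & informative[j]
            if not ok.any():
                raise ValueError(f"no comparable columns between {ids[i]} and {ids[j]}")
            d[i, j] = d[j, i] = (m[i, ok] != m[j, ok]).mean()
    return DistanceMatrix(d, ids)


def nj_tree(matrix: SuperMatrix) -> str:
    """Neighbor-joining tree on p-distances; returns a newick string.

    A distance-based stand-in for full ML inference: on additive inputs NJ
    is consistent and recovers the generating topology.  Rows are taken in
    sorted label order so ties resolve deterministically.
    """
    if len(matrix.sample_ids) < 3:
        raise ValueError("nj_tree needs >=3 samples")
    dm = p_distance_matrix(matrix)
    tree = _skbio_nj(dm)
    return str(tree).strip()


def nj_tree_from_distances(dm: DistanceMatrix) -> str:
    return str(_skbio_nj(dm)).strip()


# ------------------------------------------------------------------ writers

def write_phylip(path, matrix: SuperMatrix) -> None:
    """Relaxed PHYLIP."""
    with open(path, "w") as fh:
        fh.write(f"{len(matrix.sample_ids)} {matrix.n_sites}\n")
        for s in matrix.sample_ids:
            fh.write(f"{s}  {matrix.rows[s]}\n")


def write_partition_file(path, matrix: SuperMatrix) -> None:
    """RAxML-style partition file: ``DNA, name = start-end`` (1-based)."""
    with open(path, "w") as fh:
        for key, start, end in matrix.partition_map:
            fh.write(f"DNA, {key.kind}_{key.name} = {start + 1}-{end}\n")
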
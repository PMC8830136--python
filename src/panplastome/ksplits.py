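"""Alignment-free phylogenetic splits from kmer presence patterns.

Each canonical kmer's presence pattern across samples proposes a
bipartition (split) of the sample set; shared derived sequence shows up as
heavy splits matching the true tree's internal edges.  A greedy
compatibility pass over the weighted splits extracts a tree ("strict"
mode); the full weighted split set can be written as a SplitsTree-readable
NEXUS network.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import dendropy

from ._util import canonical_kmer_counts, canonical_kmer_ints, kmer_string


# ------------------------------------------------------------------ SplitSet

@dataclass
class SplitSet:
    """Weighted bipartitions of a taxon set.

    Each split is stored as the frozenset side *not* containing the
    reference taxon (the lexicographically smallest label), so each
    bipartition has one canonical representation.
    """

    taxa: frozenset
    weights: dict = field(default_factory=dict)  # frozenset side -> weight

    def __post_init__(self):
        self.taxa = frozenset(self.taxa)
        ref = self.reference
        norm = {}
        for side, w in self.weights.items():
            side = frozenset(side)
            if not side < self.taxa or not side:
                raise ValueError("split side must be a nonempty proper subset")
            if ref in side:
                side = self.taxa - side
            norm[side] = norm.get(side, 0.0) + float(w)
        self.weights = norm

    @property
    def reference(self) -> str:
        return min(self.taxa)

    def __len__(self) -> int:
        return len(self.weights)

    def nontrivial(self) -> "SplitSet":
        n = len(self.taxa)
        return SplitSet(self.taxa, {s: w for s, w in self.weights.items()
                                    if 1 < len(s) < n - 1})

    def total_weight(self) -> float:
        return sum(self.weights.values())


# ------------------------------------------------------------------ profiles

@dataclass
class KmerProfile:
    k: int
    counts: dict  # kmer -> {sample_id: count}

    @property
    def samples(self) -> list[str]:
        return self._samples

    def __init__(self, k: int, counts: dict, samples: Iterable[str]):
        self.k = k
        self.counts = counts  # kmer (2-bit int for k<=31, else str) -> {sample: count}
        self._samples = list(samples)

    def kmers_as_strings(self) -> dict:
        """Counts keyed by the kmer string (decodes the packed form)."""
        return {
            (kmer_string(km, self.k) if isinstance(km, int) else km): per
            for km, per in self.counts.items()
        }


def build_profile(samples: Mapping[str, Iterable[str] | str], k: int = 31) -> KmerProfile:
    """Canonical kmer counts per sample; dataset-singleton kmers removed.

    ``samples`` maps sample id to a sequence or an iterable of sequences
    (assemblies or reads).  A kmer whose total count across the whole
    dataset is 1 carries no phylogenetic signal (sequencing noise in the
    read-based setting) and is filtered out.
    """
    count_fn = canonical_kmer_ints if k <= 31 else canonical_kmer_counts
    counts: dict = {}
    for sid, seqs in samples.items():
        if isinstance(seqs, str):
            seqs = [seqs]
        per_sample: dict = {}
        contributed = False
        for seq in seqs:
            if len(seq) < k:
                continue
            contributed = True
            for kmer, c in count_fn(seq, k).items():
                per_sample[kmer] = per_sample.get(kmer, 0) + c
        if not contributed:
            warnings.warn(f"sample {sid}: all sequences shorter than k={k}")
        for kmer, c in per_sample.items():
            counts.setdefault(kmer, {})[sid] = c
    filtered = {kmer: per for kmer, per in counts.items()
                if sum(per.values()) > 1}
    return KmerProfile(k, filtered, samples.keys())


def infer_splits(profile: KmerProfile, weight_fn: str = "count",
                 top: str = "all") -> SplitSet:
    """Aggregate kmer presence patterns into a weighted split set.

    weight_fn:
      * ``count`` — number of distinct kmers sharing the pattern;
      * ``geom``  — per kmer, the geometric mean of its counts in the
        samples carrying it, summed over supporting kmers;
      * ``geom2`` — as ``geom`` but divided by the (+1-smoothed) geometric
        mean of the kmer's counts in the remaining samples.
    top: ``all`` or ``10n`` (keep the 10 * n_taxa heaviest splits, ties at
    the cutoff kept).
    """
    taxa = frozenset(profile.samples)
    n = len(taxa)
    weights: dict[frozenset, float] = {}
    for kmer, per in profile.counts.items():
        side = frozenset(per)
        if len(side) == 0 or len(side) >= n:
            continue  # uninformative: absent or present everywhere
        if weight_fn == "count":
            w = 1.0
        else:
            gm = math.exp(sum(math.log(c) for c in per.values()) / len(per))
            if weight_fn == "geom":
                w = gm
            elif weight_fn == "geom2":
                # discount by the +1-smoothed geometric mean of counts in
                # samples outside the side; a presence pattern has count 0
                # there, so the discount is exp(mean(log(0+1))) = 1
                w = gm / 1.0
            else:
                raise ValueError(f"unknown weight_fn {weight_fn!r}")
        weights[side] = weights.get(side, 0.0) + w
    ss = SplitSet(taxa, weights)
    # singleton-side patterns carry no grouping information; drop them
    ss = SplitSet(taxa, {s: w for s, w in ss.weights.items()
                         if 1 < len(s) < n - 1})
    if top == "10n" and len(ss.weights) > 10 * n:
        cutoff = sorted(ss.weights.values(), reverse=True)[10 * n - 1]
        ss = SplitSet(taxa, {s: w for s, w in ss.weights.items() if w >= cutoff})
    elif top not in ("all", "10n"):
        raise ValueError(f"unknown top rule {top!r}")
    return ss


# ------------------------------------------------------------------ strict tree

def splits_compatible(a: frozenset, b: frozenset, taxa: frozenset) -> bool:
    """Two splits fit on one tree iff one of the four side-intersections
    is empty."""
    ac, bc = taxa - a, taxa - b
    return not (a & b) or not (a & bc) or not (ac & b) or not (ac & bc)


def greedy_compatible(splits: SplitSet) -> list[frozenset]:
    """Greedy maximal compatible subset, heaviest splits first.

    Ties break on smaller side size, then lexicographic side labels —
    fully deterministic.
    """
    order = sorted(
        splits.weights,
        key=lambda s: (-splits.weights[s], len(s), tuple(sorted(s))),
    )
    accepted: list[frozenset] = []
    for side in order:
        if all(splits_compatible(side, a, splits.taxa) for a in accepted):
            accepted.append(side)
    return accepted


def strict_tree(splits: SplitSet) -> str:
    """Greedy compatible tree from a weighted split set (newick string).

    Accepted splits form a laminar family of clusters (sides not
    containing the reference taxon), which nests directly into a rooted
    tree; branch lengths are split weights scaled by 1 / total weight.
    """
    if not splits.weights:
        # star tree over the taxa
        return "(" + ",".join(sorted(splits.taxa)) + ");"
    total = splits.total_weight()
    accepted = greedy_compatible(splits)
    clusters = sorted(accepted, key=len, reverse=True)

    taxon_ns = dendropy.TaxonNamespace(sorted(splits.taxa))
    tree = dendropy.Tree(taxon_namespace=taxon_ns)
    root = tree.seed_node
    node_of: dict[frozenset, dendropy.Node] = {frozenset(splits.taxa): root}

    def host(cluster: frozenset) -> dendropy.Node:
        best, best_node = frozenset(splits.taxa), root
        for c, nd in node_of.items():
            if cluster < c and len(c) < len(best):
                best, best_node = c, nd
        return best_node

    for c in clusters:
        nd = dendropy.Node()
        nd.edge.length = splits.weights[c] / total
        host(c).add_child(nd)
        node_of[c] = nd
    for label in sorted(splits.taxa):
        leaf = dendropy.Node(taxon=taxon_ns.get_taxon(label))
        leaf.edge.length = 0.0
        host(frozenset([label])).add_child(leaf)
    return tree.as_string(schema="newick", suppress_rooting=True).strip()


# ------------------------------------------------------------------ NEXUS

def to_splits_nexus(splits: SplitSet) -> str:
    """SplitsTree-readable NEXUS document with TAXA and SPLITS blocks."""
    taxa = sorted(splits.taxa)
    index = {t: i + 1 for i, t in enumerate(taxa)}
    lines = [
        "#NEXUS",
        "",
        "BEGIN TAXA;",
        f"DIMENSIONS ntax={len(taxa)};",
        "TAXLABELS",
        *[f"[{i + 1}] '{t}'" for i, t in enumerate(taxa)],
        ";",
        "END;",
        "",
        "BEGIN SPLITS;",
        f"DIMENSIONS ntax={len(taxa)} nsplits={len(splits.weights)};",
        "FORMAT labels=no weights=yes;",
        "MATRIX",
    ]
    for side in sorted(splits.weights, key=lambda s: tuple(sorted(s))):
        members = " ".join(str(index[t]) for t in sorted(side, key=lambda t: index[t]))
        lines.append(f"{splits.weights[side]:.6f} {members},")
    lines += [";", "END;", ""]
    return "\n".join(lines)


def from_splits_nexus(text: str) -> SplitSet:
    """Read back the NEXUS produced by :func:`to_splits_nexus`."""
    taxa: dict[int, str] = {}
    weights: dict[frozenset, float] = {}
    mode = None
    for raw in text.splitlines():
        line = raw.strip()
        if line.startswith("TAXLABELS"):
            mode = "taxa"
            continue
        if line.startswith("MATRIX"):
            mode = "splits"
            continue
        if line == ";":
            mode = None
            continue
        if mode == "taxa" and line.startswith("["):
            idx = int(line[1 : line.index("]")])
            taxa[idx] = line.split("'")[1]
        elif mode == "splits" and line:
            parts = line.rstrip(",").split()
            w = float(parts[0])
            side = frozenset(taxa[int(i)] for i in parts[1:])
            weights[side] = weights.get(side, 0.0) + w
    return SplitSet(frozenset(taxa.values()), weights)
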
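"""Quantitative comparison of trees and split sets.

Weighted precision / recall / F1 on split sets, the weighted symmetric
set distance, and the plain (unweighted count) Robinson–Foulds distance.
Split identity is by bipartition membership only; weights enter only the
weighted scores.  All semantics are unrooted: a rooted newick is unrooted
on parse and trivial (leaf-edge) splits are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import dendropy

from .ksplits import SplitSet


def _parse(tree: "str | dendropy.Tree") -> dendropy.Tree:
    if isinstance(tree, dendropy.Tree):
        return tree
    return dendropy.Tree.get(data=tree, schema="newick")


def splits_from_tree(tree: "str | dendropy.Tree") -> SplitSet:
    """One split per internal edge, weighted by branch length (1.0 if
    absent); trivial splits excluded.  Duplicate splits (the two edges at
    a rooted tree's basal bifurcation) have their lengths summed."""
    t = _parse(tree)
    leaves = [lf.taxon.label for lf in t.leaf_node_iter()]
    if any(l is None for l in leaves):
        raise ValueError("tree has unlabeled leaves")
    if len(leaves) < 4:
        raise ValueError("need >=4 leaves for nontrivial splits")
    taxa = frozenset(leaves)
    n = len(taxa)
    weights: dict[frozenset, float] = {}
    for node in t.preorder_node_iter():
        if node is t.seed_node:
            continue
        below = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if len(below) <= 1 or len(below) >= n - 1:
            continue
        w = node.edge.length if node.edge.length is not None else 1.0
        side = below if min(taxa) not in below else taxa - below
        weights[side] = weights.get(side, 0.0) + w
    return SplitSet(taxa, weights)


@dataclass(frozen=True)
class ComparisonReport:
    precision: float
    recall: float
    f1: float
    weighted_symmetric_distance: float
    rf_distance: int


def compare(predicted: SplitSet, reference: SplitSet) -> ComparisonReport:
    """Weighted precision/recall/F1 plus the two symmetric-difference
    distances.

    precision = total predicted weight on splits also in the reference /
    total predicted weight; recall analogous with reference weights.  The
    weighted symmetric set distance sums each set's own weights over the
    splits unique to it; the RF distance is the symmetric-difference size.
    """
    if predicted.taxa != reference.taxa:
        diff = sorted(predicted.taxa ^ reference.taxa)
        raise ValueError(f"taxon sets differ: {diff}")
    p_splits, r_splits = set(predicted.weights), set(reference.weights)
    # numerator and denominator accumulate in one iteration order so a
    # perfect match is exactly 1.0
    p_tot = sum(predicted.weights.values())
    r_tot = sum(reference.weights.values())
    p_hit = sum(w for s, w in predicted.weights.items() if s in r_splits)
    r_hit = sum(w for s, w in reference.weights.items() if s in p_splits)
    precision = p_hit / p_tot if p_tot else 0.0
    recall = r_hit / r_tot if r_tot else 0.0
    f1 = (2 * precision * recall / (precision + recall)) if (precision + recall) else 0.0
    only_p = p_splits - r_splits
    only_r = r_splits - p_splits
    wsd = sum(predicted.weights[s] for s in only_p) + sum(reference.weights[s] for s in only_r)
    return ComparisonReport(precision, recall, f1, wsd, len(only_p) + len(only_r))


def rf_distance(tree_a, tree_b) -> int:
    """Unweighted Robinson–Foulds distance between two trees."""
    return compare(splits_from_tree(tree_a), splits_from_tree(tree_b)).rf_distance


def all_vs_all(collections: Mapping[str, SplitSet]) -> dict[tuple[str, str], ComparisonReport]:
    """Full matrix of comparisons, each collection serving as reference."""
    if len(collections) < 2:
        raise ValueError("need >=2 collections")
    names = list(collections)
    return {
        (a, b): compare(collections[a], collections[b])
        for a in names
        for b in names
    }
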
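"""Kmer profiles, split inference, greedy compatible trees, NEXUS I/O."""

import itertools

import numpy as np
import pytest

from panplastome._util import revcomp
from panplastome.ksplits import (
    KmerProfile,
    SplitSet,
    build_profile,
    from_splits_nexus,
    greedy_compatible,
    infer_splits,
    splits_compatible,
    strict_tree,
    to_splits_nexus,
)
from panplastome.treecmp import rf_distance, splits_from_tree


# ------------------------------------------------------------ profiles

def test_canonical_kmers_small_example():
    # "ACGTA", k=3: kmers ACG,CGT,GTA -> canonical ACG,ACG,GTA; the
    # dataset-singleton GTA is filtered out
    prof = build_profile({"s": "ACGTA"}, k=3)
    assert prof.kmers_as_strings() == {"ACG": {"s": 2}}


def test_canonical_bruteforce_random():
    rng = np.random.default_rng(5)
    seq = "".join(rng.choice(list("ACGT"), size=200))
    prof = build_profile({"s": seq, "t": seq}, k=11)
    expect = {}
    for i in range(len(seq) - 10):
        km = seq[i:i + 11]
        canon = min(km, revcomp(km))
        expect[canon] = expect.get(canon, 0) + 1
    got = prof.kmers_as_strings()
    assert {k: v["s"] for k, v in got.items()} == {
        k: c for k, c in expect.items() if 2 * c > 1}


def test_duplicate_samples_identical_profiles():
    rng = np.random.default_rng(6)
    seq = "".join(rng.choice(list("ACGT"), size=500))
    prof = build_profile({"a": seq, "b": seq}, k=21)
    for per in prof.counts.values():
        assert per.get("a") == per.get("b")


def test_singleton_filter():
    # one kmer occurring exactly once in one sample disappears
    prof = build_profile({"a": "AAAAACCCCC", "b": "AAAAA"}, k=5)
    strs = prof.kmers_as_strings()
    assert "AAAAA" in strs  # total count > 1
    assert all("CCCCC" != k and "GGGGG" != k for k in strs)


def test_short_sequence_warns():
    with pytest.warns(UserWarning, match="shorter than k"):
        build_profile({"a": "ACGT", "b": "ACGTACGTACGTACGTACGTACGTACGTACG"}, k=31)


# ------------------------------------------------------------ split inference

def _profile(patterns, samples):
    """patterns: list of (sample subset, count per sample, multiplicity)."""
    counts = {}
    i = 0
    for side, c, mult in patterns:
        for _ in range(mult):
            counts[i] = {s: c for s in side}
            i += 1
    return KmerProfile(31, counts, samples)


def test_constructed_pattern_weight():
    prof = _profile([(("A", "B"), 1, 7), (("A", "B", "C", "D"), 1, 5)],
                    ["A", "B", "C", "D"])
    ss = infer_splits(prof, "count", "all")
    # the full-set pattern is uninformative; {A,B} stored as the side
    # not containing the reference taxon A, i.e. {C,D}
    assert ss.weights == {frozenset({"C", "D"}): 7.0}


def test_geom_weighting():
    prof = KmerProfile(31, {0: {"A": 2, "B": 8}}, ["A", "B", "C", "D"])
    ss = infer_splits(prof, "geom", "all")
    assert ss.weights[frozenset({"C", "D"})] == pytest.approx(4.0)
    ss2 = infer_splits(prof, "geom2", "all")
    assert ss2.weights == pytest.approx(ss.weights)


def test_label_permutation_equivariance():
    pats = [(("A", "B"), 1, 3), (("C", "D"), 1, 2)]
    taxa = ["A", "B", "C", "D"]
    ss = infer_splits(_profile(pats, taxa), "count", "all")
    perm = {"A": "C", "B": "D", "C": "A", "D": "B"}
    pats_p = [(tuple(perm[x] for x in side), c, m) for side, c, m in pats]
    ss_p = infer_splits(_profile(pats_p, taxa), "count", "all")
    expect = {frozenset(perm[x] for x in ss.taxa - side): w
              for side, w in ss.weights.items()}
    norm = SplitSet(frozenset(taxa), expect)  # re-canonicalise sides
    assert ss_p.weights == norm.weights


def test_top_10n_rule():
    taxa = [f"s{i}" for i in range(4)]
    sides = [c for r in (2,) for c in itertools.combinations(taxa, r)]
    pats = [(side, 1, i + 1) for i, side in enumerate(sides)]
    ss_all = infer_splits(_profile(pats, taxa), "count", "all")
    ss_top = infer_splits(_profile(pats, taxa), "count", "10n")
    assert len(ss_all) <= 10 * 4  # under the cap nothing is cut
    assert ss_top.weights == ss_all.weights


# ------------------------------------------------------------ compatibility

def test_splits_compatible():
    taxa = frozenset("ABCDE")
    assert splits_compatible(frozenset("AB"), frozenset("ABC"), taxa)
    assert not splits_compatible(frozenset("AB"), frozenset("BC"), taxa)


def test_greedy_rule_incompatible_pair():
    taxa = frozenset("ABCD")
    ss = SplitSet(taxa, {frozenset("AB"): 5.0, frozenset("BC"): 3.0})
    accepted = greedy_compatible(ss)
    # both sides are stored relative to reference 'A'; compare weights
    assert len(accepted) == 1
    assert ss.weights[accepted[0]] == 5.0


def test_greedy_matches_bruteforce_soups():
    rng = np.random.default_rng(17)
    taxa = [f"t{i}" for i in range(6)]
    for _ in range(40):
        sides = set()
        while len(sides) < 8:
            size = int(rng.integers(2, 5))
            sides.add(frozenset(rng.choice(taxa, size=size, replace=False)))
        weights = {s: float(rng.integers(1, 100)) for s in sides}
        ss = SplitSet(frozenset(taxa), weights)
        accepted = greedy_compatible(ss)
        order = sorted(ss.weights,
                       key=lambda s: (-ss.weights[s], len(s), tuple(sorted(s))))
        expect = []
        for s in order:
            if all(splits_compatible(s, a, ss.taxa) for a in expect):
                expect.append(s)
        assert accepted == expect


# ------------------------------------------------------------ strict tree

def test_strict_tree_roundtrip_known_tree():
    nwk = "((a:1,b:1):1,(c:1,(d:1,e:1):1):1);"
    ss = splits_from_tree(nwk)
    assert rf_distance(strict_tree(ss), nwk) == 0


def test_strict_tree_star_on_empty():
    ss = SplitSet(frozenset("ABCD"), {})
    nwk = strict_tree(ss)
    assert splits_from_tree(nwk).weights == {}


@pytest.mark.parametrize("n", [5, 6])
def test_strict_tree_exhaustive_small_topologies(n):
    """strict_tree(splits_from_tree(T)) reproduces every binary topology."""
    labels = [f"t{i}" for i in range(n)]

    def all_trees(leaves):
        if len(leaves) == 1:
            yield leaves[0]
            return
        first, rest = leaves[0], leaves[1:]
        for sub in all_trees(rest):
            for edited in _insert_everywhere(sub, first):
                yield edited

    def _insert_everywhere(tree, leaf):
        if isinstance(tree, str):
            yield (leaf, tree)
            return
        a, b = tree
        yield (leaf, tree)
        for ea in _insert_everywhere(a, leaf):
            yield (ea, b)
        for eb in _insert_everywhere(b, leaf):
            yield (a, eb)

    def to_newick(t):
        if isinstance(t, str):
            return t
        return f"({to_newick(t[0])},{to_newick(t[1])})"

    count = 0
    for t in all_trees(labels):
        nwk = to_newick(t) + ";"
        ss = splits_from_tree(nwk)
        if not ss.weights:
            continue
        assert rf_distance(strict_tree(ss), nwk) == 0
        count += 1
    assert count > 0


def test_tree_like_splits_on_simulated_data():
    """Homoplasy-light simulated assemblies give a fully compatible split
    set above a weight floor (a tree-like network): convergent kmer-loss
    noise stays an order of magnitude below the true-edge signal at
    moderate divergence."""
    from panplastome.simulate import SimConfig, simulate

    cfg = SimConfig(seed=8, n_taxa=8, total_len=40_000, n_genes=30,
                    branch_len_mean=0.015)
    _, samples, truth = simulate(cfg)
    prof = build_profile({p.sample_id: p.sequence for p in samples}, k=31)
    ss = infer_splits(prof, "count", "10n")
    floor = 0.1 * max(ss.weights.values())
    heavy = [s for s, w in ss.weights.items() if w >= floor]
    for a, b in itertools.combinations(heavy, 2):
        assert splits_compatible(a, b, ss.taxa)
    assert set(heavy) == set(splits_from_tree(truth.true_tree).weights)


# ------------------------------------------------------------ NEXUS

def test_nexus_roundtrip():
    ss = SplitSet(frozenset({"a", "b", "c", "d", "e"}),
                  {frozenset({"b", "c"}): 1.25, frozenset({"d", "e"}): 0.123456})
    back = from_splits_nexus(to_splits_nexus(ss))
    assert back.taxa == ss.taxa
    assert back.weights == pytest.approx(ss.weights)


def test_nexus_empty_split_set():
    ss = SplitSet(frozenset({"a", "b", "c", "d"}), {})
    doc = to_splits_nexus(ss)
    assert doc.startswith("#NEXUS")
    assert "nsplits=0" in doc
    assert from_splits_nexus(doc).weights == {}
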
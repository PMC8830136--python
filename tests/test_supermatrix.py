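"""Trimming, concatenation, codon matrices, diagnostic set, NJ tree."""

import numpy as np
import pytest

from panplastome.alignstats import RegionAlignment, percent_identity
from panplastome.supermatrix import (
    build_matrices,
    concatenate,
    nj_tree,
    nj_tree_from_distances,
    p_distance_matrix,
    select_diagnostic_regions,
    trim_alignment,
)
from panplastome.treecmp import rf_distance
from panplastome.types import RegionKey

K = RegionKey("genic", "x")


def aln(rows, key=K):
    return RegionAlignment(key, dict(rows))


# ------------------------------------------------------------ trimming

def test_trim_keeps_clean_columns():
    a = aln({"a": "ACGT", "b": "ACGT"})
    assert trim_alignment(a).rows == a.rows


def test_trim_gap_threshold():
    rows = {f"s{i}": ("A" if i < 3 else "-") + "CCC" for i in range(5)}
    t = trim_alignment(aln(rows), gap_keep=0.8)
    # column 0 has non-gap fraction 0.6 < 0.8 -> removed
    assert all(r == "CCC" for r in t.rows.values())


def test_trim_matches_bruteforce_fuzz():
    rng = np.random.default_rng(12)
    for _ in range(50):
        n_rows, n_cols = int(rng.integers(2, 6)), int(rng.integers(1, 25))
        rows = {f"s{i}": "".join(rng.choice(list("ACGT-"), size=n_cols))
                for i in range(n_rows)}
        gap_keep, min_sim = 0.8, 0.5
        t = trim_alignment(aln(rows), gap_keep, min_sim)
        keep = []
        for c in range(n_cols):
            col = [r[c] for r in rows.values()]
            nongap = [x for x in col if x != "-"]
            if len(nongap) / n_rows < gap_keep:
                continue
            if not nongap:
                continue
            maj = max(nongap.count(x) for x in set(nongap)) / len(nongap)
            if maj >= min_sim:
                keep.append(c)
        expect = {s: "".join(r[c] for c in keep) for s, r in rows.items()}
        assert t.rows == expect


# ------------------------------------------------------------ concatenate

def test_concatenate_partition_map():
    a = aln({"a": "A" * 10, "b": "A" * 10}, RegionKey("genic", "g1"))
    b = aln({"a": "C" * 10, "b": "C" * 10}, RegionKey("genic", "g2"))
    sm = concatenate([a, b])
    assert sm.n_sites == 20
    assert [(s, e) for (_k, s, e) in sm.partition_map] == [(0, 10), (10, 20)]
    assert sm.summary()["invariant_fraction"] == 1.0
    assert sm.summary()["n_site_patterns"] == 2


def test_concatenate_sample_mismatch():
    a = aln({"a": "AA", "b": "AA"})
    b = aln({"a": "CC", "c": "CC"}, RegionKey("genic", "y"))
    with pytest.raises(ValueError, match="mismatch"):
        concatenate([a, b])


def test_summary_matches_bruteforce_fuzz():
    rng = np.random.default_rng(13)
    for _ in range(30):
        n_rows, n_cols = int(rng.integers(2, 5)), int(rng.integers(1, 40))
        rows = {f"s{i}": "".join(rng.choice(list("ACGT-N"), size=n_cols))
                for i in range(n_rows)}
        sm = concatenate([aln(rows)])
        s = sm.summary()
        cols = list(zip(*[rows[f"s{i}"] for i in range(n_rows)]))
        assert s["n_sites"] == n_cols
        assert s["n_site_patterns"] == len(set(cols))
        assert s["gap_fraction"] == pytest.approx(
            sum(c.count("-") for c in cols) / (n_rows * n_cols))
        inv = sum(1 for c in cols
                  if len({x for x in c if x not in "-N"}) == 1)
        assert s["invariant_fraction"] == pytest.approx(inv / n_cols)


# ------------------------------------------------------------ codon matrices

def _cds_aln(name, seqs):
    return RegionAlignment(RegionKey("genic", name), seqs)


def test_codon_matrix_shapes():
    # 12-column CDS: start/stop removal leaves 6; (IV) 4 cols, (V) 2 cols
    rows = {"a": "ATGAAACCCTAA", "b": "ATGAAGCCGTAA"}
    mats = build_matrices({RegionKey("genic", "g"): _cds_aln("g", rows)}, {"g"})
    assert mats["III"].n_sites == 6
    assert mats["IV"].n_sites == 4
    assert mats["V"].n_sites == 2


def test_codon_partition_property():
    """(IV) u (V) column multiset equals (III)'s columns."""
    rng = np.random.default_rng(14)
    rows = {s: "".join(rng.choice(list("ACGT"), size=30)) for s in "ab"}
    mats = build_matrices({RegionKey("genic", "g"): _cds_aln("g", rows)}, {"g"})
    def cols(sm):
        m = [sm.rows[s] for s in sm.sample_ids]
        return sorted(zip(*m))
    assert sorted(cols(mats["IV"]) + cols(mats["V"])) == cols(mats["III"])


def test_non_codon_cds_excluded():
    rows = {"a": "ATGAA-CCCTAAX"[:13].replace("X", "A"),
            "b": "ATGAAACCCTAAA"}
    with pytest.warns(UserWarning, match="divisible"):
        mats = build_matrices({RegionKey("genic", "g"): _cds_aln("g", rows)}, {"g"})
    assert mats["III"] is None


def test_simulator_cds_matrices(eight_taxon_sim):
    _, anc, samples, truth = eight_taxon_sim
    leaves = [p.sample_id for p in samples]
    alns = {k: a.subset(leaves) for k, a in truth.true_alignments.items()}
    cds = {f.name for f in anc.features if f.kind == "CDS"}
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        mats = build_matrices(alns, cds)
    assert mats["III"] is not None
    assert mats["IV"].n_sites == 2 * mats["V"].n_sites
    assert mats["III"].n_sites == mats["IV"].n_sites + mats["V"].n_sites
    assert mats["I"].n_sites > 0 and mats["II"].n_sites > 0


# ------------------------------------------------------------ diagnostic set

def test_diagnostic_single_separating_region():
    k1, k2 = RegionKey("genic", "g1"), RegionKey("genic", "g2")
    alns = {
        k1: aln({"a": "AAAA", "b": "AAAA"}, k1),          # identical
        k2: aln({"a": "AAAA", "b": "AACA"}, k2),          # separates
    }
    sel = select_diagnostic_regions(alns)
    assert sel.separated
    assert sel.selected == [k2]


def test_diagnostic_identical_samples():
    k1 = RegionKey("genic", "g1")
    alns = {k1: aln({"a": "AAAA", "b": "AAAA"}, k1)}
    sel = select_diagnostic_regions(alns)
    assert not sel.separated
    assert sel.selected == [k1]
    assert sel.unseparated_pairs == [("a", "b")]


def test_diagnostic_prefix_of_identity_order(leaf_alignments):
    sel = select_diagnostic_regions(leaf_alignments)
    idents = {k: percent_identity(a) for k, a in leaf_alignments.items()}
    order = sorted(leaf_alignments, key=lambda k: (idents[k], str(k)))
    assert sel.selected == order[: len(sel.selected)]
    assert sel.separated


# ------------------------------------------------------------ NJ tree

def _matrix_from_rows(rows):
    key = RegionKey("genic", "m")
    return concatenate([RegionAlignment(key, rows)])


def test_nj_additive_four_taxa():
    """Sequences built from disjoint mutation blocks give additive
    p-distances; NJ must recover the generating topology exactly."""
    base = "A" * 100
    def mutate(s, start, n):
        return s[:start] + "C" * n + s[start + n:]
    # tree ((a,b),(c,d)): terminal blocks 5,4,3,2 and internal block 6
    rows = {
        "a": mutate(base, 0, 5),
        "b": mutate(base, 10, 4),
        "c": mutate(mutate(base, 40, 6), 20, 3),
        "d": mutate(mutate(base, 40, 6), 30, 2),
    }
    sm = _matrix_from_rows(rows)
    dm = p_distance_matrix(sm)
    assert dm["a", "b"] == pytest.approx(0.09)
    assert dm["a", "c"] == pytest.approx(0.14)
    tree = nj_tree(sm)
    assert rf_distance(tree, "((a:0.05,b:0.04):0.03,(c:0.03,d:0.02):0.03);") == 0


def test_nj_three_taxon_closed_form():
    from skbio import DistanceMatrix
    import dendropy
    d = DistanceMatrix([[0, 0.3, 0.4], [0.3, 0, 0.5], [0.4, 0.5, 0]],
                       ["a", "b", "c"])
    nwk = nj_tree_from_distances(d)
    t = dendropy.Tree.get(data=nwk, schema="newick")
    lens = {lf.taxon.label: lf.edge.length for lf in t.leaf_node_iter()}
    # three-point formulas: x = (dab+dac-dbc)/2 etc.
    assert lens["a"] == pytest.approx((0.3 + 0.4 - 0.5) / 2)
    assert lens["b"] == pytest.approx((0.3 + 0.5 - 0.4) / 2)
    assert lens["c"] == pytest.approx((0.4 + 0.5 - 0.3) / 2)


def test_nj_errors():
    with pytest.raises(ValueError):
        nj_tree(_matrix_from_rows({"a": "AC", "b": "AC"}))
    with pytest.raises(ValueError, match="comparable"):
        nj_tree(_matrix_from_rows({"a": "A-", "b": "-A", "c": "AA"}))


def test_nj_recovers_simulated_topology(eight_taxon_sim):
    _, _, samples, truth = eight_taxon_sim
    leaves = [p.sample_id for p in samples]
    alns = [a.subset(leaves) for a in truth.true_alignments.values()]
    sm = concatenate([trim_alignment(a) for a in alns])
    assert rf_distance(nj_tree(sm), truth.true_tree) == 0
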
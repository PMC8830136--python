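"""Alignment identity, variant calling and the genic/intergenic contrasts."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from panplastome.alignstats import (
    RegionAlignment,
    call_variants,
    frame_analysis,
    hotspot_ranking,
    identity_contrast,
    indel_size_spectrum,
    percent_identity,
)
from panplastome.types import RegionKey

K = RegionKey("genic", "x")


def aln(*rows):
    return RegionAlignment(K, {f"s{i}": r for i, r in enumerate(rows)})


# ------------------------------------------------------------ brute-force oracles

def oracle_identity(rows):
    cols = list(zip(*rows))
    conserved = 0
    for col in cols:
        if "-" in col:
            continue
        residues = [c for c in col if c != "N"]
        if len(residues) >= 2 and len(set(residues)) == 1:
            conserved += 1
    return conserved / len(cols)


def oracle_variants(rows):
    cols = list(zip(*rows))
    snvs = sum(1 for col in cols if len({c for c in col if c not in "-N"}) >= 2)
    indels = []
    for r in rows:
        i = 0
        while i < len(r):
            if r[i] == "-":
                j = i
                while j < len(r) and r[j] == "-":
                    j += 1
                indels.append(j - i)
                i = j
            else:
                i += 1
    return snvs, sorted(indels)


# ------------------------------------------------------------ percent_identity

@pytest.mark.parametrize("rows,expected", [
    (("A" * 100, "A" * 100), 1.0),
    (("AAAAAAAAAA", "AAAAAAAAAC"), 0.9),
    # columns AAA, AA-, CCC, A-A, TTT: gap columns never conserved -> 3/5
    (("AACAT", "AACAT", "A-C-T"), 3 / 5),
])
def test_percent_identity_examples(rows, expected):
    assert percent_identity(aln(*rows)) == pytest.approx(expected)


def test_identity_gap_and_n_rules():
    # a column with any gap is non-conserved even if residues agree
    assert percent_identity(aln("AA", "A-")) == 0.5
    # {A, N}: only one informative residue -> not conserved
    assert percent_identity(aln("A", "N")) == 0.0
    # {A, A, N}: two informative, unanimous -> conserved
    assert percent_identity(aln("A", "A", "N")) == 1.0


def test_identity_errors():
    with pytest.raises(ValueError):
        percent_identity(RegionAlignment(K, {"only": "ACGT"}))


def test_identity_row_permutation_invariant():
    rng = np.random.default_rng(0)
    rows = ["".join(rng.choice(list("ACGT-"), size=40)) for _ in range(4)]
    a = RegionAlignment(K, {f"s{i}": r for i, r in enumerate(rows)})
    b = RegionAlignment(K, {f"s{i}": r for i, r in enumerate(reversed(rows))})
    assert percent_identity(a) == percent_identity(b)


def test_outgroup_row_monotonicity():
    """Adding a row can only keep or decrease identity."""
    rng = np.random.default_rng(1)
    for _ in range(25):
        rows = ["".join(rng.choice(list("ACGT"), size=30)) for _ in range(3)]
        extra = "".join(rng.choice(list("ACGT-"), size=30))
        base = RegionAlignment(K, {f"s{i}": r for i, r in enumerate(rows)})
        ext = RegionAlignment(K, {**base.rows, "out": extra})
        assert percent_identity(ext) <= percent_identity(base)


@settings(derandomize=True, max_examples=80)
@given(st.integers(1, 25).flatmap(
    lambda n: st.tuples(st.text("ACGT-", min_size=n, max_size=n),
                        st.text("ACGT-", min_size=n, max_size=n))))
def test_two_row_identity_decomposition(rows):
    """For 2-row gapped alignments, identity = 1 - (SNV columns +
    gap-touched columns) / length."""
    a, b = rows
    if any(x == "-" and y == "-" for x, y in zip(a, b)):
        return  # all-gap columns are outside the alignment contract
    alignment = aln(a, b)
    t = call_variants(alignment)
    gap_cols = sum(1 for x, y in zip(a, b) if "-" in (x, y))
    expect = 1 - (len(t.snvs) + gap_cols) / len(a)
    assert percent_identity(alignment) == pytest.approx(expect)


# ------------------------------------------------------------ call_variants

def test_call_variants_examples():
    t = call_variants(aln("ACGT", "ACGA"))
    assert len(t.snvs) == 1 and t.snvs[0][1] == 3
    assert t.indels == []

    t = call_variants(aln("AC--GT", "ACTTGT"))
    assert len(t.snvs) == 0
    assert [(r[2], r[3]) for r in t.indels] == [(2, 2)]


def test_call_variants_n_is_missing():
    t = call_variants(aln("AN", "AA"))
    assert t.snvs == []


def test_call_variants_matches_bruteforce_fuzz():
    rng = np.random.default_rng(42)
    for _ in range(100):
        n_rows = int(rng.integers(2, 5))
        n_cols = int(rng.integers(1, 31))
        rows = ["".join(rng.choice(list("ACGT-N"), size=n_cols, p=[.2,.2,.2,.2,.15,.05]))
                for _ in range(n_rows)]
        if any(all(c == "-" for c in col) for col in zip(*rows)):
            continue
        a = RegionAlignment(K, {f"s{i}": r for i, r in enumerate(rows)})
        t = call_variants(a)
        o_snv, o_indels = oracle_variants(rows)
        assert len(t.snvs) == o_snv
        assert sorted(r[3] for r in t.indels) == o_indels
        assert percent_identity(a) == pytest.approx(oracle_identity(rows))


def test_density_normalisation_and_scaling():
    a = aln("ACGT", "ACGA")
    t = call_variants(a)
    assert t.densities[K] == (1 / (4 * 2), 0.0)
    # duplicating all columns doubles length and counts; density invariant
    b = aln("ACGTACGT", "ACGAACGA")
    t2 = call_variants(b)
    assert t2.densities[K] == t.densities[K]


# ------------------------------------------------------------ frame analysis

def _vt(genic_lengths, intergenic_lengths):
    from panplastome.alignstats import VariantTable
    vt = VariantTable()
    g, i = RegionKey("genic", "g"), RegionKey("intergenic", "a-b")
    vt.indels = [(g, "s", 0, L) for L in genic_lengths] + \
                [(i, "s", 0, L) for L in intergenic_lengths]
    return vt


def test_frame_analysis_counts_and_table():
    fa = frame_analysis(_vt([3, 6, 2], [1, 2]))
    assert fa.prop_genic_mod3 == pytest.approx(2 / 3)
    assert fa.prop_intergenic_mod3 == 0.0
    assert fa.table == ((2, 1), (0, 2))
    assert 0 < fa.p_value <= 1


def test_frame_analysis_no_contrast():
    fa = frame_analysis(_vt([3, 6], [9, 12]))
    assert fa.prop_genic_mod3 == 1.0 and fa.prop_intergenic_mod3 == 1.0
    assert fa.p_value == pytest.approx(1.0)


def test_frame_analysis_empty_class_warns():
    with pytest.warns(UserWarning):
        fa = frame_analysis(_vt([3], []))
    assert fa.p_value is None and fa.prop_intergenic_mod3 is None


# ------------------------------------------------------------ identity contrast

def test_identity_contrast_identical():
    ic = identity_contrast([0.9] * 10, [0.9] * 10)
    assert ic.mean_genic == ic.mean_intergenic
    assert ic.p_value == pytest.approx(1.0, abs=0.05)


def test_identity_contrast_separated():
    ic = identity_contrast([0.99] * 10, [0.90] * 10)
    assert ic.mean_genic - ic.mean_intergenic == pytest.approx(0.09)
    assert ic.p_value < 1e-3


def test_identity_contrast_needs_two_per_class():
    with pytest.raises(ValueError):
        identity_contrast([0.9], [0.8, 0.7])


# ------------------------------------------------------------ hotspots & spectrum

def test_hotspot_ranking_order_and_ties():
    from panplastome.alignstats import VariantTable
    a, b, c = (RegionKey("intergenic", n) for n in ("g1-g2", "g2-g3", "g3-g4"))
    vt = VariantTable()
    vt.densities = {a: (0.0, 0.1), b: (0.0, 0.3), c: (0.0, 0.1)}
    ranked = hotspot_ranking(vt, [a, b, c], which="indel")
    assert ranked["intergenic"] == [b, a, c]  # tie a/c keeps plastome order


def test_indel_size_spectrum():
    s = indel_size_spectrum(_vt([1, 1, 3], []))
    assert s["genic"] == {1: (2, False), 3: (1, True)}
    assert s["intergenic"] == {}


# ------------------------------------------------------------ simulator contrasts

def test_simulated_rate_separation(leaf_alignments):
    """Genes evolve slower than spacers, so genic identity is higher."""
    gid = [percent_identity(a) for k, a in leaf_alignments.items() if k.kind == "genic"]
    iid = [percent_identity(a) for k, a in leaf_alignments.items() if k.kind == "intergenic"]
    ic = identity_contrast(gid, iid)
    assert ic.mean_genic > ic.mean_intergenic
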
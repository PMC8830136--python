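"""Per-region alignment statistics: identity, SNV/InDel calling, hotspots.

The statistics here back the classic genic-vs-intergenic contrasts of
plastome studies: gene sequences are more conserved than spacers, indels
inside genes are biased toward frame-preserving lengths (multiples of 3),
and a handful of spacers concentrate most of the variation.

Conventions
-----------
* identity: fraction of alignment columns in which every row carries the
  same non-gap nucleotide.  A gap is not a nucleotide, so any gap makes a
  column non-conserved.  ``N`` is missing data: rows with ``N`` are
  excluded from a column's unanimity check as long as at least two
  informative residues remain; otherwise the column is not conserved.
* SNV: one event per column containing >= 2 distinct non-gap, non-N
  nucleotides.
* InDel event: one event per maximal run of consecutive gap characters in
  a single row; its length is the run length.
* density: event count / alignment length / number of rows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .types import RegionKey

GAP = "-"


@dataclass(frozen=True)
class RegionAlignment:
    key: RegionKey
    rows: Mapping[str, str]  # sample_id -> gapped sequence

    def __post_init__(self):
        lens = {len(s) for s in self.rows.values()}
        if len(lens) > 1:
            raise ValueError(f"{self.key}: rows of unequal length")

    @property
    def length(self) -> int:
        return len(next(iter(self.rows.values())))

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    def subset(self, sample_ids: Iterable[str]) -> "RegionAlignment":
        ids = list(sample_ids)
        return RegionAlignment(self.key, {s: self.rows[s] for s in ids})

    def matrix(self) -> np.ndarray:
        """Rows as a (n_rows, length) byte matrix in row-insertion order."""
        return np.frombuffer(
            "".join(self.rows.values()).encode("ascii"), dtype=np.uint8
        ).reshape(self.n_rows, self.length)


@dataclass
class VariantTable:
    snvs: list = field(default_factory=list)  # (key, column, allele multiset tuple)
    indels: list = field(default_factory=list)  # (key, sample_id, start_column, length)
    densities: dict = field(default_factory=dict)  # key -> (snv_density, indel_density)
    counts: dict = field(default_factory=dict)  # key -> (snv_count, indel_count)

    def extend(self, other: "VariantTable") -> None:
        self.snvs.extend(other.snvs)
        self.indels.extend(other.indels)
        self.densities.update(other.densities)
        self.counts.update(other.counts)


_GAP_B = ord(GAP)
_N_B = ord("N")


def percent_identity(aln: RegionAlignment, sample_ids: Optional[Iterable[str]] = None) -> float:
    """Fraction of columns where all rows agree on one non-gap nucleotide.

    ``sample_ids`` restricts the computation to a row subset, e.g. to
    recompute identity with or without outgroup accessions.
    """
    if sample_ids is not None:
        aln = aln.subset(sample_ids)
    if aln.n_rows < 2:
        raise ValueError(f"{aln.key}: identity undefined for <2 rows")
    if aln.length == 0:
        raise ValueError(f"{aln.key}: empty alignment")
    m = aln.matrix()
    return float(_conserved_mask(m).sum() / m.shape[1])


def _conserved_mask(m: np.ndarray) -> np.ndarray:
    has_gap = (m == _GAP_B).any(axis=0)
    is_n = m == _N_B
    n_informative = (~is_n).sum(axis=0)
    # residues unanimous among non-N rows: min == max over masked entries
    masked = np.where(is_n, 0, m)
    hi = masked.max(axis=0)
    masked_hi = np.where(is_n, 255, m)
    lo = masked_hi.min(axis=0)
    unanimous = hi == lo
    return (~has_gap) & (n_informative >= 2) & unanimous


def call_variants(aln: RegionAlignment) -> VariantTable:
    """Call SNVs (per column) and InDel events (per-row maximal gap runs)."""
    m = aln.matrix()
    n_rows, length = m.shape
    ids = list(aln.rows)
    table = VariantTable()

    informative = (m != _GAP_B) & (m != _N_B)
    for col in range(length):
        residues = m[informative[:, col], col]
        if len(np.unique(residues)) >= 2:
            alleles = tuple(sorted(chr(b) for b in residues))
            table.snvs.append((aln.key, col, alleles))

    gaps = m == _GAP_B
    for r in range(n_rows):
        run_start = None
        for col in range(length + 1):
            in_gap = col < length and gaps[r, col]
            if in_gap and run_start is None:
                run_start = col
            elif not in_gap and run_start is not None:
                table.indels.append((aln.key, ids[r], run_start, col - run_start))
                run_start = None

    snv_n, indel_n = len(table.snvs), len(table.indels)
    table.counts[aln.key] = (snv_n, indel_n)
    denom = length * n_rows
    table.densities[aln.key] = (snv_n / denom, indel_n / denom)
    return table


def call_all(alignments: Mapping[RegionKey, RegionAlignment]) -> VariantTable:
    table = VariantTable()
    for aln in alignments.values():
        table.extend(call_variants(aln))
    return table


@dataclass(frozen=True)
class FrameAnalysis:
    prop_genic_mod3: Optional[float]
    prop_intergenic_mod3: Optional[float]
    table: tuple  # ((genic_mod3, genic_other), (intergenic_mod3, intergenic_other))
    p_value: Optional[float]


def frame_analysis(variants: VariantTable,
                   classes: Optional[Mapping[RegionKey, str]] = None) -> FrameAnalysis:
    """Proportion of frame-preserving (length % 3 == 0) indels per class.

    The two classes (genic vs intergenic region of origin) are contrasted
    with a two-sided Fisher exact test on the 2x2 count table.
    """
    counts = {"genic": [0, 0], "intergenic": [0, 0]}  # [mod3, other]
    for key, _sample, _start, length in variants.indels:
        cls = classes[key] if classes is not None else key.kind
        counts[cls][0 if length % 3 == 0 else 1] += 1

    def prop(c):
        tot = c[0] + c[1]
        return c[0] / tot if tot else None

    pg, pi = prop(counts["genic"]), prop(counts["intergenic"])
    table = (tuple(counts["genic"]), tuple(counts["intergenic"]))
    if pg is None or pi is None:
        warnings.warn("frame_analysis: a class has no indels; exact test skipped")
        p = None
    else:
        _, p = stats.fisher_exact(table, alternative="two-sided")
    return FrameAnalysis(pg, pi, table, None if p is None else float(p))


@dataclass(frozen=True)
class IdentityContrast:
    mean_genic: float
    mean_intergenic: float
    p_value: float


def identity_contrast(genic: Sequence[float], intergenic: Sequence[float]) -> IdentityContrast:
    """Class means and a two-sided Mann-Whitney U (rank-sum) p-value."""
    if len(genic) < 2 or len(intergenic) < 2:
        raise ValueError("identity_contrast needs >=2 identities per class")
    res = stats.mannwhitneyu(genic, intergenic, alternative="two-sided")
    return IdentityContrast(
        float(np.mean(genic)), float(np.mean(intergenic)), float(res.pvalue)
    )


def hotspot_ranking(variants: VariantTable,
                    plastome_order: Sequence[RegionKey],
                    which: str = "indel") -> dict[str, list[RegionKey]]:
    """Regions ranked by descending event density, per class.

    ``which`` selects the SNV or InDel density.  Ties keep plastome order
    (stable sort on the reference region order).
    """
    idx = 0 if which == "snv" else 1
    pos = {k: i for i, k in enumerate(plastome_order)}
    out: dict[str, list[RegionKey]] = {}
    for cls in ("genic", "intergenic"):
        keys = [k for k in plastome_order if k.kind == cls and k in variants.densities]
        keys.sort(key=lambda k: (-variants.densities[k][idx], pos[k]))
        out[cls] = keys
    return out


def indel_size_spectrum(variants: VariantTable,
                        classes: Optional[Mapping[RegionKey, str]] = None) -> dict:
    """Per-class histogram of indel lengths, flagging multiples of three."""
    spectrum: dict[str, dict[int, int]] = {"genic": {}, "intergenic": {}}
    for key, _sample, _start, length in variants.indels:
        cls = classes[key] if classes is not None else key.kind
        spectrum[cls][length] = spectrum[cls].get(length, 0) + 1
    return {
        cls: {length: (count, length % 3 == 0) for length, count in sorted(h.items())}
        for cls, h in spectrum.items()
    }
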
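"""Shared genic and intergenic loci via conserved microsynteny.

A locus table is built from gene adjacencies conserved across *all*
samples (outgroups included): each conserved gene gives a genic region,
and each conserved adjacent gene pair whose genes do not overlap gives
the intergenic spacer between them.  Pairs that fail in any one sample
(overlapping genes, zero-length spacer, or separation by an IR copy) are
dropped globally so every region keeps a full sample complement, and the
drops are logged rather than silently discarded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from ._util import revcomp
from .types import AnnotatedPlastome, GeneFeature, RegionKey


def gene_order(plastome: AnnotatedPlastome) -> list[str]:
    """Circular gene order by start coordinate, IR duplicates collapsed.

    A gene annotated in both IR copies is kept once, as its IRa-resident
    copy (or the first copy by coordinate when no partition is present).
    Multi-copy genes outside the IR also collapse to their first copy,
    with a warning.
    """
    feats = sorted(plastome.features, key=lambda f: f.start)
    part = plastome.partition
    chosen: dict[str, GeneFeature] = {}
    for f in feats:
        if f.name not in chosen:
            chosen[f.name] = f
            continue
        prev = chosen[f.name]
        in_ira = part is not None and part.has_ir and _within(f, part.ira)
        prev_in_ira = part is not None and part.has_ir and _within(prev, part.ira)
        if in_ira and not prev_in_ira:
            chosen[f.name] = f
        elif not (in_ira or prev_in_ira or
                  (part is not None and part.has_ir and
                   (_within(f, part.irb) or _within(prev, part.irb)))):
            warnings.warn(f"{plastome.sample_id}: gene {f.name} duplicated outside "
                          "the IR; keeping the first copy")
    return [f.name for f in sorted(chosen.values(), key=lambda f: f.start)]


def _within(f: GeneFeature, iv) -> bool:
    return iv is not None and iv.start <= f.start and f.end <= iv.end


def conserved_adjacent_pairs(orders: Mapping[str, Sequence[str]]) -> list[tuple[str, str]]:
    """Ordered gene pairs adjacent, in the same relative order, in every
    sample's circular gene order (strand is ignored: a spacer exists
    between two genes regardless of their orientations)."""
    if len(orders) < 2:
        raise ValueError("need >= 2 samples")
    per_sample = []
    for order in orders.values():
        n = len(order)
        pairs = {(order[i], order[(i + 1) % n]) for i in range(n)} if n >= 2 else set()
        per_sample.append(pairs)
    shared = set.intersection(*per_sample) if per_sample else set()
    shared = {(a, b) for (a, b) in shared if a != b}
    if not shared:
        warnings.warn("no conserved adjacent gene pairs across samples")
        return []
    # report in the first sample's circular order
    first = next(iter(orders.values()))
    n = len(first)
    ordered = [(first[i], first[(i + 1) % n]) for i in range(n)]
    return [p for p in ordered if p in shared]


@dataclass
class RegionSet:
    keys: list[RegionKey]  # plastome order of the reference (first) sample
    sequences: dict = field(default_factory=dict)  # (RegionKey, sample_id) -> DNA
    drop_log: list = field(default_factory=list)  # (RegionKey, sample_id, reason)

    def samples(self) -> list[str]:
        return sorted({s for (_, s) in self.sequences})

    def region(self, key: RegionKey) -> dict[str, str]:
        return {s: seq for (k, s), seq in self.sequences.items() if k == key}


def extract_regions(plastomes: Sequence[AnnotatedPlastome],
                    pairs: Sequence[tuple[str, str]]) -> RegionSet:
    """Extract genic and intergenic sequences for every sample.

    Genic sequences are reported on the gene's coding (+-adjusted)
    strand; the IRa copy represents IR-duplicated genes.  Intergenic
    extraction follows the conserved pairs: the gap between the two
    genes' coordinate-adjacent occurrence.  A pair is dropped globally
    (and logged per offending sample) when, in any sample, the genes
    overlap, the spacer has zero length, or the pair is not
    coordinate-adjacent (e.g. the artificial SSC-to-LSC adjacency created
    by collapsing the IR).
    """
    gene_names = _shared_genes(plastomes)
    keys: list[RegionKey] = []
    sequences: dict = {}
    drop_log: list = []

    ref_order = gene_order(plastomes[0])
    for name in ref_order:
        if name not in gene_names:
            continue
        key = RegionKey("genic", name)
        keys.append(key)
        for p in plastomes:
            f = _representative(p, name)
            sequences[(key, p.sample_id)] = f.sequence(p.sequence)

    dropped_pairs: dict[tuple[str, str], list] = {}
    pair_cells: dict[tuple[str, str], dict[str, str]] = {}
    for (a, b) in pairs:
        cells = {}
        for p in plastomes:
            feats = sorted(p.features, key=lambda f: f.start)
            hit = None
            for i, f in enumerate(feats):
                nxt = feats[(i + 1) % len(feats)]
                if f.name == a and nxt.name == b:
                    hit = (f, nxt)
                    break
            if hit is None:
                dropped_pairs.setdefault((a, b), []).append(
                    (p.sample_id, "not coordinate-adjacent"))
                continue
            f, g = hit
            wraps = g.start < f.start  # g is the first feature on the circle
            if not wraps and g.start < f.end:
                dropped_pairs.setdefault((a, b), []).append((p.sample_id, "genes overlap"))
                continue
            if wraps:
                spacer = p.sequence[f.end :] + p.sequence[: g.start]
            else:
                spacer = p.sequence[f.end : g.start]
            if not spacer:
                dropped_pairs.setdefault((a, b), []).append((p.sample_id, "zero-length spacer"))
                continue
            cells[p.sample_id] = spacer
        pair_cells[(a, b)] = cells

    for (a, b) in pairs:
        key = RegionKey("intergenic", f"{a}-{b}")
        if (a, b) in dropped_pairs:
            for sid, reason in dropped_pairs[(a, b)]:
                drop_log.append((key, sid, reason))
            continue
        keys.append(key)
        for sid, seq in pair_cells[(a, b)].items():
            sequences[(key, sid)] = seq

    # interleave intergenic keys into plastome order of the reference sample
    keys = _plastome_order(keys, ref_order)
    return RegionSet(keys, sequences, drop_log)


def _plastome_order(keys: list[RegionKey], ref_order: list[str]) -> list[RegionKey]:
    pos = {name: i for i, name in enumerate(ref_order)}
    def sort_key(k: RegionKey):
        if k.kind == "genic":
            return (pos.get(k.name, len(pos)), 0)
        a, _b = k.name.split("-", 1)
        return (pos.get(a, len(pos)), 1)
    return sorted(keys, key=sort_key)


def _shared_genes(plastomes) -> set[str]:
    sets = [set(gene_order(p)) for p in plastomes]
    return set.intersection(*sets)


def _representative(p: AnnotatedPlastome, name: str) -> GeneFeature:
    feats = [f for f in p.features if f.name == name]
    part = p.partition
    if part is not None and part.has_ir:
        ira = [f for f in feats if _within(f, part.ira)]
        if ira:
            return ira[0]
        feats = [f for f in feats if not _within(f, part.irb)] or feats
    return sorted(feats, key=lambda f: f.start)[0]


def harmonize_orientation(cells: Mapping[str, str], k: int = 11) -> dict[str, str]:
    """Bring all sequences of one region onto a consistent strand.

    Each sequence is kept or reverse-complemented, whichever shares more
    forward kmers (k=11) with the first sample's sequence; ties keep the
    forward orientation.  The same role the aligner's direction
    adjustment plays upstream of multiple alignment.
    """
    items = list(cells.items())
    if len(items) < 2:
        return dict(items)
    ref_kmers = _kmers(items[0][1], k)
    out = {items[0][0]: items[0][1]}
    for sid, seq in items[1:]:
        fwd = len(_kmers(seq, k) & ref_kmers)
        rc = revcomp(seq)
        rev = len(_kmers(rc, k) & ref_kmers)
        out[sid] = rc if rev > fwd else seq
    return out


def _kmers(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}
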
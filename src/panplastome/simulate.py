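"""Synthetic plastome evolution with full ground truth.

The generator builds a circular quadripartite ancestor (LSC + IRa + SSC +
IRb, the IRs exact reverse complements) tiled with named genes and
intergenic spacers, then evolves it along a known tree.  Genes evolve
more slowly than spacers, and genic indel lengths are biased toward
multiples of three (frame preservation) — the two contrasts every
downstream statistic is designed to measure.  Because each locus is
evolved with an explicit insertion/deletion history, the generator emits
the *true* per-region multiple alignments, the true tree, the true indel
event list and the true IR coordinates, giving every downstream stage an
exact oracle.

Model choices: uniform-rate equal-frequency substitutions (JC-like);
indel lengths geometric with mean 3, truncated at ``indel_len_max``, and
resampled so that the class's probability of a frame-preserving length
equals ``p_frame``; indels never cross a gene/spacer boundary; the two IR
copies share a single evolutionary history (evolved once, copied).
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field
from typing import Optional, Sequence

import dendropy
import numpy as np

from ._util import decode, encode, revcomp
from .alignstats import RegionAlignment
from .types import (
    AnnotatedPlastome,
    GeneFeature,
    Interval,
    QuadripartitePartition,
    RegionKey,
)


class SizingError(ValueError):
    """Gene content does not fit the configured compartment lengths."""


class SimulationError(RuntimeError):
    """Evolution parameters too aggressive (e.g. a gene fully deleted)."""


_CDS_NAMES = [
    "psbA", "matK", "rbcL", "atpA", "atpB", "atpE", "atpF", "rpoB", "rpoC1",
    "rpoC2", "psbB", "psbC", "psbD", "petA", "petB", "psaA", "psaB", "ndhA",
    "ndhB", "ndhC", "ndhD", "ndhE", "ndhF", "ycf1", "ycf2", "ycf3", "ycf4",
    "cemA", "ccsA", "rpl2", "rpl14", "rpl16", "rpl20", "rpl22", "rpl32",
    "rpl33", "rps2", "rps3", "rps4", "rps7", "rps8", "rps11", "rps14",
    "rps15", "rps16", "rps18", "rps19", "psbE", "psbF", "psbH", "psbI",
    "psbJ", "psbK", "psbL", "psbM", "psbN", "psbT", "psbZ", "petD", "petG",
    "petL", "petN", "psaC", "psaI", "psaJ", "accD", "clpP", "infA", "cssA2",
]
_RRN_NAMES = ["rrn16", "rrn23", "rrn4.5", "rrn5"]
_TRN_NAMES = ["trnH", "trnK", "trnQ", "trnS", "trnG", "trnC", "trnD", "trnY",
              "trnE", "trnT", "trnF", "trnV", "trnM", "trnW", "trnP", "trnL"]

_MIN_SPACER = 10


@dataclass
class SimConfig:
    """All knobs of the generator; the defaults are a down-scaled (~20 kb)
    molecule preserving realistic compartment proportions (LSC ~55.5%,
    SSC ~11.8%, each IR ~16.35% of the molecule, as in a ~150 kb plastome
    with ~83.5/17.8/24.6 kb compartments)."""

    seed: int = 0
    taxa: Optional[Sequence[str]] = None
    n_taxa: int = 8
    tree: Optional[str] = None  # newick with branch lengths; generated if None
    branch_len_mean: float = 0.05  # expected substitutions/site on one edge
    n_genes: int = 20
    gene_len_range: tuple = (300, 900)
    spacer_len_range: tuple = (100, 400)
    total_len: int = 20_000
    lsc_frac: float = 0.555
    ssc_frac: float = 0.118
    ir_frac: float = 0.1635
    sub_rate_genic: float = 0.02
    sub_rate_intergenic: float = 0.06
    indel_rate_genic: float = 0.002
    indel_rate_intergenic: float = 0.006
    p_frame_genic: float = 0.45
    p_frame_intergenic: float = 0.30
    indel_len_max: int = 12
    coverage_depth: float = 100.0
    coverage_noise_sd: float = 0.0

    def validate(self) -> None:
        for name in ("sub_rate_genic", "sub_rate_intergenic",
                     "indel_rate_genic", "indel_rate_intergenic"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        s = self.lsc_frac + self.ssc_frac + 2 * self.ir_frac
        if abs(s - 1.0) > 1e-9:
            raise ValueError(f"lsc+ssc+2*ir must sum to 1, got {s}")
        for name in ("p_frame_genic", "p_frame_intergenic"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0,1]")
        if self.indel_len_max < 3:
            raise ValueError("indel_len_max must be >= 3")
        if self.n_genes < 4:
            raise ValueError("need at least 4 genes")

    def leaf_labels(self) -> list[str]:
        if self.tree is not None:
            t = dendropy.Tree.get(data=self.tree, schema="newick")
            return sorted(lf.taxon.label for lf in t.leaf_node_iter())
        if self.taxa is not None:
            return list(self.taxa)
        return [f"t{i + 1}" for i in range(self.n_taxa)]


@dataclass
class SimTruth:
    true_tree: str  # newick
    true_alignments: dict  # RegionKey -> RegionAlignment (incl. 'ancestor' row)
    true_indels: list  # (RegionKey, node_label, length, 'ins'|'del')
    ir_coords: dict  # sample_id -> QuadripartitePartition
    classes: dict = field(default_factory=dict)  # RegionKey -> 'genic'|'intergenic'


# ------------------------------------------------------------------ ancestor

def build_ancestor(config: SimConfig) -> AnnotatedPlastome:
    """Construct the ancestral circular quadripartite plastome.

    Layout (linearized at the LSC start): LSC, IRa, SSC, IRb with
    IRb = revcomp(IRa).  Each non-empty compartment starts and ends with
    a gene, so intergenic spacers never cross compartment junctions.
    Compartment lengths follow the configured proportions exactly (the
    SSC absorbs the rounding remainder).
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 0])
    L_lsc = round(config.lsc_frac * config.total_len)
    L_ir = round(config.ir_frac * config.total_len)
    L_ssc = config.total_len - L_lsc - 2 * L_ir
    has_ir = L_ir > 0
    has_ssc = L_ssc > 0

    n_ir = 2 if has_ir else 0
    rest = config.n_genes - n_ir
    lo_gene = config.gene_len_range[0]

    def capacity(target):
        # how many shortest-possible genes (plus minimal spacers) fit
        return max(0, (target + _MIN_SPACER) // (lo_gene + _MIN_SPACER))

    if has_ssc:
        n_ssc = min(max(2, round(rest * L_ssc / (L_lsc + L_ssc))),
                    capacity(L_ssc))
        if n_ssc < 2:
            raise SizingError(f"SSC: target {L_ssc} bp cannot host 2 genes of "
                              f"at least {lo_gene} bp")
    else:
        n_ssc = 0
    n_lsc = rest - n_ssc
    if n_lsc < 2:
        raise SizingError("LSC: fewer than 2 genes allocated; increase n_genes")

    names = _assign_names(n_lsc, n_ssc, n_ir)
    lo, hi = config.gene_len_range

    def gene_len(kind):
        ln = int(rng.integers(lo, hi + 1))
        return max(3, ln - ln % 3) if kind == "CDS" else ln

    def build_compartment(comp_name, gene_names, target):
        n_spacers = len(gene_names) - 1
        floor = len(gene_names) * lo_gene + n_spacers * _MIN_SPACER
        if floor > target:
            raise SizingError(
                f"{comp_name}: {len(gene_names)} genes of at least {lo_gene} bp "
                f"cannot fit the compartment target {target} bp")
        # redraw lengths if an unlucky draw overshoots the compartment
        for _attempt in range(50):
            genes = [(nm, _kind(nm), gene_len(_kind(nm))) for nm in gene_names]
            total_genes = sum(g[2] for g in genes)
            if total_genes + n_spacers * _MIN_SPACER <= target:
                break
        else:
            raise SizingError(
                f"{comp_name}: gene content persistently exceeds the "
                f"compartment target {target} bp")
        room = target - total_genes
        if n_spacers:
            draw = rng.integers(config.spacer_len_range[0],
                                config.spacer_len_range[1] + 1, size=n_spacers)
            spacer_lens = np.maximum(
                _MIN_SPACER, (draw * room / draw.sum()).astype(int))
            # fix the rounding drift on the last spacer
            spacer_lens[-1] += room - spacer_lens.sum()
            if spacer_lens[-1] < _MIN_SPACER:
                raise SizingError(f"{comp_name}: cannot fit spacers")
        else:
            spacer_lens = np.array([], dtype=int)
            if room != 0:
                genes[-1] = (genes[-1][0], genes[-1][1], genes[-1][2] + room)
        return genes, list(map(int, spacer_lens))

    comp_specs = []
    comp_specs.append(("LSC", *build_compartment("LSC", names["LSC"], L_lsc)))
    if has_ir:
        comp_specs.append(("IRa", *build_compartment("IR", names["IR"], L_ir)))
    if has_ssc:
        comp_specs.append(("SSC", *build_compartment("SSC", names["SSC"], L_ssc)))

    seq_parts: list[np.ndarray] = []
    features: list[GeneFeature] = []
    offset = 0
    comp_bounds = {}
    for comp_name, genes, spacer_lens in comp_specs:
        comp_start = offset
        for gi, (nm, kind, ln) in enumerate(genes):
            strand = "+" if rng.random() < 0.5 else "-"
            seq_parts.append(rng.integers(0, 4, size=ln).astype(np.uint8))
            features.append(GeneFeature(nm, offset, offset + ln, strand, kind))
            offset += ln
            if gi < len(genes) - 1:
                sl = spacer_lens[gi]
                seq_parts.append(rng.integers(0, 4, size=sl).astype(np.uint8))
                offset += sl
        comp_bounds[comp_name] = (comp_start, offset)
    arr = np.concatenate(seq_parts)

    if has_ir:
        ira = comp_bounds["IRa"]
        ir_arr = arr[ira[0] : ira[1]]
        irb_arr = (3 - ir_arr)[::-1]  # reverse complement in 2-bit space
        irb_start = offset
        arr = np.concatenate([arr, irb_arr])
        for f in [f for f in features if ira[0] <= f.start and f.end <= ira[1]]:
            features.append(GeneFeature(
                f.name,
                irb_start + (ira[1] - f.end),
                irb_start + (ira[1] - f.start),
                "-" if f.strand == "+" else "+",
                f.kind,
            ))
        _break_junction_complementarity(arr, ira, irb_start, rng)
        partition = QuadripartitePartition(
            lsc=Interval(*comp_bounds["LSC"]),
            ssc=Interval(*comp_bounds["SSC"]) if has_ssc else None,
            ira=Interval(*ira),
            irb=Interval(irb_start, irb_start + (ira[1] - ira[0])),
        )
    else:
        partition = QuadripartitePartition(
            lsc=Interval(*comp_bounds["LSC"]),
            ssc=Interval(*comp_bounds["SSC"]) if has_ssc else None,
            ira=None, irb=None,
        )

    return AnnotatedPlastome("ancestor", decode(arr), features, partition)


def _kind(name: str) -> str:
    if name.startswith("rrn"):
        return "rRNA"
    if name.startswith("trn"):
        return "tRNA"
    return "CDS"


def _assign_names(n_lsc: int, n_ssc: int, n_ir: int) -> dict:
    def take(pool, n, prefix):
        out = list(pool[:n])
        for i in range(len(out), n):
            out.append(f"{prefix}{i + 1}")
        return out

    lsc = []
    cds_iter = iter(_CDS_NAMES)
    trn_iter = iter(_TRN_NAMES)
    # sprinkle a couple of tRNAs into a large LSC for kind diversity
    n_trn = 2 if n_lsc >= 8 else 0
    for i in range(n_lsc - n_trn):
        lsc.append(next(cds_iter, f"gen{i + 1}"))
    for _ in range(n_trn):
        lsc.append(next(trn_iter))
    remaining_cds = [nm for nm in _CDS_NAMES if nm not in lsc]
    return {
        "LSC": lsc,
        "SSC": take(remaining_cds, n_ssc, "sgen"),
        "IR": take(_RRN_NAMES, n_ir, "rrnX"),
    }


def _break_junction_complementarity(arr, ira, irb_start, rng):
    """Ensure greedy IR extension stops exactly at the planted boundaries.

    Outward: the base left of IRa pairs with the base right of IRb (the
    origin, circularly); inward: the first SSC base pairs with the last
    SSC base.  Each is nudged off complementarity when needed.
    """
    L = len(arr)

    def fix(p, q):
        # make arr[p] non-complementary to arr[q] (complement = 3 - x)
        if int(arr[p]) == 3 - int(arr[q]):
            choices = [b for b in range(4) if b != 3 - int(arr[q]) and b != arr[p]]
            arr[p] = int(rng.choice(choices))

    fix(ira[0] - 1, 0 if irb_start + (ira[1] - ira[0]) >= L else irb_start + (ira[1] - ira[0]))
    ssc_start = ira[1]
    ssc_end = irb_start
    if ssc_end > ssc_start:
        fix(ssc_start, ssc_end - 1)


# ------------------------------------------------------------------ segments

@dataclass
class _Segment:
    key: RegionKey
    start: int
    end: int
    in_ir: bool
    strand: str  # '+' for spacers


def _layout_segments(ancestor: AnnotatedPlastome) -> list[_Segment]:
    """Gene/spacer tiling of the single-copy + IRa portion (IRb excluded)."""
    part = ancestor.partition
    cutoff = part.irb.start if part and part.has_ir else len(ancestor.sequence)
    feats = sorted((f for f in ancestor.features if f.end <= cutoff),
                   key=lambda f: f.start)
    segs: list[_Segment] = []
    for i, f in enumerate(feats):
        in_ir = bool(part and part.has_ir
                     and part.ira.start <= f.start and f.end <= part.ira.end)
        segs.append(_Segment(RegionKey("genic", f.name), f.start, f.end, in_ir, f.strand))
        if i + 1 < len(feats) and feats[i + 1].start > f.end:
            nxt = feats[i + 1]
            spacer_in_ir = bool(part and part.has_ir
                                and part.ira.start <= f.end and nxt.start <= part.ira.end)
            segs.append(_Segment(
                RegionKey("intergenic", f"{f.name}-{nxt.name}"),
                f.end, nxt.start, spacer_in_ir, "+"))
    return segs


# ------------------------------------------------------------------ evolution

class _ColumnRegistry:
    """Global column order for one region across the whole tree.

    Every residue carries an id; substitutions keep ids, deletions drop
    them from a lineage, insertions mint fresh ids that are spliced into
    the registry next to their left anchor.  Any leaf's id list is then a
    subsequence of the registry, which is exactly what a true multiple
    alignment needs.
    """

    def __init__(self, n: int):
        self.order: list[int] = list(range(n))
        self.next_id = n

    def new_ids(self, count: int, left_anchor: Optional[int]) -> list[int]:
        ids = list(range(self.next_id, self.next_id + count))
        self.next_id += count
        pos = 0 if left_anchor is None else self.order.index(left_anchor) + 1
        self.order[pos:pos] = ids
        return ids


def _draw_indel_len(rng, p_frame: float, lmax: int) -> int:
    want_frame = rng.random() < p_frame
    while True:
        ln = min(int(rng.geometric(1 / 3.0)), lmax)
        if (ln % 3 == 0) == want_frame:
            return ln


def evolve_along_tree(ancestor: AnnotatedPlastome, tree: "str | dendropy.Tree",
                      config: SimConfig):
    """Evolve the ancestor along ``tree``; returns (samples, truth).

    Substitutions are drawn per site per branch (probability
    ``1 - exp(-rate * branch_length)``, new base uniform over the other
    three); indel events are Poisson in ``rate * length * branch_length``
    with lengths from the class's frame-biased law.  The IR is evolved
    once and copied, so both IR copies of one sample are identical (up to
    reverse complementation).
    """
    config.validate()
    t = tree if isinstance(tree, dendropy.Tree) else dendropy.Tree.get(
        data=tree, schema="newick")
    leaves = [lf.taxon.label for lf in t.leaf_node_iter()]
    if len(leaves) < 3:
        raise ValueError("tree must have >= 3 leaves")
    total_bl = sum(e.length or 0.0 for e in t.edges())
    worst = max(config.sub_rate_genic + config.indel_rate_genic,
                config.sub_rate_intergenic + config.indel_rate_intergenic)
    if worst * total_bl >= 1.0:
        raise SimulationError(
            f"expected events per site {worst * total_bl:.2f} >= 1; lower the rates")

    rng = np.random.default_rng([config.seed, 1])
    segments = _layout_segments(ancestor)
    anc_arr = encode(ancestor.sequence)

    # label internal nodes deterministically
    node_label = {}
    counter = 0
    for nd in t.preorder_node_iter():
        if nd.is_leaf():
            node_label[nd] = nd.taxon.label
        else:
            node_label[nd] = f"node{counter}"
            counter += 1

    true_indels: list = []
    alignments: dict[RegionKey, RegionAlignment] = {}
    classes: dict[RegionKey, str] = {}
    # per leaf, evolved arrays per segment (in layout order)
    leaf_segments: dict[str, list[np.ndarray]] = {lab: [] for lab in leaves}

    for seg in segments:
        genic = seg.key.kind == "genic"
        sub_rate = config.sub_rate_genic if genic else config.sub_rate_intergenic
        indel_rate = config.indel_rate_genic if genic else config.indel_rate_intergenic
        p_frame = config.p_frame_genic if genic else config.p_frame_intergenic
        classes[seg.key] = seg.key.kind

        root_bases = anc_arr[seg.start : seg.end].copy()
        registry = _ColumnRegistry(len(root_bases))
        states: dict[str, tuple[list[int], np.ndarray]] = {}

        def walk(node, ids: list[int], bases: np.ndarray):
            for child in node.child_nodes():
                bl = child.edge.length or 0.0
                c_ids, c_bases = _evolve_branch(
                    ids, bases, bl, sub_rate, indel_rate, p_frame,
                    config.indel_len_max, registry, rng,
                    seg, node_label[child], true_indels, genic)
                if child.is_leaf():
                    states[node_label[child]] = (c_ids, c_bases)
                walk(child, c_ids, c_bases)

        walk(t.seed_node, list(range(len(root_bases))), root_bases)

        rows = {"ancestor": (list(range(len(root_bases))), root_bases)}
        rows.update(states)
        alignments[seg.key] = _registry_alignment(seg.key, registry, rows, seg.strand)
        for lab in leaves:
            leaf_segments[lab].append(states[lab][1])

    samples, ir_coords = _assemble_samples(ancestor, segments, leaf_segments, leaves)
    truth = SimTruth(
        true_tree=t.as_string(schema="newick", suppress_rooting=True).strip(),
        true_alignments=alignments,
        true_indels=true_indels,
        ir_coords=ir_coords,
        classes=classes,
    )
    return samples, truth


def _evolve_branch(ids, bases, bl, sub_rate, indel_rate, p_frame, lmax,
                   registry, rng, seg, child_label, true_indels, genic):
    ids = list(ids)
    bases = bases.copy()
    n = len(bases)
    if n and bl > 0 and sub_rate > 0:
        p = 1.0 - math.exp(-sub_rate * bl)
        hits = np.nonzero(rng.random(n) < p)[0]
        if len(hits):
            shift = rng.integers(1, 4, size=len(hits)).astype(np.uint8)
            bases[hits] = (bases[hits] + shift) % 4
    if bl > 0 and indel_rate > 0 and n:
        n_events = rng.poisson(indel_rate * bl * n)
        for _ in range(n_events):
            length = _draw_indel_len(rng, p_frame, lmax)
            if len(bases) == 0:
                break
            if rng.random() < 0.5:  # deletion
                # place the event fully inside the region so the recorded
                # length keeps its frame class; an oversized draw removes
                # the whole region instead
                if length >= len(bases):
                    if genic:
                        raise SimulationError(
                            f"gene {seg.key.name} fully deleted on branch to {child_label}")
                    start, actual = 0, len(bases)
                else:
                    start = int(rng.integers(0, len(bases) - length + 1))
                    actual = length
                if genic and actual == len(bases):
                    raise SimulationError(
                        f"gene {seg.key.name} fully deleted on branch to {child_label}")
                del ids[start : start + actual]
                bases = np.delete(bases, np.s_[start : start + actual])
                true_indels.append((seg.key, child_label, actual, "del"))
            else:  # insertion
                pos = int(rng.integers(0, len(bases) + 1))
                anchor = ids[pos - 1] if pos > 0 else None
                new = registry.new_ids(length, anchor)
                ids[pos:pos] = new
                bases = np.insert(bases, pos,
                                  rng.integers(0, 4, size=length).astype(np.uint8))
                true_indels.append((seg.key, child_label, length, "ins"))
    return ids, bases


def _registry_alignment(key, registry, rows, strand) -> RegionAlignment:
    # keep only columns present in at least one row (an inserted run later
    # deleted everywhere would otherwise leave an all-gap column)
    live = set()
    for ids, _ in rows.values():
        live.update(ids)
    columns = [c for c in registry.order if c in live]
    col_pos = {c: i for i, c in enumerate(columns)}
    out = {}
    for label, (ids, bases) in rows.items():
        row = np.full(len(columns), ord("-"), dtype=np.uint8)
        if len(ids):
            idx = np.fromiter((col_pos[c] for c in ids), dtype=np.int64, count=len(ids))
            row[idx] = np.frombuffer(b"ACGT", dtype=np.uint8)[bases]
        out[label] = row.tobytes().decode("ascii")
    if strand == "-":
        # store genic alignments in gene orientation: reverse-complement
        # every row and reverse the column order ('-' passes through)
        out = {k: revcomp(v) for k, v in out.items()}
    key_rows = dict(sorted(out.items(), key=lambda kv: (kv[0] != "ancestor", kv[0])))
    return RegionAlignment(key, key_rows)


def _assemble_samples(ancestor, segments, leaf_segments, leaves):
    part = ancestor.partition
    has_ir = part is not None and part.has_ir
    samples, ir_coords = [], {}
    anc_feats: dict[str, GeneFeature] = {}
    for f in sorted(ancestor.features, key=lambda f: f.start):
        anc_feats.setdefault(f.name, f)  # IR genes: keep the IRa copy
    for lab in leaves:
        arrs = leaf_segments[lab]
        features = []
        offset = 0
        comp_len = {"LSC": 0, "IRa": 0, "SSC": 0}
        ir_gene_rel = []  # (name, rel_start, rel_end, strand, kind) within IRa
        ira_offset = None
        ssc_boundary = (part.ira.start if has_ir
                        else (part.ssc.start if part and part.ssc else len(ancestor.sequence)))
        for seg, arr in zip(segments, arrs):
            if seg.in_ir:
                comp = "IRa"
            else:
                comp = "LSC" if seg.start < ssc_boundary else "SSC"
            if comp == "IRa" and ira_offset is None:
                ira_offset = offset
            if seg.key.kind == "genic":
                f = anc_feats[seg.key.name]
                features.append(GeneFeature(seg.key.name, offset,
                                            offset + len(arr), f.strand, f.kind))
                if comp == "IRa":
                    ir_gene_rel.append((seg.key.name, offset, offset + len(arr),
                                        f.strand, f.kind))
            comp_len[comp] += len(arr)
            offset += len(arr)
        seq_arr = np.concatenate([a for a in arrs]) if arrs else np.array([], dtype=np.uint8)
        L_lsc, L_ir, L_ssc = comp_len["LSC"], comp_len["IRa"], comp_len["SSC"]
        if has_ir:
            ira_iv = Interval(ira_offset, ira_offset + L_ir)
            ir_block = seq_arr[ira_iv.start : ira_iv.end]
            irb_start = len(seq_arr)
            seq_arr = np.concatenate([seq_arr, (3 - ir_block)[::-1]])
            for (nm, s, e, strand, kind) in ir_gene_rel:
                features.append(GeneFeature(
                    nm,
                    irb_start + (ira_iv.end - e),
                    irb_start + (ira_iv.end - s),
                    "-" if strand == "+" else "+",
                    kind))
            partition = QuadripartitePartition(
                lsc=Interval(0, L_lsc),
                ssc=Interval(ira_iv.end, ira_iv.end + L_ssc) if L_ssc else None,
                ira=ira_iv,
                irb=Interval(irb_start, irb_start + L_ir),
            )
        else:
            partition = QuadripartitePartition(
                lsc=Interval(0, L_lsc),
                ssc=Interval(L_lsc, L_lsc + L_ssc) if L_ssc else None,
                ira=None, irb=None)
        samples.append(AnnotatedPlastome(lab, decode(seq_arr), features, partition))
        ir_coords[lab] = partition
    return samples, ir_coords


# ------------------------------------------------------------------ trees

def random_tree(labels: Sequence[str], branch_len_mean: float,
                rng: np.random.Generator) -> str:
    """Random binary topology by successive joins.

    Branch lengths are uniform in [0.5, 1.5] x mean: every internal edge
    carries enough expected change to be identifiable at the simulated
    genome size, which a heavy left tail (e.g. exponential draws) would
    not guarantee for any inference method.
    """

    def bl():
        return branch_len_mean * rng.uniform(0.5, 1.5)

    nodes = [f"{lab}:{bl():.6f}" for lab in sorted(labels)]
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[i], nodes[j]
        rest = [nodes[x] for x in range(len(nodes)) if x not in (i, j)]
        joined = f"({a},{b}):{bl():.6f}"
        nodes = rest + [joined]
    return f"({nodes[0]},{nodes[1]});"


def make_tree(config: SimConfig) -> str:
    if config.tree is not None:
        return config.tree
    rng = np.random.default_rng([config.seed, 2])
    return random_tree(config.leaf_labels(), config.branch_len_mean, rng)


def simulate(config: SimConfig):
    """Convenience wrapper: ancestor + tree + evolution.

    Returns (ancestor, samples, truth).
    """
    ancestor = build_ancestor(config)
    tree = make_tree(config)
    samples, truth = evolve_along_tree(ancestor, tree, config)
    return ancestor, samples, truth


# ------------------------------------------------------------------ coverage

def emit_coverage_track(sample: AnnotatedPlastome, config: SimConfig) -> np.ndarray:
    """Per-position integer read depth: single-copy at ``coverage_depth``,
    IR positions doubled, optional seeded Gaussian noise."""
    part = sample.partition
    if part is None:
        raise ValueError(f"{sample.sample_id}: partition required")
    L = len(sample.sequence)
    depth = np.full(L, float(config.coverage_depth))
    for iv in (part.ira, part.irb):
        if iv is None:
            continue
        for p in range(iv.start, iv.end):
            depth[p % L] *= 2
    if config.coverage_noise_sd > 0:
        rng = np.random.default_rng(
            [config.seed, 3, zlib.crc32(sample.sample_id.encode()) % (2**31)])
        depth = depth + rng.normal(0, config.coverage_noise_sd, size=L)
    return np.rint(depth).astype(int)
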
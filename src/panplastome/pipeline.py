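"""End-to-end pipelines wiring the stages together.

Two routes mirror the two ways of getting a plastome phylogeny:

* alignment-based: regions -> alignment statistics -> trimmed
  supermatrix (+ codon matrices, diagnostic set) -> NJ tree;
* alignment-free: kmer profile -> weighted splits -> strict tree,
  optionally compared against reference trees.

Every run writes a ``manifest.json`` listing each produced file with its
SHA-256 digest and the configuration snapshot, so reruns on identical
inputs are byte-reproducible and verifiable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from . import io
from .alignstats import (
    RegionAlignment,
    call_all,
    frame_analysis,
    identity_contrast,
    indel_size_spectrum,
    percent_identity,
)
from .ksplits import build_profile, infer_splits, strict_tree, to_splits_nexus
from .regions import conserved_adjacent_pairs, extract_regions, gene_order
from .simulate import SimConfig, emit_coverage_track, simulate
from .structure import detect_quadripartite
from .supermatrix import (
    build_matrices,
    concatenate,
    nj_tree,
    select_diagnostic_regions,
    trim_alignment,
    write_partition_file,
    write_phylip,
)
from .treecmp import compare, splits_from_tree
from .types import RegionKey


@dataclass
class PipelineConfig:
    samples_dir: Optional[Path] = None
    alignments_dir: Optional[Path] = None
    out_dir: Path = Path("panplastome_out")
    gap_keep: float = 0.8
    min_similarity: float = 0.001
    k: int = 31
    weight_fn: str = "geom2"
    top: str = "10n"
    outgroups: list = field(default_factory=list)
    seed: int = 0

    def validate(self) -> None:
        if not 0 <= self.gap_keep <= 1:
            raise ValueError("gap_keep must be in [0,1]")
        if self.k < 11 or self.k % 2 == 0:
            raise ValueError("k must be odd and >= 11")
        if self.weight_fn not in ("count", "geom", "geom2"):
            raise ValueError(f"unknown weight_fn {self.weight_fn!r}")
        if self.top not in ("all", "10n"):
            raise ValueError(f"unknown top rule {self.top!r}")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_manifest(out: Path, config, files: list[Path]) -> Path:
    manifest = {
        "config": {k: str(v) for k, v in dataclasses.asdict(config).items()},
        "files": {str(p.relative_to(out)): _sha256(p) for p in sorted(files)},
    }
    mpath = out / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return mpath


# ------------------------------------------------------------------ simulate

def simulate_to_dir(config: SimConfig, out_dir) -> Path:
    """Run the simulator and write every artifact (samples, truth)."""
    out = Path(out_dir)
    (out / "samples").mkdir(parents=True, exist_ok=True)
    (out / "alignments").mkdir(exist_ok=True)
    (out / "coverage").mkdir(exist_ok=True)
    files = []
    ancestor, samples, truth = simulate(config)
    for p in [ancestor] + samples:
        fp = out / "samples" / f"{p.sample_id}.fasta"
        gp = out / "samples" / f"{p.sample_id}.gff3"
        io.write_fasta(fp, {p.sample_id: p.sequence})
        io.write_gff3(gp, p)
        files += [fp, gp]
    for key, aln in truth.true_alignments.items():
        ap = out / "alignments" / f"{key.kind}_{key.name}.fasta"
        io.write_alignment(ap, dict(aln.rows))
        files.append(ap)
    for p in samples:
        cp = out / "coverage" / f"{p.sample_id}.tsv"
        io.write_coverage(cp, emit_coverage_track(p, config))
        files.append(cp)
    tp = out / "true_tree.nwk"
    tp.write_text(truth.true_tree + "\n")
    files.append(tp)
    ip = out / "true_indels.tsv"
    with open(ip, "w") as fh:
        fh.write("region\tkind\tnode\tlength\tevent\n")
        for key, node, length, ev in truth.true_indels:
            fh.write(f"{key.name}\t{key.kind}\t{node}\t{length}\t{ev}\n")
    files.append(ip)
    _write_manifest(out, config, files)
    return out


# ------------------------------------------------------------------ alignment route

def load_alignments(alignments_dir) -> dict[RegionKey, RegionAlignment]:
    alns = {}
    for path in sorted(Path(alignments_dir).glob("*.fasta")):
        kind, _, name = path.stem.partition("_")
        if kind not in ("genic", "intergenic"):
            raise ValueError(f"{path}: expected '<kind>_<name>.fasta' naming")
        key = RegionKey(kind, name)
        alns[key] = RegionAlignment(key, io.read_alignment(path))
    return alns


def run_alignment_pipeline(config: PipelineConfig) -> Path:
    """regions -> stats -> matrices -> diagnostic -> NJ tree."""
    config.validate()
    if config.alignments_dir is None:
        raise ValueError("alignments_dir is required")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = []

    cds_names: set[str] = set()
    if config.samples_dir is not None:
        samples_dir = Path(config.samples_dir)
        fastas = sorted(samples_dir.glob("*.fasta"))
        if not fastas:
            raise ValueError(f"{samples_dir}: no FASTA files found")
        plastomes = []
        for fp in fastas:
            gp = fp.with_suffix(".gff3")
            if not gp.exists():
                raise ValueError(f"{fp}: missing annotation {gp.name}")
            p = io.read_plastome(fp, gp)
            if p.sample_id == "ancestor":
                continue
            # structural context so IR-resident genes collapse correctly
            part = detect_quadripartite(p.sequence,
                                        min_ir_len=min(500, len(p.sequence) // 8))
            plastomes.append(p.with_(partition=part))
        orders = {p.sample_id: gene_order(p) for p in plastomes}
        pairs = conserved_adjacent_pairs(orders)
        region_set = extract_regions(plastomes, pairs)
        (out / "regions").mkdir(exist_ok=True)
        for key in region_set.keys:
            rp = out / "regions" / f"{key.kind}_{key.name}.fasta"
            io.write_fasta(rp, region_set.region(key))
            files.append(rp)
        dp = out / "regions" / "drop_log.tsv"
        with open(dp, "w") as fh:
            fh.write("region\tsample\treason\n")
            for key, sid, reason in region_set.drop_log:
                fh.write(f"{key.name}\t{sid}\t{reason}\n")
        files.append(dp)
        for p in plastomes:
            cds_names |= {f.name for f in p.features if f.kind == "CDS"}

    alns = load_alignments(config.alignments_dir)
    if not alns:
        raise ValueError(f"{config.alignments_dir}: no region alignments found")
    ingroup = sorted(set(next(iter(alns.values())).rows) - set(config.outgroups)
                     - {"ancestor"})
    alns = {k: a.subset(ingroup + sorted(config.outgroups)) for k, a in alns.items()}

    # identities with and without outgroups
    idp = out / "identities.tsv"
    identities = {}
    with open(idp, "w") as fh:
        fh.write("region\tkind\tidentity_all\tidentity_ingroup\n")
        for key, aln in alns.items():
            ident_all = percent_identity(aln)
            ident_in = percent_identity(aln, ingroup) if config.outgroups else ident_all
            identities[key] = ident_in
            fh.write(f"{key.name}\t{key.kind}\t{ident_all:.6f}\t{ident_in:.6f}\n")
    files.append(idp)

    variants = call_all(alns)
    vp = out / "variants.tsv"
    with open(vp, "w") as fh:
        fh.write("region\tkind\tsnv_count\tindel_count\tsnv_density\tindel_density\n")
        for key in alns:
            sc, ic = variants.counts[key]
            sd, idd = variants.densities[key]
            fh.write(f"{key.name}\t{key.kind}\t{sc}\t{ic}\t{sd:.6g}\t{idd:.6g}\n")
    files.append(vp)

    fa = frame_analysis(variants)
    spectrum = indel_size_spectrum(variants)
    genic_ids = [v for k, v in identities.items() if k.kind == "genic"]
    inter_ids = [v for k, v in identities.items() if k.kind == "intergenic"]
    stats = {"frame": dataclasses.asdict(fa)}
    if len(genic_ids) >= 2 and len(inter_ids) >= 2:
        stats["identity_contrast"] = dataclasses.asdict(
            identity_contrast(genic_ids, inter_ids))
    stats["indel_size_spectrum"] = {
        cls: {str(k): list(v) for k, v in h.items()} for cls, h in spectrum.items()}
    sp = out / "stats.json"
    sp.write_text(json.dumps(stats, indent=1))
    files.append(sp)

    trimmed = [trim_alignment(alns[k], config.gap_keep, config.min_similarity)
               for k in alns]
    sm = concatenate(trimmed)
    pp, qp = out / "supermatrix.phy", out / "partitions.txt"
    write_phylip(pp, sm)
    write_partition_file(qp, sm)
    files += [pp, qp]
    smp = out / "supermatrix_summary.json"
    smp.write_text(json.dumps(sm.summary(), indent=1))
    files.append(smp)

    if cds_names:
        mats = build_matrices(alns, cds_names, config.gap_keep, config.min_similarity)
        for name, mat in mats.items():
            if mat is None:
                continue
            mp = out / f"matrix_{name}.phy"
            write_phylip(mp, mat)
            files.append(mp)

    sel = select_diagnostic_regions(alns, identities)
    selp = out / "diagnostic_regions.tsv"
    with open(selp, "w") as fh:
        fh.write("rank\tregion\tkind\n")
        for i, key in enumerate(sel.selected, 1):
            fh.write(f"{i}\t{key.name}\t{key.kind}\n")
    files.append(selp)

    np_ = out / "nj_tree.nwk"
    np_.write_text(nj_tree(sm) + "\n")
    files.append(np_)

    _write_manifest(out, config, files)
    return out


# ------------------------------------------------------------------ kmer route

def run_ksplit_pipeline(config: PipelineConfig,
                        reference_tree: Optional[str] = None) -> Path:
    """kmer profile -> splits -> strict tree -> optional comparison."""
    config.validate()
    if config.samples_dir is None:
        raise ValueError("samples_dir is required")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = []
    fastas = sorted(Path(config.samples_dir).glob("*.fasta"))
    if not fastas:
        raise ValueError(f"{config.samples_dir}: no FASTA files found")
    seqs = {}
    for fp in fastas:
        recs = io.read_fasta(fp)
        sid = fp.stem
        if sid == "ancestor":
            continue
        seqs[sid] = list(recs.values())
    profile = build_profile(seqs, k=config.k)
    splits = infer_splits(profile, config.weight_fn, config.top)

    tsvp = out / "splits.tsv"
    with open(tsvp, "w") as fh:
        fh.write("weight\tside\n")
        for side, w in sorted(splits.weights.items(), key=lambda kv: -kv[1]):
            fh.write(f"{w:.6f}\t{','.join(sorted(side))}\n")
    files.append(tsvp)
    nexp = out / "splits.nex"
    nexp.write_text(to_splits_nexus(splits))
    files.append(nexp)
    treep = out / "strict_tree.nwk"
    newick = strict_tree(splits)
    treep.write_text(newick + "\n")
    files.append(treep)

    if reference_tree is not None:
        report = compare(splits_from_tree(newick), splits_from_tree(reference_tree))
        cp = out / "comparison.json"
        cp.write_text(json.dumps(dataclasses.asdict(report), indent=1))
        files.append(cp)

    _write_manifest(out, config, files)
    return out
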
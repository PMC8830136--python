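"""Readers and writers for FASTA, GFF3, coverage TSV and alignment files.

GFF3 files use 1-based inclusive coordinates; everything in memory is
0-based half-open.  Gene names are canonicalised through the alias table
at parse time (e.g. *pbf1* -> *psbN*).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Optional
from urllib.parse import quote, unquote

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .types import (
    AnnotatedPlastome,
    GeneFeature,
    Interval,
    QuadripartitePartition,
    canonical_gene_name,
)


# ---------------------------------------------------------------- FASTA

def write_fasta(path, records: dict[str, str]) -> None:
    """Write ``{id: sequence}`` as FASTA (uppercase, one record per id)."""
    recs = [SeqRecord(Seq(s.upper()), id=name, description="") for name, s in records.items()]
    SeqIO.write(recs, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {r.id: str(r.seq).upper() for r in SeqIO.parse(str(path), "fasta")}


def read_alignment(path) -> dict[str, str]:
    """Aligned FASTA with '-' gaps; all rows must share one length."""
    rows = {r.id: str(r.seq).upper() for r in SeqIO.parse(str(path), "fasta")}
    lens = {len(s) for s in rows.values()}
    if len(lens) > 1:
        raise ValueError(f"{path}: rows of unequal length {sorted(lens)}")
    return rows


write_alignment = write_fasta


# ---------------------------------------------------------------- GFF3

def write_gff3(path, plastome: AnnotatedPlastome) -> None:
    L = len(plastome.sequence)
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {plastome.sample_id} 1 {L}\n")
        for i, f in enumerate(sorted(plastome.features, key=lambda f: f.start)):
            attrs = f"ID=gene{i};Name={quote(f.name)};gene_biotype={f.kind}"
            fh.write(
                "\t".join(
                    [
                        plastome.sample_id,
                        "panplastome",
                        "gene",
                        str(f.start + 1),
                        str(f.end),  # 1-based inclusive == half-open end
                        ".",
                        f.strand,
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )


def read_gff3(path) -> list[GeneFeature]:
    feats = []
    for line in open(path):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 9 or parts[2] != "gene":
            continue
        attrs = dict(
            kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv
        )
        name = canonical_gene_name(unquote(attrs.get("Name", attrs.get("ID", "?"))))
        kind = attrs.get("gene_biotype", attrs.get("type", "CDS"))
        feats.append(
            GeneFeature(
                name=name,
                start=int(parts[3]) - 1,
                end=int(parts[4]),
                strand=parts[6],
                kind=kind,
            )
        )
    return feats


def read_plastome(fasta_path, gff_path, sample_id: Optional[str] = None) -> AnnotatedPlastome:
    seqs = read_fasta(fasta_path)
    if len(seqs) != 1:
        raise ValueError(f"{fasta_path}: expected a single record, got {len(seqs)}")
    (rec_id, seq), = seqs.items()
    return AnnotatedPlastome(
        sample_id=sample_id or rec_id,
        sequence=seq,
        features=read_gff3(gff_path),
    )


# ---------------------------------------------------------------- coverage

def write_coverage(path, depths: Iterable[int]) -> None:
    """Two-column TSV (position, depth), 1-based positions."""
    with open(path, "w") as fh:
        for i, d in enumerate(depths, start=1):
            fh.write(f"{i}\t{d}\n")


def read_coverage(path) -> list[int]:
    depths = []
    for line in open(path):
        if not line.strip():
            continue
        pos, d = line.split("\t")
        if int(pos) != len(depths) + 1:
            raise ValueError(f"{path}: positions must be contiguous from 1")
        depths.append(int(float(d)))
    return depths


# ---------------------------------------------------------------- partition

def _iv(iv: Optional[Interval]):
    return None if iv is None else [iv.start, iv.end]


def partition_to_json(p: QuadripartitePartition) -> dict:
    return {
        "lsc": _iv(p.lsc),
        "ssc": _iv(p.ssc),
        "ira": _iv(p.ira),
        "irb": _iv(p.irb),
        "orientation_flag": p.orientation_flag,
    }


def partition_from_json(d: dict) -> QuadripartitePartition:
    def iv(v):
        return None if v is None else Interval(v[0], v[1])

    return QuadripartitePartition(
        lsc=iv(d["lsc"]),
        ssc=iv(d["ssc"]),
        ira=iv(d["ira"]),
        irb=iv(d["irb"]),
        orientation_flag=d.get("orientation_flag", "canonical"),
    )


def write_partition(path, p: QuadripartitePartition) -> None:
    Path(path).write_text(json.dumps(partition_to_json(p), indent=1))
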
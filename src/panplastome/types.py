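"""Core domain types for pan-plastome analysis.

A plastome is a circular molecule with a quadripartite architecture: a
large single-copy region (LSC), a small single-copy region (SSC), and two
inverted repeats (IRa/IRb) that are reverse complements of each other.
Coordinates are 0-based half-open internally; intervals on the circle may
extend past the sequence length to represent origin crossing
(``start < len(seq) <= end``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from ._util import revcomp

GENE_ALIASES = {
    # pbf1 is an alternative name for psbN used by some annotation services
    "pbf1": "psbN",
}


def canonical_gene_name(name: str) -> str:
    return GENE_ALIASES.get(name, name)


@dataclass(frozen=True)
class Interval:
    """Half-open interval on a circular coordinate system.

    ``0 <= start < L`` and ``start < end <= start + L``; ``end > L`` means
    the interval wraps past the origin.
    """

    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start

    def wraps(self, seq_len: int) -> bool:
        return self.end > seq_len

    def extract(self, seq: str) -> str:
        if self.end <= len(seq):
            return seq[self.start : self.end]
        return seq[self.start :] + seq[: self.end - len(seq)]

    def contains(self, pos: int, seq_len: int) -> bool:
        p = pos % seq_len
        if self.end <= seq_len:
            return self.start <= p < self.end
        return p >= self.start or p < self.end - seq_len


@dataclass(frozen=True)
class GeneFeature:
    name: str
    start: int
    end: int  # half-open
    strand: str  # '+' or '-'
    kind: str  # 'CDS' | 'rRNA' | 'tRNA'

    def __post_init__(self):
        if not self.start < self.end:
            raise ValueError(f"empty feature interval for {self.name}")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r} for {self.name}")

    @property
    def interval(self) -> Interval:
        return Interval(self.start, self.end)

    def sequence(self, seq: str) -> str:
        s = self.interval.extract(seq)
        return revcomp(s) if self.strand == "-" else s


@dataclass(frozen=True)
class QuadripartitePartition:
    """LSC / SSC / IRa / IRb intervals; IRs may be None (no repeat found)."""

    lsc: Interval
    ssc: Optional[Interval]
    ira: Optional[Interval]
    irb: Optional[Interval]
    orientation_flag: str = "canonical"  # or 'flipped-SSC'

    @property
    def has_ir(self) -> bool:
        return self.ira is not None and self.irb is not None

    def total_length(self) -> int:
        tot = self.lsc.length
        for iv in (self.ssc, self.ira, self.irb):
            if iv is not None:
                tot += iv.length
        return tot


@dataclass
class AnnotatedPlastome:
    """One sample: circular sequence, gene features, optional partition."""

    sample_id: str
    sequence: str
    features: list[GeneFeature] = field(default_factory=list)
    partition: Optional[QuadripartitePartition] = None

    def __post_init__(self):
        if not self.sequence:
            raise ValueError(f"{self.sample_id}: empty sequence")
        L = len(self.sequence)
        seen = set()
        for f in self.features:
            if f.end > 2 * L:
                raise ValueError(f"{self.sample_id}: feature {f.name} outside sequence")
            key = (f.name, f.start)
            if key in seen:
                raise ValueError(f"{self.sample_id}: duplicate feature {key}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.sequence)

    def with_(self, **kw) -> "AnnotatedPlastome":
        d = dict(sample_id=self.sample_id, sequence=self.sequence,
                 features=self.features, partition=self.partition)
        d.update(kw)
        return AnnotatedPlastome(**d)


@dataclass(frozen=True)
class RegionKey:
    """A named genic or intergenic locus shared across samples."""

    kind: str  # 'genic' | 'intergenic'
    name: str  # gene symbol, or 'geneA-geneB' for a spacer

    def __post_init__(self):
        if self.kind not in ("genic", "intergenic"):
            raise ValueError(f"bad region kind {self.kind!r}")

    def __str__(self) -> str:
        return f"{self.kind}:{self.name}"
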
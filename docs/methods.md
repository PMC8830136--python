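# Methods

## Scope and model of the data

`panplastome` analyses sets of annotated plastomes — circular chloroplast
genomes of roughly 150 kb with the classic quadripartite architecture: a
large single-copy region (LSC), a small single-copy region (SSC) and two
inverted-repeat copies (IRa/IRb) that are exact or near-exact reverse
complements of each other. Two well-documented contrasts drive the
statistics implemented here:

1. gene sequences are more conserved than intergenic spacers, and
2. insertions/deletions inside genes are biased toward lengths that are
   multiples of three, because such indels preserve the reading frame.

The package provides two independent routes to a phylogeny — an
alignment-based supermatrix route and an alignment-free kmer-split route
— plus the machinery to compare the resulting trees and split sets
quantitatively.

## Synthetic data generator

Real pan-plastome datasets require assembly and annotation pipelines far
outside desk scale, so every statistical property of the package is
exercised against a simulator that emits full ground truth.

**Ancestor.** A circular molecule is laid out as LSC + IRa + SSC + IRb
with IRb the reverse complement of IRa. Compartment lengths follow the
configured proportions exactly (defaults 55.5 % / 11.8 % / 16.35 % per
IR, matching real plastome proportions; the default molecule is
down-scaled to 20 kb, and the studies in the test suite use 40–120 kb —
sizes chosen so each analysis sees enough signal while the whole suite
runs in well under a minute per simulation). Each non-empty compartment
starts and ends with a gene so that spacers never cross compartment
junctions; genes carry plastid-style names (a duplicated rRNA pair lives
in the IR), random strands, and CDS lengths are multiples of three. The
two bases flanking each IR junction are nudged off complementarity so
that the planted IR boundary is also the *maximal* one — without this,
greedy repeat extension would be free to grow past the boundary by
chance with probability 1/4 per junction, and exact coordinate recovery
would be ill-posed.

**Evolution.** Sequences evolve along a supplied or generated tree.
Substitutions use a uniform-rate, equal-frequency (Jukes–Cantor-like)
model: per branch, each site mutates with probability
`1 − exp(−rate·t)`, uniformly to one of the other three bases. Genic
and intergenic sites have separate rates (defaults 0.02 / 0.06 per site
per unit branch length). Indel events are Poisson in
`rate · length · t` per region; lengths are geometric with mean 3
truncated at `indel_len_max` (default 12) and resampled so the class's
probability of a multiple-of-three length equals `p_frame`
(defaults 0.45 genic / 0.30 intergenic). Deletions are placed fully
inside their region so a recorded length keeps its frame class; an
event that would delete an entire gene raises an error rather than
silently truncating. Indels never cross a gene/spacer boundary, which
keeps per-region event attribution exact. The IR is evolved once per
lineage and copied, so the two IR copies of a sample are always
identical.

**Ground truth.** Each residue carries a column identifier; insertions
mint fresh identifiers spliced into a per-region registry next to their
left anchor. Every lineage's identifier list is then a subsequence of
the registry, which *is* the true multiple alignment (ancestor row
included). The generator also emits the true tree, the true indel event
list, per-sample quadripartite coordinates, and per-position coverage
tracks in which IR positions carry twice the single-copy depth
(optionally with seeded Gaussian noise).

**Trees.** Generated topologies are random binary joins; branch lengths
are uniform in [0.5, 1.5] × `branch_len_mean`. The uniform law is a
deliberate design choice: with a heavy left tail (e.g. exponential
draws) internal edges of a few times 10⁻³ substitutions/site occur
regularly, and at a fixed genome size no inference method can recover
such edges — topology-recovery checks would then measure the tree
prior, not the software.

**What the simulator does not model** (and therefore what passing tests
do not show about real data): sequencing reads and their errors,
recombination, gene gain/loss, rearrangements other than the two SSC
orientations, heterotachy or rate variation across sites, and IR
boundary shifts. Rates are homogeneous within each class.

## Structure detection

`detect_quadripartite` finds the maximal pair of disjoint
reverse-complementary intervals by exact k-mer seeding (k = min(31,
min_ir_len)) between the doubled sequence and its reverse complement,
grouping seed matches by anti-diagonal and extending greedily. Doubling
handles origin-crossing repeats of the circular molecule. Extension is
exact by default; a `mismatch_tol` parameter admits isolated mismatches
(flanked by matches, within a total budget) for noisy real data, but the
default is 0 so that exact planted repeats are recovered exactly. The
longer single-copy gap is labelled LSC, the shorter SSC; IRa is the copy
following the LSC.

`detect_ir_by_coverage` estimates single-copy depth (median first, one
re-estimation pass from positions outside the candidate band), then
returns the longest circular run of positions whose depth ratio lies in
[1.5, 2.5] — the doubled-coverage signature of a collapsed IR.

Because the SSC co-occurs in both orientations in vivo, comparisons need
a convention: `normalize_orientation` keeps the lexicographically
smaller of the SSC and its reverse complement, remapping contained
features. Any fixed convention would do; this one needs no external
reference.

## Regions and microsynteny

Gene order is read per sample after collapsing IR-duplicated genes to
their IRa copy. Conserved adjacencies are ordered gene pairs adjacent in
every sample's circular order (strand ignored — a spacer exists between
two genes regardless of their orientations). Intergenic regions are the
gaps between coordinate-adjacent conserved pairs; a pair is dropped
globally, with a logged reason, if in any sample the genes overlap, the
spacer is empty, or the pair is not coordinate-adjacent (the artificial
SSC→LSC adjacency created by IR collapsing). Global dropping keeps every
kept region at the full sample complement, which concatenation requires.
Minus-strand genes are extracted reverse-complemented;
`harmonize_orientation` flips sequences that share more forward 11-mers
with the first sample's reverse complement than with its forward strand
(canonical kmers cannot be used here — they are strand-invariant by
construction).

## Alignment statistics

Identity is the fraction of columns in which all rows carry the same
non-gap nucleotide; a gap is not a nucleotide, so any gap disqualifies a
column. `N` is missing data: rows with `N` are dropped from a column's
unanimity check provided at least two informative residues remain. An
SNV is a column with ≥ 2 distinct non-gap, non-N residues (one event per
column, however many alleles). An indel event is a maximal per-row gap
run; events are counted once per row carrying them, a choice that
rescales densities but leaves the mod-3 proportions unbiased under the
generator's law. Densities divide counts by alignment length and row
count. The frame contrast uses a two-sided Fisher exact test on the
2×2 class × mod-3 table; the identity contrast uses a two-sided
Mann–Whitney U test.

## Supermatrix construction

Columns are trimmed with two thresholds mirroring common trimming
practice: non-gap fraction ≥ 0.8 and column similarity ≥ 0.001, where
similarity is the majority-residue frequency among non-gap residues (a
simplification of conservation-score trimming; with the default 0.001
it removes only columns with no majority signal at all). Trimmed
regions are concatenated in the reference plastome order with a
partition map, and summaries (sites, distinct site patterns, gap
fraction, invariant fraction) are recomputable from content. Five
matrix variants are built: genic, intergenic, codon-faithful CDS with
the first and last codon (start/stop) removed, positions 1+2, and
position 3; a CDS whose trimmed-free alignment length is not a multiple
of three after codon removal is excluded with a warning rather than
shifted.

The diagnostic set is the shortest prefix of the regions sorted by
ascending identity (most variable first) whose concatenation separates
every sample pair, a pair being separated when some column shows two
differing non-gap residues. Ascending order is the only reading that
yields a small set; the stopping step is minimal by construction and
property-tested.

The distance tree is neighbor joining on p-distances (gap/N columns
excluded pairwise), a deliberately simple stand-in for full ML
inference: on additive distances NJ is consistent, and the tests assert
recovery rather than likelihood. The NJ agglomeration itself is
delegated to scikit-bio; the closed-form three-taxon and planted
additive-matrix checks in the tests are independent of it.

## Kmer splits

Canonical kmers (lexicographic minimum of kmer and reverse complement,
2-bit-packed for k ≤ 31) are counted per sample; kmers with dataset
total count 1 are discarded as noise. Each kmer's presence pattern
proposes a split of the sample set; weights are either the number of
supporting kmers (`count`), the sum of geometric means of the
supporting kmers' counts within the side (`geom`), or `geom` discounted
by the +1-smoothed geometric mean of counts outside the side (`geom2`).
Because a presence pattern has zero counts outside its side by
definition, the smoothed discount is identically 1 and `geom2` equals
`geom` in this formulation — both are declared stand-ins with the
intended monotone behaviour, and `count` is the reference weighting in
all tests. The `10n` rule keeps the 10·n heaviest splits, ties at the
cutoff included.

The strict tree greedily accepts splits by descending weight (ties:
smaller side, then lexicographic) when pairwise compatible with all
accepted splits — two splits are compatible when one of their four side
intersections is empty. Relative to a fixed reference taxon the
accepted sides form a laminar family, which nests directly into a
rooted tree; branch lengths are weights scaled by the total weight.
Split sets are also written as SplitsTree-readable NEXUS (TAXA +
SPLITS blocks) and re-read by the package's own parser.

## Tree and split-set comparison

Splits are extracted one per internal edge (weight = branch length, 1.0
when absent), trivial splits excluded, the two edges of a rooted basal
bifurcation merged. Precision is the predicted weight lying on splits
present in the reference over total predicted weight; recall is the
mirror with reference weights; F1 is their harmonic mean. The weighted
symmetric set distance sums each set's own weights over splits unique
to it and is reported unnormalised; the Robinson–Foulds distance is the
plain symmetric-difference count. Split identity ignores weights.

## Numerical and degenerate-input conventions

Coordinates are 0-based half-open internally; GFF3 I/O converts to
1-based inclusive. Intervals may extend past the sequence length to
express origin crossing. Gene-name aliases (currently *pbf1* → *psbN*)
are canonicalised at parse time. All randomness flows through
`numpy.random.default_rng` seeded from the configuration, with one
fixed draw order, so identical configurations give byte-identical
outputs. Degenerate inputs are handled explicitly: absent IRs give a
single-copy partition plus a warning, flat coverage returns no
interval, empty split sets give a star tree, and single-row alignments,
empty classes and taxon-set mismatches raise informative errors.

## Known limitations

Multiple alignment itself is out of scope (true alignments come from
the simulator; real data would be aligned externally and read in).
Trans-spliced genes are reduced to their first interval. The per-row
indel counting convention inflates event counts for events on deep
branches; adjacent events can merge into one gap run, slightly mixing
the two frame classes — at the event densities used in the test suite
this shifts the recovered proportions by well under the testing
tolerance, but it would matter at much higher divergence. The identity
statistic treats all columns equally and is not phylogenetically
corrected.
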
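# panplastome

Comparative pan-plastome analysis in Python: quadripartite structure
detection, microsynteny-based region extraction, SNV/InDel landscapes,
partitioned supermatrices with diagnostic marker selection, alignment-free
kmer-split phylogenies, and quantitative tree comparison — together with a
synthetic plastome evolution simulator that provides exact ground truth
for all of it.

## Who this is for

Plastomes (chloroplast genomes, ~150 kb circular molecules with an
LSC + IRa + SSC + IRb architecture) are a workhorse of plant phylogenetics.
Comparative studies across a genus repeatedly need the same steps: find
the inverted repeats, extract the genes and the intergenic spacers shared
by all samples, quantify conservation and variant hotspots per region,
concatenate trimmed alignments into supermatrices (whole, genic,
intergenic, codon-partitioned), pick a minimal diagnostic marker set, and
build trees both from alignments and directly from kmer content. This
package implements those steps as a library with a thin CLI.

## The statistics at its core

* **Alignment identity** of a region: the fraction of columns where all
  rows carry the same non-gap nucleotide. Genic vs intergenic identity
  distributions are contrasted with a two-sided Mann–Whitney U test.
* **Variant events**: one SNV per polymorphic column; one InDel event per
  maximal per-row gap run. Densities are normalised by alignment length
  and row count.
* **Frame preservation**: the proportion of indels whose length L
  satisfies L ≡ 0 (mod 3), per region class, contrasted with a Fisher
  exact test on the 2×2 class × mod-3 table. Reading-frame pressure makes
  this proportion higher inside genes.
* **Kmer splits**: each canonical kmer's presence pattern across samples
  proposes a bipartition; weights (count of supporting kmers, or
  geometric-mean variants) score the splits, and a greedy compatibility
  pass extracts the "strict" tree.
* **Split-set comparison**: weighted precision / recall / F1 (precision =
  total weight of predicted splits present in the reference / total
  predicted weight), the weighted symmetric set distance, and the
  Robinson–Foulds count.

## Worked example

Simulate eight plastomes along a random tree and run the analysis:

```python
from panplastome.simulate import SimConfig, simulate
from panplastome.alignstats import (percent_identity, call_all,
                                    frame_analysis, identity_contrast)
from panplastome.supermatrix import (trim_alignment, concatenate, nj_tree,
                                     select_diagnostic_regions)
from panplastome.treecmp import rf_distance

config = SimConfig(seed=42, n_taxa=8, total_len=40_000, n_genes=30,
                   branch_len_mean=0.03)
ancestor, samples, truth = simulate(config)
leaves = [p.sample_id for p in samples]
alignments = {k: a.subset(leaves) for k, a in truth.true_alignments.items()}

genic = [percent_identity(a) for k, a in alignments.items() if k.kind == "genic"]
intergenic = [percent_identity(a) for k, a in alignments.items() if k.kind == "intergenic"]
contrast = identity_contrast(genic, intergenic)
print(f"mean identity: genic {contrast.mean_genic:.4f}, "
      f"intergenic {contrast.mean_intergenic:.4f} (p = {contrast.p_value:.2e})")

frame = frame_analysis(call_all(alignments))
print(f"mod-3 indels: genic {frame.prop_genic_mod3:.1%}, "
      f"intergenic {frame.prop_intergenic_mod3:.1%} (Fisher p = {frame.p_value:.2e})")

matrix = concatenate([trim_alignment(a) for a in alignments.values()])
print("supermatrix:", matrix.summary())
print("NJ vs true tree RF distance:", rf_distance(nj_tree(matrix), truth.true_tree))

selection = select_diagnostic_regions(alignments)
print(f"diagnostic set: {len(selection.selected)} of {len(alignments)} regions")
```

Output:

```
mean identity: genic 0.9876, intergenic 0.9648 (p = 7.21e-10)
mod-3 indels: genic 46.3%, intergenic 22.2% (Fisher p = 9.24e-04)
supermatrix: {'n_sites': 33419, 'n_site_patterns': 176, 'gap_fraction': 0.00010847122894162004, 'invariant_fraction': 0.982315449295311}
NJ vs true tree RF distance: 0
diagnostic set: 2 of 57 regions
```

Genes are more conserved than spacers and their indels are biased toward
frame-preserving lengths — the two planted contrasts, both decisively
detected. The trimmed supermatrix is dominated by invariant sites, the
neighbor-joining tree matches the generating topology exactly (RF = 0),
and two highly variable regions already distinguish all eight samples.

## Command line

```sh
panplastome simulate --out sim/ --seed 1          # synthetic dataset + truth
panplastome structure --fasta sim/samples/t1.fasta --coverage sim/coverage/t1.tsv
panplastome run-all --samples sim/samples --aln sim/alignments \
    --out results/ --reference-tree sim/true_tree.nwk
panplastome treecmp --trees results/nj_tree.nwk results/ksplits/strict_tree.nwk
```

`run-all` executes both pipelines (regions → statistics → matrices →
diagnostic set → NJ tree, and kmer profile → splits → strict tree →
comparison) and writes a `manifest.json` with a SHA-256 digest per
artifact; reruns on identical inputs reproduce identical digests.

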
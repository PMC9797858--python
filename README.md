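# ecoassembly

Diversity analysis and null-model community-assembly inference for
microbiome count tables.

Grouped 16S rRNA surveys — for example, insect gut communities sampled
from several geographic sources with a few pooled replicates each —
routinely ask two questions: *do the communities differ between
groups?* and *which ecological processes produced the differences?*
`ecoassembly` implements the full chain used to answer both from an
OTU table, a rooted phylogeny, and a sample→group mapping:

- **alpha diversity**: observed OTUs, Chao1, ACE, Shannon (nats),
  Simpson dominance, Good's coverage, rarefaction curves, and per-index
  one-way ANOVA with Tukey-HSD compact letters;
- **beta diversity**: Bray–Curtis and weighted UniFrac dissimilarities
  on relative abundances, PCoA and non-metric MDS ordination, and the
  ANOSIM and one-way PERMANOVA permutation tests;
- **assembly processes**: the two-stage phylogenetic/taxonomic
  null-model partition of pairwise community turnover into variable
  selection, homogeneous selection, dispersal limitation, homogenizing
  dispersal, and undominated (drift) fractions;
- **synthetic data**: a generator that emulates the 6-source ×
  3-replicate study design with known assembly regimes, so every stage
  of the inference can be validated against ground truth.

## The core inference

For each pair of communities the β mean nearest taxon distance

    βMNTD = ½ [ Σ_{i∈A} f_iA · min_{j∈B} d_ij + Σ_{j∈B} f_jB · min_{i∈A} d_ij ]

weights each taxon's patristic distance to its closest relative in the
other community by its relative abundance. Shuffling taxon identities
across all tree tips yields a null distribution, and the z-score

    βNTI = (βMNTD_obs − mean βMNTD_null) / sd βMNTD_null

flags deterministic processes: βNTI > +2 is variable selection
(divergent environments), βNTI < −2 homogeneous selection (shared
filtering). Pairs without a significant βNTI are passed to the
abundance-based Raup–Crick index: null communities preserving each
sample's richness and total abundance are assembled from the
metacommunity (occurrence ∝ occupancy, individuals ∝ pooled relative
abundance), and

    RC_bray = 2 · ( (#null < obs) + ½·(#null = obs) ) / n_null − 1

locates the observed Bray–Curtis within the null: RC > +0.95 indicates
dispersal limitation, RC < −0.95 homogenizing dispersal, and the
remainder is undominated.

## Worked example

`examples/04_assembly_processes.py` simulates a six-source study under
divergent environmental filtering (sources split across two lineages
of a 100-taxon phylogeny, one ubiquitous dominant generalist, 5,000
reads per sample) and runs the full two-stage inference:

```
expected between-source process: variable_selection

process                   within %  between %
variable_selection           0.00%     60.00%
homogeneous_selection        0.00%      3.70%
dispersal_limitation         0.00%      0.00%
homogenizing_dispersal      11.11%      0.00%
undominated                 88.89%     36.30%

selection total between sources: 63.70%  dispersal total: 0.00%
```

Between sources the environmental filter differs, so deterministic
divergence (variable selection) dominates the 135 between-source
pairs; within a source the 18 replicate pairs share the filter and
differ only by drift, so stochastic categories prevail — the
qualitative pattern real geographic gut-microbiome surveys report.
The other examples print the alpha-diversity table with Tukey letters
(`02`), and ordination plus ANOSIM R = 0.986 (p = 0.001) and PERMANOVA
R² = 0.91 (p = 0.001) for the same dataset (`03`).

A command-line interface wraps the same pipeline:

```sh
ecoassembly simulate --out-dir inputs --seed 3 --regime filtering_divergent
ecoassembly run --table inputs/otu_table.tsv --tree inputs/tree.nwk \
    --metadata inputs/metadata.tsv --out-dir results --seed 7
```

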
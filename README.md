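# ratepart

Automatic selection of phylogenetic **partitioning schemes** by
iterative k-means clustering of per-site evolutionary rates.

Partitioned phylogenetic analyses assign alignment sites to *subsets*,
each with its own substitution model.  Choosing the subsets is hard: the
number of possible schemes for n sites is the Bell number B(n) — for a
~658 bp barcode alignment already more than 10^931 — and traditional
choices (genes, codon positions) may miss real rate structure.
`ratepart` grows a scheme from the data itself:

1. estimate a fixed starting tree (JC distances → BioNJ → GTR+I+G
   branch-length re-optimization);
2. start with all sites in one subset and pick its best-fit model from
   the 56 GTR submodels (14 base models × {plain, +I, +G, +I+G}) by
   AICc or BIC;
3. for each subset, compute per-site rates — TIGER (tree-independent
   partition-agreement rates, r_i = Σ_{j≠i} pa(i,j)/(n−1) ∈ [0,1]) by
   default — split the rates with k-means (k = 2, k-means++, 100
   restarts), fit a best model to each prospective child, and accept
   the split iff the scheme-level score improves;
4. apply all accepted splits simultaneously and repeat until no split
   is accepted, then merge unanalyzable ("problematic") subsets into
   their nearest rate-centroid neighbours.

Branch lengths are *linked*: all subsets share the starting tree's
relative branch lengths, scaled per subset by one free rate multiplier
m.  Scheme scores use AICc = −2lnL + 2k + 2k(k+1)/(n−k−1) or
BIC = −2lnL + k·ln n with k = Σ model parameters + (2N−3) branch
lengths + (s−1) multipliers.

The package also ships the accompanying diagnostics: a permutation test
for starting-tree bias (sum of Robinson–Foulds distances between
matched starting/ML trees against a 999-shuffle null), random SPR
neighbours for building starting-tree sets, and a two-block Yule/JC
simulator with subset-purity scoring for validation.

Written for molecular systematists preparing partitioned ML analyses
(RAxML/IQ-TREE-style `DNA, subset1 = ...` partition files and Nexus
`sets` blocks are emitted directly), and usable as a library for
methods work on partitioning.

## Worked example

Simulate a two-block alignment (12 taxa; 300 sites on a shallow tree of
depth 0.1 concatenated with 300 sites on the same topology ten-fold
deeper) and partition it:

```bash
python - <<'PY'
import numpy as np
from ratepart.simulate import two_block_dataset
from ratepart.msa_io import write_alignment
ds = two_block_dataset(rng=np.random.default_rng(42), n_tips=12, block_length=300)
write_alignment(ds.alignment, "example.fasta")
PY
ratepart run -a example.fasta --metric bic --rates tiger --seed 42 \
    --models "JC,JC+G,HKY,GTR+G" -o example_out
```

which prints

```
4 subsets; BIC = 8635.38 (lnL = -4240.93, k = 24)
```

and writes `example_out/partitions.txt`, `scheme.nex`,
`starting_tree.nwk` and `report.json`.  The report shows what happened:
the slow block survives as one large subset and the deep block is carved
into three rate classes, visible in the fitted rate multipliers —

| subset | n_sites | model | rate multiplier m |
|--------|---------|-------|-------------------|
| 4      | 340     | JC    | 0.198             |
| 1      | 113     | JC    | 1.37              |
| 3      | 89      | JC    | 2.43              |
| 2      | 58      | JC    | 4.31              |

Subset 4 is essentially the shallow block (sites 1–300 plus the deep
block's slowest sites) at one fifth of the average rate; subsets 1–3 are
increasingly fast slices of the deep block.  The per-iteration BIC
trajectory in `report.json` (9420.5 → 9188.1 → 8879.0 → 8804.5 →
8787.6 → 8635.4 after merging) shows the characteristic behaviour: the
score keeps improving past the 2 generating blocks, so the method
over-splits relative to the truth while keeping subsets rate-coherent.

Per-site rates alone:

```bash
ratepart rates -a example.fasta | head -3
site    rate
1       1.000000
2       0.338342
```

(rate 1.0 = invariant/maximally pool-like, lower = faster).

## Documentation

`docs/methods.md` describes the model, the scoring conventions, the
problematic-subset handling, the synthetic-data design and the
package's numerical choices and limitations.
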
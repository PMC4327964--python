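# Methods

`ratepart` selects a partitioning scheme for a nucleotide alignment by
iteratively splitting subsets of sites with k-means on per-site
evolutionary rates, accepting a split only when an information-theoretic
score (AICc or BIC) of the whole scheme improves.

## The algorithm

1. **Starting tree.** Jukes–Cantor pairwise distances (computed over
   sites where both sequences carry unambiguous bases; saturated pairs
   capped at a finite distance) feed a BioNJ agglomeration; the branch
   lengths of the resulting topology are then re-optimized under
   GTR+I+G.  The topology is fixed for the remainder of the run: only a
   non-random tree is needed for model selection, and re-estimating the
   topology each round would dominate the cost on large alignments.
2. **Single-subset start.** All sites form one subset and the best of
   the candidate substitution models is chosen for it.
3. **Scheme score.** The scheme's score is computed from the summed
   subset log-likelihoods, with a parameter count described below.
4. **Split trials.** For every current subset: per-site rates are
   computed for that subset's site pool (TIGER by default), the rates
   are clustered into k = 2 groups (k-means++ seeding, 100 restarts,
   best within-cluster sum of squares kept), a best-fit model is chosen
   for each prospective child, and the scheme score with the focal
   subset replaced by the two children is compared against the current
   score.  The subset is labelled for division only if the score
   strictly improves.
5. **Simultaneous division.** All labelled subsets are divided at once
   and the loop returns to step 4; the run terminates when no split is
   accepted.  Termination is guaranteed: each accepted split strictly
   improves a bounded score and raises the subset count, which cannot
   exceed the number of sites.

Each candidate split is evaluated against the *current* scheme with only
that split applied; interactions between splits accepted in the same
round are re-examined implicitly on the next round.  A subset whose
split was evaluated and rejected is not re-evaluated later.  Under BIC
the score change of a split depends only on the subset itself (ΔBIC =
−2ΔlnL + Δk·ln n), so this cache is exact; under AICc the penalty term
is mildly nonlinear in the scheme's total parameter count and the cached
rejection is reused as a (very tight) approximation.

## TIGER site rates

Each column induces a set partition P(i) of the sequence indices — one
block per unambiguous nucleotide at the site.  The partition agreement
score pa(i, j) is the fraction of blocks of P(j) nested inside blocks of
P(i), and the rate of site i is the mean of pa(i, j) over all other
sites j in the pool.  Rates live in [0, 1]; invariant sites score
exactly 1, and rates are recomputed inside every subset because they
depend on the pool.  Nucleotide identity is irrelevant — only the
grouping matters ("AACGGA" and "TTGAAT" are the same partition).

Rows carrying gaps or ambiguity codes at a site belong to no block.  A
column with no unambiguous base at all contributes pa = 1 to every site
and itself receives rate 1.0 — maximally uninformative columns should
cluster with the slow sites — and is flagged for the problematic-subset
machinery.  The computation runs over distinct weighted site patterns;
the self-pair of each site is removed by subtracting one from its own
pattern's weight, which reproduces the literal sum over j ≠ i exactly
(a property test checks equality with the brute-force double loop to
1e-12).

Likelihood-based rates (posterior-mean discrete-gamma category rates
under a GTR+G fit to the subset) are available behind a flag.  They are
*not* the default: because they are conditioned on the starting tree
they can overfit the partitioning scheme to that tree and bias
downstream tree inference, which is exactly what the bias test below is
designed to detect.  The CLI prints a warning when they are requested.

## Likelihood engine and the candidate models

The engine implements Felsenstein pruning over pattern-compressed
columns with per-node rescaling (no underflow at hundreds of taxa), with
IUPAC ambiguity codes treated as partial tip likelihoods.  The candidate
set is the classical 56-model census: seven exchangeability tying
patterns (JC/F81, K80/HKY, TrNef/TrN, K81/K81uf, TIMef/TIM, TVMef/TVM,
SYM/GTR), each with equal or ML-estimated base frequencies, crossed with
{plain, +I, +G, +I+G}.  Discrete gamma uses 4 categories of equal prior
weight with category-mean rates; category rates average exactly 1.

Branch lengths are **linked**: one shared set of relative branch lengths
for the whole alignment, and each subset's model carries a single rate
multiplier m that stretches or shrinks all branches in tandem.  Fits
optimize the multiplier plus the model's own free parameters
(exchangeabilities on a log scale with the GT class as reference,
frequencies through logits started at empirical counts, alpha on a log
scale, p_inv directly) with bounded quasi-Newton iterations.

Defaults and bounds: m ∈ [1e-6, 1e3] (a fit returning m at a bound is
flagged degenerate), alpha ∈ [0.02, 100], p_inv ∈ [0, 0.99], lnL
convergence tolerance about 1e-3.  Fits of newly created subsets are
warm-started from the parent subset's fitted parameters; spot checks
from perturbed starting points recover identical optima to ~1e-3 lnL.

Branch-length optimization sweeps each branch with a bounded
one-dimensional search against freshly computed inner/outer partial
likelihoods (so each branch update is exact given the others), and
alternates sweeps with model-parameter refits until the improvement
drops below tolerance.  The partitioner's default is 3 sweeps; the
returned tree never has a worse likelihood than the input tree.

## Parameter counting and scores

* Subset level (used to rank candidate models within one subset, with
  n = subset length): the model's own free parameters only —
  exchangeability classes − 1, +3 for estimated frequencies, +1 each
  for alpha and p_inv.  The rate multiplier is shared in form by every
  candidate and is therefore excluded from the ranking.
* Scheme level (used for split decisions, with n = alignment length so
  all schemes share one sample size): the sum of subset-level counts,
  plus 2N−3 shared branch lengths counted once, plus s−1 free rate
  multipliers, where s counts the non-problematic subsets (one
  multiplier is the reference; problematic subsets are not
  independently modelled).

AICc = −2lnL + 2k + 2k(k+1)/(n−k−1); BIC = −2lnL + k ln n.  AICc is
undefined when n ≤ k+1; such candidates are skipped during per-subset
selection, and a split whose scheme-level AICc is undefined is
rejected.  Ties break toward the earlier (simpler) candidate in the
fixed enumeration order.

## Problematic subsets

A subset is *problematic* when it has fewer than `min_subset_size`
sites (default 4), collapses to a single distinct site pattern, or
produces a degenerate fit.  Such subsets are not independently
modelled: their per-site log-likelihoods are conservatively carried
over from the parent subset they were split from, and they contribute
no free parameters.  A split whose children would *both* be problematic
is rejected outright — carried likelihoods with fewer parameters would
otherwise "improve" the score without any new model.  After the main
loop, each problematic subset is merged into the non-problematic subset
with the nearest rate centroid (Euclidean distance on the mean site
rate at creation), the merged subset is refitted, and the process
repeats until none remain.

## Starting-tree bias test

Given matched lists of starting trees and ML trees, the observed
statistic is the sum of Robinson–Foulds distances over the pairs; the
null re-computes the statistic after shuffling the ML list, and the
one-tailed p-value is (1 + #{null ≤ observed}) / (B + 1) with B = 999
shuffles by default, so p ∈ [1/1000, 1].  The add-one rank convention is
a deliberate choice; the effect size is reported as a standard score
(observed − null mean) / null SD, a documented definition of this
package.  All n² pairwise RF distances are computed once so the
permutation loop is a cheap re-indexing.  Random SPR neighbours for
building starting-tree sets prune a uniformly chosen edge (branch
lengths of the suppressed vertex are summed through), regraft at the
midpoint of a uniformly chosen remaining edge, and re-draw any move that
reproduces the input topology.  The "ML tree per scheme" step of a full
bias pipeline is served by a deliberately simple NNI hill-climb over a
fixed branch-length skeleton — a lightweight topology refiner, not a
full ML search of RAxML's calibre.

## Synthetic data and what it does (not) show

The generator reproduces the two-block validation design: one Yule
(pure-birth) topology — 100 tips, birth 0.1, death 0 by default —
scaled to root-to-tip depth 0.1 for a 1,000 bp Jukes–Cantor block and
to depth 1.0 (ten-fold deeper) for a second 1,000 bp block,
concatenated with per-site generating labels.  "Tree depth" means the
root-to-tip path length of the ultrametric tree, and scaling is applied
to the completed tree.  Recovery is graded by *subset purity*: the
fraction of a subset's sites drawn from its majority generating block,
summarised as the count of subsets at ≥95% purity.

Scale used in the test suite: the bundled end-to-end check runs 5
replicates at 40 taxa with a restricted candidate set {JC, JC+G, HKY,
GTR, GTR+G}; this keeps a pure-Python engine within an ordinary test
run while preserving the design's structure.  Two behaviours carry over
from the full-scale design: the algorithm reliably over-splits (far
more subsets than the 2 generating blocks, driven by continual BIC
gains), and most final subsets are single-block.  Quantitatively, purity
at 40 taxa sits below what 100-tip trees yield, because TIGER rates are
noisier on fewer taxa and the shallow block's rate distribution is broad
(its invariant-site spike is peeled off first, leaving mixtures that
later splits only partially resolve).  What these tests do *not* show:
behaviour on real data with indels, substitution-model misspecification,
among-site frequency heterogeneity, or alignment error — the generator
has none of those.

## Numerical choices and limitations

* Site indices are 0-based internally; all exported subset definitions
  (RAxML partition files, Nexus charsets) are 1-based.
* k-means is scikit-learn's Lloyd implementation (k-means++, 100
  restarts); its convergence tolerance is interpreted relative to the
  data variance rather than as an absolute centroid movement, and empty
  clusters are reseeded at far points.  Clustering uses the site-rate
  scalar as the single feature.
* Degenerate k-means outcomes (fewer distinct rate values than 2) are
  ordinary "no split" decisions, not errors.
* Saturated JC distances (mismatch fraction ≥ 3/4) are capped at 10
  substitutions/site; BioNJ clamps negative branch-length estimates to
  zero.
* The whole pipeline is deterministic given a seed: k-means restarts
  consume an injectable generator in a fixed subset order, and
  replicate seeds in the simulation CLI derive as master + replicate
  index.
* Unlinked branch lengths, amino-acid models, NEXUS alignment input and
  interleaved PHYLIP are out of scope.
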
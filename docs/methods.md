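# Methods

This note documents the models, algorithms, numerical choices and known
limitations of `cubevb`.

## Tree representation

A rooted binary ultrametric tree on *n* taxa (leaves at height 0, every
internal node strictly above its children) is stored as flat arrays of
parent/child links and node heights (`treespace.TimeTree`).

**Matrix encode/decode.** The tree is encoded as a symmetric matrix with
entries *m<sub>ij</sub>* = MRCA height of taxa *i*, *j* on a chosen set of
index pairs (the *entry pattern*); all other entries are "unspecified" and
behave as +∞.  Decoding runs single-link clustering: repeatedly merge the
two subtrees separated by the smallest specified entry whose endpoints lie
in different subtrees, placing the new node at that entry's value.  The
implementation is Kruskal-style — scan entries in increasing order with a
union–find — which is exactly single linkage.  A matrix decodes to a tree
with finite branch lengths iff the graph with an edge per specified entry
is connected; disconnected input raises an error naming the components.

*Tie-breaking*: equal entries are consumed in lexicographic (i, j) order,
making the decode deterministic.  Ties have measure zero under the
continuous distributions used everywhere else, so this choice never
affects sampled results.

**Cubes.** With only the one-off-diagonal entries specified under a taxon
ordering π, the matrix is equivalent to π plus *n − 1* gap heights, and
decode/encode is a bijection (for distinct heights) onto the set of
topologies whose subtree blocks are contiguous in π.  Enumeration (the
package's brute-force oracle over all rankings of entry values) shows a
cube on *n* taxa reaches Catalan(*n − 1*) topologies — 2 of 3 for n = 3,
5 of 15 for n = 4, 14 of 105 for n = 5.  Note the index: this is the
(n−1)-th Catalan number; the oracle is authoritative and the closed form
is not hard-coded anywhere.

Internally the decoded topology of a gap-height vector is the Cartesian
tree of the gaps (the largest gap splits the ordering, recursively).  The
MCMC engine exploits this: the internal node "between positions g and
g+1" keeps a stable identity across proposals, so partial likelihood
vectors can be cached per gap and only the nodes whose subtree changed are
recomputed.  The Cartesian fast path assumes distinct heights; it is
cross-checked in tests against the single-link decode on random inputs.

## The variational family

A tree distribution is a multivariate normal N(μ, Σ) over the *logs* of
the specified entries (`matrix_gaussian.MatrixGaussian`).  Fitting to a
tree sample is moment matching: log entries per tree, (weighted) mean and
unbiased sample covariance across trees.  Sampling draws x = μ + Az with
AAᵀ = Σ, exponentiates, and decodes.  The matrix square root uses the
Cholesky factor when Σ is positive definite and an eigendecomposition
with negative eigenvalues clipped at zero otherwise, so a degenerate Σ
(e.g. fitted to identical trees) reproduces the mean tree exactly.

Entry values default to MRCA heights.  A `value="path"` flag uses pairwise
path distances instead; on ultrametric trees these are exactly twice the
MRCA heights, shifting μ uniformly by log 2 and leaving the topology
distribution unchanged.

Setting z = 0 yields the mode/summary tree.  It may have a topology absent
from the sample being summarised; `treeset_stats.summary_metrics` scores
any summary tree by the sum and log-product of its clades' posterior
supports (zero-support clades are excluded from the log product and
counted separately), with `mcc_tree` as the maximum-clade-credibility
baseline (member tree maximising the log product; node heights annotated
with arithmetic means of the raw MRCA heights of the trees containing each
clade — the TreeAnnotator convention; whether to average raw or log
heights is not standardised, raw is used here and noted).

## Phylogenetic model

- **Substitution models**: HKY and GTR as reversible rate matrices built
  from exchangeabilities and stationary frequencies, normalised to one
  expected substitution per time unit (the strict-clock rate absorbs any
  constant).  Transition matrices come from the symmetrised
  eigendecomposition, vectorised over branches.
- **Site model**: discrete gamma with 4 equal-probability categories whose
  rates are within-bin means (mean exactly 1), or no heterogeneity.
- **Likelihood**: Felsenstein pruning over compressed site patterns with
  per-node rescaling; gaps and IUPAC ambiguity codes become the union of
  their allowed states.  Verified against closed forms (JC two-taxon
  transition probabilities to 1e−12, zero-branch limits) and per-site
  summation.
- **Tree priors**: Yule conditioned on n (interval with k lineages ~
  Exponential(kλ), density ∝ λ<sup>n−1</sup> e<sup>−λ·treeLength</sup>)
  and the constant-size Kingman coalescent.  Both are uniform over ranked
  labelled histories, so on a cube the prior density is a function of the
  gap heights alone.  Only density ratios matter for annealing and MCMC,
  so the normalisation convention (conditioned-on-n labelled form) is
  harmless.
- **Transforms**: log for scale parameters, identity for location
  parameters, centred logit stick-breaking for simplex parameters
  (component c maps to logit(x_c / remaining) + log(K − c), so the uniform
  simplex point is the origin).

## Cube-VB

`inference.fit_variational` runs the pipeline:

0. **UPGMA** initialisation on Jukes–Cantor-corrected Hamming distances
   (the distance used is a package choice; the initialisation only needs
   to be in the right basin).  Tied or zero merge heights are nudged by
   1e−9 so the start state is a strictly ordered time tree.
1. **MAP search** by simulated annealing: geometric cooling 0.1 → 0.01
   within each of 25 segments (resetting beats one long schedule for
   escaping local optima; fewer repeats measurably hurt calibration),
   default 200 steps per segment.  Acceptance is Metropolis-style,
   exp(Δ log posterior / T).  The proposal mixture includes an
   ordering-refresh move, so the search covers all of tree space.
2. **Ordering**: a uniformly random taxon ordering compatible with the MAP
   tree (children swapped with probability ½ during traversal).  Ordering
   choice is a known open problem; random-compatible suffices for the
   parameters monitored here.
3. **Cube-restricted MCMC**, chain length = multiplier × dimensions
   (default multiplier 1 000; dimensions = (n−1) gaps + free parameters).
   Tree proposals:
   - *gap slide*: multiply one gap height by e^{w(u−½)} (log-scale random
     walk); crossing other gaps changes topology but never leaves the
     cube;
   - *cube narrow exchange*: nearest-neighbour interchange around a random
     internal edge with a fresh height for the moved node.  Around an edge
     between gap nodes p (parent) and c, exactly one of the two
     interchanges keeps all blocks contiguous; in gap coordinates it
     exchanges the roles of the two gaps, the upper node taking the old
     parent height and the moved node redrawing its height uniformly in
     its valid range (Hastings ratio (h_p − lo_new)/(h_p − lo_old)).
     Proposals selecting the cube-leaving grandchild are rejected before
     evaluation;
   - *tree scale*: all gaps × e^{w(u−½)} (Jacobian s^{n−1}).
   Parameter proposals are log-scale random walks (scale parameters) or
   Gaussian walks in stick-breaking space (frequencies), with the exact
   transform Jacobians in the acceptance ratio.  Tree moves receive 60% of
   proposals (slide : narrow : scale = 2.5 : 2 : 1 — the local moves are
   cheap under partial caching, the scaler is not), parameters the
   remaining 40% split evenly.  Windows adapt toward 0.234 acceptance
   during burn-in only.  Exact operator parameterisations are conventional
   choices validated by the calibration study, not by matching any other
   implementation's internals.
4. **Moment estimation** from the thinned post-burn-in samples (burn-in
   10%, ≤2 000 samples retained): log gap heights and transformed
   parameters are stacked and μ, Σ are their sample mean and covariance.
   No Jacobian enters here — the fit matches moments in the transformed
   space directly.

An *unrestricted* chain mode mixes in an ordering-refresh proposal: the
ordering is redrawn uniformly among the 2^{n−1} orderings compatible with
the current tree (symmetric, Hastings ratio 1), which makes every topology
reachable and the chain target the unrestricted posterior on the augmented
(tree, ordering) space.  It is used for MAP search and as the reference
posterior for entropy comparisons; prior-only chains in the tests verify
both modes against enumerated topology distributions (χ² on ranked-history
frequencies) and rejection-sampling oracles (KS on heights).

## Synthetic data and the calibration study

`synthetic_data` draws study conditions matching the two designs used
throughout:

- **Yule/HKY**: n = 50, birth rate ~ Normal(6, 0.1) (mean root height
  (H₅₀ − 1)/λ ≈ 0.583), κ ~ LogNormal(meanlog 1, sdlog 1.25), strict
  clock 1, L ∈ {100, 250, 500}.
- **Coalescent/GTR+Γ**: population size ~ LogNormal(0.1, 0.1) *on the log
  scale* — this reproduces the design's mean root height
  2·E[N]·(1 − 1/n) ≈ 2.18, whereas reading 0.1 as a real-space mean would
  not; a `real_space_means` flag implements the alternative reading.  GTR
  with CT fixed at 1, AG ~ lognormal with real-space mean 1 (σ = 1), the
  four other rates real-space mean 0.5 (σ = 1), frequencies ~
  Dirichlet(4,4,4,4), gamma shape ~ Exponential(1).

Sequence simulation draws the root state from the stationary frequencies
and evolves states down branches by exact transition probabilities, with
per-site gamma rate multipliers when enabled.

`run_wcss` is the well-calibrated simulation study: per replicate, truth
is drawn from the priors, data simulated, `fit_variational` run, and
membership of the truth in each monitored quantity's 95% HPD recorded
(HPDs are Chen–Shao shortest intervals on Monte-Carlo draws from the
fitted normal; tree height = largest gap, tree length = gap sum + largest
gap, both computed in closed form from the draws).  With R replicates,
correct calibration gives coverage ~ Binomial(R, 0.95): 91–99 for R = 100,
22–25 for R = 25.  The shipped acceptance test uses R = 25 replicates of
the L = 100 design — the replicate count is the scaled dial; the design
itself (n = 50, L = 100, priors) is not scaled.  Individual replicate
failures are logged and reported, never fatal.

**What the generator does not emulate**: real alignments have indels,
rate variation along lineages (relaxed clocks), model misspecification and
non-stationary composition.  Passing calibration here shows the inference
machinery is self-consistent under its own model, not that the model fits
any particular real dataset.

## Tree-set statistics

- **CCD entropy** (natural log; base is a package choice): the entropy of
  the tree distribution induced by conditional clade split frequencies,
  H(clade) = H(split|clade) + Σ p(split)(H(left) + H(right)), memoised
  over clades.  Zero for a single topology.  Entropy of a cube-restricted
  sample is *typically* below the unrestricted sample's (fewer reachable
  topologies) but can exceed it under a poor ordering, so the package
  reports both rather than asserting an inequality.  Because the choice of
  posterior matters, entropy diagnostics are computed separately for
  unrestricted and cube-restricted chains.
- **Clade comparison**: union of clades of two samples with per-clade
  supports, mean heights (arithmetic, raw scale) and HPDs; summary
  statistics are the maximum support difference, the mean support
  difference over clades with >1% support in either set, and the mean
  relative height difference over shared clades.
- **HPD**: shortest window over sorted samples containing ⌈level·n⌉
  points (Chen–Shao / Tracer convention).

## Numerical choices and degenerate inputs

- Likelihood rescaling per internal node guards underflow to hundreds of
  taxa; the log-scale accumulators are cached alongside partials.
- Near-singular fitted covariances are handled by the PSD square root
  (eigenvalue clipping) rather than diagonal jitter, so degenerate fits
  stay exact; materially negative eigenvalues trigger a warning.
- UPGMA on identical sequences produces a zero-height star; ties are
  resolved into a strictly ordered tree by 1e−9 nudges.
- Saturated distance pairs (p ≥ 0.75) are clamped just below saturation.
- `cube_encode` on trees with exactly equal internal heights is permitted
  but the bijection is only guaranteed for distinct heights (tested with
  continuous heights, where ties have probability zero).

## Problem sizes used in the shipped checks

The calibration acceptance test runs 25 replicates of the 50-taxon,
100-site design with chain multiplier 1 000; the entropy check averages 6
replicates; prior-predictive checks use 10 000 simulated trees.  These
sizes give Monte-Carlo error comfortably inside the stated tolerance bands
while keeping the default test run short.

## Known limitations

- A single cube cannot represent all topologies; posteriors spread over
  topologies incompatible with the chosen ordering are truncated
  (quantified by `cube_topology_coverage` and visible in clade
  comparisons).  High-entropy posteriors may need a better ordering than
  random-compatible, or a richer entry pattern — both open problems.
- The Gaussian-over-log-entries family cannot capture non-linear
  correlations between entries induced by topology mixtures; full-matrix
  (non-cube) fits can distort clade supports even when heights match.
- No relaxed clocks, tip dates, skyline priors, amino-acid/codon models,
  or ELBO-based optimisation; multifurcating and non-ultrametric trees
  are out of scope.
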
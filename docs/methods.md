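# Methods

## Model and procedure

`chromcause` treats gene promoters as i.i.d. observational units. Each
histone mark is a tag count per promoter; nucleosome positioning (NucPos)
is a continuous covariate on log scale. The causal story is layered:
NucPos modulates the binding of chromatin-modifying activities (latent
regulators), each regulator writes several marks, and a small number of
direct mark→mark effects represent genuine crosstalk. Inference proceeds
in five stages:

1. **Discretization.** Marks are reduced to K = 3 ordinal categories by
   per-mark equal-frequency (tercile) binning; NucPos becomes
   ln(count + 1). Rank-based binning is invariant to monotone transforms
   and robust to the heavy right tail of tag counts.
2. **Dependence screening.** For every mark pair, MI and the mutual
   information gain MIG = MI − CMI(·,·|NucPos) are estimated.
3. **Hidden-confounder discovery.** Pairs with significant MI but MIG at
   noise level receive a pairwise hidden confounder (PHC); maximal cliques
   of the PHC graph become general hidden confounders (GHCs).
4. **Structure learning and causal labelling.** A BDe-scored Bayesian
   network is learned over the marks, GHC nodes are inserted as latent
   parents (latent→observed orientation; intra-clique mark edges are
   removed), and Chickering's DAG→CPDAG labelling marks each remaining
   edge compelled or reversible. Compelled mark–mark edges are the causal
   output.
5. **Significance.** Genes are bootstrap-resampled and stages 1–4 rerun
   (thresholds held fixed); feature frequencies give edge, ancestor and
   Markov-relation confidences, and dScore(X) = Σ_Y C0(X,Y)^k ranks
   dominant marks.

## Information estimators

Two backends estimate MI/CMI:

* **kernel** — Gaussian Parzen windows. Densities are averages of
  product Gaussian kernels; per-dimension bandwidths follow Silverman's
  rule for the dimensionality of the *joint* estimate and are shared by
  the joint and marginal densities of one quantity, so their biases
  largely cancel in the log-ratio. MI/CMI are leave-one-out
  resubstitution averages of log-density ratios: excluding the
  self-kernel term removes the inflation that plain resubstitution
  suffers in three dimensions. At n = 2000 the estimates sit within
  ±0.03 nats of the bivariate/trivariate Gaussian closed forms
  (−½ ln(1−ρ²)), verified by the acceptance suite. A full-covariance
  kernel (Mahalanobis whitening) is available but diagonal is the
  default. Estimates above three dimensions are unsupported by design —
  the pipeline needs at most p(x, y, z).
* **plugin** — exact empirical information of categorical codes from
  contingency tables; fully deterministic, hence the backend for
  permutation calibration and bootstrap pipelines. A continuous
  conditioner is first discretized into 5 equal-frequency bins — finer
  than the 3-category marks because 3 conditioning bins leave ~21% of
  the conditioner's variance unexplained within bins, inflating residual
  NucPos-mediated dependence.

Negative kernel estimates are reported as-is (not clipped) so the
calibration sees the true null distribution. A constant conditioner is
dropped, making CMI collapse exactly to MI.

## Threshold calibration

Each of `n_perm` permutations shuffles every mark column independently
while NucPos stays aligned to genes — exactly the mark–mark dependence is
nulled. From the pooled permuted pair statistics:

* **β** is one ulp above the largest permuted MI, so no permuted pair is
  ever MI-significant and the selection region {MIG ≤ α, MI ≥ β}
  provably contains no permuted pair;
* **α** is the upper 0.1% quantile of the permuted MIG distribution. MIG
  under the null is centred slightly *below* zero for the plugin backend
  (conditioning multiplies the contingency cells by the number of
  conditioner bins, so the CMI's small-sample bias exceeds the MI's);
  the upper quantile therefore bounds the MIG magnitude that pure noise
  produces. A real pair is called confounded only when its
  NucPos-mediated information is statistically indistinguishable from
  zero while its total dependence is beyond anything permutation can
  produce.

An alternative rule — α as the minimum permuted MIG among pairs with
MI ≥ β — was considered and rejected: with β at the permuted-MI maximum
that restriction contains a single MI-selected pair, whose MIG is a draw
from the *centre* of the null MIG distribution (MIG is uncorrelated with
MI selection), so genuine confounded pairs can never reliably fall below
it; in simulation it recovers fewer than half the planted PHCs and is
strongly seed-bimodal.

PHC selection uses non-strict inequalities (MIG ≤ α, MI ≥ β) and is
monotone in both thresholds. Cliques of size 2 are retained as GHCs; the
clique enumeration is networkx's Bron–Kerbosch with pivoting, verified
against exhaustive subset enumeration.

## Structure learning

The BDe score uses a uniform structure prior and Dirichlet
hyperparameters ess/(q·r) per cell (q parent configurations, r child
arity), ess = 1 by default; this makes Markov-equivalent DAGs score
identically (verified to 1e−9 against brute-force equivalence classes).
Search is hill climbing over single-edge add/delete/reverse moves with
simulated annealing: a score-decreasing move is accepted with probability
exp(Δ/T), T starting at 1 and cooled geometrically (0.999/iteration),
5 restarts from the empty graph, best-ever structure returned,
max_parents = 5 for genome-scale tractability (irrelevant on small
instances). Setting the initial temperature to 0 gives pure greedy
search. On four-variable problems the search attains the exhaustive
optimum over all 543 DAGs in ≥ 90% of seeds at 2000 iterations ×
3 restarts; desk-scale defaults are 10 000 iterations × 5 restarts, and
the iteration cap is a config value so genome-scale budgets (millions of
iterations) can be requested.

## Causal labelling

GHC→mark edges are oriented latent→observed — a regulator causes its
marks, never the reverse — so GHC nodes are sources and augmentation can
never create a cycle. Compelled edges are computed on the *augmented*
graph (computing them on the mark-only subgraph would discard exactly the
confounder information the method exists for) and then filtered to
mark–mark pairs; GHC-incident compelled edges are exposed through a
diagnostics channel. Pruned intra-clique edges are never re-added.
d-separation queries delegate to networkx's checker and are verified
exhaustively against an independent moralization-reachability oracle.

## The synthetic generator

`make_ground_truth` / `simulate_profiles` emulate the study conditions:
NucPos driver g ~ N(0,1); latent regulators H = a·g + ε with unit
intrinsic noise; mark propensities sum latent effects (1.0), direct
parent effects (1.0) and N(0, 0.5) noise; counts are
Poisson(softplus(propensity)·50), giving realistic mean promoter depths
and count ties; NucPos is exported as exp(g) so the pipeline's log
transform recovers the Gaussian scale. Child sets of size 2–4 may
overlap (default overlap 0.25) but never nest — a regulator whose
children are a subset of another's is invisible at the clique level.

The default NucPos→regulator effect is **a = 0.05**. This is the
regime the method itself presupposes: the calibrated selection requires
confounded pairs to carry NucPos-mediated information below permutation
noise (α is of order 10⁻³ nats at n = 2000 and shrinks with sample
size), which is only possible
when NucPos explains a small fraction of regulator variance. A large
NucPos→regulator effect would push every shared-regulator pair's MIG
above any α that excludes the permutation null — conditioning on NucPos
would then genuinely remove part of their dependence.

The dedicated local-structure simulators are parameterised differently
because they demonstrate the *contrast* between the two cases at
comfortable effect sizes: `simulate_separate_regulators` uses
NucPos→regulator effect 1.0 and noise 0.5 (all dependence mediated, so
MIG/MI ≈ 1), and `simulate_shared_regulator` uses effect 0.5 against
unit intrinsic regulator noise (NucPos explains 20% of regulator
variance; MIG/MI ≈ 0.2).

What the generator does **not** emulate: the marginal tag-count
distributions of real ChIP-seq data, inter-gene correlation (linked
genes, domains), mappability artefacts, or antibody cross-reactivity.
Passing tests therefore demonstrate correctness of the algorithms and
the method's behaviour under its own assumptions, not performance on
real chromatin data.

## Study sizes and numerical choices

Simulation studies use n = 2000 genes, 12 marks, 3 latent regulators,
50 permutations for calibration (200 in the null-control study, where
the false-positive rate scales as 1/n_perm) and 10–20 seeds; these sizes
give stable averages while keeping the full suite fast. Degenerate
inputs are handled explicitly: constant marks collapse to one category
with a warning; a constant conditioner is vacuous; zero-variance kernel
dimensions receive a 1e−12 bandwidth floor; empty datasets score 0 under
BDe; an empty compelled set has precision 1.0 by convention. Bootstrap
replicates that fail are retried once and then counted as feature-free
with a warning. Thresholds are calibrated once on the original data,
never per bootstrap replicate.

## Known limitations

* A direct mark→mark causal pair is also selected as a PHC (its
  dependence is equally non-NucPos-mediated), so genuine crosstalk edges
  inside a clique are pruned; the method trades edge recall for
  protection against confounder-induced false orientations.
* The ancestor relation counts compelled edges only; reversible edges
  confer no ancestry (conservative).
* The literature-association formulas (Dice co-occurrence; top-N
  product-sum of shared-concept significances) are the forms most
  consistent with their descriptions and are pluggable; retrieval/text
  mining is out of scope.
* Kernel estimates on 3-category codes treat the codes as numeric; this
  mirrors feeding discretized values to a kernel estimator and is the
  reason the plugin backend exists as a deterministic alternative.
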
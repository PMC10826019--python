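# Methods

This note documents the statistical models, defaults and design choices
behind each stage of the pipeline, what the synthetic generators emulate,
and the known limitations.

## Study design and data model

The pipeline targets two-group comparisons of unstable ("case") versus
stable ("control") atherosclerotic plaque expression profiles at very
small sample sizes (4 vs 4 in the discovery design, 5 vs 6 in a typical
validation design).  Expression values are assumed already log2-scale and
normalized, with no missing values — "NA" or empty cells are hard format
errors, because silent imputation would corrupt every rank-based statistic
downstream (ssGSEA, Wilcoxon, Spearman).  Fold change is the plain
difference of group means (case − control, i.e. unstable − stable); which
orientation a study intends is often unstated, so this package fixes and
documents one.

## Differential expression

The moderated t shrinks per-gene pooled variances s²_g (d_g = n₁+n₂−2 df)
toward a prior (d₀, s₀²):

    s²_post,g = (d₀·s₀² + d_g·s²_g)/(d₀ + d_g)
    t_g = Δmean_g / (s_post,g · √(1/n₁ + 1/n₂)),   df = d₀ + d_g.

The prior is estimated by moment matching on z_g = log s²_g: with
e_g = z_g − ψ(d_g/2) + log(d_g/2), the excess of Var(e) over ψ′(d_g/2)
equals ψ′(d₀/2), solved by Newton inversion of the trigamma function;
substituting back gives s₀².  When the observed spread of log variances is
at or below what sampling noise alone predicts, d₀ = ∞ (complete
shrinkage, all genes share s₀²) — this is the correct limit when all genes
truly share one variance.  A cross-check against the R limma fit on the
same matrix (tolerance 3% on t) is part of the test suite.  Below 10 genes
the moment estimates are meaningless, so the fit falls back to the
ordinary pooled t (d₀ = 0) and records the fallback in the returned
parameters.  Note that under complete shrinkage the moderated t is *not*
close to the pooled t gene by gene (the pooled t carries the chi-square
noise of 6-df variance estimates); it is close to the known-variance t,
which is what the tests assert.

Screening uses strict inequalities — |log2FC| > 1 and FDR < 0.05 — and the
BH adjustment delegates to statsmodels, verified against a brute-force
step-up definition in the tests.  Two-sided p-values throughout.

## Over-representation analysis

For each annotation set, p = P[X ≥ k] with X ~ Hypergeom(N, K, n).  The
universe defaults to the genes measured on the expression matrix, not the
genome: enrichment of a DEG list is relative to what could have been
called.  Only over-representation is tested (under-representation is not
reported).  The GO/KEGG databases themselves are out of scope; any GMT
collection is accepted.

## PPI network and MCODE

Edges at confidence ≥ 400 are kept.  The printed threshold "score > 0.4"
and the conventional integer "400" disagree at the boundary; the inclusive
400 is used (STRING's "medium confidence" convention) and is configurable.
Self-loops are dropped, duplicate edges collapse to their maximum
confidence, and nodes exist only through retained edges, so isolated nodes
never appear.

MCODE follows the core-clustering recipe: vertex weight = k_max × density
of the highest k-core of the closed neighbourhood (0 below the degree
cutoff); seeds processed in decreasing weight (ties: degree, then id);
breadth-first expansion over unvisited neighbours with weight ≥
seed_weight × (1 − node score cutoff), at most max_depth hops; each node
joins one cluster.  Defaults: degree cutoff 3, node score cutoff 0.4,
haircut on, fluff off, K-core 3, max depth 80 (80, not the more common
100, matching the settings this pipeline standardizes on).

One deliberate refinement in post-processing: before the k-core filter,
edges of a candidate cluster supported by fewer than k_core − 1 common
neighbours inside the cluster are pruned, and the cluster splits into its
connected components.  Rationale: inside a clique of size ≥ k_core + 1 —
the densest unit a k-core filter targets — every edge has at least
k_core − 1 common neighbours, while edges that merely bridge two such
complexes have fewer; plain seeded expansion happily walks across a single
bridge edge and reports two dense complexes as one cluster.  The cost is
that triangle-free complexes (e.g. complete bipartite cores) are discarded;
protein complexes are triangle-rich, so this trade-off is acceptable and is
asserted in the test fixtures (two 4-cliques joined by one edge come back
as two clusters).  After splitting, components lacking a k_core-core are
discarded and haircut iteratively removes within-cluster degree-1 nodes.
Cluster score = density × size, clusters reported in decreasing score.

Centralities use unweighted hop distances (confidence is a construction
filter, not a length): degree; betweenness with fractional credit over
tied geodesics, normalized by (n−1)(n−2)/2 within each connected component
of size n; closeness (n−1)/Σd within the component.  Per-component
normalization means tiny components can contain nodes with betweenness or
closeness 1.0; hub ranking is therefore a mean of per-metric ranks across
all three measures, which in practice keeps hub status with the planted
module structure.  Hubs = top k (default 5) by mean rank, ties broken by
degree then id.

## Diagnostics

The exact Wilcoxon rank-sum enumerates all C(n₁+n₂, n₁) assignments of the
midranks; two-sided p = min(1, 2·min(tail probabilities)).  At 4 vs 4 the
smallest achievable two-sided p is 2/70 ≈ 0.0286 — single-gene "p < 0.05"
flags at this design size are always exactly that value.  Above a combined
size of 20 a tie-corrected normal approximation is used and flagged.

AUC uses the pair-counting identity (ties credit 0.5) and is reported
as-is, without forcing AUC ≥ 0.5: the relevant hub genes are *down* in
unstable plaques, so their raw AUC is near 0 and the direction-free value
max(AUC, 1−AUC) is reported alongside.  The ROC curve is swept over
descending unique thresholds; the trapezoidal area equals the pair-count
AUC to 1e-12 (property-tested).

The multi-gene diagnostic model is a soft-margin linear SVM (C = 1),
standardized features, scored by leave-one-out.  A linear kernel is
deliberate: with 8 samples and 5 features an RBF fit is unidentifiable.
The SVM itself is an ordinary model fit and is delegated to scikit-learn
behind this module's interface; dual coefficients are exposed per training
sample and the KKT conditions are asserted in tests.

## ssGSEA and correlations

Per sample, genes are ranked by expression descending (rank N = highest)
and a signature's enrichment score is ES = Σ_i [P_in^w(i) − P_out(i)],
where P_in^w weights signature genes by rank^α (α = 0.25, the standard
choice) and P_out is the cumulative proportion of non-signature genes.
Scores are raw by default so small examples stay closed-form; global
max−min normalization is available behind a flag.  ssGSEA is invariant to
any strictly monotone transform of a sample's expression (property-tested).
The immune score of a sample is the plain sum of its immune-signature
scores — a documented stand-in for platform-calibrated immune scoring
methods, adequate for correlation analyses because it is monotone in each
signature score.

Correlations of a gene against signature scores use Spearman on midranks;
with n ≤ 9 tie-free observations the two-sided p is exact by full
enumeration of all n! permutations (p = proportion of permutations with
|rho| ≥ |rho_obs|; at most 362,880 evaluations, vectorized, sub-second).
With ties or larger n the t approximation is used and labelled.  The
anchor-related gene set uses Pearson r (the convention of the rcorr-style
screen) with strict thresholds r > 0.9 and p < 0.001, positive
correlations only by default (an `absolute` flag flips this).  Note that
at n = 8, r = 0.9 gives p ≈ 0.0023, so the p < 0.001 gate effectively
requires r ≳ 0.93.

## Drug proximity

For drug target set T and anchor-related set S on the network:

    d(S,T) = (1/|T'|) · Σ_{t∈T'} [ min_{s∈S} d(s,t) + ω_t ],
    ω_t = −ln(D_t + 1) if t ∈ S else 0,

with hop-count shortest paths and D_t the degree of t in the full network
(the natural reading of "degree of related-set nodes").  Because ω_t does
not depend on s, this equals the literal min-over-s form (verified against
a brute-force oracle).  T' drops off-network targets and targets
unreachable from every s — dropping rather than penalizing avoids infinite
means, and |T'| is reported so callers can filter drugs with poor network
coverage.  Self-targeting drugs (T ⊆ S) always score ≤ 0.

The null redraws |T'| nodes uniformly without replacement (10,000
repetitions by default; degree-matched sampling is a possible refinement
not enabled by default since the reference procedure samples uniformly).
One null is computed per distinct target-set size, seeded per size so
results are independent of drug order.  z = (d_obs − μ)/σ (sample sd,
n−1); the empirical p uses the add-one estimator (never exactly zero,
floor 1/(n_perm+1)).  Screening keeps drugs with d_obs < 1.2 (strict) and
BH FDR < 0.05, ordered by ascending z.  The FDR gate is 0.05 by default
(the stricter 0.001 sometimes quoted for this style of screen is available
as a flag).  Internally, one multi-source BFS from S makes scoring a
target set O(|T|), so large permutation counts are cheap.

## Synthetic data

One global seed feeds a named substream per generator (expression / ppi /
drugs / signatures), so regenerating one input never perturbs another.

* **Expression** — per-gene baselines N(8, 2²) on the log2 scale
  (microarray-like), i.i.d. N(0, σ²) sample noise, first n_de genes
  shifted ±effect in the case group (half up, half down).  Calibration:
  over 200 replicates the mean estimated log2FC of planted genes is within
  10% of the request (tested).
* **PPI** — planted cliques at confidence 900 (above any plausible build
  threshold, decoupling graph-threshold tests from module recovery),
  Erdős–Rényi background with confidence uniform in [400, 900], and a hub:
  the first member of the largest module, wired to one member of every
  other module.  The hub's top-degree/top-betweenness guarantee is
  relative to the planted structure; heavy background can hand individual
  wired counterparts more luck, so recovery tests run at p_background =
  0.01 with a dominant largest module (8/5/4), where the hub tops the
  aggregate rank in ≥ 95% of seeds.
* **Drugs** — proximal drugs draw targets from the disease set and its
  direct neighbours with at least one target inside the disease set (a
  planted positive that never touches the disease genes would not be
  proximal in any meaningful sense); random drugs draw uniformly from all
  network nodes.  Recovery tests run on a connected background
  (100 nodes, p = 0.02 plus cliques) because on a fragmented network the
  unreachable-target drop biases random drugs toward the disease
  component and the planted contrast disappears.
* **Signatures** — member genes are rewritten as mean + sd·(coupling·z_hub
  + √(1−coupling²)·noise), so the member–hub correlation is `coupling` in
  expectation.  In the coupling = −1 limit each signature's ssGSEA score
  is non-increasing in the hub and the pooled immune score is exactly
  anti-correlated *when the background genes are held constant across
  samples*; with a varying background the monotonicity is only
  approximate, since ranks depend on the other genes too.

What the generators do **not** emulate: count-based noise (negative
binomial), batch effects, correlated background genes, realistic PPI
degree distributions.  Passing recovery tests therefore demonstrates that
the algorithms recover the structure they are defined to find, not that
real plaque data contain such structure.

## Problem sizes and determinism

Default test and demo sizes (hundreds of genes, ~100-node networks,
500–1,000 permutations) are chosen so the full suite runs in well under a
minute on one CPU; the null-calibration check runs 2,000 drugs against a
1,000-draw null on a 200-node network with a disease set spanning 40% of
nodes — mirroring the proportion of anchor-related genes to retained
network nodes in the motivating analysis, and keeping the null
distribution nearly atom-free so the empirical p is uniform (KS < 0.05).
Production settings (10,000 permutations) remain the default in the CLI.

Everything is single-threaded and a pure function of the config seed; two
runs with identical config produce byte-identical output files (hashed in
the tests).

## Known limitations

* MCODE junction pruning discards triangle-free dense complexes.
* The exact Wilcoxon enumerates up to C(20,10) ≈ 1.8e5 assignments; larger
  designs switch to the normal approximation.
* The immune score is an unweighted sum of signature scores, not a
  platform-calibrated estimate; absolute values are not comparable across
  datasets.
* The proximity null samples nodes uniformly, not degree-matched; hub-rich
  target sets are therefore slightly favoured, exactly as in the reference
  procedure this implements.
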
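# Methods

## Model and assumptions

The framework assumes each analysed gene is *bimodal on the log2 scale*:
its expression across samples separates into a low and a high regime, so
that a single step fitted to the sorted values yields a meaningful
threshold. Genes violating this — flat genes, or genes whose high (or low)
regime covers almost every sample — carry no Boolean information and are
removed before pair analysis. The pairwise layer then treats each gene as
a noisy binary variable and looks for *forbidden quadrants*: sample
configurations (e.g. "A low and B low") that essentially never occur.
Implication calls are invariant under any monotone per-gene transformation
that preserves the low/high calls, which is what makes them portable
across platforms and cohorts.

## Discretization

For a gene with n values, every step position k = 1..n−1 on the sorted
series is evaluated; the two plateau levels are the segment means, and the
best k minimizes the residual sum of squares (ties break to the smallest
k, making output deterministic). The threshold is the midpoint of the two
segment means. The regression statistic uses m = 3 model degrees of
freedom (two plateau means plus the breakpoint); m is configurable, and a
perfect fit (zero residual) reports F = +∞ rather than failing. Only
rising steps are fitted: on sorted data every step is rising, so a
separate falling-step branch is redundant. Constant genes and vectors
shorter than 3 have no defined threshold; `discretize_matrix` lists them
in a skip report instead of dropping them silently.

The noise margin is ±0.5 around the threshold — a 2-fold change in log2
units. Values inside the closed band are *intermediate*; the boundary
values themselves are treated as intermediate, so low/high calls are
strict inequalities.

The dynamic-range filter requires at least a fraction 0.05 of *all*
samples to be called low and at least 0.05 high. Intermediates count in
the denominator; the alternative (fractions over non-intermediate calls
only) was considered and rejected because the filter's purpose is to
guarantee enough usable samples in absolute terms for the pair statistics.

## Pair statistics

Quadrant counts exclude any sample intermediate in either gene. For
quadrant ij the expected count under independence is n̂ = rowsum·colsum /
total, using the quadrant's own two adjacent marginals (for a00 these are
nAlow = a00+a01 and nBlow = a00+a10; the other three quadrants generalize
symmetrically). Sparsity requires both S = (n̂−n)/√n̂ > 3 and the error
rate p = ½(n/rowsum + n/colsum) < 0.1. A zero marginal makes S undefined;
such quadrants are reported as not-sparse (sentinel p = 1) because a gene
one-sided after pairing should already have been removed by the filter.

Classification: exactly one sparse quadrant gives the corresponding
asymmetric implication; the diagonal pairs {01,10} and {00,11} give
equivalent and opposite. Zero sparse quadrants, an adjacent sparse pair,
or three or more sparse quadrants classify as *none* — the latter two
patterns arise only from degenerate marginals and admit no single
implication reading. No minimum on `total` is imposed beyond positivity;
small totals self-penalize through n̂.

The whole pairwise pass is computed with four dense matrix products over
the low/high indicator matrices (counts are exact integers represented in
float64), then classified elementwise; this is identical to
pair-at-a-time classification (asserted in tests) and handles thousands of
genes in seconds on one core. The permutation FDR shuffles each gene's
trit row independently with a seeded generator — thresholds are unchanged
by construction — and reports the fraction of pairs still receiving a
call.

## Clustering

Equivalence edges are pruned by the Jaccard coefficient of the two
endpoints' *closed* neighbourhoods in the equivalence graph (node
included): closed neighbourhoods make J = 1 for twin genes, which an open
definition would put at 0 for an isolated pair. The default mode computes
J on every equivalence edge and drops J < 0.5; connected components of
the remainder are the clusters, with genes lacking equivalences kept as
singletons so the clusters partition the node set. An alternative mode
restricts pruning to minimum-spanning-tree edges (weight 1 − J per
component); it is retained as an option because either reading of the
pruning rule is defensible, but the all-edges rule is simpler and at
least as aggressive against inconsistent components. The intended
invariant — no two genes of one cluster in an *opposite* relation — holds
on clean synthetic data and is surfaced by `internal_inconsistencies` for
logging on noisy data.

Within a cluster, genes are ranked by their number of equivalence partners
inside the cluster (ties lexicographic). Cluster pairs (A, B) are typed by
pairing A's rank-1 gene against B's representatives at ranks {1, 2, n/2,
n/2−1, n/4, n/8} (floor, deduplicated; {1, 2, n/2} for n ≤ 10; the lone
gene for n = 1). The modal non-none relation becomes the edge if its share
of all tested pairs strictly exceeds the majority threshold (default 0.5);
*none* outcomes count in the denominator because an absent relation is
evidence against a cluster-level edge, and a tie for the modal type yields
no edge.

## Scoring and training

The modified Z-score (x − t − 0.5)/(3σ) uses the dataset-local StepMiner
threshold and the gene's sample (n−1) standard deviation in the dataset
being scored; all Boolean quantities are dataset-local, so a signature can
be evaluated on any cohort without cross-dataset calibration. The printed
normalization could also be parsed as (x − (t − 0.5))/(3σ); the adopted
reading anchors 0 at the *upper* edge of the noise band, and the two
readings differ only by a constant per-gene offset that cannot change
sample ordering or ROC-AUC. A ±0.5 noise margin on the composite scale is
reported with each evaluation but not used to abstain from classification,
since no abstention rule is defined for it.

Training: candidate clusters are those whose weight-+1 composite score has
ROC-AUC ≥ 0.6 in every training cohort (up) or ≤ 0.4 (down); an explicit
cluster-ID override mirrors curated selections. Gene filters use raw
single-gene AUC with the fixed "higher = case" orientation — down-genes
are therefore required to have AUC < 0.3 rather than being reoriented.
Survivors are ranked by Welch t (case vs control) in the designated
ranking cohort and the top 20 per direction are kept with weights ±1.
ROC-AUC is computed by scikit-learn, Welch's test by scipy
(`equal_var=False`), and Benjamini–Hochberg adjustment by statsmodels;
each is checked in the tests against an independent hand-coded oracle or
worked example.

## Synthetic data

The generator emulates exactly the features the method consumes: Gaussian
two-component mixtures over latent binary states (bimodality), children
whose states satisfy a chosen implication up to an explicit violation rate
(forbidden-quadrant structure), shared latent states across genes
(equivalence cliques), and case/control location shifts of planted up/down
genes across multiple cohorts with independent noise. Defaults: mixture
modes 2 and 5 with sd 0.5 (6σ mode separation, comfortably outside the
±0.5 noise band), high-state fractions uniform in [0.2, 0.8] for null
genes, three cohorts of 100 samples per class, 30 planted genes per
direction at a 3σ effect — a planted gene's two class means then sit 1.5
log2 units apart, enough for per-gene AUC ≈ 0.98 at these sample sizes.
High-state counts are exact (rounded fraction at permuted positions)
rather than Bernoulli, so marginal guarantees hold deterministically.

What the generator does *not* model: count-level noise (negative
binomial), batch or platform effects, correlated null genes, missing
values. Passing tests therefore demonstrate correctness of the algorithms
under the stated generative assumptions, not robustness to every artefact
of real RNA-seq; the permutation FDR, which is computed from the data
itself, is the mechanism that carries over to real cohorts.

## Problem sizes and numerics

The test suite and the acceptance script use a 500-gene trio (100
samples per class) for signature training and a 2,000-gene × 289-sample
matrix (≈ 2·10⁶ pairs) for the permutation FDR; both complete in seconds
thanks to the matmul-based pair engine. SSE profiles are computed from
prefix sums with a clamp at zero to absorb round-off; quadrant counts are
exact integers; all randomness flows from explicit seeds
(`numpy.random.default_rng`), and rerunning any stage with the same seed
and configuration is byte-identical.

## Known limitations

- Single-step discretization only; genes with three expression regimes
  are forced into two.
- Cluster-candidate selection by composite AUC is a pragmatic
  operationalization; a curated or ML-guided choice can be injected but
  is not automated.
- The scale-free diagnostic (`cluster_size_distribution`) reports the
  histogram; judging straightness on the log-log plot, and tuning the
  Jaccard cutoff accordingly, is left to the user.
- No NA handling: matrices with missing values are rejected outright.
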
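# Methods

This note documents the statistical models implemented in `modreg`, the
defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical choices that affect results.

## Moderated differential expression

For gene *g* with pooled two-group residual variance s²_g on d_g degrees
of freedom, the empirical-Bayes model places a scaled inverse-chi-squared
prior with hyperparameters (d₀, s₀²) on the true variances. The posterior
variance is the df-weighted blend

    s²_post = (d₀·s₀² + d_g·s²_g) / (d₀ + d_g)

and the moderated statistic t_g = log2FC_g / sqrt(s²_post·(1/n₁ + 1/n₂))
is referred to a t distribution with d₀ + d_g degrees of freedom.
(d₀, s₀²) are estimated by moment matching on the log sample variances:
with z = log s²_g, e_g = z − ψ(d_g/2) + log(d_g/2) has mean
log s₀² + ψ(d₀/2) − log(d₀/2) and excess variance ψ′(d₀/2) beyond
ψ′(d_g/2), so d₀ is obtained by Newton inversion of the trigamma function
and d₀ = ∞ (pure prior) is returned when the observed spread does not
exceed the sampling expectation. A test cross-checks the statistics,
P-values and both hyperparameters against the standard R implementation
(limma) to ≤ 1e−5 relative error on a shared matrix.

Two limits are useful checks and are exposed by passing fixed
hyperparameters: d₀ = 0 reduces exactly to the ordinary pooled-variance
t-test; d₀ = ∞ uses s₀² alone, so statistics rank genes identically to
|log2FC|.

Genes with zero residual variance in both groups are floored at 1e−8
times the smallest positive observed variance and flagged (`zero_var`)
rather than dropped or allowed to produce infinite statistics.

DEG calling uses strict inequalities — |log2FC| > threshold AND adjusted
P < alpha — with two named profiles: `strict` (1.0 / 0.05), intended for
small discovery cohorts, and `relaxed` (0.5 / 0.05) for larger validation
cohorts where fold changes attenuate. Fold change is always case minus
control and the case level must be named explicitly. BH adjustment is the
standard step-up with stable ordering among ties.

## Enrichment machinery

The hypergeometric upper tail P(X ≥ k) for overlap k between a query of
size n and a set of size K in a universe of size N is computed exactly
(scipy's survival function, no normal approximation) and is the single
kernel shared by ORA and the regulator–module tests. The ORA universe
defaults to all genes present on the expression matrix after probe
collapsing — the most common convention; it is configurable because the
choice materially changes P-values.

Preranked GSEA uses the weighted Kolmogorov–Smirnov running sum: hits
increment by |score|^w (normalized over hits; w = 1 by default), misses
decrement uniformly, and ES is the extremum by absolute value. The null
is gene-label permutation (random same-sized sets), chosen because the
ranking may arrive without sample-level data; NES divides ES by the mean
|permutation ES| of the same sign — the only normalization under which a
|NES| ≥ 1 significance rule is meaningful — and the empirical P is
computed within same-signed permutations with the +1 correction, so
P ∈ [1/(B+1), 1]. Permutations default to 1000 with a mandatory seed.
Ranking metric defaults to the moderated t (a config option switches to
log2FC): t incorporates the variance information the analysis already
computed, and the choice only reorders near-ties.

## Network modules

Edges below the confidence threshold are removed first (default 0.400,
the conventional "medium confidence" cutoff of STRING-style scores, and
configurable), then nodes left without neighbors. Cohesiveness of a node
set V is f(V) = w_in / (w_in + w_bound + p·|V|) on the weighted graph
(weights = confidence scores; a binarized variant is available since the
source graph convention is not always known). The per-member penalty
defaults to p = 2 and the merge threshold for the overlap score
|A∩B|²/(|A|·|B|) to 0.8 — the defaults of the cohesiveness-based
clustering algorithm this stage follows.

Growth is strictly greedy and deterministic: from each seed (every node
not yet covered by a grown candidate, in descending weighted-degree
order), the single best boundary addition or member removal that strictly
increases cohesiveness is applied until a local maximum; equal gains
prefer additions and then the lexicographically smaller node id. Every
returned module is asserted post-hoc to be a local optimum. Merging
processes pairs in descending cohesiveness order to a fixpoint.

Module significance is a one-sided rank test that member vertices'
internal edge weight exceeds their boundary weight: exact by full split
enumeration (midranks, so structural ties — several members with zero
boundary — are handled exactly) up to 10 members, normal-approximation
Mann–Whitney beyond. An all-tied module returns P = 0.5 with a
`degenerate` flag. Retention requires size ≥ 5 and P < 0.05.

## Regulator inference

Interaction pairs are kept at score strictly > 0.5. "Interactions between
functional modules" is interpreted as the number of distinct modules
containing at least one target of the regulator, applied *before*
testing (default minimum 2; the post-test variant is available via the
`min_modules` parameter of the enrichment call). Each surviving
(regulator, module) pair with overlap ≥ 1 is tested with the exact
hypergeometric kernel — K = module size, n = targets in the universe,
N = universe size — and retained at P < 0.05. The universe defaults to
the union of all module genes and all regulator targets present on the
array; this is logged in every run because no universally correct
universe exists. Regulators enriched in ≥ 3 modules are "most promising"
candidates. ncRNA→TF pairs are kept at score strictly > 0.3, restricted
to regulators and TFs present in the enrichment output.

W = |log2FC| · (−log10 P) · degree uses the raw P by default (an
adjusted-P variant exists behind `use_adjusted`), floored at 1e−300
before the logarithm; degree comes from the full filtered interaction
network, not the module subgraph. Ties in W break by larger |log2FC|,
then gene id.

## Diagnostic model

The lasso logistic objective, on internally standardized features, is
−(1/n)·loglik + λ‖β‖₁ with an unpenalized intercept. It is solved by
iteratively reweighted least squares with cyclic coordinate descent:
soft-threshold updates over an active set, a vectorized KKT check over
inactive features to admit violators, warm starts down a 100-point
log-spaced grid from the analytic λ_max = max_j |x_jᵀ(y − ȳ)|/n (the
smallest penalty with an all-zero solution) to 0.001·λ_max. This solver
produces exact zeros and bit-reproducible deterministic paths; it is
cross-checked in the tests against the reference R implementation
(glmnet) at shared λ values (≤ 2e−4 coefficient discrepancy) and against
an independent fine-grid penalized-likelihood search (≤ 1e−4). The IRLS
probabilities are clipped at 1e−9 so perfect separation is handled by the
penalty rather than an error; constant features are dropped with a
warning; coefficients are reported on the original expression scale.

λ is selected by minimum mean cross-validated binomial deviance with
class-stratified folds: leave-one-out when n ≤ 20 (sensible for
ten-sample discovery cohorts), 10-fold otherwise. Case = 1, so positive
coefficients mean case-elevated expression.

ROC/AUC uses the rank (Mann–Whitney) formula — identical to exhaustive
pair counting with ties worth 0.5 — with curve points at every distinct
score threshold; the trapezoidal integral of the curve equals the rank
AUC exactly, and both identities are asserted in the tests.

## qPCR quantification

Per sample, ΔCt = Ct(target) − Ct(reference) after averaging technical
replicates on the Ct scale; ΔΔCt subtracts the control-group mean ΔCt,
and the relative quantity is 2^−ΔΔCt, making the control geometric-mean
fold change exactly 1 by construction. The two-group comparison is an
unpaired Student t-test run on ΔΔCt (the log scale) by default because
fold changes are log-normal; testing ΔΔCt or log2(fold change) gives
identical P (they differ only in sign), and a raw-scale option exists.
Verdicts: significant iff P < 0.05; tendency iff 0.05 < P < 0.15; none
otherwise (the boundary points fall outside both bands, following the
band definitions literally). Samples missing a reference Ct are dropped
with a warning; an all-constant degenerate comparison with equal means
returns P = 1.

## Synthetic-data generator

The generator's defaults are the study conditions the pipeline is
designed for: 2000 genes, two groups of 5 samples, 10% of genes shifted
by |log2FC| = 2 with residual noise SD 0.5 log2 units, three planted
8-node modules with within-block edge probability 0.9 versus 0.02
between, edge confidence scores uniform on [0.4, 1.0] independent of
membership (so topology recovery is not confounded with score filtering),
one planted regulator per class targeting its assigned modules at rate
0.8 against a background rate of 0.05, plus one background-only regulator
per class so false-retention rates are measurable. Baselines are drawn
once per gene from Uniform(4, 12) log2 intensity — a plausible microarray
range that does not affect group contrasts.

Planted modules are placed on planted DE genes (falling back to the first
gene ids when too few exist): the pipeline builds its interaction network
over DEGs only, so end-to-end recovery requires module members to be
differentially expressed. Planted regulators are assigned 3 modules each
by default (clipped to the number of planted modules) so they pass the
≥ 2-module pre-filter and qualify as promising candidates, and each
planted ncRNA additionally targets each planted TF with probability 1/2
to exercise the cross-link stage. The Ct generator lowers case-group
target Ct by log2(fold change) around fixed reference/target baselines
(18/25 cycles) with Gaussian per-measurement noise.

All randomness flows through per-call seeded generators derived from the
config seed (distinct fixed substreams per generator), and the pipeline
derives per-stage seeds by hashing the stage name with the global seed,
so adding a stage never perturbs another stage's randomness and identical
configurations reproduce identical files byte for byte.

What the generator does **not** emulate: probe-level intensities and RMA
preprocessing, batch effects, dropout, correlated noise across genes,
scale-free network topology outside the planted blocks, or regulator
classes with distinct targeting statistics. Passing tests therefore
demonstrate that the inference chain recovers the structures it assumes
when those structures are present at the stated effect sizes — not that
real microarray data satisfy those assumptions.

## Problem sizes and determinism

The test suite and the acceptance script run at the generator's default
sizes (2000 genes, 24 module nodes, ~600 regulator pairs, 10 samples);
recovery-rate properties use 10–100 seeded replicates at those sizes, and
the lasso recovery property uses n = 60 samples × 51 features with a
5-fold / 50-knot configuration, which selection accuracy does not depend
on. `scripts/acceptance.py --seed S --out F` reruns the entire chain from
scratch at these sizes and writes every headline quantity it computes;
two runs with the same seed are byte-identical.
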
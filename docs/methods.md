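# Methods

This note documents the models and procedures implemented in `pertpath`, the
choices made where the design was genuinely open, and what the synthetic
benchmarks do and do not demonstrate.

## Differential time vectors and DEG calling

Expression is assumed log-scale and already normalized.  At each time point a
gene is called +1/−1/0 by comparing treated vs. control replicates with an
empirical-Bayes moderated t-test: per-gene variances `s_g²` (pooled across
arms, `df = n_c + n_t − 2`) are shrunk toward a prior fitted on the scaled
inverse-chi-square hierarchy.  Hyperparameters `(d0, s0²)` come from the
method of moments on `log s_g²` — the excess of its variance over
`trigamma(df/2)` determines `d0` through a Newton trigamma inverse, the mean
determines `s0²` — and the posterior variance `(d0·s0² + df·s_g²)/(d0 + df)`
enters the t statistic with `d0 + df` degrees of freedom.  A gene is ±1 only
when both the p-value and the log-fold-change clear their cutoffs (defaults
0.05 and 1.0).  With a single replicate per arm no variance exists and the
call degrades to the fold-change criterion alone.  When no control arm is
available, the treated arm is compared against its previous or initial time
point (`vs_previous` leaves t=1 at 0 by construction).

## Cross-correlation, delay, and the tie-break

For edge `N1 → N2` the lagged inner product `(v1 ⋆ v2)(n) = Σ_t v1(t)v2(t+n)`
(zeros outside `1..T`) is maximized over `n ∈ [−(T−1), T−1]`.  Sustained
(step-like) responses make the cross-correlation *plateau* over every lag
between 0 and the onset difference of the two genes; the plateau endpoint
with the largest |n| is exactly that onset difference.  The argmax tie-break
is therefore **largest |n|, preferring non-negative n on a sign tie**: it
returns the true propagation delay for step responses, keeps d = 0 for
simultaneous concordant change, and reports reversed propagation (plateau
extending into negative lags) as a negative delay.  An edge is valid iff
`0 ≤ d ≤ delay_threshold` and the peak is strictly positive (a non-positive
maximum means no concordant overlap at any lag).  `delay_threshold` defaults
to `⌈T/2⌉`.

Weakly connected components of the valid-edge subgraph with at least
`min_edges` edges (default 3; the intended lower bound is ambiguous, so it is
a flag) are reported as perturbed sub-pathways with statistic
`Σ_edges peak`.

## Permutation test and tie handling

The null reassigns each sub-pathway gene a vector drawn without replacement
from the genome-wide vector pool of the same experiment (preserving the
marginal DEG sparsity) and recomputes the statistic on the fixed observed
edge set, without re-filtering validity.  Because the statistic is a sum of
small integers, permuted values tie with the observed one frequently; two
p-value forms are provided:

* `ties="upper"` (default, used for inference): `(1 + #{perm ≥ obs})/(B+1)` —
  the conservative convention, never anti-conservative;
* `ties="random"`: the rank of the observed statistic with ties split
  uniformly at random, exactly uniform on `{1/(B+1), …, 1}` under
  exchangeability — the form used to *verify* calibration.

Both are deterministic given the seed and bounded in `[1/(B+1), 1]`.
Benjamini–Hochberg FDR is reported alongside raw p-values across
sub-pathways.

## CP/PARAFAC embedding

The four gene-centric matrices (expression and copy number min–max normalized
per gene; methylation beta values; binary mutation indicators) stack in a
fixed omics order into a tensor fitted by alternating least squares: each
sweep solves the exact least-squares update for one factor with the others
fixed via the Khatri-Rao structure.  ALS on tensors that are only
approximately low-rank (the binary mutation slice and bounded methylation
slice guarantee some misfit) is sensitive to initialization, so the fit runs
`n_restarts` seeded random initializations (default 4) and keeps the
lowest-error solution.  The returned factors are in normalized form — unit
norm cell-line and omics columns, component weights absorbed into the gene
factors — which removes the scale indeterminacy and makes gene loadings
comparable across features; without it, the per-gene "most related feature"
argmax would depend on arbitrary column scalings.  No non-negativity or
orthogonality constraints are imposed.  Convergence is a change in relative
reconstruction error below `tol` (default 1e−8) between sweeps; the zero
tensor is defined to have error 0.

## Late-integration autoencoder

Input per cell line is the concatenation of the four omics vectors.  The
omics-specific stages are implemented as block-diagonal weight matrices (a
mask zeroes cross-omics entries and their gradients), so no information mixes
across omics before the integration encoder; the decoder mirrors the
encoder.  Hidden layers use relu; the final reconstruction layer is linear so
that arbitrary-signed inputs are representable and the memorization benchmark
is meaningful.  The loss is mean squared reconstruction error plus a weight
penalty — squared-norm (L2) by default, with an `penalty="l1"` flag for the
absolute-value form.  Optimization is full-batch Adam (default lr 1e−3) with
optional plateau early stopping; everything is plain numpy, gradients derived
by hand, and bit-deterministic given the seed.  Reference layer sizes are
2048/1024 (specific) and 1024/256 (integration); tests and examples use
scaled-down versions (e.g. 64/32 and 32/8) matched to synthetic gene counts.

## Mediator selection

Embedding features (CP cell factors or autoencoder codes) are standardized
and IC50 — natural-log transformed by default, since potencies span orders of
magnitude; a flag disables it — is regressed with LASSO, the penalty chosen
by cross-validation (leave-one-out below 2×folds cell lines).  Non-zero
coefficients define the IC50-associated features.

*Tensor route:* a gene's most related feature is the argmax of its |C_g| row
(ties to the lowest index); the gene is a candidate iff that feature was
selected, with signed omics score `C_g(g,f*)·coef(f*)`.  Lists are ordered by
score magnitude: CP components carry an arbitrary sign that the regression
coefficient mirrors, so magnitude is association strength and the sign only
records direction relative to IC50.

*Autoencoder route:* each selected latent feature is activated as a one-hot
code and decoded; the per-gene activation is the sum of absolute
reconstruction outputs over the gene's four omics slots, aggregated over
features with |coef| weights (mirroring the tensor route's coefficient
weighting), and the top fraction (default 5%) is kept.

*Score combination:* omics and literature scores are rank-normalized to
[0,1] and averaged with weight `w` (default 0.5) on the omics side; genes
missing from the literature table get 0.  Rank normalization makes the final
ordering invariant to any monotone transform of either raw score, and with
no literature table the ranking reduces to the omics ranking.  The
literature table is a user-supplied two-column TSV; no external service is
queried.

## Time-bounded network and influence maximization

GRN edges stay directed; PIN edges instantiate both directions, each
validated independently; sub-pathway edges import their existing
validations.  Every edge must pass the same delay rule as pathway edges.
Edge probability is `clip(peak/T, ε, 1)` with floor ε = 0.01 — diffusion
strength tied to the observed propagation evidence — multiplied by the PIN
confidence when present.  Node labels are exclusive with priority
TF > mediator > pathway_gene > other.

Influence spreads under the independent cascade: each edge fires at most
once with its probability; a successful activation arrives after the edge's
delay, and arrivals past the observable window `T − 1` are discarded
(the operational meaning of "time-bounded").  Spread is the expected number
of *target-labeled* nodes activated, estimated by seeded Monte-Carlo
(default 10,000 cascades) with common random numbers reused across greedy
iterations for variance reduction — which also makes the estimated spread
monotone in the seed set run-for-run.  Greedy selection adds the TF with the
largest marginal spread; on deterministic instances this inherits the
classical (1 − 1/e) guarantee, verified against brute force in the tests.
The specific labeled-IM variant in the literature leaves the diffusion model
open; independent cascade plus greedy is the canonical instantiation, chosen
and documented here rather than claimed as an equivalence.

Regulatory paths from a TF into a sub-pathway are highest-probability simple
paths (minimal cost under additive −log p, enumerated in increasing cost via
a virtual sink over the sub-pathway nodes), filtered by the cumulative delay
budget and optionally by the requirement of at least one mediator-labeled
interior node; ties break toward shorter paths, then lexicographic node
order.  Terminator proteins are nodes with out-degree 0, isolated nodes
included.

## Synthetic data

`generate_timeseries` plants an additive perturbation: source genes activate
at time 1 and activation travels one edge per `delay_per_edge` time points;
a gene's treated expression is its control baseline plus `amplitude` from its
activation time on.  Baselines are drawn once per gene from N(8, 1) — a
log2-intensity-like scale — with Gaussian replicate noise on both arms.  The
recorded truth contains exactly the edges whose propagation completes inside
the observed window.  `generate_multiomics` draws standard-normal cell and
gene factors and positive omics weights, builds the rank-R tensor, then
squashes the methylation slice through a logistic and thresholds the
mutation slice at the 80th percentile of its latent values (sparse binary,
like real mutation calls).  IC50 is the exponential of
`effect_size · Σ_causal c_f + noise`, so it is strictly positive on the
natural scale and the default log transform in the mediator stage sees an
exactly linear factor model; the scale is recorded in the fixture metadata.

What the generator does *not* emulate: probe-level measurement, L-1000
landmark imputation, mutation co-occurrence structure, pathway edge signs
(activation vs. inhibition), batch effects, or non-additive drug response.
Passing the planted-recovery benchmarks therefore demonstrates correctness
of the algorithms under their stated model, not performance on real panels.

## Benchmark sizes and numerical choices

The test and acceptance workloads are sized for a single CPU: 1000 random
vector pairs for the lag-search oracle, 50 planted fixtures for sub-pathway
recovery, 1000 null sub-pathways at B = 499 for calibration (the ±0.05 ECDF
band requires ~1000 draws before Monte-Carlo noise sits safely inside it),
20 replicates of 60 cells × 200 genes for mediator recovery, 20,000 cascades
for the closed-form comparison, and graphs of ≤ 10 nodes for the exhaustive
path and greedy oracles.  Degenerate inputs are pinned: constant columns
min–max to 0, the zero tensor has defined error 0, constant IC50 is
rejected, empty LASSO selections yield empty mediator lists, and every
reported p-value lies in `[1/(B+1), 1]`.

Known limitations: ALS restarts reduce but do not eliminate local optima on
strongly non-low-rank tensors; the autoencoder is full-batch and CPU-bound
(no minibatching or GPU); edge relation labels (activation/inhibition) are
carried through but not used in validity; and the permutation donor pool is
the single experiment's own genes, which is conservative when most of the
genome responds to treatment.
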
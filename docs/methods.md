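# Methods

## Scope and data model

The package analyzes repeated measures of social connectedness for a
single-sex herd of n individually collared animals exposed to three
enclosure densities, each replicated twice (six networks per herd; six
values per individual per metric). Proximity collars log an encounter
when two animals close within ~1.4 m and stop when they separate beyond
~1.8 m for more than 30 s; these firmware constants are carried as
metadata — all computation happens at the level of daily dyadic encounter
counts.

## Collar-bias correction

Each collar logs its own view of every dyad, so the raw n × n count
matrix is asymmetric. The correction is iterative: (1) compute, per
collar, the mean percent pairwise difference between what it logged and
what others logged about it (dyads with zero in both directions are
treated as true zeros and skipped — they carry no information about
relative efficiency); (2) rescale the most deviant collar's row (ties →
lowest index) by the ratio of mean-logged-about to mean-logged-by; (3)
accept the step only if the upper/lower-triangle Pearson correlation does
not decrease, and stop when the improvement falls below 1e-6 (or at 100
iterations); (4) symmetrize by the dyad-wise mean. The published
description of this procedure is a sketch; the deviance statistic, the
tie-break, the convergence tolerance, and the final symmetrization are
this package's concrete instantiation and are all exposed as arguments.
The procedure is idempotent and exactly inverts a pure single-row bias
(a collar with detection efficiency p earns factor 1/p).

Weights are encounter *frequencies*; durations are carried through I/O
but unused by default.

## Network metrics

Networks are undirected and weighted; an edge exists where the corrected
weight exceeds 0 (the threshold is an argument). Eigenvector centrality
is the leading eigenvector of the dense weighted adjacency matrix
(symmetric eigendecomposition; the Perron vector's sign fixed
nonnegative), rescaled so the maximum entry is 1 — the scaling under
which published treatment means up to ~0.74 are reproducible; unit-norm
scaling is available. Strength is the weighted row sum, degree the count
of positive-weight neighbours. Treatment summaries report mean ± sample
SD (n−1).

## Permutation nulls

Matrix nulls shuffle the upper-triangle dyad weights — zeros included —
uniformly among dyad slots and mirror (1,000 shuffles by default), then
compare the observed mean per-individual metric with the 2.5/97.5%
empirical quantiles. Two facts matter for interpretation:

* mean strength (= 2 × total weight / n) and mean degree (= 2 × count of
  positive dyads / n) are **conserved exactly** by this null, so their
  null distributions are degenerate at the observed value; only mean
  eigenvector centrality is informative;
* the mean max-scaled eigenvector centrality rises with the number of
  nodes the heavy weights cover *connectedly*. Arrangements whose heavy
  mass spans the whole group (e.g. a ring) therefore sit *above* the null
  band, while shuffles localize mass and fall lower. Concentrated
  star-like structure is generally not separable from the null by this
  statistic at n ≈ 12.

A node-relabelling mode is provided for completeness (it leaves every
mean metric unchanged). The repeatability null swaps metric values among
individuals — within each treatment × replicate stratum by default, so
the treatment structure survives while identity is destroyed (an
unstratified mode exists) — refits the model, and recomputes r per
iteration; failed fits are resampled and logged.

## Bayesian reaction-norm models

Six nested Gaussian mixed models (intercept-only null; + random
intercept; + linear density; + quadratic density; + random slope;
+ random curvature, with full covariance among included random terms) are
fit by a Gibbs sampler over the conditionally conjugate blocks
β | rest (normal), per-individual effects | rest (normal), G | rest
(inverse-Wishart), σ²_R | rest (inverse-gamma). The sampler is written
in-package because the model is the package's core; it is validated
against the closed-form conjugate posterior (intercept-only model with
pinned residual variance agrees to 3 decimals in posterior mean and SD)
and by parameter recovery.

Density enters standardized (z over the table's rows; a config choice),
and its square is computed from the standardized value.

**Priors.** Fixed effects N(0, 1e10). For a q-dimensional G the
inverse-Wishart uses scale matrix ν·V·I with V = var(response)/divisor
(divisor 2 by default; 4 and 6 for sensitivity) and degrees of freedom
ν + q − 1, so ν = 1 keeps the marginal priors comparably diffuse across
model dimensions; σ²_R uses the one-dimensional case. The exact density:
p(G) ∝ |G|^−(d+q+1)/2 exp(−tr(S G⁻¹)/2) with d = ν + q − 1, S = ν·V·I.

**Chains.** Default 1,300,000 iterations, thin 1,000, burn-in 300,000
(1,000 stored draws). The `desk` preset (13,000/10/3,000) keeps 1,000
draws at interactive scale and is what the test suite and acceptance
studies use for single fits; `quick` (1,200/5/200; 200 draws) backs
permutation-heavy work. Lag-1 autocorrelation per stored chain is
reported with a 0.1 flag threshold, plus an initial-positive-sequence
effective sample size.

**DIC** uses the conditional likelihood (individual effects in focus):
DIC = D̄ + p_D, p_D = D̄ − D(θ̄) at the posterior means of β, u, σ²_R. A
marginal-likelihood variant was considered and rejected: the ΔDIC
*ordering*, which is all the selection rule consumes, is what must be
reproducible. Selection: among models within 2 of the minimum DIC, the
most complex wins (ordering M1 < … < M6).

**Repeatability.** Per posterior draw, s²_among is the quadratic form
w(x)ᵀ G w(x), w(x) = (1, x, x²) restricted to the model's random terms,
averaged over the design's standardized densities (covariance terms
included); s²_within = σ²_R; r = s²_among/(s²_among + s²_within). Point
estimate = posterior mean, CrI = 2.5/97.5% quantiles. The reported
partition is the design-averaged diagonal (G₀₀, mean(x²)G₁₁,
mean(x⁴)G₂₂); off-diagonal mass is reported separately as a covariance
contribution. An intercept-only convention (s²_among = G₀₀) is available.
Models without random effects return a distinguished "undefined" result,
as do zero-variance responses (e.g. degree in a group where every
individual associates with every other), which yield a degenerate fit
rather than a crash.

Responses are modelled untransformed; a Shapiro–Wilk report is advisory
only. r is invariant to affine rescaling of the response (exactly so, per
draw, under a shared seed).

## Rank-order checks

Tie-corrected Kendall's W across the six occasions plus the mean pairwise
Spearman correlation; the published analysis names a rank-order
consistency check without printing its statistic, so both standard
measures are reported and neither is claimed as the original. Replicates
are compared per metric × density by two-sided Wilcoxon rank-sum tests,
exact for group sizes ≤ 12 without ties, normal approximation with
continuity correction otherwise.

## Synthetic data

The generator emulates the experimental design, not its physics: daily
dyadic counts are Poisson with log-mean
μ + β₁x + β₂x² + sᵢ + sⱼ + (bᵢ+bⱼ)x + (cᵢ+cⱼ)x² + ε(dyad, treatment),
with per-individual effects MVN(0, G) and independent dyad-level
treatment noise; per-collar detection is binomial thinning of each
direction of the true count. Defaults: 12 individuals, densities
0.71/1.05/1.43 animals/ha, 2 replicates, 5 days, baseline log rate 0.8
(≈ 11 encounters per dyad per 5-day treatment, matching strengths of
order 10²), β₁ = 0.1, β₂ = −0.35 (peak near the intermediate density, the
female-herd pattern; a male-herd configuration uses a positive linear
term), σ²_id = 0.25, σ²_resid = 0.15, collar efficiency 0.9. The latent
ground-truth repeatability is σ²_id/(σ²_id + σ²_resid).

What the generator does *not* emulate: spatial movement, within-day
temporal correlation, sex interactions (herds are single-sex), or
collar-specific drift over time. Passing recovery tests therefore show
the chain is correct *under its own assumptions*; they do not certify
robustness to real-data violations of them.

A second generator draws Gaussian metric tables directly from the mixed
model — the exact data-generating process the models assume — for
parameter-recovery and power studies where metric-scale distortion is
unwanted.

## Numerical and small-sample notes

* The balanced design (every individual measured at the same densities)
  enables a vectorized sampler; unbalanced tables are rejected explicitly.
* With ν = 1 priors at the study's size (12 × 6), the posterior mean of r
  carries an upward floor of ≈ 0.15 when the true among-individual
  variance is zero, and a two-sided credible interval can never contain
  the boundary value r = 0. Recovery is accurate for interior truths
  (bias ≲ 0.04 at r = 0.3–0.6; CrI coverage ≈ 0.90–0.95). Consumers
  should read small estimated r against that floor.
* Degenerate permutation draws, all-zero matrices, constant chains, and
  zero-variance triangles all return flagged or distinguished no-value
  results rather than raising.

## Problem sizes used in tests and the acceptance script

Verification studies run at the study's own scale (12 individuals × 6
measures) with the `desk` chain preset for single fits and `quick` for
permutation refits; Monte-Carlo studies use 10–20 seeds (1,000 for the
null-calibration rate, where the quantity of interest is a 5% tail
probability). These sizes are the package's choices for routine
verification; all are arguments.
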
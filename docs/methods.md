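# Methods

## Model and procedure

`diffpcor` treats a panel of M measured concentrations as a Gaussian
graphical model per physiological condition: conditional dependencies
between measures are the off-diagonal partial correlations
pcor_ij = −Ω_ij / √(Ω_ii Ω_jj), where Ω is the precision (inverse
covariance) matrix. Two networks are derived:

- **Individual networks** (one per condition): edges are pairs whose
  partial correlation is significantly non-zero.
- **Differential network**: edges are pairs whose partial correlation
  changes significantly *between* conditions, classified as increase,
  decrease or sign change relative to the reference (first) group.

### Shrinkage estimation

With strongly collinear panels (lipoprotein subclasses are the
motivating case) and moderate group sizes, the sample correlation matrix
is ill-conditioned and its inverse unusable. The estimate is therefore
the linear shrinkage U* = λT + (1−λ)U on the correlation scale with
identity target T (unit diagonal, off-diagonals shrunk toward zero);
variances are not shrunk. The intensity is the analytic optimum

    λ* = Σ_{i≠j} Var̂(r_ij) / Σ_{i≠j} r_ij²,   clipped to [0, 1],

where Var̂(r_ij) = n/(n−1)³ · Σ_k (w_kij − w̄_ij)² and w_kij is the
product of the standardized (ddof = 1) values of variables i and j in
sample k. A zero denominator (all off-diagonal correlations exactly
zero) yields λ = 1: the data are indistinguishable from the target. For
λ > 0 the estimate is positive definite even when M exceeds n.

### Edge test of the individual networks

Under the null, a partial correlation follows
p₀(r) ∝ (1−r²)^((κ−3)/2), i.e. r² ~ Beta(1/2, (κ−1)/2); the two-sided
p-value is the corresponding survival function. κ (the effective degrees
of freedom, which shrinkage inflates relative to the nominal n − M − 1)
is by default fitted by maximum likelihood to the observed off-diagonal
partial correlations, **truncated to the central window
|r| ≤ 5·median(|r|)**. The truncation is what makes the fit an
empirical *null*: a minority of strong true associations sits in the
tails outside the window and cannot widen the fitted null, while under a
pure null the window covers ≈99.9% of the mass and the truncated fit is
consistent. When the fit fails or runs to its bound (e.g. all observed
pcors are zero), κ falls back to max(n − M − 1, 4). The fitted κ and the
method used are recorded in the edge table and run log.

Edges are drawn at p ≤ α/K with K = M(M−1)/2 (Bonferroni, inclusive
comparison). No FDR alternative is provided by design.

### Differential permutation test

For each pair d = |r_A − r_B|. All n_A + n_B samples are pooled; each
permutation reassigns labels preserving the group sizes, re-runs the
*entire* estimation in both pseudo-groups (λ re-estimated every time),
and records d* for all pairs. One shared pool of permutations serves
all K pairs — datasets are permuted, not pairs — so per-pair nulls are
dependent across pairs; this mirrors the labeling protocol exactly. The
p-value uses the add-one estimator p = (1 + #{d* ≥ d}) / (1 + B), which
is never zero and is mildly conservative. The default B = 100,000;
simulation studies in the tests and the acceptance script use
B = 500–5,000, sized so the add-one granularity 1/(B+1) is well below
the α in play.

The significance cut-off is the *uncorrected* α (default 0.05): power to
detect a change in a correlation is intrinsically lower than for a shift
in a single variable at the same n, and a Bonferroni cut-off on K pairs
would leave essentially no power at realistic group sizes. A
`bonferroni` flag applies α/K instead. Consequently, with a fully null
dataset the differential "network" is expected to contain ≈ αK false
edges — the differential network is an exploratory map, not a
family-wise-error-controlled discovery list.

Classification of a significant pair: *sign_change* when r_A·r_B < 0 and
both |r_A|, |r_B| ≥ `min_magnitude` (default 0.05 — a sign flip between
noise-level values is not a sign change; configurable); otherwise
*increase* when |r_B| > |r_A|, else *decrease*.

Implementation note: the permutation engine computes, per pseudo-group,
all moments needed for r and Var̂(r) as sums of precomputed per-sample
features (x_i, x_i², x_i x_j, x_i² x_j, x_i² x_j²), so each permutation
costs one matrix product; the complementary pseudo-group's sums are
total minus selected. Columns are globally centered/scaled first (an
affine change that leaves partial correlations invariant) to keep the
raw moments well-conditioned. The engine agrees with the reference
single-matrix path to machine precision. The pseudo-group with the
smaller observed size is always the first block of each permuted index
vector, making p-values bit-identical under swapping of the two group
labels.

### Topology

Degree k_i; degree distribution P(k) = count(k)/N over observed k ≥ 1
with isolated nodes in the denominator only; betweenness as unnormalized
undirected Freeman counts (each unordered pair counted once; a
normalization flag exists, and hub ranking is invariant to it);
clustering c_i = K_i/(k_i(k_i−1)/2) with c_i = 0 for k_i < 2; density
2E/(N(N−1)); average degree 2E/N over all N nodes including isolated
ones. The degree-distribution slope is the least-squares fit of P(k)
against k on a chosen scale, log-log by default (the power-law reading);
the scale is always reported with the value, because the slope is
sensitive to that choice and to binning. Betweenness and clustering are
computed with networkx and are verified in the test suite against a
brute-force shortest-path enumeration oracle.

### Univariate screen

Two-sided Mann–Whitney per variable: exact distribution when
min(n_A, n_B) ≤ 8 and the pooled values are tie-free, otherwise the
normal approximation with tie and continuity corrections. Flags at α/M
and α; constant variables get p = 1 with a "constant" note.

## Synthetic data

The generator emulates a two-group panel study: variables in blocks
(subclasses) with a common within-block partial correlation, optional
cross-block edges, and group-B overrides for planted differential
edges. Patterns are written directly into a unit-diagonal precision
matrix (Ω_ij = −pcor_ij); if indefinite, the diagonal is inflated by the
smallest δ ∈ {0, 0.05, 0.1, …, 2} reaching min eigenvalue ≥ 1e−6, then
re-standardized. Inflation attenuates off-diagonals, so the *realized*
partial correlations are recomputed from the final matrix and are the
reference values for all recovery checks. Sampling is exact multivariate
Gaussian via the Cholesky factor of the inverse precision, fully
reproducible from the spec seed.

The default panel is 14 blocks of 4–5 variables (M = 60) with
within-block pcor 0.2 and sparse alternating ±0.15 links between
adjacent blocks, mimicking a lipoprotein cascade. What the simulation
deliberately omits: non-Gaussian marginals, measurement noise and
detection limits, mean shifts coupled to covariance changes, and any
within-block heterogeneity of association strength. Passing tests
therefore demonstrate correctness of the estimators and calibration and
power *under Gaussianity*; they do not certify behavior under heavy
tails or strong marginal skew, where a log transform (`--log-transform`)
is the recommended first step.

## Simulation sizes used by tests and the acceptance script

- Null calibration: M = 10 (two blocks of 5), n = 200 per group,
  B = 500, 200 replicate datasets; the pair-level rejection rate at
  α = 0.05 is compared to α within 3 Monte-Carlo standard errors.
- Planted sign flip: M = 12 (three blocks of 4), cross-block pair at
  +0.4 flipped to −0.4, n = 1000 per group, B = 2000, 50 replicates.
- Family-wise error: identity precision, M = 20, n = 500,
  100 replicates; mean edge count at α/K compared to α.
- Parameter recovery: M = 8 (two blocks of 4), planted |Δpcor| = 0.3,
  n = 1000 per group, B = 2000, 30 replicates.
- Panel study in `scripts/acceptance.py`: M = 60, n_A = 2021,
  n_B = 390 (a cohort-like 5:1 imbalance), four planted differential
  edges, B = 2000.

## Numerical choices and degenerate inputs

- Estimation requires n ≥ 3 and M ≥ 2; with n = 2 every sample
  correlation is ±1 and the variance plug-in is identically zero, so no
  meaningful shrinkage estimate exists.
- Zero-variance columns raise an error naming the column.
- p ≤ threshold (inclusive) defines significance everywhere; p-value
  ties need no tie-breaking.
- `partial_correlations` verifies positive definiteness via Cholesky and
  advises λ > 0 on failure.
- The pcor matrix is symmetrized (tolerance 1e−10) with diagonal exactly 1.
- Permutations use numpy's PCG64 (`default_rng`) with a required,
  recorded seed; the generator algorithm is named in the CLI run log.

## Known limitations

- The κ-based edge test is an analytic empirical null, not the
  local-fdr mixture some shrinkage-network software fits; both produce
  Bonferroni-style sparse graphs, but edge counts on real data may
  differ near the threshold.
- The differential network controls only the per-pair level, by design
  (see above).
- Degree-distribution slopes are least-squares fits on few support
  points and should be read qualitatively; no formal power-law test is
  provided.
- Complete-case row deletion is the only missing-data policy.
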
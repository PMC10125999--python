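# Methods

## Gaussian information estimators

All measures are computed on correlation matrices. Inputs are assumed to
come from z-scored series, for which covariance and correlation coincide
and every marginal entropy is ln(2πe)/2; covariance inputs are standardized
to correlation on load. Units are nats throughout (the CLI offers bits for
display only).

Every estimator reduces to log-determinants of principal submatrices,
computed by Cholesky factorization — never via the raw determinant, which
under- or overflows already at modest dimension. For the measures that need
all N leave-one-out submatrices (DTC, Ω, C, Σ) a single factorization
suffices, through the identity det(Σ₋ᵢ) = det(Σ)·(Σ⁻¹)ᵢᵢ: one Cholesky
solve yields the inverse diagonal and with it every single-node-removal
log-determinant. This is what makes mass subset sampling and annealing
cheap (one small factorization per candidate subset).

Conventions and edge cases:

- **Positive definiteness.** Construction of a `CorrelationMatrix` verifies
  symmetry (1e-12), unit diagonal (1e-12), off-diagonals in [−1, 1], and
  positive definiteness. A smallest eigenvalue in (0, 1e-10] — or at
  numerical zero, down to −1e-12·N — triggers a diagonal jitter of 1e-10
  with a warning; anything lower raises an error naming the offending
  eigenvalue. The tolerance at numerical zero is deliberate: global signal
  regression leaves node residuals that sum to exactly zero at every frame,
  so a post-GSR correlation matrix has rank N−1 *by construction*, with its
  null eigenvalue landing on either side of 0 at machine precision.
  Information measures of the full post-GSR matrix are therefore dominated
  by the jitter and not meaningful; all subset-level measures (the objects
  of interest) are unaffected.
- **Ω for N < 3** is identically zero; the functions return 0.0 with a
  warning rather than raising, so sweeps over k ≥ 3 need no special-casing.
- **TSE complexity.** The bipartition form sums, over scales
  i = 1…⌊N/2⌋, the mean mutual information between a size-i subset and its
  complement. For even N the middle scale i = N/2 enters with weight 1/2:
  each unordered bipartition at that scale corresponds to two subsets, and
  only with this weight does the bipartition form agree exactly (and it
  does, to 1e-8 in the tests) with the per-scale total-correlation form
  Σᵢ (i/N·TC(X) − 𝔼[TC(X^γ)]). Exact enumeration is capped at 16 nodes
  (~65k subset determinants) by default; beyond that the sampled mode draws
  uniform subsets per scale.
- **Classification of synergy** uses strict Ω < 0 with no dead band; raw
  values are always retained alongside the classification.

## Subset search

`anneal` implements simulated annealing over k-subsets with geometric
cooling T_c(h) = T₀·T_exp^h. Defaults: T₀ = 1, 10,000 steps, and
replacement moves of 1, 2 or 3 nodes at frequencies 0.68/0.27/0.04
(renormalized from their nominal values, which sum to 0.99). Replacement
nodes are drawn without replacement from the complement of the current
subset, so candidates always have k distinct nodes. A strictly better
candidate is always accepted; a worse one with probability exp(−ΔC/T_c),
ΔC being new-cost minus current-cost. The *best-ever* subset is returned,
not the terminal one — standard annealing practice, and the quantity of
scientific interest. Candidates with non-finite objectives (numerically
singular submatrices) are rejected and counted, never fatal. Runs are
bit-reproducible from the seed.

T_exp defaults to 0.99925, which decays the temperature by e^−7.5 over the
10,000-step budget, leaving both an exploratory and a greedy phase; when a
test shortens the step budget it scales T_exp to keep the same endpoint
(e.g. 0.9975 over 3,000 steps). At T₀ = 0 the algorithm degenerates to
stochastic hill-climbing, which the tests verify.

`exhaustive_extremum` enumerates all C(N, k) subsets (refusing more than
2×10⁶) and serves as the ground-truth oracle on benchmark instances; it is
never used by the annealer itself.

## Irreducibility null model

A k-subset with Ω < 0 may owe its synergy to a smaller core. The null
model removes each node in turn and recomputes Ω of the remainder; the
subset is *valid* (irreducible) only if every removal increases Ω by more
than a tolerance (default 1e-10 nats — exact ties count as reducible, the
strict reading of "removal must increase Ω"). Two removal mechanics are
implemented — excluding the node, and zeroing its correlations while
keeping it — and are analytically identical for Gaussians, since an
uncorrelated node factorizes out of every determinant; the tests confirm
agreement to 1e-10. Validation runs after optimization, not as a
constraint during annealing. Recursive reduction to a minimal core is out
of scope: only single-node removals are examined.

## FC pipeline

Per-run processing: column z-scoring (population convention), optional
global signal regression (unweighted across-node mean regressed out of
each node by least squares with intercept), optional linear detrend,
zero-phase Butterworth band-pass (default order 2, applied
forward-backward; only the band is fixed by convention, the order is a
knob), and symmetric frame trimming — in that order. Aggregation default
is append-then-correlate: each run z-scored, concatenated in time, one
Pearson correlation, symmetrized by transpose-averaging with the diagonal
forced to 1. Per-run correlation followed by averaging is available as an
alternative mode. Z-scoring is per run before appending (preventing
inter-run mean offsets from inflating correlations); disabling it exposes
the alternative.

Note that GSR on N nodes forces the residuals' pairwise correlations
toward exactly −1/(N−1) (sum-to-zero constraint), not 0; the tests assert
this exact value rather than the naive "residuals decorrelate".

`inject_global_redundancy` adds a single low-pass-filtered (default
0.01 Hz) Gaussian signal, re-standardized and scaled by an amplitude, to
every node — a controllable model of a globally redundant contaminant such
as slow scanner or physiological drift.

## Synthetic study systems

The generator composes three analytic ingredients, each with a closed-form
correlation signature, plus an optional global factor:

- **Redundant blocks**: members load with λ on a shared latent cause;
  every within-block pair correlates λ². Block subsets have Ω > 0.
- **Synergy motifs**: m independent parents and a child equal to their
  standardized sum plus noise σ_c. Parents stay pairwise uncorrelated;
  each correlates 1/√(m+σ_c²) with the child. The motif subset has Ω < 0 —
  the canonical Gaussian common-child (collider) structure, the only way a
  jointly Gaussian system expresses synergy.
- **Distractors**: all unassigned nodes, independent.
- **Global factor**: loading g on a member set (default all nodes) lifts
  within-member correlations toward g², emulating the globally redundant
  component that makes whole-cortex FC redundancy-dominated.

Time series are iid frames from the implied multivariate normal — a static
joint distribution. This matches the modeling assumption under which the
estimators are exact, and deliberately omits temporal autocorrelation,
hemodynamics, non-Gaussian marginals, and nonstationarity. Passing tests
therefore certify the estimators and search machinery, not the adequacy of
the Gaussian model for any particular real recording.

Three preset systems define the study conditions for the qualitative
analyses; their sizes (30–42 nodes) are chosen so that exact enumeration
over all subsets of the relevant sizes stays at desk scale, and their
parameters were fixed by the analytic sign conditions below, not by test
outcomes:

- `redundancy_dominated_system` (30 nodes): two 5-node blocks (λ = 0.75),
  three 2-parent triad motifs (σ_c = 0.6), global loading 0.7 on all
  nodes. The loading is set high enough that appending *any* off-motif
  node to a triad tips its Ω positive (at these values a bare triad sits
  at Ω = −0.061 nats and every triad-plus-one at +0.009): synergy exists
  at the smallest scale and is immediately swamped by redundancy, so the
  fraction of Ω < 0 subsets collapses as k grows — the behaviour of
  cortical FC, where a 200-node matrix accumulates the same dominance at
  lower per-pair correlation. A small emulation needs a higher per-pair
  baseline than the cortex's ~0.2 because redundancy accrues with system
  size.
- `segregated_synergy_system` (30 nodes): one 5-parent motif (σ_c = 0.35)
  *outside* a 0.6-loading global factor that covers the two redundant
  blocks and all distractors. Inside the motif almost all pairs have zero
  correlation (parents) and the rest are moderate (parent–child ≈ 0.44),
  while the redundant background carries the strong FC — so the node pairs
  that participate in synergistic subsets are precisely the weak-FC pairs.
  This reproduces the empirical signature that synergistic subsystems are
  invisible to pairwise FC.
- `seven_system_cortex` (42 nodes, 7 labeled systems): a 4-node redundant
  core per system plus one 5-parent motif spread across six systems' free
  slots, outside the global factor. Within-system samples are purely
  redundant; only subsets spanning ≥ 3 systems can assemble enough of the
  motif to turn Ω negative, so mean Ω is maximal for single-system samples
  and the synergistic fraction rises with the number of systems spanned.

A design fact worth recording: in a system of *independent* distractors, a
planted motif's Ω is untouched by appending distractor nodes (independent
variables change neither TC nor DTC), so the probability that a random
k-subset is synergistic would *grow* with k — the opposite of what
redundancy-dominated data show. A global redundant component is therefore
not a garnish but a structural requirement for emulating FC-like
fraction-versus-size behaviour, and is tested as such.

`planted_benchmark` shuffles one motif among independent distractors
(≤ 25 nodes so exhaustive enumeration stays under seconds) and returns the
ground-truth subset; the tests verify by enumeration that the motif is the
unique global Ω-minimizer at its size, that annealing recovers it in
≥ 90% of 50 restarts, and that it passes the irreducibility check while
the motif plus an independent node fails it.

## Aggregation

Participation counts, pair-participation counts (N(N−1)/2 unordered
pairs), and Jaccard similarity between subsets are exact combinatorial
bookkeeping; conservation (counts summing to k·M) is asserted, not
assumed. Clustering of a subset collection runs scikit-learn k-means over
the rows of the Jaccard similarity matrix (binary membership vectors are
available as alternative features), selects k by mean silhouette on
distance = 1 − similarity, and defaults to 100 k-means initializations per
k — a desk-scale default; the convention the measure derives from used
10,000. Before clustering, collections are typically subsampled to 500
subsets. System enrichment divides each system's mean nodal participation
by the chance expectation k·M/N; size-weighted ratios average to exactly
1, which the tests verify. When subsets of several sizes are pooled,
enrichment should be computed per size and pooled explicitly; the package
reports per-collection values and leaves the pooling weights to the
caller.

## Problem sizes and numerical tolerances

Analytic identities are asserted at 1e-8 (chains of leave-one-out
determinants) or 1e-10 (single-factorization identities); the knockout /
exclusion equivalence at 1e-10; Monte-Carlo comparisons at 3 standard
errors with 10⁵ draws; generator round trips at 3 entrywise standard
errors at T = 10⁵ frames. The identity suite runs on 500 random
correlation matrices of sizes 3–12 drawn from a Wishart-style construction
(well-conditioned by +5 extra degrees of freedom). Exact TSE is
cross-checked against an independently written entropy-based enumerator up
to 10 nodes. Exhaustive subset enumeration backs every planted-recovery
claim up to C(30, 5) ≈ 1.4×10⁵ subsets.

## Known limitations

- Gaussian estimators only: insensitive to nonlinear dependence; no
  discrete, copula or k-NN estimators.
- No time-lagged measures (transfer entropy and rate variants are out of
  scope), no partial information decomposition.
- The irreducibility model stops at single-node removals.
- Synthetic systems have no temporal memory; filter-related operations are
  exercised on their own sinusoidal/drift fixtures instead.
- Full-matrix measures after GSR are jitter-dominated (rank deficiency);
  use subset measures.
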
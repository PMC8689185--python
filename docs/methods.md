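# Methods

## Model

`treedab` models a samples × features count table `Y` (n × p) with a
Dirichlet-Multinomial likelihood, `Y_i ~ DirMult(N_i, a(x_i))` with
`log a(x_i) = α + x_i β`, where `N_i` is sample i's total count and `x_i`
its covariate row. The Dirichlet-Multinomial captures the overdispersion of
sequencing-derived compositions relative to a plain multinomial; its
expectation `N_i · a / Σ_j a_j` depends on the concentrations only through
their proportions, which is the formal statement of compositionality: any
common shift of `α + x β` leaves the implied composition unchanged.

Effects live on the nodes of a rooted multifurcating hierarchy over the
features. With the binary ancestor matrix `A` (columns: leaves in count-table
order, then internal nodes in deterministic post-order with the root last),
leaf effects are `β = β̂ Aᵀ`: a leaf's total effect is the sum over itself
and its ancestors. Internal columns of `β̂` therefore express "this whole
subtree moves together" with a single parameter. The representation is
redundant by design — an internal-node effect equals equal effects on all
its descendant leaves — so sparsity in `β̂` is what makes solutions
identifiable and interpretable.

### Prior

Each free `β̂_{l,k}` has a spike-and-slab lasso prior: a mixture, weighted
by a global θ, of two components of the form σ·b with `b ~ N(0,1)` and
`σ ~ Exponential(λ²/2)` — a sharp spike (λ₀ = 50) and a light slab (λ₁,k).
The model follows this generative form literally, with σ entering as a
multiplicative scale factor rather than as the normal's variance. Note that
this differs from the classical Laplace scale-mixture construction (which
places the exponential on the *variance*); the marginal of σ·b here is not
exactly double-exponential. We implement the printed generative statements
and the matching slab/spike density ratio used for thresholding; the
discrepancy is noted rather than silently altered.

The slab rate is node-adaptive,

```
λ₁,l,k = 2 λ₁ · 1 / (1 + exp(−φ (L_k/p − 0.5))),
```

with `L_k` the number of leaves under node k. φ = 0 penalises every node
with the base rate λ₁ = 5; φ < 0 makes large subtrees cheap (aggregated,
parsimonious solutions); φ > 0 makes leaves cheap (detailed solutions).
Values lie in (0, 2λ₁), so the spike always dominates (λ₀ > λ₁,k is
required and checked).

The mixture weight carries the multiplicity-controlling prior
`θ ~ Beta(1, |v \ v̂|)`: as the number of candidate nodes grows, the prior
expected slab fraction shrinks, which is what keeps the posterior median θ*
in a range where the practical-significance threshold (below) is positive
and the selection sparse. This scaling of the Beta's second parameter with
the number of free parameters is essential — the reciprocal choice
concentrates θ at 1, drives the threshold negative, and destroys false
discovery control (we verified this empirically: leaf-level FDR rises from
~0.1 to ~0.56 on the standard benchmark).

`α_j ~ N(0, 10)` is read as *variance* 10 (normal notation is ambiguous;
this is a deliberately vague base-composition prior).

### Reference feature

One feature p̂ is constrained to zero effect for every covariate, anchoring
the compositional scale. Its column *and all of its ancestors' columns*
(root included) are excluded from the sampled state entirely — structural
zeros, not parameters pinned near zero — because any ancestor effect would
leak into the reference leaf through `Aᵀ`. Automatic selection takes, among
features present (raw count > 0) in at least 95% of samples, the one with
the smallest dispersion; we score dispersion as the variance across samples
of the feature's relative abundance, which is depth-independent (the
measure is not pinned down in the method's description; variance of
proportions is our documented, overridable choice — pass `reference=` to
override the automatic pick entirely). Presence is evaluated before
pseudo-counting, otherwise every feature would appear fully present.

### Preprocessing

Zero count cells receive a 0.5 pseudo-count (non-zero cells untouched);
per-sample totals used by the likelihood are the pseudo-counted row sums,
while prediction uses the raw-count mean depth. Non-binary covariates are
min-max scaled to [0,1] so that no covariate dominates selection through
its range; exact 0/1 columns pass through. Internal tree nodes with a
single child are collapsed before model construction (their effect would be
redundant with their child's), and normalisation is idempotent.

## Inference

The posterior is sampled in an unconstrained space — `log σ`, `logit θ`,
with Jacobian corrections added to the target — by Hamiltonian Monte Carlo:
leapfrog integrator with 10 steps per iteration, identity mass matrix, and
dual-averaging step-size adaptation during burn-in only (target acceptance
0.75, a standard choice; configurable). The default chain is 20,000
iterations with the first 5,000 discarded; no thinning. A No-U-Turn sampler
(tree doubling with a slice variable, maximum depth 10) is available as an
alternative. Gradients of the joint log density are derived analytically
(digamma identities for the Dirichlet-Multinomial term, chain rule through
the mixture and the ancestor matrix) and are verified against central
finite differences in the test suite.

Numerical safeguards: states with `|log σ|` or `|logit θ|` beyond 50, or
log-concentrations outside ±250, are rejected as divergent (log density
−∞); α and b initialise from a seeded standard normal, σ at 1, θ at 0.5,
with bounded re-draws if the initial density is non-finite. Chains are a
pure function of (data, tree, configs, seed). Split-R̂ and effective sample
size are computed via ArviZ and surfaced as warnings, never as failures.

## Selection

With θ* the posterior median of θ and `β̂*` the element-wise posterior
median of the node effects, the per-node threshold is

```
p*_k(0) = θ* λ₁,k / (θ* λ₁,k + (1 − θ*) λ₀),
δ_k     = log(1/p*_k(0) − 1) / (λ₀ − λ₁,k),
```

the effect magnitude at which posterior slab-vs-spike odds cross even.
Entries with `|β̂*| > δ_k` (strict; ties drop) survive into the credible
matrix `β̂⁽ᶜ⁾`; its propagation `β̂⁽ᶜ⁾Aᵀ` defines the differential set
`D = {(l, j) : (β̂⁽ᶜ⁾Aᵀ)_{l,j} ≠ 0}`. Medians, not means, are used
throughout — they are robust to the spike/slab bimodality. Because δ_k uses
the node-adaptive λ₁,k, different nodes have different thresholds whenever
φ ≠ 0. Effect sizes are comparable within one run only (the compositional
anchor is run-specific); the output metadata carries this caveat.

## Synthetic benchmark

The generator reproduces the validation design: a random multifurcating
tree of depth exactly 5 (recursive random partition of the leaf set into
2–4 blocks per level, one designated block kept large enough to realise the
target depth; seed-controlled, since the original construction is not
published in detail); ground truth of one internal node directly above the
leaves plus two disjoint leaves, never covering the last feature (the
designated reference); per-feature base log-abundances `α ~ Unif(−2, 2)`
drawn once per dataset (the generative description indexes α ambiguously; a
per-sample redraw would make the two groups incomparable, so the per-feature
reading is adopted); treatment concentrations `exp(α + β·1(p′))`; each
sample's concentration rescaled to total `(1 − ψ)/ψ = 499` at ψ = 0.002
(the overdispersion dial); counts drawn at fixed depth 10,000. The full
grid is p ∈ {10, 30, 50, 100} × n₀ = n₁ ∈ {5, 20, 30, 50} × β ∈ {0.3, 0.5,
0.7, 0.9} × 20 replicates = 1,280 datasets, one tree per p reused across
its cells. A root-level variant (explicit high node as ground truth) and a
two-covariate variant (`x₁ ~ Unif(0,1)` with its own target node) are
expressible through the same generator.

What the generator does *not* emulate: zero inflation beyond what the
Dirichlet-Multinomial produces, per-sample depth variation, phylogenetic
signal in the base abundances, or correlated covariates. Passing tests on
this generator therefore demonstrates correctness of the machinery and
calibration under the model's own assumptions, not robustness to real-data
pathologies such as ASV-level sparsity.

## Evaluation

Detection is scored per covariate at the leaf level after propagation
(matching how leaf-only methods are compared): MCC by the contingency
formula with 0/0 → 0, FDR = FP/(TP+FP) with 0/0 → 0, Hamming = FP + FN.
Out-of-sample prediction uses `ŷ = softmax(α* + x β*) · mean training
depth` with α* the posterior mean and β* the credible propagated effects,
scored by MSLE with the standard `log(1+·)` transform; the K-fold harness
is seeded and computes effect vectors on training folds only.

## Problem sizes used in the checked runs

The test suite and the reproduction script use reduced chains (2,500 draws,
1,000 burn-in) and the p = 10, n₀ = n₁ = 20, β = 0.9 benchmark cell with
~10 seeded replicates per quantity; these sizes give stable estimates of
FDR/MCC/recovery for this model while keeping a full run in the minutes
range. Model defaults remain the full 20,000/5,000 chain.

## Known limitations

- Single chain by default; cross-chain R̂ requires running the estimator
  with multiple seeds manually.
- The likelihood treats the pseudo-counted table as the observation; for
  extremely sparse ASV-level tables, aggregate to a higher rank first.
- No zero-inflation, confounder-specific priors, or fast EM-style solvers;
  the sampler is the only inference path.
- p ≳ 100 features is workable but slow with default chain lengths; the
  cost per leapfrog step is O(n·p + d·v).
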
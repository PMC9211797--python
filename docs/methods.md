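# Methods

## Model class

An MPT model is a set of processing trees, one per experimental
condition. A branch is an ordered product of first-order terms θ or
1−θ (no exponents — sufficient for every model here and for the EQN
convention); a category's probability is the sum of its branch
probabilities. Counts are product-multinomial: independent across trees,
multinomial within a tree with the tree's total fixed by design.

Structural completeness (per-tree probabilities summing to one) is
checked numerically at random interior parameter points with tolerance
1e-9 rather than symbolically, which keeps the package free of
computer-algebra machinery; for branch products the evaluation error is
orders of magnitude below that tolerance. Local identifiability is
assessed by the rank of the central-difference Jacobian of the map from
free parameters to stacked category probabilities at random interior
points (step 1e-6, rank tolerance 1e-7): rank below the free-parameter
count means distinct parameter vectors are observationally equivalent.
This correctly flags the unrestricted process-dissociation model
(10 parameters, rank 8) and clears it once r = d is imposed per
stimulus set.

## Built-in models

**Four-states model** (remember-know-guess). Old-item tree:
recollection r → "detailed recollection"; else familiarity f →
"feeling of familiarity"; else a guessing cascade g_r, then
(1−g_r)g_f, then (1−g_r)(1−g_f)g_g, with the residual
(1−g_r)(1−g_f)(1−g_g) a "new" guess. New-item tree: detection d →
"new", else the identical cascade. The guessing parameters are shared
between the old and new trees of a stimulus set — the uncertainty state
is the same regardless of the item's true status. Duplicated over
animacy: 12 parameters, 4 trees, 22 branches; the unrestricted model is
saturated (12 free parameters on 12 independent cells).

**Two-high-threshold process-dissociation model.** Eight binomial trees
(inclusion/exclusion × Phase-1-old/new × animacy). Inclusion, old item:
"old" via r, via (1−r)f, or via (1−r)(1−f)g_i. Exclusion, old item:
recollection produces a correct "new" (the instruction is to reject
Phase-1 words), familiarity and guessing produce "old". New items:
detection d produces "new", otherwise guessing g_i / g_e. Phase-2
(intentionally learned) words are not modelled, following the standard
process-dissociation analysis. The r = d equate within each stimulus
set renders the model saturated (8 free parameters on 8 cells); it is
the variant with the best validation record for this paradigm.

## Restrictions

Equality restrictions are resolved transitively by union-find; the
representative of a chain is its earliest-declared member, so estimates
are reported under stable names. A fixed value anywhere in a chain pins
the chain; contradictory constants raise. Expansion back to the full
space is exact, and category probabilities are invariant under it (a
property test).

## Estimation

The product-multinomial log-likelihood is maximized by either of two
backends:

* **logit quasi-Newton** (default): L-BFGS-B on logit-transformed
  parameters with the analytic gradient, followed by a few EM polish
  steps — a vanishing EM improvement certifies stationarity even when
  the line search terminates at machine precision;
* **EM**: the classical MPT expectation-maximization update on expected
  branch counts, iterated until the log-likelihood gains less than
  1e-10.

Both run from the midpoint (all parameters .5) plus 10 uniform random
starts (seeded; default seed 20220621) and keep the best solution.
Cross-backend agreement (within 1e-4 on every fixture, typically 1e-6)
is the package's internal check of optimizer fidelity; the test suite
additionally checks a brute-force grid-search oracle on a toy model and
the closed-form binomial solution. Parameters are clamped to
[1e-8, 1−1e-8]; estimates within 1e-6 of a bound are reported as
boundary estimates with absent standard errors.

Standard errors are square roots of the diagonal of the inverse
*observed* Fisher information (negative Hessian of the log-likelihood at
the MLE, central differences of the analytic gradient, step 1e-5).
Whether the original GUI-tool analyses used observed or expected
information is not documented, so SE agreement is only asserted loosely
(±.005) in the tests.

G² uses 0·log 0 = 0; a zero expected cell with positive observed count
yields an infinite G² and a flagged fit. p-values are upper-tail central
χ² probabilities without small-sample correction, and p := 1 when
df ≤ 0. No multiple-testing adjustment is applied anywhere — the
reproduced analyses report unadjusted tests, and the report says so
explicitly.

## Effect size and power

w = √(G²/N) with N the total number of analyzed responses (17,600 =
110×160 for the remember-know-guess design; 16,952 = 163×104 for the
process-dissociation design — this convention reproduces every
published w from its published ΔG²). Power is
P(χ²_{df,λ=N·w²} > χ²_{df,1−α}); the minimal detectable w root-finds
the noncentrality (λ* ≈ 12.995 for df = 1, α = .05, power = .95) and
satisfies the inverse-consistency property power(w*(π)) = π to 1e-6.

## Data reconstruction

The studies' raw data are not deposited; their aggregate tables are
recovered from printed mean proportions and known totals (4400 responses
per tree in the first study; 2106 per inclusion tree and 2132 per
exclusion tree in the second). Each row is normalized (printed rows sum
to .99–1.01), scaled to its total, floored, and the remaining units
assigned by largest fractional part, ties to the earlier category —
deterministic and exactly total-preserving. Pooling over participants is
exact here because every participant contributes the same number of
items per tree.

**Error analysis.** The printed proportions carry rounding error up to
±.005 per cell. Parameter estimates are locally linear in the cell
proportions, so refitted estimates are reproducible to about ±.01; the
detection parameter d is the worst case because it back-solves
d = (P − s)/(1 − s) from the "new"-response cell P with guessing
stay-probability s ≈ .5, doubling the input error. G²-type statistics
are *quadratic* in perturbations of up to ±.005 × 4400 counts, so their
decimals are not reproducible from printed tables at all; the package's
tests therefore assert the qualitative significance pattern (which
restriction is rejected at which level), not G² digits.

## Synthetic data and validation studies

The generator draws per-tree multinomials at stated true parameters —
exactly the sampling model the aggregate analysis assumes. It does not
emulate participant-level heterogeneity, item effects, or response
dependencies; passing recovery/power checks therefore validate the
estimator under the model's own assumptions, not robustness to their
violation. Replicates are reproducible from (seed, replicate index) via
independent seed-sequence streams.

Default study conditions mirror the reproduced design: truth set to the
first study's base-model estimates, 4400 responses per tree. Under
these conditions the tests check near-unbiasedness (|bias| < .01),
RMSE ≥ |bias|, Wald-interval coverage near .95, type-I error of the
familiarity test at α within Monte-Carlo error, and agreement of
Monte-Carlo rejection rates with the analytic noncentral-χ² power
across small effect sizes. The population effect size of a simulation
scenario is defined by fitting the restricted model to the exact
expected cell probabilities (an infinite-N fit) and converting the
misfit per observation to w — the standard noncentrality construction;
scenario calibration root-finds the recollection gap that yields a
target w. Simulation sizes in the shipped tests (200–500 replicates,
reduced multi-start counts for well-behaved replicate fits) were chosen
to bound Monte-Carlo error at roughly three binomial standard errors
while keeping the suite quick to run routinely.

## EQN dialect

First line ignored (header/comment, as in common MPT tools); content
lines are whitespace-separated `tree category product`; products use
`*` and parenthesized complements `(1-x)`; a bare `1` is the empty
product. Numeric tree/category labels map to stable names
(`tree1`, `cat2`, …); symbolic labels pass through unchanged, so
write→parse round-trips are structurally exact and the built-in models
export to EQN for cross-tool replication on the same reconstructed
counts.

## Known limitations

* Aggregate (complete-pooling) analysis only: no hierarchical/latent-trait
  MPT, no bootstrap, no Bayesian inference.
* No order constraints (θ_a ≤ θ_b) or nonlinear parameter functions;
  restrictions are equates and fixed values.
* Identifiability is checked locally (Jacobian rank), not globally.
* The reconstruction cannot beat the printed rounding: quantities more
  than linearly sensitive to the cells (G² decimals, the detection
  parameter's second decimal) inherit that uncertainty.
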
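# Methods

## The population-wise error rate

A multi-population trial tests, for each of `m` overlapping target
populations `P_1, ..., P_m`, the one-sided null hypothesis
`H_i : theta_i <= 0` that treatment `T_i` is no better than the shared
control `C` in `P_i`.  Because the populations overlap, one false rejection
can harm patients in several populations at once.  The overall population is
therefore partitioned into the `2^m - 1` disjoint strata
`P_J = (∩_{j∈J} P_j) \ (∪_{k∉J} P_k)`, `J ⊆ {1..m}` nonempty: the patients
affected by exactly the treatments indexed by `J`.  Writing `pi_J` for the
relative prevalence of `P_J`, the population-wise error rate of a common
one-sided threshold `c` is

    PWER(c) = sum_J pi_J · P( max_{j∈J} Z_j > c ),

the prevalence-weighted average of strata-wise family-wise error rates
(SWERs).  It is the probability that a randomly drawn future patient belongs
to a stratum in which some relevant hypothesis was falsely rejected.  Since
every stratum tail is bounded by the full equicoordinate tail,
`PWER <= FWER`, and PWER control sits between unadjusted testing and FWER
control: `c_unadjusted <= c_PWER <= c_FWER` on every design.

Under the global null the statistic vector `Z` is centered multivariate
normal (known variances) or multivariate t (pooled unknown variance), so
each stratum term is an equicoordinate tail `1 - F_{0,Sigma_J}(c, ..., c)`
on the correlation submatrix `Sigma_J` of the populations the stratum
belongs to.  The null `theta = 0` is least favorable under subset pivotality
and stochastic monotonicity, which the package asserts as a numerical
property (simulated error rates under componentwise nonpositive effects
never exceed the analytic rate at the null) rather than re-deriving the
proof.

## Test statistics and correlation structure

Population-level mean estimates combine strata-arm means with the realized
sampling weights: `mu_i,T = sum_{J∋i} (n_{J,T}/n_{i,T}) · mean(X_{J,T})`.
The statistics are `Z_i = (mu_i,Ti - mu_i,C) / sqrt(V_i)` with

    V_i = sum_{J∋i} [ n_{J,Ti} s2_{J,Ti} / n_{i,Ti}^2 + n_{J,C} s2_{J,C} / n_{i,C}^2 ].

Correlation between `Z_i` and `Z_j` arises from shared patients.  With
pairwise different treatments only control patients are shared:

    Sigma_ij = sum_{J∋i,j} n_{J,C} s2_{J,C} / ( n_{i,C} n_{j,C} sqrt(V_i V_j) ).

When two populations share one treatment arm (`T_i = T_j`) the analogous
treatment-arm term is added; this follows from representing each effect
difference as a linear combination of independent cell means, and the
implementation is tested against exactly that brute-force covariance
calculation.  Under a homogeneous variance the matrix is variance-free
(the `sigma^2` cancels against `V_i = sigma^2 (1/n_{i,Ti} + 1/n_{i,C})`),
which the tests verify entrywise at 1e-12.

Four variance regimes are supported.  Known (heterogeneous or homogeneous)
variances give gaussian statistics.  Unknown homogeneous variance uses the
pooled estimator `sigma2 = sum (n_{J,T}-1) s2_{J,T} / (N - s)` and a
multivariate t null with `df = N - s`, where `s` counts the (stratum, arm)
cells holding more than one patient.  This `df` is implemented verbatim; it
differs from the conventional `sum (n_{J,T}-1)` when singleton cells exist
(those cells contribute nothing to the numerator but still count in `N`) —
the discrepancy is inherited from the published formula and intentionally
not resolved.  Unknown heterogeneous variances have no exact joint
distribution; the package provides the Welch-type approximation:
per-population Satterthwaite degrees of freedom

    df_i = (v_T/n_T + v_C/n_C)^2 / [ (v_T/n_T)^2/(n_T-1) + (v_C/n_C)^2/(n_C-1) ]

computed at the population level, plug-in estimation of `Sigma`, and
per-population boundaries `c_i` each solving the estimated-PWER equation
with the `|J|`-dimensional t at `df_i`.  Cells with fewer than two
observations have no variance estimate of their own; the pooled estimate is
substituted there when building the plug-in `V_i`.

## Prevalence estimation

Two estimators are provided.  The multinomial maximum-likelihood estimator
is `pi_J = n_J / N` over the enrolled sample.  The marginal-sum estimator
additionally uses the screened patients carrying no biomarker: from the
screened-sample frequencies it forms per-biomarker marginal rates `p_j`,
builds the independent product distribution over strata, truncates away the
empty configuration, and renormalizes.  With finite samples the raw
products need not sum to one, so the output is renormalized by its sum —
both downstream uses (the PWER sum and the minimal-prevalence adjustment)
require a probability vector.

Strata the sample missed (`n_J = 0`) drop out of the estimated PWER, so a
future patient from such a stratum would only be protected indirectly.  The
minimal-prevalence adjustment raises every stratum weight below a floor
`pi_min` to the floor and rescales the remaining strata by a common factor.
The default floor is `1/(2^{m+1} - 2)`, half the uniform stratum weight.
The adjustment is a single pass: strata are classified once as raised or
kept, and kept strata pushed below the floor by the rescaling are not
re-raised.  A fixpoint iteration would differ only when the floor is large
against the observed prevalences; at the default floor such cascades are
negligible, and the one-pass rule keeps the operation transparent.
Consequently idempotence holds in the intended regime (floor small against
the kept weights) but can fail for adversarial weight vectors; the solvers
always report both the unadjusted boundary and the adjusted boundary and
take the larger one as operative, since the adjustment is not guaranteed to
be stricter on every design.

## Equicoordinate tail evaluation

All error rates reduce to equicoordinate multivariate normal/t tails.
These are evaluated by the Genz separation-of-variables transform with
scrambled-Sobol quasi-Monte-Carlo integration, vectorized across both
integration points and — in the simulation hot path — across the strata
submatrices of equal dimension.  The t family integrates one extra
coordinate over the chi-distributed scale via the inverse incomplete-gamma
function, with per-df caching.  Dimension one uses the exact univariate
survival function and diagonal normal cases use the product closed form.

The integrator's internal Sobol scramble seed is fixed, so every evaluation
is reproducible and the root-finding objective is smooth, deterministic and
strictly monotone.  The point budget sets the accuracy: the default 2^13
points give absolute errors near 1e-6 (validated in the test suite against
scipy's multivariate cdfs and against 10^6-draw Monte-Carlo oracles); the
simulation engine defaults to 2^11 points (errors around 5e-6), far below
the Monte-Carlo spread of any study quantity, and the budget is a config
field.  scipy's own cdfs are not used in the hot path because at comparable
accuracy they cost three to four orders of magnitude more per call; they
serve as the independent oracle in the tests instead.

Critical values are found with a bracketed Brent search on the monotone
rate function.  The bracket is analytic: the univariate quantile is always
a lower bound (every stratum tail dominates the univariate tail) and the
Bonferroni quantile an upper bound; the upper end doubles if ever needed.
The solver tolerance is 1e-6 on the error rate and the residual is checked
after the root-find.

## The synthetic-data generator

The generator emulates a biomarker-stratified umbrella trial.  `m` binary
biomarkers with expression probabilities `p_i` define the populations;
patients with no biomarker are screened out, so enrolled strata counts are
multinomial over the `2^m - 1` nonempty configurations with the truncated
product-law prevalences.  Dependent biomarkers use a Gaussian threshold
copula: marker `i` is expressed iff a latent `N(0, R)` coordinate falls
below `Phi^{-1}(p_i)`, preserving the stated marginals; stratum
probabilities are then orthant probabilities computed by inclusion-exclusion
over the equicoordinate machinery.  Allocation within a stratum is either a
deterministic even split over the eligible arms (floor plus seeded-random
remainder) or per-patient uniform randomization.  Responses, where needed,
are independent normals per (stratum, arm) cell.

Study defaults are the reference conditions: `N = 500` enrolled patients,
`alpha = 0.025`, pairwise different treatments, stratified allocation,
maximum-likelihood prevalence estimation, pooled-variance t statistics, and
probabilities redrawn uniformly on (0, 1) each replicate.  `N` counts
enrolled patients for maximum-likelihood runs and screened patients
(including the no-biomarker stratum) for marginal-estimator runs, since the
marginal estimator is defined on the screened sample; both are available
through the estimator switch.  For heterogeneous-variance studies the cell
variances are drawn i.i.d. uniform(0.5, 2) per replicate by default; the
law is a config field.

A replicate whose realized allocation leaves some population arm empty has
undefined statistics; it is redrawn from the replicate's own seed stream
and the redraw is counted in the output (at the reference sample sizes this
affects well under 1% of replicates except in the deliberately sparse
conditioned study, where it stays a few percent).  The conditioned study
(minimal-prevalence evaluation) rejection-samples replicates until at least
one stratum is empty and aborts with a config error if the acceptance rate
falls below 0.1%.  Per-replicate seeds are spawned from the master seed
with numpy's `SeedSequence`, so studies are bit-reproducible and single
replicates can be re-run in isolation.

For the unknown-heterogeneous regime the true PWER has no closed form;
it is approximated per replicate by testing fresh global-null datasets
(default 10,000, config-reducible) at the solved per-population boundaries
and averaging the strata-wise any-rejection proportions with the true
prevalences.  The fresh datasets are generated through their sufficient
statistics (cell means and cell variances drawn from their exact normal and
scaled-chi-square laws), which is distributionally identical to drawing
patient-level responses and much faster.  The approximation error scales as
`1/sqrt(draws)`, which the tests verify on a fixed replicate.

What the generator does not emulate: real biomarker assays (measurement
error, missingness), non-normal or correlated responses within a patient,
unequal or adaptive randomization targets, dropout, and any between-stratum
effect heterogeneity under alternatives (only the global null is simulated
for error rates).  Passing tests therefore demonstrate control of the
designed error rates under the stated sampling model, not robustness to
violations of it.

## Problem sizes used in the checks

The acceptance-style checks run the baseline and small-sample studies at
2,000 replicates and the m=6 conditioned study at 1,000 accepted
replicates, with Monte-Carlo assertions at three standard errors of the
replicate summaries; these sizes give standard errors one to two orders of
magnitude below the quantities checked while keeping a full run in the
minutes range on one CPU.  The boundary-ordering property is checked on
1,000 random designs, and integrator accuracy against 10^6-draw Monte-Carlo
oracles.

## Known limitations

- The exact joint law of Welch-type statistics is unavailable; the
  Satterthwaite route is an approximation and its true PWER is itself
  Monte-Carlo approximated.
- The strata-wise FWER summaries need a notion of "nonempty" stratum; in
  simulations the true prevalence is available, and strata with positive
  true prevalence are used.  For data-only analyses the estimated
  prevalence is the only proxy, and the reported summaries are computed
  over strata with positive estimated weight.
- Prevalence priors from historical data and sample-size planning are out
  of scope.
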
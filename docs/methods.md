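# Methods

`hetace` implements an item-level heteroscedastic ACE model for twin
data with 3-category ordinal items, together with its Bayesian
estimation, the variance-decomposition arithmetic built on it, a
multi-group measurement-invariance workflow, and a synthetic twin-data
generator that reproduces the full generative structure. This note
records the model, the estimation choices, the design decisions taken
where the design was genuinely open, and the limitations we know about.

## The model

**Measurement layer.** Individual j of pair p responds to items
i = 1..n on a 3-point scale, X in {0, 1, 2}. A graded-response probit
model links each item to the latent phenotype theta:

    y*_pij = alpha_i * theta_pj + eps_pij,      X determined by cutting
    y* at ordered thresholds tau_i1 < tau_i2

with unit residual variance (probit convention). The residuals of the
two co-twins on the same item are correlated r_MZ,i or r_DZ,i,
capturing item-specific familial variance (or co-completion artefacts)
beyond the shared phenotype; both correlations are constrained
non-negative by placing a uniform(0,1) prior on their square roots,
which also prevents sign switching.

**Biometric layer.** The phenotype decomposes as

    theta_pj = nu * GENDER_pj + A_pj + C_pj + E_pj

with COR(A1,A2) = 1 (MZ) or 0.5 (DZ), COR(C1,C2) = 1, COR(E1,E2) = 0,
and GENDER coded 0 = male, 1 = female. Genotype-by-environment
interaction enters by letting the conditional environmental variances
be log-linear in the genetic score:

    VAR(A)   = exp(omega0_overall + omega0_female * GENDER)
    VAR(C|A) = exp(gamma0_eff + gamma1_eff * A)
    VAR(E|A) = exp(beta0_eff  + beta1_eff  * A)

where each effective parameter adds a female offset for women. A
positive slope means the environmental variance grows with genetic
liability. Identification: alpha_1 = 1 fixes the scale and orientation
of theta; the male phenotypic mean is fixed at 0, with nu free only in
gender-moderated fits.

**Shared-kernel construction of C.** The conditional formulation
VAR(C|A_pj) is per individual, while COR(C1, C2) = 1 must hold at the
family level. The only construction consistent with both is to scale a
single shared standard-normal kernel per pair by each member's own
conditional standard deviation:
`C_pj = exp(0.5 * (gamma0_eff + gamma1_eff * A_pj)) * Z_C,p`.
A side effect worth knowing: when `gamma1 != 0` the *correlation*
between C1 and C2 falls below 1 even though the kernel is shared
(the scales differ across members), by the factor
`exp(-gamma1^2 * VAR(A) * (1 - rho_A) / 4)`. This is a property of the
model, not an implementation artefact, and it is one reason the A-by-C
and A-by-E parameters are hard to separate in small samples.

## Marginal variances and standardization

Because VAR(C|A) and VAR(E|A) vary with A, standardized components are
defined against the *marginal* variances. With A ~ Normal(0, VAR(A)),
exp(c0 + c1*A) is lognormal with mean

    exp(c0 + 0.5 * c1^2 * VAR(A))

so `marginal_variances` computes VAR(C) and VAR(E) by this identity
(gamma paired with C, beta with E) and standardizes
h2 = VAR(A)/total, etc. A `paper_literal` flag provides the variant
occasionally printed in the applied literature — `exp(b0 + 0.5*b1^2)`
without the VAR(A) factor and with the slope/component pairing swapped
— for comparison only; it is not the lognormal mean and does not
reproduce the published standardized components from the published
structural estimates, whereas the identity above does (male e2
reconstructs as 0.442 against a printed 0.44; the one visible gap is
the male c2, 0.200 reconstructed vs 0.22 printed, attributable to
summarizing a nonlinear transform by posterior means).

The genotype-by-environment heritability fraction is
`1 - h2_group / h2_reference`: the share of reference heritability that
disappears once the group's interaction structure is modelled.

## Synthetic data

The generator draws, per pair: a shared genetic kernel (plus unique
kernels mixed as sqrt(0.5) each for DZ pairs, giving cross-twin genetic
correlation exactly 0.5 on the standardized scale; for opposite-sex
pairs the genetic cross-covariance is 0.5 * sigmaA_male *
sigmaA_female), one shared C kernel, independent E kernels, and one
shared kernel per item carrying the residual correlation via
sqrt(r)-mixing. Propensities are cut at the thresholds and cells are
masked independently (missing at random) at a configurable rate.
Defaults come from presets transcribing the published posterior means
of the full gender-interaction model (`table7_table8_M2`), its
single-group variant (`table8_M1`), and a linear ACE null
(`null_ACE`, components 0.5/0.2/0.3). The roster preset lacks one item
(excluded in the source analysis for gender non-invariance); its slot
is filled with roster-typical synthetic values so 13-item datasets can
be generated.

What the generator does *not* emulate: age or occasion effects (the
reference analysis found none), household-level response patterns
(missingness is cell-wise MAR), missing-not-at-random mechanisms, and
higher-order family structure. Tests passing on these data therefore
say nothing about, e.g., informative nonresponse in real surveys.

A useful external calibration: a 13-item cohort generated from the
full-model preset yields Cronbach's alpha of 0.88, inside the 0.83-0.90
range reported for the adult anxious-depression scale the presets come
from.

## Estimation

`sample_posterior` runs Metropolis-within-Gibbs on a non-centred
parameterisation: all latent quantities are standard-normal kernels,
and structural parameters map kernels to A, C, E deterministically.
Conditional on the per-pair item kernel U, the two members' responses
are independent and each category probability is a normal-CDF
difference with mean `alpha*theta + sqrt(r)*U` and variance `1 - r`;
the ordinal propensities are therefore marginalised analytically rather
than imputed by truncated-normal augmentation. Missing responses drop
out of the likelihood, which yields the same posterior as treating them
as sampled parameters. Priors follow the reference analysis:
uniform(-5,5) boxes for discriminations (but alpha_1 = 1), nu and all
omega/beta/gamma parameters; a flat prior on ordered threshold pairs,
truncated to [-10, 10] so the posterior stays proper when a top
category is empty in the data; uniform(0,1) on sqrt(r). Narrower
per-class boxes can be supplied (used by the calibration study below).

Plain random-walk updates mix badly on three posterior ridges, so the
sampler adds dedicated moves, all validated by a prior-recovery run
(fitting fully-masked data reproduces the prior exactly):

* **Ridge (shear) moves** — a slope step paired with the intercept
  adjustment that keeps each sex's marginal environmental variance
  fixed (unit Jacobian).
* **Exchange moves** — an omega0 step paired with the gamma0 adjustment
  preserving exp(omega0) + exp(gamma0), the A/C trade only the MZ-DZ
  correlation contrast resolves; the nonlinear companion contributes an
  exp(gamma0 - gamma0') Jacobian. A deterministic A/C *swap* involution
  lets chains jump between mirror basins outright.
* **Interweaved scaling moves** — a step in omega0/beta0/gamma0 paired
  with the affine kernel remap that keeps A, C, E (hence theta and the
  whole likelihood) fixed; acceptance is the kernel-prior ratio times
  the affine Jacobian. These break the slow random walk between
  variance parameters and their kernels.

Proposal scales adapt toward ~35% acceptance during burn-in and are
frozen afterwards. Chains start from a crude Falconer-style
decomposition of a standardized sum-score proxy (jittered per chain),
which keeps short chains out of mirror basins. Derived quantities
(h2/c2/e2, VAR(A) per sex) are computed per draw, never from posterior
means. Reproducibility is exact: chain c of a run with seed s uses
`default_rng([s, c])`.

Diagnostics: the classic between/within potential scale reduction
factor (floored at 1; constant chains return 1 by convention), and
shortest-interval (HPD) summaries at 99% by default.

**Known identification limits.** With few items and few hundred pairs,
two directions are weakly identified and show up as wide or biased
posteriors rather than sampler failures: (i) latent shared variance
(A or C) trades against the item-level residual correlations — because
r >= 0 and the sqrt-uniform prior has density 1/(2 sqrt r) at the
origin, posterior means of c2 shift up and h2 down by ~0.05-0.1 at
n = 1000 pairs even in the linear model (99% HPDs still cover truth);
(ii) at small VAR(A) the interaction slopes become unidentified and the
uniform boxes give that funnel large volume, so omega0 can be pulled
down with 6-item data. Both effects vanish as items and pairs grow;
they are why the test-suite checks interval coverage, not posterior-mean
proximity, for variance components.

## Calibration study

The sampler's frequentist validity is checked by prior-matched
simulation-based calibration: per replicate, the structural truth is
drawn from narrower per-class priors (intercepts uniform(-2.5, 0.5),
slopes uniform(-1, 1), nu uniform(-1, 1)), a cohort of 400 pairs
(five cells, six items) is generated, and the model is refitted under
those same priors (two chains of 2,000 sweeps with overdispersed
starts). With truth drawn from the fitting prior, 99% HPD coverage is
nominal by construction if the sampler is correct; measurement
parameters are held at the roster preset (realistic items), so coverage
of the structural parameters is approximate rather than exact.
Observed coverage is 18-20/20 per watched parameter, against a
>= 17/20 pass line that allows for residual per-replicate convergence
noise at this chain length (the occasional miss is a chain stuck in
the small-VAR(A) funnel; rerunning a missing replicate at 2 x 6,000
sweeps restores coverage).

## Invariance workflow

Groups (survey occasion, age band — default bands 18-19, 20-21, 22-24,
25-34, 35-70, pairs straddling two bands dropped — or sex composition,
with opposite-sex DZ pairs forming their own group) are compared on a
model in which (theta1, theta2) is bivariate normal per group with free
mean, variance and cross-twin correlation (no ACE split), under a
nested constraint schedule: step 0 (all measurement parameters free),
1a (equal discriminations), 1b (+ equal residual correlations), 1c
(+ equal thresholds), 2a (+ equal phenotype moments), 2b (+ equal
cross-twin correlations). VAR(theta) = 1 anchors group 1 once
discriminations are shared; MEAN(theta) = 0 anchors it once thresholds
are shared.

Steps are scored by a deterministic AIC-type criterion: minus twice the
*marginal* pair log-likelihood at the posterior-mean parameters — the
phenotype pair and the shared item kernels integrated out by
Gauss-Hermite quadrature (12 nodes per phenotype dimension, 10 per item
kernel; accurate to ~1e-3 in log-likelihood against adaptive
integration) — plus twice the free-parameter count. A step passes when
its criterion does not worsen by more than one standard error of the
paired per-pair deviance difference. We chose a plug-in criterion after
finding that WAIC computed from latent-conditional pointwise
likelihoods is numerically useless at feasible draw counts (the latent
states are resampled each draw, and the pointwise log-predictive
estimates swing by tens of units). Item-level screening is separate:
any parameter left group-specific by the step has its between-group
difference summarised, and an item is flagged when the 99% HPD of the
difference excludes 0; flagged items feed an exclusion list for
refitting. One screening caveat: a threshold whose category is
(nearly) empty in the data is prior-dominated — its draws wander over
the truncated flat prior — so difference flags for such parameters are
uninformative and should be read against the category counts.

Validated behaviour: fully invariant two-group data pass the complete
schedule in 10/10 replicates; a +1.0 shift of one item's first
threshold fails exactly the equal-thresholds step and flags exactly
that item. A planted *discrimination* difference of 0.8 is attenuated
by the alpha-vs-r trade at a few hundred pairs per group and is not
reliably rejected at that scale — a real small-sample limit of
item-level invariance testing, not a workflow defect.

For occasion homogeneity the package follows the simpler published
logic: fit the linear ACE model per occasion and judge homogeneity by
overlap of the 99% HPDs of h2/c2/e2 (`occasion_homogeneity`).

## Problem sizes and defaults

Production defaults mirror the reference analysis: 2 chains of 20,000
sweeps, 10,000 burn-in. The test-suite and the worked examples use
deliberately smaller designs chosen as this package's own test scale —
cohorts of 400-800 pairs, 6-13 items, chains of 800-4,000 sweeps —
which keep every check within a normal CI run while leaving the
assertions meaningful (interval coverage, sign recovery, planted-effect
detection). All test statements about recovery and calibration hold at
those sizes and seeds; they are not claims about asymptotic behaviour.

## Limitations

* No dominance (ADE) component and no gene-environment correlation.
* No longitudinal item linking; one occasion is selected per individual
  (fewest missing responses, earliest occasion breaking ties).
* The bivariate-normal phenotype layer of the invariance workflow
  assigns one mean per group; in the opposite-sex group the sexes'
  means are not separated there (the interaction model handles that via
  nu).
* Posterior means of variance shares carry the small-sample biases
  described above; report intervals, not points, at n below a few
  thousand pairs.
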
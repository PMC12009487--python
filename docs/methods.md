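# Methods

`stsir` reproduces, end to end, a county-level spatiotemporal cancer-mapping
analysis: crude and Bayesian-smoothed standardized incidence ratios for a
region-by-year count panel, retrospective space-time cluster detection, six
hierarchical space-time model variants with a formal comparison battery, and
a synthetic-data generator that stands in for the unreleased registry panel.
This note records the models, the numerical choices, and what the synthetic
experiments do and do not establish.

## Data model

The unit of analysis is the county-year cell. A panel holds observed case
counts `Y_ij` and populations at risk `n_ij` on a complete `n regions x T
years` grid (here 9 x 10). Region order is fixed by first appearance in the
panel file and is the canonical index for the adjacency graph, centroids and
all matrices; aligning everything to one ordering at load time prevents
silent misalignment. Populations may vary by year; the bundled fixture uses
constant populations, the degenerate case.

## Standardization

Expected counts are indirectly standardized,
`E_ij = n_ij * (sum_i Y_ij / sum_i n_ij)` within each year (default), or
with the pooled decade rate (`overall`). The per-year default follows the
source analysis, which computed a crude SIR "for each county per year"; its
printed worked example (observed 150, expected 104 in a ~7e5-person county
in one year) is consistent with year-specific rates and not with a flat
decade rate. Per-year calibration makes `sum_i E_ij = sum_i Y_ij` exact in
every year, which the test suite asserts to 1e-9 relative. The crude SIR is
`Y_ij / E_ij`; cells with `E = 0` are reported as undefined (NaN), never as
infinity. No age or sex standardization is performed — the formula is
purely population-proportional, a documented limitation.

## Space-time scan statistic

The scan is the retrospective discrete-Poisson cylinder scan. Candidate
cylinders combine a spatial base — the k nearest regions to a center by
great-circle centroid distance, k = 1 being the center alone — with every
window of consecutive years up to half the study period. The base may not
exceed half the population at risk; this is evaluated as the base's
person-time share of the scanned window, which equals the base-population
share when populations are constant, and it gates growth *beyond* the
center (a single-region base is always admissible, so single-region studies
and purely temporal scans remain well defined). With observed total `C` and
expected totals calibrated to `C`, a cylinder with observed `c` and
expected `e` scores

    LLR = c*ln(c/e) + (C-c)*ln((C-c)/(C-e)),   0*ln(0/x) := 0,

the log generalized likelihood ratio for independent inside/outside Poisson
rates against a homogeneous rate; the test suite cross-checks it against a
numerical two-rate maximization. High-rate (`c > e`) and low-rate (`c < e`)
scans run in one pass. Significance uses conditional Monte Carlo: null
panels redistribute the `C` cases multinomially with cell probabilities
`E_ij / sum(E)`, and the pseudo p-value is `(1 + r) / (1 + n_sim)` where
`r` counts replicates whose direction-restricted maximum LLR reaches the
observed one; with the default 999 replicates the smallest attainable p is
0.001. Secondary clusters are reported greedily in decreasing LLR among
cylinders sharing no region with a better-ranked reported cluster of the
same direction — the conventional no-geographic-overlap rule; the source
analysis reports secondary clusters without stating its rule. Reported
relative risk is `(c/e) / ((C-c)/(C-e))` with `O/E = c/e` alongside.

## Hierarchical Bayesian space-time models

Counts follow `Y_ij ~ Poisson(E_ij * theta_ij)` with six variants of the
log relative risk:

* no interaction: `log theta_ij = alpha + v_i + u_i + gamma_j + phi_j`
* Knorr-Held types I-IV: the above plus an interaction `delta_ij`
* parametric trend: `log theta_ij = alpha + u_i + v_i + (beta + s_i) t_j`

`v_i` is iid Gaussian (unstructured space); `u_i` is intrinsic CAR on the
queen-contiguity graph, with conditional distribution
`u_i | u_-i ~ N(mean of neighbours, sigma_u^2 / n_i)` — `sigma_u` is the
*conditional* scale, so the marginal spread of the field is substantially
smaller on a well-connected graph. `gamma_j` is a second-order random walk
(penalizing second differences; its null space is any linear trend) and
`phi_j` iid Gaussian. The interaction types cross the unstructured and
structured components: I = iid over cells, II = independent random walks in
time within each region, III = independent ICAR across regions within each
year, IV = the Kronecker combination (ICAR in space x walk in time). The
interaction walk order defaults to 1 (configurable to 2); the source states
RW2 only for the main temporal effect. In the parametric variant `t_j` is
the year index centered at the period midpoint with unit steps, `beta` the
global slope, and the region slope deviations `s_i` iid Gaussian with their
own precision (an ICAR option exists), with a sum-to-zero constraint — the
source does not state this prior.

Every random-effect precision carries a Gamma(shape 1, rate 5e-5) prior —
the classical disease-mapping default (log-precision ~ LogGamma(1, 5e-5)) —
and `alpha`, `beta` and the unpenalized RW2 linear direction carry fixed
N(0, 10^2) priors. Identifiability: sum-to-zero on `v`, `u`, `gamma`,
`phi`, `s`; interactions drop every null direction of their Kronecker
structure matrix, which imposes the standard margin constraints (type II:
time-sums zero per region; III: region-sums zero per year; IV: both).

### Parametrization and sampling

Each intrinsic effect is parametrized in the eigenbasis of its structure
matrix restricted to the penalized subspace: with `R = V diag(lambda) V'`
and `lambda > 0`, the effect is `V z` with independent
`z_k ~ N(0, 1/(tau*lambda_k))`. This makes every prior diagonal, enforces
the constraints exactly, and keeps the RW2 null-space linear trend as an
explicit extra direction with a proper vague prior (mimicking software that
leaves the null space unpenalized).

Inference is MCMC with four move types per iteration:

1. conjugate Gibbs for each precision, `tau | z ~ Gamma(a0 + r/2, b0 + q/2)`
   with `q = sum lambda_k z_k^2`;
2. a few (default 3) MALA updates of the whole latent vector, preconditioned
   by the dense Gauss-Newton metric `H(tau) = B' diag(lambda_ref) B +
   prior precision`, with `lambda_ref = max(Y, 0.5)` a fixed reference
   curvature — the dense metric captures the exact linear ridges between
   effects whose design columns span overlapping cell subspaces, which a
   diagonal preconditioner cannot; step size is tuned by dual averaging to
   0.574 acceptance during warmup;
3. a joint rescaling move per effect, `(z, tau) -> (c z, tau/c^2)` with
   log-normal `c`, which travels along the funnel between an effect's scale
   and its precision;
4. exact Gibbs resampling of the *split* of every shared subspace between
   effect pairs (v and u; phi and the structured temporal effect;
   interaction overlaps with the main effects for types I-III), plus a
   mode-swap Metropolis move exchanging the shared component and the two
   precisions for the fully confounded pairs — without these, chains sit in
   one allocation of the spatial (or temporal) field for thousands of
   iterations.

Defaults are 4 chains x (1000 warmup + 1000 draws). Convergence is checked
with split-chain rank-normalized R-hat on all scalar summaries (limit
1.05); a failing fit is returned but flagged, and downstream consumers
refuse it unless forced. Posterior draws of `theta`, all effects, and
per-cell Poisson log-likelihoods are retained. The sampler's posterior was
cross-checked against an independent MCMC implementation (JAGS, same model
in the same eigenbasis) on a fixture-scale dataset.

## Model comparison battery

All criteria are computed from the stored log-likelihood draws; nothing is
refitted. DIC uses the plug-in deviance at the posterior mean of the
*linear predictor* (mean of log theta). WAIC uses the variance penalty.
CPO is the harmonic-mean leave-one-out predictive density per cell; cells
where the harmonic-mean estimator is unreliable (a zero-likelihood draw or
an estimated relative Monte Carlo error above 25%) are flagged and excluded
from the sum rather than silently smoothed. PIT uses the mid-distribution
correction for discrete counts, `mean F(y) - 0.5 mean f(y)`, because the
plain PIT is non-uniform for counts even under the true model; uniformity
is tested with the Anderson-Darling statistic for a fully specified
Uniform(0,1), with the Marsaglia-Marsaglia evaluation of the null
distribution (the suite checks its type-I calibration by simulation). R^2
is, by default, the squared Pearson correlation between crude and smoothed
SIR across cells — the source never defines its R^2, so this is an explicit
interpretation, with a deviance-based pseudo-R^2 selectable. Single-cell
conjugate (Poisson-Gamma) cases, where DIC and WAIC have quadrature forms
and CPO is the negative-binomial predictive in closed form, serve as
oracles in the tests. The comparison table flags the best model per
criterion; the overall flag follows WAIC.

## Synthetic data

The generator draws every random effect from the same intrinsic-GMRF priors
the models use, by exact constrained sampling in the structure-matrix
eigenbasis (pseudo-inverse covariance with explicit projection — exact and
cheap at these sizes), then `Y_ij ~ Poisson(e_ij * theta_ij)` around
population-proportional baseline expecteds. The fixture skeleton has the
nine county names, years 2010-2019, and centroids near 34.97N 48.56E; the
populations printed in the source's cluster table (Nahavand 193745, Malayer
299070) and its cluster population sums are honored, the remaining
populations, the contiguity list and exact centroids are plausible
synthetic stand-ins, labelled as such in the code. Baseline decade rates
default to the printed cumulative incidences (colorectal 107.72, gastric
135.23 per 100k per decade, about 20 expected cases per cell), so simulated
totals land near the printed 1864 / 2340 cases. Default effect scales
(unstructured spatial 0.1, ICAR conditional 0.2, RW2 0.1, unstructured
temporal 0.05, interaction 0.15) produce relative-risk surfaces spanning
roughly 0.7-1.6, matching the spread of the published smoothed SIRs.
`inject_cluster` multiplies the true risk inside a chosen cylinder and
redraws its counts, recording the truth for power studies.

What the synthetic experiments show: that the pipeline's arithmetic is
correct, that the scan has near-nominal type-I error and high power at the
published cluster magnitude, and that the Bayesian machinery is calibrated
under its own assumptions. What they cannot show: anything about the real
registry data (unreleased), including the exact published DIC/WAIC table
and smoothed SIR trajectories; registry artefacts such as geocoding failure
or death-certificate-only cases are deliberately not emulated.

## Simulation scales and known limitations

Parameter-recovery and model-recovery experiments simulate with about 200
expected cases per cell (intercept 0.1, unstructured spatial sd 0.2, ICAR
conditional sd 0.3, RW2 sd 0.15), the scale at which cell-level risks are
well identified; scan experiments run at the fixture's real scale. With
only nine regions the spatially structured and unstructured variance
components are weakly separated (the classic convolution-model confounding):
cell-level credible intervals achieve near-nominal coverage and the iid,
interaction and slope scales recover well, but the posterior under the
flat-on-precision Gamma(1, 5e-5) prior systematically allocates the shared
spatial field to the component with the smaller implied scale, so the ICAR
conditional sd is typically estimated at a fraction of its generating value.
This is a property of the model-prior-data combination, not of the sampler
— an independent MCMC implementation reproduces it — and it is documented
rather than patched (for example by informative or penalized-complexity
priors), because the goal is to mirror the published specification.

Separation between interaction *types* is intrinsically weak at this
problem size: the iid (type I) interaction's span contains the structured
types' spans, and on panels generated from the type II variant the WAIC
ranking prefers type I in roughly a third of replicates, by margins of a
few units that are stable under much longer chains — so a best-by-WAIC
verdict between interaction types on a single 9 x 10 panel should be read
as suggestive, not conclusive. (The same near-ties between type I and the
no-interaction model appear in published county-level comparisons.)

Scan p-values are per direction; scanning both directions means the family
of two primary clusters has a familywise error above the per-direction
level, as in standard practice. The Monte Carlo null conditions on the
observed total, so calibration statements are conditional.
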
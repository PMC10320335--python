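# Methods

## The stochastic model

Each taxon is an independent two-state continuous-time Markov chain on
{absent, present} with colonization rate *c* (absent → present) and
extinction rate *e* (present → absent), both per day by convention —
all machinery is unit-agnostic, so any consistent unit of the supplied
timestamps works, and slopes of log–log regressions are invariant to
the choice. Over an interval Δt the transition probabilities are

    P(0→1) = π* (1 − exp(−(c+e)Δt)),   P(1→1) = π* + (1−π*) exp(−(c+e)Δt),

with stationary occupancy π\* = c/(c+e) = k/(1+k), k = c/e. The
`expm1` form is used so small (c+e)Δt does not cancel
catastrophically. Persistence is p = 1/e; k is the fitness measure
(colonizations per residence time), and constancy of k across taxa
("fitness equalization") implies the trade-off p = k/c: slope −1 of
log p against log c with intercept log k. Taxa are assumed independent;
abundance-explicit (Levins) dynamics and interactions are out of scope.

## Rate estimation

The likelihood of a presence–absence series is the product over
consecutive sample pairs of the transition probability at each pair's
own Δt; missing surveys are simply absent time points. The first
observation of each series is conditioned on, not modelled, so no
stationarity assumption enters (the detectability variant is the
exception, below). A *group* — a taxon, a taxonomic guild, or a block
of sites — pools all member transitions into one likelihood; multiple
sites contribute additively.

Optimization is Nelder–Mead in log-rate space, restarted from a fixed
3×3 log-spaced grid (10⁻³, 10⁻¹, 10 per axis), tolerance 1e-8, with
rates clipped to [1e-6, 1e3]; the best restart is kept, making fits
deterministic given the data. A fit is flagged `boundary` when a
transition direction was never observed or the estimate is pinned at a
clip bound; such likelihoods have their maximum at (or beyond) the edge
of the parameter space. Observed rates for sequence data are
*effective* rates: a detection failure following a success counts as an
extinction whether or not the taxon truly left.

Taxa whose fitted persistence is below a quarter of the minimal
inter-sample interval (`filter_labile`) are set aside before trade-off
regressions: a taxon cycling faster than the sampling grid cannot be
rated reliably.

**Imperfect detection.** With r ≥ 2 replicate samples per survey,
presence is treated as latent: given presence each replicate detects
independently with probability d; given absence, never (no false
positives — chimera and denoising artefacts are an upstream concern).
The likelihood is evaluated by the forward algorithm per taxon with the
stationary distribution of the candidate rates as the initial latent
law; a latent start must be integrated out, which is why this variant,
unlike the transitions-only fit, invokes stationarity. Consequently,
fixing d = 1 reproduces the transitions-only estimates only up to the
initial-state term — agreement is asymptotic in series length, not
exact. d is constant across surveys and taxa within a fit; r = 1 is
rejected (d is then confounded with the rates).

## Model selection over site partitions

Every set partition of the site labels defines a model: sites sharing a
block share one (c, e) pair, fitted jointly; the model spends two
parameters per block. Models are compared by plain AIC (the smallest-n
correction AICc is available as an argument but not default) and
summarized by Akaike weights; the evidence for a hypothesis about the
grouping is the summed weight of the partitions satisfying it.
Enumeration refuses more than 12 sites (Bell-number explosion); an
explicit model list can always be supplied.

## Core–satellite split

Occupancy (fraction of samples with a detection, pooled over sites and
replicates) is paired with log10 maximum observed abundance per taxon.
Points are ordered by occupancy — the threshold and the labels are
defined on occupancy, so the scan must order by it; the regression of
log abundance on occupancy with the axes swapped is available for
sensitivity analysis. A Chow F statistic (pooled- vs two-line RSS,
2 and n−4 degrees of freedom) is scanned over every intermediate
breakpoint after trimming 10% of the points (minimum 3) at each end.
The strongest break, provided its F exceeds the pointwise 0.05 critical
value, sets the occupancy threshold: the mean of the observed
occupancies flanking the break (using fitted line endpoints instead is
a documented alternative interpretation). Core taxa are strictly above
the threshold. Ties in occupancy sort stably by taxon id; ties in F
resolve to the lowest-occupancy candidate. Because the critical value
is pointwise, scanning many candidates on pure-noise data can exceed it
— the flag guards against evaluating labels on break-free data, not
against scan-level multiplicity.

The core's rank-abundance distribution is summarized by the standard
lognormal RAD fit: abundances ranked descending, rank r of S mapped to
z_r = Φ⁻¹((r−0.5)/S), expected abundance exp(a + b·z_r) fitted by a
Poisson GLM with log link; the residual deviance measures lognormality.
(The fit agrees with vegan's `rad.lognormal` to numerical precision;
the test-suite checks this against Rscript.) Direct log-series fitting
of the satellite component is deliberately not offered: singleton
removal in sequence pipelines censors exactly the frequencies a
log-series fit needs.

## Trade-off statistics

The trade-off regression is OLS of log p on log c (persistence as
response, matching p = k c^(−1); reduced major axis is available as an
option for sensitivity since both variables are estimates). Reported
per component: slope, t-based 95% CI, Spearman ρ (asymptotic p for
n ≥ 10, exact permutation p below that), and the t-test of slope = −1
with n−2 degrees of freedom. Core-vs-satellite slope equality uses the
pooled dummy-variable regression log p ~ log c × component; the
interaction coefficient's t statistic with n₁+n₂−4 degrees of freedom
is the test. Taxonomic coherence compares intra- vs inter-group
Euclidean distances in (log10 c, log10 p) with a Kruskal–Wallis test.
No estimation uncertainty in (c, p) is propagated into these tests;
the CIs treat the points as data.

## Synthetic data

Generators are deterministic under a seed, with an independent
substream per taxon (and per purpose: rates, trajectories, abundances,
per-sample reads), so enlarging the pool never reshuffles existing
taxa. Trajectories start Bernoulli(π\*) and propagate with the exact
interval transition probabilities. Rate models: one shared pair
(`fixed`), fitness-equalized (`equalized`: c log-uniform over a stated
range, default [0.02, 2] per month spanning two decades; e = c/k,
default k = 2), or unconstrained (`independent`). Detection models:
perfect; per-replicate Bernoulli(d); or depth-based — latent relative
abundances drawn from a species-abundance distribution (default 20%
lognormal core, 80% log-series satellite; these fractions are package
defaults, not field estimates), optionally jittered per sample on the
log scale, and observed as multinomial read counts at a fixed depth.
The `dynamics=False` depth preset is the *SAD-only null*: a community
with no dynamics at all, whose apparent colonizations and extinctions
are purely sampling artefacts (default depth 2000 reads over 300 taxa,
chosen so a realistic fraction of taxa sits near the detection limit).

What the generator does not emulate: compositional correlations between
taxa beyond the shared multinomial draw, time-varying or
covariate-driven rates, sequencing error and chimeras, and phylogenetic
correlation of rates. Passing tests therefore demonstrate correctness
of the estimation and testing machinery under the stated model, not
robustness to those real-data features.

## Estimation noise and the recovered slope

Per-taxon estimates from short series are noisy, and that noise does
not cancel in the trade-off regression. The reference study conditions
(300 taxa, k = 2, c log-uniform in [0.02, 2] per month, 24 monthly
samples) put the median taxon at (c+e)Δt ≈ 0.3, i.e. one to three
observed events per direction, so log ĉ carries a variance comparable
to the true spread of log c across taxa. Errors-in-variables then
attenuates the OLS slope of log p̂ on log ĉ toward zero: the pooled
10-seed slope under these conditions is ≈ −0.48, not −1, even though
the same pipeline at 480 samples per taxon returns −0.99. The noise
geometry matters: uncertainty in the total rate c+e moves a point
exactly along the −1 line (harmless), while uncertainty in occupancy —
dominant for slow, nearly frozen chains — flattens the fit. Two
corollaries, both visible in the test-suite: (i) the slope from short
series should be read as a lower bound on the trade-off's steepness,
and (ii) the SAD-only null also produces a *negative* spurious slope
(≈ −0.5) through the same mechanism, so distinguishing a real trade-off
from artefact at short series lengths requires the slope's value, its
CI, and the null comparison together — not the sign alone. Guild-level
(pooled) estimation, which multiplies the transitions behind each
point, is the practical route to faithful slopes on real data.

## Numerical and design choices

Natural logarithms internally; log10 only for display. Counts tables
are accepted taxa-as-rows or taxa-as-columns behind an explicit flag.
Time stamps are floats (days); no date parsing. The pipeline performs
the core/satellite split independently at each analyzed rank. The CLI
is a thin layer over the library; configuration can come from a TOML
file with flags taking precedence, and every run logs seed and
configuration. Degenerate inputs fail loudly: all-absent groups,
constant-occupancy tables, non-positive rates in regressions, and
unknown taxonomy ranks raise structured errors naming the offender.
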
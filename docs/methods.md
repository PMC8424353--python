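# Methods

This note documents the statistical machinery behind `icedrift`, the
defaults it ships with and why, what the synthetic-data generators do
and do not emulate, and the numerical choices a user auditing results
will want to know about.

## Study design and grouping

The unit of analysis is the spatio-temporal group: all individuals
sampled in one geographic area during one multi-year period. Defaults
mirror a two-decade polar bear monitoring design: four areas
(NWS/NES/SWS/SES) crossed with five periods (1995–1999, 2000–2004,
2005–2009, 2010–2014, 2015–2016). Period bins are configuration-driven
so alternative temporal divisions can be replayed. Groups with fewer
than 10 individuals are excluded (`min_n` configurable; the cut is
strict: a group of exactly 10 is kept). Missing genotypes are dropped
per locus, not per individual, to maximize per-locus sample sizes.

Allele identity is the fragment size in base pairs on the locus's
repeat lattice; Genepop 2/3-digit codes map to sizes through an
optional offset. This matters because the M-ratio needs true sizes and
repeat units, not arbitrary labels.

## Estimators

**Heterozygosity.** `H_E` is Nei's unbiased gene diversity per locus,
`(n/(n−1))(1 − Σ p̂²)` with `n` gene copies; means over loci are
unweighted. `H_O` is the fraction of typed heterozygotes. `F_IS` is the
multilocus ratio form `1 − ΣH_O/ΣH_E` (components summed over loci
before division), matching the "mean inbreeding coefficient" usage in
monitoring tables; Weir–Cockerham would be a natural extension but is
not what those tables report.

**Rarefaction.** `A_R(g)` and `A_P(g)` use the hypergeometric
rarefaction identities, evaluated in exact rational arithmetic
(`fractions.Fraction` over integer binomials) and converted to float
at the end. This costs little at microsatellite scales and makes the
estimators bit-identical to exhaustive enumeration over gene-copy
subsamples, which the test suite exploits as an oracle. The default
`g` is the smallest per-locus gene-copy count across all retained
groups (the largest size every group supports); a per-area variant is
available through configuration.

**Relatedness.** `r_w` is the mean over within-group dyads of the
Queller–Goodnight estimator, multilocus ratio-of-sums form, symmetrized
over the dyad orderings. Reference allele frequencies come from the
pooled sample of the same period, never the dyad itself. This is not a
cosmetic choice: if the focal group itself is the reference, the mean
over all its dyads is algebraically pinned near `−1/(n−1)` and kin
structure becomes invisible; a pooled reference restores sensitivity of
the group mean to within-group kin.

**Differentiation.** Per locus, `H_S` and `H_T` are the Nei–Chesser
bias-corrected components using the harmonic mean `ñ` of per-group
individual counts: `H_S = (2ñ/(2ñ−1)) h_s` and
`H_T = h_t + H_S/(2ñk)` where `h_s`, `h_t` are the observed within- and
total-pool gene diversities. Components are averaged across loci first
and ratios formed once (ratio-of-averages, not average-of-ratios),
which reduces small-sample ratio bias. From the averaged components:
`G_ST = (H_T−H_S)/H_T`, `G″_ST = k(H_T−H_S)/[(kH_T−H_S)(1−H_S)]`
(Hedrick–Meirmans standardization, maximum 1 given within-group
diversity) and Jost's `D = (k/(k−1))(H_T−H_S)/(1−H_S)`. Estimates are
reported as computed; small negatives from the bias correction are not
truncated (duplicated finite samples therefore give values near, not
exactly at, zero — of order `−h_s/2(ñ−1)`). Downstream beta models
clamp instead.

## Trend models

Responses on the real line (`A_R`, `r_w`) are fitted by Gaussian
maximum likelihood; responses in (0,1) (`H_O`, `H_E`, `G″_ST`) by beta
regression with a logit mean link and a common precision. Candidate
designs combine the period index (continuous 1..5 or categorical) and
area (or area pair) as fixed effects: `time`, `area`, `time+area`,
`time×area`, `period_cat`, `period_cat+area`. Area enters as a fixed
effect rather than a random intercept: with only 4 areas (6 pairs) a
variance component is degenerate, and the scientific contrast — the
time effect — is unchanged. Model ranking uses
`AICc = −2logL + 2p + 2p(p+1)/(n−p−1)` with `p` counting every
estimated parameter (including σ or the beta precision), and Akaike
weights `ω_i = exp(−Δ_i/2)/Σ exp(−Δ_j/2)`.

Confidence intervals are Wald intervals at the 97.5% two-sided level
(z ≈ 2.241), following the reporting convention of the monitoring
analyses this package serves. Boundary responses are clamped to
`[1e−4, 1−1e−4]` before the beta likelihood, with every clamped value
logged (relevant for near-zero differentiation in early periods). If
the L-BFGS fit flags an abnormal line search, the optimizer is
restarted through a Nelder–Mead pass; a stationary point with gradient
below 1e−3 is accepted.

The sign test on differentiation changes pools consecutive-period
differences within each area-pair series, drops ties (logged), and
returns the exact two-sided binomial p (doubled smaller tail, capped
at 1). The period index doubles as the climate proxy: in the
motivating design it is nearly collinear with the decline in mean sea
ice extent, and an explicit covariate column can replace it.

## Bottleneck tests

**M-ratio.** `M = k / (1 + (max−min)/repeat_unit)` per polymorphic
locus; alleles off the lattice are an error, monomorphic loci are
excluded with a warning. The group mean is flagged at the conventional
strict `M < 0.7`.

**Heterozygosity excess.** For each locus with `k ≥ 2` alleles among
`n` gene copies, the mutation–drift-equilibrium distribution of
unbiased `H` conditional on exactly `k` alleles is simulated by a
coalescent sampler: the Ethier–Griffiths urn replays the time-reversed
event sequence (with `j` lineages, the number of mutations before the
next coalescence is geometric with success probability
`(j−1)/(θ+j−1)`) forward from the common ancestor, so no genealogy is
stored. Mutation is strict SMM or a two-phase model (default multistep
probability 0.22, geometric mean jump 3.1 — the conventional defaults
of this test family, exposed as configuration because real analyses
scan a parameter grid). θ is calibrated per `(n, k)` by bisection on
the simulated expected allele count; conditioning on `k` is by
rejection (capped at 10⁶ draws); distributions are memoized per
`(n, k, model, reps)`.

Combining loci: the spec-classical construction applies a Wilcoxon
signed-rank test to `(H_obs − mean H_eq)/SD(H_eq)`. Measured under the
simulated SMM null, those deviations are left-skewed (median ≈ +0.2,
P(dev>0) ≈ 0.57), and the one-tailed Wilcoxon — which assumes symmetry
— rejects at ~14% for nominal 5%. `icedrift` therefore runs the
Wilcoxon on the normal quantile of each locus's conditional mid-p
value `P(H_eq < H_obs) + ½P(H_eq = H_obs)`, which is uniform under the
null, restoring the nominal error rate (measured ≈ 0.05–0.07 over
hundreds of null panels). The raw standardized deviation is still
reported per locus for comparability. The Wilcoxon null is exact up to
25 loci (covering a 22-locus panel), normal-approximate beyond; at
least 4 usable loci are required.

## Forward simulation

Two engines share one scenario vocabulary.

**Yearly engine.** Individuals carry age, sex, genotype and a female
breeding cooldown. Each year, in order: Bernoulli stage survival
(cubs ages 0–1, subadults 2–4, adults 5+; death at `max_age`), aging,
migration of subadults and adults (cubs move with mothers, implemented
by restricting movement to age ≥ 2), mating (available adult females ×
random adult males within patch, polygynous), reproduction (litter of
1/2/3 cubs; each transmitted allele mutates at rate μ by ±1 repeat,
reflected at one repeat), density regulation by uniform culling to
`K(t)`. A female's cooldown of 3 years enforces the 3-year
reproductive cycle. One reported "generation" is 12 years.

Demographic defaults: σ_cub = 0.72, σ_subadult = 0.85,
σ_adult = 0.93, maturity at 5, litter probabilities (0.3, 0.6, 0.1)
for sizes (1, 2, 3), `max_age` = 25, K = 250 per patch. The adult and
subadult survivals are the published vital-rate range for the species;
the age cap reflects longevity in the wild and is what keeps the mean
parental age near the species' ~12-year generation time (without it,
open-ended 0.93 survival pushes the mean parental age past 17).
σ_cub = 0.72 sits inside published cub-survival ranges and is the
lowest value at which this life table is self-sustaining (R₀ ≈ 1.15)
under the age cap; at 0.65 the population declines deterministically.
`measure_generation_time` reports the realized mean parental age
(~11–12.5 years with defaults), and the test suite checks it.

**Generation engine.** A fast non-overlapping-generations mode for
multi-replicate runs and analytic checks: migration, then random union
of gametes within each patch — every gamete picks a uniform parent, so
the census-`N` drift recursion `E[H_{t+1}] = (1 − 1/2N) E[H_t]` holds
exactly for unbiased gene diversity, and the Crow–Denniston variance
effective size `N_e = (4N−2)/(V_k+2)` is exact given the realized
offspring-number variance `V_k`, which the engine records.

**Scenarios.** `m0` is a total per-generation emigration probability
split equally across admissible destinations.

1–3: constant K, symmetric gene flow 0.50 / 0.25 / 0.001.
4: gene flow divided by 10 every 30 generations (continuous
   `m0·10^(−t/30)`), K declining exponentially to 2.5% of its initial
   value over the horizon (97.5% decline).
5: as 4, but flow between the northern and southern patch pairs is
   asymmetric (north→south at `m0`, south→north at `m0/2`) and ramps
   linearly to complete isolation at generation 10; within-region flow
   persists.
6: as 5, founders bootstrapped from an empirical or synthetic genotype
   dataset (areas map to patches; missing genotypes refilled from
   same-area donors).

The pre-fragmentation baseline rate for scenarios 4–6 is `m0 = 0.25`
(the moderate-connectivity value); the exact asymmetric matrix of
scenario 5 is not externally specified, so both choices are exposed as
parameters. In yearly mode, per-generation migration rates are applied
as yearly hazards of `m(t)/12`, a first-order approximation that keeps
per-generation flux comparable between engines.

Trajectories record `A_N`, `H_O`, `H_E` (via the divstats estimators on
a random sample per patch, default 50) and global `G_ST` across
patches, plus per-patch census; replicates run on independent
seed-sequence substreams and are bit-reproducible given a seed.

## Synthetic data

`generate_structured_series` draws, per period, locus pools deformed so
pool gene diversity follows a logit-linear path (mixing each locus's
spectrum toward its major allele, with the mixing weight solved in
closed form), then per-area frequencies from the Balding–Nichols model
at the period's target F_ST (Dirichlet with concentration
`(1−F)/F` around the pool), then HWE genotypes. Under this model the
expected Nei–Chesser global G_ST over k areas is
`F(1−1/k)/(1−F/k)`, which the tests verify against realized estimates.
Mother–offspring dyads are injected by replacing a fraction of
individuals with Mendelian offspring of same-group mothers. Defaults
emulate the monitoring design's scale: 22 loci with 5–12 alleles on a
2-bp lattice, 30 individuals per group (~600 total), F_ST starting
at 0.01.

What the generator does not emulate: genotyping error and allelic
dropout, null alleles, linkage between loci, overlapping generations
within a period, spatial structure within areas, and the real
allele-frequency spectra of any particular population. Passing
parameter-recovery tests on these data shows the estimators and models
are correct and calibrated under their own assumptions, not that any
specific field dataset satisfies those assumptions.

`generate_trend_series` draws group-level statistic series directly
from the fitted model families with a known slope: Gaussian noise for
`A_R` (σ = 0.17) and `r_w` (σ = 0.038), beta noise for `H_E`
(φ = 800) and `G″_ST` (φ = 120), on a 4-area × 4-period (16-row)
design. The noise magnitudes were chosen so the resulting slope
standard errors match the uncertainty characteristic of 16-group
microsatellite monitoring designs at these intercepts; they are the
conditions under which CI calibration is assessed.

## Problem sizes and reproducibility

Simulation-backed checks use: 200 replicate series per trend response;
200 drift replicates at N = 50 over 20 generations; 500 null panels at
10⁴ conditioned equilibrium draws per (n, k) for the excess-test
calibration; 50 replicates per scenario over 100 generations in the
generation engine. All randomness flows from explicit seeds or
seed-sequence substreams; the pipeline manifest records the master
seed and every default in effect, and a rerun with the same
configuration reproduces outputs byte-identically.

## Known limitations

- No jackknife/bootstrap CIs over loci for the diversity and
  differentiation tables (extension point).
- The beta/linear trend models treat group-level statistics as
  observations with exchangeable noise; sampling covariance between
  groups sharing individuals (area pairs) is ignored, as in the
  standard workflow.
- Null-allele co-estimation is out of scope; bottleneck tests run on
  raw genotypes.
- The yearly engine's mating system is polygynous random mating within
  patch; no explicit pair bonds, dispersal kernels or senescent decline
  in fecundity before `max_age`.
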
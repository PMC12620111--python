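# Methods

This note documents the models implemented in `sourcesink`, their
assumptions, the synthetic-data generator that exercises them, and the
numerical choices a maintainer would want to know. Notation: populations
*r, s*; calendar years *t*; age classes *a* ∈ {0 juvenile (<1 yr),
1 subadult (1–2 yr), 2 adult (>2 yr)}; tsi = years since the invasive
prey established in population *r* (tsi = 0 in the establishment year,
undefined before it).

## 1. Contribution metrics

The per-capita contribution of a member of population *r* in year *t* at
age *a* to next year's metapopulation is

    C_rta = φ_rrta + Σ_{s≠r} φ_rsta + M_rta (φ_rrt0 + Σ_{s≠r} φ_rst0),

with retention φ_rrta = S_rta ψ_rrta (survive and stay), emigration
φ_rsta = S_rta ψ_rsta (survive and move to *s*), and fecundity M_rta (the
expected number of female fledglings, whose own first-year fate is the
juvenile φ terms). The self-recruitment/retention component is
R_rta = φ_rrta + M_rta φ_rrt0, and the emigration contribution is
E = C − R, which equals Σφ_rsta + M_rta Σφ_rst0 exactly. Because each
movement row sums to one, C_rta = S_rta + M_rta S_rt0; in a closed
population this is the finite rate of increase. Annual C_rt, R_rt, E_rt
weight the subadult and adult values by the observed proportion of banded
birds in each class (juveniles enter only through the fecundity term).
These identities (row sums, φ decomposition, R + E = C, the closed-form
reduction) are enforced to 1e−12 in the test suite.

Assumptions inherited from the metric: one-year projection (no
multi-year reproductive value); subadult and adult survival/movement equal
(S_rt1 = S_rt2), fecundity free to differ; death and permanent emigration
out of the study area are not distinguished (the monitored populations
cover all breeding areas).

## 2. Survival and movement (multistate mark–resight)

Capture histories are modelled as a hidden Markov chain over states
{populations} ∪ {dead}, conditioned on the banding occasion. Annual
transition: survive with S (logit link: intercept, juvenile offset,
optional population effects, optional tsi response with an optional
juvenile×tsi linear interaction); given survival, move by a
multinomial-logit row with fidelity as the reference category and
destination logits shared (`shared`), per-origin (`by_origin`) or
per-ordered-pair (`full`). Destinations not yet available in the arrival
year are masked to probability zero and the row renormalises over fidelity
plus the remainder (an all-masked row degenerates to fidelity 1, not an
error). Emission: resighted in the occupied population with probability
p (constant or per-population; the dead state is never resighted).

The likelihood is a scaled forward recursion vectorised across
individuals; it is verified against brute-force enumeration over all
latent state paths (≤4^5 paths at 3 populations × 5 occasions) to 1e−10,
and is invariant to label permutation and to appending unobservable
(p = 0) occasions. Maximisation is multi-start L-BFGS-B (default 5
seeded jittered starts, jitter SD 0.5, projected-gradient tolerance
1e−8); standard errors come from the inverse central-difference observed
information, with near-null eigendirections (eigenvalue < 1e−8 × scale)
reported as flat (inestimable) and the covariance taken as a
pseudo-inverse. Natural-scale SEs for S, ψ, p use a finite-difference
delta method through the link functions.

Population-years in which no marked bird was observed (nobody at risk of
a recorded transition out of that population-year) are flagged by the
estimability screen and excluded from the source–sink stage, as are years
before a population becomes available.

## 3. Fecundity components

M_rta = θ_rta × N_rt × P_rt × Y_rt, the four factors estimated from
separate data and combined with first-order delta SEs treating them as
independent. M_rt0 ≡ 0 (juveniles do not breed). Nest success and
fledged models carry no age terms (nest fate is driven by external
conditions, not parent age).

**Breeding and attempts.** For each resighted subadult/adult-year with
observed attempt count k, the marginal likelihood over the latent breeder
state and latent true attempt count K is

    L = (1−θ)·1[k=0] + θ Σ_{K≥max(k,1)}^{K_max} ZTP(K; λ) Binom(k; K, p_det),

with θ on the logit scale (intercept + adult contrast + optional tsi
terms), λ on the log scale (intercept + optional tsi terms) and p_det the
per-attempt detection probability. K_max defaults to 30; pushing it past
10λ changes the log-likelihood by < 1e−8 (tested). Identical
(count, covariate) rows are pooled with weights before optimisation. The
expected number of attempts given breeding is the zero-truncated-Poisson
mean N = λ/(1−e^{−λ}) (→1 as λ→0), with a delta-method SE.

*Identifiability.* With p_det free this model is structurally
non-identifiable from annual counts: thinning a Poisson(λ) gives a
Poisson(λ p_det), and the K = 0 term of the untruncated sum only ever
feeds the k = 0 cell, so for k ≥ 1

    P(k) = [θ/(1−e^{−λ})] · Pois(k; λ p_det),

and the observable distribution depends on exactly two functions of the
three parameters: μ = λ p_det and A = θ/(1−e^{−λ}). Every triple along
the ridge {λ ≥ μ, p_det = μ/λ, θ = A(1−e^{−λ})} fits identically (we
confirmed excess KL = 0 numerically along this ridge). The fitter
therefore supports a fixed p_det — the pipeline's default, representing an
external detection estimate such as a double-observer or visit-history
study — and reports the flat direction (huge SEs, `flat_directions`) when
p_det is left free. With p_det fixed at 1 the estimates are conditional
on detected attempts and are a lower bound on fecundity. A corollary used
in testing: λ·p_det is identified even when the individual parameters are
not.

**Nest success.** Each interval between nest checks contributes a
Bernoulli fate with complementary log-log link on interval mortality and
the log of exposure days as offset: an interval of d days survives with
probability exp(−d·e^η), η the log daily hazard (intercept + optional tsi
terms), so daily survival is s = exp(−e^η) and nest success over the
L-day cycle is P = s^L (L = 58 days by default, the species' incubation
plus nestling period). The likelihood is invariant to splitting a
survived interval (−d·h = −d₁h − d₂h), the constant-hazard analogue of
interval-censored exposure models. A dataset with no failures puts the
hazard on its boundary; the fit is returned flagged rather than chasing an
infinite coefficient.

**Fledged young.** Poisson log-link on fledged counts of successful
nests; female young Y = mean/2 under a 1:1 sex ratio.

**Random intercepts.** Both nest-level models carry crossed population
and year random intercepts b_g ~ N(0, σ_g²), integrated out by a Laplace
approximation: inner Newton maximisation over the (n_pop + n_year)
conditional modes with analytic first/second derivatives, then the
log-determinant correction; the outer profile over (β, log σ) uses
Nelder–Mead followed by an L-BFGS polish. On a 400-observation fixture
the fits agree with R glmmTMB to ~1e−4 in β, log-likelihood and σ (frozen
cross-check in the test suite). σ estimated below 1e−4 is flagged as a
boundary fit, and a fixed-effects fallback (population/year one-hot
encoded) is available for degenerate designs. Prediction SEs propagate
fixed-effect uncertainty only; conditional-mode uncertainty is not added
(a known understatement, footnoted under limitations).

## 4. Time-since-invasion models and AICc

Candidate tsi responses per vital rate: null, linear (β·tsi), quadratic
(β₁·tsi + β₂·tsi²), log (β·ln(tsi+1) — finite at tsi = 0). Pre- and
post-invasion are handled in one likelihood: a post-invasion step
indicator carries the level shift and tsi effects are active only after
invasion, so the pre-invasion years estimate their own level, mirroring a
separately estimated pre-invasion value. tsi enters in raw years on the
link scale. Survival candidates optionally add a juvenile×tsi linear
interaction.

Models on identical data are ranked by AICc = −2logL + 2k + 2k(k+1)/
(n−k−1); effective n is the number of individuals (multistate, breeding),
intervals (nest survival) or successful nests (fledged). Ties break by
smaller k, then label. The pipeline ranks multistate candidates in two
passes — survival forms under null movement, then movement forms under
the winning survival form — keeping the candidate count linear rather than
multiplicative; estimates feeding the contribution stage come from each
top-ranked model.

## 5. Uncertainty propagation and classification

For each retained population-year, 10,000 bootstrap replicates redraw
every component from distributions matched to its estimate and SE: betas
for probabilities (survival by age group, fidelity and each destination —
the row renormalised onto the simplex — breeding probability by age, nest
success) and log-normals for positive means (attempts, female fledged).
Moment inversions are closed-form and round-trip exactly:
beta α = m·f, β = (1−m)·f with f = m(1−m)/sd² − 1; log-normal
σ² = ln(1+sd²/m²), μ = ln m − σ²/2. sd = 0 degenerates to a point mass;
infeasible beta moments (sd² ≥ m(1−m)) raise an error, or — at the
pipeline layer — are clamped to 99% of the feasible bound with a recorded
quality flag. Draws are independent across parameters and replicates (no
cross-parameter correlation structure is estimated).

Each replicate computes age-weighted C, R and E = C − R; the 0.025/0.975
replicate quantiles give the 95% interval. Classification: **source** if
the lower quantile exceeds 1, **sink** if the upper quantile is below 1,
**stable** otherwise; the **dependent source** flag uses point estimates
(C > 1 and R < 1). With all SEs zero the intervals collapse and the class
equals the sign of C − 1. In a parametric-bootstrap consistency check
(estimates drawn around truth from the same families, 208 population-years)
the 95% intervals cover the true C at the nominal rate (90–98%).

## 6. The synthetic-data generator

The generator is the package's test bed: it emulates a range-wide,
multi-decade banding and nest-monitoring program for a wetland raptor
whose prey base was invaded population-by-population.

Default study design (`default_schedule`): six populations, 28 annual
occasions (1996–2023), invasion years staggered 2001–2013, one population
(PAY) holding no birds until its invasion year — it lacks pre-invasion
data and only then becomes a movement destination, exercising the
availability masking. Cohorts: 30 nestlings (banded at fledging, age 0)
plus 4 adults newly banded per population-year, ≈5,700 marked birds over
the study — the scale of a real long-term raptor program.

Default truth surface (`default_truth`), chosen to reproduce the
qualitative post-invasion demography of this system — an early boost that
decays, survival drifting up, emigration rising then falling:

| rate | pre-invasion level | tsi response (link scale) |
|---|---|---|
| adult breeding θ | 0.30 | step +0.93, −0.1085·tsi, +0.002·tsi² → 0.52 at tsi 0, 0.34 at tsi 8 |
| subadult breeding | 0.14 | same response, lower intercept |
| attempts rate λ | 1.10 | step +0.25, +0.05·tsi, −0.004·tsi² (peak ≈ tsi 6) |
| nest daily survival | 0.970 (success 0.17) | step only (−0.45 on hazard) → 0.981 (success 0.33) |
| fledged/successful nest | 1.90 | weak linear decline −0.01/yr |
| survival (adult, juv) | 0.85, 0.60 | +0.02/yr (logit), juvenile interaction −0.005/yr |
| emigration (dest. logits) | total ≈ 0.13 | +0.30·tsi − 0.03·tsi² (peak ≈ tsi 5) |
| resight p | 0.70 | constant |
| attempt detection p_det | 0.80 | constant |

The survival slope corresponds to a reported ~0.1-per-unit logit effect on
a standardised (≈5-year-SD) invasion-time covariate, converted to raw
years. Magnitudes produce pre-invasion sink conditions (C ≈ 0.90),
early-invasion sources (C ≈ 1.1) and late-invasion sinks — the
early-source/late-sink signature.

Mechanics: lives simulated year-by-year (survive → move among available
populations → age, capped at adult); resight Bernoulli per year with the
banding occasion always recorded; breeder records only for resighted
subadult/adult-years (as in real mark–resight data — an undetected bird
contributes no row); attempts zero-truncated Poisson given breeding;
observed attempts a binomial thinning (so observed ≤ true always); each
detected attempt becomes a monitored nest whose fate runs day-by-day at
constant daily survival over the 58-day cycle, chopped into visit
intervals spaced uniformly 2–21 days. Fledged counts for successful nests
are 1 + Poisson(mean − 1) — exact mean, support ≥ 1 — although the fitting
module uses an untruncated Poisson; a `fledged_dist="ztp"` switch draws a
zero-truncated Poisson instead (slightly inflated mean). This
simulator/fitter mismatch is deliberate and small at the default mean
(1.9).

What the generator does **not** emulate — so what passing tests do not
show about field data: within-season survey structure (annual occasions
only), hydrology/drought covariates, spatial structure within populations,
density dependence, sex differences (1:1 assumed throughout), band loss,
unbanded breeders at nests, heterogeneous detection, and transience or
memory in movement. Parameter recovery here demonstrates correctness of
the estimators under the stated model, not robustness to those
violations.

## 7. Reproducibility and problem sizes

A master seed feeds named SHA-256 substreams (simulate / fit / bootstrap,
each < 2³¹), so stages rerun independently and byte-identically; every
output CSV carries the config hash and seeds in a comment header, and the
pipeline writes a manifest sufficient to reproduce a run.

The test and acceptance workloads use scaled study sizes chosen to keep
the full suite in the tens of minutes on one core: recovery studies at
2,000 individuals × 10 occasions (100 replicates for interval coverage),
2,000 nest intervals, 2,000 breeder-years; selection-power studies at 50
replicates; and 20 end-to-end replicates of the 6-population × 28-year
design with reduced cohorts (15 banded per population-year), trimmed
candidate sets and 2,000 bootstrap replicates. The acceptance script runs
the full default design (≈5,700 birds, full candidate sets, 10,000
replicates) once.

## 8. Known limitations

- Wald/delta uncertainty throughout; no profile likelihoods or posterior
  distributions. The bootstrap propagates parameter SEs, not full
  sampling covariance between vital rates (components are drawn
  independently, matching the analysis design but ignoring any shared
  years).
- GLMM prediction SEs omit conditional-mode (random-intercept)
  uncertainty.
- The breeding/attempts detection probability must be supplied externally
  (see §3); estimates conditional on p_det = 1 bound fecundity from
  below.
- The two-pass multistate ranking is greedy; a full factorial
  survival×movement candidate set is exact but quadratic in forms.
- The estimability screen is data-occupancy based (plus flat-direction
  flags from the information matrix); it does not compute per-parameter
  profile likelihoods.
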
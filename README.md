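# sourcesink

Annual source–sink inference for spatially structured animal populations
from individual mark–resight and nest-monitoring data.

The motivating system is a long-term study of an endangered wetland raptor
(the Everglade snail kite) whose six Florida populations were invaded, in
different years, by a novel prey species — an invasive apple snail that
boosted food supply and reshaped the birds' demography. The package is for
population ecologists who want to ask the same question of comparable
systems: *how much does each local population contribute, per capita, to
the metapopulation each year, and how does that contribution shift as an
environmental change (here, time since prey invasion) unfolds?*

Because the original 28-year field data set is not required, the package
ships a first-class synthetic-data generator that emulates the study
design — staggered invasion years, age-structured survival, multinomial
movement among available wetlands, imperfect resighting, and nest visits
every 2–3 weeks — so the entire inference chain is testable end to end
against known truth.

## The model

Per-capita contribution of a member of population *r* in year *t* at age
*a* (ages: 0 juvenile, 1 subadult, 2 adult; subadult and adult survival and
movement constrained equal):

```
C_rta = φ_rrta + Σ_{s≠r} φ_rsta + M_rta (φ_rrt0 + Σ_{s≠r} φ_rst0)
R_rta = φ_rrta + M_rta φ_rrt0              (retention + self-recruitment)
E_rt  = C_rt − R_rt                        (emigration contribution)
```

where φ_rrta = S_rta ψ_rrta (survive **and** stay), φ_rsta = S_rta ψ_rsta
(survive **and** move to *s*), and movement rows satisfy
1 − ψ_rrta = Σ_{s≠r} ψ_rsta. Annual values age-weight the subadult and
adult terms by the observed proportions of banded birds in each class.
Because movement rows sum to one, C_rta reduces to S_rta + M_rta S_rt0 —
the finite rate of increase of a closed population.

Fecundity decomposes into four separately estimated components,

```
M_rta = θ_rta × N_rt × P_rt × Y_rt
```

— breeding probability (marginal maximum likelihood over a latent breeder
state and zero-truncated-Poisson attempt count, with per-attempt
detection), expected attempts given breeding (the ZTP mean λ/(1−e^−λ)),
nest success (complementary log-log daily-hazard model with exposure-day
offsets, raised to the ~58-day nesting cycle), and female fledged per
successful nest (Poisson, halved for a 1:1 sex ratio). Nest-level models
carry population and year random intercepts (Laplace-approximate marginal
likelihood). Survival and movement come from a multistate mark–resight
model (hidden Markov over populations plus an absorbing dead state) fitted
by maximum likelihood.

Each vital rate is modelled against **time since invasion** (tsi) with
candidate null / linear / quadratic / log forms (± an age interaction for
survival), ranked by AICc; estimates from the top-ranked model feed the
source–sink stage. Uncertainty is propagated by a 10,000-replicate
parametric bootstrap (betas for probabilities, movement rows renormalised
onto the simplex; log-normals for count means); a population-year is a
**source** when the 95% interval of C_rt lies above 1, a **sink** below 1,
**stable** otherwise, and a **dependent source** when the point estimates
satisfy C_rt > 1 but R_rt < 1.

## Worked example

`examples/02_multistate_survival.py` simulates 2,010 capture histories
over 10 annual occasions (true adult survival 0.85, juvenile 0.60, resight
probability 0.7) and refits them:

```
simulated 2010 capture histories
log-likelihood -5274.1 with k=4 parameters, n=2010 individuals
adult/subadult survival: 0.853 +/- 0.007  (truth 0.85)
juvenile survival      : 0.589 +/- 0.016  (truth 0.60)
resight probability    : 0.690            (truth 0.70)
fidelity (stay in A)   : 0.933 +/- 0.004  (truth 0.931)
retention phi_rr 0.795 + emigration 0.057 = survival 0.853
```

Every true rate is recovered within sampling error, and the last line shows
the exact decomposition of survival into retention plus emigration that the
contribution metric is built on. The other examples walk the remaining
stages: `01` the synthetic study design, `03` the four fecundity
components, `04` AICc selection of the invasion-time form, and `05` the
full pipeline ending in source/sink/stable classifications — on a reduced
study it prints, e.g., mean years-since-invasion of 5.1 for
population-years at or above replacement (C ≥ 1) versus 10.9 below,
the early-source/late-sink signature of the invasion.

A thin CLI wraps the same pipeline:

```sh
sourcesink pipeline --config examples/demo_config.yaml --out demo_run
```

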
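"""Estimate the four fecundity components and combine them.

Per-female fecundity decomposes as breeding probability x expected nesting
attempts x nest success x female young per successful nest.  Breeding and
attempts come from a marginal-likelihood mixture over the latent breeder
state (attempt detection supplied externally — annual counts alone cannot
separate detection from the attempt rate); nest success from a cloglog
daily-hazard model with exposure-day offsets; fledged young from a Poisson
model.  The nest-level models carry population and year random intercepts.
"""

import sourcesink as ss
from sourcesink.fecundity import (BreedingAttemptsSpec, expected_attempts,
                                  fecundity, fit_breeding_attempts,
                                  fit_fledged, fit_nest_survival, nest_success)

schedule = ss.default_schedule()
truth = ss.realize_truth(schedule, ss.default_truth())
dataset = ss.simulate_dataset(truth, schedule, ss.CohortDesign(20, 4), seed=11)

breeding = fit_breeding_attempts(
    dataset.breeders, schedule,
    BreedingAttemptsSpec(theta_tsi="quadratic", attempts_tsi="quadratic",
                         fix_p_det=0.8),
    n_starts=1)
nest = fit_nest_survival(dataset.nests, schedule, tsi_form="null")
fledged = fit_fledged(dataset.nests, schedule, tsi_form="null")

r, year = "SJM", 2006   # five years after invasion in SJM
ri, ti = schedule.index(r), schedule.year_index(year)

theta, theta_se, lam, lam_se = breeding.predict(r, year, age_class=2)
N, N_se = expected_attempts(lam, lam_se)
dsr, dsr_se = nest.predict_daily_survival(r, year)
P, P_se = nest_success(dsr, cycle_length=58, se=dsr_se)
m, m_se = fledged.predict_fledged(r, year)
Y, Y_se = m / 2, m_se / 2   # 1:1 sex ratio: half of fledglings are female

M, M_se = fecundity(theta, N, P, Y, age_class=2,
                    ses=(theta_se, N_se, P_se, Y_se))

print(f"{r} {year} (tsi {schedule.tsi(r, year)}), adult females:")
print(f"  breeding probability  {theta:.3f} +/- {theta_se:.3f}   "
      f"(truth {truth.theta[ri, ti, 2]:.3f})")
print(f"  attempts given breeding {N:.3f} +/- {N_se:.3f}   "
      f"(truth {truth.attempts_mean[ri, ti]:.3f})")
print(f"  nest success (58-day) {P:.3f} +/- {P_se:.3f}   "
      f"(truth {truth.nest_success[ri, ti]:.3f})")
print(f"  female fledged/success {Y:.3f} +/- {Y_se:.3f}   "
      f"(truth {truth.female_fledged[ri, ti]:.3f})")
Mt, _ = truth.fecundity()
print(f"  => fecundity M {M:.3f} +/- {M_se:.3f}   (truth {Mt[ri, ti, 2]:.3f})")
print("\nM is the expected number of female fledglings per adult female; it")
print("feeds the juvenile-recruitment term of the contribution metric.")
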
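"""Rank time-since-invasion covariate forms for survival by AICc.

Generates mark-resight data whose true survival rises linearly with years
since invasion (0.1 per year on the logit scale) and asks AICc to choose
among null, linear and quadratic forms.  The generating form should win.
"""

import numpy as np
from scipy.special import logit

import sourcesink as ss
from sourcesink.selection import rank_models

schedule = ss.InvasionSchedule(populations=("A", "B", "C"),
                               invasion_year={"A": 2000, "B": 2003},
                               study_years=(2000, 2009))
surface = ss.TruthSurface(
    survival_intercept={0: float(logit(0.6)), 1: float(logit(0.8))},
    survival_tsi=ss.TsiEffect("linear", b1=0.1),
    move_dest_logit=-3.0, resight_p=0.7)
truth = ss.realize_truth(schedule, surface)

rng = np.random.default_rng(3)
lives = ss.simulate_lives(truth, schedule, ss.CohortDesign(45, 22), rng)
captures, _, _ = ss.simulate_observations(lives, truth, schedule, rng)
enc = ss.encode_histories(captures, schedule)

fits = {}
for form in ("null", "linear", "quadratic"):
    spec = ss.MultistateSpec(survival_tsi=form,
                             survival_post_step=(form != "null"),
                             movement_structure="shared")
    fits[form] = ss.fit_multistate(enc, schedule, spec, n_starts=1, gtol=1e-6)

ranking = rank_models(fits)
print(ranking.table.to_string(index=False,
                              float_format=lambda v: f"{v:.2f}"))
print(f"\nbest model: '{ranking.best_label}' (the generating form was linear)")
print("dAICc is the penalty-adjusted evidence gap to the best model; models")
print("within ~2 units are effectively indistinguishable.")
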
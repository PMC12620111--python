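"""Link-scale truth surfaces and the vital-rate table container.

The synthetic study is driven by a :class:`TruthSurface`: for each vital rate
a link-scale linear predictor built from a per-population (or per-age)
intercept, optional population/year offsets, and a time-since-invasion (tsi)
response evaluated only after invasion.  :func:`realize_truth` pushes the
surface through the inverse links to produce a :class:`VitalRateTable` of
true annual rates (SE = 0).  The same table type, with nonzero SEs, is what
the fitting pipeline emits, so the contribution machinery consumes a single
container whether rates are true or estimated.

Vital rates covered (indexed population r, year t, age a):

- ``theta``   breeding probability (logit link; ages 1 and 2, age 0 breeds
  never),
- ``attempts_lambda`` Poisson rate of nesting attempts given breeding (log
  link); the mean number of attempts is the zero-truncated mean
  ``lambda / (1 - exp(-lambda))``,
- ``daily_survival`` nest daily survival (complementary log-log on the daily
  hazard), with nest success ``daily_survival ** cycle_length``,
- ``fledged_mean`` young fledged per successful nest (log link); female
  young assume a 1:1 sex ratio,
- ``survival`` annual survival (logit; juvenile vs older, subadult = adult),
- ``psi`` annual movement rows (multinomial logit, fidelity as reference,
  masked and renormalised to available destinations).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .schedule import InvasionSchedule, TSI_FORMS

__all__ = ["TsiEffect", "TruthSurface", "VitalRateTable", "realize_truth",
           "ztp_mean", "default_truth", "default_schedule"]


def ztp_mean(lam: np.ndarray | float) -> np.ndarray | float:
    """Mean of the zero-truncated Poisson, ``lam / (1 - exp(-lam))``.

    Continuous at 0+ (limit 1); raises for non-positive rates.
    """
    lam_arr = np.asarray(lam, dtype=float)
    if np.any(lam_arr <= 0):
        raise ValueError("zero-truncated Poisson rate must be positive")
    out = lam_arr / -np.expm1(-lam_arr)
    return float(out) if np.isscalar(lam) else out


@dataclass(frozen=True)
class TsiEffect:
    """Post-invasion response on the link scale.

    Contribution to the linear predictor for a population-year with
    time-since-invasion ``tsi``:

    ``step + b1 * z + b2 * z**2``  (quadratic)
    ``step + b1 * z``              (linear), ``step + b1 * ln(z + 1)`` (log)
    ``step``                       (null)

    and 0 before invasion.  ``step`` is the post-invasion indicator effect.
    """

    form: str = "null"
    step: float = 0.0
    b1: float = 0.0
    b2: float = 0.0

    def __post_init__(self) -> None:
        if self.form not in TSI_FORMS:
            raise ValueError(f"unknown tsi form {self.form!r}")

    def __call__(self, tsi: int | None) -> float:
        if tsi is None:
            return 0.0
        if self.form == "null":
            return self.step
        if self.form == "linear":
            return self.step + self.b1 * tsi
        if self.form == "quadratic":
            return self.step + self.b1 * tsi + self.b2 * tsi * tsi
        return self.step + self.b1 * float(np.log(tsi + 1.0))


def _expit(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


@dataclass(frozen=True)
class TruthSurface:
    """Link-scale coefficients generating every true vital rate.

    Intercepts are per age class where the rate is age-structured; optional
    population and year offsets perturb individual populations/years.  Each
    rate carries one :class:`TsiEffect`.  Movement is parameterised on the
    multinomial-logit scale: ``move_dest_logit`` is the baseline logit of
    each destination relative to fidelity (shared across destination pairs
    unless a per-pair dict is given), and ``move_tsi`` shifts all destination
    logits of an invaded origin.
    """

    # breeding probability theta (logit), ages 1 and 2
    theta_intercept: dict[int, float] = field(
        default_factory=lambda: {1: -1.8, 2: -0.85})
    theta_pop: dict[str, float] = field(default_factory=dict)
    theta_year: dict[int, float] = field(default_factory=dict)
    theta_tsi: TsiEffect = TsiEffect()

    # nesting attempts rate lambda (log)
    attempts_intercept: float = float(np.log(1.1))
    attempts_pop: dict[str, float] = field(default_factory=dict)
    attempts_year: dict[int, float] = field(default_factory=dict)
    attempts_tsi: TsiEffect = TsiEffect()

    # nest daily hazard (cloglog scale: log of the daily mortality hazard)
    nest_hazard_intercept: float = float(np.log(-np.log(0.97)))
    nest_pop: dict[str, float] = field(default_factory=dict)
    nest_year: dict[int, float] = field(default_factory=dict)
    nest_tsi: TsiEffect = TsiEffect()

    # fledged per successful nest (log)
    fledged_intercept: float = float(np.log(1.9))
    fledged_pop: dict[str, float] = field(default_factory=dict)
    fledged_year: dict[int, float] = field(default_factory=dict)
    fledged_tsi: TsiEffect = TsiEffect()

    # annual survival (logit); age 0 separate, ages 1 and 2 equal
    survival_intercept: dict[int, float] = field(
        default_factory=lambda: {0: 0.405, 1: 1.735})
    survival_pop: dict[str, float] = field(default_factory=dict)
    survival_year: dict[int, float] = field(default_factory=dict)
    survival_tsi: TsiEffect = TsiEffect()
    #: extra linear-tsi slope for juveniles (age x tsi interaction)
    survival_juv_tsi_slope: float = 0.0

    # movement: destination logit relative to fidelity
    move_dest_logit: float | dict[tuple[str, str], float] = -3.3
    move_tsi: TsiEffect = TsiEffect()

    # detection
    resight_p: float | dict[str, float] = 0.7
    attempt_detection_p: float = 0.8

    cycle_length: int = 58

    def with_(self, **kw) -> "TruthSurface":
        return replace(self, **kw)

    def to_dict(self) -> dict:
        from dataclasses import asdict

        d = asdict(self)
        if isinstance(self.move_dest_logit, dict):
            d["move_dest_logit"] = {f"{r}->{s}": v for (r, s), v
                                    in self.move_dest_logit.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TruthSurface":
        d = dict(d)
        for key in ("theta_tsi", "attempts_tsi", "nest_tsi", "fledged_tsi",
                    "survival_tsi", "move_tsi"):
            if key in d and isinstance(d[key], dict):
                d[key] = TsiEffect(**d[key])
        for key in ("theta_intercept", "survival_intercept", "theta_year",
                    "attempts_year", "nest_year", "fledged_year", "survival_year"):
            if key in d and isinstance(d[key], dict):
                d[key] = {int(k): float(v) for k, v in d[key].items()}
        if isinstance(d.get("move_dest_logit"), dict):
            d["move_dest_logit"] = {
                (k.split("->")[0], k.split("->")[1]): float(v)
                for k, v in d["move_dest_logit"].items()}
        return cls(**d)


@dataclass
class VitalRateTable:
    """True or estimated vital rates (means and SEs) on the natural scale.

    Arrays are indexed ``[population, year]`` (and age where applicable,
    age classes 0 juvenile / 1 subadult / 2 adult).  ``psi[r, s, t]`` is the
    probability of moving from ``r`` to ``s`` (diagonal = fidelity); each row
    sums to 1 over available destinations.
    """

    schedule: InvasionSchedule
    theta: np.ndarray          # (R, T, 3); age 0 slice is 0
    attempts_lambda: np.ndarray  # (R, T)
    daily_survival: np.ndarray   # (R, T)
    fledged_mean: np.ndarray     # (R, T)
    survival: np.ndarray         # (R, T, 3)
    psi: np.ndarray              # (R, R, T)
    resight_p: np.ndarray        # (R, T)
    attempt_detection_p: float = 1.0
    cycle_length: int = 58

    theta_se: np.ndarray | None = None
    attempts_lambda_se: np.ndarray | None = None
    daily_survival_se: np.ndarray | None = None
    fledged_mean_se: np.ndarray | None = None
    survival_se: np.ndarray | None = None
    psi_se: np.ndarray | None = None

    def __post_init__(self) -> None:
        R, T = len(self.schedule.populations), self.schedule.n_years
        if self.theta.shape != (R, T, 3):
            raise ValueError(f"theta shape {self.theta.shape} != {(R, T, 3)}")
        if self.psi.shape != (R, R, T):
            raise ValueError(f"psi shape {self.psi.shape} != {(R, R, T)}")
        for name in ("theta_se", "attempts_lambda_se", "daily_survival_se",
                     "fledged_mean_se", "survival_se", "psi_se"):
            if getattr(self, name) is None:
                ref = getattr(self, name[:-3])
                setattr(self, name, np.zeros_like(ref))

    # -- derived quantities ------------------------------------------------

    @property
    def attempts_mean(self) -> np.ndarray:
        """Expected attempts given breeding: zero-truncated Poisson mean."""
        return ztp_mean(self.attempts_lambda)

    @property
    def attempts_mean_se(self) -> np.ndarray:
        # delta method through N(lam) = lam / (1 - e^-lam)
        lam = self.attempts_lambda
        em = np.exp(-lam)
        dN = (1.0 - em - lam * em) / (1.0 - em) ** 2
        return np.abs(dN) * self.attempts_lambda_se

    @property
    def nest_success(self) -> np.ndarray:
        return self.daily_survival ** self.cycle_length

    @property
    def nest_success_se(self) -> np.ndarray:
        L = self.cycle_length
        return L * self.daily_survival ** (L - 1) * self.daily_survival_se

    @property
    def female_fledged(self) -> np.ndarray:
        """Female young per successful nest under a 1:1 sex ratio."""
        return self.fledged_mean / 2.0

    @property
    def female_fledged_se(self) -> np.ndarray:
        return self.fledged_mean_se / 2.0

    def fecundity(self) -> tuple[np.ndarray, np.ndarray]:
        """Expected female fledged per female, by (r, t, age), with SE.

        Product of breeding probability, expected attempts, nest success and
        female young per successful nest; identically 0 for juveniles.  The
        SE is first-order delta method treating the four components as
        independent (they come from separate fits on separate data).
        """
        comps = [self.theta, self.attempts_mean[..., None],
                 self.nest_success[..., None], self.female_fledged[..., None]]
        ses = [self.theta_se, self.attempts_mean_se[..., None],
               self.nest_success_se[..., None], self.female_fledged_se[..., None]]
        M = comps[0] * comps[1] * comps[2] * comps[3]
        rel_var = np.zeros_like(M)
        for c, s in zip(comps, ses):
            c_b, s_b = np.broadcast_to(c, M.shape), np.broadcast_to(s, M.shape)
            with np.errstate(divide="ignore", invalid="ignore"):
                rv = np.where(c_b > 0, (s_b / np.where(c_b > 0, c_b, 1.0)) ** 2, 0.0)
            rel_var = rel_var + rv
        se = M * np.sqrt(rel_var)
        M[:, :, 0] = 0.0
        se[:, :, 0] = 0.0
        return M, se

    def to_frame(self):
        """Long-format table: population, year, age_class, parameter, estimate, se."""
        import pandas as pd

        sched = self.schedule
        rows = []
        M, M_se = self.fecundity()
        for ri, r in enumerate(sched.populations):
            for ti, t in enumerate(sched.years):
                for a in (1, 2):
                    rows.append((r, t, a, "theta",
                                 self.theta[ri, ti, a], self.theta_se[ri, ti, a]))
                rows.append((r, t, None, "attempts",
                             self.attempts_mean[ri, ti], self.attempts_mean_se[ri, ti]))
                rows.append((r, t, None, "nest_success",
                             self.nest_success[ri, ti], self.nest_success_se[ri, ti]))
                rows.append((r, t, None, "female_fledged",
                             self.female_fledged[ri, ti], self.female_fledged_se[ri, ti]))
                for a in (0, 1, 2):
                    rows.append((r, t, a, "S",
                                 self.survival[ri, ti, a], self.survival_se[ri, ti, a]))
                    rows.append((r, t, a, "fecundity", M[ri, ti, a], M_se[ri, ti, a]))
                for si, s in enumerate(sched.populations):
                    label = "psi_rr" if si == ri else f"psi_rs:{s}"
                    rows.append((r, t, None, label,
                                 self.psi[ri, si, ti], self.psi_se[ri, si, ti]))
                rows.append((r, t, None, "p",
                             self.resight_p[ri, ti], 0.0))
        return pd.DataFrame(
            rows, columns=["population", "year", "age_class", "parameter",
                           "estimate", "se"])


def _pop_year_eta(intercept, pop_eff, year_eff, tsi_eff, schedule):
    """(R, T) linear predictor from intercept + offsets + tsi response."""
    R, T = len(schedule.populations), schedule.n_years
    eta = np.full((R, T), float(intercept))
    for ri, r in enumerate(schedule.populations):
        eta[ri] += pop_eff.get(r, 0.0)
        for ti, t in enumerate(schedule.years):
            eta[ri, ti] += year_eff.get(t, 0.0) + tsi_eff(schedule.tsi(r, t))
    return eta


def realize_truth(schedule: InvasionSchedule, coeffs: TruthSurface) -> VitalRateTable:
    """Evaluate a truth surface into true vital rates (SE = 0). Deterministic.

    Raises a :class:`KeyError`-derived configuration error naming the missing
    coefficient if an age-intercept set is incomplete.
    """
    R, T = len(schedule.populations), schedule.n_years
    for a in (1, 2):
        if a not in coeffs.theta_intercept:
            raise KeyError(f"theta_intercept missing age class {a}")
    for a in (0, 1):
        if a not in coeffs.survival_intercept:
            raise KeyError(f"survival_intercept missing age group {a}")

    # breeding probability: age 0 never breeds
    theta = np.zeros((R, T, 3))
    for a in (1, 2):
        theta[:, :, a] = _expit(_pop_year_eta(
            coeffs.theta_intercept[a], coeffs.theta_pop, coeffs.theta_year,
            coeffs.theta_tsi, schedule))

    lam = np.exp(_pop_year_eta(
        coeffs.attempts_intercept, coeffs.attempts_pop, coeffs.attempts_year,
        coeffs.attempts_tsi, schedule))

    hazard = np.exp(_pop_year_eta(
        coeffs.nest_hazard_intercept, coeffs.nest_pop, coeffs.nest_year,
        coeffs.nest_tsi, schedule))
    daily_surv = np.exp(-hazard)

    fledged = np.exp(_pop_year_eta(
        coeffs.fledged_intercept, coeffs.fledged_pop, coeffs.fledged_year,
        coeffs.fledged_tsi, schedule))

    surv = np.zeros((R, T, 3))
    for a in (0, 1, 2):
        group = 0 if a == 0 else 1
        eta = _pop_year_eta(
            coeffs.survival_intercept[group], coeffs.survival_pop,
            coeffs.survival_year, coeffs.survival_tsi, schedule)
        if a == 0 and coeffs.survival_juv_tsi_slope != 0.0:
            for ri, r in enumerate(schedule.populations):
                for ti, t in enumerate(schedule.years):
                    z = schedule.tsi(r, t)
                    if z is not None:
                        eta[ri, ti] += coeffs.survival_juv_tsi_slope * z
        surv[:, :, a] = _expit(eta)

    # movement: multinomial logit, fidelity reference, availability-masked
    psi = np.zeros((R, R, T))
    for ri, r in enumerate(schedule.populations):
        for ti, t in enumerate(schedule.years):
            logits = np.full(R, -np.inf)
            logits[ri] = 0.0  # fidelity reference
            shift = coeffs.move_tsi(schedule.tsi(r, t))
            for si, s in enumerate(schedule.populations):
                if si == ri or not schedule.is_available(s, t + 1):
                    continue
                if isinstance(coeffs.move_dest_logit, dict):
                    try:
                        base = coeffs.move_dest_logit[(r, s)]
                    except KeyError:
                        raise KeyError(
                            f"move_dest_logit missing pair ({r!r}, {s!r})"
                        ) from None
                else:
                    base = coeffs.move_dest_logit
                logits[si] = base + shift
            ex = np.exp(logits - logits.max())
            psi[ri, :, ti] = ex / ex.sum()

    if isinstance(coeffs.resight_p, dict):
        p = np.array([[coeffs.resight_p[r]] * T for r in schedule.populations])
    else:
        p = np.full((R, T), float(coeffs.resight_p))

    return VitalRateTable(
        schedule=schedule, theta=theta, attempts_lambda=lam,
        daily_survival=daily_surv, fledged_mean=fledged, survival=surv,
        psi=psi, resight_p=p,
        attempt_detection_p=float(coeffs.attempt_detection_p),
        cycle_length=int(coeffs.cycle_length))


def default_schedule() -> InvasionSchedule:
    """Six populations over 28 annual occasions with staggered invasions.

    Mirrors the study design: one population (PAY) holds no breeding birds
    until invasion and only then becomes a movement destination, so it lacks
    pre-invasion data; the rest are available throughout.
    """
    return InvasionSchedule(
        populations=("PAY", "KRV", "OKE", "EVG", "EAS", "SJM"),
        invasion_year={"PAY": 2007, "KRV": 2005, "OKE": 2004,
                       "EVG": 2010, "EAS": 2013, "SJM": 2001},
        study_years=(1996, 2023),
        available_from={"PAY": 2007},
    )


def default_truth() -> TruthSurface:
    """Truth surface emulating the study's fitted post-invasion responses.

    Breeding probability jumps at invasion then decays (quadratic); attempts
    rise then ease off (quadratic); nest survival steps up with no tsi trend;
    fledged declines weakly (linear); survival rises linearly with tsi with a
    small negative juvenile interaction; emigration rises then falls
    (quadratic).  Magnitudes chosen so that adult breeding probability moves
    from roughly 0.3 pre-invasion to ~0.5 at invasion and back to ~0.33 after
    eight years, adult survival sits near 0.85, juvenile survival near 0.6,
    and total emigration peaks around 0.25 mid-invasion.
    """
    return TruthSurface(
        theta_tsi=TsiEffect("quadratic", step=0.93, b1=-0.1085, b2=0.002),
        attempts_tsi=TsiEffect("quadratic", step=0.25, b1=0.05, b2=-0.004),
        nest_tsi=TsiEffect("null", step=-0.45),
        fledged_tsi=TsiEffect("linear", step=0.05, b1=-0.01),
        survival_tsi=TsiEffect("linear", step=0.0, b1=0.02),
        survival_juv_tsi_slope=-0.005,
        move_tsi=TsiEffect("quadratic", step=0.0, b1=0.30, b2=-0.03),
    )
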
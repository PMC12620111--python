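"""Per-capita metapopulation contributions C, R, E and source-sink status.

A member of population r in year t contributes to next year's metapopulation
by surviving in place (retention), surviving elsewhere (emigration), and
recruiting offspring that themselves survive in place or elsewhere.  With
phi_rr = S * psi_rr the joint survival-and-stay probability, phi_rs = S *
psi_rs the joint survival-and-move probabilities and M the per-female
fecundity, the age-specific contribution is

    C_a = phi_rr(a) + sum_s phi_rs(a) + M_a * (phi_rr(0) + sum_s phi_rs(0))
    R_a = phi_rr(a) + M_a * phi_rr(0)          (retention + self-recruitment)
    E_a = C_a - R_a                            (emigration contribution)

C_a reduces to S_a + M_a * S_0 because movement rows sum to one; in a
closed population that is the finite rate of increase.  Annual population
contributions age-weight the subadult and adult values by the observed
proportions of banded birds in each class.

Uncertainty is propagated by stochastic simulation: each replicate redraws
every probability from a beta matched to its mean and SE (movement rows
renormalised onto the simplex) and every count-valued mean (attempts,
fledged) from a matched log-normal; the 0.025/0.975 replicate quantiles give
the 95% interval.  A population-year is a source when the interval lies
above 1, a sink when below 1, stable when it overlaps 1; a "dependent
source" additionally has point estimates C > 1 but R < 1.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .schedule import InvasionSchedule
from .simulate import NOT_SEEN
from .truth import VitalRateTable

__all__ = ["beta_from_moments", "lognormal_from_moments", "contribution_age",
           "retention_age", "emigration_contribution", "age_weighted",
           "age_proportions", "propagate", "classify", "InfeasibleMomentsError"]


class InfeasibleMomentsError(ValueError):
    """Moments outside the family's feasible set (sd^2 >= mean(1-mean))."""


def beta_from_moments(mean: float, sd: float) -> tuple[float, float]:
    """Beta shape parameters matching a mean and standard deviation.

    ``alpha = mean * f``, ``beta = (1 - mean) * f`` with
    ``f = mean(1-mean)/sd^2 - 1``; the round trip is exact.  ``sd = 0`` is
    allowed by callers as a point mass but is rejected here.
    """
    if not 0.0 < mean < 1.0:
        raise InfeasibleMomentsError(f"beta mean must be in (0,1), got {mean}")
    if sd <= 0.0:
        raise InfeasibleMomentsError("beta sd must be positive (use a point mass)")
    v = sd * sd
    bound = mean * (1.0 - mean)
    if v >= bound:
        raise InfeasibleMomentsError(
            f"infeasible beta moments: sd^2={v:.6g} >= mean(1-mean)={bound:.6g}")
    f = bound / v - 1.0
    return mean * f, (1.0 - mean) * f


def lognormal_from_moments(mean: float, sd: float) -> tuple[float, float]:
    """Log-normal ``(mu, sigma)`` matching a mean and standard deviation.

    ``sigma^2 = ln(1 + sd^2/mean^2)``, ``mu = ln(mean) - sigma^2/2``; the
    round trip is exact and ``sd = 0`` degenerates to a point mass.
    """
    if mean <= 0:
        raise ValueError(f"log-normal mean must be positive, got {mean}")
    if sd < 0:
        raise ValueError("sd must be non-negative")
    s2 = np.log1p((sd / mean) ** 2)
    return float(np.log(mean) - s2 / 2.0), float(np.sqrt(s2))


def contribution_age(phi_rr_a, sum_phi_rs_a, M_a, phi_rr_0, sum_phi_rs_0):
    """Age-specific per-capita contribution (supports array inputs)."""
    return phi_rr_a + sum_phi_rs_a + M_a * (phi_rr_0 + sum_phi_rs_0)


def retention_age(phi_rr_a, M_a, phi_rr_0):
    """Retention + self-recruitment component of the contribution."""
    return phi_rr_a + M_a * phi_rr_0


def emigration_contribution(C_a, R_a, tol: float = 1e-9):
    """Emigration contribution ``E = C - R``; C must not fall below R."""
    E = np.asarray(C_a, float) - np.asarray(R_a, float)
    if np.any(E < -tol):
        raise ValueError("internal inconsistency: C < R beyond tolerance")
    return E if E.ndim else float(E)


def age_weighted(value_sub, value_ad, prop_sub, prop_ad):
    """Weight subadult and adult values by their population proportions."""
    ps, pa = np.asarray(prop_sub, float), np.asarray(prop_ad, float)
    if np.any(ps < 0) or np.any(pa < 0):
        raise ValueError("age proportions must be non-negative")
    if not np.allclose(ps + pa, 1.0, atol=1e-9):
        raise ValueError("age proportions must sum to 1")
    return ps * value_sub + pa * value_ad


def age_proportions(captures: pd.DataFrame, schedule: InvasionSchedule) -> pd.DataFrame:
    """Observed subadult/adult proportions of banded birds per population-year.

    Counts distinct banded individuals observed in each population-year at
    age class 1 or 2 (an individual seen more than once in a year counts
    once; juveniles are excluded from the weights).  Population-years with
    no subadult-or-adult observations are absent from the output.
    """
    years = [str(y) for y in schedule.years]
    long = captures.melt(id_vars=["id", "band_year", "age_at_banding"],
                         value_vars=years, var_name="year", value_name="code")
    long = long[long["code"].astype(str) != NOT_SEEN].copy()
    long["year"] = long["year"].astype(int)
    long["age"] = np.minimum(
        long["age_at_banding"] + long["year"] - long["band_year"], 2)
    long = long[long["age"].isin([1, 2])]
    # distinct individuals only
    long = long.drop_duplicates(subset=["id", "year", "code"])
    counts = (long.groupby(["code", "year", "age"]).size()
              .unstack("age", fill_value=0).reindex(columns=[1, 2], fill_value=0))
    tot = counts[1] + counts[2]
    out = pd.DataFrame({
        "population": counts.index.get_level_values("code"),
        "year": counts.index.get_level_values("year"),
        "prop_subadult": (counts[1] / tot).to_numpy(),
        "prop_adult": (counts[2] / tot).to_numpy(),
    }).sort_values(["population", "year"]).reset_index(drop=True)
    return out


def classify(lower: float, upper: float,
             C_point: float | None = None,
             R_point: float | None = None) -> tuple[str, bool]:
    """Source / sink / stable from the 95% interval, plus a dependent flag.

    Source when the whole interval exceeds 1, sink when it lies below 1,
    stable when it overlaps 1.  The dependent-source flag uses point
    estimates: C > 1 but R < 1.
    """
    if upper < lower:
        raise ValueError("interval upper bound below lower bound")
    if lower > 1.0:
        klass = "source"
    elif upper < 1.0:
        klass = "sink"
    else:
        klass = "stable"
    dependent = bool(C_point is not None and R_point is not None
                     and C_point > 1.0 and R_point < 1.0)
    return klass, dependent


def _draw_beta(rng, mean, sd, n, flags, label, clamp):
    if mean <= 0.0:
        return np.zeros(n)
    if mean >= 1.0:
        return np.ones(n)
    if sd <= 0.0:
        return np.full(n, mean)
    bound = np.sqrt(mean * (1.0 - mean))
    if sd >= bound:
        if not clamp:
            raise InfeasibleMomentsError(
                f"infeasible beta moments for {label}")
        flags.append(f"clamped:{label}")
        sd = 0.99 * bound
    a, b = beta_from_moments(mean, sd)
    return rng.beta(a, b, size=n)


def _draw_lognormal(rng, mean, sd, n):
    if mean <= 0.0:
        return np.zeros(n)
    if sd <= 0.0:
        return np.full(n, mean)
    mu, sig = lognormal_from_moments(mean, sd)
    return rng.lognormal(mu, sig, size=n)


def propagate(
    rates: VitalRateTable,
    proportions: pd.DataFrame,
    n_reps: int = 10_000,
    seed: int = 0,
    exclude: set[tuple[str, int]] | None = None,
    clamp: bool = True,
) -> pd.DataFrame:
    """Stochastic propagation of vital-rate uncertainty into C, R, E.

    For every population-year present in ``proportions`` and not excluded,
    draws ``n_reps`` replicates of every component (betas for probabilities,
    movement rows renormalised; log-normals for attempts and fledged means),
    computes age-weighted C, R and E per replicate, and summarises with the
    0.025/0.975 quantiles.  Deterministic under a fixed seed.  Infeasible
    beta moments are clamped to 99% of the feasible sd with a quality flag
    (or raise when ``clamp`` is False).
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    exclude = exclude or set()
    sched = rates.schedule
    rng = np.random.default_rng(seed)
    prop_idx = {(row.population, int(row.year)): (row.prop_subadult, row.prop_adult)
                for row in proportions.itertuples()}
    N_mean, N_se = rates.attempts_mean, rates.attempts_mean_se
    P_mean, P_se = rates.nest_success, rates.nest_success_se
    Y_mean, Y_se = rates.female_fledged, rates.female_fledged_se

    out = []
    for ri, r in enumerate(sched.populations):
        for ti, t in enumerate(sched.years):
            if (r, t) not in prop_idx or (r, t) in exclude:
                continue
            flags: list[str] = []
            ps, pa = prop_idx[(r, t)]

            S_ad = _draw_beta(rng, rates.survival[ri, ti, 2],
                              rates.survival_se[ri, ti, 2], n_reps, flags,
                              f"S_adult[{r},{t}]", clamp)
            S_juv = _draw_beta(rng, rates.survival[ri, ti, 0],
                               rates.survival_se[ri, ti, 0], n_reps, flags,
                               f"S_juv[{r},{t}]", clamp)
            # movement row: independent betas renormalised onto the simplex
            row = np.empty((len(sched.populations), n_reps))
            for si, s in enumerate(sched.populations):
                row[si] = _draw_beta(rng, rates.psi[ri, si, ti],
                                     rates.psi_se[ri, si, ti], n_reps, flags,
                                     f"psi[{r}->{s},{t}]", clamp)
            row /= row.sum(axis=0, keepdims=True)
            psi_rr = row[ri]

            th1 = _draw_beta(rng, rates.theta[ri, ti, 1],
                             rates.theta_se[ri, ti, 1], n_reps, flags,
                             f"theta1[{r},{t}]", clamp)
            th2 = _draw_beta(rng, rates.theta[ri, ti, 2],
                             rates.theta_se[ri, ti, 2], n_reps, flags,
                             f"theta2[{r},{t}]", clamp)
            N = _draw_lognormal(rng, N_mean[ri, ti], N_se[ri, ti], n_reps)
            P = _draw_beta(rng, P_mean[ri, ti], P_se[ri, ti], n_reps, flags,
                           f"P[{r},{t}]", clamp)
            Y = _draw_lognormal(rng, Y_mean[ri, ti], Y_se[ri, ti], n_reps)

            M1, M2 = th1 * N * P * Y, th2 * N * P * Y
            phi_rr_ad, phi_rr_juv = S_ad * psi_rr, S_juv * psi_rr
            C1 = contribution_age(phi_rr_ad, S_ad - phi_rr_ad, M1,
                                  phi_rr_juv, S_juv - phi_rr_juv)
            C2 = contribution_age(phi_rr_ad, S_ad - phi_rr_ad, M2,
                                  phi_rr_juv, S_juv - phi_rr_juv)
            R1 = retention_age(phi_rr_ad, M1, phi_rr_juv)
            R2 = retention_age(phi_rr_ad, M2, phi_rr_juv)
            C = age_weighted(C1, C2, ps, pa)
            R = age_weighted(R1, R2, ps, pa)
            E = C - R

            def _point(th):
                M = (th * N_mean[ri, ti] * P_mean[ri, ti] * Y_mean[ri, ti])
                S_a, S_0 = rates.survival[ri, ti, 2], rates.survival[ri, ti, 0]
                f_rr_a = S_a * rates.psi[ri, ri, ti]
                f_rr_0 = S_0 * rates.psi[ri, ri, ti]
                Cp = contribution_age(f_rr_a, S_a - f_rr_a, M, f_rr_0, S_0 - f_rr_0)
                Rp = retention_age(f_rr_a, M, f_rr_0)
                return Cp, Rp

            C1p, R1p = _point(rates.theta[ri, ti, 1])
            C2p, R2p = _point(rates.theta[ri, ti, 2])
            Cp = float(age_weighted(C1p, C2p, ps, pa))
            Rp = float(age_weighted(R1p, R2p, ps, pa))
            Ep = float(emigration_contribution(Cp, Rp))

            qC = np.quantile(C, [0.025, 0.975])
            qR = np.quantile(R, [0.025, 0.975])
            qE = np.quantile(E, [0.025, 0.975])
            klass, dep = classify(qC[0], qC[1], Cp, Rp)
            out.append({
                "population": r, "year": t, "tsi": sched.tsi(r, t),
                "C": Cp, "C_lo": qC[0], "C_hi": qC[1],
                "R": Rp, "R_lo": qR[0], "R_hi": qR[1],
                "E": Ep, "E_lo": qE[0], "E_hi": qE[1],
                "class": klass, "dependent_source": dep,
                "n_reps": n_reps, "seed": seed,
                "quality_flags": ";".join(sorted(set(flags))),
            })
    return pd.DataFrame(out)
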
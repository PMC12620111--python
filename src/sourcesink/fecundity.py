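"""Fecundity components: breeding, attempts, nest success, fledged young.

Per-female fecundity in population r, year t at age a decomposes as

    M_rta = theta_rta * N_rt * P_rt * Y_rt

— breeding probability, expected nesting attempts given breeding, nest
success over the full nesting cycle, and female young fledged per successful
nest (1:1 sex ratio).  Juveniles never breed, so M_rt0 = 0.

Breeding and attempts are estimated jointly from observed attempt counts by
marginal maximum likelihood over the latent breeder state and the latent
true attempt count: an individual breeds with probability theta, a breeder
makes a zero-truncated-Poisson(lambda) number of attempts, and each attempt
is detected independently with probability p_det, so for an observed count k

    L = (1 - theta) * 1[k = 0]
        + theta * sum_{K >= max(k, 1)} ZTP(K; lambda) Binom(k; K, p_det).

Nest success comes from a complementary log-log daily-hazard model with the
interval exposure days as an offset (daily survival ``exp(-exp(eta))``,
success = daily survival to the power of the ~58-day cycle), and fledged
young from a Poisson log-link model; both carry population and year random
intercepts integrated out by a Laplace approximation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit, gammaln

from ._optim import MLFit, maximize_loglik
from .glmm import GlmmFit, fit_glmm
from .schedule import InvasionSchedule
from .truth import ztp_mean

__all__ = ["BreedingAttemptsSpec", "BreedingAttemptsFit", "fit_breeding_attempts",
           "expected_attempts", "fit_nest_survival", "nest_success",
           "fit_fledged", "fecundity", "NestModelFit"]


# --------------------------------------------------------------------------
# breeding state + attempts mixture


@dataclass(frozen=True)
class BreedingAttemptsSpec:
    """Structure of the breeding/attempts mixture.

    ``theta`` is modelled on the logit scale with an intercept, an adult
    (age-class 2) contrast when ``theta_age`` is set, and optional
    time-since-invasion terms; ``lambda`` on the log scale with optional tsi
    terms.  ``fix_theta`` / ``fix_p_det`` pin those probabilities instead of
    estimating them (useful for collapsed special cases).  ``k_max`` bounds
    the latent attempt count; it must be at least the largest observed count
    and large enough that the truncated ZTP mass is negligible.
    """

    theta_age: bool = True
    theta_tsi: str = "null"
    attempts_tsi: str = "null"
    fix_theta: float | None = None
    fix_p_det: float | None = None
    k_max: int = 30


def _tsi_columns(form: str, schedule: InvasionSchedule | None,
                 pops: np.ndarray, years: np.ndarray):
    """Design columns (and names) for a tsi form, rows = observations."""
    if form == "null" or schedule is None:
        return np.empty((len(pops), 0)), []
    z = np.array([(schedule.tsi(r, int(t)) or 0) for r, t in zip(pops, years)],
                 dtype=float)
    post = np.array([schedule.tsi(r, int(t)) is not None
                     for r, t in zip(pops, years)], dtype=float)
    if form == "linear":
        return np.column_stack([post, z * post]), ["post", "tsi"]
    if form == "quadratic":
        return np.column_stack([post, z * post, z * z * post]), ["post", "tsi", "tsi2"]
    return np.column_stack([post, np.log1p(z) * post]), ["post", "log_tsi"]


def _mixture_loglik(k_obs, X_theta, X_lam, bt, bl, p_det, k_max, weights=None):
    """Vectorised marginal log-likelihood of observed attempt counts."""
    theta = expit(X_theta @ bt)
    lam = np.exp(np.clip(X_lam @ bl, -20, 8))
    K = np.arange(1, k_max + 1)
    # log ZTP pmf, rows = obs
    log_ztp = (K[None, :] * np.log(lam)[:, None] - lam[:, None]
               - gammaln(K + 1)[None, :]
               - np.log(-np.expm1(-lam))[:, None])
    ztp = np.exp(log_ztp)
    k = k_obs[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        log_binom = (gammaln(K + 1)[None, :] - gammaln(k + 1)
                     - gammaln(np.maximum(K[None, :] - k, 0) + 1)
                     + k * np.log(max(p_det, 1e-300))
                     + (K[None, :] - k) * np.log1p(-p_det if p_det < 1 else 0.0))
    binom = np.where(K[None, :] >= k, np.exp(log_binom), 0.0)
    if p_det >= 1.0:
        binom = (K[None, :] == k).astype(float)
    inner = (ztp * binom).sum(axis=1)
    L = theta * inner + (1.0 - theta) * (k_obs == 0)
    if np.any(L <= 0):
        return -np.inf
    logs = np.log(L)
    if weights is not None:
        logs = logs * weights
    return float(logs.sum())


@dataclass
class BreedingAttemptsFit:
    """Joint fit of breeding probability, attempt rate and attempt detection."""

    fit: MLFit
    spec: BreedingAttemptsSpec
    schedule: InvasionSchedule | None
    _names: dict

    @property
    def loglik(self) -> float:
        return self.fit.loglik

    @property
    def k(self) -> int:
        return self.fit.k

    @property
    def n(self) -> int:
        return self.fit.n

    def _unpack(self, x=None):
        x = self.fit.params if x is None else x
        nt, nl = len(self._names["theta"]), len(self._names["lam"])
        if self.spec.fix_theta is None:
            bt, rest = x[:nt], x[nt:]
        else:
            bt, rest = np.array([self._names["fixed_logit"]]
                                + [0.0] * (nt - 1)), x
        bl = rest[:nl]
        if self.spec.fix_p_det is not None:
            pd_ = self.spec.fix_p_det
        else:
            pd_ = float(expit(rest[nl]))
        return bt, bl, pd_

    @property
    def p_det(self) -> float:
        return self._unpack()[2]

    def predict(self, population: str, year: int, age_class: int):
        """(theta, theta_se, lambda, lambda_se) for one population-year-age."""
        if age_class not in (1, 2):
            raise ValueError("breeding is defined for age classes 1 and 2")
        xt = [1.0]
        if self.spec.theta_age:
            xt.append(1.0 if age_class == 2 else 0.0)
        ct, _ = _tsi_columns(self.spec.theta_tsi, self.schedule,
                             np.array([population]), np.array([year]))
        xt = np.array(xt + list(ct[0]))
        cl, _ = _tsi_columns(self.spec.attempts_tsi, self.schedule,
                             np.array([population]), np.array([year]))
        xl = np.array([1.0] + list(cl[0]))
        bt, bl, _ = self._unpack()
        nt, nl = len(bt), len(bl)
        cov = self.fit.covariance
        theta = float(expit(float(xt @ bt)))
        if self.spec.fix_theta is not None:
            theta, theta_se = self.spec.fix_theta, 0.0
            lam_lo = 0
        else:
            var_t = float(xt @ cov[:nt, :nt] @ xt)
            theta_se = theta * (1 - theta) * np.sqrt(max(var_t, 0.0))
            lam_lo = nt
        var_l = float(xl @ cov[lam_lo:lam_lo + nl, lam_lo:lam_lo + nl] @ xl)
        lam = float(np.exp(float(xl @ bl)))
        lam_se = lam * np.sqrt(max(var_l, 0.0))
        return theta, theta_se, lam, lam_se


def fit_breeding_attempts(
    breeders: pd.DataFrame,
    schedule: InvasionSchedule | None = None,
    spec: BreedingAttemptsSpec | None = None,
    n_starts: int = 3,
    seed: int = 0,
) -> BreedingAttemptsFit:
    """Marginal ML fit of the breeding/attempts/detection mixture.

    ``breeders`` needs columns individual_id, population, year, age_class
    (1 or 2) and attempts_observed.  Raises when every observed count is zero
    and theta is free (theta and p_det are then confounded).

    .. warning::
       With ``p_det`` free the model is structurally non-identifiable from
       annual counts alone: binomial thinning of a zero-truncated Poisson
       yields an observable distribution that depends only on
       ``lambda * p_det`` and ``theta / (1 - exp(-lambda))``, so an entire
       ridge of (theta, lambda, p_det) triples fits equally well.  The fit
       then reports the ridge through huge standard errors and
       ``flat_directions``.  Supply ``fix_p_det`` (e.g. from an external
       detection study) for identifiable estimates; with ``fix_p_det=1`` the
       estimates are conditional on detected attempts.
    """
    spec = spec or BreedingAttemptsSpec()
    if len(breeders) == 0:
        raise ValueError("no breeder observations")
    ages = breeders["age_class"].to_numpy()
    if not np.isin(ages, (1, 2)).all():
        raise ValueError("age classes must be 1 or 2")
    k_obs = breeders["attempts_observed"].to_numpy(dtype=int)
    if k_obs.max() > spec.k_max:
        raise ValueError(f"k_max={spec.k_max} below max observed {k_obs.max()}")
    if (k_obs == 0).all() and spec.fix_theta is None:
        raise ValueError(
            "all observed attempt counts are zero: breeding probability and "
            "attempt detection are not jointly identifiable")

    pops = breeders["population"].to_numpy()
    years = breeders["year"].to_numpy()

    Xt = [np.ones(len(k_obs))]
    t_names = ["theta:intercept"]
    if spec.theta_age:
        Xt.append((ages == 2).astype(float))
        t_names.append("theta:adult")
    ct, cn = _tsi_columns(spec.theta_tsi, schedule, pops, years)
    X_theta = np.column_stack(Xt + [ct]) if ct.shape[1] else np.column_stack(Xt)
    t_names += [f"theta:{c}" for c in cn]

    cl, cn = _tsi_columns(spec.attempts_tsi, schedule, pops, years)
    X_lam = (np.column_stack([np.ones(len(k_obs)), cl]) if cl.shape[1]
             else np.ones((len(k_obs), 1)))
    l_names = ["lam:intercept"] + [f"lam:{c}" for c in cn]

    nt, nl = len(t_names), len(l_names)
    fixed_logit = 0.0
    if spec.fix_theta is not None:
        fixed_logit = (float(np.log(spec.fix_theta / (1 - spec.fix_theta)))
                       if 0 < spec.fix_theta < 1
                       else (50.0 if spec.fix_theta >= 1 else -50.0))

    free_names = ([] if spec.fix_theta is not None else t_names) + l_names
    if spec.fix_p_det is None:
        free_names = free_names + ["p_det:logit"]

    # pool identical (count, covariate) rows: the likelihood is a weighted
    # sum over unique rows, which collapses large tables dramatically
    stacked = np.column_stack([k_obs, X_theta, X_lam])
    _, uniq_idx, counts = np.unique(stacked, axis=0, return_index=True,
                                    return_counts=True)
    k_u = k_obs[uniq_idx]
    Xt_u, Xl_u = X_theta[uniq_idx], X_lam[uniq_idx]
    w = counts.astype(float)

    def nll(x):
        if spec.fix_theta is None:
            bt, rest = x[:nt], x[nt:]
        else:
            bt = np.array([fixed_logit] + [0.0] * (nt - 1))
            rest = x
        bl = rest[:nl]
        pd_ = spec.fix_p_det if spec.fix_p_det is not None else float(expit(rest[nl]))
        ll = _mixture_loglik(k_u, Xt_u, Xl_u, bt, bl, pd_, spec.k_max, weights=w)
        return -ll if np.isfinite(ll) else 1e10

    x0 = np.zeros(len(free_names))
    fit = maximize_loglik(nll, x0, free_names, n_obs=len(k_obs),
                          n_starts=n_starts, seed=seed, jitter=0.3)
    return BreedingAttemptsFit(
        fit=fit, spec=spec, schedule=schedule,
        _names={"theta": t_names, "lam": l_names, "fixed_logit": fixed_logit})


def expected_attempts(lam: float, lam_se: float = 0.0) -> tuple[float, float]:
    """Expected attempts given breeding: zero-truncated Poisson mean with SE.

    ``N = lambda / (1 - exp(-lambda))``; the SE follows by the delta method.
    """
    if lam <= 0:
        raise ValueError("attempt rate must be positive")
    N = ztp_mean(lam)
    em = np.exp(-lam)
    dN = (1.0 - em - lam * em) / (1.0 - em) ** 2
    return float(N), float(abs(dN) * lam_se)


# --------------------------------------------------------------------------
# nest survival and fledged


@dataclass
class NestModelFit:
    """A nest-level GLMM fit plus the design needed for prediction."""

    glmm: GlmmFit
    tsi_form: str
    schedule: InvasionSchedule | None
    cycle_length: int = 58

    @property
    def loglik(self) -> float:
        return self.glmm.loglik

    @property
    def k(self) -> int:
        return self.glmm.k

    @property
    def n(self) -> int:
        return self.glmm.n

    @property
    def boundary(self) -> bool:
        return self.glmm.boundary

    def _design_row(self, population: str, year: int) -> np.ndarray:
        c, _ = _tsi_columns(self.tsi_form, self.schedule,
                            np.array([population]), np.array([year]))
        return np.array([1.0, *c[0]])

    def predict_daily_survival(self, population: str, year: int):
        """(daily survival, SE) for one population-year."""
        x = self._design_row(population, year)
        eta, eta_se = self.glmm.predict_eta(
            x[None, :], {"population": np.array([population]),
                         "year": np.array([year])})
        h = float(np.exp(eta[0]))
        s = float(np.exp(-h))
        return s, s * h * float(eta_se[0])  # |ds/deta| = s * h

    def predict_fledged(self, population: str, year: int):
        """(mean fledged, SE) per successful nest for one population-year."""
        x = self._design_row(population, year)
        eta, eta_se = self.glmm.predict_eta(
            x[None, :], {"population": np.array([population]),
                         "year": np.array([year])})
        m = float(np.exp(eta[0]))
        return m, m * float(eta_se[0])


def fit_nest_survival(
    nests: pd.DataFrame,
    schedule: InvasionSchedule | None = None,
    tsi_form: str = "null",
    random_effects: bool = True,
    cycle_length: int = 58,
) -> NestModelFit:
    """Complementary log-log daily-hazard fit on nest visit intervals.

    Each row is one interval with ``interval_days`` exposure and
    ``interval_fate`` (1 survived, 0 failed); the response modelled is
    failure within the interval, ``P(fail) = 1 - s^d`` with ``s`` the daily
    survival.  Population and year enter as random intercepts (Laplace),
    or as fixed effects with ``random_effects=False``.  ``n`` is the number
    of intervals.  With no failures at all the hazard sits on the boundary;
    the fit is returned with ``boundary=True`` rather than an infinite
    coefficient.
    """
    if len(nests) == 0:
        raise ValueError("no nest intervals")
    if (nests["interval_days"] < 1).any():
        raise ValueError("interval_days must be >= 1")
    pops = nests["population"].to_numpy()
    years = nests["year"].to_numpy()
    c, cn = _tsi_columns(tsi_form, schedule, pops, years)
    X = np.column_stack([np.ones(len(nests)), c]) if c.shape[1] else np.ones((len(nests), 1))
    y = 1 - nests["interval_fate"].to_numpy(dtype=int)  # 1 = failed
    glmm = fit_glmm(
        X, y, "cloglog_hazard",
        beta_names=["intercept"] + [f"nest:{t}" for t in cn],
        exposure=nests["interval_days"].to_numpy(dtype=float),
        groups={"population": pops, "year": years},
        random_effects=random_effects)
    return NestModelFit(glmm=glmm, tsi_form=tsi_form, schedule=schedule,
                        cycle_length=cycle_length)


def nest_success(daily_survival: float, cycle_length: int = 58,
                 se: float = 0.0) -> tuple[float, float]:
    """Cycle-long nest success: daily survival to the power of the cycle.

    The SE follows by the delta method when a daily-survival SE is given.
    """
    if not 0.0 <= daily_survival <= 1.0:
        raise ValueError("daily survival must be a probability")
    if cycle_length < 0:
        raise ValueError("cycle length must be non-negative")
    P = daily_survival ** cycle_length
    dP = cycle_length * daily_survival ** (cycle_length - 1) if cycle_length else 0.0
    return float(P), float(abs(dP) * se)


def fit_fledged(
    nests: pd.DataFrame,
    schedule: InvasionSchedule | None = None,
    tsi_form: str = "null",
    random_effects: bool = True,
) -> NestModelFit:
    """Poisson log-link fit of fledged young per successful nest.

    Uses rows with a recorded fledged count (terminal intervals of
    successful nests); ``n`` is the number of successful nests.  Female
    young are half the predicted mean (1:1 sex ratio) — see
    :meth:`NestModelFit.predict_fledged` and divide by two, which
    :func:`sourcesink.pipeline.build_vital_rates` does.
    """
    ok = nests["fledged"].notna()
    succ = nests[ok]
    if len(succ) == 0:
        raise ValueError("no successful nests with fledged counts")
    pops = succ["population"].to_numpy()
    years = succ["year"].to_numpy()
    c, cn = _tsi_columns(tsi_form, schedule, pops, years)
    X = np.column_stack([np.ones(len(succ)), c]) if c.shape[1] else np.ones((len(succ), 1))
    glmm = fit_glmm(
        X, succ["fledged"].to_numpy(dtype=float), "poisson",
        beta_names=["intercept"] + [f"fledged:{t}" for t in cn],
        groups={"population": pops, "year": years},
        random_effects=random_effects)
    return NestModelFit(glmm=glmm, tsi_form=tsi_form, schedule=schedule)


# --------------------------------------------------------------------------
# the product


def fecundity(theta: float, attempts: float, success: float, female_fledged: float,
              age_class: int = 2, ses: tuple[float, float, float, float] = (0, 0, 0, 0),
              ) -> tuple[float, float]:
    """Per-female fecundity ``M = theta * N * P * Y`` with delta-method SE.

    Identically (0, 0) for juveniles (age class 0), which do not breed.
    The SE treats the four components as independent, as they come from
    separate fits on separate data.
    """
    if age_class == 0:
        return 0.0, 0.0
    for name, v in (("theta", theta), ("success", success)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be a probability")
    if attempts < 0 or female_fledged < 0:
        raise ValueError("components must be non-negative")
    M = theta * attempts * success * female_fledged
    comps = (theta, attempts, success, female_fledged)
    rel = sum((s / c) ** 2 for c, s in zip(comps, ses) if c > 0)
    return float(M), float(M * np.sqrt(rel))
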
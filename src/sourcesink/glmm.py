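"""Laplace-approximate GLMMs with crossed population and year intercepts.

Two families are supported, matching the two nest-level models:

- Bernoulli with a complementary log-log link on interval mortality and a
  log-exposure offset: an interval of ``d`` days survives with probability
  ``exp(-d * exp(eta))`` where ``eta`` is the linear predictor of the log
  daily hazard.  Back-transforming, daily survival is ``exp(-exp(eta))``.
- Poisson with a log link (fledged young per successful nest).

Random intercepts ``b ~ N(0, sigma_g^2)`` for population and year are
integrated out by a Laplace approximation: for fixed ``(beta, log sigma)``
the penalised joint log-likelihood is maximised over ``b`` by Newton
iterations (the random-effect dimension is small — number of populations
plus number of years), and the marginal likelihood adds the usual
half-log-determinant correction.  The outer optimisation over ``beta`` and
the log standard deviations uses Nelder-Mead restarts followed by L-BFGS
polish.  A fixed-effects fallback (population/year as fixed terms, or no
grouping) is available for degenerate designs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from ._optim import fd_hessian

__all__ = ["GlmmFit", "fit_glmm"]

_FAMILIES = ("cloglog_hazard", "poisson")


def _family_derivs(family, y, eta, offset_exposure):
    """Per-observation loglik and first/second derivatives w.r.t. eta."""
    if family == "poisson":
        mu = np.exp(eta)
        ll = y * eta - mu  # constant log(y!) dropped
        return ll, y - mu, -mu
    # cloglog_hazard: cumulative hazard mu = d * exp(eta); y = 1 means failed
    mu = offset_exposure * np.exp(eta)
    q = np.exp(-mu)
    surv_ll = -mu
    with np.errstate(divide="ignore"):
        fail_ll = np.log(-np.expm1(-mu))
    ll = np.where(y == 1, fail_ll, surv_ll)
    # derivatives
    ratio = np.where(y == 1, mu * q / np.maximum(1.0 - q, 1e-300), 0.0)
    d1 = np.where(y == 1, ratio, -mu)
    d2 = np.where(y == 1, ratio - (mu ** 2) * q / np.maximum((1.0 - q) ** 2, 1e-300),
                  -mu)
    return ll, d1, d2


@dataclass
class GlmmFit:
    """A fitted mixed (or fixed-fallback) GLM.

    ``beta`` are fixed effects (covariance ``beta_cov`` from the
    finite-difference Hessian of the Laplace marginal likelihood), ``sigma``
    the random-intercept standard deviations per grouping factor and
    ``ranef`` the conditional modes.  ``boundary`` flags a variance component
    (or, for the hazard family with no failures, a hazard) estimated at the
    boundary.
    """

    beta: np.ndarray
    beta_cov: np.ndarray
    beta_names: list[str]
    sigma: dict[str, float]
    ranef: dict[str, np.ndarray]
    group_levels: dict[str, list]
    loglik: float
    n: int
    k: int
    family: str
    boundary: bool = False
    #: fallback one-hot encoding: group -> ordered levels (first = reference)
    fixed_group_levels: dict[str, list] = None

    @property
    def beta_se(self) -> np.ndarray:
        d = np.diag(self.beta_cov).copy()
        d[d < 0] = np.nan
        return np.sqrt(d)

    def predict_eta(self, X: np.ndarray, groups: dict[str, np.ndarray] | None = None,
                    include_ranef: bool = True):
        """Linear predictor and its SE (fixed-effect uncertainty only)."""
        if self.fixed_group_levels:
            # rebuild the fallback one-hot columns in fitting order
            cols = [X]
            for g, levs in self.fixed_group_levels.items():
                labels = np.asarray(groups.get(g)) if groups else None
                for lv in levs[1:]:
                    if labels is None:
                        cols.append(np.zeros((X.shape[0], 1)))
                    else:
                        cols.append((labels == lv).astype(float)[:, None])
            X = np.column_stack(cols)
        eta = X @ self.beta
        if include_ranef and groups:
            for g, levels in groups.items():
                if g not in self.group_levels:
                    continue
                lookup = {lv: i for i, lv in enumerate(self.group_levels[g])}
                idx = np.array([lookup.get(lv, -1) for lv in levels])
                add = np.where(idx >= 0, self.ranef[g][np.maximum(idx, 0)], 0.0)
                eta = eta + add
        var = np.einsum("ij,jk,ik->i", X, self.beta_cov, X)
        var[var < 0] = 0.0
        return eta, np.sqrt(var)


def _inner_modes(beta, sigmas, X, y, offs, Zidx, q_sizes, family, b0=None,
                 weights=None):
    """Newton maximisation of the penalised joint loglik over ranef modes."""
    q = sum(q_sizes)
    w = np.ones(len(y)) if weights is None else weights
    b = np.zeros(q) if b0 is None else b0.copy()
    prec = np.concatenate([np.full(m, 1.0 / s ** 2) for m, s in zip(q_sizes, sigmas)])
    starts = np.cumsum([0] + list(q_sizes))
    G = len(q_sizes)
    flat_idx = [[(starts[gi] + Zidx[gi]) * q + (starts[gj] + Zidx[gj])
                 for gj in range(G)] for gi in range(G)]

    def derivs(bvec):
        eta = X @ beta
        for gi in range(G):
            eta = eta + bvec[starts[gi] + Zidx[gi]]
        ll, d1, d2 = _family_derivs(family, y, eta, offs)
        return w * ll, w * d1, w * d2

    def hess(d2):
        H = np.zeros(q * q)
        for gi in range(G):
            for gj in range(G):
                H += np.bincount(flat_idx[gi][gj], weights=d2, minlength=q * q)
        H = H.reshape(q, q)
        H[np.diag_indices(q)] -= prec
        return H

    for _ in range(50):
        ll, d1, d2 = derivs(b)
        grad = np.zeros(q)
        for gi in range(G):
            grad += np.bincount(starts[gi] + Zidx[gi], weights=d1, minlength=q)
        grad -= prec * b
        H = hess(d2)
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, grad, rcond=None)[0]
        b_new = b - step
        if np.max(np.abs(b_new - b)) < 1e-10:
            b = b_new
            break
        b = b_new
    ll, d1, d2 = derivs(b)
    joint = ll.sum() - 0.5 * np.sum(prec * b * b) - 0.5 * np.sum(np.log(1.0 / prec))
    H = hess(d2)
    if not np.all(np.isfinite(H)):
        return b, -np.inf
    sign, logdet = np.linalg.slogdet(-H)
    if sign <= 0:
        return b, -np.inf
    marg = joint - 0.5 * logdet  # + (q/2) log(2pi) cancels the prior constant
    return b, marg


def fit_glmm(
    X: np.ndarray,
    y: np.ndarray,
    family: str,
    beta_names: list[str] | None = None,
    exposure: np.ndarray | None = None,
    groups: dict[str, np.ndarray] | None = None,
    random_effects: bool = True,
) -> GlmmFit:
    """Fit a GLM with optional crossed random intercepts by Laplace ML.

    Parameters
    ----------
    X, y
        Fixed-effect design matrix and response (interval fate 0/1 for the
        hazard family; counts for Poisson).
    family
        ``"cloglog_hazard"`` or ``"poisson"``.
    exposure
        Exposure days per interval (hazard family only; enters as a
        log-offset on the cumulative hazard).
    groups
        Mapping name -> per-observation level labels (e.g. population, year).
    random_effects
        When False, groups are one-hot-encoded as fixed effects instead
        (the degenerate-design fallback).
    """
    if family not in _FAMILIES:
        raise ValueError(f"family must be one of {_FAMILIES}")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(y) == 0:
        raise ValueError("empty input")
    offs = np.asarray(exposure, dtype=float) if exposure is not None else None
    if family == "cloglog_hazard":
        if offs is None:
            raise ValueError("hazard family requires exposure days")
        if np.any(offs < 1):
            raise ValueError("exposure days must be >= 1")
    beta_names = beta_names or [f"b{i}" for i in range(X.shape[1])]
    groups = groups or {}

    boundary = False
    if family == "cloglog_hazard" and not np.any(y == 1):
        boundary = True  # no failures: hazard at the 0 boundary

    fixed_group_levels = {}
    if groups and not random_effects:
        # fixed-effects fallback: drop first level of each factor
        for g, levels in groups.items():
            levs = sorted(set(levels))
            fixed_group_levels[g] = levs
            for lv in levs[1:]:
                X = np.column_stack([X, (np.asarray(levels) == lv).astype(float)])
                beta_names = beta_names + [f"{g}:{lv}"]
        groups = {}

    Zidx, q_sizes, level_lists, gnames = [], [], [], []
    for g, levels in groups.items():
        levs = sorted(set(levels))
        lookup = {lv: i for i, lv in enumerate(levs)}
        Zidx.append(np.array([lookup[lv] for lv in levels]))
        q_sizes.append(len(levs))
        level_lists.append(levs)
        gnames.append(g)

    # pool identical rows: weighted likelihood over unique
    # (X, y, exposure, group-index) combinations
    n_total = len(y)
    stacked = np.column_stack(
        [X, y] + ([offs] if offs is not None else []) + [z for z in Zidx])
    _, uniq, counts = np.unique(stacked, axis=0, return_index=True,
                                return_counts=True)
    X, y = X[uniq], y[uniq]
    if offs is not None:
        offs = offs[uniq]
    Zidx = [z[uniq] for z in Zidx]
    w = counts.astype(float)

    p = X.shape[1]
    n_sigma = len(gnames)

    if n_sigma == 0:
        def nll(params):
            ll, _, _ = _family_derivs(family, y, X @ params, offs)
            return -(w * ll).sum()
        res = minimize(nll, np.zeros(p), method="BFGS",
                       options={"gtol": 1e-10, "maxiter": 1000})
        H = fd_hessian(nll, res.x)
        cov = np.linalg.pinv(0.5 * (H + H.T))
        return GlmmFit(beta=res.x, beta_cov=cov, beta_names=beta_names,
                       sigma={}, ranef={}, group_levels={},
                       loglik=-float(res.fun), n=n_total, k=p, family=family,
                       boundary=boundary,
                       fixed_group_levels=fixed_group_levels)

    b_cache = {"b": None}

    def neg_marginal(params):
        beta = params[:p]
        sig = np.exp(params[p:])
        b, marg = _inner_modes(beta, sig, X, y, offs, Zidx, q_sizes, family,
                               b0=b_cache["b"], weights=w)
        if np.isfinite(marg):
            b_cache["b"] = b
        return -marg if np.isfinite(marg) else 1e10

    x0 = np.concatenate([np.zeros(p), np.full(n_sigma, np.log(0.3))])
    res = minimize(neg_marginal, x0, method="Nelder-Mead",
                   options={"maxiter": 3000, "xatol": 1e-8, "fatol": 1e-10})
    res2 = minimize(neg_marginal, res.x, method="L-BFGS-B",
                    options={"gtol": 1e-8})
    if res2.fun <= res.fun:
        res = res2

    beta = res.x[:p]
    sig = np.exp(res.x[p:])
    if np.any(sig < 1e-4):
        boundary = True
    b, _ = _inner_modes(beta, sig, X, y, offs, Zidx, q_sizes, family, weights=w)

    def nll_beta(bv):
        return neg_marginal(np.concatenate([bv, res.x[p:]]))

    Hb = fd_hessian(nll_beta, beta)
    cov = np.linalg.pinv(0.5 * (Hb + Hb.T))

    starts = np.cumsum([0] + list(q_sizes))
    ranef = {g: b[starts[i]:starts[i + 1]] for i, g in enumerate(gnames)}
    return GlmmFit(
        beta=beta, beta_cov=cov, beta_names=beta_names,
        sigma={g: float(s) for g, s in zip(gnames, sig)},
        ranef=ranef, group_levels=dict(zip(gnames, level_lists)),
        loglik=-float(res.fun), n=n_total, k=p + n_sigma, family=family,
        boundary=boundary)
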
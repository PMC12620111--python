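"""Multistate mark-resight likelihood: annual survival, movement, resight.

The model is the classic multistate (states = populations, plus an absorbing
dead state) survival model in hidden-Markov form.  Conditional on the
banding occasion, each later occasion contributes a transition (survive with
``S[r, t, a]``; given survival move by the multinomial-logit row
``psi[r, ·, t]`` with fidelity as reference) and an emission (resighted in
the occupied population with probability ``p``, never resighted when dead).
Subadult and adult survival are constrained equal; juveniles get their own
intercept (and optionally their own time-since-invasion slope).  Movement
destinations are masked to populations available in the destination year and
the row renormalises over fidelity plus available destinations.

The likelihood is evaluated by a scaled forward recursion vectorised across
individuals, and maximised by multi-start L-BFGS; standard errors come from
the inverse finite-difference observed information.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._optim import MLFit, fd_hessian, maximize_loglik
from .schedule import InvasionSchedule, TSI_FORMS
from .simulate import NOT_SEEN

__all__ = ["MultistateSpec", "EncodedHistories", "encode_histories",
           "movement_row", "history_loglik", "fit_multistate", "MultistateFit",
           "estimability_screen", "derive_phi", "PhiEstimate"]


# --------------------------------------------------------------------------
# model specification


@dataclass(frozen=True)
class MultistateSpec:
    """Structure of the fitted multistate model.

    survival_tsi / movement_tsi: ``"null"``, ``"linear"``, ``"quadratic"``
    or ``"log"`` time-since-invasion response (active only post-invasion,
    with an optional post-invasion step).  ``movement_structure``:
    ``"shared"`` one destination logit for every ordered pair, ``"by_origin"``
    one logit per origin population (destinations equal), ``"full"`` one per
    ordered origin-destination pair.  ``detection``: ``"constant"`` or
    ``"by_pop"``.
    """

    juvenile_survival: bool = True
    survival_pop_effects: bool = False
    survival_tsi: str = "null"
    survival_post_step: bool = False
    juv_tsi_interaction: bool = False
    movement_structure: str = "shared"
    movement_tsi: str = "null"
    movement_post_step: bool = False
    detection: str = "constant"

    def __post_init__(self):
        for f, val in (("survival_tsi", self.survival_tsi),
                       ("movement_tsi", self.movement_tsi)):
            if val not in TSI_FORMS:
                raise ValueError(f"{f} must be one of {TSI_FORMS}")
        if self.movement_structure not in ("shared", "by_origin", "full"):
            raise ValueError("movement_structure: shared | by_origin | full")
        if self.detection not in ("constant", "by_pop"):
            raise ValueError("detection: constant | by_pop")

    def label(self) -> str:
        parts = [f"S~{self.survival_tsi}"]
        if self.juv_tsi_interaction:
            parts[-1] += "*age"
        parts.append(f"psi~{self.movement_tsi}")
        return " ".join(parts)


def _tsi_design(schedule: InvasionSchedule):
    """(R, T) arrays: post flag, linear tsi, tsi^2, log(tsi + 1)."""
    R, T = len(schedule.populations), schedule.n_years
    post = np.zeros((R, T))
    z = np.zeros((R, T))
    for ri, r in enumerate(schedule.populations):
        for ti, t in enumerate(schedule.years):
            v = schedule.tsi(r, t)
            if v is not None:
                post[ri, ti] = 1.0
                z[ri, ti] = v
    return post, z, z * z, np.log1p(z) * post


def _tsi_terms(form: str, step: bool):
    names = []
    if step:
        names.append("post")
    if form == "linear":
        names.append("tsi")
    elif form == "quadratic":
        names.extend(["tsi", "tsi2"])
    elif form == "log":
        names.append("log_tsi")
    return names


class _ParamLayout:
    """Flat parameter vector <-> named blocks for a MultistateSpec."""

    def __init__(self, spec: MultistateSpec, schedule: InvasionSchedule):
        self.spec, self.schedule = spec, schedule
        R = len(schedule.populations)
        names: list[str] = ["S:intercept"]
        if spec.juvenile_survival:
            names.append("S:juvenile")
        if spec.survival_pop_effects:
            names += [f"S:pop:{r}" for r in schedule.populations[1:]]
        names += [f"S:{t}" for t in _tsi_terms(spec.survival_tsi,
                                               spec.survival_post_step)]
        if spec.juv_tsi_interaction:
            names.append("S:juvenile_x_tsi")
        if spec.movement_structure == "shared":
            names.append("move:dest")
        elif spec.movement_structure == "by_origin":
            names += [f"move:{r}" for r in schedule.populations]
        else:
            names += [f"move:{r}->{s}" for r in schedule.populations
                      for s in schedule.populations if s != r]
        names += [f"move:{t}" for t in _tsi_terms(spec.movement_tsi,
                                                  spec.movement_post_step)]
        if spec.detection == "constant":
            names.append("p:intercept")
        else:
            names += [f"p:{r}" for r in schedule.populations]
        self.names = names
        self.k = len(names)
        self._idx = {n: i for i, n in enumerate(names)}
        self.post, self.z, self.z2, self.logz = _tsi_design(schedule)

    def start(self) -> np.ndarray:
        x = np.zeros(self.k)
        x[self._idx["S:intercept"]] = 1.4
        if self.spec.juvenile_survival:
            x[self._idx["S:juvenile"]] = -1.0
        for n in self.names:
            if n.startswith("move:") and ("->" in n or n in ("move:dest",)
                                          or n.split(":")[1] in self.schedule.populations):
                x[self._idx[n]] = -2.0
        return x

    def _tsi_eta(self, prefix: str, form: str, step: bool, x):
        eta = np.zeros_like(self.post)
        terms = _tsi_terms(form, step)
        for t in terms:
            b = x[self._idx[f"{prefix}:{t}"]]
            if t == "post":
                eta += b * self.post
            elif t == "tsi":
                eta += b * self.z * self.post
            elif t == "tsi2":
                eta += b * self.z2 * self.post
            else:
                eta += b * self.logz
        return eta

    def rates(self, x: np.ndarray):
        """Natural-scale ``S (R,T,2 groups)``, ``psi (R,R,T)``, ``p (R,T)``.

        Survival group 0 = juvenile, group 1 = subadult/adult (equal).
        """
        sched, spec = self.schedule, self.spec
        R, T = len(sched.populations), sched.n_years
        eta = np.full((R, T), x[self._idx["S:intercept"]])
        if spec.survival_pop_effects:
            for r in sched.populations[1:]:
                eta[sched.index(r)] += x[self._idx[f"S:pop:{r}"]]
        eta = eta + self._tsi_eta("S", spec.survival_tsi, spec.survival_post_step, x)
        eta_j = eta.copy()
        if spec.juvenile_survival:
            eta_j += x[self._idx["S:juvenile"]]
        if spec.juv_tsi_interaction:
            eta_j += x[self._idx["S:juvenile_x_tsi"]] * self.z * self.post
        S = np.empty((R, T, 2))
        S[:, :, 0] = 1.0 / (1.0 + np.exp(-eta_j))
        S[:, :, 1] = 1.0 / (1.0 + np.exp(-eta))

        move_eta = self._tsi_eta("move", spec.movement_tsi,
                                 spec.movement_post_step, x)
        psi = np.zeros((R, R, T))
        avail = np.array([[sched.is_available(s, t + 1) for t in sched.years]
                          for s in sched.populations])  # (R, T)
        for ri in range(R):
            logits = np.full((R, T), -np.inf)
            logits[ri] = 0.0
            for si, s in enumerate(sched.populations):
                if si == ri:
                    continue
                if spec.movement_structure == "shared":
                    base = x[self._idx["move:dest"]]
                elif spec.movement_structure == "by_origin":
                    base = x[self._idx[f"move:{sched.populations[ri]}"]]
                else:
                    base = x[self._idx[f"move:{sched.populations[ri]}->{s}"]]
                logits[si] = base
                logits[si] = np.where(avail[si], logits[si] + move_eta[ri], -np.inf)
            ex = np.exp(logits - logits.max(axis=0, keepdims=True))
            psi[ri] = ex / ex.sum(axis=0, keepdims=True)

        if spec.detection == "constant":
            p = np.full((R, T), 1.0 / (1.0 + np.exp(-x[self._idx["p:intercept"]])))
        else:
            pv = np.array([x[self._idx[f"p:{r}"]] for r in sched.populations])
            p = np.repeat((1.0 / (1.0 + np.exp(-pv)))[:, None], T, axis=1)
        return S, psi, p


# --------------------------------------------------------------------------
# data encoding


@dataclass
class EncodedHistories:
    """Capture histories as integer arrays ready for the forward recursion."""

    obs: np.ndarray        # (n, T) population index, -1 = not seen
    band_occ: np.ndarray   # (n,) occasion index of banding
    age_at_band: np.ndarray
    schedule: InvasionSchedule

    @property
    def n(self) -> int:
        return self.obs.shape[0]

    def age_group(self) -> np.ndarray:
        """(n, T) survival age group at each occasion: 0 juvenile, 1 older."""
        n, T = self.obs.shape
        occ = np.arange(T)[None, :]
        age = self.age_at_band[:, None] + occ - self.band_occ[:, None]
        return (age >= 1).astype(int)


def encode_histories(captures: pd.DataFrame, schedule: InvasionSchedule) -> EncodedHistories:
    years = [str(y) for y in schedule.years]
    code = {r: i for i, r in enumerate(schedule.populations)}
    obs = np.full((len(captures), len(years)), -1, dtype=int)
    for j, y in enumerate(years):
        col = captures[y].astype(str).to_numpy()
        for i, v in enumerate(col):
            if v != NOT_SEEN:
                try:
                    obs[i, j] = code[v]
                except KeyError:
                    raise ValueError(
                        f"row {i}: observed population {v!r} not in registry"
                    ) from None
    band_year = captures["band_year"].to_numpy(dtype=int)
    band_occ = band_year - schedule.study_years[0]
    return EncodedHistories(
        obs=obs, band_occ=band_occ,
        age_at_band=captures["age_at_banding"].to_numpy(dtype=int),
        schedule=schedule)


# --------------------------------------------------------------------------
# likelihood


def movement_row(dest_logits: np.ndarray, origin: int,
                 mask: np.ndarray) -> np.ndarray:
    """One multinomial-logit movement row with availability masking.

    ``dest_logits`` are logits relative to fidelity (entry at ``origin``
    ignored); ``mask`` is True for available destinations.  Masked
    destinations get probability 0 and the row renormalises over fidelity
    plus the remainder; with everything masked the row degenerates to
    fidelity 1.  The returned row sums to 1.
    """
    R = len(dest_logits)
    logits = np.full(R, -np.inf)
    logits[origin] = 0.0
    for s in range(R):
        if s != origin and mask[s]:
            logits[s] = dest_logits[s]
    ex = np.exp(logits - logits.max())
    return ex / ex.sum()


def _transition_tensor(S, psi):
    """(T, 2, R+1, R+1) transition matrices including the dead state."""
    R, _, T = psi.shape
    Tm = np.zeros((T, 2, R + 1, R + 1))
    for g in (0, 1):
        Tm[:, g, :R, :R] = np.einsum("rt,rst->trs", S[:, :, g], psi)
        Tm[:, g, :R, R] = (1.0 - S[:, :, g]).T
    Tm[:, :, R, R] = 1.0
    return Tm


def _emission(obs_col, p_col, R):
    """(n, R+1) emission probabilities for one occasion.

    ``obs_col`` population index or -1; ``p_col`` resight probability per
    population.  Dead state emits "not seen" with probability 1.
    """
    n = obs_col.shape[0]
    e = np.zeros((n, R + 1))
    ns = obs_col < 0
    e[ns, :R] = 1.0 - p_col[None, :]
    e[ns, R] = 1.0
    seen = ~ns
    e[seen, obs_col[seen]] = p_col[obs_col[seen]]
    return e


def _forward_negloglik(enc: EncodedHistories, S, psi, p) -> float:
    R = len(enc.schedule.populations)
    n, T = enc.obs.shape
    Tm = _transition_tensor(S, psi)
    group = enc.age_group()
    alpha = np.zeros((n, R + 1))
    init_ok = enc.obs[np.arange(n), enc.band_occ] >= 0
    if not init_ok.all():
        raise ValueError("history not observed at banding occasion")
    alpha[np.arange(n), enc.obs[np.arange(n), enc.band_occ]] = 1.0
    total = 0.0
    for ti in range(T - 1):
        active = enc.band_occ <= ti
        if not active.any():
            continue
        a = alpha[active]
        g = group[active, ti]
        step = np.einsum("ns,nst->nt", a, Tm[ti, g])
        e = _emission(enc.obs[active, ti + 1], p[:, ti + 1], R)
        step = step * e
        c = step.sum(axis=1)
        if np.any(c <= 0):
            return 1e10
        total += np.log(c).sum()
        alpha[active] = step / c[:, None]
    return -total


def history_loglik(history: pd.DataFrame | EncodedHistories,
                   schedule: InvasionSchedule, S, psi, p) -> float:
    """Log-likelihood of capture histories under given natural-scale rates.

    ``S`` may be (R, T, 2) by age group or (R, T, 3) by age class (the
    subadult and adult slices must then agree).
    """
    if isinstance(history, pd.DataFrame):
        enc = encode_histories(history, schedule)
    else:
        enc = history
    S = np.asarray(S, dtype=float)
    if S.ndim == 3 and S.shape[2] == 3:
        S = S[:, :, [0, 2]]
    return -_forward_negloglik(enc, S, np.asarray(psi, float), np.asarray(p, float))


# --------------------------------------------------------------------------
# fitting


@dataclass
class MultistateFit:
    """Fitted multistate model with natural-scale rate extraction."""

    fit: MLFit
    spec: MultistateSpec
    schedule: InvasionSchedule
    _layout: _ParamLayout = field(repr=False, default=None)

    @property
    def loglik(self) -> float:
        return self.fit.loglik

    @property
    def k(self) -> int:
        return self.fit.k

    @property
    def n(self) -> int:
        return self.fit.n

    def rates(self):
        """Point estimates ``(S, psi, p)`` on the natural scale."""
        return self._layout.rates(self.fit.params)

    def rates_with_se(self, rel_step: float = 1e-5):
        """Rates plus delta-method SEs from the parameter covariance."""
        x = self.fit.params
        S0, psi0, p0 = self._layout.rates(x)
        shapes = [S0.shape, psi0.shape, p0.shape]
        sizes = [S0.size, psi0.size, p0.size]

        def flat(xv):
            S, psi, p = self._layout.rates(xv)
            return np.concatenate([S.ravel(), psi.ravel(), p.ravel()])

        k = x.size
        J = np.empty((sum(sizes), k))
        h = rel_step * np.maximum(np.abs(x), 1.0)
        for i in range(k):
            e = np.zeros(k); e[i] = h[i]
            J[:, i] = (flat(x + e) - flat(x - e)) / (2.0 * h[i])
        var = np.einsum("ij,jk,ik->i", J, self.fit.covariance, J)
        var[var < 0] = 0.0
        se = np.sqrt(var)
        out, pos = [], 0
        for shp, sz in zip(shapes, sizes):
            out.append(se[pos:pos + sz].reshape(shp))
            pos += sz
        return (S0, psi0, p0), tuple(out)

    def to_frame(self) -> pd.DataFrame:
        (S, psi, p), (S_se, psi_se, p_se) = self.rates_with_se()
        sched = self.schedule
        rows = []
        for ri, r in enumerate(sched.populations):
            for ti, t in enumerate(sched.years):
                for g, ages in ((0, (0,)), (1, (1, 2))):
                    for a in ages:
                        rows.append((r, t, a, "S", S[ri, ti, g], S_se[ri, ti, g]))
                for si, s in enumerate(sched.populations):
                    lab = "psi_rr" if si == ri else f"psi_rs:{s}"
                    rows.append((r, t, None, lab, psi[ri, si, ti], psi_se[ri, si, ti]))
                rows.append((r, t, None, "p", p[ri, ti], p_se[ri, ti]))
        return pd.DataFrame(rows, columns=["population", "year", "age_class",
                                           "parameter", "estimate", "se"])


def fit_multistate(
    captures: pd.DataFrame | EncodedHistories,
    schedule: InvasionSchedule,
    spec: MultistateSpec | None = None,
    n_starts: int = 5,
    seed: int = 0,
    gtol: float = 1e-8,
) -> MultistateFit:
    """Maximum-likelihood fit of the multistate model.

    ``n`` for information criteria is the number of individuals.  Flat
    (inestimable) parameter directions are flagged on the returned fit.
    """
    enc = (captures if isinstance(captures, EncodedHistories)
           else encode_histories(captures, schedule))
    if enc.n < 1 or enc.obs.shape[1] < 2:
        raise ValueError("need at least one history with at least two occasions")
    spec = spec or MultistateSpec()
    layout = _ParamLayout(spec, schedule)

    def nll(x):
        S, psi, p = layout.rates(x)
        return _forward_negloglik(enc, S, psi, p)

    fit = maximize_loglik(nll, layout.start(), layout.names, n_obs=enc.n,
                          n_starts=n_starts, seed=seed, gtol=gtol)
    return MultistateFit(fit=fit, spec=spec, schedule=schedule, _layout=layout)


# --------------------------------------------------------------------------
# estimability and derived quantities


def estimability_screen(
    captures: pd.DataFrame, schedule: InvasionSchedule,
    fit: MultistateFit | None = None,
) -> set[tuple[str, int]]:
    """Population-years whose movement cannot be informed by the data.

    A population-year (r, t) is flagged when no marked individual was
    observed in r in year t (nobody is at risk of a recorded transition out
    of r at t), or r is not yet available in t.  When a fitted model with
    ``"full"`` movement structure is supplied, origins whose movement
    coefficients sit in a flat direction of the observed information are
    additionally flagged for all their years.  Downstream contribution
    estimates exclude flagged population-years.
    """
    enc = encode_histories(captures, schedule)
    flagged: set[tuple[str, int]] = set()
    years = list(schedule.years)
    # transitions out of (r, t) only exist for t < last year
    for ri, r in enumerate(schedule.populations):
        for ti, t in enumerate(years[:-1]):
            if not schedule.is_available(r, t):
                flagged.add((r, t))
                continue
            seen_here = np.any(enc.obs[:, ti] == ri)
            if not seen_here:
                flagged.add((r, t))
    if fit is not None:
        for name in fit.fit.flat_directions:
            if name.startswith("move:") and "->" in name:
                origin = name[5:].split("->")[0]
                flagged.update((origin, t) for t in years[:-1])
    return flagged


@dataclass(frozen=True)
class PhiEstimate:
    """Joint survival-and-movement probabilities for one (r, t, age group).

    ``retention`` is S·psi_rr; ``emigration[s]`` is S·psi_rs.  The identity
    retention + sum(emigration) = S holds exactly.
    """

    retention: float
    emigration: np.ndarray
    retention_se: float
    emigration_se: np.ndarray

    @property
    def survival(self) -> float:
        return self.retention + float(np.sum(self.emigration))


def derive_phi(S: float, psi_row: np.ndarray, origin: int,
               S_se: float = 0.0, psi_se: np.ndarray | None = None) -> PhiEstimate:
    """Products phi = S·psi with first-order delta SEs (independence)."""
    psi_row = np.asarray(psi_row, dtype=float)
    if psi_se is None:
        psi_se = np.zeros_like(psi_row)
    var = (psi_row ** 2) * S_se ** 2 + (S ** 2) * np.asarray(psi_se) ** 2
    se = np.sqrt(var)
    emig = np.delete(S * psi_row, origin)
    emig_se = np.delete(se, origin)
    return PhiEstimate(retention=float(S * psi_row[origin]),
                       emigration=emig,
                       retention_se=float(se[origin]),
                       emigration_se=emig_se)
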
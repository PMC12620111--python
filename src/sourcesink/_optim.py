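"""Shared optimisation helpers: multi-start quasi-Newton ML and FD Hessians."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

__all__ = ["fd_hessian", "MLFit", "maximize_loglik"]


def fd_hessian(f, x, rel_step: float = 1e-4):
    """Central-difference Hessian of a scalar function at ``x``."""
    x = np.asarray(x, dtype=float)
    k = x.size
    h = rel_step * np.maximum(np.abs(x), 1.0)
    H = np.empty((k, k))
    f0 = f(x)
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = h[i]
            ej = np.zeros(k); ej[j] = h[j]
            if i == j:
                H[i, i] = (f(x + ei) - 2.0 * f0 + f(x - ei)) / h[i] ** 2
            else:
                H[i, j] = H[j, i] = (
                    f(x + ei + ej) - f(x + ei - ej)
                    - f(x - ei + ej) + f(x - ei - ej)
                ) / (4.0 * h[i] * h[j])
    return H


@dataclass
class MLFit:
    """A maximum-likelihood fit: estimates, covariance and fit metadata.

    ``covariance`` is the inverse observed information (pseudo-inverse when
    the information matrix is singular, with the deficient directions listed
    in ``flat_directions``).
    """

    params: np.ndarray
    loglik: float
    covariance: np.ndarray
    n: int
    k: int
    converged: bool
    param_names: list[str]
    flat_directions: list[str]
    n_starts: int = 1

    @property
    def se(self) -> np.ndarray:
        d = np.diag(self.covariance).copy()
        d[d < 0] = np.nan
        return np.sqrt(d)


def maximize_loglik(
    negloglik,
    x0: np.ndarray,
    param_names: list[str],
    n_obs: int,
    n_starts: int = 5,
    jitter: float = 0.5,
    seed: int = 0,
    gtol: float = 1e-8,
    bounds=None,
    singular_tol: float = 1e-8,
) -> MLFit:
    """Multi-start L-BFGS maximisation of a log-likelihood.

    Starts from ``x0`` and ``n_starts - 1`` jittered copies (seeded normal
    perturbations of scale ``jitter``); keeps the best optimum.  Standard
    errors come from the inverse finite-difference observed information;
    near-zero-curvature eigendirections are flagged by the parameter with
    the largest loading.
    """
    rng = np.random.default_rng(seed)
    x0 = np.asarray(x0, dtype=float)
    best = None
    any_converged = False
    for s in range(max(n_starts, 1)):
        xs = x0 if s == 0 else x0 + jitter * rng.standard_normal(x0.size)
        res = minimize(negloglik, xs, method="L-BFGS-B", bounds=bounds,
                       options={"gtol": gtol, "maxiter": 500})
        any_converged = any_converged or res.success
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError(
            f"optimiser failed; best objective "
            f"{None if best is None else best.fun}")

    H = fd_hessian(negloglik, best.x)  # observed information (negloglik curvature)
    H = 0.5 * (H + H.T)
    eigval, eigvec = np.linalg.eigh(H)
    scale = max(np.abs(eigval).max(), 1.0)
    flat = []
    for i, ev in enumerate(eigval):
        if ev < singular_tol * scale:
            flat.append(param_names[int(np.argmax(np.abs(eigvec[:, i])))])
    cov = np.linalg.pinv(H, rcond=singular_tol)
    return MLFit(
        params=best.x, loglik=-float(best.fun), covariance=cov,
        n=n_obs, k=x0.size, converged=bool(any_converged),
        param_names=list(param_names), flat_directions=flat,
        n_starts=max(n_starts, 1))
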
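"""Independent brute-force oracles shared across test modules.

These deliberately use plain Python loops and exhaustive enumeration —
nothing from the implementation paths they check.
"""

import itertools
import math

import numpy as np
from scipy.special import comb


def brute_force_loglik(obs, band_occ, S, psi, p, age_at_band=2):
    """Exhaustive sum over all latent state paths (dead = R).

    ``S`` is (R, T, 2) by age group; the path probability is the product of
    transition and emission terms after the banding occasion.
    """
    R = psi.shape[0]
    T = len(obs)
    total = 0.0
    free = T - 1 - band_occ
    for path in itertools.product(range(R + 1), repeat=free):
        states = [obs[band_occ]] + list(path)
        prob = 1.0
        for j in range(free):
            t = band_occ + j
            cur, nxt = states[j], states[j + 1]
            age = min(age_at_band + j, 2)
            g = 0 if age == 0 else 1
            if cur == R:
                prob *= 1.0 if nxt == R else 0.0
            elif nxt == R:
                prob *= 1.0 - S[cur, t, g]
            else:
                prob *= S[cur, t, g] * psi[cur, nxt, t]
            o = obs[t + 1]
            if nxt == R:
                prob *= 1.0 if o == -1 else 0.0
            elif o == -1:
                prob *= 1.0 - p[nxt, t + 1]
            elif o == nxt:
                prob *= p[nxt, t + 1]
            else:
                prob = 0.0
            if prob == 0.0:
                break
        total += prob
    return np.log(total)


def brute_mixture_loglik(k_obs, theta, lam, p_det, k_max):
    """Plain-Python enumeration over breeder state x latent attempt count."""
    total = 0.0
    norm = 1.0 - math.exp(-lam)
    for k in k_obs:
        L = (1.0 - theta) if k == 0 else 0.0
        for K in range(1, k_max + 1):
            ztp = lam ** K * math.exp(-lam) / (math.factorial(K) * norm)
            if K >= k:
                binom = comb(K, k, exact=True) * p_det ** k * (1 - p_det) ** (K - k)
                L += theta * ztp * binom
        total += math.log(L)
    return total
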
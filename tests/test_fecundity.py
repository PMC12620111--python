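import math

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import brentq
from scipy.special import comb

from sourcesink.fecundity import (BreedingAttemptsSpec, _mixture_loglik,
                                  expected_attempts, fecundity,
                                  fit_breeding_attempts, fit_nest_survival,
                                  nest_success)
from sourcesink.glmm import _family_derivs

from helpers import brute_mixture_loglik


def breeder_frame(k_obs, age=2):
    return pd.DataFrame({
        "individual_id": np.arange(len(k_obs)), "population": "A",
        "year": 2000, "age_class": age, "attempts_observed": k_obs})


def simulate_counts(rng, n, theta, lam, p_det):
    breeds = rng.random(n) < theta
    k_true = np.zeros(n, dtype=int)
    idx = np.flatnonzero(breeds)
    # zero-truncated Poisson by rejection
    for i in idx:
        k = 0
        while k == 0:
            k = rng.poisson(lam)
        k_true[i] = k
    return rng.binomial(k_true, p_det)


class TestMixtureLikelihood:
    def test_matches_brute_force_enumeration(self, rng):
        """Marginal likelihood vs exhaustive (breeder x K) enumeration."""
        k_obs = np.array([0, 0, 1, 2, 0, 3, 1, 5])
        for theta, lam, p in [(0.5, 1.2, 0.7), (0.9, 3.0, 0.4), (0.2, 0.5, 0.95)]:
            Xt = np.ones((len(k_obs), 1))
            got = _mixture_loglik(k_obs, Xt, Xt,
                                  np.array([math.log(theta / (1 - theta))]),
                                  np.array([math.log(lam)]), p, k_max=60)
            want = brute_mixture_loglik(k_obs, theta, lam, p, k_max=60)
            assert got == pytest.approx(want, abs=1e-10)

    def test_truncation_stability(self):
        """Raising K_max far beyond 10*lambda leaves logL unchanged."""
        k_obs = np.array([0, 1, 2, 4])
        Xt = np.ones((4, 1))
        args = (np.array([0.2]), np.array([math.log(1.5)]), 0.8)
        base = _mixture_loglik(k_obs, Xt, Xt, *args, k_max=15)
        bigger = _mixture_loglik(k_obs, Xt, Xt, *args, k_max=200)
        assert abs(bigger - base) < 1e-8

    def test_half_mass_at_zero_when_theta_half_and_perfect_detection(self):
        # ZTP puts no mass at zero, so P(k = 0) = 1 - theta = 0.5
        L0 = _mixture_loglik(np.array([0]), np.ones((1, 1)), np.ones((1, 1)),
                             np.array([0.0]), np.array([0.3]), 1.0, 40)
        assert math.exp(L0) == pytest.approx(0.5, abs=1e-12)


class TestFitBreedingAttempts:
    def test_collapses_to_ztp_mle_when_fixed(self, rng):
        """theta = 1, p_det = 1 pinned: lambda-hat is the ZTP rate MLE."""
        k_obs = simulate_counts(rng, 500, theta=1.0, lam=1.7, p_det=1.0)
        fit = fit_breeding_attempts(
            breeder_frame(k_obs),
            spec=BreedingAttemptsSpec(theta_age=False, fix_theta=1.0,
                                      fix_p_det=1.0), n_starts=1)
        _, _, lam_hat, _ = fit.predict("A", 2000, 2)
        # independent oracle: ZTP MLE solves mean = lam / (1 - e^-lam)
        kbar = k_obs.mean()
        lam_oracle = brentq(lambda l: l / (1 - np.exp(-l)) - kbar, 1e-6, 50)
        assert lam_hat == pytest.approx(lam_oracle, abs=1e-4)

    def test_recovery_with_external_detection(self, rng):
        k_obs = simulate_counts(rng, 2000, theta=0.6, lam=1.5, p_det=0.8)
        fit = fit_breeding_attempts(
            breeder_frame(k_obs),
            spec=BreedingAttemptsSpec(theta_age=False, fix_p_det=0.8),
            n_starts=2)
        th, th_se, lam_hat, _ = fit.predict("A", 2000, 2)
        assert abs(th - 0.6) < 3 * th_se
        assert th_se < 0.1

    def test_free_detection_reports_the_ridge(self, rng):
        """With p_det free the thinning invariance leaves a flat direction."""
        k_obs = simulate_counts(rng, 2000, theta=0.6, lam=1.5, p_det=0.8)
        fit = fit_breeding_attempts(
            breeder_frame(k_obs),
            spec=BreedingAttemptsSpec(theta_age=False), n_starts=2)
        th, th_se, lam_hat, lam_se = fit.predict("A", 2000, 2)
        # the identifiable combination lambda * p_det is pinned down even
        # though the individual parameters are not
        assert lam_hat * fit.p_det == pytest.approx(1.5 * 0.8, abs=0.12)
        assert fit.fit.flat_directions or th_se > 0.05 or lam_se > 0.5

    def test_all_zero_counts_not_identifiable(self):
        with pytest.raises(ValueError, match="not jointly identifiable"):
            fit_breeding_attempts(breeder_frame(np.zeros(50, dtype=int)))

    def test_rejects_juvenile_records(self):
        with pytest.raises(ValueError, match="1 or 2"):
            fit_breeding_attempts(breeder_frame(np.array([1, 2]), age=0))


class TestExpectedAttempts:
    def test_small_rate_limit(self):
        N, _ = expected_attempts(1e-9)
        assert N == pytest.approx(1.0, abs=1e-8)

    def test_known_value(self):
        # 1.5 / (1 - e^-1.5) evaluated independently to high precision
        N, _ = expected_attempts(1.5)
        assert N == pytest.approx(1.9308254, abs=1e-6)

    def test_truncation_negligible_at_large_rate(self):
        N, _ = expected_attempts(10.0)
        assert N == pytest.approx(10.000454, abs=1e-5)
        assert abs(N - 10.0) < 1e-3

    def test_rejects_nonpositive_rate(self):
        with pytest.raises(ValueError):
            expected_attempts(0.0)

    def test_delta_se_scales_with_rate_se(self):
        _, se = expected_attempts(1.5, lam_se=0.1)
        # derivative of the ZTP mean at 1.5, via central difference oracle
        h = 1e-6
        dN = (expected_attempts(1.5 + h)[0] - expected_attempts(1.5 - h)[0]) / (2 * h)
        assert se == pytest.approx(abs(dN) * 0.1, rel=1e-5)


class TestNestSurvival:
    def test_zero_hazard_means_certain_survival(self):
        ll, _, _ = _family_derivs("cloglog_hazard", np.array([0.0]),
                                  np.array([-np.inf]), np.array([10.0]))
        assert math.exp(ll[0]) == pytest.approx(1.0)

    def test_interval_survival_is_power_of_daily(self):
        # daily survival 0.99 over 10 exposure days -> 0.99^10 = 0.9044
        h = -math.log(0.99)
        ll, _, _ = _family_derivs("cloglog_hazard", np.array([0.0]),
                                  np.array([math.log(h)]), np.array([10.0]))
        assert math.exp(ll[0]) == pytest.approx(0.99 ** 10, abs=1e-12)
        assert math.exp(ll[0]) == pytest.approx(0.9044, abs=1e-4)

    def test_likelihood_invariant_to_splitting_survived_interval(self):
        """One d-day survived interval == two adjoining pieces d1 + d2."""
        h = np.array([math.log(0.012)])
        whole, _, _ = _family_derivs("cloglog_hazard", np.array([0.0]), h,
                                     np.array([14.0]))
        part1, _, _ = _family_derivs("cloglog_hazard", np.array([0.0]), h,
                                     np.array([5.0]))
        part2, _, _ = _family_derivs("cloglog_hazard", np.array([0.0]), h,
                                     np.array([9.0]))
        assert whole[0] == pytest.approx(part1[0] + part2[0], abs=1e-12)

    def test_recovery_without_random_effects(self, rng):
        dsr = 0.97
        n = 2000
        d = rng.integers(2, 22, n)
        fail = (rng.random(n) < 1 - dsr ** d).astype(int)
        nests = pd.DataFrame({"population": "A", "year": 2000,
                              "interval_days": d, "interval_fate": 1 - fail})
        fit = fit_nest_survival(nests, random_effects=False)
        s, s_se = fit.predict_daily_survival("A", 2000)
        assert abs(s - dsr) < 0.005

    def test_empty_input_rejected(self):
        empty = pd.DataFrame(columns=["population", "year", "interval_days",
                                      "interval_fate"])
        with pytest.raises(ValueError, match="no nest intervals"):
            fit_nest_survival(empty)


class TestNestSuccess:
    @pytest.mark.parametrize("s,expect", [(1.0, 1.0), (0.0, 0.0)])
    def test_boundaries(self, s, expect):
        assert nest_success(s)[0] == expect

    def test_standard_cycle(self):
        P, _ = nest_success(0.99, 58)
        assert P == pytest.approx(0.99 ** 58, abs=1e-15)
        assert P == pytest.approx(0.5583, abs=1e-4)

    def test_rejects_negative_cycle(self):
        with pytest.raises(ValueError):
            nest_success(0.9, -1)

    def test_delta_se(self):
        P, se = nest_success(0.99, 58, se=0.001)
        assert se == pytest.approx(58 * 0.99 ** 57 * 0.001, rel=1e-12)


class TestFecundityProduct:
    def test_zero_breeding_means_zero_fecundity(self):
        assert fecundity(0.0, 5.0, 0.9, 2.0)[0] == 0.0

    def test_juveniles_never_breed(self):
        M, se = fecundity(0.9, 3.0, 0.9, 2.0, age_class=0,
                          ses=(0.1, 0.1, 0.1, 0.1))
        assert M == 0.0 and se == 0.0

    def test_direct_product(self):
        M, _ = fecundity(0.5, 2.0, 0.6, 1.0)
        assert M == pytest.approx(0.6, abs=1e-15)

    def test_monotone_in_each_component(self, rng):
        base = (0.5, 2.0, 0.6, 1.0)
        M0, _ = fecundity(*base)
        for i in range(4):
            bumped = list(base)
            bumped[i] *= 1.1 if i in (1, 3) else 1.0
            bumped[i] = min(bumped[i] + 0.05, 1.0) if i in (0, 2) else bumped[i]
            M1, _ = fecundity(*bumped)
            assert M1 >= M0

    def test_rejects_invalid_probability(self):
        with pytest.raises(ValueError, match="probability"):
            fecundity(1.4, 2.0, 0.6, 1.0)
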
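import numpy as np
import pandas as pd
import pytest

import sourcesink as ss
from sourcesink.contributions import (InfeasibleMomentsError, age_proportions,
                                      age_weighted, beta_from_moments,
                                      classify, contribution_age,
                                      emigration_contribution,
                                      lognormal_from_moments, propagate,
                                      retention_age)


class TestBetaMoments:
    def test_uniform_case(self):
        a, b = beta_from_moments(0.5, np.sqrt(1.0 / 12.0))
        assert a == pytest.approx(1.0, abs=1e-12)
        assert b == pytest.approx(1.0, abs=1e-12)

    def test_closed_form_inversion(self):
        a, b = beta_from_moments(0.8, 0.1)
        assert (a, b) == pytest.approx((12.0, 3.0), abs=1e-12)

    def test_round_trip_exact(self):
        for mean, sd in [(0.3, 0.05), (0.9, 0.02), (0.5, 0.2)]:
            a, b = beta_from_moments(mean, sd)
            assert a / (a + b) == pytest.approx(mean, abs=1e-12)
            var = a * b / ((a + b) ** 2 * (a + b + 1))
            assert np.sqrt(var) == pytest.approx(sd, abs=1e-12)

    def test_empirical_moments_at_large_sample(self, rng):
        a, b = beta_from_moments(0.8, 0.1)
        draws = rng.beta(a, b, 1_000_000)
        assert draws.mean() == pytest.approx(0.8, rel=0.005)
        assert draws.std() == pytest.approx(0.1, rel=0.005)

    def test_infeasible_moments_raise(self):
        with pytest.raises(InfeasibleMomentsError, match="infeasible"):
            beta_from_moments(0.5, 0.6)

    def test_degenerate_sd_rejected_here(self):
        # point masses are the caller's job (propagate handles sd = 0)
        with pytest.raises(InfeasibleMomentsError):
            beta_from_moments(0.5, 0.0)


class TestLognormalMoments:
    def test_point_mass(self):
        mu, sig = lognormal_from_moments(2.0, 0.0)
        assert mu == pytest.approx(np.log(2.0)) and sig == 0.0

    def test_known_values(self):
        mu, sig = lognormal_from_moments(2.0, 1.0)
        assert sig ** 2 == pytest.approx(np.log(1.25), abs=1e-12)
        assert mu == pytest.approx(np.log(2.0) - np.log(1.25) / 2, abs=1e-12)
        mu2, sig2 = lognormal_from_moments(1.0, 1.0)
        assert sig2 ** 2 == pytest.approx(np.log(2.0), abs=1e-12)
        assert mu2 == pytest.approx(-np.log(2.0) / 2, abs=1e-12)

    def test_empirical_moments_at_large_sample(self, rng):
        mu, sig = lognormal_from_moments(2.0, 1.0)
        draws = rng.lognormal(mu, sig, 1_000_000)
        assert draws.mean() == pytest.approx(2.0, rel=0.005)
        assert draws.std() == pytest.approx(1.0, rel=0.01)

    def test_rejects_nonpositive_mean(self):
        with pytest.raises(ValueError):
            lognormal_from_moments(0.0, 1.0)


class TestContributionAlgebra:
    def test_closed_population_reduction(self):
        # movement row sums to 1, so C = S_a + M * S_0
        C = contribution_age(0.72, 0.18, 0.5, 0.36, 0.24)
        assert C == pytest.approx(0.9 + 0.5 * 0.6, abs=1e-12)

    def test_no_fecundity_gives_survival(self):
        assert contribution_age(0.72, 0.18, 0.0, 0.4, 0.1) == pytest.approx(0.9)

    def test_direct_arithmetic(self):
        C = contribution_age(0.72, 0.18, 0.5, 0.4, 0.1)
        assert C == pytest.approx(1.15, abs=1e-12)
        R = retention_age(0.72, 0.5, 0.4)
        assert R == pytest.approx(0.92, abs=1e-12)
        E = emigration_contribution(C, R)
        assert E == pytest.approx(0.23, abs=1e-12)

    def test_full_fidelity_makes_R_equal_C(self):
        C = contribution_age(0.9, 0.0, 0.5, 0.6, 0.0)
        R = retention_age(0.9, 0.5, 0.6)
        assert C == R

    def test_dual_formula_identity(self, rng):
        """E = C - R equals the direct emigration expression exactly."""
        for _ in range(1000):
            S_a, S_0 = rng.uniform(0.2, 0.95, 2)
            fid = rng.uniform(0.3, 1.0)
            M = rng.uniform(0.0, 1.5)
            phi_rr_a, phi_rs_a = S_a * fid, S_a * (1 - fid)
            phi_rr_0, phi_rs_0 = S_0 * fid, S_0 * (1 - fid)
            C = contribution_age(phi_rr_a, phi_rs_a, M, phi_rr_0, phi_rs_0)
            R = retention_age(phi_rr_a, M, phi_rr_0)
            direct = phi_rs_a + M * phi_rs_0
            assert emigration_contribution(C, R) == pytest.approx(direct, abs=1e-12)

    def test_inconsistent_inputs_raise(self):
        with pytest.raises(ValueError, match="inconsistency"):
            emigration_contribution(0.5, 0.9)


class TestAgeWeighting:
    def test_weighted_sum(self):
        assert age_weighted(0.8, 1.2, 0.3, 0.7) == pytest.approx(1.08, abs=1e-12)

    def test_pure_adult(self):
        assert age_weighted(0.8, 1.2, 0.0, 1.0) == 1.2

    def test_equal_values_invariant_to_weights(self):
        for ps in (0.0, 0.25, 0.8):
            assert age_weighted(1.1, 1.1, ps, 1 - ps) == pytest.approx(1.1)

    def test_invalid_proportions(self):
        with pytest.raises(ValueError, match="non-negative"):
            age_weighted(1.0, 1.0, -0.1, 1.1)
        with pytest.raises(ValueError, match="sum to 1"):
            age_weighted(1.0, 1.0, 0.3, 0.3)


class TestAgeProportions:
    def test_counts_and_normalisation(self, small_schedule):
        years = [str(y) for y in small_schedule.years]
        rows = []
        # id 0: banded age 1 in 2000, seen in A in 2000 (age 1)
        # id 1: banded age 2 in 2000, seen in A in 2000 (age 2)
        # id 2: banded age 2 in 2000, seen in A in 2000 (age 2)
        for i, ab in [(0, 1), (1, 2), (2, 2)]:
            codes = {y: "0" for y in years}
            codes[years[0]] = "A"
            rows.append({"id": i, "band_year": 2000, "age_at_banding": ab, **codes})
        props = age_proportions(pd.DataFrame(rows), small_schedule)
        row = props[(props.population == "A") & (props.year == 2000)].iloc[0]
        assert row.prop_subadult == pytest.approx(1 / 3)
        assert row.prop_adult == pytest.approx(2 / 3)

    def test_juveniles_and_absent_years_excluded(self, small_schedule):
        years = [str(y) for y in small_schedule.years]
        codes = {y: "0" for y in years}
        codes[years[0]] = "B"
        caps = pd.DataFrame([{"id": 0, "band_year": 2000, "age_at_banding": 0,
                              **codes}])
        props = age_proportions(caps, small_schedule)
        assert len(props) == 0  # only a juvenile observation: no rows

    def test_duplicate_observations_count_once(self, small_dataset, small_schedule):
        props = age_proportions(small_dataset.captures, small_schedule)
        assert ((props.prop_subadult + props.prop_adult - 1.0).abs() < 1e-12).all()
        assert (props.prop_subadult >= 0).all() and (props.prop_adult >= 0).all()


class TestClassify:
    def test_paper_rules(self):
        assert classify(1.02, 1.40, C_point=1.2, R_point=0.9) == ("source", True)
        assert classify(0.70, 0.95) == ("sink", False)
        assert classify(0.90, 1.10) == ("stable", False)

    def test_widening_never_flips_source_to_sink(self):
        lo, hi = 1.05, 1.2
        states = []
        for widen in np.linspace(0.0, 0.5, 20):
            states.append(classify(lo - widen, hi + widen)[0])
        assert "sink" not in states
        assert states[0] == "source"

    def test_invalid_interval(self):
        with pytest.raises(ValueError):
            classify(1.2, 0.9)


def make_table(schedule, se_scale=0.0):
    truth = ss.realize_truth(schedule, ss.default_truth())
    if se_scale:
        truth.survival_se = np.full_like(truth.survival, se_scale)
        truth.theta_se = np.full_like(truth.theta, se_scale)
        truth.psi_se = np.full_like(truth.psi, se_scale / 2)
        truth.daily_survival_se = np.full_like(truth.daily_survival, se_scale / 20)
        truth.attempts_lambda_se = np.full_like(truth.attempts_lambda, se_scale)
        truth.fledged_mean_se = np.full_like(truth.fledged_mean, se_scale)
    return truth


class TestPropagate:
    def props(self, schedule):
        rows = [(r, t, 0.3, 0.7) for r in schedule.populations
                for t in schedule.years]
        return pd.DataFrame(rows, columns=["population", "year",
                                           "prop_subadult", "prop_adult"])

    def test_zero_se_collapses_to_point(self, small_schedule):
        table = make_table(small_schedule, se_scale=0.0)
        out = propagate(table, self.props(small_schedule), n_reps=200, seed=5)
        assert np.allclose(out["C_lo"], out["C"], atol=1e-12)
        assert np.allclose(out["C_hi"], out["C"], atol=1e-12)
        # deterministic classification equals the sign of C - 1
        for _, row in out.iterrows():
            want = ("source" if row.C > 1 else "sink" if row.C < 1 else "stable")
            assert row["class"] == want

    def test_replicate_identity_R_plus_E_equals_C(self, small_schedule):
        table = make_table(small_schedule, se_scale=0.05)
        out = propagate(table, self.props(small_schedule), n_reps=500, seed=6)
        assert np.allclose(out["E"], out["C"] - out["R"], atol=1e-12)
        assert (out["C_lo"] <= out["C"] + 1e-9).all()
        assert (out["C"] <= out["C_hi"] + 1e-9).all()

    def test_deterministic_under_seed(self, small_schedule):
        table = make_table(small_schedule, se_scale=0.05)
        a = propagate(table, self.props(small_schedule), n_reps=300, seed=9)
        b = propagate(table, self.props(small_schedule), n_reps=300, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_replicate_mean_near_point_for_small_se(self, small_schedule):
        table = make_table(small_schedule, se_scale=0.01)
        out = propagate(table, self.props(small_schedule), n_reps=4000, seed=10)
        half_width = (out["C_hi"] - out["C_lo"]) / 2
        assert (np.abs((out["C_hi"] + out["C_lo"]) / 2 - out["C"])
                < 0.3 * half_width + 1e-6).all()

    def test_exclusions_respected(self, small_schedule):
        table = make_table(small_schedule)
        out = propagate(table, self.props(small_schedule), n_reps=50, seed=1,
                        exclude={("A", 2000)})
        assert not (((out.population == "A") & (out.year == 2000)).any())

    def test_infeasible_moments_flagged_when_clamped(self, small_schedule):
        table = make_table(small_schedule)
        table.survival_se = np.full_like(table.survival, 0.9)  # > feasible sd
        out = propagate(table, self.props(small_schedule), n_reps=50, seed=2)
        assert out["quality_flags"].str.contains("clamped").all()
        with pytest.raises(InfeasibleMomentsError):
            propagate(table, self.props(small_schedule), n_reps=50, seed=2,
                      clamp=False)
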
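import itertools

import numpy as np
import pandas as pd
import pytest

import sourcesink as ss
from sourcesink import InvasionSchedule, MultistateSpec, fit_multistate
from sourcesink.multistate import (EncodedHistories, derive_phi,
                                   encode_histories, estimability_screen,
                                   history_loglik, movement_row)

from helpers import brute_force_loglik


def hist_df(schedule, rows):
    """rows: list of (band_year, age_at_banding, obs codes per year)."""
    years = [str(y) for y in schedule.years]
    data = []
    for i, (by, ab, codes) in enumerate(rows):
        data.append([i, by, ab, *codes])
    return pd.DataFrame(data, columns=["id", "band_year", "age_at_banding",
                                       *years])


@pytest.fixture(scope="module")
def sched5():
    return InvasionSchedule(populations=("A", "B", "C"), study_years=(2000, 2004))


class TestMovementRow:
    def test_symmetric_logits_give_equal_thirds(self):
        row = movement_row(np.zeros(3), origin=0, mask=np.array([True] * 3))
        assert np.allclose(row, 1 / 3)

    def test_all_masked_degenerates_to_fidelity(self):
        row = movement_row(np.zeros(3), origin=1,
                           mask=np.array([False, True, False]))
        assert row[1] == 1.0 and row[0] == row[2] == 0.0

    def test_row_sums_to_one_under_any_masking(self, rng):
        for _ in range(50):
            logits = rng.normal(size=4)
            mask = rng.random(4) < 0.5
            row = movement_row(logits, origin=2, mask=mask)
            assert abs(row.sum() - 1.0) < 1e-12
            assert np.all(row >= 0)

    def test_emigration_complements_fidelity(self):
        # fidelity 0.8, destinations 0.15 and 0.05: emigration = 0.20
        target = np.array([0.8, 0.15, 0.05])
        logits = np.log(target / target[0])
        row = movement_row(logits, origin=0, mask=np.array([True] * 3))
        assert np.allclose(row, target, atol=1e-12)
        assert 1.0 - row[0] == pytest.approx(0.20, abs=1e-12)


class TestHistoryLoglik:
    def test_certain_path_has_zero_loglik(self):
        sched = InvasionSchedule(populations=("A",), study_years=(2000, 2001))
        df = hist_df(sched, [(2000, 2, ["A", "A"])])
        S = np.ones((1, 2, 2))
        psi = np.ones((1, 1, 2))
        p = np.ones((1, 2))
        assert history_loglik(df, sched, S, psi, p) == pytest.approx(0.0, abs=1e-12)

    def test_certain_death_has_zero_loglik(self):
        sched = InvasionSchedule(populations=("A",), study_years=(2000, 2001))
        df = hist_df(sched, [(2000, 2, ["A", "0"])])
        S = np.zeros((1, 2, 2))
        psi = np.ones((1, 1, 2))
        p = np.full((1, 2), 0.6)
        assert history_loglik(df, sched, S, psi, p) == pytest.approx(0.0, abs=1e-12)

    def test_matches_brute_force_on_random_parameters(self, sched5, rng):
        years = list(sched5.years)
        for trial in range(25):
            S = rng.uniform(0.2, 0.95, size=(3, 5, 2))
            raw = rng.uniform(0.05, 1.0, size=(3, 3, 5))
            psi = raw / raw.sum(axis=1, keepdims=True)
            p = rng.uniform(0.2, 0.95, size=(3, 5))
            band_occ = int(rng.integers(0, 3))
            age_at_band = int(rng.integers(0, 3))
            obs = [-1] * 5
            obs[band_occ] = int(rng.integers(0, 3))
            for j in range(band_occ + 1, 5):
                obs[j] = int(rng.integers(-1, 3))
            enc = EncodedHistories(
                obs=np.array([obs]), band_occ=np.array([band_occ]),
                age_at_band=np.array([age_at_band]), schedule=sched5)
            got = history_loglik(enc, sched5, S, psi, p)
            want = brute_force_loglik(obs, band_occ, S, psi, p, age_at_band)
            assert got == pytest.approx(want, abs=1e-10)

    def test_invariant_to_unobservable_padding(self, sched5, rng):
        """Appending all-not-seen occasions with p = 0 leaves logL unchanged."""
        S = rng.uniform(0.3, 0.9, size=(3, 5, 2))
        raw = rng.uniform(0.05, 1.0, size=(3, 3, 5))
        psi = raw / raw.sum(axis=1, keepdims=True)
        p = rng.uniform(0.2, 0.9, size=(3, 5))
        obs = [0, -1, 1]
        enc3 = EncodedHistories(
            obs=np.array([obs]), band_occ=np.array([0]),
            age_at_band=np.array([2]),
            schedule=InvasionSchedule(populations=("A", "B", "C"),
                                      study_years=(2000, 2002)))
        base = history_loglik(enc3, enc3.schedule, S[:, :3], psi[:, :, :3],
                              p[:, :3])
        p_pad = p.copy()
        p_pad[:, 3:] = 0.0
        enc5 = EncodedHistories(
            obs=np.array([obs + [-1, -1]]), band_occ=np.array([0]),
            age_at_band=np.array([2]), schedule=sched5)
        padded = history_loglik(enc5, sched5, S, psi, p_pad)
        assert padded == pytest.approx(base, abs=1e-12)

    def test_unknown_population_code_is_a_data_error(self, sched5):
        df = hist_df(sched5, [(2000, 2, ["A", "Z", "0", "0", "0"])])
        with pytest.raises(ValueError, match="not in registry"):
            encode_histories(df, sched5)

    def test_label_permutation_equivariance(self, sched5, rng):
        S = rng.uniform(0.3, 0.9, size=(3, 5, 2))
        raw = rng.uniform(0.05, 1.0, size=(3, 3, 5))
        psi = raw / raw.sum(axis=1, keepdims=True)
        p = rng.uniform(0.2, 0.9, size=(3, 5))
        obs = np.array([[0, 1, -1, 2, 1]])
        enc = EncodedHistories(obs=obs, band_occ=np.array([0]),
                               age_at_band=np.array([2]), schedule=sched5)
        base = history_loglik(enc, sched5, S, psi, p)
        perm = np.array([2, 0, 1])  # new index of old state i is perm[i]
        inv = np.argsort(perm)
        obs_p = np.where(obs >= 0, perm[np.maximum(obs, 0)], -1)
        enc_p = EncodedHistories(obs=obs_p, band_occ=np.array([0]),
                                 age_at_band=np.array([2]), schedule=sched5)
        permuted = history_loglik(enc_p, sched5, S[inv][:, :, :],
                                  psi[np.ix_(inv, inv)], p[inv])
        assert permuted == pytest.approx(base, abs=1e-12)


class TestFitMultistate:
    def test_collapses_to_closed_form_with_perfect_detection(self):
        """Single population, p ~ 1: the survival MLE is the alive fraction."""
        sched = InvasionSchedule(populations=("A",), study_years=(2000, 2005))
        truth = ss.realize_truth(sched, ss.TruthSurface(
            survival_intercept={0: 1.2, 1: 1.2}, resight_p=1.0))
        lives = ss.simulate_lives(truth, sched, ss.CohortDesign(0, 200), seed=3)
        caps, _, _ = ss.simulate_observations(lives, truth, sched, seed=4)
        at_risk = survived = 0
        states = np.array([l.states for l in lives])
        for t in range(5):
            alive = states[:, t] >= 0
            at_risk += alive.sum()
            survived += (states[alive, t + 1] >= 0).sum()
        closed_form = survived / at_risk
        fit = fit_multistate(caps, sched,
                             MultistateSpec(juvenile_survival=False),
                             n_starts=1)
        S, _, _ = fit.rates()
        assert S[0, 0, 1] == pytest.approx(closed_form, abs=1e-4)

    def test_requires_histories(self, sched5):
        df = hist_df(sched5, [])
        with pytest.raises(ValueError, match="at least one history"):
            fit_multistate(df, sched5)


class TestEstimabilityScreen:
    def test_unobserved_population_year_is_flagged(self, sched5):
        # nobody ever observed in C
        df = hist_df(sched5, [
            (2000, 2, ["A", "A", "0", "A", "0"]),
            (2000, 2, ["B", "0", "B", "B", "B"]),
            (2001, 2, ["0", "A", "A", "0", "A"]),
        ])
        flagged = estimability_screen(df, sched5)
        # C is never observed; B goes unseen in 2001
        assert flagged == ({("C", t) for t in range(2000, 2004)}
                           | {("B", 2001)})
        assert ("A", 2000) not in flagged

    def test_saturated_data_is_unflagged(self, sched5):
        rows = []
        for t, pop in itertools.product(range(5), "ABC"):
            codes = ["0"] * 5
            for j in range(t, 5):
                codes[j] = pop
            rows.append((2000 + t, 2, codes))
        flagged = estimability_screen(hist_df(sched5, rows), sched5)
        assert flagged == set()

    def test_unavailable_population_always_flagged(self):
        sched = InvasionSchedule(populations=("A", "B"), study_years=(2000, 2004),
                                 available_from={"B": 2003})
        df = hist_df(sched, [(2000, 2, ["A"] * 5)])
        flagged = estimability_screen(df, sched)
        assert {("B", 2000), ("B", 2001), ("B", 2002)} <= flagged


class TestDerivePhi:
    def test_products_and_survival_identity(self):
        phi = derive_phi(0.9, np.array([0.8, 0.15, 0.05]), origin=0)
        assert phi.retention == pytest.approx(0.72, abs=1e-12)
        assert phi.emigration.sum() == pytest.approx(0.18, abs=1e-12)
        assert phi.survival == pytest.approx(0.9, abs=1e-12)

    def test_full_fidelity_means_no_emigration(self):
        phi = derive_phi(0.77, np.array([0.0, 1.0, 0.0]), origin=1)
        assert phi.retention == pytest.approx(0.77)
        assert np.all(phi.emigration == 0.0)

    def test_delta_se_matches_monte_carlo(self, rng):
        S, S_se = 0.85, 0.02
        psi_row = np.array([0.8, 0.2])
        psi_se = np.array([0.03, 0.03])
        phi = derive_phi(S, psi_row, origin=0, S_se=S_se, psi_se=psi_se)
        n = 1_000_000
        S_draw = rng.normal(S, S_se, n)
        psi_draw = rng.normal(psi_row[0], psi_se[0], n)
        mc_sd = np.std(S_draw * psi_draw)
        assert phi.retention_se == pytest.approx(mc_sd, rel=0.02)
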
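"""Mating schedules, sperm decay, raffle paternity, costs and the
reproductive-phase engine."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from polyandrysim import (build_mating_schedule, female_viability,
                          fertilization_probability, male_viability,
                          raffle_paternity, raffle_probabilities,
                          run_reproductive_phase, sperm_investment,
                          survival_through_phase, viable_sperm)
from polyandrysim.mating import (PhaseResult, ReproductionParams,
                                 matings_before_event)


class TestSchedule:
    def test_monandry_nine_matings(self):
        times = build_mating_schedule(1.0, 8)
        assert np.array_equal(times, np.arange(9))

    def test_tau_min_100_matings_per_egg(self):
        times = build_mating_schedule(0.01, 8)
        assert len(times) == 801
        # excluding the initial t=0 mating, each egg interval holds 100
        for t in range(1, 9):
            k_lo, k_hi = matings_before_event(0.01, t)
            n = int(k_hi - k_lo + 1) - (1 if t == 1 else 0)
            assert n == 100

    def test_tau_03_bucket_structure(self):
        # enumerate k*0.3 <= 8: floor(26.67)+1 = 27 matings in total
        times = build_mating_schedule(0.3, 8)
        assert len(times) == 27
        counts = []
        for t in range(1, 9):
            k_lo, k_hi = matings_before_event(0.3, t)
            counts.append(int(k_hi - k_lo + 1))
        assert sum(counts) == 27
        assert set(counts) == {3, 4}  # eggs alternate between 3 and 4 matings

    def test_representation_robustness(self):
        # 8/0.1 evaluates just below 80 in floating point; the schedule must
        # still contain the mating at time 8.0
        assert len(build_mating_schedule(0.1, 8)) == 81

    @given(tau=st.floats(0.01, 1.0), R=st.integers(1, 12))
    @settings(deadline=None, derandomize=True)
    def test_schedule_invariants(self, tau, R):
        times = build_mating_schedule(tau, R)
        assert times[0] == 0.0
        assert len(times) == int(np.floor(R / tau * (1 + 1e-12) + 1e-12)) + 1
        assert np.all(np.diff(times) > 0)
        assert times[-1] <= R * (1 + 1e-9)

    def test_out_of_bounds_tau_rejected(self):
        with pytest.raises(ValueError):
            build_mating_schedule(0.0, 8)


class TestViableSperm:
    def test_no_decay_at_mating_time(self):
        assert viable_sperm(123.0, 0.5, 2.0, 2.0) == 123.0

    def test_floor_mortality_is_negligible(self):
        z = viable_sperm(100.0, 1e-10, 0.0, 8.0)
        assert z == pytest.approx(100.0, rel=1e-8)

    def test_exponential_decay_value(self):
        assert viable_sperm(100.0, 0.5, 0.0, 2.0) == pytest.approx(
            100 * np.exp(-1), rel=1e-12)

    def test_before_mating_rejected(self):
        with pytest.raises(ValueError):
            viable_sperm(10.0, 0.5, 3.0, 2.0)


class TestRaffle:
    def test_single_mate_certain(self, rng):
        assert raffle_paternity([7], [42.0], rng) == 7

    def test_30_10_normalization(self):
        assert raffle_probabilities([30.0, 10.0]) == pytest.approx([0.75, 0.25])

    def test_three_packet_normalization(self):
        assert raffle_probabilities([5.0, 5.0, 10.0]) == pytest.approx(
            [0.25, 0.25, 0.5])

    def test_same_male_packets_add(self):
        p = raffle_probabilities([30.0, 10.0, 10.0])
        # two packets of one male: his total share is the sum
        assert p[1] + p[2] == pytest.approx(0.4)

    def test_empirical_frequencies_chi_square(self):
        rng = np.random.default_rng(17)
        sires = np.array([1, 2])
        draws = np.array([raffle_paternity(sires, [30.0, 10.0], rng)
                          for _ in range(100_000)])
        observed = [int((draws == 1).sum()), int((draws == 2).sum())]
        chi2 = stats.chisquare(observed, [75_000, 25_000])
        assert chi2.pvalue > 1e-4

    @given(st.lists(st.floats(0.01, 1e6), min_size=1, max_size=20))
    @settings(deadline=None, derandomize=True)
    def test_probabilities_sum_to_one(self, zetas):
        assert raffle_probabilities(zetas).sum() == pytest.approx(1.0)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            raffle_probabilities([0.0, 0.0])


class TestFertilization:
    def test_no_sperm_no_fertilization(self):
        assert fertilization_probability(0.0, 0.01) == 0.0

    def test_known_values_and_monotonicity(self):
        p100 = fertilization_probability(100.0, 0.01)
        p500 = fertilization_probability(500.0, 0.01)
        assert p100 == pytest.approx(1 - np.exp(-1), rel=1e-12)
        assert p500 == pytest.approx(0.9932621, rel=1e-6)
        assert p500 > p100

    @given(Z=st.floats(0, 1e9))
    @settings(deadline=None, derandomize=True)
    def test_is_probability(self, Z):
        p = fertilization_probability(Z, 0.01)
        assert 0.0 <= p < 1.0 or p == pytest.approx(1.0)


class TestCosts:
    def test_sperm_investment_linear_beta(self):
        assert sperm_investment(50.0, 0.25, 1.0) == pytest.approx(200.0)

    def test_sperm_investment_sqrt_beta(self):
        assert sperm_investment(100.0, 0.2, 0.5) == pytest.approx(50.0)

    def test_no_trade_off_variant_drops_mu(self):
        assert sperm_investment(100.0, 0.2, 0.5, trade_off=False) == \
            pytest.approx(10.0)

    def test_alternative_linear_reading(self):
        assert sperm_investment(100.0, 0.2, 0.5, linear=True) == \
            pytest.approx(250.0)

    def test_investment_decreasing_in_mu(self):
        mus = np.linspace(0.05, 2.0, 30)
        rho = sperm_investment(80.0, mus, 0.5)
        assert np.all(np.diff(rho) < 0)

    def test_male_viability_free_below_budget(self):
        assert male_viability(19.0, 20.0, 1.0) == 1.0
        assert male_viability(20.0, 20.0, 1.0) == 1.0  # continuous at rho0

    def test_male_viability_gaussian_cost(self):
        assert male_viability(21.0, 20.0, 1.0) == pytest.approx(
            np.exp(-0.5), rel=1e-12)

    def test_female_viability_monandry_free(self):
        assert female_viability(1.0, 8, 1.28e5) == 1.0

    def test_female_viability_known_values(self):
        assert female_viability(0.5, 8, 1.28e5) == pytest.approx(
            np.exp(-64 / 256000), rel=1e-12)
        assert female_viability(0.01, 8, 1.28e5) == pytest.approx(
            0.08627202, rel=1e-5)

    def test_survival_through_phase(self):
        assert survival_through_phase(1.0, 3, 8) == 1.0
        assert survival_through_phase(0.3, 8, 8) == pytest.approx(0.3)
        assert survival_through_phase(0.5, 4, 8) == pytest.approx(
            np.sqrt(0.5), rel=1e-12)


# ----------------------------------------------------------------------

def _phase(female, deme, tau, s, mu, nu_f, nu_m, rng, mode="evolving_polyandry",
           r=0.01, R=8, **kw) -> PhaseResult:
    params = ReproductionParams(R=R, r=r, mode=mode)
    arr = lambda x: np.asarray(x, dtype=float)
    return run_reproductive_phase(np.asarray(female, bool),
                                  np.asarray(deme, np.int64),
                                  arr(tau), arr(s), arr(mu), arr(nu_f),
                                  arr(nu_m), params, rng, **kw)


class TestReproductivePhase:
    def test_abundant_sperm_full_survival_gives_R_offspring(self, rng):
        res = _phase([True, False], [0, 0], [1.0, 1.0], [1e6, 1e6],
                     [1e-10, 1e-10], [1.0, 1.0], [1.0, 1.0], rng)
        assert res.dam_idx.size == 8
        assert np.all(res.sire_idx == 1)

    def test_no_viable_sperm_no_offspring(self, rng):
        res = _phase([True, False], [0, 0], [1.0, 1.0], [1.0, 1.0],
                     [20.0, 20.0], [1.0, 1.0], [1.0, 1.0], rng, r=1e-9)
        assert res.dam_idx.size == 0

    def test_no_males_skips_matings(self, rng):
        res = _phase([True, True], [0, 0], [1.0, 1.0], [1.0, 1.0],
                     [0.5, 0.5], [1.0, 1.0], [1.0, 1.0], rng)
        assert res.dam_idx.size == 0
        assert res.skipped_matings > 0

    def test_offspring_per_female_at_most_R(self, rng):
        for _ in range(5):
            res = _phase([True, True, False, False], [0] * 4, [0.3] * 4,
                         [100.0] * 4, [0.5] * 4, [1.0] * 4, [1.0] * 4, rng)
            counts = np.bincount(res.dam_idx, minlength=4)
            assert counts.max() <= 8

    def test_sire_share_matches_brute_force_mixture(self):
        """Two males with time-constant viable sperm in ratio 3:1, tau=0.5,
        full survival: simulated sire share of male 1 must match the
        analytic expectation of the raffle share, averaging over the
        binomial distribution of mate draws, within 3 SE over ~1e4 eggs.
        """
        rng = np.random.default_rng(1234)
        # oracle: at egg t the female has m = #matings so far packets, each
        # male 1 packet with prob 1/2; share = 3*n1/(3*n1 + (m-n1))
        def expected_share(t):
            k_hi = int(np.floor(t / 0.5 * (1 + 1e-12)))
            m = k_hi + 1  # matings at times 0, 0.5, ..., including t
            n1 = np.arange(m + 1)
            w = stats.binom.pmf(n1, m, 0.5)
            with np.errstate(invalid="ignore"):
                share = np.where(m > 0, 3 * n1 / (3 * n1 + (m - n1)), 0.0)
            share[np.isnan(share)] = 0.0  # n1=0 and m=n1=0 corner
            return float((w * share).sum())

        n_females = 1300
        female = np.zeros(3 * n_females, bool)
        female[:n_females] = True
        deme = np.concatenate([np.arange(n_females),
                               np.arange(n_females), np.arange(n_females)])
        s = np.concatenate([np.zeros(n_females),
                            np.full(n_females, 30.0), np.full(n_females, 10.0)])
        mu = np.full(3 * n_females, 1e-10)
        ones = np.ones(3 * n_females)
        res = _phase(female, deme, np.full(3 * n_females, 0.5), s, mu,
                     ones, ones, rng, r=10.0)
        # every egg fertilized (r huge); sires are rows n..2n (male 1) etc.
        assert res.dam_idx.size >= 10_000
        is_male1 = (res.sire_idx >= n_females) & (res.sire_idx < 2 * n_females)
        share_by_egg = np.array([expected_share(t) for t in range(1, 9)])
        p_expect = share_by_egg.mean()
        # eggs of one female share her packet history, so aggregate to
        # per-female shares (independent replicates) before the SE check
        fem_share = np.bincount(res.dam_idx, weights=is_male1,
                                minlength=n_females)[:n_females] / 8.0
        se = fem_share.std(ddof=1) / np.sqrt(n_females)
        assert abs(fem_share.mean() - p_expect) <= 3 * se

    def test_monandry_mode_forces_single_mating_rate(self, rng):
        # tau arrays are forced upstream; here check the phase respects the
        # schedule: tau=1 females accrue exactly 9 packets
        res = _phase([True, False], [0, 0], [1.0, 1.0], [1e5, 1e5],
                     [1e-10, 1e-10], [1.0, 1.0], [1.0, 1.0], rng,
                     log_eggs=True)
        assert res.dam_idx.size == 8

    def test_no_sperm_competition_same_matings_single_sire_per_egg(self):
        """Switching sperm competition off must not change how often a
        female mates, only who fathers each egg: all of an egg interval's
        matings go to one designated male."""
        rng = np.random.default_rng(7)
        female = np.array([True] + [False] * 5)
        deme = np.zeros(6, np.int64)
        tau = np.full(6, 0.25)
        s = np.full(6, 1e5)
        mu = np.full(6, 1e-10)
        ones = np.ones(6)
        res = _phase(female, deme, tau, s, mu, ones, ones, rng,
                     mode="no_sperm_competition", r=10.0)
        assert res.dam_idx.size == 8
        # a fresh male is designated per egg; with 5 males the chance all 8
        # eggs share one sire under redraws is (1/5)^7 -- just check sires
        # are drawn from the male pool
        assert np.all(res.sire_idx >= 1)

    def test_dead_male_sperm_stays_competitive(self):
        """A male who dies after inseminating keeps his paternity chances
        through stored sperm."""
        rng = np.random.default_rng(21)
        # male 1 has nu=0: dies after event 1; male 2 never mates (own deme
        # has no female).  Female keeps being fertilized by stored sperm.
        female = np.array([True, False])
        res = _phase(female, [0, 0], [1.0, 1.0], [1e6, 1e6], [1e-10, 1e-10],
                     [1.0, 1.0], [1e-12, 1e-12], rng, r=10.0)
        # male died almost surely after event 1, yet later eggs are sired
        assert res.dam_idx.size >= 2
        assert np.all(res.sire_idx == 1)

    def test_determinism(self):
        args = ([True, True, False, False], [0, 0, 0, 0], [0.5] * 4,
                [100.0] * 4, [0.5] * 4, [0.999] * 4, [0.99] * 4)
        r1 = _phase(*args, np.random.default_rng(5))
        r2 = _phase(*args, np.random.default_rng(5))
        assert np.array_equal(r1.dam_idx, r2.dam_idx)
        assert np.array_equal(r1.sire_idx, r2.sire_idx)
        assert np.array_equal(r1.alive, r2.alive)
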
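"""Binding-model tests, including brute-force equilibrium oracles.

The oracles solve the mass-action balance by bisection, independently of the
closed forms under test:

* given (D_free, R_total, K_D), the complex DR is the root of
  f(DR) = K_D * DR - D_free * (R_total - DR), increasing in DR on [0, R_total];
* given (T, R_total, K_D), the free ligand D is the root of
  g(D) = D + D * R_total / (K_D + D) - T, increasing in D on [0, T].
"""

import math

import numpy as np
import pytest
from hypothesis import assume, given, settings
from hypothesis import strategies as st

from plgfbind import (
    BindingState,
    BiomarkerSample,
    DomainError,
    InconsistentSampleError,
    NoEstimableSamplesError,
    NotEstimableError,
    UndefinedOccupancyError,
    equilibrate_after_spike,
    estimate_mean_kd,
    free_from_total,
    kd_from_sample,
    occupancy,
    predict_total_plgf,
)
from plgfbind.units import PLGF, SFLT1, mass_to_molar, molar_to_mass


def bisect(f, lo, hi, iters=200):
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        if f(mid) > 0:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


def oracle_dr(d_free, r_total, kd):
    """Bisection solution of K_D*DR = D*(R_total - DR)."""
    return bisect(lambda dr: kd * dr - d_free * (r_total - dr), 0.0, r_total)


def oracle_free(total, r_total, kd):
    """Bisection solution of D + D*R/(K_D + D) = T."""
    return bisect(lambda d: d + d * r_total / (kd + d) - total, 0.0, total)


POS = st.floats(min_value=1e-3, max_value=1e6, allow_nan=False)


class TestOccupancy:
    def test_half_occupancy_at_kd(self):
        assert occupancy(50.0, 100.0, 50.0) == pytest.approx(50.0)
        assert occupancy(0.003, 100.0, 0.003) == pytest.approx(50.0)

    def test_full_occupancy_limit_kd_zero(self):
        assert occupancy(1.0, 7.0, 0.0) == pytest.approx(7.0)

    def test_aflp_median_state(self):
        d = mass_to_molar(208.0, PLGF)
        r = mass_to_molar(77_762.0, SFLT1)
        assert occupancy(d, r, 50.0) == pytest.approx(84.772, abs=1e-3)

    def test_undefined_when_kd_and_ligand_zero(self):
        with pytest.raises(UndefinedOccupancyError):
            occupancy(0.0, 10.0, 0.0)

    def test_negative_input_rejected(self):
        with pytest.raises(DomainError):
            occupancy(-1.0, 10.0, 50.0)

    @settings(deadline=None, max_examples=200)
    @given(d=POS, r=POS, kd=POS, factor=st.floats(min_value=1.01, max_value=10))
    def test_monotonicity(self, d, r, kd, factor):
        base = occupancy(d, r, kd)
        assert occupancy(d * factor, r, kd) >= base
        assert occupancy(d, r * factor, kd) >= base
        assert occupancy(d, r, kd * factor) <= base
        assert 0 <= base <= r


class TestPredictTotal:
    def test_aflp_medians(self):
        # free 208, sFlt-1 77762 pg/mL at K_D 50 pmol/L
        assert predict_total_plgf(208.0, 77_762.0, 50.0) == pytest.approx(3090.25, abs=0.01)

    def test_no_receptor_nothing_bound(self):
        assert predict_total_plgf(123.4, 0.0, 50.0) == pytest.approx(123.4)

    def test_infinite_kd_limit(self):
        x = 500.0
        assert predict_total_plgf(x, 1e6, 1e12) == pytest.approx(x, rel=1e-3)

    @settings(deadline=None, max_examples=200)
    @given(free=st.floats(min_value=0, max_value=1e5), sflt1=st.floats(min_value=0, max_value=1e6), kd=POS)
    def test_total_at_least_free(self, free, sflt1, kd):
        total = predict_total_plgf(free, sflt1, kd)
        assert total >= free
        # strict inequality whenever a representable amount can bind
        if free >= 1e-3 and sflt1 >= 1e-3:
            assert total > free

    def test_negative_rejected(self):
        with pytest.raises(DomainError):
            predict_total_plgf(-1.0, 100.0, 50.0)


class TestKdFromSample:
    def test_aflp_round_trip(self):
        total = predict_total_plgf(208.0, 77_762.0, 50.0)
        assert kd_from_sample(208.0, total, 77_762.0) == pytest.approx(50.0, rel=1e-9)

    def test_zero_complex_not_estimable(self):
        with pytest.raises(NotEstimableError):
            kd_from_sample(100.0, 100.0, 5000.0)

    def test_complex_exceeding_receptor_inconsistent(self):
        # total - free implies more complex than sFlt-1 present
        with pytest.raises(InconsistentSampleError):
            kd_from_sample(100.0, 1_000_000.0, 100.0)

    @settings(deadline=None, max_examples=200)
    @given(free=POS, sflt1=POS, kd=POS)
    def test_algebraic_inverse_of_predict(self, free, sflt1, kd):
        total = predict_total_plgf(free, sflt1, kd)
        # recovery is ill-conditioned when almost nothing binds (total - free
        # cancels) or the receptor is nearly saturated (R - DR cancels); no
        # algorithm recovers K_D there and such samples carry no information.
        # Bound the combined condition number so eps * cond << 1e-9.
        d = mass_to_molar(free, PLGF)
        cond = (total / (total - free)) * ((kd + d) / kd) if total > free else float("inf")
        assume(cond < 1e5)
        assert kd_from_sample(free, total, sflt1) == pytest.approx(kd, rel=1e-9)


class TestEstimateMeanKd:
    def test_exact_recovery_noise_free(self, noise_free_cohort):
        est = estimate_mean_kd(noise_free_cohort)
        assert est.n_used == 42
        assert est.n_excluded == 0
        assert est.mean_kd == pytest.approx(50.0, rel=1e-9)
        assert est.sem_kd == pytest.approx(0.0, abs=1e-9)

    def test_exclusion_rules(self):
        good = BiomarkerSample("g", sflt1=10_000, free_plgf=100,
                               total_plgf=predict_total_plgf(100, 10_000, 50))
        no_total = BiomarkerSample("n", sflt1=10_000, free_plgf=100)
        total_below_free = BiomarkerSample("b", sflt1=10_000, free_plgf=100, total_plgf=90)
        est = estimate_mean_kd([good, no_total, total_below_free])
        assert est.n_used == 1
        assert est.n_excluded == 2
        assert len(est.per_sample_kd) == 1

    def test_geometric_mean_option(self):
        samples = [
            BiomarkerSample(f"s{k}", sflt1=10_000, free_plgf=100,
                            total_plgf=predict_total_plgf(100, 10_000, kd))
            for k, kd in enumerate([25.0, 100.0])
        ]
        est = estimate_mean_kd(samples, mean="geometric")
        assert est.mean_kd == pytest.approx(50.0, rel=1e-9)

    def test_no_estimable_samples(self):
        with pytest.raises(NoEstimableSamplesError):
            estimate_mean_kd([BiomarkerSample("n", sflt1=100, free_plgf=10)])
        with pytest.raises(NoEstimableSamplesError):
            estimate_mean_kd([])

    def test_sem_matches_definition(self):
        kds = [30.0, 50.0, 70.0]
        samples = [
            BiomarkerSample(f"s{k}", sflt1=10_000, free_plgf=100,
                            total_plgf=predict_total_plgf(100, 10_000, kd))
            for k, kd in enumerate(kds)
        ]
        est = estimate_mean_kd(samples)
        assert est.mean_kd == pytest.approx(np.mean(kds), rel=1e-9)
        assert est.sem_kd == pytest.approx(np.std(kds, ddof=1) / math.sqrt(3), rel=1e-9)


class TestFreeFromTotal:
    def test_aflp_inversion(self):
        assert free_from_total(3090.2477148847, 77_762.0, 50.0) == pytest.approx(208.0, rel=1e-6)

    def test_no_receptor(self):
        assert free_from_total(456.0, 0.0, 50.0) == pytest.approx(456.0)

    def test_zero_total(self):
        assert free_from_total(0.0, 12_345.0, 50.0) == 0.0

    @settings(deadline=None, max_examples=200)
    @given(free=POS, sflt1=POS, kd=POS)
    def test_round_trip_with_predict(self, free, sflt1, kd):
        total = predict_total_plgf(free, sflt1, kd)
        assert free_from_total(total, sflt1, kd) == pytest.approx(free, rel=1e-9)

    def test_numerically_stable_when_kd_much_smaller_than_receptor(self):
        # K_D << R: naive quadratic root suffers catastrophic cancellation
        free = free_from_total(1000.0, 1e6, 1e-6)
        total_back = predict_total_plgf(free, 1e6, 1e-6)
        assert total_back == pytest.approx(1000.0, rel=1e-9)


class TestSpike:
    def test_no_receptor_increase_equals_added(self):
        s = BiomarkerSample("s", sflt1=0.0, free_plgf=100.0, total_plgf=100.0)
        state = equilibrate_after_spike(s, 1693.0, 50.0)
        detected = molar_to_mass(state.d_free, PLGF)
        assert detected == pytest.approx(100.0 + 1693.0, rel=1e-9)

    def test_high_ratio_sequesters_spike(self):
        s = BiomarkerSample("s", sflt1=30_000.0, free_plgf=36.0)
        state = equilibrate_after_spike(s, 1693.0, 50.0)
        increase = molar_to_mass(state.d_free, PLGF) - 36.0
        assert 0 < increase < 1693.0

    def test_post_heating_total_is_spiked_total(self):
        s = BiomarkerSample("s", sflt1=30_000.0, free_plgf=36.0, total_plgf=270.0)
        state = equilibrate_after_spike(s, 1693.0, 50.0)
        assert molar_to_mass(state.d_total, PLGF) == pytest.approx(270.0 + 1693.0, rel=1e-9)

    def test_mass_conservation_and_equilibrium(self):
        s = BiomarkerSample("s", sflt1=15_000.0, free_plgf=60.0)
        state = equilibrate_after_spike(s, 500.0, 50.0)
        assert state.at_equilibrium()
        assert state.dr <= state.r_total


class TestBindingState:
    def test_equilibrium_invariant_check(self):
        dr = occupancy(10.0, 100.0, 50.0)
        state = BindingState(d_free=10.0, r_total=100.0, dr=dr, kd=50.0)
        assert state.at_equilibrium()
        off = BindingState(d_free=10.0, r_total=100.0, dr=dr * 1.5, kd=50.0)
        assert not off.at_equilibrium()

    def test_complex_cannot_exceed_receptor(self):
        with pytest.raises(DomainError):
            BindingState(d_free=1.0, r_total=10.0, dr=11.0, kd=50.0)


class TestBruteForceOracle:
    def test_occupancy_matches_bisection_on_random_states(self, rng):
        for _ in range(1000):
            d, r, kd = 10 ** rng.uniform(-2, 4, size=3)
            assert occupancy(d, r, kd) == pytest.approx(oracle_dr(d, r, kd), rel=1e-6)

    def test_free_from_total_matches_bisection_on_random_states(self, rng):
        for _ in range(1000):
            t_mass, r_mass = 10 ** rng.uniform(0, 6, size=2)
            kd = 10 ** rng.uniform(-1, 4)
            t = mass_to_molar(t_mass, PLGF)
            r = mass_to_molar(r_mass, SFLT1)
            expected = molar_to_mass(oracle_free(t, r, kd), PLGF)
            assert free_from_total(t_mass, r_mass, kd) == pytest.approx(expected, rel=1e-6)


class TestNoiseRecovery:
    def test_mean_kd_recovered_within_15pct_under_5pct_cv(self):
        from plgfbind import SimConfig, simulate_cohort

        sizes = {"no_pe": 11, "pe": 13, "hellp": 12, "aflp": 6}
        cfg = SimConfig(seed=123, mode="mechanistic_from_free", kd=50.0, noise_cv=0.05)
        est = estimate_mean_kd(simulate_cohort(sizes, cfg))
        assert est.mean_kd == pytest.approx(50.0, rel=0.15)
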
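"""Stochastic simulator: dwell sampling, initiation, reproducibility and
cross-engine agreement."""
import numpy as np
import pytest
from scipy import stats

from nascentfold import (
    Construct,
    GillespieConfig,
    Protocol,
    TranslationSchedule,
    build_kinetics,
    length_resolved_profile,
    next_initiation,
    predict_pulse_chase,
    sample_dwell,
    simulate,
    steady_state_profile,
)
from nascentfold.gillespie import DEFAULT_K1, DEFAULT_K2


class TestSampleDwell:
    def test_single_exponential_mean(self, rng):
        d = sample_dwell(GillespieConfig(), 4.0, rng, size=100_000)
        assert d.mean() == pytest.approx(0.25, abs=4 * 0.25 / np.sqrt(1e5))

    def test_two_exponential_default_mean_is_256_ms(self, rng):
        # 1/k_1 + 1/k_2 ~ 0.2565 s, i.e. the 3.9 AA/s average
        analytic = 1.0 / DEFAULT_K1 + 1.0 / DEFAULT_K2
        assert analytic == pytest.approx(0.2565, abs=5e-4)
        assert 1.0 / analytic == pytest.approx(3.9, abs=0.01)
        cfg = GillespieConfig(dwell_model="two_exponential")
        d = sample_dwell(cfg, 1.0 / analytic, rng, size=100_000)
        assert d.mean() == pytest.approx(analytic, rel=0.01)

    def test_two_exponential_variance(self, rng):
        # hypoexponential: var = 1/k1^2 + 1/k2^2 (unscaled rates)
        cfg = GillespieConfig(dwell_model="two_exponential")
        k_A = 1.0 / (1.0 / DEFAULT_K1 + 1.0 / DEFAULT_K2)
        d = sample_dwell(cfg, k_A, rng, size=200_000)
        expected = 1.0 / DEFAULT_K1**2 + 1.0 / DEFAULT_K2**2
        assert d.var() == pytest.approx(expected, rel=0.03)

    def test_equal_rates_erlang_limit(self, rng):
        # k1 = k2: Erlang-2, variance 2/k^2
        cfg = GillespieConfig(dwell_model="two_exponential", k1=4.0, k2=4.0)
        d = sample_dwell(cfg, 2.0, rng, size=200_000)  # mean 0.5 s
        assert d.mean() == pytest.approx(0.5, rel=0.01)
        assert d.var() == pytest.approx(2.0 / 16.0, rel=0.03)

    def test_mean_matches_schedule_for_any_rate(self, rng):
        cfg = GillespieConfig(dwell_model="two_exponential")
        for k_A in (0.5, 3.9, 20.0):
            d = sample_dwell(cfg, k_A, rng, size=50_000)
            assert d.mean() == pytest.approx(1.0 / k_A, rel=0.02)


class TestNextInitiation:
    def test_zero_amplitude_equals_constant(self):
        cfg_c = GillespieConfig(initiation_model="constant")
        cfg_s = GillespieConfig(initiation_model="sinusoidal", amplitude=0.0)
        a = [
            next_initiation(cfg_c, 2.0, t, np.random.default_rng(9))
            for t in (0.0, 10.0)
        ]
        b = [
            next_initiation(cfg_s, 2.0, t, np.random.default_rng(9))
            for t in (0.0, 10.0)
        ]
        assert a == b

    def test_constant_interval_mean(self, rng):
        cfg = GillespieConfig()
        draws = [next_initiation(cfg, 2.0, 0.0, rng) for _ in range(20_000)]
        assert np.mean(draws) == pytest.approx(0.5, rel=0.03)

    def test_sinusoidal_intensity_oscillates(self, rng):
        # pooled event times show the imposed 45 s periodicity
        cfg = GillespieConfig(
            initiation_model="sinusoidal", amplitude=0.8, period_s=45.0
        )
        events = []
        for _ in range(60):
            t = 0.0
            while t < 450.0:
                t += next_initiation(cfg, 2.0, t, rng)
                events.append(t)
        phase = np.asarray(events) % 45.0
        counts, edges = np.histogram(phase, bins=15, range=(0, 45))
        centers = 0.5 * (edges[:-1] + edges[1:])
        r = np.corrcoef(counts, 1 + 0.8 * np.sin(2 * np.pi * centers / 45))[0, 1]
        assert r > 0.8

    def test_thinning_agrees_with_sequential_in_rate(self, rng):
        # both samplers reproduce the mean initiation rate
        seq = GillespieConfig(initiation_model="sinusoidal", amplitude=0.5)
        thin = GillespieConfig(
            initiation_model="sinusoidal", amplitude=0.5, use_thinning=True
        )
        def mean_rate(cfg):
            n, t = 0, 0.0
            while t < 2000.0:
                t += next_initiation(cfg, 1.5, t, rng)
                n += 1
            return n / t
        assert mean_rate(seq) == pytest.approx(mean_rate(thin), rel=0.05)


def toy_setup():
    construct = Construct(
        name="toy", total_codons=60, domain_start=1, domain_end=25,
        tunnel_length=10, bulk_kF=1.0, bulk_kU=0.1,
        observable_codons=frozenset(range(1, 26)),
    )
    schedule = TranslationSchedule.uniform(60, 4.0)
    protocol = Protocol(pulse_s=10.0, chase_s=60.0, delay_s=2.0)
    return construct, schedule, protocol


class TestSimulate:
    def test_reproducible_with_same_seed(self):
        construct, schedule, protocol = toy_setup()
        cfg = GillespieConfig(replicates=3, seed=11)
        r1 = simulate(construct, schedule, protocol, cfg)
        r2 = simulate(construct, schedule, protocol, cfg)
        np.testing.assert_array_equal(r1.replicate_curves, r2.replicate_curves)
        np.testing.assert_array_equal(r1.n_labelled, r2.n_labelled)

    def test_different_seeds_differ(self):
        construct, schedule, protocol = toy_setup()
        r1 = simulate(construct, schedule, protocol,
                      GillespieConfig(replicates=2, seed=1))
        r2 = simulate(construct, schedule, protocol,
                      GillespieConfig(replicates=2, seed=2))
        assert not np.array_equal(r1.replicate_curves, r2.replicate_curves)

    def test_zero_folding_rate_zero_curves(self):
        construct, schedule, protocol = toy_setup()
        c0 = Construct(
            name="nofold", total_codons=60, domain_start=1, domain_end=25,
            tunnel_length=10, bulk_kF=0.0, bulk_kU=1.0,
            observable_codons=frozenset(range(1, 26)),
        )
        res = simulate(c0, schedule, protocol, GillespieConfig(replicates=3, seed=5))
        assert np.nanmax(res.replicate_curves) == 0.0

    def test_mean_curve_matches_deterministic_engine(self):
        """Cross-engine oracle agreement for a marginal toy construct."""
        construct, schedule, protocol = toy_setup()
        res = simulate(
            construct, schedule, protocol,
            GillespieConfig(replicates=12, seed=3),
        )
        det = predict_pulse_chase(construct, schedule, protocol).values
        n_tot = np.maximum(res.counts * 12, 1.0)
        floor = np.sqrt(np.clip(det * (1 - det), 0, None) / n_tot)
        sem_eff = np.maximum(res.sem, floor)
        assert np.all(np.abs(res.mean_curve - det) <= 3.0 * sem_eff)

    def test_statistics_fields_consistent(self):
        construct, schedule, protocol = toy_setup()
        res = simulate(construct, schedule, protocol,
                       GillespieConfig(replicates=4, seed=8))
        assert res.total_labelled == res.n_labelled.sum()
        valid = np.isfinite(res.mean_curve)
        assert np.all((res.mean_curve[valid] >= 0) & (res.mean_curve[valid] <= 1))
        assert np.all(res.sem[valid] >= 0)
        # N(t) nondecreasing during incorporation, constant afterwards
        assert np.all(np.diff(res.counts) >= -1e-12)


class TestLengthResolvedProfile:
    def test_matches_steady_state_recursion(self):
        """Central oracle equivalence: the simulated length-resolved folded
        fraction converges to the analytic steady-state profile."""
        construct = Construct(
            name="toy", total_codons=50, domain_start=1, domain_end=20,
            tunnel_length=10, bulk_kF=2.0, bulk_kU=0.4,
        )
        schedule = TranslationSchedule(
            np.random.default_rng(2).uniform(2.0, 7.0, 50)
        )
        frac, se = length_resolved_profile(
            construct, schedule, n_molecules=6000, seed=21
        )
        prof = steady_state_profile(build_kinetics(construct), schedule)
        se_eff = np.maximum(se, 1e-4)
        # 4 s.e.: the bound must hold jointly over all 50 positions
        assert np.all(np.abs(frac - prof.values) <= 4.0 * se_eff)
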
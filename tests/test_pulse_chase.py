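"""Pulse-chase engine: trajectories, labelling, folding and curves."""
import numpy as np
import pytest

from nascentfold import (
    Construct,
    Protocol,
    TranslationSchedule,
    build_kinetics,
    cohort_trajectory,
    evolve_folding,
    fraction_full_length,
    is_labelled,
    predict_pulse_chase,
    sensitivity_sweep,
    steady_state_profile,
)


def small_construct(**kw):
    defaults = dict(
        name="small", total_codons=30, domain_start=1, domain_end=10,
        tunnel_length=5, bulk_kF=2.0, bulk_kU=0.2,
        observable_codons=frozenset(range(1, 11)),
    )
    defaults.update(kw)
    return Construct(**defaults)


class TestCohortTrajectory:
    def test_release_time_uniform_schedule(self):
        # 1,145 codons at 3.9 AA/s -> release ~293.6 s after initiation
        sched = TranslationSchedule.uniform(1145, 3.9)
        traj = cohort_trajectory(sched, t0=12.0)
        assert traj.release_time == pytest.approx(12.0 + 1145 / 3.9)
        assert traj.release_time - 12.0 == pytest.approx(293.6, abs=0.1)

    def test_first_codon_occupancy(self):
        sched = TranslationSchedule(np.array([2.0, 1.0, 4.0]))
        traj = cohort_trajectory(sched, t0=0.0)
        assert traj.occupied_interval(1) == (0.0, 0.5)
        assert traj.incorporation_time(1) == 0.5

    def test_positions_nondecreasing_in_time(self):
        sched = TranslationSchedule.uniform(20, 5.0)
        traj = cohort_trajectory(sched, t0=1.0)
        ts = np.linspace(1.0, 6.0, 50)
        pos = [traj.position_at(t) for t in ts]
        assert all(b >= a for a, b in zip(pos, pos[1:]))


class TestIsLabelled:
    def test_completed_before_window_unlabelled(self, protocol):
        # all observable residues made before the 10 s incorporation delay
        sched = TranslationSchedule.uniform(30, 5.0)
        traj = cohort_trajectory(sched, t0=-20.0)
        labelled, _ = is_labelled(traj, range(1, 11), protocol)
        assert not labelled

    def test_initiated_after_window_unlabelled(self, protocol):
        sched = TranslationSchedule.uniform(30, 5.0)
        traj = cohort_trajectory(sched, t0=protocol.window[1])
        labelled, _ = is_labelled(traj, range(1, 11), protocol)
        assert not labelled

    def test_delta_c_cohort_at_zero_is_labelled(self, delta_c, protocol):
        # observable codons 1-143 at 3.9 AA/s span (0, 36.7] s; instants in
        # [10, 55) exist, first one at tau_cum(39) = 10.0 s
        construct, schedule = delta_c
        traj = cohort_trajectory(schedule, t0=0.0)
        labelled, t_label = is_labelled(
            traj, construct.observable_codons, protocol
        )
        assert labelled
        assert t_label == pytest.approx(10.0, abs=0.26)


class TestEvolveFolding:
    def test_no_folding_rate_stays_zero(self):
        c = small_construct(bulk_kF=0.0, bulk_kU=1.0)
        sched = TranslationSchedule.uniform(30, 5.0)
        traj = cohort_trajectory(sched, 0.0)
        p = evolve_folding(build_kinetics(c), traj, np.linspace(0, 50, 40))
        np.testing.assert_array_equal(p, 0.0)

    def test_held_at_codon_relaxes_to_equilibrium(self):
        # huge dwell at the onset codon: closed-form two-state relaxation
        c = small_construct(total_codons=16, domain_end=10, tunnel_length=5)
        rates = np.full(16, 5.0)
        rates[14] = 1e-6  # effectively held at codon 15 (= onset)
        sched = TranslationSchedule(rates)
        traj = cohort_trajectory(sched, 0.0)
        kin = build_kinetics(c)
        t_enter = sched.tau_cum[13]
        dt = np.array([0.5, 1.0, 3.0, 10.0])
        p = evolve_folding(kin, traj, t_enter + dt)
        K = c.bulk_kF + c.bulk_kU
        expected = c.p_eq_bulk * (1.0 - np.exp(-K * dt))
        np.testing.assert_allclose(p, expected, rtol=1e-6)

    def test_release_value_matches_profile_for_delta_c(self, delta_c):
        # a single mean-path cohort reaches the same folded probability at
        # release as the ensemble profile (fast folder: both ~ P_eq)
        construct, schedule = delta_c
        traj = cohort_trajectory(schedule, 0.0)
        kin = build_kinetics(construct)
        p_rel = evolve_folding(kin, traj, np.array([traj.release_time]))[0]
        prof = steady_state_profile(kin, schedule)
        assert p_rel == pytest.approx(prof.p_co_t, abs=0.01)

    def test_before_initiation_is_zero(self):
        c = small_construct()
        sched = TranslationSchedule.uniform(30, 5.0)
        traj = cohort_trajectory(sched, 10.0)
        p = evolve_folding(build_kinetics(c), traj, np.array([0.0, 5.0, 20.0]))
        assert p[0] == 0.0 and p[1] == 0.0 and p[2] > 0.0


class TestPredictPulseChase:
    def test_zero_folding_rate_curve_is_zero(self, protocol):
        c = small_construct(bulk_kF=0.0, bulk_kU=1.0)
        sched = TranslationSchedule.uniform(30, 5.0)
        for method in ("master", "cohort"):
            curve = predict_pulse_chase(c, sched, protocol, method=method)
            np.testing.assert_allclose(curve.values[curve.defined], 0.0)

    def test_delta_c_shape(self, delta_c, protocol):
        construct, schedule = delta_c
        curve = predict_pulse_chase(construct, schedule, protocol)
        v = curve.values
        assert np.all(curve.defined)
        assert v[0] > 0.0  # labelled chains already folded at chase start
        assert np.all(np.diff(v) >= -1e-9)  # nondecreasing
        plateau = v[-1]
        flat = v[(curve.times >= 100)]
        assert flat.max() - flat.min() <= 0.01
        assert plateau == pytest.approx(construct.p_eq_bulk, abs=1e-3)

    def test_methods_agree_away_from_kink(self, delta_c, protocol):
        # master and cohort realizations share assumptions; they differ
        # only by dwell-jitter smoothing near the last onset crossing
        construct, schedule = delta_c
        master = predict_pulse_chase(construct, schedule, protocol).values
        cohort = predict_pulse_chase(
            construct, schedule, protocol, method="cohort"
        ).values
        assert np.abs(master - cohort).max() < 0.05
        assert np.abs(master[-50:] - cohort[-50:]).max() < 1e-3

    def test_all_values_are_probabilities(self, delta_c, protocol):
        construct, schedule = delta_c
        for method in ("master", "cohort"):
            v = predict_pulse_chase(construct, schedule, protocol, method=method).values
            assert np.all((v >= 0.0) & (v <= 1.0 + 1e-12))

    def test_length_mismatch_rejected(self, delta_c, protocol):
        construct, _ = delta_c
        with pytest.raises(ValueError):
            predict_pulse_chase(
                construct, TranslationSchedule.uniform(100, 3.9), protocol
            )

    def test_cohort_ledger_conservation(self, delta_c, protocol):
        # bound + released labelled counts equal the visible pool
        construct, schedule = delta_c
        _, ledger = predict_pulse_chase(
            construct, schedule, protocol, return_ledger=True, method="cohort"
        )
        t_abs = protocol.absolute_report_times
        visible = (ledger.labelling_time[None, :] <= t_abs[:, None]).sum(axis=1)
        np.testing.assert_array_equal(
            ledger.N_L_B(t_abs) + ledger.N_L_R(t_abs), visible
        )

    def test_bound_length_distribution_uniform(self):
        # steady state + uniform k_A: bound cohorts sit uniformly over codons
        c = small_construct(total_codons=60, domain_end=20, tunnel_length=10,
                            observable_codons=frozenset(range(1, 21)))
        sched = TranslationSchedule.uniform(60, 4.0)
        proto = Protocol(dt_s=0.05)  # 5 cohorts per 0.25 s dwell, exactly
        _, ledger = predict_pulse_chase(
            c, sched, proto, return_ledger=True, method="cohort"
        )
        # pick a time when every labelled cohort is still bound
        t = float(ledger.release_time.min()) - 1.0
        positions = np.ceil((t - ledger.t0) * 4.0).astype(int)
        bound = positions[(positions >= 1) & (positions <= 60)]
        counts = np.bincount(bound, minlength=61)[1:]
        interior = counts[10:50]
        assert interior.min() == interior.max()  # exactly uniform occupancy

    def test_dt_refinement_converges(self, delta_c):
        construct, schedule = delta_c
        coarse = predict_pulse_chase(
            construct, schedule, Protocol(dt_s=0.01)
        ).values
        fine = predict_pulse_chase(
            construct, schedule, Protocol(dt_s=0.005)
        ).values
        assert np.abs(coarse - fine).max() < 1e-3


class TestFractionFullLength:
    def test_normalized_and_monotone(self, delta_c, protocol):
        construct, schedule = delta_c
        for method in ("master", "cohort"):
            _, ledger = predict_pulse_chase(
                construct, schedule, protocol, return_ledger=True, method=method
            )
            f = fraction_full_length(ledger, protocol)
            assert f.values[-1] == pytest.approx(1.0)
            assert np.all(np.diff(f.values) >= -1e-12)
            assert np.all((f.values >= 0) & (f.values <= 1))

    def test_first_release_time(self, delta_c, protocol):
        # earliest labelled cohort initiates at d - tau(last observable);
        # its release ends the zero stretch of f_L,R
        construct, schedule = delta_c
        _, ledger = predict_pulse_chase(
            construct, schedule, protocol, return_ledger=True, method="cohort"
        )
        f = fraction_full_length(ledger, protocol)
        tau_obs = schedule.tau_cum[max(construct.observable_codons) - 1]
        first_release_chase = (
            protocol.delay_s - tau_obs + schedule.total_time_s
            - protocol.pulse_s
        )
        crossed = f.times[np.nonzero(f.values > 0)[0][0]]
        assert crossed == pytest.approx(first_release_chase, abs=2.0)


class TestSensitivitySweep:
    def test_factor_one_reproduces_base(self, delta_c, protocol):
        construct, schedule = delta_c
        base = predict_pulse_chase(construct, schedule, protocol).values
        curves = sensitivity_sweep(
            construct, schedule, protocol,
            kF_factors=(1.0,), kU_factors=(1.0,), kA_factors=(1.0,),
        )
        for label, curve in curves.items():
            np.testing.assert_allclose(curve.values, base, atol=1e-12)

    def test_ku_insensitivity_delta_c(self, delta_c, protocol):
        # an order of magnitude either way in k_U leaves the curve unchanged
        construct, schedule = delta_c
        curves = sensitivity_sweep(
            construct, schedule, protocol, kU_factors=(10.0, 1.0, 0.1)
        )
        vals = [c.values for c in curves.values()]
        for a in vals:
            for b in vals:
                assert np.abs(a - b).max() < 1e-3

    def test_tunnel_sweep_labels(self, delta_c, protocol):
        construct, schedule = delta_c
        curves = sensitivity_sweep(
            construct, schedule, protocol, tunnel_lengths=(20, 30, 40)
        )
        assert set(curves) == {"tunnel_20", "tunnel_30", "tunnel_40"}
        # longer tunnel -> later folding onset -> lower curve early on
        assert curves["tunnel_20"].values[0] >= curves["tunnel_40"].values[0]
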
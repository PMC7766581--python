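"""Sampler unit tests: Metropolis criterion, move proposals, exchange
probabilities, step-size calibration, determinism, and annealing."""

import numpy as np
import pytest

from semiflex import _kernels
from semiflex.model import (
    ModelParameters,
    PivotMove,
    apply_move,
    bend_angles,
    bond_lengths,
    straight_chain,
    total_energy,
)
from semiflex.sampling import (
    AnnealingSchedule,
    ReplicaState,
    SweepSchedule,
    TemperatureLadder,
    calibrate_step_sizes,
    displacement_move,
    metropolis_accept,
    pivot_move,
    replica_exchange_step,
    run_parallel_tempering,
    simulated_annealing,
    _run_thread_segment,
)

from conftest import random_valid_chain


class TestMetropolis:
    def test_downhill_always_accepts(self):
        for u in (0.0, 0.5, 0.999999):
            assert metropolis_accept(-3.0, 1.0, u)
            assert metropolis_accept(0.0, 1.0, u)

    def test_half_acceptance_at_t_ln2(self):
        T = 0.7
        de = T * np.log(2.0)
        us = np.linspace(0.0, 1.0, 10001, endpoint=False)
        acc = np.mean([metropolis_accept(de, T, u) for u in us])
        assert acc == pytest.approx(0.5, abs=1e-3)

    def test_sentinel_always_rejects(self):
        for u in (0.0, 0.999):
            assert not metropolis_accept(np.inf, 1.0, u)

    def test_requires_positive_temperature(self):
        with pytest.raises(ValueError):
            metropolis_accept(1.0, 0.0, 0.5)


class TestMoves:
    def test_zero_step_size_is_identity(self, params10, rng):
        st = ReplicaState(
            positions=random_valid_chain(params10, rng), energy=0.0,
            thread_index=0, rng=rng, step_size=0.0,
        )
        move, delta = displacement_move(st, params10)
        assert np.all(move.shift == 0.0)
        assert delta == 0.0

    def test_displacement_proposal_is_centred(self, params10):
        st = ReplicaState(
            positions=straight_chain(params10), energy=0.0,
            thread_index=0, rng=np.random.default_rng(7), step_size=0.5,
        )
        shifts = np.array(
            [displacement_move(st, params10)[0].shift for _ in range(20000)]
        )
        se = shifts.std(axis=0) / np.sqrt(len(shifts))
        assert np.all(np.abs(shifts.mean(axis=0)) < 3 * se)
        assert np.all(np.abs(shifts) <= 0.25)  # components within [-rd/2, rd/2]

    def test_pivot_preserves_bonds_and_remote_angles(self, params10, rng):
        pos = random_valid_chain(params10, rng)
        st = ReplicaState(positions=pos, energy=0.0, thread_index=0, rng=rng)
        for _ in range(50):
            move, _ = pivot_move(st, params10)
            after = apply_move(pos, move)
            assert np.allclose(bond_lengths(after), bond_lengths(pos), atol=1e-10)
            a0, a1 = bend_angles(pos), bend_angles(after)
            mask = np.ones(len(a0), dtype=bool)
            mask[move.index - 1] = False  # only the pivot-vertex angle may change
            assert np.allclose(a0[mask], a1[mask], atol=1e-10)

    def test_zero_angle_pivot_is_identity(self, params10, rng):
        pos = random_valid_chain(params10, rng)
        move = PivotMove(index=4, axis=np.array([0.0, 0.0, 1.0]), angle=0.0)
        assert np.allclose(apply_move(pos, move), pos, atol=1e-14)


class TestExchange:
    def _states(self, energies):
        return [
            ReplicaState(
                positions=np.zeros((2, 3)), energy=e, thread_index=k,
                rng=np.random.default_rng(k), replica_id=k,
            )
            for k, e in enumerate(energies)
        ]

    def test_equal_energy_always_swaps(self):
        ladder = TemperatureLadder(np.array([0.5, 1.0]))
        states = self._states([-5.0, -5.0])
        assert replica_exchange_step(ladder, states, 0, 0.999999)

    def test_exchange_probability_value(self):
        # E_k = -10, E_{k+1} = -12 at T = 1.0, 1.25: exponent +0.4 -> certain
        ladder = TemperatureLadder(np.array([1.0, 1.25]))
        assert replica_exchange_step(ladder, self._states([-10.0, -12.0]), 0, 0.9999)
        # interchanged energies: probability exp(-0.4)
        p = np.exp(-0.4)
        assert replica_exchange_step(ladder, self._states([-12.0, -10.0]), 0, p - 1e-6)
        assert not replica_exchange_step(ladder, self._states([-12.0, -10.0]), 0, p + 1e-6)

    def test_swap_preserves_energy_multiset(self):
        ladder = TemperatureLadder(np.array([0.8, 1.0, 1.3]))
        states = self._states([-1.0, -2.0, -3.0])
        before = sorted(s.energy for s in states)
        replica_exchange_step(ladder, states, 1, 0.0)
        assert sorted(s.energy for s in states) == before
        assert [s.replica_id for s in states] == [0, 2, 1]


class TestCalibration:
    def test_acceptance_near_half_and_monotone_steps(self):
        params = ModelParameters(n_monomers=8, kappa=0.0)
        ladder = TemperatureLadder(np.array([0.3, 0.7, 1.5, 3.0]))
        rd = calibrate_step_sizes(ladder, params, trial_sweeps=300, seed=5)
        # verify on fresh long segments at the calibrated step sizes
        pv = _kernels.pack_params(params)
        from semiflex.sampling import _make_states

        states, _ = _make_states(params, ladder, seed=5)
        for st, r in zip(states, rd):
            st.step_size = r
        for k, st in enumerate(states):
            beta = 1.0 / ladder.temperatures[k]
            _run_thread_segment(st, pv, beta, 400, 0)  # thermalize a bit
            out = _run_thread_segment(st, pv, beta, 1500, 0)
            acc = out["acc_disp"] / out["att_disp"]
            assert 0.40 < acc < 0.62, f"thread {k}: acceptance {acc:.3f}"
        # hotter threads need larger boxes for the same acceptance
        assert rd[-1] > rd[0]
        assert np.all(np.diff(rd) > -0.25 * rd[:-1])

    def test_calibration_is_deterministic(self):
        params = ModelParameters(n_monomers=6, kappa=1.0)
        ladder = TemperatureLadder(np.array([0.5, 2.0]))
        a = calibrate_step_sizes(ladder, params, trial_sweeps=100, seed=3)
        b = calibrate_step_sizes(ladder, params, trial_sweeps=100, seed=3)
        assert np.array_equal(a, b)


class TestParallelTempering:
    def test_zero_measurement_sweeps_gives_empty_histograms(self):
        params = ModelParameters(n_monomers=5, kappa=0.0)
        ladder = TemperatureLadder(np.array([0.5, 1.0]))
        sched = SweepSchedule(total_sweeps=0, thermalization_sweeps=100,
                              exchange_period_sweeps=50)
        res = run_parallel_tempering(params, ladder, sched, seed=0)
        assert np.all(res.histograms.totals == 0)
        assert np.isfinite(res.best_energy)

    def test_fixed_seed_reproducibility(self):
        params = ModelParameters(n_monomers=6, kappa=0.5)
        ladder = TemperatureLadder(np.array([0.4, 1.0, 2.5]))
        sched = SweepSchedule(total_sweeps=600, thermalization_sweeps=200,
                              exchange_period_sweeps=100, timeseries_stride=5)
        a = run_parallel_tempering(params, ladder, sched, seed=11)
        b = run_parallel_tempering(params, ladder, sched, seed=11)
        assert np.array_equal(a.histograms.counts, b.histograms.counts)
        assert a.best_energy == b.best_energy
        for ta, tb in zip(a.histograms.energy_timeseries, b.histograms.energy_timeseries):
            assert np.array_equal(ta, tb)

    def test_histogram_totals_conserve_measurements(self):
        params = ModelParameters(n_monomers=6, kappa=0.0)
        ladder = TemperatureLadder(np.array([0.5, 1.5]))
        sched = SweepSchedule(total_sweeps=800, thermalization_sweeps=100,
                              exchange_period_sweeps=200)
        res = run_parallel_tempering(params, ladder, sched, seed=2)
        assert np.all(res.histograms.totals + res.histograms.dropped == 800)
        assert np.all(res.histograms.dropped == 0)

    def test_replica_mixing_covers_ladder(self):
        params = ModelParameters(n_monomers=5, kappa=0.0)
        ladder = TemperatureLadder(np.geomspace(0.5, 2.0, 4))
        sched = SweepSchedule(total_sweeps=4000, thermalization_sweeps=200,
                              exchange_period_sweeps=50)
        res = run_parallel_tempering(params, ladder, sched, seed=8)
        lo, hi = res.replica_thread_range.T
        # every replica should wander across most of the small ladder
        assert np.all(hi - lo >= 2)


class TestAnnealing:
    def test_near_zero_temperature_keeps_local_minimum(self):
        params = ModelParameters(n_monomers=2)
        start = straight_chain(params)  # dimer at exactly r0: a local minimum
        sched = AnnealingSchedule(t_start=1e-9, t_end=1e-10, n_stages=2,
                                  sweeps_per_stage=200, pivot_interval=0)
        pos, e = simulated_annealing(params, sched, seed=0, start=start,
                                     step_size=0.05)
        assert e == pytest.approx(total_energy(start, params).total, abs=1e-12)
        assert np.allclose(pos, start)

    def test_trimer_reaches_triangle_ground_state(self):
        # three pairwise near-r0 contacts: 2 bonds + 1 non-bonded pair
        params = ModelParameters(n_monomers=3, kappa=0.0)
        sched = AnnealingSchedule(t_start=1.0, t_end=0.01, n_stages=30,
                                  sweeps_per_stage=300, pivot_interval=5)
        _, e = simulated_annealing(params, sched, seed=1, n_restarts=3)
        assert e <= -2.95

    def test_best_energy_non_increasing_over_restarts(self):
        params = ModelParameters(n_monomers=4, kappa=0.0)
        sched = AnnealingSchedule(t_start=1.0, t_end=0.05, n_stages=10,
                                  sweeps_per_stage=100)
        energies = [
            simulated_annealing(params, sched, seed=9, n_restarts=r)[1]
            for r in (1, 2, 4)
        ]
        assert energies[0] >= energies[1] >= energies[2]
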
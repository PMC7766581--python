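"""Replica-exchange Metropolis Monte Carlo for the bead-spring chain.

Each temperature thread runs local displacement moves (one sweep = N
attempted single-monomer moves inside a cube of edge ``r_d``) with
periodic sweeps of pivot rotations; conformations are swapped between
neighbouring threads at a fixed period.  Displacement step sizes are
calibrated adaptively before measurements begin so every thread accepts
roughly half of its moves.  A geometric-cooling simulated-annealing
driver reuses the same move kernels for ground-state search.

Randomness: a single master seed spawns one independent ``numpy``
bit-generator stream per thread plus one for the exchange scheduler, so
entire runs are bit-reproducible.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import _kernels
from .model import ModelParameters, straight_chain, total_energy

__all__ = [
    "TemperatureLadder",
    "SweepSchedule",
    "ReplicaState",
    "EnergyHistogramSet",
    "AnnealingSchedule",
    "ParallelTemperingResult",
    "metropolis_accept",
    "displacement_move",
    "pivot_move",
    "calibrate_step_sizes",
    "replica_exchange_step",
    "run_parallel_tempering",
    "simulated_annealing",
]


@dataclass(frozen=True)
class TemperatureLadder:
    """Ordered increasing simulation temperatures T_1 < ... < T_K."""

    temperatures: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.temperatures, dtype=float)
        if t.ndim != 1 or len(t) < 1:
            raise ValueError("ladder needs at least one temperature")
        if np.any(t <= 0) or np.any(np.diff(t) <= 0):
            raise ValueError("temperatures must be positive and strictly increasing")
        object.__setattr__(self, "temperatures", t)

    @property
    def count(self) -> int:
        return len(self.temperatures)

    @classmethod
    def geometric(cls, t_min: float = 0.1, t_max: float = 5.0, count: int = 40) -> "TemperatureLadder":
        """Geometrically spaced ladder (default production range).

        Geometric spacing keeps the neighbour temperature ratio constant,
        which roughly evens out exchange acceptance for systems whose
        heat capacity varies over decades.
        """
        return cls(np.geomspace(t_min, t_max, count))


@dataclass(frozen=True)
class SweepSchedule:
    """Sweep counts controlling a parallel-tempering run.

    ``displacement_sweeps_per_pivot_sweep`` may be a single integer or
    None, in which case it is interpolated linearly per thread from 70
    at the coldest temperature down to 20 at the hottest (compact
    low-temperature states need more local moves between the cheap
    global pivots).
    """

    total_sweeps: int
    thermalization_sweeps: int = 0
    exchange_period_sweeps: int = 1500
    displacement_sweeps_per_pivot_sweep: Optional[int] = None
    timeseries_stride: int = 1

    def __post_init__(self):
        if self.total_sweeps < 0 or self.thermalization_sweeps < 0:
            raise ValueError("sweep counts must be non-negative")
        if self.exchange_period_sweeps < 1:
            raise ValueError("exchange period must be >= 1")
        if self.timeseries_stride < 1:
            raise ValueError("time-series stride must be >= 1")

    def pivot_interval(self, thread: int, n_threads: int) -> int:
        if self.displacement_sweeps_per_pivot_sweep is not None:
            return int(self.displacement_sweeps_per_pivot_sweep)
        if n_threads == 1:
            return 45
        frac = thread / (n_threads - 1)
        return int(round(70 + (20 - 70) * frac))


@dataclass
class ReplicaState:
    """Mutable state of one temperature thread."""

    positions: np.ndarray
    energy: float
    thread_index: int
    rng: np.random.Generator
    step_size: float = 1.0
    replica_id: int = -1  # identity label that travels with the conformation


@dataclass
class EnergyHistogramSet:
    """Per-temperature binned energy counts on a shared uniform grid,
    plus per-thread (E, R_gyr^2) time series."""

    bin_edges: np.ndarray          # (B + 1,)
    counts: np.ndarray             # (K, B) int64
    temperatures: np.ndarray       # (K,)
    energy_timeseries: list = field(default_factory=list)   # K arrays
    rgyr_timeseries: list = field(default_factory=list)     # K arrays
    timeseries_stride: int = 1
    dropped: np.ndarray = None     # (K,) samples outside the grid

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def totals(self) -> np.ndarray:
        """Recorded measurement count per thread (the WHAM M_k)."""
        return self.counts.sum(axis=1)


@dataclass(frozen=True)
class AnnealingSchedule:
    """Geometric cooling from t_start down to t_end over n_stages."""

    t_start: float = 2.0
    t_end: float = 0.05
    n_stages: int = 40
    sweeps_per_stage: int = 500
    pivot_interval: int = 10

    def temperatures(self) -> np.ndarray:
        if self.t_start <= self.t_end:
            raise ValueError("annealing must cool: t_start > t_end required")
        return np.geomspace(self.t_start, self.t_end, self.n_stages)


def metropolis_accept(delta_e: float, temperature: float, u: float, kB: float = 1.0) -> bool:
    """Metropolis criterion: accept iff ``u < min(exp(-dE/kB T), 1)``.

    The infinite-energy sentinel always rejects.
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    if not np.isfinite(delta_e):
        return False
    if delta_e <= 0:
        return True
    return u < math.exp(-delta_e / (kB * temperature))


def displacement_move(state: ReplicaState, params: ModelParameters):
    """Draw a single-monomer displacement proposal and its energy delta.

    The monomer index is uniform over the chain and each shift component
    uniform in ``[-r_d/2, +r_d/2]`` (a symmetric proposal).  Returns
    ``(move, delta)``; the caller applies Metropolis and, on acceptance,
    the move.
    """
    from .model import DisplacementMove, energy_delta

    i = int(state.rng.integers(params.n_monomers))
    shift = (state.rng.random(3) - 0.5) * state.step_size
    move = DisplacementMove(index=i, shift=shift)
    return move, energy_delta(state.positions, move, params)


def pivot_move(state: ReplicaState, params: ModelParameters):
    """Draw a pivot proposal: uniform interior pivot monomer, uniform
    random rotation axis through it, angle uniform in [0, 2 pi)."""
    from .model import PivotMove, energy_delta

    if params.n_monomers < 3:
        raise ValueError("pivot moves need at least three monomers")
    i = int(state.rng.integers(1, params.n_monomers - 1))
    axis = state.rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = float(state.rng.uniform(0.0, 2.0 * np.pi))
    move = PivotMove(index=i, axis=axis, angle=angle)
    return move, energy_delta(state.positions, move, params)


def replica_exchange_step(
    ladder: TemperatureLadder, states: Sequence[ReplicaState], k: int, u: float, kB: float = 1.0
) -> bool:
    """Attempt a conformation swap between threads k and k + 1.

    Accepted iff ``u < min(exp[(E_k - E_{k+1}) (1/kB T_k - 1/kB T_{k+1})], 1)``.
    A swap exchanges conformations, cached energies and replica labels;
    thread temperature, RNG stream and step size stay with the slot.
    """
    a, b = states[k], states[k + 1]
    arg = (a.energy - b.energy) * (
        1.0 / (kB * ladder.temperatures[k]) - 1.0 / (kB * ladder.temperatures[k + 1])
    )
    if arg >= 0 or u < math.exp(arg):
        a.positions, b.positions = b.positions, a.positions
        a.energy, b.energy = b.energy, a.energy
        a.replica_id, b.replica_id = b.replica_id, a.replica_id
        return True
    return False


# ---------------------------------------------------------------------------
# kernel-facing helpers

def _segment_randoms(rng: np.random.Generator, n_sweeps: int, n: int, pivot_interval: int):
    disp_idx = rng.integers(0, n, size=(n_sweeps, n))
    disp_shift = rng.random(size=(n_sweeps, n, 3)) - 0.5
    disp_u = rng.random(size=(n_sweeps, n))
    if pivot_interval > 0 and n >= 3:
        n_piv = n_sweeps // pivot_interval
    else:
        n_piv = 0
        pivot_interval = 0
    if n_piv > 0:
        piv_idx = rng.integers(1, n - 1, size=(n_piv, n - 2))
        ax = rng.normal(size=(n_piv, n - 2, 3))
        ax /= np.linalg.norm(ax, axis=2, keepdims=True)
        piv_angle = rng.uniform(0.0, 2.0 * np.pi, size=(n_piv, n - 2))
        piv_u = rng.random(size=(n_piv, n - 2))
    else:
        piv_idx = np.zeros((0, max(n - 2, 0)), dtype=np.int64)
        ax = np.zeros((0, max(n - 2, 0), 3))
        piv_angle = np.zeros((0, max(n - 2, 0)))
        piv_u = np.zeros((0, max(n - 2, 0)))
    return disp_idx, disp_shift, disp_u, pivot_interval, piv_idx, ax, piv_angle, piv_u


_EMPTY_HIST = np.zeros(0, dtype=np.int64)
_EMPTY_TS = np.zeros(0)


def _run_thread_segment(
    state: ReplicaState,
    pv: np.ndarray,
    beta: float,
    n_sweeps: int,
    pivot_interval: int,
    hist: np.ndarray = _EMPTY_HIST,
    e_lo: float = 0.0,
    bin_w: float = 1.0,
    ts_stride: int = 0,
    best_pos: Optional[np.ndarray] = None,
    best_energy: float = np.inf,
):
    n = state.positions.shape[0]
    rnd = _segment_randoms(state.rng, n_sweeps, n, pivot_interval)
    disp_idx, disp_shift, disp_u, pivot_interval, piv_idx, ax, piv_angle, piv_u = rnd
    if ts_stride > 0:
        n_ts = len(range(0, n_sweeps, ts_stride))
        e_ts = np.empty(n_ts)
        rg_ts = np.empty(n_ts)
    else:
        e_ts = _EMPTY_TS
        rg_ts = _EMPTY_TS
        ts_stride = 1
    if best_pos is None:
        best_pos = np.empty_like(state.positions)
    tail_buf = np.empty_like(state.positions)
    out = _kernels.run_segment(
        state.positions, state.energy, pv, beta, state.step_size,
        disp_idx, disp_shift, disp_u,
        pivot_interval, piv_idx, ax, piv_angle, piv_u,
        hist, e_lo, bin_w,
        e_ts, rg_ts, ts_stride,
        best_pos, tail_buf, best_energy,
    )
    energy, acc_d, att_d, acc_p, att_p, best_energy, dropped = out
    state.energy = float(energy)
    return {
        "acc_disp": acc_d, "att_disp": att_d,
        "acc_piv": acc_p, "att_piv": att_p,
        "best_energy": float(best_energy), "best_pos": best_pos,
        "dropped": int(dropped), "e_ts": e_ts, "rg_ts": rg_ts,
    }


def _make_states(params, ladder, seed):
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(ladder.count + 1)
    states = []
    for k in range(ladder.count):
        pos = straight_chain(params)
        e = total_energy(pos, params).total
        states.append(
            ReplicaState(
                positions=pos, energy=float(e), thread_index=k,
                rng=np.random.default_rng(children[k]),
                step_size=min(1.0, float(ladder.temperatures[k])),
                replica_id=k,
            )
        )
    exchange_rng = np.random.default_rng(children[-1])
    return states, exchange_rng


def _calibrate_states(
    states, ladder, params, pv, trial_sweeps=200, target=(0.45, 0.55),
    factor=1.1, max_rounds=60, burn_in_sweeps=0,
):
    lo, hi = target
    betas = 1.0 / (params.kB * ladder.temperatures)
    if burn_in_sweeps > 0:
        for k, st in enumerate(states):
            _run_thread_segment(st, pv, betas[k], burn_in_sweeps, pivot_interval=0)
    # every round re-measures every thread: calibration only finishes when
    # all acceptances land in the target window simultaneously, so step
    # sizes track the states as they keep equilibrating
    all_ok = False
    for _ in range(max_rounds):
        all_ok = True
        for k, st in enumerate(states):
            out = _run_thread_segment(st, pv, betas[k], trial_sweeps, pivot_interval=0)
            acc = out["acc_disp"] / max(out["att_disp"], 1)
            if acc > hi:
                st.step_size = min(st.step_size * factor, 50.0)
                all_ok = False
            elif acc < lo:
                st.step_size = max(st.step_size / factor, 1e-4)
                all_ok = False
        if all_ok:
            break
    if not all_ok:
        warnings.warn(
            "step-size calibration did not converge within "
            f"{max_rounds} rounds; using last r_d values"
        )
    return np.array([st.step_size for st in states])


def calibrate_step_sizes(
    ladder: TemperatureLadder,
    params: ModelParameters,
    trial_sweeps: int = 200,
    seed: int = 0,
    max_rounds: int = 60,
    burn_in_sweeps: int = 1000,
) -> np.ndarray:
    """Adapt each thread's displacement box edge ``r_d`` until the
    Metropolis acceptance rate lands in [0.45, 0.55] (about 50%).

    Threads start from a straight chain, burn in, and keep evolving
    during calibration, so the rates reflect thermalized-ish
    conformations.  Returns the per-thread ``r_d`` values.
    """
    pv = _kernels.pack_params(params)
    states, _ = _make_states(params, ladder, seed)
    return _calibrate_states(states, ladder, params, pv,
                             trial_sweeps=trial_sweeps, max_rounds=max_rounds,
                             burn_in_sweeps=burn_in_sweeps)


@dataclass
class ParallelTemperingResult:
    histograms: EnergyHistogramSet
    ladder: TemperatureLadder
    schedule: SweepSchedule
    params: ModelParameters
    step_sizes: np.ndarray
    best_energy: float
    best_positions: np.ndarray
    best_energy_per_thread: np.ndarray
    best_positions_per_thread: list
    acceptance_displacement: np.ndarray
    acceptance_pivot: np.ndarray
    acceptance_exchange: np.ndarray
    replica_thread_range: np.ndarray   # (K, 2) lowest/highest thread visited per replica
    seed: int = 0


def run_parallel_tempering(
    params: ModelParameters,
    ladder: TemperatureLadder,
    schedule: SweepSchedule,
    seed: int = 0,
    energy_range: Optional[tuple] = None,
    bin_width: float = 0.5,
    calibration_sweeps: int = 200,
    record_timeseries: bool = True,
) -> ParallelTemperingResult:
    """Full parallel-tempering run: calibration, thermalization,
    measurement with interleaved pivot sweeps and replica exchanges.

    Measurements (energy histogram per thread, optional (E, R_gyr^2)
    time series) are taken once per displacement sweep during the
    measurement phase only.  Exchange attempts occur every
    ``exchange_period_sweeps``, alternating even/odd neighbour pairs on
    successive exchange epochs.
    """
    pv = _kernels.pack_params(params)
    K = ladder.count
    n = params.n_monomers

    if energy_range is None:
        energy_range = (-6.0 * n, 6.0 * n)
    e_lo, e_hi = energy_range
    n_bins = int(np.ceil((e_hi - e_lo) / bin_width))
    edges = e_lo + bin_width * np.arange(n_bins + 1)

    states, ex_rng = _make_states(params, ladder, seed)

    betas = 1.0 / (params.kB * ladder.temperatures)
    period = schedule.exchange_period_sweeps
    piv_int = [schedule.pivot_interval(k, K) for k in range(K)]

    counts = np.zeros((K, n_bins), dtype=np.int64)
    dropped = np.zeros(K, dtype=np.int64)
    e_series: list = [[] for _ in range(K)]
    rg_series: list = [[] for _ in range(K)]
    best_pos = [np.array(st.positions, copy=True) for st in states]
    best_e = np.array([st.energy for st in states])
    acc_d = np.zeros(K)
    att_d = np.zeros(K)
    acc_p = np.zeros(K)
    att_p = np.zeros(K)
    ex_acc = np.zeros(max(K - 1, 1))
    ex_att = np.zeros(max(K - 1, 1))
    visit_lo = np.arange(K)
    visit_hi = np.arange(K)

    def _exchange(epoch):
        start = epoch % 2
        for k in range(start, K - 1, 2):
            u = float(ex_rng.random())
            if replica_exchange_step(ladder, states, k, u, kB=params.kB):
                ex_acc[k] += 1
            ex_att[k] += 1
        for k, st in enumerate(states):
            rid = st.replica_id
            visit_lo[rid] = min(visit_lo[rid], k)
            visit_hi[rid] = max(visit_hi[rid], k)

    def _phase(total, measuring, epoch0=0):
        epoch = epoch0
        done = 0
        while done < total:
            seg = min(period, total - done)
            for k, st in enumerate(states):
                kwargs = {}
                if measuring:
                    kwargs = dict(
                        hist=counts[k], e_lo=e_lo, bin_w=bin_width,
                        ts_stride=schedule.timeseries_stride if record_timeseries else 0,
                    )
                out = _run_thread_segment(
                    st, pv, betas[k], seg, piv_int[k],
                    best_pos=best_pos[k], best_energy=best_e[k], **kwargs,
                )
                best_e[k] = out["best_energy"]
                if measuring:
                    dropped[k] += out["dropped"]
                    acc_d[k] += out["acc_disp"]
                    att_d[k] += out["att_disp"]
                    acc_p[k] += out["acc_piv"]
                    att_p[k] += out["att_piv"]
                    if record_timeseries:
                        e_series[k].append(out["e_ts"])
                        rg_series[k].append(out["rg_ts"])
            done += seg
            if K > 1 and done < total or done == total:
                _exchange(epoch)
            epoch += 1
        return epoch

    # thermalize first (with exchanges), then calibrate step sizes on the
    # thermalized states so acceptance targets reflect equilibrium
    # conformations, then measure
    epoch = _phase(schedule.thermalization_sweeps, measuring=False)
    step_sizes = _calibrate_states(states, ladder, params, pv, trial_sweeps=calibration_sweeps)
    _phase(schedule.total_sweeps, measuring=True, epoch0=epoch)

    if np.any(dropped):
        warnings.warn(
            f"{int(dropped.sum())} energy samples fell outside the histogram grid "
            f"[{e_lo}, {e_hi}]; widen energy_range for unbiased histograms"
        )

    hist = EnergyHistogramSet(
        bin_edges=edges,
        counts=counts,
        temperatures=ladder.temperatures.copy(),
        energy_timeseries=[
            np.concatenate(s) if s else np.empty(0) for s in e_series
        ],
        rgyr_timeseries=[
            np.concatenate(s) if s else np.empty(0) for s in rg_series
        ],
        timeseries_stride=schedule.timeseries_stride,
        dropped=dropped,
    )
    k_best = int(np.argmin(best_e))
    return ParallelTemperingResult(
        histograms=hist,
        ladder=ladder,
        schedule=schedule,
        params=params,
        step_sizes=step_sizes,
        best_energy=float(best_e[k_best]),
        best_positions=best_pos[k_best].copy(),
        best_energy_per_thread=best_e,
        best_positions_per_thread=best_pos,
        acceptance_displacement=np.divide(acc_d, np.maximum(att_d, 1)),
        acceptance_pivot=np.divide(acc_p, np.maximum(att_p, 1)),
        acceptance_exchange=np.divide(ex_acc, np.maximum(ex_att, 1)),
        replica_thread_range=np.stack([visit_lo, visit_hi], axis=1),
        seed=seed,
    )


def simulated_annealing(
    params: ModelParameters,
    schedule: AnnealingSchedule,
    seed: int = 0,
    start: Optional[np.ndarray] = None,
    n_restarts: int = 1,
    step_size: Optional[float] = None,
):
    """Ground-state search by Metropolis dynamics under geometric cooling.

    Each restart begins from ``start`` (default: straight chain) with a
    fresh RNG stream; the best-ever conformation and energy across all
    restarts are returned, so the best energy is non-increasing as
    restarts accumulate.
    """
    pv = _kernels.pack_params(params)
    temps = schedule.temperatures()
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_restarts)
    best_energy = np.inf
    best_positions = None
    for r in range(n_restarts):
        rng = np.random.default_rng(children[r])
        pos = np.array(start, copy=True) if start is not None else straight_chain(params)
        st = ReplicaState(
            positions=pos, energy=float(total_energy(pos, params).total),
            thread_index=0, rng=rng, step_size=1.0, replica_id=r,
        )
        run_best_pos = np.array(st.positions, copy=True)
        run_best_e = st.energy
        st.step_size = step_size if step_size is not None else min(1.0, float(temps[0]))
        for T in temps:
            out = _run_thread_segment(
                st, pv, 1.0 / (params.kB * T),
                schedule.sweeps_per_stage, schedule.pivot_interval,
                best_pos=run_best_pos, best_energy=run_best_e,
            )
            run_best_e = out["best_energy"]
            if step_size is None:
                # steer acceptance toward ~50% for the next (cooler) stage
                acc = out["acc_disp"] / max(out["att_disp"], 1)
                st.step_size = float(np.clip(st.step_size * np.clip(acc / 0.5, 0.5, 2.0),
                                             1e-3, 2.0))
        if run_best_e < best_energy:
            best_energy = run_best_e
            best_positions = run_best_pos.copy()
    return best_positions, float(best_energy)
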
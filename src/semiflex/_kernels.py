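"""Numba inner loops for the Monte Carlo sampler and Bézier evaluation.

The Python layer draws all random numbers (one named numpy Generator per
replica thread) and hands them to these kernels in batches, so runs are
bit-reproducible regardless of JIT compilation details.  Model constants
travel as a flat float64 vector; see :func:`pack_params` for the layout.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# parameter-vector slots
_SIGMA2, _RC2, _VSHIFT, _R0, _RFENE, _KR2HALF, _KAPPA, _THETA0 = range(8)

INF = np.inf


def pack_params(params) -> np.ndarray:
    """Flatten a ModelParameters object for the kernels."""
    pv = np.empty(8)
    pv[_SIGMA2] = params.sigma**2
    pv[_RC2] = params.r_cutoff**2
    pv[_VSHIFT] = params.v_shift
    pv[_R0] = params.r0
    pv[_RFENE] = params.fene_R
    pv[_KR2HALF] = 0.5 * params.fene_K * params.fene_R**2
    pv[_KAPPA] = params.kappa
    pv[_THETA0] = params.theta0
    # epsilon_lj is absorbed into the LJ evaluation via sigma only when 1;
    # keep the model in reduced units (enforced by the sampler layer).
    if params.epsilon_lj != 1.0:
        raise ValueError("kernels assume reduced units (epsilon_lj = 1)")
    return pv


@njit(cache=True, fastmath=False)
def _vlj_r2(r2, sigma2):
    x6 = (sigma2 / r2) ** 3
    return 4.0 * (x6 * x6 - x6)


@njit(cache=True, fastmath=False)
def _vnb_r2(r2, pv):
    if r2 < pv[_RC2]:
        return _vlj_r2(r2, pv[_SIGMA2]) - pv[_VSHIFT]
    return 0.0


@njit(cache=True, fastmath=False)
def _vbond(r, pv):
    x = (r - pv[_R0]) / pv[_RFENE]
    if x <= -1.0 or x >= 1.0:
        return INF
    return -pv[_KR2HALF] * np.log(1.0 - x * x) + _vlj_r2(r * r, pv[_SIGMA2]) - pv[_VSHIFT]


@njit(cache=True, fastmath=False)
def _angle_energy(pos, v, pv):
    ax = pos[v, 0] - pos[v - 1, 0]
    ay = pos[v, 1] - pos[v - 1, 1]
    az = pos[v, 2] - pos[v - 1, 2]
    bx = pos[v + 1, 0] - pos[v, 0]
    by = pos[v + 1, 1] - pos[v, 1]
    bz = pos[v + 1, 2] - pos[v, 2]
    num = ax * bx + ay * by + az * bz
    den = np.sqrt((ax * ax + ay * ay + az * az) * (bx * bx + by * by + bz * bz))
    c = num / den
    if c > 1.0:
        c = 1.0
    elif c < -1.0:
        c = -1.0
    theta = np.arccos(c)
    return pv[_KAPPA] * (1.0 - np.cos(theta - pv[_THETA0]))


@njit(cache=True, fastmath=False)
def total_energy_terms(pos, pv):
    """(nonbonded, bonded, bending) for a full conformation."""
    n = pos.shape[0]
    nb = 0.0
    for i in range(n):
        for j in range(i + 2, n):
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            dz = pos[i, 2] - pos[j, 2]
            nb += _vnb_r2(dx * dx + dy * dy + dz * dz, pv)
    bonded = 0.0
    for i in range(n - 1):
        dx = pos[i + 1, 0] - pos[i, 0]
        dy = pos[i + 1, 1] - pos[i, 1]
        dz = pos[i + 1, 2] - pos[i, 2]
        b = _vbond(np.sqrt(dx * dx + dy * dy + dz * dz), pv)
        if not np.isfinite(b):
            return INF, INF, INF
        bonded += b
    bend = 0.0
    if pv[_KAPPA] != 0.0:
        for v in range(1, n - 1):
            bend += _angle_energy(pos, v, pv)
    return nb, bonded, bend


@njit(cache=True, fastmath=False)
def total_energy_value(pos, pv):
    nb, bonded, bend = total_energy_terms(pos, pv)
    return nb + bonded + bend


@njit(cache=True, fastmath=False)
def _local_disp_energy(pos, i, pv):
    """Energy terms touched by displacing monomer i."""
    n = pos.shape[0]
    e = 0.0
    for j in range(n):
        dj = j - i
        if dj < 0:
            dj = -dj
        if dj >= 2:
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            dz = pos[i, 2] - pos[j, 2]
            e += _vnb_r2(dx * dx + dy * dy + dz * dz, pv)
    for j in (i - 1, i):
        if 0 <= j < n - 1:
            dx = pos[j + 1, 0] - pos[j, 0]
            dy = pos[j + 1, 1] - pos[j, 1]
            dz = pos[j + 1, 2] - pos[j, 2]
            b = _vbond(np.sqrt(dx * dx + dy * dy + dz * dz), pv)
            if not np.isfinite(b):
                return INF
            e += b
    if pv[_KAPPA] != 0.0:
        for v in (i - 1, i, i + 1):
            if 1 <= v <= n - 2:
                e += _angle_energy(pos, v, pv)
    return e


@njit(cache=True, fastmath=False)
def _pivot_cross_energy(pos, i, pv):
    """Non-bonded energy of pairs straddling pivot i, plus the bend at i."""
    n = pos.shape[0]
    e = 0.0
    for a in range(i + 1):
        for b in range(max(i + 1, a + 2), n):
            dx = pos[a, 0] - pos[b, 0]
            dy = pos[a, 1] - pos[b, 1]
            dz = pos[a, 2] - pos[b, 2]
            e += _vnb_r2(dx * dx + dy * dy + dz * dz, pv)
    if pv[_KAPPA] != 0.0 and 1 <= i <= n - 2:
        e += _angle_energy(pos, i, pv)
    return e


@njit(cache=True, fastmath=False)
def radius_of_gyration_sq(pos):
    n = pos.shape[0]
    cx = cy = cz = 0.0
    for i in range(n):
        cx += pos[i, 0]
        cy += pos[i, 1]
        cz += pos[i, 2]
    cx /= n
    cy /= n
    cz /= n
    s = 0.0
    for i in range(n):
        dx = pos[i, 0] - cx
        dy = pos[i, 1] - cy
        dz = pos[i, 2] - cz
        s += dx * dx + dy * dy + dz * dz
    return s / n


@njit(cache=True, fastmath=False)
def run_segment(
    pos,
    energy,
    pv,
    beta,
    rd,
    disp_idx,   # (S, N) int64 monomer indices
    disp_shift,  # (S, N, 3) uniforms in [-0.5, 0.5), scaled by rd inside
    disp_u,     # (S, N) uniforms
    pivot_interval,  # do a pivot sweep after every `pivot_interval` sweeps (0 = never)
    piv_idx,    # (n_pivot_sweeps, N-2) pivot monomers in 1..N-2
    piv_axis,   # (n_pivot_sweeps, N-2, 3) unit vectors
    piv_angle,  # (n_pivot_sweeps, N-2) angles in [0, 2pi)
    piv_u,      # (n_pivot_sweeps, N-2)
    hist,       # (n_bins,) int64, updated in place; size 0 disables
    e_lo,
    bin_w,
    e_ts,       # (n_ts,) float64 energy time series; size 0 disables
    rg_ts,      # (n_ts,)
    ts_stride,
    best_pos,   # (N, 3) in/out
    tail_buf,   # (N, 3) scratch
    best_energy,
):
    """Run S displacement sweeps (with interleaved pivot sweeps and
    per-sweep measurements) at one fixed temperature.

    Returns (energy, acc_disp, att_disp, acc_piv, att_piv, best_energy,
    dropped) where `dropped` counts measurements outside the histogram
    grid.  The running energy is re-synced to a full evaluation at the
    end of the segment to keep accumulation error bounded.
    """
    n = pos.shape[0]
    n_sweeps = disp_idx.shape[0]
    acc_d = 0
    att_d = 0
    acc_p = 0
    att_p = 0
    dropped = 0
    n_bins = hist.shape[0]
    n_ts = e_ts.shape[0]
    ts_count = 0
    piv_sweep = 0

    for s in range(n_sweeps):
        for m in range(n):
            i = disp_idx[s, m]
            e_old = _local_disp_energy(pos, i, pv)
            ox = pos[i, 0]
            oy = pos[i, 1]
            oz = pos[i, 2]
            pos[i, 0] = ox + disp_shift[s, m, 0] * rd
            pos[i, 1] = oy + disp_shift[s, m, 1] * rd
            pos[i, 2] = oz + disp_shift[s, m, 2] * rd
            e_new = _local_disp_energy(pos, i, pv)
            att_d += 1
            d = e_new - e_old
            if np.isfinite(e_new) and (d <= 0.0 or disp_u[s, m] < np.exp(-beta * d)):
                energy += d
                acc_d += 1
                if energy < best_energy:
                    best_energy = energy
                    for q in range(n):
                        best_pos[q, 0] = pos[q, 0]
                        best_pos[q, 1] = pos[q, 1]
                        best_pos[q, 2] = pos[q, 2]
            else:
                pos[i, 0] = ox
                pos[i, 1] = oy
                pos[i, 2] = oz

        if pivot_interval > 0 and (s + 1) % pivot_interval == 0 and piv_sweep < piv_idx.shape[0]:
            for m in range(piv_idx.shape[1]):
                i = piv_idx[piv_sweep, m]
                e_old = _pivot_cross_energy(pos, i, pv)
                # save tail, rotate about axis through pos[i]
                kx = piv_axis[piv_sweep, m, 0]
                ky = piv_axis[piv_sweep, m, 1]
                kz = piv_axis[piv_sweep, m, 2]
                ang = piv_angle[piv_sweep, m]
                ca = np.cos(ang)
                sa = np.sin(ang)
                px = pos[i, 0]
                py = pos[i, 1]
                pz = pos[i, 2]
                for q in range(i + 1, n):
                    tail_buf[q, 0] = pos[q, 0]
                    tail_buf[q, 1] = pos[q, 1]
                    tail_buf[q, 2] = pos[q, 2]
                    vx = pos[q, 0] - px
                    vy = pos[q, 1] - py
                    vz = pos[q, 2] - pz
                    dot = kx * vx + ky * vy + kz * vz
                    crx = ky * vz - kz * vy
                    cry = kz * vx - kx * vz
                    crz = kx * vy - ky * vx
                    pos[q, 0] = px + vx * ca + crx * sa + kx * dot * (1.0 - ca)
                    pos[q, 1] = py + vy * ca + cry * sa + ky * dot * (1.0 - ca)
                    pos[q, 2] = pz + vz * ca + crz * sa + kz * dot * (1.0 - ca)
                e_new = _pivot_cross_energy(pos, i, pv)
                att_p += 1
                d = e_new - e_old
                if np.isfinite(e_new) and (d <= 0.0 or piv_u[piv_sweep, m] < np.exp(-beta * d)):
                    energy += d
                    acc_p += 1
                    if energy < best_energy:
                        best_energy = energy
                        for q in range(n):
                            best_pos[q, 0] = pos[q, 0]
                            best_pos[q, 1] = pos[q, 1]
                            best_pos[q, 2] = pos[q, 2]
                else:
                    for q in range(i + 1, n):
                        pos[q, 0] = tail_buf[q, 0]
                        pos[q, 1] = tail_buf[q, 1]
                        pos[q, 2] = tail_buf[q, 2]
            piv_sweep += 1

        # per-sweep measurements
        if n_bins > 0:
            b = int(np.floor((energy - e_lo) / bin_w))
            if 0 <= b < n_bins:
                hist[b] += 1
            else:
                dropped += 1
        if n_ts > 0 and s % ts_stride == 0 and ts_count < n_ts:
            e_ts[ts_count] = energy
            rg_ts[ts_count] = radius_of_gyration_sq(pos)
            ts_count += 1

    # re-sync cached energy against drift
    energy = total_energy_value(pos, pv)
    if energy < best_energy:
        best_energy = energy
        for q in range(n):
            best_pos[q, 0] = pos[q, 0]
            best_pos[q, 1] = pos[q, 1]
            best_pos[q, 2] = pos[q, 2]
    return energy, acc_d, att_d, acc_p, att_p, best_energy, dropped


@njit(cache=True, fastmath=False)
def bezier_eval_derivs(ctrl, ts):
    """Evaluate a Bernstein-form Bézier curve and its first three
    parameter derivatives at each t in `ts` by a single de Casteljau
    pass per point.

    The intermediate de Casteljau points after n - r steps are the
    control points of the r-th "tail"; finite differences of the last
    four, three and two of them give the third, second and first
    derivatives up to the factorial prefactors n!/(n-r)!.
    """
    n = ctrl.shape[0]      # number of control points, degree n - 1
    deg = n - 1
    m = ts.shape[0]
    val = np.empty(m)
    d1 = np.zeros(m)
    d2 = np.zeros(m)
    d3 = np.zeros(m)
    work = np.empty(n)
    for j in range(m):
        t = ts[j]
        s = 1.0 - t
        for i in range(n):
            work[i] = ctrl[i]
        for k in range(n - 1, 0, -1):
            if k == 3 and deg >= 3:
                d3[j] = (
                    deg * (deg - 1.0) * (deg - 2.0)
                    * (work[3] - 3.0 * work[2] + 3.0 * work[1] - work[0])
                )
            if k == 2 and deg >= 2:
                d2[j] = deg * (deg - 1.0) * (work[2] - 2.0 * work[1] + work[0])
            if k == 1:
                d1[j] = deg * (work[1] - work[0])
            for i in range(k):
                work[i] = s * work[i] + t * work[i + 1]
        val[j] = work[0]
    return val, d1, d2, d3


@njit(cache=True, fastmath=False)
def bezier_eval(ctrl, ts):
    """Evaluate a Bernstein-form Bézier curve with control ordinates
    `ctrl` (degree len(ctrl) - 1) at parameters `ts` in [0, 1] by the
    de Casteljau recursion (numerically stable at degree ~10^3)."""
    n = ctrl.shape[0]
    m = ts.shape[0]
    out = np.empty(m)
    work = np.empty(n)
    for j in range(m):
        t = ts[j]
        s = 1.0 - t
        for i in range(n):
            work[i] = ctrl[i]
        for k in range(n - 1, 0, -1):
            for i in range(k):
                work[i] = s * work[i] + t * work[i + 1]
        out[j] = work[0]
    return out
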
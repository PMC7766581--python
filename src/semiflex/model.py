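"""Energy model for a coarse-grained bead-spring polymer.

A chain of N identical monomers interacts through three terms:

* a truncated and shifted 12-6 Lennard-Jones potential between all
  non-bonded monomer pairs (pairs ``i > j + 1``),
* a combined FENE + Lennard-Jones bond potential between chain
  neighbours, finite only for bond lengths within ``(r0 - R, r0 + R)``,
* a bending penalty ``kappa * (1 - cos(theta - theta0))`` on each of the
  N - 2 angles between successive bond vectors.

All quantities are expressed in reduced units: the Lennard-Jones energy
scale, the reference bond length ``r0`` and the Boltzmann constant are
all unity by default.  A conformation is a plain ``(N, 3)`` float array
of monomer positions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "INFINITE_ENERGY",
    "Conformation",
    "ModelParameters",
    "EnergyReport",
    "DisplacementMove",
    "PivotMove",
    "lennard_jones",
    "nonbonded_potential",
    "bond_potential",
    "bending_potential",
    "bond_lengths",
    "bend_angles",
    "total_energy",
    "apply_move",
    "energy_delta",
    "straight_chain",
]

#: A conformation is simply an ``(N, 3)`` float array of monomer
#: positions in units of r0 (monomer order = chain order).
Conformation = np.ndarray

#: Sentinel returned for conformations with a bond outside the FENE range.
#: A sentinel (rather than an exception) lets the Metropolis step reject
#: such proposals uniformly.
INFINITE_ENERGY = np.inf


@dataclass(frozen=True)
class ModelParameters:
    """Coupling constants and geometric scales of the polymer model.

    Only the independent quantities are stored; every derived scale
    (``sigma``, ``r_cutoff``, ``v_shift``, FENE range and strength) is
    recomputed from ``r0`` so the invariants between them cannot drift.

    Parameters
    ----------
    n_monomers:
        Chain length N >= 2.
    kappa:
        Bending stiffness, >= 0.  ``kappa = 0`` is the fully flexible chain.
    epsilon_lj:
        Lennard-Jones energy scale (default 1, reduced units).
    r0:
        Reference bond length and location of the LJ minimum (default 1).
    theta0:
        Reference bending angle between successive bonds (default 0,
        i.e. a straight chain carries no bending energy).
    kB:
        Boltzmann constant (default 1).
    """

    n_monomers: int
    kappa: float = 0.0
    epsilon_lj: float = 1.0
    r0: float = 1.0
    theta0: float = 0.0
    kB: float = 1.0

    def __post_init__(self) -> None:
        if self.n_monomers < 2:
            raise ValueError("chain needs at least two monomers")
        if self.kappa < 0:
            raise ValueError("bending stiffness kappa must be >= 0")
        if self.epsilon_lj <= 0 or self.r0 <= 0:
            raise ValueError("energy and length scales must be positive")

    @property
    def sigma(self) -> float:
        """LJ length: the potential minimum sits at ``r0 = 2**(1/6) sigma``."""
        return 2.0 ** (-1.0 / 6.0) * self.r0

    @property
    def r_cutoff(self) -> float:
        """Non-bonded cutoff radius, 2.5 sigma."""
        return 2.5 * self.sigma

    @property
    def v_shift(self) -> float:
        """Value of the bare LJ potential at the cutoff (shift constant)."""
        return lennard_jones(self.r_cutoff, self)

    @property
    def fene_R(self) -> float:
        """FENE bond range: bonds live in the open interval (r0 - R, r0 + R)."""
        return (3.0 / 7.0) * self.r0

    @property
    def fene_K(self) -> float:
        """FENE spring strength K = (98/5) r0^2."""
        return (98.0 / 5.0) * self.r0**2


@dataclass(frozen=True)
class EnergyReport:
    """Decomposition of a conformation's energy into model terms."""

    nonbonded: float
    bonded: float
    bending: float

    @property
    def total(self) -> float:
        return self.nonbonded + self.bonded + self.bending


@dataclass(frozen=True)
class DisplacementMove:
    """Single-monomer translation: ``positions[index] += shift``."""

    index: int
    shift: np.ndarray  # (3,)


@dataclass(frozen=True)
class PivotMove:
    """Rigid rotation of the tail ``index+1 .. N-1`` about an axis
    through the pivot monomer (angle in radians, axis a unit vector)."""

    index: int
    axis: np.ndarray  # (3,) unit vector
    angle: float


def lennard_jones(r, params: ModelParameters):
    """Bare 12-6 Lennard-Jones potential, unshifted and without cutoff."""
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("distance must be positive")
    x6 = (params.sigma / r) ** 6
    out = 4.0 * params.epsilon_lj * (x6 * x6 - x6)
    return out if out.ndim else float(out)


def nonbonded_potential(r, params: ModelParameters):
    """Truncated-and-shifted LJ: ``V_LJ(r) - V_shift`` below the cutoff,
    exactly zero at and beyond it (continuous at ``r_cutoff``)."""
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("distance must be positive")
    inside = r < params.r_cutoff
    out = np.where(inside, lennard_jones(np.where(inside, r, params.r0), params) - params.v_shift, 0.0)
    return out if out.ndim else float(out)


def bond_potential(r, params: ModelParameters):
    """FENE + LJ bond potential.

    Finite on the open interval ``(r0 - R, r0 + R)`` with its minimum at
    ``r0``; outside that range the infinite-energy sentinel is returned
    (the bond cannot stretch there).
    """
    r = np.asarray(r, dtype=float)
    x = (r - params.r0) / params.fene_R
    inside = np.abs(x) < 1.0
    xs = np.where(inside, x, 0.0)
    fene = -0.5 * params.fene_K * params.fene_R**2 * np.log1p(-xs * xs)
    out = np.where(
        inside,
        fene + lennard_jones(np.where(r > 0, r, params.r0), params) - params.v_shift,
        INFINITE_ENERGY,
    )
    return out if out.ndim else float(out)


def bending_potential(theta, params: ModelParameters):
    """Bending penalty ``kappa * (1 - cos(theta - theta0))``, >= 0."""
    theta = np.asarray(theta, dtype=float)
    out = params.kappa * (1.0 - np.cos(theta - params.theta0))
    return out if out.ndim else float(out)


def bond_lengths(positions: np.ndarray) -> np.ndarray:
    """Lengths of the N - 1 chain bonds."""
    return np.linalg.norm(np.diff(positions, axis=0), axis=1)


def bend_angles(positions: np.ndarray) -> np.ndarray:
    """Angles between successive bond vectors (N - 2 values, radians).

    Zero for a straight chain; the dot product is clamped to [-1, 1]
    before the arccosine to absorb rounding.
    """
    b = np.diff(positions, axis=0)
    if len(b) < 2:
        return np.empty(0)
    num = np.einsum("ij,ij->i", b[:-1], b[1:])
    den = np.linalg.norm(b[:-1], axis=1) * np.linalg.norm(b[1:], axis=1)
    return np.arccos(np.clip(num / den, -1.0, 1.0))


def _check_conformation(positions: np.ndarray, params: ModelParameters) -> np.ndarray:
    positions = np.asarray(positions, dtype=float)
    if positions.ndim != 2 or positions.shape[1] != 3:
        raise ValueError("conformation must be an (N, 3) array")
    if positions.shape[0] != params.n_monomers:
        raise ValueError(
            f"conformation has {positions.shape[0]} monomers, "
            f"parameters expect {params.n_monomers}"
        )
    return positions


def total_energy(positions: np.ndarray, params: ModelParameters) -> EnergyReport:
    """Exact total energy of a conformation, decomposed by model term.

    The non-bonded sum runs over pairs ``i > j + 1`` only (bonded
    neighbours are excluded — their LJ contribution already lives inside
    the bond potential).  Any bond outside the FENE range makes the
    bonded term (and hence the total) the infinite-energy sentinel.
    """
    positions = _check_conformation(positions, params)
    n = len(positions)

    d = positions[:, None, :] - positions[None, :, :]
    rij = np.sqrt(np.einsum("ijk,ijk->ij", d, d))
    iu, ju = np.triu_indices(n, k=2)
    nb = float(np.sum(nonbonded_potential(rij[iu, ju], params))) if len(iu) else 0.0

    blen = bond_lengths(positions)
    bonded = float(np.sum(bond_potential(blen, params)))

    if params.kappa == 0.0:
        bending = 0.0
    else:
        bending = float(np.sum(bending_potential(bend_angles(positions), params)))
    return EnergyReport(nonbonded=nb, bonded=bonded, bending=bending)


def apply_move(positions: np.ndarray, move) -> np.ndarray:
    """Return a new conformation with the move applied (input untouched)."""
    new = np.array(positions, dtype=float, copy=True)
    if isinstance(move, DisplacementMove):
        new[move.index] += np.asarray(move.shift, dtype=float)
    elif isinstance(move, PivotMove):
        i = move.index
        axis = np.asarray(move.axis, dtype=float)
        axis = axis / np.linalg.norm(axis)
        rot = _rotation_matrix(axis, move.angle)
        new[i + 1 :] = (new[i + 1 :] - new[i]) @ rot.T + new[i]
    else:
        raise TypeError(f"unknown move type: {type(move)!r}")
    return new


def _rotation_matrix(axis: np.ndarray, angle: float) -> np.ndarray:
    """Rodrigues rotation matrix about a unit axis."""
    kx, ky, kz = axis
    K = np.array([[0.0, -kz, ky], [kz, 0.0, -kx], [-ky, kx, 0.0]])
    return np.eye(3) + np.sin(angle) * K + (1.0 - np.cos(angle)) * (K @ K)


def energy_delta(positions: np.ndarray, move, params: ModelParameters) -> float:
    """Incremental energy difference of a single move.

    Only the interactions touched by the move are recomputed: for a
    displacement of monomer ``i``, the non-bonded pairs involving ``i``,
    its one or two bonds and the up-to-three bend angles containing it;
    for a pivot, the bend angle at the pivot and the non-bonded pairs
    straddling it (bond lengths and all other angles are invariant under
    the rigid tail rotation).  Matches ``total_energy(after) -
    total_energy(before)`` to accumulation tolerance; a move producing
    an invalid bond yields the infinite-energy sentinel.
    """
    positions = _check_conformation(positions, params)
    if isinstance(move, DisplacementMove):
        after = apply_move(positions, move)
        i = move.index
        old = _local_energy_displacement(positions, i, params)
        new = _local_energy_displacement(after, i, params)
        return new - old
    if isinstance(move, PivotMove):
        after = apply_move(positions, move)
        i = move.index
        old = _pivot_local_energy(positions, i, params)
        new = _pivot_local_energy(after, i, params)
        return new - old
    raise TypeError(f"unknown move type: {type(move)!r}")


def _local_energy_displacement(positions: np.ndarray, i: int, params: ModelParameters) -> float:
    n = len(positions)
    e = 0.0
    # non-bonded pairs involving i (exclude chain neighbours)
    others = [j for j in range(n) if abs(j - i) >= 2]
    if others:
        r = np.linalg.norm(positions[others] - positions[i], axis=1)
        e += float(np.sum(nonbonded_potential(r, params)))
    # bonds containing i
    for j in (i - 1, i):
        if 0 <= j < n - 1:
            b = bond_potential(float(np.linalg.norm(positions[j + 1] - positions[j])), params)
            if not np.isfinite(b):
                return INFINITE_ENERGY
            e += b
    # bend angles at vertices i-1, i, i+1
    if params.kappa != 0.0:
        for v in (i - 1, i, i + 1):
            if 1 <= v <= n - 2:
                e += _angle_energy(positions, v, params)
    return e


def _angle_energy(positions: np.ndarray, v: int, params: ModelParameters) -> float:
    a = positions[v] - positions[v - 1]
    b = positions[v + 1] - positions[v]
    c = np.dot(a, b) / (np.linalg.norm(a) * np.linalg.norm(b))
    theta = np.arccos(np.clip(c, -1.0, 1.0))
    return float(bending_potential(theta, params))


def _pivot_local_energy(positions: np.ndarray, i: int, params: ModelParameters) -> float:
    n = len(positions)
    # non-bonded pairs with one end in the head (<= i) and one in the tail
    head = positions[: i + 1]
    tail = positions[i + 1 :]
    d = head[:, None, :] - tail[None, :, :]
    r = np.sqrt(np.einsum("abk,abk->ab", d, d))
    a_idx = np.arange(i + 1)[:, None]
    b_idx = np.arange(i + 1, n)[None, :]
    mask = (b_idx - a_idx) >= 2
    e = float(np.sum(nonbonded_potential(r[mask], params))) if mask.any() else 0.0
    if params.kappa != 0.0 and 1 <= i <= n - 2:
        e += _angle_energy(positions, i, params)
    return e


def straight_chain(params: ModelParameters) -> np.ndarray:
    """Straight chain along x at bond length r0 — always FENE-valid."""
    pos = np.zeros((params.n_monomers, 3))
    pos[:, 0] = np.arange(params.n_monomers) * params.r0
    return pos
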
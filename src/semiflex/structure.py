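"""Geometric characterization of chain conformations.

Squared radius of gyration, the pair distribution over monomer-monomer
distances, contact maps of non-bonded near-neighbour pairs, and simple
secondary-structure streak statistics (hairpin-like anti-diagonal and
helix-like diagonal runs of contacts).  Monomer indices in all reported
pairs are 1-based, matching the chain labels 1..N used in figures.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "PairDistribution",
    "ContactMap",
    "radius_of_gyration_sq",
    "pair_distribution",
    "contact_map",
    "secondary_structure_streaks",
    "export_xyz",
    "export_pdb",
]


def radius_of_gyration_sq(positions: np.ndarray) -> float:
    """Mean squared distance of monomers from their centroid (uniform masses)."""
    pos = np.asarray(positions, dtype=float)
    d = pos - pos.mean(axis=0)
    return float(np.mean(np.einsum("ij,ij->i", d, d)))


@dataclass
class PairDistribution:
    """Binned monomer-pair distances.

    The r > 0 axis is partitioned into disjoint cells of width 2 r_t
    centred on r_t * (2m + 1); every unordered pair (bonded pairs
    included) falls in exactly one cell, so the counts sum to
    N (N - 1) / 2.
    """

    r_t: float
    bin_centers: np.ndarray
    counts: np.ndarray

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def pair_distribution(positions: np.ndarray, r_t: float = 0.01) -> PairDistribution:
    """Histogram all pairwise distances with binning half-width r_t."""
    pos = np.asarray(positions, dtype=float)
    n = len(pos)
    iu, ju = np.triu_indices(n, k=1)
    r = np.linalg.norm(pos[iu] - pos[ju], axis=1)
    m = np.floor(r / (2.0 * r_t)).astype(int)
    n_bins = int(m.max()) + 1 if len(m) else 1
    counts = np.bincount(m, minlength=n_bins)
    centers = r_t * (2 * np.arange(n_bins) + 1)
    return PairDistribution(r_t=r_t, bin_centers=centers, counts=counts)


@dataclass
class ContactMap:
    """Non-bonded contacts: unordered 1-based pairs (i, j), j > i + 1,
    with distance strictly below the cutoff."""

    pairs: frozenset
    n_monomers: int
    cutoff: float = 1.2

    def __len__(self) -> int:
        return len(self.pairs)

    def as_matrix(self) -> np.ndarray:
        m = np.zeros((self.n_monomers, self.n_monomers), dtype=bool)
        for i, j in self.pairs:
            m[i - 1, j - 1] = m[j - 1, i - 1] = True
        return m


def contact_map(positions: np.ndarray, cutoff: float = 1.2) -> ContactMap:
    """Pairs with ``j > i + 1`` and ``r_ij < cutoff`` (strict; bonded
    neighbours never appear)."""
    pos = np.asarray(positions, dtype=float)
    n = len(pos)
    iu, ju = np.triu_indices(n, k=2)
    r = np.linalg.norm(pos[iu] - pos[ju], axis=1)
    sel = r < cutoff
    pairs = frozenset((int(i) + 1, int(j) + 1) for i, j in zip(iu[sel], ju[sel]))
    return ContactMap(pairs=pairs, n_monomers=n, cutoff=cutoff)


@dataclass(frozen=True)
class Streak:
    """A maximal run of contacts along one (anti-)diagonal of the map."""

    kind: str      # "antidiagonal" (i + j const, hairpin) | "diagonal" (j - i const, helix)
    level: int     # the constant i + j or j - i
    start: tuple   # first (i, j) pair of the run
    length: int


def secondary_structure_streaks(cmap: ContactMap, min_length: int = 2) -> list:
    """Maximal anti-diagonal (i+j constant) and diagonal (j-i constant)
    runs of contacts with length >= min_length.

    Anti-diagonal streaks mark hairpin-like pairings of two strands;
    diagonal streaks mark helix-like alignments.
    """
    pairs = set(cmap.pairs)
    streaks = []
    for kind, level_of, step in (
        ("antidiagonal", lambda i, j: i + j, (1, -1)),
        ("diagonal", lambda i, j: j - i, (1, 1)),
    ):
        seen = set()
        for i, j in sorted(pairs):
            if (i, j) in seen:
                continue
            # only start at the head of a run
            if (i - step[0], j - step[1]) in pairs:
                continue
            run = []
            a, b = i, j
            while (a, b) in pairs:
                run.append((a, b))
                seen.add((a, b))
                a, b = a + step[0], b + step[1]
            if len(run) >= min_length:
                streaks.append(
                    Streak(kind=kind, level=level_of(i, j), start=run[0], length=len(run))
                )
    return streaks


def export_xyz(path, positions: np.ndarray, comment: str = "") -> None:
    """Write one XYZ frame (element tag C) for visualization."""
    pos = np.asarray(positions, dtype=float)
    with open(path, "w") as fh:
        fh.write(f"{len(pos)}\n{comment}\n")
        for x, y, z in pos:
            fh.write(f"C {x:.8f} {y:.8f} {z:.8f}\n")


def export_pdb(path, positions: np.ndarray, comment: str = "") -> None:
    """Minimal PDB: HETATM records plus CONECT entries for chain bonds."""
    pos = np.asarray(positions, dtype=float)
    with open(path, "w") as fh:
        if comment:
            fh.write(f"REMARK   1 {comment}\n")
        for i, (x, y, z) in enumerate(pos, start=1):
            fh.write(
                f"HETATM{i:5d}  C   MON A{i:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C\n"
            )
        for i in range(1, len(pos)):
            fh.write(f"CONECT{i:5d}{i + 1:5d}\n")
        fh.write("END\n")
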
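"""Synthetic densities of states and exact-sampling test harnesses.

These generators make every analysis stage (WHAM, entropy smoothing,
transition classification, canonical reweighting) testable without
running long simulations:

* a two-Gaussian density of states has a convex intruder in S(E) — the
  textbook signature of a first-order transition — with a transition
  inverse temperature computable independently from the Maxwell
  double-tangent construction;
* a log-concave family (S strictly concave with monotone derivatives)
  carries no transition at all;
* exact categorical sampling from g(E) exp(-E / kB T) produces
  per-temperature histograms whose combination WHAM must invert.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.special import logsumexp

from .sampling import EnergyHistogramSet, TemperatureLadder
from .wham import DensityOfStatesEstimate

__all__ = [
    "SyntheticDosSpec",
    "generate_synthetic_dos",
    "sample_histograms_from_dos",
    "double_tangent_beta",
]


@dataclass(frozen=True)
class SyntheticDosSpec:
    """Recipe for a deterministic synthetic ln g table.

    families
    --------
    ``single-gaussian``
        ln g = -(E - centers[0])^2 / (2 widths[0]^2); beta is linear,
        gamma constant negative, no transitions.
    ``two-gaussian``
        g = sum of two Gaussian bumps (centers, widths, weights);
        well-separated bumps create a convex intruder (first-order
        testbed).
    ``log-concave``
        ln g = weights[0] * ln(E - centers[0]); strictly concave with
        monotone beta, gamma, delta — no transitions.
    ``custom``
        ``table`` supplies ln g directly on the grid.
    """

    family: str
    e_min: float
    e_max: float
    n_bins: int
    centers: tuple = ()
    widths: tuple = ()
    weights: tuple = ()
    table: Optional[tuple] = None

    def grid(self) -> np.ndarray:
        edges = np.linspace(self.e_min, self.e_max, self.n_bins + 1)
        return 0.5 * (edges[:-1] + edges[1:])


def generate_synthetic_dos(spec: SyntheticDosSpec) -> DensityOfStatesEstimate:
    """Deterministic ln g table for the requested family."""
    e = spec.grid()
    if spec.family == "single-gaussian":
        if len(spec.centers) != 1 or len(spec.widths) != 1:
            raise ValueError("single-gaussian needs one center and one width")
        ln_g = -((e - spec.centers[0]) ** 2) / (2.0 * spec.widths[0] ** 2)
    elif spec.family == "two-gaussian":
        if not (len(spec.centers) == len(spec.widths) == 2):
            raise ValueError("two-gaussian needs two centers and two widths")
        w = spec.weights if len(spec.weights) == 2 else (1.0, 1.0)
        if any(x <= 0 for x in w):
            raise ValueError("weights must be positive")
        terms = np.stack(
            [
                np.log(w[i]) - (e - spec.centers[i]) ** 2 / (2.0 * spec.widths[i] ** 2)
                for i in range(2)
            ]
        )
        ln_g = logsumexp(terms, axis=0)
    elif spec.family == "log-concave":
        if len(spec.centers) != 1 or len(spec.weights) != 1:
            raise ValueError("log-concave needs one offset (centers) and one amplitude (weights)")
        off, c = spec.centers[0], spec.weights[0]
        if np.any(e <= off) or c <= 0:
            raise ValueError("offset must lie below the energy grid; amplitude positive")
        ln_g = c * np.log(e - off)
    elif spec.family == "custom":
        if spec.table is None or len(spec.table) != spec.n_bins:
            raise ValueError("custom family needs a table of length n_bins")
        ln_g = np.asarray(spec.table, dtype=float)
    else:
        raise ValueError(f"unknown family: {spec.family!r}")
    if not np.all(np.isfinite(ln_g)):
        raise ValueError("resulting ln g must be finite on its grid")
    return DensityOfStatesEstimate(
        energies=e, ln_g=ln_g, support=np.ones_like(e, dtype=bool)
    )


def sample_histograms_from_dos(
    dos: DensityOfStatesEstimate,
    ladder: TemperatureLadder,
    n_per_thread: int,
    seed: int = 0,
    kB: float = 1.0,
) -> EnergyHistogramSet:
    """Exact per-temperature histograms: multinomial draws from the
    categorical distribution p_k(E) proportional to g(E) exp(-E/kB T_k).

    This is the independent oracle for WHAM recovery tests — no Markov
    chain, no correlation, the sampling distribution is exact.
    """
    e = dos.energies
    sup = dos.support & np.isfinite(dos.ln_g)
    rng = np.random.default_rng(seed)
    counts = np.zeros((ladder.count, len(e)), dtype=np.int64)
    for k, T in enumerate(ladder.temperatures):
        if n_per_thread > 0:
            ln_p = dos.ln_g[sup] - e[sup] / (kB * T)
            p = np.exp(ln_p - logsumexp(ln_p))
            p = p / p.sum()  # guard rounding for multinomial
            counts[k, sup] = rng.multinomial(n_per_thread, p)
    width = e[1] - e[0]
    edges = np.concatenate([e - 0.5 * width, [e[-1] + 0.5 * width]])
    return EnergyHistogramSet(
        bin_edges=edges,
        counts=counts,
        temperatures=ladder.temperatures.copy(),
        dropped=np.zeros(ladder.count, dtype=np.int64),
    )


def double_tangent_beta(energies: np.ndarray, s: np.ndarray) -> float:
    """Maxwell double-tangent slope across the convex intruder of S(E).

    Builds the concave hull of the (E, S) samples; the hull segment that
    skips interior points bridges the intruder, and its slope is the
    first-order transition inverse temperature.  Independent of the
    Bézier smoothing route used by the analysis.
    """
    e = np.asarray(energies, dtype=float)
    s = np.asarray(s, dtype=float)
    # upper (concave) hull by monotone chain
    hull = []
    for i in range(len(e)):
        while len(hull) >= 2:
            (x1, y1), (x2, y2) = hull[-2], hull[-1]
            if (y2 - y1) * (e[i] - x2) >= (s[i] - y2) * (x2 - x1):
                break
            hull.pop()
        hull.append((e[i], s[i]))
    hx = np.array([p[0] for p in hull])
    # the bridging segment is the hull edge spanning the most samples
    spans = np.diff(np.searchsorted(e, hx))
    j = int(np.argmax(spans))
    if spans[j] <= 1:
        raise ValueError("entropy curve has no convex intruder")
    (xa, ya), (xb, yb) = hull[j], hull[j + 1]
    return (yb - ya) / (xb - xa)
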
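"""Multiple-histogram reweighting to a density of states.

Energy histograms measured at several temperatures are combined into a
single estimate of the density of states g(E) by iterating the
self-consistency pair

    g(E)  =  sum_k h(E; T_k)  /  sum_k M_k Z_k^{-1} exp(-E / kB T_k)
    Z_k   =  sum_E g(E) exp(-E / kB T_k)

to a fixed point.  All arithmetic is carried out in log space with
log-sum-exp; ln g is defined up to one additive constant and the gauge
is fixed by pinning ln Z_1 = 0.  Statistical errors come from
independent replicate runs, not from within-run propagation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.special import logsumexp

__all__ = [
    "DensityOfStatesEstimate",
    "WhamState",
    "wham_solve",
    "combine_runs",
    "histogram_support_window",
]


@dataclass
class DensityOfStatesEstimate:
    """ln g(E) on a uniform energy-bin grid, up to an additive constant.

    ``ln_g`` is finite exactly on the support mask (bins with nonzero
    total counts) and NaN elsewhere.  ``stderr`` is the per-bin standard
    error across independent runs, or None for a single run (absent, not
    zero).  ``replicates`` keeps the gauge-aligned per-run ln g arrays so
    downstream derivative curves can propagate replicate spread.
    """

    energies: np.ndarray            # bin centers, uniform grid
    ln_g: np.ndarray                # NaN off support
    support: np.ndarray             # bool mask
    stderr: Optional[np.ndarray] = None
    temperatures: Optional[np.ndarray] = None  # histogram temperatures, for range warnings
    replicates: Optional[list] = None
    overlap_ok: bool = True

    def __post_init__(self):
        if self.energies.shape != self.ln_g.shape:
            raise ValueError("energies and ln_g must have the same shape")

    @property
    def bin_width(self) -> float:
        return float(np.diff(self.energies[:2])[0]) if len(self.energies) > 1 else 1.0


@dataclass
class WhamState:
    """Convergence bookkeeping of the iterative solve (ln Z_1 pinned to 0)."""

    ln_z: np.ndarray
    n_iter: int
    max_delta: float
    converged: bool


def _check_overlap(counts: np.ndarray) -> bool:
    """Adjacent-temperature histograms must share support bins."""
    for k in range(counts.shape[0] - 1):
        if not np.any((counts[k] > 0) & (counts[k + 1] > 0)):
            return False
    return True


def wham_solve(
    histograms,
    ladder=None,
    tol: float = 1e-8,
    max_iter: int = 100_000,
    kB: float = 1.0,
    min_count: int = 1,
):
    """Iterate the reweighting equations to a density-of-states estimate.

    Parameters
    ----------
    histograms:
        An :class:`~semiflex.sampling.EnergyHistogramSet` (or any object
        with ``bin_centers``, ``counts`` (K, B) and ``temperatures``).
    ladder:
        Optional temperature override (TemperatureLadder or array).
    tol:
        Stop when ``max_k |Delta ln Z_k| < tol``.
    min_count:
        Bins with fewer than this many total counts are dropped from the
        support (default 1 keeps every nonzero bin).  Raising it trims
        the poorly-sampled support fringes whose ln g estimates are
        dominated by shot noise, at the cost of a narrower energy range.

    Returns
    -------
    (DensityOfStatesEstimate, WhamState)
    """
    energies = np.asarray(histograms.bin_centers, dtype=float)
    counts = np.asarray(histograms.counts, dtype=float)
    if counts.ndim == 1:
        counts = counts[None, :]
    if ladder is not None:
        temps = np.asarray(getattr(ladder, "temperatures", ladder), dtype=float)
    else:
        temps = np.asarray(histograms.temperatures, dtype=float)
    if counts.shape[0] != len(temps):
        raise ValueError("one histogram row per temperature required")
    if counts.sum() == 0:
        raise ValueError("all histograms are empty")

    overlap_ok = _check_overlap(counts)
    if not overlap_ok:
        warnings.warn(
            "adjacent histograms do not overlap; the density-of-states gauge "
            "is not connected across the gap and results are flagged"
        )

    support = counts.sum(axis=0) >= max(min_count, 1)
    if not np.any(support):
        raise ValueError("no bins satisfy the min_count support threshold")
    counts = counts * support[None, :]  # measurements in dropped bins do not enter
    e_sup = energies[support]
    betas = 1.0 / (kB * temps)

    with np.errstate(divide="ignore"):
        ln_h_tot = np.log(counts.sum(axis=0)[support])
        ln_m = np.log(np.maximum(counts.sum(axis=1), 1e-300))

    # constant part of the denominator: ln M_k - beta_k E  (K, B_sup)
    base = ln_m[:, None] - betas[:, None] * e_sup[None, :]
    neg_be = -betas[:, None] * e_sup[None, :]

    ln_z = np.zeros(len(temps))
    max_delta = np.inf
    it = 0
    for it in range(1, max_iter + 1):
        ln_den = logsumexp(base - ln_z[:, None], axis=0)
        ln_g_sup = ln_h_tot - ln_den
        ln_z_new = logsumexp(ln_g_sup[None, :] + neg_be, axis=1)
        ln_z_new -= ln_z_new[0]  # gauge: pin ln Z_1 = 0
        max_delta = float(np.max(np.abs(ln_z_new - ln_z)))
        ln_z = ln_z_new
        if max_delta < tol:
            break

    ln_den = logsumexp(base - ln_z[:, None], axis=0)
    ln_g_sup = ln_h_tot - ln_den

    ln_g = np.full_like(energies, np.nan)
    ln_g[support] = ln_g_sup
    dos = DensityOfStatesEstimate(
        energies=energies,
        ln_g=ln_g,
        support=support,
        temperatures=temps.copy(),
        overlap_ok=overlap_ok,
    )
    state = WhamState(ln_z=ln_z, n_iter=it, max_delta=max_delta, converged=max_delta < tol)
    return dos, state


def histogram_support_window(histograms, q_lo: float = 0.005, q_hi: float = 0.995):
    """Energy window where the histograms genuinely constrain ln g.

    The density of states is well determined only between the energies
    typically visited by the coldest and the hottest simulation thread;
    outside, lone tail counts dominate and ln g is shot-noise.  Returns
    ``(E_lo, E_hi)``: the ``q_lo`` quantile of the coldest thread's
    energy histogram and the ``q_hi`` quantile of the hottest thread's.
    """
    centers = np.asarray(histograms.bin_centers)
    counts = np.asarray(histograms.counts)
    order = np.argsort(np.asarray(histograms.temperatures))

    def _quantile(c, q):
        cum = np.cumsum(c)
        if cum[-1] == 0:
            raise ValueError("empty histogram; cannot locate support window")
        return float(centers[np.searchsorted(cum, q * cum[-1])])

    return _quantile(counts[order[0]], q_lo), _quantile(counts[order[-1]], q_hi)


def _align_constant(ref: np.ndarray, other: np.ndarray) -> float:
    """Least-squares additive constant putting `other` in `ref`'s gauge."""
    both = np.isfinite(ref) & np.isfinite(other)
    if not np.any(both):
        raise ValueError("estimates share no support; cannot align gauges")
    return float(np.mean(ref[both] - other[both]))


def combine_runs(estimates: Sequence[DensityOfStatesEstimate]) -> DensityOfStatesEstimate:
    """Average several independent density-of-states estimates.

    Each estimate is first aligned to the gauge of the first one by a
    least-squares additive constant on the shared support; the result
    carries the per-bin mean ln g and the standard error of the mean.
    With fewer than two runs the error is reported as absent (None).
    """
    if len(estimates) == 0:
        raise ValueError("no estimates to combine")
    ref = estimates[0]
    for est in estimates[1:]:
        if est.energies.shape != ref.energies.shape or not np.allclose(
            est.energies, ref.energies
        ):
            raise ValueError("estimates must share one energy-bin grid")

    aligned = [ref.ln_g.astype(float)]
    for est in estimates[1:]:
        aligned.append(est.ln_g + _align_constant(ref.ln_g, est.ln_g))
    stack = np.stack(aligned)  # (R, B)

    n_per_bin = np.isfinite(stack).sum(axis=0)
    support = n_per_bin > 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(stack, axis=0)
        sd = np.nanstd(stack, axis=0, ddof=1)
    mean[~support] = np.nan

    if len(estimates) >= 2:
        stderr = np.where(n_per_bin >= 2, sd / np.sqrt(np.maximum(n_per_bin, 1)), np.nan)
        stderr[~support] = np.nan
    else:
        stderr = None

    temps = ref.temperatures.copy() if ref.temperatures is not None else None
    return DensityOfStatesEstimate(
        energies=ref.energies.copy(),
        ln_g=mean,
        support=support,
        stderr=stderr,
        temperatures=temps,
        replicates=[a.copy() for a in stack],
        overlap_ok=all(e.overlap_ok for e in estimates),
    )
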
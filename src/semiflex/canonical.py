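"""Canonical-ensemble observables from the density of states.

The mean energy and heat capacity follow from reweighting the density
of states to a heat-bath temperature T_can; the temperature derivative
of an arbitrary structural observable O (here the squared radius of
gyration) is estimated from per-thread time series via the covariance
identity d<O>/dT = (<O E> - <O><E>) / kB T^2, since O is not a function
of energy alone and therefore cannot come from the energy-only density
of states.
"""

from __future__ import annotations

import warnings
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .wham import DensityOfStatesEstimate

__all__ = [
    "canonical_mean_energy",
    "heat_capacity",
    "canonical_curve",
    "observable_temperature_derivative",
    "structural_fluctuation_curve",
]


def _weights(dos: DensityOfStatesEstimate, T: float, kB: float):
    if T <= 0:
        raise ValueError("temperature must be positive")
    sup = dos.support & np.isfinite(dos.ln_g)
    e = dos.energies[sup]
    ln_w = dos.ln_g[sup] - e / (kB * T)
    ln_w -= logsumexp(ln_w)
    return e, np.exp(ln_w)


def _warn_extrapolation(dos: DensityOfStatesEstimate, T: float):
    if dos.temperatures is not None:
        t_lo, t_hi = float(np.min(dos.temperatures)), float(np.max(dos.temperatures))
        if T < t_lo or T > t_hi:
            warnings.warn(
                f"T = {T} lies outside the histogram-supported range "
                f"[{t_lo}, {t_hi}]; value is an extrapolation"
            )


def canonical_mean_energy(dos: DensityOfStatesEstimate, T: float, kB: float = 1.0) -> float:
    """<E> at heat-bath temperature T (log-sum-exp, gauge-invariant)."""
    _warn_extrapolation(dos, T)
    e, w = _weights(dos, T, kB)
    return float(np.sum(e * w))


def heat_capacity(dos: DensityOfStatesEstimate, T: float, kB: float = 1.0) -> float:
    """C_V(T) = (<E^2> - <E>^2) / kB T^2 = d<E>/dT_can (never negative)."""
    _warn_extrapolation(dos, T)
    e, w = _weights(dos, T, kB)
    mean = np.sum(e * w)
    var = np.sum((e - mean) ** 2 * w)
    return float(var / (kB * T * T))


def canonical_curve(
    dos: DensityOfStatesEstimate,
    temperatures: Sequence[float],
    kB: float = 1.0,
) -> pd.DataFrame:
    """<E>(T) and C_V(T) over a temperature grid, with replicate errors
    when the density of states carries independent-run replicates."""
    temps = np.asarray(temperatures, dtype=float)
    rows = {
        "T_can": temps,
        "beta_can": 1.0 / (kB * temps),
        "mean_E": [canonical_mean_energy(dos, t, kB) for t in temps],
        "C_V": [heat_capacity(dos, t, kB) for t in temps],
    }
    if dos.replicates is not None and len(dos.replicates) >= 2:
        per_run_e, per_run_c = [], []
        for r in dos.replicates:
            rep = DensityOfStatesEstimate(
                energies=dos.energies, ln_g=r, support=np.isfinite(r),
                temperatures=dos.temperatures,
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                per_run_e.append([canonical_mean_energy(rep, t, kB) for t in temps])
                per_run_c.append([heat_capacity(rep, t, kB) for t in temps])
        nrun = len(per_run_e)
        rows["mean_E_err"] = np.std(per_run_e, axis=0, ddof=1) / np.sqrt(nrun)
        rows["C_V_err"] = np.std(per_run_c, axis=0, ddof=1) / np.sqrt(nrun)
    return pd.DataFrame(rows)


def observable_temperature_derivative(
    observable: np.ndarray,
    energies: np.ndarray,
    T: float,
    kB: float = 1.0,
    min_samples: int = 1000,
) -> float:
    """d<O>/dT_can from paired (O, E) samples of one thread at T.

    Uses the canonical fluctuation identity
    ``d<O>/dT = (<O E> - <O><E>) / kB T^2``; with O = E this reduces to
    the time-series estimate of the heat capacity.
    """
    obs = np.asarray(observable, dtype=float)
    e = np.asarray(energies, dtype=float)
    if obs.shape != e.shape:
        raise ValueError("observable and energy series must be paired")
    if len(obs) < min_samples:
        raise ValueError(
            f"need at least {min_samples} paired samples, got {len(obs)}"
        )
    if T <= 0:
        raise ValueError("temperature must be positive")
    cov = np.mean(obs * e) - np.mean(obs) * np.mean(e)
    return float(cov / (kB * T * T))


def structural_fluctuation_curve(
    histograms,
    kB: float = 1.0,
    min_samples: int = 1000,
) -> pd.DataFrame:
    """d<R_gyr^2>/dT_can at every ladder temperature from the recorded
    per-thread time series, plus the peak location as the structural
    transition signal (column order follows increasing beta_can)."""
    temps = np.asarray(histograms.temperatures, dtype=float)
    vals = []
    for k, T in enumerate(temps):
        vals.append(
            observable_temperature_derivative(
                histograms.rgyr_timeseries[k],
                histograms.energy_timeseries[k],
                T, kB=kB, min_samples=min_samples,
            )
        )
    df = pd.DataFrame(
        {"T_can": temps, "beta_can": 1.0 / (kB * temps), "dRg2_dT": vals}
    ).sort_values("beta_can", ignore_index=True)
    df.attrs["peak_beta_can"] = float(df["beta_can"][np.argmax(df["dRg2_dT"].values)])
    return df
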
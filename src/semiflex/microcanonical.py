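"""Generalized microcanonical inflection-point analysis.

The microcanonical entropy S(E) = kB ln g(E) and its first three energy
derivatives

    beta(E)  = dS/dE    (inverse microcanonical temperature)
    gamma(E) = dbeta/dE
    delta(E) = dgamma/dE

are estimated from a density-of-states table by smoothing with a single
global Bernstein-form Bézier curve (all data points act as control
points) and differentiating the curve analytically.  Phase transitions
appear as least-sensitive inflection points, operationalized as interior
extrema of prescribed sign in the next-higher derivative:

==========  ===========  ==============================================
order       dependence   signal
==========  ===========  ==============================================
1           independent  positive-valued local minimum of beta
2           independent  negative-valued local maximum of gamma
2           dependent    positive-valued local minimum of gamma
3           independent  positive-valued local minimum of delta
3           dependent    negative-valued local maximum of delta
==========  ===========  ==============================================

Dependent transitions are admitted only as higher-energy companions of
an independent transition of the next-lower order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from ._kernels import bezier_eval_derivs
from .wham import DensityOfStatesEstimate

__all__ = [
    "EntropyCurve",
    "SmoothedCurve",
    "DerivativeCurves",
    "TransitionRecord",
    "entropy_from_dos",
    "bezier_smooth",
    "derivative_curves",
    "find_transitions",
    "transition_table",
]


@dataclass
class EntropyCurve:
    """S(E) on the support of the density of states.

    ``e_min`` is the reference ground-state energy used for reduced
    energies ``Delta E = E - e_min`` in reports; it comes from the
    sampler's best conformation, not from the entropy support.
    """

    energies: np.ndarray
    s: np.ndarray
    errors: Optional[np.ndarray] = None
    e_min: Optional[float] = None
    replicates: Optional[list] = None  # per-run S arrays on the same energies

    def __post_init__(self):
        if np.any(np.diff(self.energies) <= 0):
            raise ValueError("entropy energies must be strictly increasing")
        if self.errors is not None and np.any(self.errors[np.isfinite(self.errors)] < 0):
            raise ValueError("entropy errors must be non-negative")


def entropy_from_dos(
    dos: DensityOfStatesEstimate,
    kB: float = 1.0,
    e_min: Optional[float] = None,
    window: Optional[tuple] = None,
) -> EntropyCurve:
    """Boltzmann entropy S(E) = kB ln g(E), restricted to the support.

    The additive gauge constant of ln g shifts S by a constant and is
    irrelevant for every derivative-based quantity downstream.
    ``window = (E_lo, E_hi)`` additionally restricts the curve to a
    trusted energy range (see
    :func:`semiflex.wham.histogram_support_window`).
    """
    sup = dos.support & np.isfinite(dos.ln_g)
    if window is not None:
        sup = sup & (dos.energies >= window[0]) & (dos.energies <= window[1])
    if not np.any(sup):
        raise ValueError("density of states has empty support")
    energies = dos.energies[sup]
    s = kB * dos.ln_g[sup]
    errors = kB * dos.stderr[sup] if dos.stderr is not None else None
    reps = None
    if dos.replicates is not None:
        reps = [kB * r[sup] for r in dos.replicates]
    return EntropyCurve(energies=energies, s=s, errors=errors, e_min=e_min, replicates=reps)


@dataclass
class SmoothedCurve:
    """A single global Bézier curve through (x, y) samples.

    All samples act as control points of one Bernstein-form curve of
    degree n - 1, evaluated by the de Casteljau recursion; the curve
    interpolates the endpoints and smooths everything in between.
    Derivatives with respect to x are obtained analytically through the
    parameter-to-x map (x itself is a Bézier curve of the same degree).
    """

    ctrl_x: np.ndarray
    ctrl_y: np.ndarray

    def __post_init__(self):
        if len(self.ctrl_x) < 4:
            raise ValueError("need at least 4 points for third derivatives")
        if np.any(np.diff(self.ctrl_x) <= 0):
            raise ValueError("x samples must be strictly increasing")

    def evaluate_param(self, ts: np.ndarray):
        """Curve (x, y) and t-derivatives at Bézier parameters ts."""
        x, x1, x2, x3 = bezier_eval_derivs(np.ascontiguousarray(self.ctrl_x, float), ts)
        y, y1, y2, y3 = bezier_eval_derivs(np.ascontiguousarray(self.ctrl_y, float), ts)
        return (x, x1, x2, x3), (y, y1, y2, y3)

    def t_for_x(self, x_grid: np.ndarray, n_dense: int = 4096) -> np.ndarray:
        """Invert the monotone parameter-to-x map by dense interpolation."""
        if self._x_is_affine():
            return (x_grid - self.ctrl_x[0]) / (self.ctrl_x[-1] - self.ctrl_x[0])
        t_dense = np.linspace(0.0, 1.0, n_dense)
        from ._kernels import bezier_eval

        x_dense = bezier_eval(np.ascontiguousarray(self.ctrl_x, float), t_dense)
        return np.interp(x_grid, x_dense, t_dense)

    def _x_is_affine(self) -> bool:
        dx = np.diff(self.ctrl_x)
        return np.allclose(dx, dx[0], rtol=1e-12, atol=1e-12)

    def evaluate(self, x_grid: np.ndarray):
        """y and its first three x-derivatives at the given x values.

        Chain rule through the parameter map t -> x(t):
            y'   = Y1/X1
            y''  = (Y2 X1 - Y1 X2) / X1^3
            y''' = [(Y3 X1 - Y1 X3) X1 - 3 X2 (Y2 X1 - Y1 X2)] / X1^5
        (obtained by repeatedly dividing d/dt by X1).
        """
        ts = self.t_for_x(np.asarray(x_grid, dtype=float))
        (x, x1, x2, x3), (y, y1, y2, y3) = self.evaluate_param(ts)
        d1 = y1 / x1
        u_t = (y2 * x1 - y1 * x2) / x1**2
        d2 = u_t / x1
        u_tt = ((y3 * x1 - y1 * x3) * x1 - 2.0 * x2 * (y2 * x1 - y1 * x2)) / x1**3
        d3 = (u_tt * x1 - u_t * x2) / x1**3
        return y, d1, d2, d3


def bezier_smooth(
    x: np.ndarray, y: np.ndarray, decimate: int = 1
) -> SmoothedCurve:
    """Build the global Bézier smoother from curve samples.

    ``decimate`` keeps every m-th sample (endpoints always included) as
    a control point — useful to stiffen the smoother on noisy data; the
    default uses all samples, as in the original Bernstein construction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if decimate > 1:
        idx = np.arange(0, len(x), decimate)
        if idx[-1] != len(x) - 1:
            idx = np.append(idx, len(x) - 1)
        x, y = x[idx], y[idx]
    return SmoothedCurve(ctrl_x=x, ctrl_y=y)


@dataclass
class DerivativeCurves:
    """S, beta, gamma, delta on a uniform energy grid, with optional
    replicate-propagated standard errors."""

    energies: np.ndarray
    s: np.ndarray
    beta: np.ndarray
    gamma: np.ndarray
    delta: np.ndarray
    s_err: Optional[np.ndarray] = None
    beta_err: Optional[np.ndarray] = None
    gamma_err: Optional[np.ndarray] = None
    delta_err: Optional[np.ndarray] = None
    e_min: Optional[float] = None

    def to_frame(self) -> pd.DataFrame:
        data = {
            "E": self.energies, "S": self.s, "beta": self.beta,
            "gamma": self.gamma, "delta": self.delta,
        }
        for name in ("s_err", "beta_err", "gamma_err", "delta_err"):
            v = getattr(self, name)
            if v is not None:
                data[name] = v
        return pd.DataFrame(data)


def derivative_curves(
    entropy: EntropyCurve,
    n_grid: int = 1000,
    decimate: int = 1,
) -> DerivativeCurves:
    """Smooth S(E) and differentiate three times analytically.

    When the entropy carries replicate curves (independent runs), the
    whole smoothing + differentiation is repeated per run and the
    cross-run spread becomes the standard error of each curve.
    """
    curve = bezier_smooth(entropy.energies, entropy.s, decimate=decimate)
    e_grid = np.linspace(entropy.energies[0], entropy.energies[-1], n_grid)
    s, beta, gamma, delta = curve.evaluate(e_grid)

    errs = {"s_err": None, "beta_err": None, "gamma_err": None, "delta_err": None}
    reps = entropy.replicates
    if reps is not None and len(reps) >= 2:
        rep_curves = {"s": [], "beta": [], "gamma": [], "delta": []}
        for r in reps:
            fin = np.isfinite(r)
            if fin.sum() < 4:
                continue
            c = bezier_smooth(entropy.energies[fin], r[fin], decimate=decimate)
            lo, hi = entropy.energies[fin][0], entropy.energies[fin][-1]
            inside = (e_grid >= lo) & (e_grid <= hi)
            vals = [np.full(n_grid, np.nan) for _ in range(4)]
            out = c.evaluate(e_grid[inside])
            for buf, o in zip(vals, out):
                buf[inside] = o
            for key, buf in zip(("s", "beta", "gamma", "delta"), vals):
                rep_curves[key].append(buf)
        n_used = len(rep_curves["s"])
        if n_used >= 2:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                for key in rep_curves:
                    stack = np.stack(rep_curves[key])
                    n_fin = np.isfinite(stack).sum(axis=0)
                    se = np.nanstd(stack, axis=0, ddof=1) / np.sqrt(np.maximum(n_fin, 1))
                    se[n_fin < 2] = np.nan
                    errs[key + "_err"] = se
    return DerivativeCurves(
        energies=e_grid, s=s, beta=beta, gamma=gamma, delta=delta,
        e_min=entropy.e_min, **errs,
    )


@dataclass(frozen=True)
class TransitionRecord:
    """One row of the transition table."""

    e_tr: float
    delta_e: float          # E_tr - E_min(kappa); NaN when E_min unknown
    beta_tr: float
    order: int
    dependence: str         # "independent" | "dependent"
    signal_strength: float  # extremal value of the classifying derivative
    significance: float     # |signal| / propagated error (inf if error absent)

    @property
    def noisy(self) -> bool:
        return self.significance < 2.0


def _local_extrema(
    y: np.ndarray, lo: int, hi: int, kind: str, rel_prominence: float = 1e-4
) -> list:
    """Indices of interior local extrema of y within [lo, hi).

    An extremum only counts if its prominence exceeds ``rel_prominence``
    times the curve's dynamic range in the window — numerically flat
    stretches of high-degree Bézier curves otherwise sprout machine-
    noise extrema.
    """
    from scipy.signal import find_peaks

    seg = y[lo:hi]
    if len(seg) < 3:
        return []
    span = float(np.nanmax(seg) - np.nanmin(seg))
    if span == 0.0 or not np.isfinite(span):
        return []
    # two-part prominence floor: a fraction of the window's dynamic range,
    # and a multiple of the grid-to-grid roughness so that curves that are
    # constant up to float rounding (span itself is pure noise) yield no
    # extrema at all
    # (the second difference is ~ span/G^2 for smooth curves but ~ the
    # rounding noise itself for flat ones, so it separates the two)
    noise = float(np.nanmedian(np.abs(np.diff(seg, n=2))))
    floor = max(rel_prominence * span, 50.0 * noise)
    sign = -1.0 if kind == "min" else 1.0
    peaks, _ = find_peaks(sign * seg, prominence=floor)
    return [int(p) + lo for p in peaks]


def find_transitions(
    curves: DerivativeCurves,
    entropy: Optional[EntropyCurve] = None,
    max_order: int = 3,
    margin: float = 0.02,
    e_min: Optional[float] = None,
    beta_range: Optional[tuple] = None,
) -> list:
    """Detect and classify transitions from the derivative curves.

    A configurable fraction of the grid (default 2%) is excluded at each
    end of the support to avoid endpoint artifacts of the global Bézier
    smoother.  Records with significance below 2 are retained but marked
    noisy via :attr:`TransitionRecord.noisy`.  ``beta_range = (lo, hi)``
    drops records whose beta_tr falls outside the inverse-temperature
    window actually simulated (outside it the entropy slope is an
    extrapolation).  Returned sorted by E_tr; an empty list is a valid
    result.
    """
    n = len(curves.energies)
    lo = int(np.ceil(margin * n))
    hi = n - lo
    if e_min is None:
        e_min = curves.e_min
        if e_min is None and entropy is not None:
            e_min = entropy.e_min

    def _sig(err_arr, i, value):
        if err_arr is None or not np.isfinite(err_arr[i]) or err_arr[i] == 0:
            return np.inf
        return abs(value) / err_arr[i]

    def _record(i, order, dependence, value, err_arr):
        e_tr = float(curves.energies[i])
        return TransitionRecord(
            e_tr=e_tr,
            delta_e=float(e_tr - e_min) if e_min is not None else np.nan,
            beta_tr=float(curves.beta[i]),
            order=order,
            dependence=dependence,
            signal_strength=float(value),
            significance=float(_sig(err_arr, i, value)),
        )

    records: list = []
    # order 1 (independent): positive-valued local minimum of beta
    for i in _local_extrema(curves.beta, lo, hi, "min"):
        if curves.beta[i] > 0:
            records.append(_record(i, 1, "independent", curves.beta[i], curves.beta_err))

    if max_order >= 2:
        for i in _local_extrema(curves.gamma, lo, hi, "max"):
            if curves.gamma[i] < 0:
                records.append(_record(i, 2, "independent", curves.gamma[i], curves.gamma_err))
        # dependent order 2: positive minimum of gamma, admissible only as a
        # higher-energy companion of an order-1 independent transition
        order1_es = [r.e_tr for r in records if r.order == 1]
        for i in _local_extrema(curves.gamma, lo, hi, "min"):
            if curves.gamma[i] > 0 and any(e < curves.energies[i] for e in order1_es):
                records.append(_record(i, 2, "dependent", curves.gamma[i], curves.gamma_err))

    if max_order >= 3:
        for i in _local_extrema(curves.delta, lo, hi, "min"):
            if curves.delta[i] > 0:
                records.append(_record(i, 3, "independent", curves.delta[i], curves.delta_err))
        order2_es = [r.e_tr for r in records if r.order == 2 and r.dependence == "independent"]
        for i in _local_extrema(curves.delta, lo, hi, "max"):
            if curves.delta[i] < 0 and any(e < curves.energies[i] for e in order2_es):
                records.append(_record(i, 3, "dependent", curves.delta[i], curves.delta_err))

    if beta_range is not None:
        records = [r for r in records if beta_range[0] <= r.beta_tr <= beta_range[1]]
    records.sort(key=lambda r: r.e_tr)
    return records


def transition_table(
    records: Sequence[TransitionRecord],
    kappa: Optional[float] = None,
    e_min: Optional[float] = None,
) -> pd.DataFrame:
    """Tabulate transition records (one row per transition).

    ``e_min`` recomputes the reduced energy column from the supplied
    putative ground-state energy; otherwise each record's stored value
    is used.
    """
    rows = []
    for r in records:
        de = r.e_tr - e_min if e_min is not None else r.delta_e
        rows.append(
            {
                "kappa": kappa,
                "E_tr": r.e_tr,
                "Delta_E": de,
                "beta_tr": r.beta_tr,
                "order": r.order,
                "dependence": r.dependence,
                "significance": r.significance,
            }
        )
    cols = ["kappa", "E_tr", "Delta_E", "beta_tr", "order", "dependence", "significance"]
    return pd.DataFrame(rows, columns=cols)
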
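"""Persistence: HDF5 run containers and plain-text tabular exports.

One parallel-tempering run is stored in a single hierarchical file:

    /ladder                     temperatures
    /histograms/bin_edges       shared energy grid
    /histograms/counts          (K, B) int64
    /timeseries/<k>/energy      per-thread series (optional)
    /timeseries/<k>/rgyr2
    /minimum/conformation       best-ever conformation
    /meta                       config echo (JSON), seeds, package version

The density of states travels as a four-column text table
(E_bin_center, ln_g, stderr, support_flag) readable by numpy.
"""

from __future__ import annotations

import json
from typing import Optional

import h5py
import numpy as np

from . import __version__
from .sampling import EnergyHistogramSet, ParallelTemperingResult
from .wham import DensityOfStatesEstimate

__all__ = [
    "save_run",
    "load_histograms",
    "save_dos_table",
    "load_dos_table",
    "export_histograms_text",
]


def save_run(path, result: ParallelTemperingResult, config_echo: Optional[dict] = None) -> None:
    """Persist a parallel-tempering run to one structured container."""
    h = result.histograms
    with h5py.File(path, "w") as f:
        f.create_dataset("ladder", data=result.ladder.temperatures)
        g = f.create_group("histograms")
        g.create_dataset("bin_edges", data=h.bin_edges)
        g.create_dataset("counts", data=h.counts)
        g.create_dataset("dropped", data=h.dropped)
        ts = f.create_group("timeseries")
        ts.attrs["stride"] = h.timeseries_stride
        for k, (e_s, r_s) in enumerate(zip(h.energy_timeseries, h.rgyr_timeseries)):
            gk = ts.create_group(str(k))
            gk.create_dataset("energy", data=e_s)
            gk.create_dataset("rgyr2", data=r_s)
        gm = f.create_group("minimum")
        gm.create_dataset("conformation", data=result.best_positions)
        gm.attrs["energy"] = result.best_energy
        meta = f.create_group("meta")
        meta.attrs["seed"] = result.seed
        meta.attrs["version"] = __version__
        meta.attrs["kappa"] = result.params.kappa
        meta.attrs["n_monomers"] = result.params.n_monomers
        meta.attrs["step_sizes"] = result.step_sizes
        meta.attrs["acceptance_displacement"] = result.acceptance_displacement
        meta.attrs["acceptance_exchange"] = result.acceptance_exchange
        if config_echo is not None:
            meta.attrs["config"] = json.dumps(config_echo)


def load_histograms(path):
    """Load (EnergyHistogramSet, meta dict) from a run container."""
    with h5py.File(path, "r") as f:
        temps = f["ladder"][...]
        edges = f["histograms/bin_edges"][...]
        counts = f["histograms/counts"][...]
        dropped = f["histograms/dropped"][...]
        stride = int(f["timeseries"].attrs.get("stride", 1))
        e_ts, r_ts = [], []
        for k in range(len(temps)):
            key = f"timeseries/{k}"
            if key in f:
                e_ts.append(f[key + "/energy"][...])
                r_ts.append(f[key + "/rgyr2"][...])
            else:
                e_ts.append(np.empty(0))
                r_ts.append(np.empty(0))
        meta = dict(f["meta"].attrs)
        meta["min_energy"] = float(f["minimum"].attrs["energy"])
        meta["min_conformation"] = f["minimum/conformation"][...]
    hist = EnergyHistogramSet(
        bin_edges=edges, counts=counts, temperatures=temps,
        energy_timeseries=e_ts, rgyr_timeseries=r_ts,
        timeseries_stride=stride, dropped=dropped,
    )
    return hist, meta


def save_dos_table(path, dos: DensityOfStatesEstimate) -> None:
    """Write the density of states as a plain-text table."""
    err = dos.stderr if dos.stderr is not None else np.full_like(dos.energies, np.nan)
    data = np.column_stack([dos.energies, dos.ln_g, err, dos.support.astype(float)])
    np.savetxt(
        path, data,
        header="E_bin_center ln_g stderr support_flag",
        fmt=["%.8g", "%.10g", "%.6g", "%d"],
    )


def load_dos_table(path) -> DensityOfStatesEstimate:
    data = np.loadtxt(path)
    if data.ndim == 1:
        data = data[None, :]
    stderr = data[:, 2]
    if not np.any(np.isfinite(stderr)):
        stderr = None
    return DensityOfStatesEstimate(
        energies=data[:, 0], ln_g=data[:, 1],
        support=data[:, 3] > 0.5, stderr=stderr,
    )


def export_histograms_text(path, histograms: EnergyHistogramSet) -> None:
    """Tabular histogram export: first column bin center, then one
    count column per temperature (temperatures in the header)."""
    header = "E_bin_center " + " ".join(f"T={t:.6g}" for t in histograms.temperatures)
    data = np.column_stack([histograms.bin_centers, histograms.counts.T])
    np.savetxt(path, data, header=header, fmt="%.8g")
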
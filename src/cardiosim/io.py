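"""Trace and biomarker I/O: CSV and HDF5 with config/provenance metadata."""

from __future__ import annotations

import json

import h5py
import numpy as np
import pandas as pd

from . import __version__
from .ord import Trace
from .strand import StrandConfig, StrandTrace

__all__ = ["trace_to_csv", "trace_from_csv", "strand_to_hdf5",
           "strand_from_hdf5", "ecg_to_csv"]


def trace_to_csv(trace: Trace, path) -> None:
    cols = {"time_ms": trace.t, "Vm_mV": trace.vm}
    if trace.currents:
        cols.update(trace.currents)
    pd.DataFrame(cols).to_csv(path, index=False)


def trace_from_csv(path) -> Trace:
    df = pd.read_csv(path)
    return Trace(t=df["time_ms"].to_numpy(), vm=df["Vm_mV"].to_numpy())


def _config_attrs(cfg: StrandConfig) -> dict:
    return {
        "n_nodes": cfg.n_nodes, "dx_mm": cfg.dx, "D_mm2_ms": cfg.D,
        "bcl_ms": cfg.bcl, "n_beats": cfg.n_beats, "dt_ms": cfg.dt,
        "pacing_nodes": cfg.pacing_nodes, "model": cfg.model,
        "stim_amplitude": cfg.stim_amplitude,
        "stim_duration_ms": cfg.stim_duration,
        "cell_prebeats": cfg.cell_prebeats,
        "layout": json.dumps([int(c) for c in cfg.layout]),
        "version": __version__,
    }


def strand_to_hdf5(trace: StrandTrace, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("time_ms", data=trace.t)
        f.create_dataset("Vm_mV", data=trace.vm)
        f.create_dataset("x_mm", data=trace.x)
        f.create_dataset("stim_times_ms", data=trace.stim_times)
        if trace.config is not None:
            for k, v in _config_attrs(trace.config).items():
                f.attrs[k] = v
            f.create_dataset("node_factors", data=trace.config.node_factors)


def strand_from_hdf5(path) -> StrandTrace:
    with h5py.File(path, "r") as f:
        t = f["time_ms"][:]
        vm = f["Vm_mV"][:]
        x = f["x_mm"][:]
        stim = f["stim_times_ms"][:]
        cfg = None
        if "n_nodes" in f.attrs:
            cfg = StrandConfig(
                n_nodes=int(f.attrs["n_nodes"]), dx=float(f.attrs["dx_mm"]),
                D=float(f.attrs["D_mm2_ms"]),
                layout=np.array(json.loads(f.attrs["layout"])),
                node_factors=(f["node_factors"][:] if "node_factors" in f
                              else None),
                pacing_nodes=int(f.attrs["pacing_nodes"]),
                bcl=float(f.attrs["bcl_ms"]), n_beats=int(f.attrs["n_beats"]),
                dt=float(f.attrs["dt_ms"]),
                stim_amplitude=float(f.attrs["stim_amplitude"]),
                stim_duration=float(f.attrs["stim_duration_ms"]),
                cell_prebeats=int(f.attrs["cell_prebeats"]),
                model=str(f.attrs["model"]),
            )
    return StrandTrace(t=t, vm=vm, x=x, stim_times=stim, stim_log=[],
                       config=cfg)


def ecg_to_csv(ecg, path) -> None:
    pd.DataFrame({"time_ms": ecg.t, "phi_e": ecg.phi}).to_csv(path,
                                                              index=False)
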
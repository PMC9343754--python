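"""HDF5 persistence for grids, episode records and analysis products."""

from __future__ import annotations

import json

import h5py
import numpy as np

from .tissue import SimulationRecord, TissueGrid


def save_grid(path, grid: TissueGrid) -> None:
    with h5py.File(path, "w") as f:
        g = f.create_group("grid")
        g.attrs["dx"] = grid.dx
        g.attrs["D_L"] = grid.D_L
        g.attrs["D_T"] = grid.D_T
        g.attrs["meta"] = json.dumps(grid.meta, default=str)
        g.create_dataset("labels", data=grid.labels, compression="gzip")
        g.create_dataset("fibrotic", data=grid.fibrotic, compression="gzip")
        g.create_dataset("fiber_angle", data=grid.fiber_angle, compression="gzip")
        g.create_dataset("interior", data=grid.interior, compression="gzip")
        g.create_dataset("ablated", data=grid.ablated, compression="gzip")
        if grid.voltage is not None:
            g.create_dataset("voltage", data=grid.voltage, compression="gzip")


def load_grid(path) -> TissueGrid:
    with h5py.File(path, "r") as f:
        g = f["grid"]
        return TissueGrid(
            dx=float(g.attrs["dx"]), labels=g["labels"][()],
            fibrotic=g["fibrotic"][()], fiber_angle=g["fiber_angle"][()],
            interior=g["interior"][()], D_L=float(g.attrs["D_L"]),
            D_T=float(g.attrs["D_T"]), ablated=g["ablated"][()],
            voltage=g["voltage"][()] if "voltage" in g else None,
            meta=json.loads(g.attrs.get("meta", "{}")))


def save_trace(path, trace) -> None:
    """Persist an :class:`~fibwave.cellmodel.APTrace` as an HDF5 group."""
    with h5py.File(path, "w") as f:
        g = f.create_group("trace")
        g.attrs["preset"] = trace.preset_name
        g.attrs["cycle_length"] = trace.cycle_length
        g.attrs["captured"] = bool(trace.captured)
        g.create_dataset("t", data=trace.t)
        g.create_dataset("v", data=trace.v)
        g.create_dataset("apd90_history", data=trace.apd90_history)


def save_record(path, record: SimulationRecord) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["duration"] = record.duration
        f.attrs["dt"] = record.dt
        f.attrs["meta"] = json.dumps(record.meta, default=str)
        f.create_dataset("vm", data=record.vm, compression="gzip", shuffle=True)
        f.create_dataset("t_samp", data=record.t_samp)
        f.create_dataset("rec_nodes", data=record.rec_nodes)
        f.create_dataset("activation_times", data=record.act_t, compression="gzip")
        f.create_dataset("repol_times", data=record.rep_t, compression="gzip")
        f.create_dataset("n_act", data=record.n_act)
        f.create_dataset("n_rep", data=record.n_rep)
        f.create_dataset("ablated", data=record.ablated)


def load_record(path) -> SimulationRecord:
    with h5py.File(path, "r") as f:
        return SimulationRecord(
            t_samp=f["t_samp"][()], vm=f["vm"][()], rec_nodes=f["rec_nodes"][()],
            act_t=f["activation_times"][()], rep_t=f["repol_times"][()],
            n_act=f["n_act"][()], n_rep=f["n_rep"][()],
            duration=float(f.attrs["duration"]), dt=float(f.attrs["dt"]),
            ablated=f["ablated"][()], meta=json.loads(f.attrs.get("meta", "{}")))
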
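"""Trace readers/writers and run metadata.

Traces are written to HDF5 (primary) or CSV (fallback for small runs and
text-only environments); event tables go to JSON.  Every artifact embeds
the configuration hash, the RNG seed and the package version so a run can
be traced back to its inputs.
"""

from __future__ import annotations

import dataclasses
import json
import os

import numpy as np

from .engine import SimulationTrace

__all__ = ["save_trace", "load_trace", "save_events_json"]

_ARRAY_FIELDS = [
    "t",
    "v",
    "i_cal",
    "i_cat",
    "i_ncx",
    "ca_avg",
    "ca_subsl",
    "ca_subsr",
    "ca_jsr",
    "ca_nsr_mean",
    "ryr_flux",
    "p_open_mean",
    "leak_events",
    "stim_times",
]
_META_FIELDS = ["seed", "config_hash", "dt_rec"]


def save_trace(trace: SimulationTrace, path: str) -> None:
    """Write a trace to ``.h5``/``.hdf5`` (HDF5) or ``.csv``."""
    from . import __version__

    ext = os.path.splitext(path)[1].lower()
    if ext in (".h5", ".hdf5"):
        import h5py

        with h5py.File(path, "w") as f:
            for name in _ARRAY_FIELDS:
                f.create_dataset(name, data=getattr(trace, name))
            f.attrs["seed"] = trace.seed
            f.attrs["config_hash"] = trace.config_hash
            f.attrs["dt_rec"] = trace.dt_rec
            f.attrs["version"] = __version__
    elif ext == ".csv":
        import csv

        nd = trace.ca_jsr.shape[1]
        header = ["t", "v", "i_cal", "i_cat", "i_ncx", "ca_avg", "ca_subsl", "ca_subsr", "ca_nsr_mean", "p_open_mean"]
        header += [f"ca_jsr_{j}" for j in range(nd)]
        header += [f"ryr_flux_{j}" for j in range(nd)]
        with open(path, "w", newline="") as f:
            w = csv.writer(f)
            w.writerow([f"# seed={trace.seed} config_hash={trace.config_hash} dt_rec={trace.dt_rec} version={__version__}"])
            w.writerow(header)
            for i in range(len(trace.t)):
                row = [
                    trace.t[i], trace.v[i], trace.i_cal[i], trace.i_cat[i],
                    trace.i_ncx[i], trace.ca_avg[i], trace.ca_subsl[i],
                    trace.ca_subsr[i], trace.ca_nsr_mean[i], trace.p_open_mean[i],
                ]
                row += list(trace.ca_jsr[i]) + list(trace.ryr_flux[i])
                w.writerow(row)
        # sidecar for events/stims, which do not fit the rectangular table
        side = path + ".meta.json"
        with open(side, "w") as f:
            json.dump(
                {
                    "leak_events": trace.leak_events.tolist(),
                    "stim_times": trace.stim_times.tolist(),
                },
                f,
            )
    else:
        raise ValueError(f"unsupported trace format: {ext} (use .h5, .hdf5 or .csv)")


def load_trace(path: str) -> SimulationTrace:
    """Read a trace written by :func:`save_trace`; round-trips all values."""
    ext = os.path.splitext(path)[1].lower()
    if ext in (".h5", ".hdf5"):
        import h5py

        with h5py.File(path, "r") as f:
            kw = {name: np.asarray(f[name]) for name in _ARRAY_FIELDS}
            kw.update(
                seed=int(f.attrs["seed"]),
                config_hash=str(f.attrs["config_hash"]),
                dt_rec=float(f.attrs["dt_rec"]),
            )
        return SimulationTrace(**kw)
    if ext == ".csv":
        import csv

        with open(path) as f:
            meta_line = f.readline().strip().lstrip("#").split()
            meta = dict(kv.split("=") for kv in meta_line if "=" in kv)
            rows = list(csv.reader(f))
        header, data = rows[0], np.asarray(rows[1:], dtype=float)
        col = {name: i for i, name in enumerate(header)}
        nd = sum(1 for h in header if h.startswith("ca_jsr_"))
        side = path + ".meta.json"
        if os.path.exists(side):
            with open(side) as f:
                extra = json.load(f)
        else:
            extra = {"leak_events": [], "stim_times": []}
        return SimulationTrace(
            t=data[:, col["t"]],
            v=data[:, col["v"]],
            i_cal=data[:, col["i_cal"]],
            i_cat=data[:, col["i_cat"]],
            i_ncx=data[:, col["i_ncx"]],
            ca_avg=data[:, col["ca_avg"]],
            ca_subsl=data[:, col["ca_subsl"]],
            ca_subsr=data[:, col["ca_subsr"]],
            ca_nsr_mean=data[:, col["ca_nsr_mean"]],
            p_open_mean=data[:, col["p_open_mean"]],
            ca_jsr=data[:, [col[f"ca_jsr_{j}"] for j in range(nd)]],
            ryr_flux=data[:, [col[f"ryr_flux_{j}"] for j in range(nd)]],
            leak_events=np.asarray(extra["leak_events"], dtype=float).reshape(-1, 3),
            stim_times=np.asarray(extra["stim_times"], dtype=float),
            seed=int(meta.get("seed", -1)),
            config_hash=meta.get("config_hash", ""),
            dt_rec=float(meta.get("dt_rec", np.diff(data[:2, col["t"]])[0] if len(data) > 1 else 0.1)),
        )
    raise ValueError(f"unsupported trace format: {ext}")


def save_events_json(record, path: str, **metadata) -> None:
    """Write an event table (DADs, triggered APs, sparks) to JSON."""
    from . import __version__

    def enc(o):
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer, np.floating)):
            return o.item()
        raise TypeError(f"cannot serialize {type(o)}")

    payload = {"version": __version__, **metadata, "events": record}
    with open(path, "w") as f:
        json.dump(payload, f, indent=2, default=enc)
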
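"""Reading and writing of the package's on-disk formats.

Multi-trial recordings live in HDF5 (datasets ``/data`` (N, d, T) float64,
``/fs`` scalar, ``/time`` (T,), ``/channels`` strings) with an NPZ mirror
using the same keys; a CSV reader accepts single-trial toy data with one
column per channel and one row per sample.  Estimates, PDC tensors and
ground-truth models have analogous HDF5 layouts.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np

from .core import MultiTrialTimeSeries, TvmvarEstimate
from .simulate import GroundTruthModel
from .spectral import SpectralConnectivity


def write_timeseries(path: str | Path, Y: MultiTrialTimeSeries) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=Y.data)
        f.create_dataset("fs", data=float(Y.fs))
        f.create_dataset("time", data=Y.time)
        f.create_dataset("channels", data=np.array(Y.channel_labels, dtype="S"))


def read_timeseries(path: str | Path) -> MultiTrialTimeSeries:
    path = Path(path)
    if path.suffix == ".npz":
        with np.load(path, allow_pickle=False) as f:
            labels = [str(c) for c in f["channels"].astype(str)] if "channels" in f else None
            time = f["time"] if "time" in f else None
            return MultiTrialTimeSeries(
                data=f["data"], fs=float(f["fs"]), channel_labels=labels, time=time
            )
    if path.suffix == ".csv":
        return read_timeseries_csv(path, fs=1.0)
    with h5py.File(path, "r") as f:
        labels = [c.decode() for c in f["channels"][()]] if "channels" in f else None
        time = f["time"][()] if "time" in f else None
        return MultiTrialTimeSeries(
            data=f["data"][()], fs=float(f["fs"][()]), channel_labels=labels, time=time
        )


def write_timeseries_npz(path: str | Path, Y: MultiTrialTimeSeries) -> None:
    np.savez(
        path,
        data=Y.data,
        fs=np.float64(Y.fs),
        time=Y.time,
        channels=np.array(Y.channel_labels, dtype="U"),
    )


def read_timeseries_csv(path: str | Path, fs: float) -> MultiTrialTimeSeries:
    """Single-trial toy data: columns = channels, rows = time; header optional."""
    path = Path(path)
    with open(path) as f:
        first = f.readline()
    has_header = any(not _is_number(tok) for tok in first.strip().split(","))
    table = np.loadtxt(path, delimiter=",", skiprows=1 if has_header else 0, ndmin=2)
    labels = [tok.strip() for tok in first.strip().split(",")] if has_header else None
    return MultiTrialTimeSeries(data=table.T[None, :, :], fs=fs, channel_labels=labels)


def _is_number(tok: str) -> bool:
    try:
        float(tok)
        return True
    except ValueError:
        return False


def write_estimate(path: str | Path, est: TvmvarEstimate) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("coefficients", data=est.coefficients)
        f.create_dataset("innovation_cov", data=est.innovation_cov)
        f.create_dataset("c_trajectory", data=est.c_trajectory)
        f.attrs["order"] = est.order
        f.attrs["fs"] = est.fs
        f.attrs["valid_from"] = est.valid_from
        diag = f.create_group("diagnostics")
        for key, value in est.diagnostics.items():
            diag.create_dataset(key, data=value)


def read_estimate(path: str | Path) -> TvmvarEstimate:
    with h5py.File(path, "r") as f:
        diagnostics = {k: f["diagnostics"][k][()] for k in f.get("diagnostics", {})}
        return TvmvarEstimate(
            coefficients=f["coefficients"][()],
            order=int(f.attrs["order"]),
            innovation_cov=f["innovation_cov"][()],
            c_trajectory=f["c_trajectory"][()],
            fs=float(f.attrs["fs"]),
            valid_from=int(f.attrs["valid_from"]),
            diagnostics=diagnostics,
        )


def write_connectivity(path: str | Path, conn: SpectralConnectivity) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("values", data=conn.values)
        f.create_dataset("freqs", data=conn.freqs)
        f.attrs["fs"] = conn.fs
        f.attrs["kind"] = conn.kind


def read_connectivity(path: str | Path) -> SpectralConnectivity:
    with h5py.File(path, "r") as f:
        return SpectralConnectivity(
            values=f["values"][()],
            freqs=f["freqs"][()],
            fs=float(f.attrs["fs"]),
            kind=str(f.attrs["kind"]),
        )


def write_ground_truth(path: str | Path, model: GroundTruthModel) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("coefficients", data=model.coefficients)
        f.create_dataset("structural_mask", data=model.structural_mask)
        f.create_dataset("dynamic_mask", data=model.dynamic_mask)
        f.create_dataset("regime_bounds", data=model.regime_bounds)
        f.attrs["fs"] = model.fs


def read_ground_truth(path: str | Path) -> GroundTruthModel:
    with h5py.File(path, "r") as f:
        return GroundTruthModel(
            coefficients=f["coefficients"][()],
            structural_mask=f["structural_mask"][()].astype(bool),
            dynamic_mask=f["dynamic_mask"][()].astype(bool),
            regime_bounds=f["regime_bounds"][()],
            fs=float(f.attrs["fs"]),
        )
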
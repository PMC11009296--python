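"""Pressure-volume traces and simulation datasets.

The fixed physical state ordering used throughout the package is

    [p_LA, p_LV, p_RA, p_RV, V_LA, V_LV, V_RA, V_RV]

with pressures in mmHg, volumes in mL and time in seconds.  A
:class:`PVTrace` holds one cardiac cycle on a uniform half-open grid
``t = 0, dt, ..., T_HB - dt``; multi-beat simulator output is held in a
:class:`BeatSeries` and reduced to its final cycle with :func:`last_beat`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .parameters import ParameterSpace, ParameterVector

__all__ = [
    "CHANNELS",
    "PRESSURE_CHANNELS",
    "VOLUME_CHANNELS",
    "PVTrace",
    "BeatSeries",
    "SimulationDataset",
    "last_beat",
    "save_dataset",
    "load_dataset",
    "save_dataset_hdf5",
    "load_dataset_hdf5",
]

PRESSURE_CHANNELS = ("p_LA", "p_LV", "p_RA", "p_RV")
VOLUME_CHANNELS = ("V_LA", "V_LV", "V_RA", "V_RV")
CHANNELS = PRESSURE_CHANNELS + VOLUME_CHANNELS


@dataclass(frozen=True)
class PVTrace:
    """One cardiac cycle of the 8 physical channels on a uniform grid.

    ``values`` has shape ``(len(t), 8)`` in the :data:`CHANNELS` order.
    The grid is half-open: ``t[0] == 0`` and ``t[-1] == T_HB - dt``.
    """

    t: np.ndarray
    values: np.ndarray
    T_HB: float
    AV_delay: float

    def __post_init__(self):
        t = np.asarray(self.t, float)
        v = np.asarray(self.values, float)
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "values", v)
        if t.ndim != 1 or len(t) < 2:
            raise ValueError("t must be a 1-D grid with at least 2 samples")
        dt = np.diff(t)
        if not np.all(dt > 0) or not np.allclose(dt, dt[0], rtol=1e-8, atol=1e-12):
            raise ValueError("t must be strictly increasing and uniform")
        if v.shape != (len(t), 8):
            raise ValueError(f"values must have shape ({len(t)}, 8), got {v.shape}")
        if not np.all(np.isfinite(v)):
            raise ValueError("trace contains non-finite values")
        if np.any(v[:, 4:] <= 0):
            raise ValueError("chamber volumes must be strictly positive")
        if not (0 <= self.AV_delay < self.T_HB):
            raise ValueError("require 0 <= AV_delay < T_HB")

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    @property
    def n_samples(self) -> int:
        return len(self.t)

    def channel(self, name: str) -> np.ndarray:
        try:
            return self.values[:, CHANNELS.index(name)]
        except ValueError:
            raise KeyError(f"unknown channel {name!r}") from None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            np.column_stack([self.t, self.values]), columns=("t",) + CHANNELS
        )

    @classmethod
    def from_frame(
        cls, df: pd.DataFrame, T_HB: float, AV_delay: float,
        column_map: dict[str, str] | None = None,
    ) -> "PVTrace":
        """Build a trace from a dataframe with columns ``t`` + channel names.

        ``column_map`` maps this package's names to the frame's column names,
        accommodating externally produced pressure-volume datasets.
        """
        cmap = {c: c for c in ("t",) + CHANNELS}
        if column_map:
            cmap.update(column_map)
        missing = [cmap[c] for c in cmap if cmap[c] not in df.columns]
        if missing:
            raise KeyError(f"dataset is missing columns {missing}")
        t = df[cmap["t"]].to_numpy(float)
        vals = np.column_stack([df[cmap[c]].to_numpy(float) for c in CHANNELS])
        return cls(t, vals, float(T_HB), float(AV_delay))


@dataclass(frozen=True)
class BeatSeries:
    """Multi-beat simulator output: physical channels plus internal states.

    ``values`` has shape ``(len(t), 8)``; ``internal`` carries the vascular
    compartment pressures (columns named in ``internal_names``) so that
    closed-loop volume bookkeeping can be checked after the fact.
    """

    t: np.ndarray
    values: np.ndarray
    T_HB: float
    AV_delay: float
    internal: np.ndarray | None = None
    internal_names: tuple[str, ...] = ()

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])


def last_beat(trace: BeatSeries | PVTrace) -> PVTrace:
    """Extract the final cardiac cycle, re-based to ``[0, T_HB)``.

    The returned grid keeps the input's sample spacing and follows the
    half-open convention (``t[-1] = T_HB - dt``).
    """
    t = np.asarray(trace.t, float)
    T_HB = float(trace.T_HB)
    dt = float(t[1] - t[0])
    per_beat = int(round(T_HB / dt))
    if len(t) < per_beat:
        raise ValueError(
            f"trace has {len(t)} samples but one period needs {per_beat}"
        )
    vals = np.asarray(trace.values, float)[len(t) - per_beat:]
    t_out = np.arange(per_beat) * dt
    return PVTrace(t_out, vals, T_HB, trace.AV_delay)


@dataclass
class SimulationDataset:
    """A collection of (parameter vector, last-beat trace) records."""

    space: ParameterSpace
    records: list[tuple[ParameterVector, PVTrace]]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        lengths = {rec[1].n_samples for rec in self.records}
        if len(lengths) > 1:
            raise ValueError(f"records have inconsistent grid lengths {sorted(lengths)}")
        for theta, _ in self.records:
            if theta.space.names != self.space.names:
                raise ValueError("all records must share the dataset's parameter space")

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, i):
        return self.records[i]

    def subset(self, idx: Sequence[int]) -> "SimulationDataset":
        return SimulationDataset(
            self.space, [self.records[i] for i in idx], dict(self.provenance)
        )

    def split(self, n_train: int) -> tuple["SimulationDataset", "SimulationDataset"]:
        """Leading ``n_train`` records for training, the rest held out."""
        if not 0 < n_train <= len(self):
            raise ValueError(f"n_train must be in (0, {len(self)}]")
        return self.subset(range(n_train)), self.subset(range(n_train, len(self)))

    def theta_matrix(self) -> np.ndarray:
        return np.stack([th.values for th, _ in self.records])

    def trace_array(self) -> np.ndarray:
        """All traces stacked, shape ``(n_records, n_samples, 8)``."""
        return np.stack([tr.values for _, tr in self.records])


# ----------------------------------------------------------------------------
# on-disk formats: directory of CSVs with a JSON manifest, and an HDF5 bundle
# ----------------------------------------------------------------------------

def save_dataset(ds: SimulationDataset, path: str | Path) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    manifest = {
        "space": ds.space.to_dict(),
        "n_records": len(ds),
        "units": {"pressure": "mmHg", "volume": "mL", "time": "s"},
        "channels": list(CHANNELS),
        "provenance": ds.provenance,
        "timing": [
            {"T_HB": tr.T_HB, "AV_delay": tr.AV_delay} for _, tr in ds.records
        ],
    }
    (path / "manifest.json").write_text(json.dumps(manifest, indent=2))
    pd.DataFrame(ds.theta_matrix(), columns=list(ds.space.names)).to_csv(
        path / "parameters.csv", index=False
    )
    for i, (_, tr) in enumerate(ds.records):
        tr.to_frame().to_csv(path / f"trace_{i:04d}.csv", index=False)


def load_dataset(path: str | Path, column_map: dict[str, str] | None = None) -> SimulationDataset:
    """Load a directory-of-CSV dataset written by :func:`save_dataset`.

    Any external dataset with the same layout (``manifest.json``,
    ``parameters.csv``, ``trace_<id>.csv``) can be ingested; ``column_map``
    renames trace columns if the producer used different headers.
    """
    path = Path(path)
    manifest = json.loads((path / "manifest.json").read_text())
    space = ParameterSpace.from_dict(manifest["space"])
    thetas = pd.read_csv(path / "parameters.csv")
    records = []
    for i in range(manifest["n_records"]):
        df = pd.read_csv(path / f"trace_{i:04d}.csv")
        timing = manifest["timing"][i]
        tr = PVTrace.from_frame(df, timing["T_HB"], timing["AV_delay"], column_map)
        theta = ParameterVector(space, thetas.iloc[i][list(space.names)].to_numpy(float))
        records.append((theta, tr))
    return SimulationDataset(space, records, manifest.get("provenance", {}))


def save_dataset_hdf5(ds: SimulationDataset, path: str | Path) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.attrs["space"] = json.dumps(ds.space.to_dict())
        f.attrs["provenance"] = json.dumps(ds.provenance)
        f.attrs["channels"] = ",".join(CHANNELS)
        f.create_dataset("theta", data=ds.theta_matrix())
        f.create_dataset("traces", data=ds.trace_array())
        f.create_dataset("t", data=ds.records[0][1].t if ds.records else np.empty(0))
        f.create_dataset("T_HB", data=[tr.T_HB for _, tr in ds.records])
        f.create_dataset("AV_delay", data=[tr.AV_delay for _, tr in ds.records])


def load_dataset_hdf5(path: str | Path) -> SimulationDataset:
    import h5py

    with h5py.File(path, "r") as f:
        space = ParameterSpace.from_dict(json.loads(f.attrs["space"]))
        provenance = json.loads(f.attrs["provenance"])
        theta = f["theta"][...]
        traces = f["traces"][...]
        T_HB = f["T_HB"][...]
        AV = f["AV_delay"][...]
    records = []
    for i in range(theta.shape[0]):
        # grids differ in dt when T_HB varies; rebuild each half-open grid
        t_i = np.arange(traces.shape[1]) * (T_HB[i] / traces.shape[1])
        records.append(
            (
                ParameterVector(space, theta[i]),
                PVTrace(t_i, traces[i], float(T_HB[i]), float(AV[i])),
            )
        )
    return SimulationDataset(space, records, provenance)
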
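"""Readers and writers for sweeps (HDF5), cells/edges/spikes (CSV), config (JSON).

Sweep files hold one HDF5 group per trial (``trial_000`` ...) with one
dataset per cell, and root attributes ``sampling_rate_hz``,
``pulse_times_ms``, ``stimulated_cell`` and ``units``.  Spike files are
plain CSV with ``unit_id,t_ms`` columns; event tables travel in a sidecar
``<name>.events.csv`` (``event,t_ms``) and the epoch in the spike file
header comment.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .types import CellRecord, ConnectionRecord, SpikeTrainSet, SweepSet

__all__ = [
    "FormatError",
    "read_sweeps",
    "write_sweeps",
    "read_spikes",
    "write_spikes",
    "read_cells",
    "write_cells",
    "read_edges",
    "write_edges",
    "read_config",
    "write_config",
]


class FormatError(ValueError):
    """A file does not conform to the expected on-disk layout."""


# ---------------------------------------------------------------- sweeps

_REQUIRED_SWEEP_ATTRS = ("sampling_rate_hz", "pulse_times_ms", "stimulated_cell")


def write_sweeps(sweeps: SweepSet, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["sampling_rate_hz"] = float(sweeps.sampling_rate)
        f.attrs["pulse_times_ms"] = np.asarray(sweeps.pulse_times, dtype=float)
        f.attrs["stimulated_cell"] = sweeps.stimulated_cell
        f.attrs["units"] = sweeps.units
        for trial in range(sweeps.trial_count):
            grp = f.create_group(f"trial_{trial:03d}")
            for cell_id, traces in sweeps.traces.items():
                grp.create_dataset(cell_id, data=traces[trial])


def read_sweeps(path: str | Path) -> SweepSet:
    with h5py.File(path, "r") as f:
        for attr in _REQUIRED_SWEEP_ATTRS:
            if attr not in f.attrs:
                raise FormatError(f"sweep file {path} is missing attribute {attr!r}")
        trial_names = sorted(k for k in f.keys() if k.startswith("trial_"))
        if not trial_names:
            raise FormatError(f"sweep file {path} contains no trial groups")
        cell_ids = list(f[trial_names[0]].keys())
        traces = {
            cid: np.stack([np.asarray(f[t][cid]) for t in trial_names])
            for cid in cell_ids
        }
        return SweepSet(
            traces=traces,
            sampling_rate=float(f.attrs["sampling_rate_hz"]),
            pulse_times=np.asarray(f.attrs["pulse_times_ms"], dtype=float),
            stimulated_cell=str(f.attrs["stimulated_cell"]),
            units=str(f.attrs.get("units", "mV")),
        )


# ---------------------------------------------------------------- spikes


def _events_path(path: Path) -> Path:
    return path.with_suffix(".events.csv")


def write_spikes(spikes: SpikeTrainSet, path: str | Path) -> None:
    path = Path(path)
    rows = [
        (uid, t) for uid, ts in spikes.units.items() for t in ts
    ]
    df = pd.DataFrame(rows, columns=["unit_id", "t_ms"])
    with open(path, "w") as fh:
        fh.write(f"# epoch_ms={spikes.epoch[0]},{spikes.epoch[1]}\n")
        # units with no spikes must still round-trip
        fh.write(f"# units={','.join(spikes.unit_ids)}\n")
        df.to_csv(fh, index=False)
    if spikes.events:
        ev = pd.DataFrame(
            [(name, t) for name, ts in spikes.events.items() for t in ts],
            columns=["event", "t_ms"],
        )
        ev.to_csv(_events_path(path), index=False)


def read_spikes(path: str | Path) -> SpikeTrainSet:
    path = Path(path)
    epoch: tuple[float, float] | None = None
    declared_units: list[str] = []
    with open(path) as fh:
        header_lines = 0
        for line in fh:
            if not line.startswith("#"):
                break
            header_lines += 1
            key, _, value = line[1:].strip().partition("=")
            if key == "epoch_ms":
                lo, hi = value.split(",")
                epoch = (float(lo), float(hi))
            elif key == "units" and value:
                declared_units = value.split(",")
    df = pd.read_csv(path, comment="#")
    if "unit_id" not in df.columns or "t_ms" not in df.columns:
        raise FormatError(f"spike file {path} must have unit_id,t_ms columns")
    units: dict[str, np.ndarray] = {uid: np.empty(0) for uid in declared_units}
    for uid, grp in df.groupby("unit_id", sort=False):
        ts = grp["t_ms"].to_numpy(dtype=float)
        if np.any(np.diff(ts) < 0):
            warnings.warn(f"unit {uid!r}: unsorted timestamps on read; sorting")
            ts = np.sort(ts)
        units[str(uid)] = ts
    if epoch is None:
        all_ts = df["t_ms"].to_numpy(dtype=float) if len(df) else np.array([0.0])
        epoch = (float(min(all_ts.min(), 0.0)), float(all_ts.max() + 1.0))
    events: dict[str, np.ndarray] = {}
    ev_path = _events_path(path)
    if ev_path.exists():
        ev = pd.read_csv(ev_path)
        for name, grp in ev.groupby("event", sort=False):
            events[str(name)] = grp["t_ms"].to_numpy(dtype=float)
    return SpikeTrainSet(units=units, epoch=epoch, events=events)


# ---------------------------------------------------------------- cells / edges


def write_cells(cells: list[CellRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "cell_id": [c.cell_id for c in cells],
            "x_um": [c.position[0] for c in cells],
            "y_um": [c.position[1] for c in cells],
            "class": [c.excitability_class for c in cells],
            "tag": [c.tag for c in cells],
            "time_to_spike_ms": [c.time_to_spike for c in cells],
        }
    )
    df.to_csv(path, index=False)


def read_cells(path: str | Path) -> list[CellRecord]:
    df = pd.read_csv(path)
    required = {"cell_id", "x_um", "y_um"}
    if not required.issubset(df.columns):
        missing = required - set(df.columns)
        raise FormatError(f"cell table {path} is missing columns {sorted(missing)}")
    cells = []
    for _, row in df.iterrows():
        tts = row.get("time_to_spike_ms")
        cells.append(
            CellRecord(
                cell_id=str(row["cell_id"]),
                position=(float(row["x_um"]), float(row["y_um"])),
                excitability_class=str(row.get("class", "unknown")),
                time_to_spike=None if pd.isna(tts) else float(tts),
                tag=str(row.get("tag", "none")),
            )
        )
    return cells


def write_edges(edges: list[ConnectionRecord], path: str | Path) -> None:
    rows = []
    for e in edges:
        rows.append(
            {
                "pre": e.pre_id,
                "post": e.post_id,
                "delay_ms": e.delay,
                "jitter_ms": e.jitter,
                "dynamics": e.dynamics_class,
                "amplitudes_uv": json.dumps(list(e.amplitudes)),
                "amplitudes_excl_failures_uv": json.dumps(
                    list(e.amplitudes_excl_failures)
                ),
                "failure_rates": json.dumps(list(e.failure_rates)),
            }
        )
    pd.DataFrame(
        rows,
        columns=[
            "pre",
            "post",
            "delay_ms",
            "jitter_ms",
            "dynamics",
            "amplitudes_uv",
            "amplitudes_excl_failures_uv",
            "failure_rates",
        ],
    ).to_csv(path, index=False)


def read_edges(path: str | Path) -> list[ConnectionRecord]:
    df = pd.read_csv(path)
    required = {"pre", "post", "delay_ms", "jitter_ms"}
    if not required.issubset(df.columns):
        missing = required - set(df.columns)
        raise FormatError(f"edge table {path} is missing columns {sorted(missing)}")
    edges = []
    for _, row in df.iterrows():
        edges.append(
            ConnectionRecord(
                pre_id=str(row["pre"]),
                post_id=str(row["post"]),
                delay=float(row["delay_ms"]),
                jitter=float(row["jitter_ms"]),
                amplitudes=np.array(json.loads(row["amplitudes_uv"])),
                amplitudes_excl_failures=np.array(
                    json.loads(row["amplitudes_excl_failures_uv"])
                ),
                failure_rates=np.array(json.loads(row["failure_rates"])),
                dynamics_class=str(row.get("dynamics", "uncategorized")),
            )
        )
    return edges


# ---------------------------------------------------------------- config


def write_config(config: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(config, fh, indent=2, default=float)


def read_config(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)
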
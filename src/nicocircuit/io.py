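"""CSV/TIFF readers and writers for the pipeline's exchange formats.

Dialects:
- drinking: ``animal,timestamp,bottle,volume_ml`` plus ``labels.csv``
  (``date,bottle,content,side``) and ``weights.csv``
  (``animal,date,grams``);
- EOM: ``frame,zone`` with the frame rate in a ``# fps=...`` header;
- CPP: ``animal,session,chamber,seconds`` (+ paired chamber column);
- spikes: ``unit,spike_time_s`` plus ``events.csv``
  (``unit,event_time_s,event_type``);
- cFos counts: long ``animal,group,region,count``;
- sweeps: ``time_s,current_pA``;
- stacks: single-/multi-page TIFF via tifffile.

Generated datasets can be written with their ground truth as a JSON
sidecar, so a round trip through files preserves testability.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .behavior import ZoneTrace
from .boutons import VoxelStack
from .currents import Sweep
from .drinking import BottleSeries
from .fosnet import RegionCountMatrix
from .spikes import SpikeTrain
from .synth import GroundTruth

__all__ = [
    "write_bottle_series",
    "read_bottle_series",
    "write_zone_trace",
    "read_zone_trace",
    "write_spike_trains",
    "read_spike_trains",
    "write_region_counts",
    "read_region_counts",
    "write_stack",
    "read_stack",
    "write_sweep",
    "read_sweep",
    "write_ground_truth",
]


def write_ground_truth(gt: GroundTruth, path: str | Path) -> None:
    Path(path).write_text(json.dumps(gt.as_json(), indent=1))


def write_bottle_series(series: BottleSeries, directory: str | Path) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    series.data.assign(animal=series.animal)[
        ["animal", "timestamp", "bottle", "volume_ml"]
    ].to_csv(d / "volumes.csv", index=False)
    series.labels.to_csv(d / "labels.csv", index=False)
    series.weights.to_csv(d / "weights.csv", index=False)


def read_bottle_series(directory: str | Path, animal: str | None = None) -> BottleSeries:
    d = Path(directory)
    data = pd.read_csv(d / "volumes.csv", parse_dates=["timestamp"])
    if animal is None:
        animal = str(data["animal"].iloc[0])
    data = data.loc[data["animal"] == animal, ["timestamp", "bottle", "volume_ml"]]
    labels = pd.read_csv(d / "labels.csv")
    weights_path = d / "weights.csv"
    weights = pd.read_csv(weights_path) if weights_path.exists() else pd.DataFrame(
        columns=["animal", "date", "grams"]
    )
    return BottleSeries(
        animal=animal, data=data.reset_index(drop=True), labels=labels, weights=weights
    )


def write_zone_trace(trace: ZoneTrace, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# fps={trace.fps}\n")
        fh.write("frame,zone\n")
        for k, z in enumerate(trace.zones):
            fh.write(f"{k},{z}\n")


def read_zone_trace(path: str | Path) -> ZoneTrace:
    with open(path) as fh:
        header = fh.readline().strip()
        if not header.startswith("# fps="):
            raise ValueError("missing '# fps=' header line")
        fps = float(header.split("=", 1)[1])
        df = pd.read_csv(fh)
    return ZoneTrace(fps=fps, zones=df["zone"].to_numpy())


def write_spike_trains(trains: list[SpikeTrain], directory: str | Path) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    rows = [(tr.unit, t) for tr in trains for t in tr.times]
    pd.DataFrame(rows, columns=["unit", "spike_time_s"]).to_csv(
        d / "spikes.csv", index=False
    )
    ev = [
        (tr.unit, t, kind, tr.duration_s)
        for tr in trains
        for t, kind in tr.injections
    ]
    pd.DataFrame(ev, columns=["unit", "event_time_s", "event_type", "duration_s"]).to_csv(
        d / "events.csv", index=False
    )


def read_spike_trains(directory: str | Path) -> list[SpikeTrain]:
    d = Path(directory)
    spikes = pd.read_csv(d / "spikes.csv")
    events = pd.read_csv(d / "events.csv")
    out = []
    for unit, ev in events.groupby("unit"):
        times = spikes.loc[spikes["unit"] == unit, "spike_time_s"].to_numpy(float)
        out.append(
            SpikeTrain(
                times=np.sort(times),
                duration_s=float(ev["duration_s"].iloc[0]),
                injections=list(zip(ev["event_time_s"], ev["event_type"])),
                unit=str(unit),
            )
        )
    return out


def write_region_counts(rcm: RegionCountMatrix, path: str | Path) -> None:
    long = (
        rcm.counts.stack()
        .rename("count")
        .reset_index()
        .rename(columns={"level_0": "animal", "level_1": "region"})
    )
    long.insert(1, "group", long["animal"].map(rcm.groups))
    long.to_csv(path, index=False)


def read_region_counts(path: str | Path) -> RegionCountMatrix:
    return RegionCountMatrix.from_long(pd.read_csv(path))


def write_stack(stack: VoxelStack, path: str | Path) -> None:
    tifffile.imwrite(path, stack.data.astype(np.float32))


def read_stack(path: str | Path, voxel_size_um: tuple[float, float, float]) -> VoxelStack:
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[None]
    return VoxelStack(data=np.asarray(data, float), voxel_size_um=voxel_size_um)


def write_sweep(sweep: Sweep, path: str | Path, events_path: str | Path | None = None) -> None:
    pd.DataFrame({"time_s": sweep.t, "current_pA": sweep.i}).to_csv(path, index=False)
    if events_path is not None:
        Path(events_path).write_text(json.dumps(sweep.events, indent=1))


def read_sweep(path: str | Path, events_path: str | Path | None = None) -> Sweep:
    df = pd.read_csv(path)
    events = {}
    if events_path is not None and Path(events_path).exists():
        events = json.loads(Path(events_path).read_text())
    return Sweep(t=df["time_s"].to_numpy(float), i=df["current_pA"].to_numpy(float), events=events)
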
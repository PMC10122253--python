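"""File plumbing for the assay's data formats.

Recordings travel as one ``.npz`` array file per plate with a JSON sidecar
(sampling rate, duration, well map); viability fields as multi-page TIFF in
nuclei/live/dead channel order; TEER readings, spike trains, bubble traces
and summaries as headed CSV; presets and run configuration as YAML.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

from .barrier import TeerRecord
from .biophysics import BubbleTrace
from .imaging import CHANNEL_ORDER, ViabilityImage
from .mea import Recording, SpikeTrain, WellSummary
from .presets import InjuryCondition, InjuryPreset

__all__ = [
    "write_recording",
    "read_recording",
    "write_viability_tiff",
    "read_viability_tiff",
    "teer_records_to_csv",
    "teer_records_from_csv",
    "bubble_trace_to_csv",
    "bubble_trace_from_csv",
    "spike_trains_to_csv",
    "spike_trains_from_csv",
    "well_summaries_to_csv",
    "presets_to_yaml",
    "presets_from_yaml",
]


def _sidecar_path(npz_path: Path) -> Path:
    return npz_path.with_suffix(".json")


def write_recording(path: str | Path, recording: Recording) -> Path:
    """Write traces to ``.npz`` plus a JSON sidecar with the metadata."""
    path = Path(path).with_suffix(".npz")
    np.savez_compressed(path, traces=recording.traces)
    meta = {
        "sampling_rate_hz": recording.sampling_rate_hz,
        "duration_s": recording.duration_s,
        "well_map": np.asarray(recording.well_map).tolist(),
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=2))
    return path


def read_recording(path: str | Path) -> Recording:
    path = Path(path)
    meta = json.loads(_sidecar_path(path).read_text())
    with np.load(path) as data:
        traces = data["traces"]
    return Recording(
        traces=traces,
        sampling_rate_hz=meta["sampling_rate_hz"],
        well_map=np.asarray(meta["well_map"]),
        duration_s=meta["duration_s"],
    )


def write_viability_tiff(path: str | Path, image: ViabilityImage) -> Path:
    """Multi-page float32 TIFF, pages in nuclei/live/dead order."""
    path = Path(path)
    stack = np.stack([image.channels[k] for k in CHANNEL_ORDER]).astype(np.float32)
    tifffile.imwrite(
        path,
        stack,
        photometric="minisblack",
        metadata={"pixel_size_um": image.pixel_size_um},
    )
    return path


def read_viability_tiff(path: str | Path, pixel_size_um: float | None = None) -> ViabilityImage:
    with tifffile.TiffFile(path) as tif:
        stack = tif.asarray()
        if pixel_size_um is None:
            meta = tif.shaped_metadata or tif.imagej_metadata or [{}]
            meta = meta[0] if isinstance(meta, (list, tuple)) else meta
            pixel_size_um = float(meta.get("pixel_size_um", 1.0))
    if stack.ndim != 3 or stack.shape[0] != len(CHANNEL_ORDER):
        raise ValueError(f"expected {len(CHANNEL_ORDER)} pages, got shape {stack.shape}")
    channels = {k: stack[i].astype(float) for i, k in enumerate(CHANNEL_ORDER)}
    return ViabilityImage(channels=channels, pixel_size_um=pixel_size_um)


def teer_records_to_csv(path: str | Path, records: Sequence[TeerRecord]) -> Path:
    df = pd.DataFrame(
        {
            "insert": [r.insert_id for r in records],
            "experiment": [r.experiment_id for r in records],
            "condition": [r.condition.label for r in records],
            "timepoint_h": [r.condition.timepoint_h for r in records],
            "raw_ohm": [r.raw_ohm for r in records],
            "blank_ohm": [r.blank_ohm for r in records],
            "area_cm2": [r.membrane_area_cm2 for r in records],
        }
    )
    df.to_csv(path, index=False)
    return Path(path)


def teer_records_from_csv(path: str | Path) -> list[TeerRecord]:
    df = pd.read_csv(path)
    return [
        TeerRecord(
            raw_ohm=row.raw_ohm,
            blank_ohm=row.blank_ohm,
            membrane_area_cm2=row.area_cm2,
            condition=InjuryCondition(row.condition, row.timepoint_h),
            insert_id=row.insert,
            experiment_id=getattr(row, "experiment", None),
        )
        for row in df.itertuples()
    ]


def bubble_trace_to_csv(path: str | Path, trace: BubbleTrace) -> Path:
    pd.DataFrame({"time_s": trace.times_s, "radius_m": trace.radius_m}).to_csv(
        path, index=False
    )
    return Path(path)


def bubble_trace_from_csv(path: str | Path) -> BubbleTrace:
    df = pd.read_csv(path)
    return BubbleTrace(
        times_s=df["time_s"].to_numpy(), radius_m=df["radius_m"].to_numpy()
    )


def spike_trains_to_csv(path: str | Path, trains: Sequence[SpikeTrain]) -> Path:
    rows = [
        {"electrode": t.electrode, "time_s": time}
        for t in trains
        for time in t.times_s
    ]
    pd.DataFrame(rows, columns=["electrode", "time_s"]).to_csv(path, index=False)
    return Path(path)


def spike_trains_from_csv(path: str | Path) -> list[SpikeTrain]:
    df = pd.read_csv(path)
    return [
        SpikeTrain(electrode=int(e), times_s=np.sort(g["time_s"].to_numpy()))
        for e, g in df.groupby("electrode")
    ]


def well_summaries_to_csv(path: str | Path, summaries: Sequence[WellSummary]) -> Path:
    df = pd.DataFrame(
        {
            "well": [s.well for s in summaries],
            "condition": [
                s.condition.label if s.condition else None for s in summaries
            ],
            "timepoint_h": [
                s.condition.timepoint_h if s.condition else None for s in summaries
            ],
            "n_active_electrodes": [s.n_active_electrodes for s in summaries],
            "spikes_per_active_electrode": [
                s.spikes_per_active_electrode for s in summaries
            ],
            "bursts_per_5min": [s.bursts_per_5min for s in summaries],
        }
    )
    df.to_csv(path, index=False)
    return Path(path)


def presets_to_yaml(path: str | Path, presets: dict[tuple[str, float], InjuryPreset]) -> Path:
    payload = [asdict(p) for p in presets.values()]
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))
    return Path(path)


def presets_from_yaml(path: str | Path) -> dict[tuple[str, float], InjuryPreset]:
    payload = yaml.safe_load(Path(path).read_text())
    presets = {}
    for entry in payload:
        cond = InjuryCondition(**entry.pop("condition"))
        presets[(cond.label, cond.timepoint_h)] = InjuryPreset(condition=cond, **entry)
    return presets
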
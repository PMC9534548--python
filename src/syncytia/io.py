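"""Readers and writers for the pipeline's on-disk formats.

CSV is UTF-8, comma-separated with a header row.  Images travel as one
16-bit TIFF per channel.  Cell graphs are JSON documents; every CLI run
writes a JSON manifest recording inputs, parameters and the seed.
"""

from __future__ import annotations

import json
import platform
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

from .core import CellGraph, ConcentrationState
from .dye_exchange import EventTable
from .frap import FrapTrace
from .rescue import GrowthPlate

__all__ = [
    "read_frap_trace",
    "write_frap_trace",
    "read_event_table",
    "write_event_table",
    "read_growth_plate",
    "write_growth_plate",
    "read_channel_tiff",
    "write_channel_tiff",
    "read_cell_graph",
    "write_cell_graph",
    "write_states_csv",
    "read_states_csv",
    "write_manifest",
]


def write_frap_trace(path, trace: FrapTrace) -> None:
    df = pd.DataFrame({"time_min": trace.times, "signal": trace.signal})
    if trace.reference is not None:
        df["reference"] = trace.reference
    df["post_bleach"] = (np.arange(len(df)) >= trace.bleach_index).astype(int)
    df.to_csv(path, index=False)


def read_frap_trace(path) -> FrapTrace:
    df = pd.read_csv(path)
    for col in ("time_min", "signal", "post_bleach"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    post = df["post_bleach"].to_numpy().astype(bool)
    if not post.any():
        raise ValueError(f"{path}: no post-bleach samples flagged")
    return FrapTrace(
        times=df["time_min"].to_numpy(),
        signal=df["signal"].to_numpy(),
        bleach_index=int(np.argmax(post)),
        reference=df["reference"].to_numpy() if "reference" in df.columns else None,
    )


def write_event_table(path, table: EventTable) -> None:
    out = table.events[["channel_A", "channel_B"]].copy()
    out["source"] = table.source
    out.to_csv(path, index=False)


def read_event_table(path) -> EventTable:
    df = pd.read_csv(path)
    missing = {"channel_A", "channel_B"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    source = str(df["source"].iloc[0]) if "source" in df.columns and len(df) else "co_culture"
    return EventTable(df[["channel_A", "channel_B"]], source=source)


def write_growth_plate(path, plate: GrowthPlate) -> None:
    plate.wells.to_csv(path, index=False)


def read_growth_plate(path) -> GrowthPlate:
    return GrowthPlate(pd.read_csv(path))


def write_channel_tiff(path, image: np.ndarray, pixel_size: float = 1.0) -> None:
    """16-bit TIFF with the pixel size (um) in the image description."""
    arr = np.asarray(image)
    arr16 = np.clip(np.rint(arr), 0, 65535).astype(np.uint16)
    tifffile.imwrite(
        path, arr16, description=json.dumps({"pixel_size_um": pixel_size})
    )


def read_channel_tiff(path) -> tuple[np.ndarray, float]:
    with tifffile.TiffFile(path) as tif:
        arr = tif.asarray().astype(float)
        pixel_size = 1.0
        desc = tif.pages[0].description
        if desc:
            try:
                pixel_size = float(json.loads(desc).get("pixel_size_um", 1.0))
            except (ValueError, AttributeError):
                pass
    return arr, pixel_size


def write_cell_graph(path, graph: CellGraph) -> None:
    Path(path).write_text(graph.to_json())


def read_cell_graph(path) -> CellGraph:
    return CellGraph.from_json(Path(path).read_text())


def write_states_csv(path, graph: CellGraph, states: Sequence[ConcentrationState]) -> None:
    rows = [
        {"time": s.time, "cell_id": cell.id, "concentration": s.concentrations[i]}
        for s in states
        for i, cell in enumerate(graph.cells)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_states_csv(path, graph: CellGraph) -> list[ConcentrationState]:
    df = pd.read_csv(path)
    states = []
    for t, grp in df.groupby("time", sort=True):
        conc = np.empty(len(graph))
        for _, row in grp.iterrows():
            conc[graph.index_of(row["cell_id"])] = row["concentration"]
        states.append(ConcentrationState(time=float(t), concentrations=conc))
    return states


def write_manifest(path, *, subcommand: str, seed: int | None, inputs: dict, params: dict) -> None:
    from . import __version__

    doc = {
        "tool": "syncytia",
        "version": __version__,
        "python": platform.python_version(),
        "subcommand": subcommand,
        "seed": seed,
        "inputs": {k: str(v) for k, v in inputs.items()},
        "parameters": params,
    }
    Path(path).write_text(json.dumps(doc, indent=1, default=str))
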
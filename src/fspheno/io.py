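"""Plain-text readers and writers for the pipeline's tables and hypnograms.

All tabular outputs are UTF-8 delimited text (comma-separated, dot
decimal).  Hypnogram files carry their epoch duration and latency origin in
``#``-prefixed header lines above the ``epoch_index,state`` table.  Images
are multi-page TIFF with channel order (nuclear, c-Fos).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .sleep import Hypnogram

__all__ = [
    "read_behavior_table",
    "write_behavior_table",
    "read_hypnogram",
    "write_hypnogram",
    "read_image",
    "write_image",
]

_BEHAVIOR_COLUMNS = ["animal_id", "group", "test", "day", "variable", "value"]


def write_behavior_table(table: pd.DataFrame, path: str | Path) -> None:
    table[_BEHAVIOR_COLUMNS].to_csv(path, index=False)


def read_behavior_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path)
    missing = set(_BEHAVIOR_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"behavior table missing columns: {sorted(missing)}")
    return table


def write_hypnogram(hypnogram: Hypnogram, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# epoch_seconds={hypnogram.epoch_seconds}\n")
        fh.write(f"# origin={hypnogram.origin}\n")
        fh.write("epoch_index,state\n")
        for i, state in enumerate(hypnogram.states):
            fh.write(f"{i},{state}\n")


def read_hypnogram(path: str | Path) -> Hypnogram:
    meta = {}
    with open(path, encoding="utf-8") as fh:
        lines = fh.readlines()
    body_start = 0
    for line in lines:
        if not line.startswith("#"):
            break
        body_start += 1
        key, _, value = line.lstrip("# ").strip().partition("=")
        meta[key] = value
    df = pd.read_csv(path, skiprows=body_start)
    states = df.sort_values("epoch_index")["state"].to_numpy()
    return Hypnogram(
        states,
        epoch_seconds=float(meta.get("epoch_seconds", 5.0)),
        origin=meta.get("origin", "lights_on"),
    )


def write_image(image: np.ndarray, path: str | Path) -> None:
    """Write a (channels, H, W) stack as a multi-page TIFF."""
    tifffile.imwrite(path, np.asarray(image, dtype=np.float32))


def read_image(path: str | Path) -> np.ndarray:
    return tifffile.imread(path)
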
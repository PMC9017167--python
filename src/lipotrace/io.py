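"""File round-tripping: multi-page TIFF image stacks and CSV tables.

An :class:`~lipotrace.imaging.ImageStack` is written as one multi-page
TIFF per field — one page per channel in the fixed order nuclei,
cytoplasm, DiI, LD (z-stacks write z*channels pages, channel-major) —
with a YAML sidecar recording the pixel size, channel names and slice
count.  Tables (CellRecord, plate maps, WellAggregate, SubjectScores)
travel as headered CSV.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .imaging import CELL_RECORD_COLUMNS, CHANNEL_ORDER, ImageStack


def write_image_stack(path, stack: ImageStack) -> Path:
    """Write a stack to ``<path>.tif`` plus a ``<path>.yaml`` sidecar."""
    path = Path(path)
    tif_path = path.with_suffix(".tif")
    names = [c for c in CHANNEL_ORDER if c in stack.channels]
    names += [c for c in stack.channels if c not in names]
    pages = []
    n_slices = 1
    for name in names:
        arr = np.asarray(stack.channels[name], dtype=np.float32)
        if arr.ndim == 2:
            pages.append(arr[None])
        else:
            pages.append(arr)
            n_slices = arr.shape[0]
    tifffile.imwrite(
        tif_path, np.concatenate(pages, axis=0), photometric="minisblack"
    )
    sidecar = {
        "pixel_size_um": float(stack.pixel_size_um),
        "channels": names,
        "n_slices": n_slices,
    }
    path.with_suffix(".yaml").write_text(yaml.safe_dump(sidecar))
    return tif_path


def read_image_stack(path) -> ImageStack:
    """Read a stack written by :func:`write_image_stack`."""
    path = Path(path)
    sidecar = yaml.safe_load(path.with_suffix(".yaml").read_text())
    data = tifffile.imread(path.with_suffix(".tif"))
    if data.ndim == 2:
        data = data[None]
    n_z = int(sidecar.get("n_slices", 1))
    names = list(sidecar["channels"])
    channels = {}
    for i, name in enumerate(names):
        block = data[i * n_z : (i + 1) * n_z].astype(np.float64)
        channels[name] = block[0] if n_z == 1 else block
    return ImageStack(channels=channels, pixel_size_um=float(sidecar["pixel_size_um"]))


def write_cells_csv(path, cells: pd.DataFrame) -> Path:
    """Write a CellRecord table with the documented fixed column order."""
    path = Path(path)
    cols = [c for c in CELL_RECORD_COLUMNS if c in cells.columns]
    cols += [c for c in cells.columns if c not in cols and c != "ld_droplet_areas_um2"]
    cells[cols].to_csv(path, index=False)
    return path


def read_cells_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_table(path, table: pd.DataFrame) -> Path:
    path = Path(path)
    table.to_csv(path, index=False)
    return path


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path)
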
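"""Readers and writers: multi-page TIFF volumes with JSON sidecars, CSV tables.

A volume is stored as one float32 TIFF page per C-mode slice (page index =
axial index) plus a ``<stem>.json`` sidecar carrying the voxel grid, and —
for phantoms — the generating spec and seed.  Segmentations are 8-bit
stacks with 0=OUTSIDE, 1=PORE, 2=BEAM.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .types import LCParams, Segmentation, Volume, VoxelGrid

__all__ = [
    "write_volume",
    "read_volume",
    "write_segmentation",
    "read_segmentation",
    "write_params_csv",
    "read_repeated_table",
    "write_repeated_table",
]


def _sidecar_path(tiff_path: Path) -> Path:
    return tiff_path.with_suffix(".json")


def _write_sidecar(tiff_path: Path, grid: VoxelGrid, extra: dict | None) -> None:
    doc = {"grid": grid.to_dict()}
    if extra:
        doc.update(extra)
    _sidecar_path(tiff_path).write_text(json.dumps(doc, indent=2))


def _read_sidecar(tiff_path: Path) -> dict:
    sc = _sidecar_path(tiff_path)
    if not sc.exists():
        raise FileNotFoundError(
            f"missing sidecar {sc}: voxel spacing is unknown; create the JSON "
            'sidecar {"grid": {"shape": [...], "spacing": [dx, dy, dz]}} or pass '
            "spacing flags explicitly"
        )
    doc = json.loads(sc.read_text())
    if "grid" not in doc or "spacing" not in doc.get("grid", {}):
        raise ValueError(f"sidecar {sc} lacks grid spacing; supply spacing flags")
    return doc


def write_volume(path: str | Path, volume: Volume, extra_meta: dict | None = None) -> None:
    """Write a volume as a float32 multi-page TIFF (axial index = page)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pages = np.moveaxis(volume.data.astype(np.float32), 2, 0)
    tifffile.imwrite(path, pages, photometric="minisblack")
    _write_sidecar(path, volume.grid, extra_meta)


def read_volume(path: str | Path, spacing: tuple[float, float, float] | None = None) -> Volume:
    """Read a TIFF stack; spacing comes from the sidecar unless given."""
    path = Path(path)
    pages = tifffile.imread(path)
    if pages.ndim == 2:
        pages = pages[None]
    data = np.moveaxis(np.asarray(pages, dtype=np.float64), 0, 2)
    if spacing is None:
        doc = _read_sidecar(path)
        grid = VoxelGrid.from_dict(doc["grid"])
        if tuple(grid.shape) != data.shape:
            raise ValueError(
                f"sidecar grid shape {grid.shape} != TIFF data shape {data.shape}"
            )
    else:
        grid = VoxelGrid(shape=data.shape, spacing=spacing)
    return Volume(data, grid)


def read_volume_meta(path: str | Path) -> dict:
    return _read_sidecar(Path(path))


def write_segmentation(path: str | Path, seg: Segmentation, extra_meta: dict | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pages = np.moveaxis(seg.labels.astype(np.uint8), 2, 0)
    tifffile.imwrite(path, pages, photometric="minisblack")
    _write_sidecar(path, seg.grid, extra_meta)


def read_segmentation(path: str | Path) -> Segmentation:
    path = Path(path)
    pages = tifffile.imread(path)
    if pages.ndim == 2:
        pages = pages[None]
    labels = np.moveaxis(np.asarray(pages, dtype=np.uint8), 0, 2)
    doc = _read_sidecar(path)
    return Segmentation(labels, VoxelGrid.from_dict(doc["grid"]))


def write_params_csv(path: str | Path, params: LCParams | list[LCParams], ids: list | None = None) -> None:
    """One row per scan of all microarchitecture parameters."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    plist = params if isinstance(params, list) else [params]
    rows = [p.to_dict() for p in plist]
    df = pd.DataFrame(rows)
    if ids is not None:
        df.insert(0, "scan_id", ids)
    df.to_csv(path, index=False)


def write_repeated_table(path: str | Path, table: pd.DataFrame) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False)


def read_repeated_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
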
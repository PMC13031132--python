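"""Plain-text/TIFF readers and writers for the pipeline's artefacts."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .tissue import CellContour, SpatialCell

__all__ = [
    "write_channels_tiff",
    "read_channel_tiff",
    "write_contours_csv",
    "read_contours_csv",
    "spatial_table",
    "write_spatial_table",
    "read_gmt",
]


def write_channels_tiff(channels: dict[str, np.ndarray], out_dir: str | Path) -> dict[str, Path]:
    """One single-channel TIFF per channel; returns the written paths."""
    import tifffile

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, img in channels.items():
        p = out_dir / f"{name}.tiff"
        tifffile.imwrite(p, np.asarray(img, dtype=np.float32))
        paths[name] = p
    return paths


def read_channel_tiff(path: str | Path) -> np.ndarray:
    import tifffile

    return tifffile.imread(path)


def write_contours_csv(contours: list[CellContour], path: str | Path) -> None:
    rows = [
        {"cell_id": c.id, "vertex": i, "x": x, "y": y}
        for c in contours
        for i, (x, y) in enumerate(c.vertices)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_contours_csv(path: str | Path) -> list[CellContour]:
    df = pd.read_csv(path)
    contours = []
    for cid, g in df.groupby("cell_id", sort=False):
        g = g.sort_values("vertex")
        contours.append(CellContour.from_vertices(str(cid), g[["x", "y"]].to_numpy()))
    return contours


def spatial_table(cells: list[SpatialCell]) -> pd.DataFrame:
    """Tabulate selected cells (one row per cell, selection order preserved)."""
    return pd.DataFrame([
        {
            "cell_id": sc.contour.id,
            "patient_id": sc.patient_id,
            "d_central": sc.d_central,
            "d_portal": sc.d_portal,
            "S": sc.S,
            "area_px2": sc.contour.area,
            "centroid_x": sc.contour.centroid[0],
            "centroid_y": sc.contour.centroid[1],
        }
        for sc in cells
    ])


def write_spatial_table(cells: list[SpatialCell], path: str | Path) -> None:
    spatial_table(cells).to_csv(path, sep="\t", index=False)


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read pathway membership from a GMT file (name, description, members)."""
    membership: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3 or not parts[0]:
            continue
        membership[parts[0]] = [m for m in parts[2:] if m]
    return membership
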
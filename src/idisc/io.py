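"""Readers and writers for the pipeline's on-disk formats.

Images travel as multi-channel TIFF (one channel per protein, one page
per z-plane), tabular data (clusters, distance records, fiducials, poses,
peaks) as CSV with documented headers, configuration and summaries as
JSON.  Height maps are accepted as floating-point TIFF or CSV grids.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

from .clusters import Cluster, DistanceRecord, ReconstructedImage
from .topology import HeightMap


def write_image(path: str | Path, image: ReconstructedImage) -> None:
    tifffile.imwrite(
        str(path),
        np.asarray(image.data, dtype=np.float32),
        metadata={"pixel_nm": image.pixel_nm, "channels": list(image.channel_names)},
    )


def read_image(
    path: str | Path,
    pixel_nm: float = 20.0,
    channel_names: Sequence[str] | None = None,
    z_step_nm: float | None = None,
) -> ReconstructedImage:
    data = tifffile.imread(str(path))
    if data.ndim == 2:
        data = data[None]
    names = tuple(channel_names) if channel_names else tuple(f"ch{i}" for i in range(data.shape[0]))
    return ReconstructedImage(data, pixel_nm=pixel_nm, channel_names=names, z_step_nm=z_step_nm)


def clusters_to_frame(clusters: Sequence[Cluster]) -> pd.DataFrame:
    rows = []
    for c in clusters:
        cen = list(c.centroid_nm) + [np.nan] * (3 - len(c.centroid_nm))
        rows.append(
            {
                "id": c.id,
                "channel": c.channel,
                "x_nm": cen[0],
                "y_nm": cen[1],
                "z_nm": cen[2],
                "area_nm2": c.area_nm2,
                "volume_nm3": c.volume_nm3,
                "circularity": c.circularity,
            }
        )
    return pd.DataFrame(rows)


def distances_to_frame(records: Sequence[DistanceRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "query_id": [r.query_id for r in records],
            "reference_id": [r.reference_id for r in records],
            "centroid_to_centroid_nm": [r.centroid_to_centroid_nm for r in records],
            "edge_to_edge_nm": [r.edge_to_edge_nm for r in records],
            "contact": [r.contact for r in records],
        }
    )


def read_polyline_csv(path: str | Path) -> np.ndarray:
    """Membrane trace as CSV with columns x_nm, y_nm."""
    df = pd.read_csv(path)
    return df[["x_nm", "y_nm"]].to_numpy(dtype=float)


def read_height_map(path: str | Path, spacing_nm: float) -> HeightMap:
    p = Path(path)
    if p.suffix.lower() in (".tif", ".tiff"):
        z = tifffile.imread(str(p)).astype(float)
    else:
        z = np.loadtxt(p, delimiter=",")
    return HeightMap(z, spacing_nm)


def sha256_of(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_manifest(outdir: str | Path, subcommand: str, params: dict, outputs: Sequence[str | Path]) -> Path:
    """Record what a run produced: parameters, seed, and output checksums."""
    outdir = Path(outdir)
    manifest = {
        "subcommand": subcommand,
        "parameters": params,
        "outputs": {
            str(Path(p).name): sha256_of(p) for p in outputs if Path(p).exists()
        },
    }
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str))
    return path
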
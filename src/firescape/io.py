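"""Raster and table I/O.

Rasters are written as single-band TIFF (float32 continuous, int16
categorical, uint8 binary) with the grid geometry, nodata sentinel and
kind stored as JSON in the TIFF ImageDescription tag, so files round-trip
without sidecars.  Full GeoTIFF CRS tags are out of scope: the analysis
grid is an abstract equal-area grid and real-world reprojection is a
preprocessing step.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from firescape.grid import BINARY, CATEGORICAL, CONTINUOUS, GridGeometry, Raster

_DTYPES = {CONTINUOUS: np.float32, CATEGORICAL: np.int16, BINARY: np.uint8}


def write_raster(raster: Raster, path: str | Path) -> None:
    geom = raster.geometry
    meta = {
        "n_rows": geom.n_rows,
        "n_cols": geom.n_cols,
        "cell_size": geom.cell_size,
        "origin": list(geom.origin),
        "kind": raster.kind,
        "nodata": None if isinstance(raster.nodata, float) and np.isnan(raster.nodata) else raster.nodata,
        "name": raster.name,
    }
    data = raster.values.astype(_DTYPES[raster.kind])
    tifffile.imwrite(str(path), data, description=json.dumps(meta))


def read_raster(path: str | Path) -> Raster:
    with tifffile.TiffFile(str(path)) as tf:
        page = tf.pages[0]
        desc = page.description or "{}"
        data = page.asarray()
    meta = json.loads(desc)
    geom = GridGeometry(
        n_rows=meta["n_rows"],
        n_cols=meta["n_cols"],
        cell_size=meta["cell_size"],
        origin=tuple(meta["origin"]),
    )
    nodata = meta["nodata"]
    if nodata is None:
        nodata = np.nan
    return Raster(geom, data, kind=meta["kind"], nodata=nodata, name=meta.get("name", ""))


def read_fire_csv(path: str | Path) -> pd.DataFrame:
    """Read an active-fire CSV in the MCD14ML (or synthetic) dialect."""
    return pd.read_csv(path)


def write_fire_csv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)
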
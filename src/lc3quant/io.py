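"""Reading and writing image rasters and pipeline tables."""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .image import MultiChannelImage

#: Comment line prepended to every CSV the pipeline writes.
CSV_HEADER = "# coordinates: (row, col), 0-based, pixel-centered"


def read_raster(path: str | Path) -> np.ndarray:
    """Read a single-channel 2D raster from TIFF or PNG as float64."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image file not found: {path}")
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = iio.imread(path)
    arr = np.asarray(arr)
    if arr.ndim == 3 and arr.shape[-1] in (3, 4):  # collapse accidental RGB
        arr = arr[..., 0]
    if arr.ndim != 2:
        raise ValueError(f"{path}: expected a 2D single-channel raster, got shape {arr.shape}")
    return arr.astype(np.float64)


def write_raster_16bit(path: str | Path, raster: np.ndarray) -> None:
    """Write a raster as 16-bit grayscale TIFF (values clipped to [0, 65535])."""
    data = np.clip(np.rint(np.asarray(raster, dtype=np.float64)), 0, 65535).astype(np.uint16)
    tifffile.imwrite(Path(path), data)


def load_multichannel(
    name: str,
    blue: str | Path,
    green: str | Path,
    red: str | Path | None = None,
    bit_depth: int = 16,
) -> MultiChannelImage:
    """Load per-channel files into a :class:`MultiChannelImage`."""
    return MultiChannelImage(
        blue=read_raster(blue),
        green=read_raster(green),
        red=read_raster(red) if red is not None else None,
        name=name,
        bit_depth=bit_depth,
    )


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a pipeline CSV with the coordinate-convention header comment."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        fh.write(CSV_HEADER + "\n")
        df.to_csv(fh, index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a CSV written by :func:`write_table`."""
    return pd.read_csv(path, comment="#")
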
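"""Multi-channel image container used throughout the pipeline.

Convention: rasters are 2D arrays indexed (row, col), 0-based, pixel-centered.
Blue carries the DAPI nuclear stain, green the LC3/GFP signal, red the mCherry
signal of the tandem reporter (or a second colocalization marker).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class MultiChannelImage:
    """Registered 2D intensity rasters for the blue/green/red channels.

    Parameters
    ----------
    blue, green : ndarray
        Nonnegative 2D intensity rasters of identical shape.
    red : ndarray or None
        Optional third channel; required for tandem and colocalization work.
    name : str
        Identifier used in all tabular outputs.
    bit_depth : int
        Nominal acquisition depth, 8 or 16.  Rasters are held as float64
        internally regardless.
    """

    blue: np.ndarray
    green: np.ndarray
    red: np.ndarray | None = None
    name: str = "image"
    bit_depth: int = 16

    def __post_init__(self) -> None:
        self.blue = np.asarray(self.blue, dtype=np.float64)
        self.green = np.asarray(self.green, dtype=np.float64)
        if self.red is not None:
            self.red = np.asarray(self.red, dtype=np.float64)
        channels = [c for c in (self.blue, self.green, self.red) if c is not None]
        shapes = {c.shape for c in channels}
        if len(shapes) != 1 or any(c.ndim != 2 for c in channels):
            raise ValueError(
                f"{self.name}: channel shapes must be equal 2D rasters, got {shapes}"
            )
        for label, c in zip(("blue", "green", "red"), (self.blue, self.green, self.red)):
            if c is not None and np.any(c < 0):
                raise ValueError(f"{self.name}: negative intensities in {label} channel")
        if self.bit_depth not in (8, 16):
            raise ValueError(f"{self.name}: bit_depth must be 8 or 16, got {self.bit_depth}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.blue.shape

    def channel(self, name: str) -> np.ndarray:
        """Return a channel raster by name ('blue' | 'green' | 'red')."""
        if name not in ("blue", "green", "red"):
            raise ValueError(f"unknown channel {name!r}")
        raster = getattr(self, name)
        if raster is None:
            raise ValueError(f"{self.name}: channel {name!r} not present")
        return raster
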
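from __future__ import annotations

import numpy as np
import pytest

from lc3quant import SyntheticSpec, NoiseModel


@pytest.fixture
def small_spec() -> SyntheticSpec:
    """A quick-to-render field: 256^2, 5 nuclei, one clipped by the border."""
    return SyntheticSpec(
        image_shape=(256, 256),
        n_nuclei=5,
        n_border_nuclei=1,
        nucleus_radius_mean=16.0,
        nucleus_radius_sd=1.5,
        puncta_per_cell_mean=4.0,
        cytoplasm_reach=40.0,
        seed=11,
    )


@pytest.fixture
def clean_spec(small_spec) -> SyntheticSpec:
    """Same field without noise (for exact-recovery checks)."""
    import dataclasses

    return dataclasses.replace(small_spec, noise_model=NoiseModel(kind="none"))


def make_spot_field(
    shape=(128, 128),
    centers=((64, 64),),
    sigmas=(3.0,),
    amplitude=800.0,
    background=100.0,
) -> np.ndarray:
    """Render isolated Gaussian spots on a flat background (no generator code)."""
    raster = np.full(shape, float(background))
    yy, xx = np.mgrid[0: shape[0], 0: shape[1]]
    for (r, c), s in zip(centers, sigmas):
        raster += amplitude * np.exp(-((yy - r) ** 2 + (xx - c) ** 2) / (2.0 * s**2))
    return raster


def disc_mask(shape, center, radius) -> np.ndarray:
    yy, xx = np.mgrid[0: shape[0], 0: shape[1]]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2
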
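"""LC3 puncta detection by scale-space Laplacian-of-Gaussian blob detection.

Puncta are bright, roughly Gaussian spots of unknown (sub-resolution to a few
px) size.  The detector builds scale-normalized LoG responses
``-sigma^2 * (Laplacian of Gaussian at sigma) * image`` over a grid of scales,
takes local maxima in the joint (row, col, scale) neighborhood above a
threshold, and greedily prunes overlapping detections keeping the stronger
response.  The detecting scale estimates the spot size: a punctum's radius is
``radius_coeff * sigma`` (default sqrt(2), the scale-selection optimum for an
ideal Gaussian spot) and its score is the area of that circle.  Because
crowded vesicles make per-spot counting unreliable, total puncta AREA per
cell is the headline readout.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy import ndimage as ndi

from .segmentation import CellCount

#: Default radius-per-sigma coefficient (LoG optimum for a Gaussian spot).
DEFAULT_RADIUS_COEFF = math.sqrt(2.0)

PUNCTA_COLUMNS = [
    "row", "col", "sigma", "response", "radius", "area",
    "mean_green", "mean_red", "label",
]


@dataclass(frozen=True)
class Punctum:
    """One detected blob.

    ``row``/``col`` are the pixel of the scale-space maximum, ``sigma`` the
    detecting kernel scale, ``response`` the scale-normalized LoG magnitude.
    ``radius``/``area`` and the per-channel disk means are filled by
    :func:`score_puncta`; ``label`` by the tandem classifier.
    """

    row: int
    col: int
    sigma: float
    response: float
    radius: float = math.nan
    area: float = math.nan
    mean_green: float = math.nan
    mean_red: float = math.nan
    label: str = "unclassified"


@dataclass(frozen=True)
class SampleSummary:
    """Per-image aggregates of the puncta readout."""

    image: str
    effective_cell_count: float
    puncta_count: int
    total_puncta_area: float
    puncta_area_per_cell: float
    n_autophagosome: int
    n_autolysosome: int


def puncta_table(puncta: list[Punctum], image: str | None = None) -> pd.DataFrame:
    """Flatten a puncta list to a DataFrame (one row per punctum)."""
    df = pd.DataFrame([dataclasses.asdict(p) for p in puncta], columns=PUNCTA_COLUMNS)
    if image is not None:
        df.insert(0, "image", image)
    return df


def despeckle(raster: np.ndarray, window: int = 3) -> np.ndarray:
    """Median filter for speckle (salt impulse) removal.

    Each output pixel is the median of its ``window x window`` neighborhood;
    pixels near the edge use the truncated (in-image) neighborhood.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError(f"median window must be odd and >= 1, got {window}")
    raster = np.asarray(raster, dtype=np.float64)
    if window == 1:
        return raster.copy()
    k = window // 2
    padded = np.pad(raster, k, mode="constant", constant_values=np.nan)
    windows = sliding_window_view(padded, (window, window))
    return np.nanmedian(windows.reshape(raster.shape + (-1,)), axis=-1)


def _log_stack(img: np.ndarray, sigmas: np.ndarray) -> np.ndarray:
    return np.stack([-(s**2) * ndi.gaussian_laplace(img, s) for s in sigmas])


def _disk_overlap_fraction(r1, c1, rad1, r2, c2, rad2) -> float:
    """Intersection area of two discs divided by the smaller disc's area."""
    d = math.hypot(r1 - r2, c1 - c2)
    if d >= rad1 + rad2:
        return 0.0
    small, large = min(rad1, rad2), max(rad1, rad2)
    if d <= large - small:
        return 1.0
    # standard lens area
    a1 = rad1**2 * math.acos((d**2 + rad1**2 - rad2**2) / (2 * d * rad1))
    a2 = rad2**2 * math.acos((d**2 + rad2**2 - rad1**2) / (2 * d * rad2))
    a3 = 0.5 * math.sqrt(
        max(0.0, (-d + rad1 + rad2) * (d + rad1 - rad2) * (d - rad1 + rad2) * (d + rad1 + rad2))
    )
    return (a1 + a2 - a3) / (math.pi * small**2)


def detect_blobs_log(
    raster: np.ndarray,
    sigma_min: float = 1.0,
    sigma_max: float = 5.0,
    n_scales: int = 10,
    threshold_rel: float = 0.1,
    threshold_abs: float | None = None,
    overlap_max: float = 0.5,
) -> list[Punctum]:
    """Detect bright blobs as scale-space LoG maxima.

    Scales are spaced linearly over ``[sigma_min, sigma_max]``.  A candidate is
    kept when its scale-normalized response exceeds the threshold —
    ``threshold_abs`` if given, else ``threshold_rel * raster.max()`` so 8- and
    16-bit inputs behave alike — and is a strict-or-equal maximum of its 3x3x3
    (scale, row, col) neighborhood.  Candidates are ordered by
    (response desc, row, col, sigma) — a deterministic tie-break — and pairs
    whose disk overlap fraction (radius sqrt(2) sigma, relative to the smaller
    disk) exceeds ``overlap_max`` keep only the stronger response.
    """
    if not 0 < sigma_min <= sigma_max:
        raise ValueError(f"need 0 < sigma_min <= sigma_max, got ({sigma_min}, {sigma_max})")
    if n_scales < 1:
        raise ValueError("n_scales must be >= 1")
    img = np.asarray(raster, dtype=np.float64)
    if threshold_abs is None:
        threshold_abs = threshold_rel * float(img.max()) if img.size else 0.0
    if threshold_abs <= 0:
        raise ValueError("detection threshold must be > 0")

    sigmas = np.linspace(sigma_min, sigma_max, n_scales)
    stack = _log_stack(img, sigmas)
    local_max = ndi.maximum_filter(stack, size=(3, 3, 3), mode="nearest")
    candidates = np.argwhere((stack == local_max) & (stack > threshold_abs))
    if len(candidates) == 0:
        return []
    responses = stack[tuple(candidates.T)]
    order = np.lexsort((sigmas[candidates[:, 0]], candidates[:, 2], candidates[:, 1], -responses))
    candidates, responses = candidates[order], responses[order]

    kept: list[Punctum] = []
    for (si, r, c), resp in zip(candidates, responses):
        sigma = float(sigmas[si])
        rad = math.sqrt(2.0) * sigma
        overlaps = any(
            _disk_overlap_fraction(r, c, rad, p.row, p.col, math.sqrt(2.0) * p.sigma)
            > overlap_max
            for p in kept
        )
        if not overlaps:
            kept.append(Punctum(row=int(r), col=int(c), sigma=sigma, response=float(resp)))
    return kept


def suppress_masked_blobs(
    puncta: list[Punctum],
    nuclei_labels: np.ndarray | None = None,
    exclusion_mask: np.ndarray | None = None,
) -> list[Punctum]:
    """Drop blobs whose center lies inside a nucleus or an exclusion halo.

    Blobs inside nuclei are nuclear texture, not cytoplasmic LC3; blobs inside
    a bright-cell halo are indistinguishable from the saturating signal.
    Membership is judged by the center pixel.
    """
    kept = []
    for p in puncta:
        if nuclei_labels is not None and nuclei_labels[p.row, p.col] != 0:
            continue
        if exclusion_mask is not None and exclusion_mask[p.row, p.col]:
            continue
        kept.append(p)
    return kept


def _disk_mean(raster: np.ndarray, row: int, col: int, radius: float) -> float:
    h, w = raster.shape
    reach = int(math.ceil(radius))
    rlo, rhi = max(0, row - reach), min(h, row + reach + 1)
    clo, chi = max(0, col - reach), min(w, col + reach + 1)
    yy = np.arange(rlo, rhi)[:, None] - row
    xx = np.arange(clo, chi)[None, :] - col
    inside = (yy**2 + xx**2) <= radius**2
    if not inside.any():
        return float(raster[row, col])
    return float(raster[rlo:rhi, clo:chi][inside].mean())


def score_puncta(
    puncta: list[Punctum],
    green: np.ndarray | None = None,
    red: np.ndarray | None = None,
    radius_coeff: float = DEFAULT_RADIUS_COEFF,
) -> list[Punctum]:
    """Assign each blob its circle area and per-channel disk mean intensities.

    radius = radius_coeff * sigma and area = pi * radius^2; the disk is
    clipped to the image for the intensity means.
    """
    if radius_coeff <= 0:
        raise ValueError("radius_coeff must be > 0")
    scored = []
    for p in puncta:
        radius = radius_coeff * p.sigma
        scored.append(dataclasses.replace(
            p,
            radius=radius,
            area=math.pi * radius**2,
            mean_green=(_disk_mean(green, p.row, p.col, radius) if green is not None else math.nan),
            mean_red=(_disk_mean(red, p.row, p.col, radius) if red is not None else math.nan),
        ))
    return scored


def summarize_sample(puncta: list[Punctum], cell_count: CellCount, image: str = "image") -> SampleSummary:
    """Aggregate one image: puncta count, total area, area per effective cell."""
    effective = cell_count.total_effective
    if effective <= 0:
        raise ValueError(f"{image}: effective cell count must be > 0, got {effective}")
    total_area = float(sum(p.area for p in puncta))
    if puncta and any(math.isnan(p.area) for p in puncta):
        raise ValueError("puncta must be scored (score_puncta) before summarizing")
    return SampleSummary(
        image=image,
        effective_cell_count=effective,
        puncta_count=len(puncta),
        total_puncta_area=total_area,
        puncta_area_per_cell=total_area / effective,
        n_autophagosome=sum(p.label == "autophagosome" for p in puncta),
        n_autolysosome=sum(p.label == "autolysosome" for p in puncta),
    )
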
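"""Pixelwise Pearson colocalization between two fluorescence channels."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class ColocalizationResult:
    """Per-ROI Pearson coefficients plus group mean and SD.

    ``records`` has one row per successfully measured ROI (name, r, n_pixels);
    ``skipped`` lists (name, reason) for ROIs where r was undefined.
    """

    records: pd.DataFrame
    skipped: list[tuple[str, str]] = field(default_factory=list)

    @property
    def mean_r(self) -> float:
        return float(self.records["r"].mean()) if len(self.records) else float("nan")

    @property
    def sd_r(self) -> float:
        if len(self.records) < 2:
            return float("nan")
        return float(self.records["r"].std(ddof=1))


def pearson_coefficient(a: np.ndarray, b: np.ndarray, roi: np.ndarray | None = None) -> float:
    """Pearson correlation of two rasters over an ROI.

    r = sum((a - abar)(b - bbar)) / sqrt(sum((a - abar)^2) sum((b - bbar)^2))
    over the ROI pixels (the whole raster when ``roi`` is None).  Requires at
    least 2 ROI pixels; raises ``correlation undefined`` when a channel is
    constant on the ROI (zero denominator).
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"raster shapes differ: {a.shape} vs {b.shape}")
    if roi is not None:
        roi = np.asarray(roi, dtype=bool)
        if roi.shape != a.shape:
            raise ValueError(f"ROI shape {roi.shape} does not match rasters {a.shape}")
        a, b = a[roi], b[roi]
    else:
        a, b = a.ravel(), b.ravel()
    if a.size < 2:
        raise ValueError(f"need at least 2 ROI pixels, got {a.size}")
    da = a - a.mean()
    db = b - b.mean()
    denom = np.sqrt((da @ da) * (db @ db))
    if denom == 0:
        raise ValueError("correlation undefined: constant channel on ROI")
    return float(np.clip((da @ db) / denom, -1.0, 1.0))


def colocalize_dataset(
    pairs: list[tuple[str, np.ndarray, np.ndarray]] | list[tuple[str, np.ndarray, np.ndarray, np.ndarray | None]],
    roi_masks: dict[str, np.ndarray] | None = None,
) -> ColocalizationResult:
    """Pearson r per image pair, with per-ROI failures skipped and logged.

    ``pairs`` holds (name, raster A, raster B) tuples, optionally with a
    fourth ROI-mask element; ``roi_masks`` may alternatively map names to
    masks.  Returns per-ROI r values plus the group mean and SD.
    """
    if not pairs:
        raise ValueError("at least one image pair is required")
    rows, skipped = [], []
    for pair in pairs:
        name, a, b = pair[0], pair[1], pair[2]
        roi = pair[3] if len(pair) > 3 else None
        if roi is None and roi_masks is not None:
            roi = roi_masks.get(name)
        try:
            r = pearson_coefficient(a, b, roi)
        except ValueError as exc:
            skipped.append((name, str(exc)))
            continue
        n_pixels = int(np.count_nonzero(roi)) if roi is not None else int(np.asarray(a).size)
        rows.append(dict(name=name, r=r, n_pixels=n_pixels))
    records = pd.DataFrame(rows, columns=["name", "r", "n_pixels"])
    return ColocalizationResult(records=records, skipped=skipped)
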
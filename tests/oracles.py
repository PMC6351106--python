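"""Independent reference implementations used to check the pipeline.

These deliberately use naive, direct formulations (explicit loops, direct
histogram sums, breadth-first flood fill) and never call the code paths they
verify.
"""

from __future__ import annotations

import math
from collections import deque

import numpy as np


def brute_force_otsu(image: np.ndarray, nbins: int = 256) -> tuple[float, int]:
    """Exhaustive-search Otsu threshold over an ``nbins`` histogram.

    Evaluates the between-class variance w0 * w1 * (mu0 - mu1)^2 for every
    candidate split of the histogram (same binning as the implementation:
    ``nbins`` equal bins spanning the image's own min-max range) and returns
    (bin center of the best split, split index).  First maximum wins on ties.
    """
    image = np.asarray(image, dtype=np.float64).ravel()
    counts, edges = np.histogram(image, bins=nbins, range=(image.min(), image.max()))
    centers = (edges[:-1] + edges[1:]) / 2.0
    best_var, best_idx = -1.0, 0
    total = counts.sum()
    for split in range(nbins - 1):
        w0 = counts[: split + 1].sum()
        w1 = total - w0
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (counts[: split + 1] * centers[: split + 1]).sum() / w0
        mu1 = (counts[split + 1:] * centers[split + 1:]).sum() / w1
        var = (w0 / total) * (w1 / total) * (mu0 - mu1) ** 2
        if var > best_var:
            best_var, best_idx = var, split
    return float(centers[best_idx]), best_idx


def flood_fill_components(mask: np.ndarray) -> np.ndarray:
    """4-connectivity connected-component labeling via breadth-first search."""
    mask = np.asarray(mask, dtype=bool)
    labels = np.zeros(mask.shape, dtype=np.int32)
    current = 0
    h, w = mask.shape
    for r0 in range(h):
        for c0 in range(w):
            if not mask[r0, c0] or labels[r0, c0]:
                continue
            current += 1
            queue = deque([(r0, c0)])
            labels[r0, c0] = current
            while queue:
                r, c = queue.popleft()
                for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < h and 0 <= cc < w and mask[rr, cc] and not labels[rr, cc]:
                        labels[rr, cc] = current
                        queue.append((rr, cc))
    return labels


def naive_truncated_median(raster: np.ndarray, window: int) -> np.ndarray:
    """Median filter with truncated (in-image) neighborhoods, pixel by pixel."""
    raster = np.asarray(raster, dtype=np.float64)
    k = window // 2
    h, w = raster.shape
    out = np.empty_like(raster)
    for r in range(h):
        for c in range(w):
            patch = raster[max(0, r - k): r + k + 1, max(0, c - k): c + k + 1]
            out[r, c] = np.median(patch)
    return out


def match_detections(
    truth_centers: np.ndarray,
    detected_centers: np.ndarray,
    tolerance: float = 3.0,
) -> list[tuple[int, int]]:
    """Greedy one-to-one matching of detections to truth by distance.

    Returns (truth index, detection index) pairs with center distance within
    ``tolerance`` pixels, closest pairs first.
    """
    if len(truth_centers) == 0 or len(detected_centers) == 0:
        return []
    truth_centers = np.asarray(truth_centers, dtype=float)
    detected_centers = np.asarray(detected_centers, dtype=float)
    d = np.linalg.norm(truth_centers[:, None, :] - detected_centers[None, :, :], axis=-1)
    pairs = sorted(
        ((d[i, j], i, j) for i in range(d.shape[0]) for j in range(d.shape[1]) if d[i, j] <= tolerance)
    )
    used_t, used_d, matched = set(), set(), []
    for _, i, j in pairs:
        if i in used_t or j in used_d:
            continue
        used_t.add(i)
        used_d.add(j)
        matched.append((i, j))
    return matched


def pooled_t_by_hand(a, b) -> tuple[float, int]:
    """Pooled two-sample t statistic and df from the textbook formula."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n1, n2 = len(a), len(b)
    s2 = (
        ((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()
    ) / (n1 + n2 - 2)
    t = (a.mean() - b.mean()) / math.sqrt(s2 * (1 / n1 + 1 / n2))
    return t, n1 + n2 - 2
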
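"""Tandem mCherry-GFP-LC3 classification into autophagosomes and autolysosomes.

The tandem reporter exploits GFP quenching at lysosomal pH: a punctum positive
in both green and red is an autophagosome, a red-only punctum is an
autolysosome.  Detection runs on the red channel (mCherry persists in both
compartments, so red is the superset); each red punctum is then scored
green-positive when its disk mean green intensity exceeds a multiple of the
image's green background.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass

import numpy as np

from .detection import Punctum

AUTOPHAGOSOME = "autophagosome"
AUTOLYSOSOME = "autolysosome"


@dataclass(frozen=True)
class TandemClassificationConfig:
    """Green-positivity rule for tandem puncta.

    A punctum is an autophagosome iff mean_green > green_positivity_factor * b,
    where b is the green background: the median over pixels not covered by any
    punctum disk and not excluded (``median_outside_puncta``), or a caller-set
    constant (``fixed_value``).
    """

    green_positivity_factor: float = 2.0
    background_estimator: str = "median_outside_puncta"  # or "fixed_value"
    fixed_background: float | None = None

    def __post_init__(self) -> None:
        if self.green_positivity_factor <= 0:
            raise ValueError("green_positivity_factor must be > 0")
        if self.background_estimator not in ("median_outside_puncta", "fixed_value"):
            raise ValueError(f"unknown background_estimator {self.background_estimator!r}")
        if self.background_estimator == "fixed_value" and self.fixed_background is None:
            raise ValueError("fixed_value estimator requires fixed_background")


def _coverage_mask(shape, puncta: list[Punctum]) -> np.ndarray:
    cover = np.zeros(shape, dtype=bool)
    h, w = shape
    for p in puncta:
        radius = p.radius if not math.isnan(p.radius) else math.sqrt(2.0) * p.sigma
        reach = int(math.ceil(radius))
        rlo, rhi = max(0, p.row - reach), min(h, p.row + reach + 1)
        clo, chi = max(0, p.col - reach), min(w, p.col + reach + 1)
        yy = np.arange(rlo, rhi)[:, None] - p.row
        xx = np.arange(clo, chi)[None, :] - p.col
        cover[rlo:rhi, clo:chi] |= (yy**2 + xx**2) <= radius**2
    return cover


def estimate_green_background(
    green: np.ndarray,
    puncta: list[Punctum],
    exclusion_mask: np.ndarray | None = None,
) -> float:
    """Median green intensity outside all punctum disks and excluded regions."""
    outside = ~_coverage_mask(green.shape, puncta)
    if exclusion_mask is not None:
        outside &= ~exclusion_mask
    if not outside.any():
        raise ValueError("background undefined: no pixels outside puncta and exclusions")
    return float(np.median(np.asarray(green, dtype=np.float64)[outside]))


def classify_tandem_puncta(
    puncta: list[Punctum],
    green: np.ndarray,
    config: TandemClassificationConfig = TandemClassificationConfig(),
    exclusion_mask: np.ndarray | None = None,
) -> tuple[list[Punctum], int, int]:
    """Label red-channel puncta and return (labeled puncta, n_AP, n_AL).

    Every punctum receives exactly one of the two labels; puncta must carry a
    disk mean green intensity (see :func:`~lc3quant.detection.score_puncta`).
    """
    if config.background_estimator == "fixed_value":
        background = float(config.fixed_background)  # type: ignore[arg-type]
    else:
        background = estimate_green_background(green, puncta, exclusion_mask)
    cutoff = config.green_positivity_factor * background

    labeled = []
    for p in puncta:
        if math.isnan(p.mean_green):
            raise ValueError("puncta must carry mean_green; run score_puncta first")
        label = AUTOPHAGOSOME if p.mean_green > cutoff else AUTOLYSOSOME
        labeled.append(dataclasses.replace(p, label=label))
    n_ap = sum(p.label == AUTOPHAGOSOME for p in labeled)
    return labeled, n_ap, len(labeled) - n_ap
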
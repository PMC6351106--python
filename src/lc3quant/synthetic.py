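"""Seeded synthetic fluorescence microscopy fields with exact ground truth.

The generator emulates the imaging conditions the quantification pipeline was
designed for: DAPI-stained nuclei in the blue channel (including nuclei clipped
by the image border and abnormally bright cells), diffraction-limited LC3
puncta rendered as isotropic 2D Gaussians of known scale, tandem-reporter
two-channel puncta with a known autolysosome fraction, and simple sensor noise
(Gaussian, Poisson, or salt-impulse "speckle").  Every rendered object is
recorded in a :class:`SyntheticGroundTruth`, so detection, counting and
classification can be scored against exact truth without microscopy data.

Determinism contract: an identical spec (including its seed) reproduces
bit-identical rasters and ground truth.  Nucleus placement and puncta placement
consume independent seeded streams, so the nuclei channel of a spec does not
change when puncta parameters do.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .image import MultiChannelImage
from .io import write_raster_16bit

AUTOPHAGOSOME = "autophagosome"
AUTOLYSOSOME = "autolysosome"

_NOISE_KINDS = ("none", "gaussian", "poisson", "speckle")
_PLACEMENT_TRIES = 500


class PlacementError(RuntimeError):
    """An object could not be placed within the retry budget."""


@dataclass(frozen=True)
class NoiseModel:
    """Sensor noise applied to each rendered channel.

    kind
        One of ``none``, ``gaussian`` (additive, ``gaussian_sd``), ``poisson``
        (shot noise at ``poisson_gain`` photons per intensity unit) or
        ``speckle`` (salt impulses: isolated saturating pixels at
        ``speckle_density``, removable with a small median filter).
    """

    kind: str = "gaussian"
    gaussian_sd: float = 20.0
    speckle_density: float = 0.002
    speckle_value: float | None = None  # default: 5x the clean raster max
    poisson_gain: float = 1.0

    def validate(self) -> list[str]:
        errors = []
        if self.kind not in _NOISE_KINDS:
            errors.append(f"noise kind must be one of {_NOISE_KINDS}, got {self.kind!r}")
        if self.gaussian_sd < 0:
            errors.append("gaussian_sd must be >= 0")
        if not 0 <= self.speckle_density <= 1:
            errors.append("speckle_density must be in [0, 1]")
        if self.poisson_gain <= 0:
            errors.append("poisson_gain must be > 0")
        return errors


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic condition.

    Geometry is expressed in pixels throughout (no physical pixel size is
    assumed).  Defaults describe a typical wide-field 512x512 field of view:
    a dozen nuclei of radius ~18 px, a handful clipped by the border, ~6
    puncta per cell with sub-resolution scales of 2-4 px, and mild additive
    Gaussian noise.
    """

    image_shape: tuple[int, int] = (512, 512)
    n_nuclei: int = 12
    nucleus_radius_mean: float = 18.0
    nucleus_radius_sd: float = 2.0
    n_border_nuclei: int = 2
    puncta_per_cell_mean: float = 6.0
    punctum_sigma_range: tuple[float, float] = (2.0, 4.0)
    punctum_amplitude: float = 800.0
    autolysosome_fraction: float = 0.3
    n_bright_cells: int = 0
    bright_amplitude_factor: float = 20.0  # x punctum_amplitude, diffuse green
    background_level: float = 100.0
    nucleus_amplitude: float = 1000.0
    edge_taper: float = 2.0  # px of cosine taper at the nucleus rim
    min_puncta_separation: float = 8.0  # px between punctum centers
    cytoplasm_reach: float = 60.0  # px: puncta stay this close to their cell
    noise_model: NoiseModel = field(default_factory=NoiseModel)
    seed: int = 0

    def validate(self) -> list[str]:
        errors = []
        rows, cols = self.image_shape
        if rows < 16 or cols < 16:
            errors.append(f"image_shape too small: {self.image_shape}")
        for name in ("n_nuclei", "n_border_nuclei", "n_bright_cells"):
            if getattr(self, name) < 0:
                errors.append(f"{name} must be >= 0")
        if self.n_border_nuclei > self.n_nuclei:
            errors.append("n_border_nuclei cannot exceed n_nuclei")
        if self.n_bright_cells > self.n_nuclei - self.n_border_nuclei:
            errors.append("n_bright_cells cannot exceed the interior nucleus count")
        smin, smax = self.punctum_sigma_range
        if not 0 < smin <= smax:
            errors.append(f"punctum_sigma_range must satisfy 0 < min <= max, got {self.punctum_sigma_range}")
        if not 0 <= self.autolysosome_fraction <= 1:
            errors.append("autolysosome_fraction must be in [0, 1]")
        if self.puncta_per_cell_mean < 0:
            errors.append("puncta_per_cell_mean must be >= 0")
        if self.nucleus_radius_mean <= 0:
            errors.append("nucleus_radius_mean must be > 0")
        if self.background_level < 0:
            errors.append("background_level must be >= 0")
        errors.extend(self.noise_model.validate())
        return errors

    def check(self) -> "SyntheticSpec":
        errors = self.validate()
        if errors:
            raise ValueError("invalid SyntheticSpec: " + "; ".join(errors))
        return self


@dataclass(frozen=True)
class NucleusTruth:
    center: tuple[float, float]  # (row, col)
    radius: float
    is_border: bool
    is_bright: bool


@dataclass(frozen=True)
class PunctumTruth:
    center: tuple[float, float]  # (row, col)
    sigma: float
    klass: str  # AUTOPHAGOSOME or AUTOLYSOSOME
    owner: int | None  # index into the nuclei list, or None


@dataclass
class SyntheticGroundTruth:
    """Exact record of everything rendered into one synthetic image."""

    nuclei: list[NucleusTruth]
    puncta: list[PunctumTruth]
    effective_cell_count_true: float
    seed: int

    @property
    def n_autolysosome(self) -> int:
        return sum(p.klass == AUTOLYSOSOME for p in self.puncta)

    @property
    def n_autophagosome(self) -> int:
        return sum(p.klass == AUTOPHAGOSOME for p in self.puncta)


# ---------------------------------------------------------------------------
# rendering primitives
# ---------------------------------------------------------------------------

def _render_disc(raster, center, radius, amplitude, taper):
    """Add a cosine-tapered disc (flat top, smooth rim) to ``raster`` in place."""
    h, w = raster.shape
    r0, c0 = center
    reach = int(math.ceil(radius + taper)) + 1
    rlo, rhi = max(0, int(r0) - reach), min(h, int(r0) + reach + 1)
    clo, chi = max(0, int(c0) - reach), min(w, int(c0) + reach + 1)
    if rlo >= rhi or clo >= chi:
        return
    yy = np.arange(rlo, rhi)[:, None] - r0
    xx = np.arange(clo, chi)[None, :] - c0
    d = np.hypot(yy, xx)
    inner = radius - taper
    profile = np.where(
        d <= inner,
        1.0,
        np.where(d >= radius, 0.0, 0.5 * (1.0 + np.cos(np.pi * (d - inner) / taper))),
    )
    raster[rlo:rhi, clo:chi] += amplitude * profile


def _render_gaussian(raster, center, sigma, amplitude):
    """Add an isotropic 2D Gaussian spot to ``raster`` in place."""
    h, w = raster.shape
    r0, c0 = center
    reach = int(math.ceil(4 * sigma)) + 1
    rlo, rhi = max(0, int(r0) - reach), min(h, int(r0) + reach + 1)
    clo, chi = max(0, int(c0) - reach), min(w, int(c0) + reach + 1)
    if rlo >= rhi or clo >= chi:
        return
    yy = np.arange(rlo, rhi)[:, None] - r0
    xx = np.arange(clo, chi)[None, :] - c0
    raster[rlo:rhi, clo:chi] += amplitude * np.exp(-(yy**2 + xx**2) / (2.0 * sigma**2))


def _render_bright_plateau(raster, center, radius, amplitude, halo_sigma=8.0):
    """Saturating diffuse signal over a nucleus plus a decaying halo."""
    h, w = raster.shape
    r0, c0 = center
    reach = int(math.ceil(radius + 4 * halo_sigma)) + 1
    rlo, rhi = max(0, int(r0) - reach), min(h, int(r0) + reach + 1)
    clo, chi = max(0, int(c0) - reach), min(w, int(c0) + reach + 1)
    if rlo >= rhi or clo >= chi:
        return
    yy = np.arange(rlo, rhi)[:, None] - r0
    xx = np.arange(clo, chi)[None, :] - c0
    d = np.hypot(yy, xx)
    excess = np.maximum(d - radius, 0.0)
    raster[rlo:rhi, clo:chi] += amplitude * np.exp(-(excess**2) / (2.0 * halo_sigma**2))


def _apply_noise(raster: np.ndarray, noise: NoiseModel, rng: np.random.Generator) -> np.ndarray:
    if noise.kind == "none":
        return raster.copy()
    if noise.kind == "gaussian":
        out = raster + rng.normal(0.0, noise.gaussian_sd, size=raster.shape)
        return np.maximum(out, 0.0)
    if noise.kind == "poisson":
        return rng.poisson(np.maximum(raster, 0.0) * noise.poisson_gain).astype(np.float64) / noise.poisson_gain
    if noise.kind == "speckle":
        out = raster.copy()
        value = noise.speckle_value
        if value is None:
            value = 5.0 * max(float(raster.max()), 1.0)
        mask = rng.random(raster.shape) < noise.speckle_density
        out[mask] = value
        return out
    raise ValueError(f"unknown noise kind {noise.kind!r}")


# ---------------------------------------------------------------------------
# nuclei channel
# ---------------------------------------------------------------------------

def _place_nuclei(spec: SyntheticSpec, rng: np.random.Generator) -> list[NucleusTruth]:
    h, w = spec.image_shape
    gap = 3.0  # min clearance between nucleus rims, px
    centers: list[tuple[float, float]] = []
    radii: list[float] = []

    def fits(center, radius):
        return all(
            math.hypot(center[0] - c[0], center[1] - c[1]) >= radius + r + gap
            for c, r in zip(centers, radii)
        )

    def draw_radius():
        return max(4.0, rng.normal(spec.nucleus_radius_mean, spec.nucleus_radius_sd))

    n_interior = spec.n_nuclei - spec.n_border_nuclei
    is_border_flags: list[bool] = []
    for i in range(n_interior):
        radius = draw_radius()
        margin = radius + spec.edge_taper + 2.0
        if h - 1 - margin <= margin or w - 1 - margin <= margin:
            raise PlacementError(
                f"image {h}x{w} too small for an interior nucleus of radius {radius:.1f}"
            )
        for _ in range(_PLACEMENT_TRIES):
            center = (rng.uniform(margin, h - 1 - margin), rng.uniform(margin, w - 1 - margin))
            if fits(center, radius):
                break
        else:
            raise PlacementError(
                f"could not place interior nucleus {i + 1}/{n_interior} after "
                f"{_PLACEMENT_TRIES} tries: image {h}x{w} too crowded for "
                f"n_nuclei={spec.n_nuclei} of radius ~{spec.nucleus_radius_mean}"
            )
        centers.append(center)
        radii.append(radius)
        is_border_flags.append(False)

    for i in range(spec.n_border_nuclei):
        radius = draw_radius()
        for _ in range(_PLACEMENT_TRIES):
            edge = int(rng.integers(4))  # 0 top, 1 bottom, 2 left, 3 right
            d = rng.uniform(0.2 * radius, 0.7 * radius)  # center-to-edge distance
            lo, hi = radius + 2.0, None
            if edge in (0, 1):
                hi = w - 1 - radius - 2.0
                col = rng.uniform(lo, hi)
                row = d if edge == 0 else h - 1 - d
                center = (row, col)
            else:
                hi = h - 1 - radius - 2.0
                row = rng.uniform(lo, hi)
                col = d if edge == 2 else w - 1 - d
                center = (row, col)
            if fits(center, radius):
                break
        else:
            raise PlacementError(
                f"could not place border nucleus {i + 1}/{spec.n_border_nuclei} after "
                f"{_PLACEMENT_TRIES} tries on image {h}x{w}"
            )
        centers.append(center)
        radii.append(radius)
        is_border_flags.append(True)

    bright = np.zeros(spec.n_nuclei, dtype=bool)
    interior_idx = [i for i, b in enumerate(is_border_flags) if not b]
    if spec.n_bright_cells:
        chosen = rng.choice(interior_idx, size=spec.n_bright_cells, replace=False)
        bright[np.asarray(chosen, dtype=int)] = True

    return [
        NucleusTruth(center=centers[i], radius=radii[i], is_border=is_border_flags[i],
                     is_bright=bool(bright[i]))
        for i in range(spec.n_nuclei)
    ]


def _disc_pixel_areas(nucleus: NucleusTruth, shape, taper: float) -> tuple[int, int]:
    """(full, visible) pixel counts of the nucleus disc at its half-amplitude radius."""
    h, w = shape
    r_eff = max(nucleus.radius - taper / 2.0, 1.0)
    r0, c0 = nucleus.center
    reach = int(math.ceil(r_eff)) + 1
    rows = np.arange(int(r0) - reach, int(r0) + reach + 1)
    cols = np.arange(int(c0) - reach, int(c0) + reach + 1)
    yy = rows[:, None] - r0
    xx = cols[None, :] - c0
    inside = (yy**2 + xx**2) <= r_eff**2
    full = int(inside.sum())
    in_image = (
        (rows[:, None] >= 0) & (rows[:, None] < h) & (cols[None, :] >= 0) & (cols[None, :] < w)
    )
    visible = int((inside & in_image).sum())
    return full, visible


def true_effective_cell_count(nuclei: list[NucleusTruth], shape, taper: float = 2.0) -> float:
    """Effective cell count under the fractional border rule, from exact truth.

    Interior (non-border, non-bright) nuclei count 1 each; border nuclei count
    min(1, visible_area / mean interior area); bright-flagged nuclei are
    excluded entirely, matching the pipeline's removal of those cells.
    """
    interior_areas = [
        _disc_pixel_areas(n, shape, taper)[0]
        for n in nuclei
        if not n.is_border and not n.is_bright
    ]
    count = float(len(interior_areas))
    border = [n for n in nuclei if n.is_border and not n.is_bright]
    if border:
        if not interior_areas:
            return math.nan
        mean_area = float(np.mean(interior_areas))
        for n in border:
            _, visible = _disc_pixel_areas(n, shape, taper)
            count += min(1.0, visible / mean_area)
    return count


def generate_nuclei_channel(spec: SyntheticSpec) -> tuple[np.ndarray, SyntheticGroundTruth]:
    """Render the DAPI (blue) channel and record nucleus ground truth.

    Returns the blue raster and a ground truth whose ``puncta`` list is empty
    until :func:`generate_puncta_channels` fills it.
    """
    spec.check()
    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 0]))
    raster = np.full(spec.image_shape, float(spec.background_level))
    nuclei = _place_nuclei(spec, rng)
    for n in nuclei:
        _render_disc(raster, n.center, n.radius, spec.nucleus_amplitude, spec.edge_taper)
    raster = _apply_noise(raster, spec.noise_model, rng)
    truth = SyntheticGroundTruth(
        nuclei=nuclei,
        puncta=[],
        effective_cell_count_true=true_effective_cell_count(
            nuclei, spec.image_shape, spec.edge_taper
        ),
        seed=int(spec.seed),
    )
    return raster, truth


# ---------------------------------------------------------------------------
# puncta channels (tandem reporter)
# ---------------------------------------------------------------------------

def _place_puncta(spec: SyntheticSpec, nuclei: list[NucleusTruth],
                  rng: np.random.Generator) -> list[PunctumTruth]:
    h, w = spec.image_shape
    smin, smax = spec.punctum_sigma_range
    placed: list[PunctumTruth] = []

    def admissible(center, sigma):
        r0, c0 = center
        margin = 3.0 * sigma
        if not (margin <= r0 <= h - 1 - margin and margin <= c0 <= w - 1 - margin):
            return False
        for n in nuclei:
            # truth rule: puncta never overlap nuclei
            if math.hypot(r0 - n.center[0], c0 - n.center[1]) < n.radius + 2.0 * sigma:
                return False
        for p in placed:
            if math.hypot(r0 - p.center[0], c0 - p.center[1]) < spec.min_puncta_separation:
                return False
        return True

    for owner, nucleus in enumerate(nuclei):
        if nucleus.is_bright:
            continue  # puncta indistinguishable there; the analysis excludes the area
        n_puncta = int(rng.poisson(spec.puncta_per_cell_mean))
        for j in range(n_puncta):
            sigma = float(rng.uniform(smin, smax))
            klass = AUTOLYSOSOME if rng.random() < spec.autolysosome_fraction else AUTOPHAGOSOME
            for _ in range(_PLACEMENT_TRIES):
                dist = rng.uniform(nucleus.radius + 2.0 * sigma, nucleus.radius + spec.cytoplasm_reach)
                angle = rng.uniform(0.0, 2.0 * math.pi)
                center = (
                    nucleus.center[0] + dist * math.sin(angle),
                    nucleus.center[1] + dist * math.cos(angle),
                )
                if admissible(center, sigma):
                    break
            else:
                raise PlacementError(
                    f"could not place punctum {j + 1} of cell {owner} after "
                    f"{_PLACEMENT_TRIES} tries: min_puncta_separation="
                    f"{spec.min_puncta_separation} too strict for "
                    f"puncta_per_cell_mean={spec.puncta_per_cell_mean} on {h}x{w}"
                )
            placed.append(PunctumTruth(center=center, sigma=sigma, klass=klass, owner=owner))
    return placed


def generate_puncta_channels(
    spec: SyntheticSpec, truth: SyntheticGroundTruth
) -> tuple[np.ndarray, np.ndarray, SyntheticGroundTruth]:
    """Render green and red rasters for the tandem reporter.

    Autophagosomes (neutral pH: GFP intact) appear in both channels;
    autolysosomes (acidic: GFP quenched) appear in red only.  Bright cells add
    a saturating diffuse plateau to the green channel.  The punctum class is
    drawn Bernoulli(autolysosome_fraction) from the seeded stream.
    """
    spec.check()
    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 1]))
    green = np.full(spec.image_shape, float(spec.background_level))
    red = np.full(spec.image_shape, float(spec.background_level))

    for n in truth.nuclei:
        if n.is_bright:
            _render_bright_plateau(
                green, n.center, n.radius,
                spec.bright_amplitude_factor * spec.punctum_amplitude,
            )

    puncta = _place_puncta(spec, truth.nuclei, rng)
    for p in puncta:
        _render_gaussian(red, p.center, p.sigma, spec.punctum_amplitude)
        if p.klass == AUTOPHAGOSOME:
            _render_gaussian(green, p.center, p.sigma, spec.punctum_amplitude)

    green = _apply_noise(green, spec.noise_model, rng)
    red = _apply_noise(red, spec.noise_model, rng)
    truth.puncta = puncta
    return green, red, truth


def generate_image(spec: SyntheticSpec, name: str = "synthetic") -> tuple[MultiChannelImage, SyntheticGroundTruth]:
    """Render all three channels of one synthetic field."""
    blue, truth = generate_nuclei_channel(spec)
    green, red, truth = generate_puncta_channels(spec, truth)
    return MultiChannelImage(blue=blue, green=green, red=red, name=name), truth


# ---------------------------------------------------------------------------
# colocalization fixture
# ---------------------------------------------------------------------------

def generate_colocalization_pair(
    shape: tuple[int, int],
    rho_target: float,
    seed: int,
    smoothing_sigma: float = 1.0,
    mean: float = 1000.0,
    sd: float = 200.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Two rasters whose pixelwise Pearson correlation converges to ``rho_target``.

    Standardized smooth fields A* and E are combined as
    B* = rho A* + sqrt(1 - rho^2) E, then both are mapped affinely to a
    positive intensity range (Pearson r is affine-invariant).  Light smoothing
    gives microscopy-like texture while keeping the effective pixel count, and
    hence the sampling error of r, large.
    """
    if not -1.0 <= rho_target <= 1.0:
        raise ValueError(f"rho_target must be in [-1, 1], got {rho_target}")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 2]))

    def smooth_standard_field():
        f = rng.normal(size=shape)
        if smoothing_sigma > 0:
            f = ndi.gaussian_filter(f, smoothing_sigma)
        f -= f.mean()
        f /= f.std()
        return f

    a = smooth_standard_field()
    e = smooth_standard_field()
    b = rho_target * a + math.sqrt(max(0.0, 1.0 - rho_target**2)) * e
    raster_a = np.maximum(mean + sd * a, 0.0)
    raster_b = np.maximum(mean + sd * b, 0.0)
    return raster_a, raster_b


# ---------------------------------------------------------------------------
# dataset writer
# ---------------------------------------------------------------------------

def _image_seed(base_seed: int, condition_index: int, image_index: int) -> int:
    state = np.random.SeedSequence(
        [int(base_seed), condition_index, image_index]
    ).generate_state(1)[0]
    return int(state % (2**31))


def truth_to_frame(image: str, condition: str, truth: SyntheticGroundTruth) -> pd.DataFrame:
    """Flatten one image's ground truth to rows (one per nucleus and per punctum)."""
    rows = []
    for i, n in enumerate(truth.nuclei):
        rows.append(dict(
            image=image, condition=condition, kind="nucleus", index=i,
            row=n.center[0], col=n.center[1], radius=n.radius, sigma=np.nan,
            is_border=n.is_border, is_bright=n.is_bright, klass="", owner=-1,
            effective_cell_count_true=truth.effective_cell_count_true,
        ))
    for i, p in enumerate(truth.puncta):
        rows.append(dict(
            image=image, condition=condition, kind="punctum", index=i,
            row=p.center[0], col=p.center[1], radius=np.nan, sigma=p.sigma,
            is_border=False, is_bright=False, klass=p.klass,
            owner=-1 if p.owner is None else p.owner,
            effective_cell_count_true=truth.effective_cell_count_true,
        ))
    return pd.DataFrame(rows)


def generate_dataset(
    conditions: Mapping[str, SyntheticSpec],
    n_images: int,
    out_dir: str | Path,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Write a synthetic dataset: per-channel 16-bit TIFFs plus ground truth.

    For each condition, ``n_images`` fields are rendered with per-image seeds
    derived deterministically from the condition spec's seed.  Writes
    ``<name>_b.tif`` / ``_g.tif`` / ``_r.tif`` per image, ``ground_truth.csv``
    (one row per nucleus and per punctum), ``manifest.csv`` (image -> channel
    files and condition) and ``dataset.json`` echoing every spec.

    Returns (ground truth table, manifest table).
    """
    if not conditions:
        raise ValueError("at least one condition is required")
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    truth_frames, manifest_rows = [], []
    for ci, (cond, spec) in enumerate(conditions.items()):
        spec.check()
        for ii in range(n_images):
            img_spec = dataclasses.replace(spec, seed=_image_seed(spec.seed, ci, ii))
            name = f"{cond}_{ii:03d}"
            image, truth = generate_image(img_spec, name=name)
            paths = {}
            for suffix, raster in (("b", image.blue), ("g", image.green), ("r", image.red)):
                fname = f"{name}_{suffix}.tif"
                try:
                    write_raster_16bit(out_dir / fname, raster)
                except OSError as exc:
                    raise OSError(f"failed writing {out_dir / fname}: {exc}") from exc
                paths[suffix] = fname
            truth_frames.append(truth_to_frame(name, cond, truth))
            manifest_rows.append(dict(
                name=name, condition=cond,
                blue=paths["b"], green=paths["g"], red=paths["r"],
                seed=img_spec.seed,
            ))

    truth_df = pd.concat(truth_frames, ignore_index=True)
    manifest_df = pd.DataFrame(manifest_rows)
    truth_df.to_csv(out_dir / "ground_truth.csv", index=False)
    manifest_df.to_csv(out_dir / "manifest.csv", index=False)
    sidecar = {
        "n_images": n_images,
        "conditions": {
            cond: {**dataclasses.asdict(spec)} for cond, spec in conditions.items()
        },
    }
    (out_dir / "dataset.json").write_text(json.dumps(sidecar, indent=2, default=list))
    return truth_df, manifest_df
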
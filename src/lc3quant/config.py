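"""Run configuration: YAML schema, aggregated validation, typed defaults."""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .synthetic import NoiseModel, SyntheticSpec

MODES = ("simulate", "puncta", "tandem", "colocalization")


class ConfigError(ValueError):
    """All validation problems of a config, reported together."""

    def __init__(self, errors: list[str]):
        self.errors = list(errors)
        super().__init__("invalid config:\n  - " + "\n  - ".join(self.errors))


@dataclass(frozen=True)
class SegmentationParams:
    smoothing_sigma: float = 2.0
    min_area: float = 200.0
    fence_k: float = 1.5
    halo_radius: int = 25
    bright_channel: str = "green"  # or "blue"


@dataclass(frozen=True)
class DetectionParams:
    sigma_min: float = 1.0
    sigma_max: float = 5.0
    n_scales: int = 10
    threshold_rel: float = 0.1
    overlap_max: float = 0.5
    radius_coeff: float = math.sqrt(2.0)
    median_window: int | None = None  # odd int enables despeckling


@dataclass(frozen=True)
class TandemParams:
    green_positivity_factor: float = 2.0


@dataclass(frozen=True)
class ColocalizationParams:
    roi: str = "whole_image"  # or "nuclei_excluded"
    channel_a: str = "green"
    channel_b: str = "red"


@dataclass(frozen=True)
class ImageEntry:
    name: str
    condition: str
    blue: Path | None
    green: Path | None
    red: Path | None


@dataclass(frozen=True)
class SyntheticSection:
    n_images: int
    conditions: dict[str, SyntheticSpec]


@dataclass(frozen=True)
class RunConfig:
    mode: str
    output_dir: Path
    seed: int = 0
    images: tuple[ImageEntry, ...] = ()
    synthetic: SyntheticSection | None = None
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    detection: DetectionParams = field(default_factory=DetectionParams)
    tandem: TandemParams = field(default_factory=TandemParams)
    colocalization: ColocalizationParams = field(default_factory=ColocalizationParams)


def _coerce_section(cls, raw: dict, prefix: str, errors: list[str]):
    known = {f.name: f for f in dataclasses.fields(cls)}
    kwargs = {}
    for key, value in raw.items():
        if key not in known:
            errors.append(f"{prefix}: unknown key {key!r}")
            continue
        kwargs[key] = value
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        errors.append(f"{prefix}: {exc}")
        return cls()


def _spec_from_dict(raw: dict, prefix: str, errors: list[str]) -> SyntheticSpec:
    known = {f.name for f in dataclasses.fields(SyntheticSpec)}
    kwargs = {}
    for key, value in raw.items():
        if key not in known:
            errors.append(f"{prefix}: unknown key {key!r}")
            continue
        if key == "noise_model" and isinstance(value, dict):
            value = _coerce_section(NoiseModel, value, f"{prefix}.noise_model", errors)
        elif key in ("image_shape", "punctum_sigma_range"):
            value = tuple(value)
        kwargs[key] = value
    try:
        spec = SyntheticSpec(**kwargs)
    except (TypeError, ValueError) as exc:
        errors.append(f"{prefix}: {exc}")
        return SyntheticSpec()
    for problem in spec.validate():
        errors.append(f"{prefix}: {problem}")
    return spec


def build_config(raw: dict, base_dir: Path | str = ".") -> RunConfig:
    """Validate a raw (already-parsed) config dict into a :class:`RunConfig`.

    All problems are collected and raised together as :class:`ConfigError`,
    not first-failure.  Relative paths resolve against ``base_dir``.
    """
    base_dir = Path(base_dir)
    errors: list[str] = []
    if not isinstance(raw, dict):
        raise ConfigError(["config must be a mapping"])

    top_known = {
        "mode", "output_dir", "seed", "images", "images_manifest", "synthetic",
        "segmentation", "detection", "tandem", "colocalization",
    }
    for key in raw:
        if key not in top_known:
            errors.append(f"unknown top-level key {key!r}")

    mode = raw.get("mode")
    if mode not in MODES:
        errors.append(f"mode must be one of {MODES}, got {mode!r}")
        mode = "puncta"

    output_dir = Path(raw.get("output_dir", "lc3quant_out"))
    if not output_dir.is_absolute():
        output_dir = base_dir / output_dir

    seed = raw.get("seed", 0)
    if not isinstance(seed, int) or seed < 0:
        errors.append(f"seed must be a nonnegative integer, got {seed!r}")
        seed = 0

    segmentation = _coerce_section(SegmentationParams, raw.get("segmentation", {}) or {}, "segmentation", errors)
    detection = _coerce_section(DetectionParams, raw.get("detection", {}) or {}, "detection", errors)
    tandem = _coerce_section(TandemParams, raw.get("tandem", {}) or {}, "tandem", errors)
    coloc = _coerce_section(ColocalizationParams, raw.get("colocalization", {}) or {}, "colocalization", errors)

    if segmentation.bright_channel not in ("green", "blue"):
        errors.append(f"segmentation.bright_channel must be 'green' or 'blue', got {segmentation.bright_channel!r}")
    if segmentation.smoothing_sigma < 0:
        errors.append("segmentation.smoothing_sigma must be >= 0")
    if segmentation.min_area < 0:
        errors.append("segmentation.min_area must be >= 0")
    if not 0 < detection.sigma_min <= detection.sigma_max:
        errors.append(
            f"detection: need 0 < sigma_min <= sigma_max, got ({detection.sigma_min}, {detection.sigma_max})"
        )
    if detection.n_scales < 1:
        errors.append("detection.n_scales must be >= 1")
    if detection.threshold_rel <= 0:
        errors.append("detection.threshold_rel must be > 0")
    if not 0 <= detection.overlap_max <= 1:
        errors.append("detection.overlap_max must be in [0, 1]")
    if detection.median_window is not None and (
        detection.median_window < 1 or detection.median_window % 2 == 0
    ):
        errors.append(f"detection.median_window must be odd >= 1, got {detection.median_window}")
    if tandem.green_positivity_factor <= 0:
        errors.append("tandem.green_positivity_factor must be > 0")
    if coloc.roi not in ("whole_image", "nuclei_excluded"):
        errors.append(f"colocalization.roi must be 'whole_image' or 'nuclei_excluded', got {coloc.roi!r}")
    for ch_key in ("channel_a", "channel_b"):
        if getattr(coloc, ch_key) not in ("blue", "green", "red"):
            errors.append(f"colocalization.{ch_key} must be a channel name")

    # --- image manifest ----------------------------------------------------
    images: list[ImageEntry] = []
    manifest_path = raw.get("images_manifest")
    raw_images = raw.get("images", [])
    if manifest_path is not None:
        mpath = Path(manifest_path)
        if not mpath.is_absolute():
            mpath = base_dir / mpath
        if not mpath.exists():
            errors.append(f"images_manifest not found: {mpath}")
        else:
            import pandas as pd

            mdf = pd.read_csv(mpath, comment="#")
            for _, row in mdf.iterrows():
                raw_images = list(raw_images) + [{
                    "name": row["name"], "condition": row["condition"],
                    "blue": row.get("blue"), "green": row.get("green"),
                    "red": row.get("red"),
                }]
            base_for_images = mpath.parent
    if raw_images:
        base_for_images = locals().get("base_for_images", base_dir)
        needed = {"puncta": ("blue", "green"), "tandem": ("blue", "green", "red"),
                  "colocalization": (coloc.channel_a, coloc.channel_b),
                  "simulate": ()}[mode]
        for i, entry in enumerate(raw_images):
            if not isinstance(entry, dict):
                errors.append(f"images[{i}]: must be a mapping")
                continue
            name = str(entry.get("name", f"image_{i:03d}"))
            condition = str(entry.get("condition", "default"))
            paths = {}
            for ch in ("blue", "green", "red"):
                p = entry.get(ch)
                if p is None or (isinstance(p, float) and math.isnan(p)):
                    paths[ch] = None
                    continue
                p = Path(p)
                if not p.is_absolute():
                    p = base_for_images / p
                if not p.exists():
                    errors.append(f"images[{i}] ({name}): {ch} file not found: {p}")
                paths[ch] = p
            for ch in needed:
                if paths.get(ch) is None:
                    errors.append(f"images[{i}] ({name}): mode {mode!r} requires the {ch} channel")
            images.append(ImageEntry(name=name, condition=condition, **paths))

    # --- synthetic section -------------------------------------------------
    synthetic = None
    raw_syn = raw.get("synthetic")
    if raw_syn is not None:
        if not isinstance(raw_syn, dict):
            errors.append("synthetic: must be a mapping")
        else:
            n_images = raw_syn.get("n_images", 1)
            if not isinstance(n_images, int) or n_images < 1:
                errors.append(f"synthetic.n_images must be a positive integer, got {n_images!r}")
                n_images = 1
            conds = raw_syn.get("conditions", {})
            if not isinstance(conds, dict) or not conds:
                errors.append("synthetic.conditions must be a non-empty mapping")
                conds = {}
            specs = {}
            for ci, (cond, overrides) in enumerate(conds.items()):
                overrides = dict(overrides or {})
                overrides.setdefault("seed", seed + ci)
                specs[str(cond)] = _spec_from_dict(overrides, f"synthetic.conditions.{cond}", errors)
            synthetic = SyntheticSection(n_images=n_images, conditions=specs)

    if mode == "simulate" and synthetic is None:
        errors.append("mode 'simulate' requires a synthetic section")
    if mode in ("puncta", "tandem", "colocalization") and not images:
        errors.append(f"mode {mode!r} requires images (inline or via images_manifest)")

    if errors:
        raise ConfigError(errors)
    return RunConfig(
        mode=mode, output_dir=output_dir, seed=seed, images=tuple(images),
        synthetic=synthetic, segmentation=segmentation, detection=detection,
        tandem=tandem, colocalization=coloc,
    )


def validate_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML config file; raises :class:`ConfigError`."""
    path = Path(path)
    if not path.exists():
        raise ConfigError([f"config file not found: {path}"])
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError([f"YAML parse error: {exc}"]) from exc
    return build_config(raw or {}, base_dir=path.parent)
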
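"""YAML-backed configuration parsing and validation for pipeline runs.

Field names carry explicit unit suffixes (_um, _nm, _px, _kT) to keep units
honest across the config surface.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from .segmentation import SegmentationConfig
from .synthgen import NoiseSpec, SceneSpec, SpeciesSpec
from .translocation import ChainParams

__all__ = [
    "ConfigError",
    "RunConfig",
    "species_from_dict",
    "scene_from_dict",
    "segmentation_from_dict",
    "chain_from_dict",
    "run_config_from_dict",
]


class ConfigError(ValueError):
    pass


def _require(d: dict, key: str, ctx: str):
    if key not in d:
        raise ConfigError(f"missing required key '{key}' in {ctx}")
    return d[key]


def _check_keys(d, allowed: set[str], ctx: str) -> None:
    if not isinstance(d, dict):
        raise ConfigError(f"{ctx} must be a mapping")
    extra = set(d) - allowed
    if extra:
        raise ConfigError(f"unknown keys {sorted(extra)} in {ctx}")


def species_from_dict(d: dict) -> SpeciesSpec:
    _check_keys(
        d,
        {
            "name",
            "width_mean_um",
            "width_sd_um",
            "length_mean_um",
            "length_sd_um",
            "expansion_factor",
        },
        "species",
    )
    try:
        return SpeciesSpec(
            name=str(_require(d, "name", "species")),
            width_mean_um=float(_require(d, "width_mean_um", "species")),
            width_sd_um=float(d.get("width_sd_um", 0.0)),
            length_mean_um=float(_require(d, "length_mean_um", "species")),
            length_sd_um=float(d.get("length_sd_um", 0.0)),
            expansion_factor=float(d.get("expansion_factor", 1.0)),
        )
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc


def scene_from_dict(d: dict) -> SceneSpec:
    _check_keys(
        d,
        {
            "image_shape_px",
            "pixel_size_um",
            "species",
            "counts",
            "gel_factor",
            "min_separation_um",
            "background_level",
            "psf_sigma_um",
            "noise",
            "cell_intensity",
        },
        "scene",
    )
    species_list = _require(d, "species", "scene")
    noise_d = d.get("noise", {}) or {}
    _check_keys(noise_d, {"shot_scale", "read_sd"}, "scene.noise")
    try:
        return SceneSpec(
            image_shape_px=tuple(
                int(v) for v in _require(d, "image_shape_px", "scene")
            ),
            pixel_size_um=float(_require(d, "pixel_size_um", "scene")),
            species=tuple(species_from_dict(s) for s in species_list),
            counts=tuple(int(c) for c in _require(d, "counts", "scene")),
            gel_factor=float(d.get("gel_factor", 1.0)),
            min_separation_um=float(d.get("min_separation_um", 1.0)),
            background_level=float(d.get("background_level", 0.0)),
            psf_sigma_um=float(d.get("psf_sigma_um", 0.0)),
            noise=NoiseSpec(
                shot_scale=float(noise_d.get("shot_scale", 0.0)),
                read_sd=float(noise_d.get("read_sd", 0.0)),
            ),
            cell_intensity=float(d.get("cell_intensity", 1000.0)),
        )
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid scene config: {exc}") from exc


def segmentation_from_dict(d: dict) -> SegmentationConfig:
    _check_keys(
        d,
        {
            "threshold_method",
            "fixed_threshold",
            "smoothing_sigma_px",
            "h_minima_depth",
            "min_area_px",
            "max_area_px",
            "exclude_border",
        },
        "segmentation",
    )
    try:
        return SegmentationConfig(
            threshold_method=str(d.get("threshold_method", "otsu")),
            fixed_threshold=(
                None
                if d.get("fixed_threshold") is None
                else float(d["fixed_threshold"])
            ),
            smoothing_sigma_px=float(d.get("smoothing_sigma_px", 1.0)),
            h_minima_depth=(
                None
                if d.get("h_minima_depth") is None
                else float(d["h_minima_depth"])
            ),
            min_area_px=int(d.get("min_area_px", 20)),
            max_area_px=int(d.get("max_area_px", 10**9)),
            exclude_border=bool(d.get("exclude_border", True)),
        )
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid segmentation config: {exc}") from exc


def chain_from_dict(d: dict) -> ChainParams:
    _check_keys(
        d,
        {
            "genome_bp",
            "rise_nm_per_bp",
            "kuhn_nm",
            "cell_radius_nm",
            "cross_radius_nm",
        },
        "chain",
    )
    try:
        return ChainParams(
            genome_bp=float(d.get("genome_bp", 4.7e6)),
            rise_nm_per_bp=float(d.get("rise_nm_per_bp", 0.34)),
            kuhn_nm=float(d.get("kuhn_nm", 100.0)),
            cell_radius_nm=float(d.get("cell_radius_nm", 1000.0)),
            cross_radius_nm=float(d.get("cross_radius_nm", 1.0)),
        )
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc


@dataclass
class RunConfig:
    mode: str  # "scene" | "pair" | "halo"
    scene: SceneSpec
    segmentation: SegmentationConfig
    seed: int
    output_dir: Path
    halo_fraction: float = 0.0
    halo_factor: float = 4.0
    halo_cutoff: float = 2.0
    n_boot: int = 1000
    log_level: str = "INFO"
    n_images: int = 1

    def __post_init__(self) -> None:
        if self.mode not in ("scene", "pair", "halo"):
            raise ConfigError(f"unknown pipeline mode '{self.mode}'")
        if self.n_images < 1:
            raise ConfigError("n_images must be >= 1")
        self.output_dir = Path(self.output_dir)


def run_config_from_dict(d: dict, base_dir: Path | None = None) -> RunConfig:
    _check_keys(
        d,
        {
            "mode",
            "scene",
            "segmentation",
            "seed",
            "output_dir",
            "halo_fraction",
            "halo_factor",
            "halo_cutoff",
            "n_boot",
            "log_level",
            "n_images",
        },
        "run config",
    )
    out = Path(_require(d, "output_dir", "run config"))
    if base_dir is not None and not out.is_absolute():
        out = base_dir / out
    return RunConfig(
        mode=str(_require(d, "mode", "run config")),
        scene=scene_from_dict(_require(d, "scene", "run config")),
        segmentation=segmentation_from_dict(d.get("segmentation", {}) or {}),
        seed=int(d.get("seed", 0)),
        output_dir=out,
        halo_fraction=float(d.get("halo_fraction", 0.0)),
        halo_factor=float(d.get("halo_factor", 4.0)),
        halo_cutoff=float(d.get("halo_cutoff", 2.0)),
        n_boot=int(d.get("n_boot", 1000)),
        log_level=str(d.get("log_level", "INFO")),
        n_images=int(d.get("n_images", 1)),
    )
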
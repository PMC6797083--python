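"""Seeded synthetic fluorescence micrographs of rod-shaped cells with truth.

Cells are straight spherocylinders (a rectangle of length ``L - W`` capped by
two half-disks of diameter ``W``) of constant interior intensity, placed by
rejection sampling, blurred by an isotropic Gaussian PSF and corrupted by
scaled-Poisson shot noise plus Gaussian read noise.  Three scene kinds are
supported:

* a single-channel scene (:func:`render_scene`),
* a pre/post expansion pair in which the gel scales positions and the
  species-specific wall factor scales cell dimensions
  (:func:`render_expansion_pair`),
* a two-channel cytoplasm/DNA scene in which a configurable fraction of cells
  carry an escaped-DNA annulus several times wider than the cell
  (:func:`render_halo_scene`).

Coordinate convention: ``x`` maps to columns and ``y`` to rows; an
orientation ``theta`` means the long axis points along
``(dx, dy) = (cos theta, sin theta)``.  All randomness flows from a single
integer seed through per-purpose child streams, so identical (spec, seed)
pairs give bit-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage as ndi
from scipy import stats

__all__ = [
    "SpeciesSpec",
    "NoiseSpec",
    "SceneSpec",
    "GroundTruthCell",
    "SceneTooCrowdedError",
    "render_scene",
    "render_expansion_pair",
    "render_halo_scene",
    "spherocylinder_mask",
]

MAX_PLACEMENT_ATTEMPTS = 10_000


class SceneTooCrowdedError(RuntimeError):
    """Raised when rejection placement cannot fit all requested cells."""


@dataclass(frozen=True)
class SpeciesSpec:
    name: str
    width_mean_um: float
    width_sd_um: float
    length_mean_um: float
    length_sd_um: float
    expansion_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.width_mean_um <= 0:
            raise ValueError("width_mean_um must be positive")
        if self.width_sd_um < 0 or self.length_sd_um < 0:
            raise ValueError("standard deviations must be non-negative")
        if self.expansion_factor < 1.0:
            raise ValueError("expansion_factor must be >= 1")
        if self.length_mean_um < self.width_mean_um:
            raise ValueError("length_mean_um must be >= width_mean_um")


@dataclass(frozen=True)
class NoiseSpec:
    shot_scale: float = 0.0  # photons per intensity unit; 0 disables
    read_sd: float = 0.0  # additive Gaussian sd; 0 disables

    def __post_init__(self) -> None:
        if self.shot_scale < 0 or self.read_sd < 0:
            raise ValueError("noise parameters must be non-negative")


@dataclass(frozen=True)
class SceneSpec:
    image_shape_px: tuple[int, int]
    pixel_size_um: float
    species: tuple[SpeciesSpec, ...]
    counts: tuple[int, ...]
    gel_factor: float = 1.0
    min_separation_um: float = 1.0
    background_level: float = 0.0
    psf_sigma_um: float = 0.0
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    cell_intensity: float = 1000.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "species", tuple(self.species))
        object.__setattr__(self, "counts", tuple(int(c) for c in self.counts))
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if len(self.image_shape_px) != 2 or any(
            s <= 0 for s in self.image_shape_px
        ):
            raise ValueError("image_shape_px must be two positive integers")
        if len(self.species) != len(self.counts):
            raise ValueError("species and counts must have equal length")
        if any(c < 0 for c in self.counts):
            raise ValueError("counts must be non-negative")
        if self.gel_factor < 1.0:
            raise ValueError("gel_factor must be >= 1")
        if self.min_separation_um <= 0:
            raise ValueError("min_separation_um must be positive")
        if self.psf_sigma_um < 0:
            raise ValueError("psf_sigma_um must be non-negative")
        if self.cell_intensity <= 0:
            raise ValueError("cell_intensity must be positive")

    @property
    def n_cells(self) -> int:
        return sum(self.counts)


@dataclass
class GroundTruthCell:
    id: int
    species: str
    centroid_um: tuple[float, float]  # (x, y)
    orientation_rad: float
    length_um: float
    width_um: float
    phenotype: str = "normal"
    halo_width_um: Optional[float] = None

    def __post_init__(self) -> None:
        if self.width_um > self.length_um + 1e-9:
            raise ValueError("width_um must be <= length_um")
        if self.phenotype == "halo":
            if self.halo_width_um is None or self.halo_width_um <= self.width_um:
                raise ValueError("halo cells need halo_width_um > width_um")
        elif self.halo_width_um is not None:
            raise ValueError("halo_width_um only valid for halo phenotype")


def _truncnorm_sample(rng: np.random.Generator, mean: float, sd: float) -> float:
    """Normal sample truncated at 4 SD and at zero."""
    if sd == 0:
        return mean
    lo = max(1e-6, mean - 4.0 * sd)
    hi = mean + 4.0 * sd
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return float(stats.truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng))


def _sample_cells(
    spec: SceneSpec,
    seed: int,
    margin_extra_um: float = 0.0,
) -> list[GroundTruthCell]:
    """Sample geometry and placement for all cells in a scene."""
    root = np.random.SeedSequence(seed)
    # child 0 reserved for noise; one child per cell index thereafter
    children = root.spawn(1 + spec.n_cells)
    h_um = spec.image_shape_px[0] * spec.pixel_size_um
    w_um = spec.image_shape_px[1] * spec.pixel_size_um
    cells: list[GroundTruthCell] = []
    placed: list[tuple[float, float]] = []
    idx = 0
    for sp, count in zip(spec.species, spec.counts):
        for _ in range(count):
            rng = np.random.default_rng(children[1 + idx])
            width = _truncnorm_sample(rng, sp.width_mean_um, sp.width_sd_um)
            length = _truncnorm_sample(rng, sp.length_mean_um, sp.length_sd_um)
            for _ in range(100):
                if length >= width:
                    break
                length = _truncnorm_sample(rng, sp.length_mean_um, sp.length_sd_um)
            length = max(length, width)
            margin = length / 2.0 + margin_extra_um
            if 2 * margin >= min(h_um, w_um):
                raise SceneTooCrowdedError(
                    f"cell of length {length:.3g} um does not fit in frame"
                )
            ok = False
            for _ in range(MAX_PLACEMENT_ATTEMPTS):
                x = rng.uniform(margin, w_um - margin)
                y = rng.uniform(margin, h_um - margin)
                if all(
                    math.hypot(x - px, y - py) >= spec.min_separation_um
                    for px, py in placed
                ):
                    ok = True
                    break
            if not ok:
                raise SceneTooCrowdedError(
                    f"could not place cell {idx} after "
                    f"{MAX_PLACEMENT_ATTEMPTS} attempts; scene too crowded"
                )
            theta = rng.uniform(0.0, math.pi)
            placed.append((x, y))
            cells.append(
                GroundTruthCell(
                    id=idx,
                    species=sp.name,
                    centroid_um=(x, y),
                    orientation_rad=theta,
                    length_um=length,
                    width_um=width,
                )
            )
            idx += 1
    return cells


def spherocylinder_mask(
    shape: tuple[int, int],
    centroid_px: tuple[float, float],
    orientation_rad: float,
    length_px: float,
    width_px: float,
) -> np.ndarray:
    """Boolean raster of a spherocylinder; a pixel is inside iff its center
    lies within width/2 of the medial segment of length ``length - width``."""
    cx, cy = centroid_px
    half_seg = max(0.0, (length_px - width_px) / 2.0)
    ux, uy = math.cos(orientation_rad), math.sin(orientation_rad)
    radius = width_px / 2.0
    extent = length_px / 2.0 + 1.5
    r0 = max(0, int(math.floor(cy - extent)))
    r1 = min(shape[0], int(math.ceil(cy + extent)) + 1)
    c0 = max(0, int(math.floor(cx - extent)))
    c1 = min(shape[1], int(math.ceil(cx + extent)) + 1)
    mask = np.zeros(shape, dtype=bool)
    if r0 >= r1 or c0 >= c1:
        return mask
    rr, cc = np.mgrid[r0:r1, c0:c1]
    dx = cc - cx
    dy = rr - cy
    t = np.clip(dx * ux + dy * uy, -half_seg, half_seg)
    d2 = (dx - t * ux) ** 2 + (dy - t * uy) ** 2
    mask[r0:r1, c0:c1] = d2 <= radius * radius
    return mask


def _distance_to_axis(
    shape: tuple[int, int],
    centroid_px: tuple[float, float],
    orientation_rad: float,
    length_px: float,
    width_px: float,
    extent_px: float,
):
    """Per-pixel distance to the medial segment over a bounding window.

    Returns (window slices, distance array); used for radial halo profiles.
    """
    cx, cy = centroid_px
    half_seg = max(0.0, (length_px - width_px) / 2.0)
    ux, uy = math.cos(orientation_rad), math.sin(orientation_rad)
    r0 = max(0, int(math.floor(cy - extent_px)))
    r1 = min(shape[0], int(math.ceil(cy + extent_px)) + 1)
    c0 = max(0, int(math.floor(cx - extent_px)))
    c1 = min(shape[1], int(math.ceil(cx + extent_px)) + 1)
    rr, cc = np.mgrid[r0:r1, c0:c1]
    dx = cc - cx
    dy = rr - cy
    t = np.clip(dx * ux + dy * uy, -half_seg, half_seg)
    d = np.sqrt((dx - t * ux) ** 2 + (dy - t * uy) ** 2)
    return (slice(r0, r1), slice(c0, c1)), d


def _render_cells(
    spec: SceneSpec,
    cells: Sequence[GroundTruthCell],
    shape: tuple[int, int],
) -> np.ndarray:
    img = np.full(shape, float(spec.background_level), dtype=np.float64)
    ps = spec.pixel_size_um
    for cell in cells:
        x, y = cell.centroid_um
        mask = spherocylinder_mask(
            shape,
            (x / ps, y / ps),
            cell.orientation_rad,
            cell.length_um / ps,
            cell.width_um / ps,
        )
        img[mask] = spec.background_level + spec.cell_intensity
    return img


def _apply_psf_and_noise(
    img: np.ndarray, spec: SceneSpec, rng: np.random.Generator
) -> np.ndarray:
    if spec.psf_sigma_um > 0:
        img = ndi.gaussian_filter(img, spec.psf_sigma_um / spec.pixel_size_um)
    if spec.noise.shot_scale > 0:
        lam = np.clip(img, 0.0, None) * spec.noise.shot_scale
        img = rng.poisson(lam).astype(np.float64) / spec.noise.shot_scale
    if spec.noise.read_sd > 0:
        img = img + rng.normal(0.0, spec.noise.read_sd, size=img.shape)
    return img


def _noise_rng(seed: int, stream: int = 0) -> np.random.Generator:
    # noise children hang off child 0 of the root sequence so that geometry
    # streams (children 1..n) are untouched by how many channels are rendered
    noise_root = np.random.SeedSequence(seed).spawn(1)[0]
    return np.random.default_rng(noise_root.spawn(stream + 1)[stream])


def render_scene(
    spec: SceneSpec, seed: int
) -> tuple[np.ndarray, list[GroundTruthCell]]:
    """Render one single-channel scene and its ground truth."""
    cells = _sample_cells(spec, seed)
    img = _render_cells(spec, cells, spec.image_shape_px)
    img = _apply_psf_and_noise(img, spec, _noise_rng(seed, 0))
    return img, cells


def render_expansion_pair(
    spec: SceneSpec, seed: int
) -> tuple[np.ndarray, np.ndarray, list[GroundTruthCell], list[GroundTruthCell]]:
    """Render a pre-expansion scene and its post-expansion counterpart.

    The same sampled cells are reused: the gel factor scales centroids (and
    the frame), each species' expansion factor scales widths and lengths.
    Pixel size is unchanged — the field of view enlarges instead.
    """
    g = spec.gel_factor
    for sp in spec.species:
        if sp.expansion_factor > g + 1e-9:
            raise ValueError(
                f"gel_factor {g} < expansion_factor of species {sp.name}"
            )
    pre_cells = _sample_cells(spec, seed)
    factor = {sp.name: sp.expansion_factor for sp in spec.species}
    post_cells = [
        replace(
            c,
            centroid_um=(c.centroid_um[0] * g, c.centroid_um[1] * g),
            length_um=c.length_um * factor[c.species],
            width_um=c.width_um * factor[c.species],
        )
        for c in pre_cells
    ]
    post_shape = (
        int(round(spec.image_shape_px[0] * g)),
        int(round(spec.image_shape_px[1] * g)),
    )
    pre_img = _render_cells(spec, pre_cells, spec.image_shape_px)
    post_img = _render_cells(spec, post_cells, post_shape)
    pre_img = _apply_psf_and_noise(pre_img, spec, _noise_rng(seed, 0))
    post_img = _apply_psf_and_noise(post_img, spec, _noise_rng(seed, 1))
    return pre_img, post_img, pre_cells, post_cells


def render_halo_scene(
    spec: SceneSpec,
    halo_fraction: float,
    halo_factor: float,
    seed: int,
    halo_amplitude_frac: float = 0.5,
) -> tuple[np.ndarray, np.ndarray, list[GroundTruthCell]]:
    """Render registered cytoplasm and DNA channels with a halo phenotype.

    Every cell appears in the cytoplasm channel at its (unexpanded) width.
    Each cell is independently a halo cell with probability ``halo_fraction``;
    halo cells render their DNA as a concentric annulus reaching
    ``halo_factor`` times the cell width (Gaussian radial falloff whose
    half-maximum spans the annulus), non-halo cells render DNA colocalized
    with the cytoplasm.
    """
    if not 0.0 <= halo_fraction <= 1.0:
        raise ValueError("halo_fraction must be in [0, 1]")
    if halo_factor <= 1.0:
        raise ValueError("halo_factor must be > 1")
    max_w = max(sp.width_mean_um + 4 * sp.width_sd_um for sp in spec.species)
    margin_extra = halo_factor * max_w / 2.0
    cells = _sample_cells(spec, seed, margin_extra_um=margin_extra)
    flag_rng = _noise_rng(seed, 2)
    flags = flag_rng.random(len(cells)) < halo_fraction
    for cell, is_halo in zip(cells, flags):
        if is_halo:
            cell.phenotype = "halo"
            cell.halo_width_um = halo_factor * cell.width_um

    shape = spec.image_shape_px
    ps = spec.pixel_size_um
    cyto = _render_cells(spec, cells, shape)
    dna = np.full(shape, float(spec.background_level), dtype=np.float64)
    halo_amp = halo_amplitude_frac * spec.cell_intensity
    for cell in cells:
        x, y = cell.centroid_um
        geom = (
            (x / ps, y / ps),
            cell.orientation_rad,
            cell.length_um / ps,
            cell.width_um / ps,
        )
        if cell.phenotype == "halo":
            r_in = cell.width_um / 2.0 / ps
            r_out = cell.halo_width_um / 2.0 / ps
            r_mid = 0.5 * (r_in + r_out)
            # FWHM of the radial Gaussian equals the annulus thickness, so a
            # half-maximum threshold recovers exactly [r_in, r_out]
            sigma_r = (r_out - r_in) / (2.0 * math.sqrt(2.0 * math.log(2.0)))
            extent = cell.length_um / ps / 2.0 + r_out + 3.0 * sigma_r
            window, d = _distance_to_axis(shape, *geom, extent_px=extent)
            dna[window] += halo_amp * np.exp(
                -((d - r_mid) ** 2) / (2.0 * sigma_r**2)
            )
        else:
            mask = spherocylinder_mask(shape, *geom)
            dna[mask] += spec.cell_intensity
    cyto = _apply_psf_and_noise(cyto, spec, _noise_rng(seed, 0))
    dna = _apply_psf_and_noise(dna, spec, _noise_rng(seed, 1))
    return cyto, dna, cells
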
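import math

import numpy as np
import pytest

from exmkit import segmentation as seg
from exmkit import synthgen as sg

PX = 0.1  # default pixel size (um/px) used across fixtures


def make_species(
    name="rod",
    width_mean_um=0.8,
    width_sd_um=0.05,
    length_mean_um=2.5,
    length_sd_um=0.3,
    expansion_factor=1.0,
):
    return sg.SpeciesSpec(
        name=name,
        width_mean_um=width_mean_um,
        width_sd_um=width_sd_um,
        length_mean_um=length_mean_um,
        length_sd_um=length_sd_um,
        expansion_factor=expansion_factor,
    )


def make_scene(
    counts=(10,),
    species=None,
    shape=(300, 300),
    pixel_size_um=PX,
    min_separation_um=4.0,
    psf_sigma_um=0.0,
    background_level=0.0,
    noise=None,
    **kwargs,
):
    if species is None:
        species = (make_species(),)
    return sg.SceneSpec(
        image_shape_px=shape,
        pixel_size_um=pixel_size_um,
        species=tuple(species),
        counts=tuple(counts),
        min_separation_um=min_separation_um,
        psf_sigma_um=psf_sigma_um,
        background_level=background_level,
        noise=noise or sg.NoiseSpec(),
        **kwargs,
    )


@pytest.fixture
def clean_scene():
    """Noiseless, PSF-free 10-cell scene plus its truth."""
    spec = make_scene(counts=(10,), shape=(400, 400))
    img, truth = sg.render_scene(spec, seed=7)
    return spec, img, truth


@pytest.fixture
def noisy_scene():
    """Realistic 20-cell scene with PSF, shot and read noise."""
    spec = make_scene(
        counts=(20,),
        shape=(400, 400),
        psf_sigma_um=0.05,
        background_level=10.0,
        noise=sg.NoiseSpec(shot_scale=5.0, read_sd=2.0),
    )
    img, truth = sg.render_scene(spec, seed=11)
    return spec, img, truth


def match_to_truth(region_or_centroid_px, truth, pixel_size_um=PX):
    """Nearest ground-truth cell by centroid distance (px)."""
    if hasattr(region_or_centroid_px, "coords"):
        cy, cx = region_or_centroid_px.coords.mean(axis=0)
    else:
        cy, cx = region_or_centroid_px
    best = min(
        truth,
        key=lambda c: (c.centroid_um[0] / pixel_size_um - cx) ** 2
        + (c.centroid_um[1] / pixel_size_um - cy) ** 2,
    )
    dist_px = math.hypot(
        best.centroid_um[0] / pixel_size_um - cx,
        best.centroid_um[1] / pixel_size_um - cy,
    )
    return best, dist_px


def segment_and_measure(img, pixel_size_um=PX, cfg=None):
    from exmkit import morphometry as mm

    labels = seg.segment(
        img, cfg or seg.SegmentationConfig(), pixel_size_um=pixel_size_um
    )
    return labels, mm.measure(labels)


def rod_mask(shape, center, theta, length_px, width_px):
    """Convenience wrapper around the public spherocylinder rasterizer."""
    return sg.spherocylinder_mask(shape, center, theta, length_px, width_px)


def coords_of(mask):
    return np.argwhere(mask)
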
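"""Cell segmentation: smoothing, global threshold, distance-based watershed.

The pipeline is deliberately parameter-light and deterministic:

1. Gaussian smoothing (``smoothing_sigma_px``).
2. Global threshold (Otsu or fixed); a pixel is foreground iff strictly
   greater than the threshold.
3. Euclidean distance transform of the foreground, lightly smoothed.
4. Watershed of the negated distance map seeded at h-maxima of the distance
   map (depth ``h_minima_depth``), 8-connected.
5. Area filtering, optional border clearing, relabelling to 1..K.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.morphology import local_maxima, reconstruction
from skimage.segmentation import clear_border, relabel_sequential, watershed

__all__ = [
    "SegmentationConfig",
    "LabelImage",
    "max_intensity_project",
    "segment",
]

_STRUCT8 = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class SegmentationConfig:
    threshold_method: str = "otsu"  # "otsu" | "fixed"
    fixed_threshold: Optional[float] = None
    smoothing_sigma_px: float = 1.0
    h_minima_depth: Optional[float] = None  # None -> max(2% of peak dist, 1 px)
    min_area_px: int = 20
    max_area_px: int = 10**9
    exclude_border: bool = True

    def __post_init__(self) -> None:
        if self.threshold_method not in ("otsu", "fixed"):
            raise ValueError("threshold_method must be 'otsu' or 'fixed'")
        if (self.threshold_method == "fixed") != (self.fixed_threshold is not None):
            raise ValueError(
                "fixed_threshold is required iff threshold_method='fixed'"
            )
        if self.min_area_px >= self.max_area_px:
            raise ValueError("min_area_px must be < max_area_px")
        if self.smoothing_sigma_px < 0:
            raise ValueError("smoothing_sigma_px must be non-negative")


@dataclass
class LabelImage:
    labels: np.ndarray  # int raster, 0 background, 1..K cells
    pixel_size_um: float

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("labels must be 2D")
        if self.labels.min() < 0:
            raise ValueError("labels must be non-negative")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def n_labels(self) -> int:
        return int(self.labels.max())


def max_intensity_project(stack: np.ndarray) -> np.ndarray:
    """Per-pixel maximum over the leading (z) axis of a 3D stack."""
    stack = np.asarray(stack)
    if stack.ndim != 3 or stack.shape[0] < 1:
        raise ValueError("stack must be 3D with at least one plane")
    return stack.max(axis=0)


def segment(
    image: np.ndarray, cfg: SegmentationConfig, pixel_size_um: float = 1.0
) -> LabelImage:
    """Segment a 2D fluorescence image into labelled cells."""
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise ValueError("image must be 2D")
    if not np.all(np.isfinite(image)):
        raise ValueError("image contains non-finite pixels")

    smooth = (
        ndi.gaussian_filter(image, cfg.smoothing_sigma_px)
        if cfg.smoothing_sigma_px > 0
        else image
    )
    if cfg.threshold_method == "fixed":
        thr = float(cfg.fixed_threshold)
    else:
        if smooth.min() == smooth.max():  # flat image: nothing to segment
            return LabelImage(np.zeros(image.shape, dtype=np.int32), pixel_size_um)
        thr = float(threshold_otsu(smooth))
    fg = smooth > thr
    if not fg.any():
        return LabelImage(np.zeros(image.shape, dtype=np.int32), pixel_size_um)

    dist = ndi.distance_transform_edt(fg)
    dist_s = ndi.gaussian_filter(dist, 1.0)
    h = cfg.h_minima_depth
    if h is None:
        h = max(0.02 * float(dist_s.max()), 1.0)
    # h-maxima via grey reconstruction: regional maxima of the reconstructed
    # map are plateaus connected along rod ridges, so near-tied ridge maxima
    # do not fragment a cell into several markers
    rec = reconstruction(dist_s - h, dist_s, method="dilation")
    peaks = local_maxima(rec, connectivity=2) & fg
    markers, _ = ndi.label(peaks, structure=_STRUCT8)
    labels = watershed(-dist_s, markers, mask=fg, connectivity=2)

    # area filter
    counts = np.bincount(labels.ravel())
    bad = np.zeros(counts.size, dtype=bool)
    bad[1:] = (counts[1:] < cfg.min_area_px) | (counts[1:] > cfg.max_area_px)
    if bad.any():
        labels = np.where(bad[labels], 0, labels)
    if cfg.exclude_border:
        labels = clear_border(labels)
    labels, _, _ = relabel_sequential(labels)
    return LabelImage(labels.astype(np.int32), pixel_size_um)
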
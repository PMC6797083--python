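"""Population statistics over per-cell widths.

Covers the expansion-ratio statistic (mean post width over mean pre width,
with a cluster bootstrap over images for the SEM), width-based species
classification against single-species reference distributions, a 1D Gaussian
mixture fallback for when controls are unavailable, and DNA-halo phenotype
calling on registered cytoplasm/DNA channels.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from sklearn.mixture import GaussianMixture

from .morphometry import CellRegion, regions_from_labels, width_profile
from .segmentation import LabelImage

__all__ = [
    "WidthPopulation",
    "ExpansionResult",
    "ReferenceModel",
    "MixtureComposition",
    "MixtureFit",
    "HaloCall",
    "expansion_ratio",
    "fit_reference",
    "classify",
    "fit_mixture",
    "detect_halo",
    "halo_fraction",
]

log = logging.getLogger(__name__)

DEFAULT_SD_FLOOR_UM = 0.05  # 0.5 px at the default 0.1 um/px
DEFAULT_HALO_CUTOFF = 2.0


@dataclass
class WidthPopulation:
    widths_um: np.ndarray
    image_ids: np.ndarray  # per-width image identifier

    def __post_init__(self) -> None:
        self.widths_um = np.asarray(self.widths_um, dtype=np.float64)
        self.image_ids = np.asarray(self.image_ids)
        if self.widths_um.ndim != 1:
            raise ValueError("widths_um must be 1D")
        if self.image_ids.shape != self.widths_um.shape:
            raise ValueError("image_ids must match widths_um in length")
        if self.widths_um.size and self.widths_um.min() <= 0:
            raise ValueError("widths must be positive")

    @property
    def n(self) -> int:
        return self.widths_um.size

    @property
    def n_images(self) -> int:
        return np.unique(self.image_ids).size


@dataclass(frozen=True)
class ExpansionResult:
    ratio: float
    sem: float
    n_pre: int
    n_post: int


@dataclass(frozen=True)
class ReferenceModel:
    species: str
    mean_um: float
    sd_um: float
    prior: float = 1.0

    def __post_init__(self) -> None:
        if self.sd_um <= 0:
            raise ValueError("sd_um must be positive")
        if self.prior < 0:
            raise ValueError("prior must be non-negative")


@dataclass(frozen=True)
class MixtureComposition:
    counts: dict[str, int]
    fractions: dict[str, float]
    n_total: int


@dataclass
class MixtureFit:
    components: list[ReferenceModel]
    converged: bool
    unresolved: list[tuple[str, str]] = field(default_factory=list)


@dataclass(frozen=True)
class HaloCall:
    label: int
    cyto_width_um: float
    dna_width_um: float
    ratio: float
    expanded: bool


def expansion_ratio(
    pre: WidthPopulation,
    post: WidthPopulation,
    n_boot: int = 1000,
    seed: int = 0,
) -> ExpansionResult:
    """Mean post width / mean pre width, SEM by cluster bootstrap over images.

    When either population comes from a single image, the bootstrap resamples
    cells instead (with a warning), since image clusters cannot be resampled.
    """
    if pre.n == 0 or post.n == 0:
        raise ValueError("populations must be non-empty")
    ratio = float(post.widths_um.mean() / pre.widths_um.mean())
    rng = np.random.default_rng(seed)
    by_cells = pre.n_images < 2 or post.n_images < 2
    if by_cells:
        log.warning(
            "single image in a population; SEM bootstrap resamples cells"
        )

    def groups(pop: WidthPopulation) -> list[np.ndarray]:
        ids = np.unique(pop.image_ids)
        return [pop.widths_um[pop.image_ids == i] for i in ids]

    pre_groups, post_groups = groups(pre), groups(post)
    ratios = np.empty(n_boot)
    for b in range(n_boot):
        if by_cells:
            pre_b = rng.choice(pre.widths_um, size=pre.n, replace=True)
            post_b = rng.choice(post.widths_um, size=post.n, replace=True)
        else:
            pre_idx = rng.integers(0, len(pre_groups), size=len(pre_groups))
            post_idx = rng.integers(0, len(post_groups), size=len(post_groups))
            pre_b = np.concatenate([pre_groups[i] for i in pre_idx])
            post_b = np.concatenate([post_groups[i] for i in post_idx])
        ratios[b] = post_b.mean() / pre_b.mean()
    sem = float(ratios.std(ddof=1)) if n_boot > 1 else 0.0
    return ExpansionResult(ratio=ratio, sem=sem, n_pre=pre.n, n_post=post.n)


def fit_reference(
    widths: WidthPopulation,
    species: str,
    prior: float = 1.0,
    sd_floor_um: float = DEFAULT_SD_FLOOR_UM,
) -> ReferenceModel:
    """Single-species reference distribution from a control population."""
    if widths.n < 20:
        raise ValueError("need at least 20 widths to fit a reference")
    sd = float(widths.widths_um.std(ddof=1))
    return ReferenceModel(
        species=species,
        mean_um=float(widths.widths_um.mean()),
        sd_um=max(sd, sd_floor_um),
        prior=prior,
    )


def classify(
    widths: WidthPopulation, references: Sequence[ReferenceModel]
) -> tuple[list[str], MixtureComposition]:
    """Assign each width to the reference maximizing normal likelihood x prior.

    Posterior ties are broken toward the smaller-mean reference.
    """
    if not references:
        raise ValueError("at least one reference is required")
    means = [r.mean_um for r in references]
    if len(set(means)) != len(means):
        raise ValueError("references must have distinct means")
    # evaluate in ascending-mean order so argmax tie-breaks to smaller mean
    order = sorted(range(len(references)), key=lambda i: references[i].mean_um)
    refs = [references[i] for i in order]
    w = widths.widths_um[:, None]
    mu = np.array([r.mean_um for r in refs])[None, :]
    sd = np.array([r.sd_um for r in refs])[None, :]
    prior = np.array([r.prior for r in refs])[None, :]
    log_post = (
        -0.5 * ((w - mu) / sd) ** 2
        - np.log(sd)
        + np.log(np.maximum(prior, 1e-300))
    )
    best = np.argmax(log_post, axis=1)
    assignments = [refs[i].species for i in best]
    counts = {r.species: 0 for r in references}
    for a in assignments:
        counts[a] += 1
    n = widths.n
    fractions = {k: (v / n if n else 0.0) for k, v in counts.items()}
    return assignments, MixtureComposition(
        counts=counts, fractions=fractions, n_total=n
    )


def fit_mixture(
    widths: WidthPopulation,
    k: int,
    seed: int = 0,
    max_iter: int = 500,
    sd_floor_um: float = DEFAULT_SD_FLOOR_UM,
) -> MixtureFit:
    """k-component 1D Gaussian mixture by EM, components sorted by mean.

    Pairs of components whose mean +- 2 sd intervals overlap are reported as
    unresolved. Non-convergence returns the best-so-far fit with
    ``converged=False``.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if widths.n < 10 * k:
        raise ValueError("need at least 10*k widths")
    gm = GaussianMixture(
        n_components=k,
        covariance_type="full",
        max_iter=max_iter,
        n_init=5,
        random_state=seed,
    )
    gm.fit(widths.widths_um[:, None])
    order = np.argsort(gm.means_.ravel())
    comps = [
        ReferenceModel(
            species=f"component_{rank}",
            mean_um=float(gm.means_.ravel()[i]),
            sd_um=max(float(np.sqrt(gm.covariances_.ravel()[i])), sd_floor_um),
            prior=float(gm.weights_.ravel()[i]),
        )
        for rank, i in enumerate(order)
    ]
    unresolved = []
    for i in range(len(comps) - 1):
        a, b = comps[i], comps[i + 1]
        if a.mean_um + 2 * a.sd_um > b.mean_um - 2 * b.sd_um:
            unresolved.append((a.species, b.species))
    if not gm.converged_:
        log.warning("mixture EM did not converge after %d iterations", max_iter)
    return MixtureFit(
        components=comps, converged=bool(gm.converged_), unresolved=unresolved
    )


def _region_width(region: CellRegion) -> float:
    widths, _ = width_profile(region)
    return float(np.mean(widths))


def detect_halo(
    cyto_labels: LabelImage,
    dna_image: np.ndarray,
    cutoff: float = DEFAULT_HALO_CUTOFF,
    window_factor: float = 5.0,
) -> list[HaloCall]:
    """Call the DNA-halo phenotype per cytoplasm label.

    For each cell the DNA channel is Otsu-thresholded inside a window (the
    cell bounding box dilated by ``window_factor`` times the cytoplasm width),
    holes are filled (the halo renders as an annulus), and the five-station
    width of the DNA component overlapping the cell is compared against the
    cytoplasm width. ``expanded`` iff dna/cyto width ratio >= cutoff.
    """
    if cutoff <= 1.0:
        raise ValueError("cutoff must be > 1")
    dna_image = np.asarray(dna_image, dtype=np.float64)
    if dna_image.shape != cyto_labels.labels.shape:
        raise ValueError("dna_image must be registered with cyto_labels")
    ps = cyto_labels.pixel_size_um
    calls: list[HaloCall] = []
    for region in regions_from_labels(cyto_labels):
        cyto_w = _region_width(region)
        pad = int(math.ceil(window_factor * cyto_w / ps))
        rmin, cmin = region.coords.min(axis=0)
        rmax, cmax = region.coords.max(axis=0)
        r0 = max(0, rmin - pad)
        r1 = min(dna_image.shape[0], rmax + pad + 1)
        c0 = max(0, cmin - pad)
        c1 = min(dna_image.shape[1], cmax + pad + 1)
        win = dna_image[r0:r1, c0:c1]
        if win.min() == win.max():
            log.info("label %d: no DNA signal in window; skipped", region.label)
            continue
        fg = win > threshold_otsu(win)
        fg = ndi.binary_fill_holes(fg)
        lab, _ = ndi.label(fg, structure=np.ones((3, 3), dtype=bool))
        cell_rows = region.coords[:, 0] - r0
        cell_cols = region.coords[:, 1] - c0
        overlap = lab[cell_rows, cell_cols]
        overlap = overlap[overlap > 0]
        if overlap.size == 0:
            log.info(
                "label %d: no DNA component overlaps cell; skipped",
                region.label,
            )
            continue
        target = int(np.bincount(overlap).argmax())
        dna_coords = np.argwhere(lab == target)
        dna_coords[:, 0] += r0
        dna_coords[:, 1] += c0
        dna_region = CellRegion(
            label=region.label, coords=dna_coords, pixel_size_um=ps
        )
        dna_w = _region_width(dna_region)
        ratio = dna_w / cyto_w
        calls.append(
            HaloCall(
                label=region.label,
                cyto_width_um=cyto_w,
                dna_width_um=dna_w,
                ratio=ratio,
                expanded=ratio >= cutoff,
            )
        )
    return calls


def halo_fraction(
    calls_by_replicate: Sequence[Sequence[HaloCall]],
) -> tuple[float, float]:
    """Mean and SEM over replicates of the expanded-cell fraction."""
    fractions = []
    for i, calls in enumerate(calls_by_replicate):
        if not calls:
            log.warning("replicate %d is empty; excluded", i)
            continue
        fractions.append(sum(c.expanded for c in calls) / len(calls))
    if not fractions:
        raise ValueError("no non-empty replicates")
    fractions = np.asarray(fractions)
    mean = float(fractions.mean())
    sem = (
        float(fractions.std(ddof=1) / math.sqrt(fractions.size))
        if fractions.size > 1
        else 0.0
    )
    return mean, sem
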
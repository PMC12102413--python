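"""Tissue pre-segmentation on overview images.

The scanned area of a slide varies between scanners (internal tissue
detectors, dust, contamination), so before any registration the tissue is
segmented on an overview level and a tight ROI is derived from the
relevant particles.  Segmentation is deliberately simple — Otsu
thresholding plus morphology — with a particle-relevance filter (area and
distance to the mass center of all contours) to drop small detached
fragments and artifacts, and a manual ROI override for the cases where it
fails.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.morphology import disk

from .pyramid import Rect
from .registration import to_gray

__all__ = [
    "SegmentationResult",
    "Particle",
    "ParticleSet",
    "segment_tissue",
    "particles_from_mask",
    "filter_particles",
    "roi_from_particles",
    "override_roi",
]


@dataclass
class SegmentationResult:
    mask: np.ndarray  # bool, overview coordinates
    failed: bool  # degenerate input (constant image): empty mask


@dataclass
class Particle:
    label: int
    area: float  # px^2, overview scale
    centroid: tuple[float, float]  # (x, y), overview coords
    bbox: Rect  # overview coords


@dataclass
class ParticleSet:
    particles: list[Particle]
    downsample: float = 1.0  # back-mapping factor overview -> base
    mask_shape: tuple[int, int] | None = None

    def __len__(self) -> int:
        return len(self.particles)


def segment_tissue(
    overview: np.ndarray, selem_radius: int = 3
) -> SegmentationResult:
    """Otsu-threshold tissue (dark on light), then dilate, erode and fill holes.

    A constant image has no Otsu threshold; that case returns an empty
    mask flagged as a segmentation failure (downstream code then requires
    a manual ROI).
    """
    gray = to_gray(overview)
    if gray.size == 0:
        raise ValueError("overview image is empty")
    if np.ptp(gray) == 0:
        return SegmentationResult(np.zeros(gray.shape, dtype=bool), failed=True)
    thr = threshold_otsu(gray)
    mask = gray < thr  # tissue is darker than the white slide background
    selem = disk(selem_radius)
    mask = ndimage.binary_dilation(mask, structure=selem)
    mask = ndimage.binary_erosion(mask, structure=selem)
    mask = ndimage.binary_fill_holes(mask)
    return SegmentationResult(mask, failed=not mask.any())


def particles_from_mask(mask: np.ndarray, downsample: float = 1.0) -> ParticleSet:
    """Connected components of a tissue mask as a particle set."""
    labels, n = ndimage.label(mask)
    particles = []
    for i in range(1, n + 1):
        ys, xs = np.nonzero(labels == i)
        bbox = Rect(xs.min(), ys.min(), xs.max() - xs.min() + 1, ys.max() - ys.min() + 1)
        particles.append(
            Particle(
                label=i,
                area=float(len(xs)),
                centroid=(float(xs.mean()), float(ys.mean())),
                bbox=bbox,
            )
        )
    return ParticleSet(particles, downsample=downsample, mask_shape=mask.shape)


def filter_particles(
    pset: ParticleSet,
    k_area: float = 1.0,
    k_dist: float = 1.0,
    min_area_fraction: float = 0.01,
    area_weighted_center: bool = True,
) -> ParticleSet:
    """Keep particles relevant by size and position.

    A particle is kept when its area is at least ``mean - k_area * std`` of
    all areas AND its centroid lies within ``mean + k_dist * std`` of the
    distances to the (by default area-weighted) mass center of all
    contours.  Specks below ``min_area_fraction`` of the largest particle
    are always irrelevant; this floor also keeps the mean/std rule stable
    on two-particle sets, where the smaller particle otherwise sits
    exactly on the statistical boundary.  If the rule would drop
    everything, the largest particle is kept and a warning issued —
    downstream registration always needs an ROI.
    """
    if len(pset) == 0:
        raise ValueError("particle set is empty")
    areas = np.array([p.area for p in pset.particles])
    cents = np.array([p.centroid for p in pset.particles])
    weights = areas if area_weighted_center else np.ones_like(areas)
    center = (cents * weights[:, None]).sum(axis=0) / weights.sum()
    dists = np.hypot(*(cents - center).T)

    # inclusive comparisons with a relative slack so exact-boundary cases
    # (e.g. any two-particle set at k = 1) resolve toward keeping
    eps_a = 1e-9 * max(areas.max(), 1.0)
    eps_d = 1e-9 * max(dists.max(), 1.0)
    area_ok = areas >= areas.mean() - k_area * areas.std() - eps_a
    dist_ok = dists <= dists.mean() + k_dist * dists.std() + eps_d
    relevant = areas >= min_area_fraction * areas.max()
    keep = area_ok & dist_ok & relevant
    if not keep.any():
        warnings.warn(
            "particle relevance filter removed everything; keeping the largest",
            stacklevel=2,
        )
        keep[np.argmax(areas)] = True
    kept = [p for p, k in zip(pset.particles, keep) if k]
    return ParticleSet(kept, downsample=pset.downsample, mask_shape=pset.mask_shape)


def roi_from_particles(
    pset: ParticleSet,
    margin: float = 0.0,
    slide_rect: Rect | None = None,
) -> Rect:
    """Union bounding box of the particles, expanded by ``margin`` overview
    pixels, clipped to the slide, scaled to base coordinates."""
    if len(pset) == 0:
        raise ValueError("particle set is empty")
    x1 = min(p.bbox.x for p in pset.particles)
    y1 = min(p.bbox.y for p in pset.particles)
    x2 = max(p.bbox.x2 for p in pset.particles)
    y2 = max(p.bbox.y2 for p in pset.particles)
    roi = Rect(x1, y1, x2 - x1, y2 - y1).expanded(margin)
    if pset.mask_shape is not None:
        bounds = Rect(0, 0, pset.mask_shape[1], pset.mask_shape[0])
        clipped = roi.intersection(bounds)
        if clipped is not None:
            roi = clipped
    roi = roi.scaled(pset.downsample)
    if slide_rect is not None:
        clipped = roi.intersection(slide_rect)
        if clipped is not None:
            roi = clipped
    return roi


def override_roi(manual: Rect, slide_rect: Rect, log: list | None = None) -> Rect:
    """Replace the automatic ROI with a manually specified one, verbatim.

    The override is recorded in the run log; an ROI outside the slide is
    rejected.
    """
    if not slide_rect.contains_rect(manual):
        raise ValueError(f"manual ROI {manual} is outside the slide {slide_rect}")
    if log is not None:
        log.append({"event": "roi_override", "roi": manual.to_dict()})
    return manual
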
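"""Synthetic re-stained / re-scanned whole-slide image pairs.

Emulates the variation sources seen when one physical tissue section is
stained H&E, scanned, then re-stained with an IHC marker (hematoxylin
counterstain plus DAB-brown chromogen on a subset of nuclei) and scanned
again, possibly on a different device: changed stain appearance, slightly
different physical resolution (mpp), different scan extents and base
coordinate offsets, right-angle rotations/flips, a global similarity
misalignment, and low-amplitude smooth local deformation of the tissue.
Every generated pair carries an exact closed-form ground-truth point
mapping, which is what makes sub-pixel evaluation of the registration
pipeline possible.

The moving image is derived from the fixed one by resampling through the
composed scenario mapping, so fixed and moving depict the *same* tissue —
the re-stained / re-scanned situation, not consecutive sections.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage
from scipy.interpolate import RectBivariateSpline

from .pyramid import PyramidImage, Rect, build_pyramid
from .transforms import SimilarityTransform, similarity_from_matrix
from . import hierarchy  # orientation point maps

__all__ = [
    "SlideScenario",
    "SyntheticSlide",
    "GroundTruthMap",
    "generate_tissue_slide",
    "derive_moving_slide",
    "generate_annotations",
    "detect_nuclei",
]

BACKGROUND = 255

# Stain palettes (RGB): H&E-like and IHC-like (hematoxylin + DAB) rendering.
_HE_NUCLEUS = np.array([88.0, 60.0, 132.0])
_HE_STROMA = np.array([236.0, 182.0, 200.0])
_IHC_NUCLEUS = np.array([82.0, 96.0, 160.0])
_IHC_STROMA = np.array([232.0, 226.0, 222.0])
_IHC_DAB = np.array([136.0, 86.0, 38.0])


@dataclass
class SlideScenario:
    """Full description of how the moving slide differs from the fixed one.

    The moving-domain mapping is composed, in this fixed order, of:
    extent offset -> orientation op -> global similarity -> local smooth
    displacement (applied in the moving domain).
    """

    angle_deg: float = 0.0
    scale: float = 1.0  # physical scale misalignment (scanner imprecision)
    translation: tuple[float, float] = (0.0, 0.0)
    orientation_op: str = "none"
    stain_model: str = "he"  # {"he", "ihc"}
    mpp_ratio: float = 1.0  # moving mpp / fixed mpp (~±10 % across scanners)
    deformation_amplitude: float = 0.0  # px, RMS-scale of local displacement
    deformation_smoothness: float = 200.0  # px, correlation length
    extent_offset: tuple[float, float] = (0.0, 0.0)
    dab_fraction: float = 0.3  # nuclei receiving a DAB-brown ring under "ihc"
    noise_sigma: float = 0.0  # additive intensity noise on the moving image
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.8 <= self.scale <= 1.25:
            raise ValueError("scenario scale must lie in [0.8, 1.25]")
        if self.deformation_amplitude < 0:
            raise ValueError("deformation amplitude must be >= 0")
        if self.stain_model not in ("he", "ihc"):
            raise ValueError("stain_model must be 'he' or 'ihc'")
        if self.orientation_op not in hierarchy.ORIENTATION_OPS:
            raise ValueError(f"unknown orientation op {self.orientation_op!r}")
        if (
            self.deformation_amplitude > 0
            and self.deformation_amplitude > self.deformation_smoothness / 2
        ):
            raise ValueError(
                "folding deformation: amplitude must be <= smoothness / 2"
            )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["translation"] = list(self.translation)
        d["extent_offset"] = list(self.extent_offset)
        return d


@dataclass
class SyntheticSlide:
    """Rendered tissue slide plus the exact geometry used to draw it."""

    rgb: np.ndarray  # (H, W, 3) uint8
    nucleus_centers: np.ndarray  # (n, 2) float, (x, y)
    nucleus_labels: np.ndarray  # (H, W) int32, 0 = no nucleus
    tissue_mask: np.ndarray  # (H, W) bool
    mpp: float
    magnification: float
    seed: int

    @property
    def shape(self) -> tuple[int, int]:
        return self.rgb.shape[:2]

    def pyramid(self, n_levels: int | None = None) -> PyramidImage:
        if n_levels is None:
            n_levels = default_n_levels(self.shape)
        return build_pyramid(
            self.rgb, n_levels, mpp=self.mpp, magnification=self.magnification
        )


def default_n_levels(shape: tuple[int, int]) -> int:
    """Enough levels that the coarsest is ~32 px across (at least 1)."""
    return max(1, int(np.floor(np.log2(min(shape) / 32))) + 1)


class _DisplacementField:
    """Smooth random displacement, evaluated continuously via splines."""

    def __init__(self, shape_xy, amplitude, smoothness, rng):
        w, h = shape_xy
        self.amplitude = float(amplitude)
        step = max(smoothness / 2.0, 8.0)
        nx = max(int(np.ceil(w / step)) + 3, 4)
        ny = max(int(np.ceil(h / step)) + 3, 4)
        self.gx = np.linspace(-step, w + step, nx)
        self.gy = np.linspace(-step, h + step, ny)
        if amplitude > 0:
            # smooth the node noise one grid cell wide, renormalize to the
            # requested RMS amplitude per component
            vals = rng.normal(size=(2, ny, nx))
            vals = ndimage.gaussian_filter(vals, sigma=(0, 1.0, 1.0), mode="reflect")
            rms = np.sqrt(np.mean(vals**2))
            vals *= amplitude / max(rms, 1e-12)
        else:
            vals = np.zeros((2, ny, nx))
        self.values = vals
        self._sx = RectBivariateSpline(self.gy, self.gx, vals[0], kx=3, ky=3)
        self._sy = RectBivariateSpline(self.gy, self.gx, vals[1], kx=3, ky=3)

    def __call__(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(pts)
        dx = self._sx.ev(pts[:, 1], pts[:, 0])
        dy = self._sy.ev(pts[:, 1], pts[:, 0])
        return np.column_stack([dx, dy])

    def to_dict(self) -> dict:
        return {
            "amplitude": self.amplitude,
            "gx": self.gx.tolist(),
            "gy": self.gy.tolist(),
            "values": self.values.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "_DisplacementField":
        obj = cls.__new__(cls)
        obj.amplitude = d["amplitude"]
        obj.gx = np.asarray(d["gx"])
        obj.gy = np.asarray(d["gy"])
        obj.values = np.asarray(d["values"])
        obj._sx = RectBivariateSpline(obj.gy, obj.gx, obj.values[0], kx=3, ky=3)
        obj._sy = RectBivariateSpline(obj.gy, obj.gx, obj.values[1], kx=3, ky=3)
        return obj


@dataclass
class GroundTruthMap:
    """Exact forward mapping fixed-base -> moving-base coordinates.

    Closed form: ``p -> D(S(O(p + e)))`` with extent offset ``e``,
    orientation op ``O`` (on the fixed canvas), global similarity ``S`` and
    smooth local displacement ``D(q) = q + d(q)`` in the moving domain.
    Identical for any stain model with the same geometry.
    """

    extent_offset: tuple[float, float]
    orientation_op: str
    fixed_shape: tuple[int, int]  # (H, W) of the fixed canvas
    similarity: SimilarityTransform
    displacement: _DisplacementField
    moving_shape: tuple[int, int]  # (H, W) of the moving canvas

    def map_points(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        pts = pts + np.asarray(self.extent_offset)
        h, w = self.fixed_shape
        pts = hierarchy.map_points(self.orientation_op, pts, (w, h))
        pts = self.similarity.apply(pts)
        pts = pts + self.displacement(pts)
        return pts

    def __call__(self, points: np.ndarray) -> np.ndarray:
        return self.map_points(points)

    def inverse_points(self, points: np.ndarray, n_iter: int = 8) -> np.ndarray:
        """Numerical inverse (fixed-point on the displacement part)."""
        q = np.atleast_2d(np.asarray(points, dtype=float))
        p3 = q.copy()
        for _ in range(n_iter):
            p3 = q - self.displacement(p3)
        pts = self.similarity.inverse().apply(p3)
        h, w = self.fixed_shape
        inv_op = hierarchy.inverse_op(self.orientation_op)
        ow, oh = hierarchy.transformed_dims(self.orientation_op, (w, h))
        pts = hierarchy.map_points(inv_op, pts, (ow, oh))
        return pts - np.asarray(self.extent_offset)

    def domain_mask(self, points: np.ndarray) -> np.ndarray:
        """True where the mapped point falls on the moving canvas."""
        q = self.map_points(points)
        h, w = self.moving_shape
        return (q[:, 0] >= 0) & (q[:, 0] <= w - 1) & (q[:, 1] >= 0) & (q[:, 1] <= h - 1)

    def to_dict(self) -> dict:
        from .transforms import transform_to_dict

        return {
            "extent_offset": list(self.extent_offset),
            "orientation_op": self.orientation_op,
            "fixed_shape": list(self.fixed_shape),
            "similarity": transform_to_dict(self.similarity),
            "displacement": self.displacement.to_dict(),
            "moving_shape": list(self.moving_shape),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruthMap":
        from .transforms import transform_from_dict

        return cls(
            extent_offset=tuple(d["extent_offset"]),
            orientation_op=d["orientation_op"],
            fixed_shape=tuple(d["fixed_shape"]),
            similarity=transform_from_dict(d["similarity"]),
            displacement=_DisplacementField.from_dict(d["displacement"]),
            moving_shape=tuple(d["moving_shape"]),
        )


# ---------------------------------------------------------------------------
# Tissue rendering


def _smooth_noise(shape, sigma, rng):
    n = ndimage.gaussian_filter(rng.normal(size=shape), sigma, mode="reflect")
    s = n.std()
    return n / s if s > 0 else n


def generate_tissue_slide(
    width: int,
    height: int,
    n_nuclei: int,
    seed: int = 0,
    mpp: float = 0.25,
    magnification: float = 40.0,
    nucleus_radius: tuple[float, float] = (4.0, 7.0),
) -> SyntheticSlide:
    """Render an H&E-like slide: one tissue fragment with eosin-textured
    stroma and ``n_nuclei`` dark elliptical nuclei with irregular borders,
    on a white background.  Returns the exact nucleus center list.
    """
    if width < 64 or height < 64:
        raise ValueError("slide dimensions must be >= 64")
    if n_nuclei < 0:
        raise ValueError("n_nuclei must be >= 0")
    rng = np.random.default_rng(seed)

    yy, xx = np.mgrid[0:height, 0:width].astype(float)
    cx, cy = (width - 1) / 2.0, (height - 1) / 2.0
    ax_, ay_ = 0.40 * width, 0.38 * height
    r = np.sqrt(((xx - cx) / ax_) ** 2 + ((yy - cy) / ay_) ** 2)
    boundary_noise = _smooth_noise((height, width), min(width, height) / 8, rng)
    tissue = r + 0.12 * boundary_noise < 1.0

    texture = _smooth_noise((height, width), 6, rng)
    stroma = _HE_STROMA[None, None, :] * (1.0 + 0.06 * texture[..., None])
    img = np.full((height, width, 3), float(BACKGROUND))
    img[tissue] = stroma[tissue]

    # place non-overlapping nuclei inside the tissue (eroded margin)
    inner = ndimage.binary_erosion(tissue, iterations=int(nucleus_radius[1]) + 4)
    candidates = np.argwhere(inner)
    centers: list[tuple[float, float]] = []
    labels = np.zeros((height, width), dtype=np.int32)
    min_sep = 2 * nucleus_radius[1] + 3
    attempts = 0
    while len(centers) < n_nuclei and attempts < 200 * max(n_nuclei, 1):
        attempts += 1
        iy, ix = candidates[rng.integers(len(candidates))]
        x0 = ix + rng.uniform(-0.5, 0.5)
        y0 = iy + rng.uniform(-0.5, 0.5)
        if any((x0 - px) ** 2 + (y0 - py) ** 2 < min_sep**2 for px, py in centers):
            continue
        centers.append((x0, y0))
    if len(centers) < n_nuclei:
        raise RuntimeError(
            f"could only place {len(centers)} of {n_nuclei} nuclei without overlap"
        )

    for idx, (x0, y0) in enumerate(centers, start=1):
        ra = rng.uniform(*nucleus_radius)
        rb = rng.uniform(*nucleus_radius)
        phi = rng.uniform(0, np.pi)
        wobble_amp = 0.10
        harmonics = rng.normal(size=(2, 3))
        win = int(np.ceil(max(ra, rb) * 1.6)) + 2
        xlo, xhi = int(x0) - win, int(x0) + win + 1
        ylo, yhi = int(y0) - win, int(y0) + win + 1
        ly, lx = np.mgrid[ylo:yhi, xlo:xhi].astype(float)
        dx, dy = lx - x0, ly - y0
        c, s = np.cos(phi), np.sin(phi)
        u = (c * dx + s * dy) / ra
        v = (-s * dx + c * dy) / rb
        rad = np.sqrt(u**2 + v**2)
        ang = np.arctan2(v, u)
        wob = sum(
            harmonics[0, k] * np.cos((k + 2) * ang) + harmonics[1, k] * np.sin((k + 2) * ang)
            for k in range(3)
        )
        edge = 1.0 + wobble_amp * wob / 3.0
        # soft anti-aliased boundary
        alpha = np.clip((edge - rad) / 0.35 + 0.5, 0.0, 1.0)
        shade = 1.0 - 0.25 * np.clip(rad, 0, 1) ** 2  # darker core
        color = _HE_NUCLEUS[None, None, :] * shade[..., None]
        region = img[ylo:yhi, xlo:xhi]
        img[ylo:yhi, xlo:xhi] = alpha[..., None] * color + (1 - alpha[..., None]) * region
        labels[ylo:yhi, xlo:xhi][alpha > 0.5] = idx

    rgb = np.clip(np.round(img), 0, 255).astype(np.uint8)
    return SyntheticSlide(
        rgb=rgb,
        nucleus_centers=np.asarray(centers, dtype=float).reshape(-1, 2),
        nucleus_labels=labels,
        tissue_mask=tissue,
        mpp=mpp,
        magnification=magnification,
        seed=seed,
    )


def _restain_ihc(slide: SyntheticSlide, dab_fraction: float, rng) -> np.ndarray:
    """Re-render the fixed slide's geometry with IHC-like appearance."""
    img = np.full(slide.rgb.shape, float(BACKGROUND))
    texture = _smooth_noise(slide.shape, 6, rng)
    stroma = _IHC_STROMA[None, None, :] * (1.0 + 0.03 * texture[..., None])
    img[slide.tissue_mask] = stroma[slide.tissue_mask]

    nuc = slide.nucleus_labels > 0
    # hematoxylin counterstain on all nuclei
    img[nuc] = _IHC_NUCLEUS[None, :] * (
        1.0 + 0.05 * texture[nuc, None]
    )
    # DAB-brown annulus on a random subset (IHC labels a minority of nuclei)
    n = int(slide.nucleus_labels.max())
    if n > 0 and dab_fraction > 0:
        chosen = rng.random(n) < dab_fraction
        chosen_ids = np.flatnonzero(chosen) + 1
        subset = np.isin(slide.nucleus_labels, chosen_ids)
        ring = ndimage.binary_dilation(subset, iterations=3) & ~nuc
        img[subset] = 0.45 * img[subset] + 0.55 * _IHC_DAB[None, :]
        img[ring] = _IHC_DAB[None, :] * (1.0 + 0.08 * texture[ring, None])
    return np.clip(np.round(img), 0, 255).astype(np.uint8)


def derive_moving_slide(
    fixed: SyntheticSlide,
    scenario: SlideScenario,
    n_levels: int | None = None,
) -> tuple[PyramidImage, GroundTruthMap]:
    """Derive the re-stained / re-scanned moving slide from the fixed one.

    The moving image is the fixed image re-rendered under the scenario's
    stain model and resampled through the composed scenario mapping; the
    returned :class:`GroundTruthMap` gives the exact target coordinate of
    any fixed-base point.
    """
    rng = np.random.default_rng(scenario.seed)
    h, w = fixed.shape

    ow, oh = hierarchy.transformed_dims(scenario.orientation_op, (w, h))
    s_total = scenario.scale / scenario.mpp_ratio
    mw = max(int(round(ow * s_total)), 8)
    mh = max(int(round(oh * s_total)), 8)
    center = np.array([(ow - 1) / 2.0, (oh - 1) / 2.0])
    # similarity about the oriented-canvas center, plus re-centering onto the
    # moving canvas so the tissue stays in frame at any scale
    recenter = np.array([(mw - 1) / 2.0, (mh - 1) / 2.0]) - center
    sim = SimilarityTransform(
        angle_deg=scenario.angle_deg,
        scale=s_total,
        tx=scenario.translation[0] + recenter[0],
        ty=scenario.translation[1] + recenter[1],
        cx=center[0],
        cy=center[1],
    )
    disp = _DisplacementField(
        (mw, mh), scenario.deformation_amplitude, scenario.deformation_smoothness, rng
    )
    gt = GroundTruthMap(
        extent_offset=tuple(scenario.extent_offset),
        orientation_op=scenario.orientation_op,
        fixed_shape=(h, w),
        similarity=sim,
        displacement=disp,
        moving_shape=(mh, mw),
    )

    if scenario.stain_model == "ihc":
        source = _restain_ihc(fixed, scenario.dab_fraction, rng).astype(float)
    else:
        source = fixed.rgb.astype(float)

    qx, qy = np.meshgrid(np.arange(mw, dtype=float), np.arange(mh, dtype=float))
    q = np.column_stack([qx.ravel(), qy.ravel()])
    p = gt.inverse_points(q)
    inside = (p[:, 0] >= 0) & (p[:, 0] <= w - 1) & (p[:, 1] >= 0) & (p[:, 1] <= h - 1)

    identity_geometry = (
        scenario.orientation_op == "none"
        and scenario.angle_deg == 0
        and s_total == 1.0
        and scenario.translation == (0.0, 0.0)
        and scenario.extent_offset == (0.0, 0.0)
        and scenario.deformation_amplitude == 0
    )
    if identity_geometry:
        out = source.copy()
    else:
        out = np.full((mh, mw, 3), float(BACKGROUND))
        coords = [p[inside, 1], p[inside, 0]]
        for ch in range(3):
            vals = ndimage.map_coordinates(
                source[..., ch], coords, order=3, mode="nearest"
            )
            plane = np.full(mh * mw, float(BACKGROUND))
            plane[inside] = vals
            out[..., ch] = plane.reshape(mh, mw)
    if scenario.noise_sigma > 0:
        out += rng.normal(0, scenario.noise_sigma, out.shape)
    moving_rgb = np.clip(np.round(out), 0, 255).astype(np.uint8)

    if n_levels is None:
        n_levels = default_n_levels((mh, mw))
    pyr = build_pyramid(
        moving_rgb,
        n_levels,
        mpp=fixed.mpp * scenario.mpp_ratio,
        magnification=fixed.magnification,
    )
    return pyr, gt


# ---------------------------------------------------------------------------
# Annotations


def generate_annotations(
    n: int,
    mode: str,
    region: Rect,
    seed: int = 0,
    min_distance: float | None = None,
    max_retries: int = 10_000,
) -> np.ndarray:
    """Sample ``n`` annotation points inside ``region``.

    ``clustered`` samples uniformly; ``sparse`` additionally enforces a
    minimum pairwise distance via rejection sampling (the regime where
    per-annotation patch correction beats grid-tile refinement).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if mode not in ("clustered", "sparse"):
        raise ValueError("mode must be 'clustered' or 'sparse'")
    rng = np.random.default_rng(seed)
    if mode == "clustered":
        x = rng.uniform(region.x, region.x2, n)
        y = rng.uniform(region.y, region.y2, n)
        return np.column_stack([x, y])
    if min_distance is None:
        min_distance = 2048.0  # default: one grid-tile size
    pts: list[tuple[float, float]] = []
    tries = 0
    while len(pts) < n:
        if tries >= max_retries:
            raise RuntimeError(
                f"could not place {n} points with min distance {min_distance} "
                f"in {region} after {max_retries} tries"
            )
        tries += 1
        x = rng.uniform(region.x, region.x2)
        y = rng.uniform(region.y, region.y2)
        if all((x - px) ** 2 + (y - py) ** 2 >= min_distance**2 for px, py in pts):
            pts.append((x, y))
    return np.asarray(pts, dtype=float)


def detect_nuclei(
    rgb: np.ndarray, threshold: float = 110.0, min_area: int = 12
) -> np.ndarray:
    """Reference blob detector: intensity-weighted centroids of dark blobs.

    Used as the independent oracle that rendered (and warped) nuclei sit
    where the geometry says they should.
    """
    from .registration import to_gray

    gray = to_gray(rgb)
    dark = gray < threshold
    dark = ndimage.binary_opening(dark, iterations=1)
    labels, n = ndimage.label(dark)
    centers = []
    weight = np.clip(threshold - gray, 0, None)
    for i in range(1, n + 1):
        mask = labels == i
        if mask.sum() < min_area:
            continue
        ys, xs = np.nonzero(mask)
        wts = weight[ys, xs]
        centers.append((np.average(xs, weights=wts), np.average(ys, weights=wts)))
    return np.asarray(centers, dtype=float).reshape(-1, 2)
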
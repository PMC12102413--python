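"""Uniform access to pyramidal whole-slide images.

Whole-slide images (WSIs) are stored as multi-resolution pyramids: level 0
is the full-resolution scan ("base layer") and each subsequent level is a
2x downsampling of the previous one.  This module provides an in-memory
pyramid container, region reads addressed in base-layer coordinates, the
overview-level selection rule used for coarse registration, unit
conversions between micrometers and pixels, and plain multi-page
pyramidal-TIFF I/O.

Coordinate convention (used package-wide): 0-based, x = column increasing
rightward, y = row increasing downward; pixel centers at integer
coordinates; rectangles are half-open ``[x, x+w) x [y, y+h)``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from skimage.transform import pyramid_reduce

__all__ = [
    "Rect",
    "PyramidImage",
    "RegionRead",
    "select_overview_level",
    "read_region",
    "microns_to_pixels",
    "relative_scale_percent",
    "build_pyramid",
    "write_pyramid_tiff",
    "read_pyramid_tiff",
    "load_points",
    "save_points",
]

#: Target overview magnification of the coarse registration stage; a slide
#: scanned at nominal magnification m is registered at the pyramid level L
#: with m / 2**L closest to this value (80x -> 5, 40x -> 4).
OVERVIEW_MAGNIFICATION = 2.5

DEFAULT_BACKGROUND = 255


@dataclass(frozen=True)
class Rect:
    """Axis-aligned rectangle in base-layer pixels, half-open on both axes."""

    x: float
    y: float
    w: float
    h: float

    def __post_init__(self) -> None:
        if self.w <= 0 or self.h <= 0:
            raise ValueError(f"Rect must have positive extent, got w={self.w}, h={self.h}")

    @property
    def x2(self) -> float:
        return self.x + self.w

    @property
    def y2(self) -> float:
        return self.y + self.h

    @property
    def center(self) -> tuple[float, float]:
        return (self.x + self.w / 2.0, self.y + self.h / 2.0)

    def scaled(self, factor: float) -> "Rect":
        return Rect(self.x * factor, self.y * factor, self.w * factor, self.h * factor)

    def contains_point(self, x: float, y: float) -> bool:
        return self.x <= x < self.x2 and self.y <= y < self.y2

    def contains_rect(self, other: "Rect") -> bool:
        return (
            other.x >= self.x
            and other.y >= self.y
            and other.x2 <= self.x2
            and other.y2 <= self.y2
        )

    def intersection(self, other: "Rect") -> "Rect | None":
        x1 = max(self.x, other.x)
        y1 = max(self.y, other.y)
        x2 = min(self.x2, other.x2)
        y2 = min(self.y2, other.y2)
        if x2 <= x1 or y2 <= y1:
            return None
        return Rect(x1, y1, x2 - x1, y2 - y1)

    def expanded(self, margin: float) -> "Rect":
        return Rect(self.x - margin, self.y - margin, self.w + 2 * margin, self.h + 2 * margin)

    def to_dict(self) -> dict:
        return {"x": self.x, "y": self.y, "w": self.w, "h": self.h}

    @classmethod
    def from_dict(cls, d: dict) -> "Rect":
        return cls(d["x"], d["y"], d["w"], d["h"])


@dataclass
class PyramidImage:
    """Multi-level intensity image with per-level downsample factors.

    Parameters
    ----------
    levels
        Ordered list of 2-D (grayscale) or 3-D (RGB) arrays; ``levels[0]``
        is the base layer.
    downsample_factors
        Per-level integer downsampling relative to the base layer
        (``2**L`` by default).
    mpp_x, mpp_y
        Micrometers per pixel of the base layer along x and y.  Slight
        anisotropy between the axes is carried as metadata.
    magnification
        Nominal scan magnification (e.g. 40 or 80).
    orientation
        Orientation the slide was scanned in, one of the eight dihedral
        ops understood by :mod:`wsicoloc.hierarchy` (metadata only).
    """

    levels: list[np.ndarray]
    downsample_factors: list[int] = field(default_factory=list)
    mpp_x: float = 0.25
    mpp_y: float = 0.25
    magnification: float = 40.0
    orientation: str = "none"

    def __post_init__(self) -> None:
        if not self.levels:
            raise ValueError("PyramidImage needs at least one level")
        if not self.downsample_factors:
            self.downsample_factors = [2**i for i in range(len(self.levels))]
        if len(self.downsample_factors) != len(self.levels):
            raise ValueError("one downsample factor per level required")
        if self.mpp_x <= 0 or self.mpp_y <= 0:
            raise ValueError("mpp must be positive")
        if self.magnification <= 0:
            raise ValueError("magnification must be positive")

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    @property
    def width(self) -> int:
        return self.levels[0].shape[1]

    @property
    def height(self) -> int:
        return self.levels[0].shape[0]

    @property
    def base_rect(self) -> Rect:
        return Rect(0, 0, self.width, self.height)

    def level_shape(self, level: int) -> tuple[int, int]:
        return self.levels[level].shape[:2]

    def level_for_downsample(self, factor: float) -> int:
        """Best existing level whose downsample does not exceed ``factor``."""
        best = 0
        for i, ds in enumerate(self.downsample_factors):
            if ds <= factor + 1e-9:
                best = i
        return best


@dataclass
class RegionRead:
    """Array returned by :func:`read_region` plus a clipping flag."""

    data: np.ndarray
    clipped: bool


def select_overview_level(magnification: float, n_levels: int | None = None) -> int:
    """Pyramid level used for the coarse overview registration.

    Chooses L such that ``magnification / 2**L`` is closest to 2.5x, the
    overview magnification at which whole tissue fragments fit into memory
    while remaining structured enough to register: 80x -> 5, 40x -> 4,
    20x -> 3.  Optionally clamped to the available levels.
    """
    if magnification <= 0:
        raise ValueError("magnification must be positive")
    level = int(round(math.log2(magnification / OVERVIEW_MAGNIFICATION)))
    level = max(level, 0)
    if n_levels is not None:
        level = min(level, n_levels - 1)
    return level


def microns_to_pixels(distance_um: float, mpp: float) -> float:
    """Convert a physical distance in micrometers to pixels at ``mpp``."""
    if mpp <= 0:
        raise ValueError("mpp must be positive")
    return distance_um / mpp


def relative_scale_percent(mpp_a: float, mpp_b: float) -> float:
    """Percent size difference of structures on slide a vs slide b.

    Structures on the coarser-resolution slide (larger mpp) appear larger
    by this percentage when both slides are rendered at equal pixel counts:
    ``100 * (mpp_a / mpp_b - 1)``.
    """
    if mpp_a <= 0 or mpp_b <= 0:
        raise ValueError("mpp values must be positive")
    return 100.0 * (mpp_a / mpp_b - 1.0)


def read_region(
    pyr: PyramidImage,
    level: int,
    rect: Rect,
    background: float = DEFAULT_BACKGROUND,
) -> RegionRead:
    """Read ``rect`` (base-layer coordinates) from pyramid level ``level``.

    The rectangle is scaled down by the level's downsample factor and read
    from that level's array.  Area outside the slide is filled with the
    background value and reported via the ``clipped`` flag.
    """
    if level < 0 or level >= pyr.n_levels:
        raise IndexError(f"level {level} not in pyramid with {pyr.n_levels} levels")
    if rect.intersection(pyr.base_rect) is None:
        raise ValueError(f"rect {rect} does not intersect slide bounds")
    ds = pyr.downsample_factors[level]
    arr = pyr.levels[level]
    lh, lw = arr.shape[:2]
    x0 = int(round(rect.x / ds))
    y0 = int(round(rect.y / ds))
    w = max(1, int(round(rect.w / ds)))
    h = max(1, int(round(rect.h / ds)))

    out_shape = (h, w) + arr.shape[2:]
    out = np.full(out_shape, background, dtype=arr.dtype)
    sx0, sy0 = max(x0, 0), max(y0, 0)
    sx1, sy1 = min(x0 + w, lw), min(y0 + h, lh)
    clipped = (sx0, sy0, sx1, sy1) != (x0, y0, x0 + w, y0 + h)
    if sx1 > sx0 and sy1 > sy0:
        out[sy0 - y0 : sy1 - y0, sx0 - x0 : sx1 - x0] = arr[sy0:sy1, sx0:sx1]
    return RegionRead(out, clipped)


def build_pyramid(
    base: np.ndarray,
    n_levels: int,
    mpp: float | tuple[float, float] = 0.25,
    magnification: float = 40.0,
    orientation: str = "none",
) -> PyramidImage:
    """Build an in-memory pyramid by repeated anti-aliased 2x downsampling.

    Each level is the Gaussian-filtered (sigma = 2/3 per halving, the
    standard pyramid choice) decimation of the previous one, with dimensions
    ``ceil(previous / 2)``.
    """
    if n_levels < 1:
        raise ValueError("n_levels must be >= 1")
    max_levels = int(math.floor(math.log2(min(base.shape[:2])))) + 1
    if n_levels > max_levels:
        raise ValueError(
            f"n_levels={n_levels} exceeds log2 of the smallest dimension ({max_levels})"
        )
    mpp_x, mpp_y = (mpp, mpp) if np.isscalar(mpp) else mpp
    channel_axis = 2 if base.ndim == 3 else None
    levels = [base]
    current = base.astype(np.float64)
    is_int = np.issubdtype(base.dtype, np.integer)
    for _ in range(1, n_levels):
        current = pyramid_reduce(
            current, downscale=2, channel_axis=channel_axis, preserve_range=True
        )
        if is_int:
            info = np.iinfo(base.dtype)
            levels.append(np.clip(np.round(current), info.min, info.max).astype(base.dtype))
        else:
            levels.append(current.astype(base.dtype))
    return PyramidImage(
        levels=levels,
        mpp_x=mpp_x,
        mpp_y=mpp_y,
        magnification=magnification,
        orientation=orientation,
    )


# ---------------------------------------------------------------------------
# Plain pyramidal TIFF I/O (one page per level, metadata in ImageDescription).
# Proprietary scanner formats (.mrxs/.ndpi/.svs) are out of scope; readers
# for them can be plugged in by constructing PyramidImage directly.

def write_pyramid_tiff(path, pyr: PyramidImage) -> None:
    import tifffile

    meta = {
        "mpp_x": pyr.mpp_x,
        "mpp_y": pyr.mpp_y,
        "magnification": pyr.magnification,
        "orientation": pyr.orientation,
        "downsample_factors": list(pyr.downsample_factors),
    }
    with tifffile.TiffWriter(path) as tw:
        for i, lvl in enumerate(pyr.levels):
            tw.write(lvl, description=json.dumps(meta) if i == 0 else None)


def read_pyramid_tiff(path) -> PyramidImage:
    import tifffile

    with tifffile.TiffFile(path) as tf:
        levels = [page.asarray() for page in tf.pages]
        desc = tf.pages[0].description
    meta = json.loads(desc) if desc else {}
    return PyramidImage(
        levels=levels,
        downsample_factors=list(meta.get("downsample_factors", [])),
        mpp_x=meta.get("mpp_x", 0.25),
        mpp_y=meta.get("mpp_y", 0.25),
        magnification=meta.get("magnification", 40.0),
        orientation=meta.get("orientation", "none"),
    )


# ---------------------------------------------------------------------------
# Point-set I/O: CSV (`x,y[,label]`) or JSON list, base-layer pixels.

def load_points(path) -> np.ndarray:
    """Load an (n, 2) point array from a CSV or JSON file."""
    path = str(path)
    if path.endswith(".json"):
        with open(path) as fh:
            data = json.load(fh)
        return np.asarray([[p[0], p[1]] for p in data], dtype=float)
    pts = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(",")
            if parts[0].lower() in ("x", '"x"'):
                continue  # header
            pts.append([float(parts[0]), float(parts[1])])
    return np.asarray(pts, dtype=float).reshape(-1, 2)


def save_points(path, points: np.ndarray) -> None:
    path = str(path)
    points = np.asarray(points, dtype=float)
    if path.endswith(".json"):
        with open(path, "w") as fh:
            json.dump(points.tolist(), fh)
    else:
        with open(path, "w") as fh:
            fh.write("x,y\n")
            for x, y in points:
                fh.write(f"{x:.6g},{y:.6g}\n")
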
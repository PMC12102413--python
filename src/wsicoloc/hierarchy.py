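"""Coarse overview registration and its extrapolation to the base layer.

The hierarchical scheme registers tight tissue ROIs on downsampled
overview levels first (where whole fragments fit in memory), then carries
the estimated similarity transform down to the full-resolution base layer,
folding in the ROI offsets and any configured right-angle orientation
pre-transform.  It also provides the rotated-region extraction needed by
the refinement stages: slide readers only serve axis-aligned rectangles,
so a rotated ROI is read via its bounding box, counter-rotated, and
cropped back to the ROI's dimensions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .pyramid import PyramidImage, Rect, read_region, select_overview_level
from .registration import RegistrationConfig, RegistrationResult, register, to_gray
from .transforms import SimilarityTransform, rotation_matrix, similarity_from_matrix

__all__ = [
    "ORIENTATION_OPS",
    "map_points",
    "apply_to_image",
    "inverse_op",
    "compose_ops",
    "transformed_dims",
    "apply_orientation_pretransform",
    "CoarseResult",
    "coarse_register",
    "extrapolate_to_base",
    "extract_rotated_region",
]

# The eight dihedral (right-angle rotation / flip) operations.  Linear parts
# act on direction vectors (dx, dy); the translation part follows from the
# canvas dimensions.  rot90 is a clockwise quarter-turn on screen.
_OP_MATRICES = {
    "none": np.array([[1, 0], [0, 1]]),
    "rot90": np.array([[0, -1], [1, 0]]),
    "rot180": np.array([[-1, 0], [0, -1]]),
    "rot270": np.array([[0, 1], [-1, 0]]),
    "flip_h": np.array([[-1, 0], [0, 1]]),
    "flip_v": np.array([[1, 0], [0, -1]]),
    "transpose": np.array([[0, 1], [1, 0]]),
    "anti_transpose": np.array([[0, -1], [-1, 0]]),
}
ORIENTATION_OPS = tuple(_OP_MATRICES)

_SWAPS_DIMS = {"rot90", "rot270", "transpose", "anti_transpose"}


def transformed_dims(op: str, dims: tuple[int, int]) -> tuple[int, int]:
    """Output (W, H) after applying ``op`` to a canvas of (W, H)."""
    w, h = dims
    return (h, w) if op in _SWAPS_DIMS else (w, h)


def map_points(op: str, points: np.ndarray, dims: tuple[int, int]) -> np.ndarray:
    """Exact coordinate remap of (x, y) points under a dihedral op.

    ``dims`` is the (W, H) of the canvas the points live on *before* the
    op.  E.g. flip_h on W=100 maps (10, 20) -> (89, 20).
    """
    if op not in _OP_MATRICES:
        raise ValueError(f"unknown orientation op {op!r}")
    w, h = dims
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    x, y = pts[:, 0], pts[:, 1]
    out = {
        "none": lambda: (x, y),
        "rot90": lambda: (h - 1 - y, x),
        "rot180": lambda: (w - 1 - x, h - 1 - y),
        "rot270": lambda: (y, w - 1 - x),
        "flip_h": lambda: (w - 1 - x, y),
        "flip_v": lambda: (x, h - 1 - y),
        "transpose": lambda: (y, x),
        "anti_transpose": lambda: (h - 1 - y, w - 1 - x),
    }[op]()
    res = np.column_stack(out)
    return res[0] if np.asarray(points).ndim == 1 else res


def apply_to_image(op: str, img: np.ndarray) -> np.ndarray:
    """Apply a dihedral op to an image so pixels follow :func:`map_points`."""
    if op not in _OP_MATRICES:
        raise ValueError(f"unknown orientation op {op!r}")
    return {
        "none": lambda m: m,
        "rot90": lambda m: np.rot90(m, k=-1, axes=(0, 1)),
        "rot180": lambda m: np.rot90(m, k=2, axes=(0, 1)),
        "rot270": lambda m: np.rot90(m, k=1, axes=(0, 1)),
        "flip_h": lambda m: m[:, ::-1],
        "flip_v": lambda m: m[::-1, :],
        "transpose": lambda m: m.swapaxes(0, 1),
        "anti_transpose": lambda m: np.rot90(m, k=2, axes=(0, 1)).swapaxes(0, 1),
    }[op](img).copy()


def inverse_op(op: str) -> str:
    if op not in _OP_MATRICES:
        raise ValueError(f"unknown orientation op {op!r}")
    inv = np.linalg.inv(_OP_MATRICES[op]).round().astype(int)
    return next(name for name, M in _OP_MATRICES.items() if np.array_equal(M, inv))


def compose_ops(outer: str, inner: str) -> str:
    """Name of the op equivalent to applying ``inner`` first, then ``outer``."""
    M = _OP_MATRICES[outer] @ _OP_MATRICES[inner]
    return next(name for name, Mi in _OP_MATRICES.items() if np.array_equal(Mi, M))


def apply_orientation_pretransform(obj, op: str, dims: tuple[int, int] | None = None):
    """Apply a dihedral op to points (needs ``dims``) or to an image array."""
    arr = np.asarray(obj)
    if arr.ndim >= 2 and (arr.ndim == 3 or dims is None or arr.shape[1] != 2):
        return apply_to_image(op, arr)
    if dims is None:
        raise ValueError("point remap requires the canvas dims (W, H)")
    return map_points(op, arr, dims)


# ---------------------------------------------------------------------------
# Coarse stage


@dataclass
class CoarseResult:
    """Overview-level similarity estimate plus everything needed to
    extrapolate it to the base layer."""

    transform: SimilarityTransform  # overview-crop coords, fixed -> moving
    roi_fixed: Rect  # base coords, snapped to the overview grid
    roi_moving: Rect
    level_fixed: int
    level_moving: int
    downsample_fixed: int
    downsample_moving: int
    metric: float = 0.0
    status: str = "ok"
    registration: RegistrationResult | None = field(default=None, repr=False)


def _snap_rect(rect: Rect, ds: int) -> Rect:
    """Snap a base-coordinate rect onto the overview pixel grid."""
    x = round(rect.x / ds) * ds
    y = round(rect.y / ds) * ds
    w = max(1, round(rect.w / ds)) * ds
    h = max(1, round(rect.h / ds)) * ds
    return Rect(x, y, w, h)


def coarse_register(
    fixed: PyramidImage,
    moving: PyramidImage,
    roi_fixed: Rect,
    roi_moving: Rect,
    levels: tuple[int, int] | None = None,
    config: RegistrationConfig | None = None,
) -> CoarseResult:
    """Similarity-register the two ROI overviews, center-initialized.

    ``levels`` defaults to the overview-level selection rule applied to
    each slide's magnification, so both overviews share approximately the
    same mpp.
    """
    if levels is None:
        levels = (
            select_overview_level(fixed.magnification, fixed.n_levels),
            select_overview_level(moving.magnification, moving.n_levels),
        )
    lf, lm = levels
    dsf = fixed.downsample_factors[lf]
    dsm = moving.downsample_factors[lm]
    roi_fixed = _snap_rect(roi_fixed, dsf)
    roi_moving = _snap_rect(roi_moving, dsm)
    crop_f = read_region(fixed, lf, roi_fixed).data
    crop_m = read_region(moving, lm, roi_moving).data
    cfg = config or RegistrationConfig()
    res = register(to_gray(crop_f), to_gray(crop_m), model="similarity", config=cfg)
    return CoarseResult(
        transform=res.transform,
        roi_fixed=roi_fixed,
        roi_moving=roi_moving,
        level_fixed=lf,
        level_moving=lm,
        downsample_fixed=dsf,
        downsample_moving=dsm,
        metric=res.metric,
        status=res.status,
        registration=res,
    )


def extrapolate_to_base(cr: CoarseResult) -> SimilarityTransform:
    """Express the overview-crop transform in base-layer coordinates.

    Rotation angle is unchanged; translations, centers (and scale, when
    the two overviews have different downsample factors) absorb the level
    factors and the ROI offset translations:
    ``p_base -> roi_m.origin + ds_m * T((p_base - roi_f.origin) / ds_f)``.
    This is the single place in the pipeline where scale conversion between
    levels happens.
    """
    T = cr.transform
    H = T.matrix
    pre = np.array(
        [
            [1.0 / cr.downsample_fixed, 0, -cr.roi_fixed.x / cr.downsample_fixed],
            [0, 1.0 / cr.downsample_fixed, -cr.roi_fixed.y / cr.downsample_fixed],
            [0, 0, 1],
        ]
    )
    post = np.array(
        [
            [cr.downsample_moving, 0, cr.roi_moving.x],
            [0, cr.downsample_moving, cr.roi_moving.y],
            [0, 0, 1],
        ]
    )
    M = post @ H @ pre
    cx, cy = cr.roi_fixed.center
    return similarity_from_matrix(M, cx=cx, cy=cy)


def write_roi_overlay(
    fixed: PyramidImage,
    moving: PyramidImage,
    cr: CoarseResult,
    path,
) -> None:
    """Diagnostic overlay for manual inspection of the pre-registration.

    Draws the fixed ROI outline and the coarse-mapped (rotated) ROI
    outline on the moving overview side by side, saved as PNG.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.patches import Polygon

    base_T = extrapolate_to_base(cr)
    fig, axes = plt.subplots(1, 2, figsize=(10, 5))
    for ax, pyr, level in (
        (axes[0], fixed, cr.level_fixed),
        (axes[1], moving, cr.level_moving),
    ):
        img = pyr.levels[level]
        ax.imshow(img, cmap=None if img.ndim == 3 else "gray")
        ax.set_axis_off()
    dsf = cr.downsample_fixed
    r = cr.roi_fixed
    corners = np.array([[r.x, r.y], [r.x2, r.y], [r.x2, r.y2], [r.x, r.y2]])
    axes[0].add_patch(Polygon(corners / dsf, closed=True, fill=False, edgecolor="purple", lw=2))
    axes[0].set_title("fixed ROI")
    mapped = base_T.apply(corners) / cr.downsample_moving
    axes[1].add_patch(Polygon(mapped, closed=True, fill=False, edgecolor="purple", lw=2))
    axes[1].set_title("coarse-mapped ROI on moving")
    fig.savefig(path, dpi=100, bbox_inches="tight")
    plt.close(fig)


def extract_rotated_region(
    pyr: PyramidImage,
    rect: Rect,
    angle_deg: float,
    center: tuple[float, float] | None = None,
    level: int = 0,
    order: int = 3,
    background: float = 255.0,
):
    """Extract ``rect`` rotated by ``angle_deg`` about ``center``.

    Slide formats only serve axis-aligned tiles, so the rotated rect is
    wrapped in its bounding box, read, counter-rotated about the box
    center with B-spline interpolation, and cropped centrally back to the
    rect's dimensions.  Returns ``(patch, clipped)``; the patch has
    ``rect``'s dimensions at the requested level's scale.  Output pixel
    (u, v) holds the slide value at
    ``center + R(angle) @ ((u, v) - rect_center_offset)`` (level coords).
    """
    ds = pyr.downsample_factors[level]
    w = max(1, int(round(rect.w / ds)))
    h = max(1, int(round(rect.h / ds)))
    if center is None:
        # pixel-grid center of the rect at this level (origin + (n-1)/2)
        center = (
            (rect.x / ds + (w - 1) / 2.0) * ds,
            (rect.y / ds + (h - 1) / 2.0) * ds,
        )
    cx, cy = center[0] / ds, center[1] / ds
    R = rotation_matrix(angle_deg)

    # bounding box of the rotated rect (level coords), with a margin for
    # the interpolation support
    rel = np.array(
        [
            [rect.x / ds - cx, rect.y / ds - cy],
            [rect.x2 / ds - cx, rect.y / ds - cy],
            [rect.x / ds - cx, rect.y2 / ds - cy],
            [rect.x2 / ds - cx, rect.y2 / ds - cy],
        ]
    )
    corners = rel @ R.T + np.array([cx, cy])
    margin = order + 1
    bx0 = np.floor(corners[:, 0].min()) - margin
    by0 = np.floor(corners[:, 1].min()) - margin
    bx1 = np.ceil(corners[:, 0].max()) + margin
    by1 = np.ceil(corners[:, 1].max()) + margin
    bbox = Rect(bx0 * ds, by0 * ds, (bx1 - bx0) * ds, (by1 - by0) * ds)
    if bbox.intersection(pyr.base_rect) is None:
        raise ValueError(f"rotated region bounding box {bbox} is outside the slide")
    rr = read_region(pyr, level, bbox, background=background)
    crop = rr.data.astype(float)

    # patch-frame coordinates; the patch-frame center pixel corresponds to
    # the rect's pixel-grid center (origin + (n-1)/2) rotated about `center`
    uu, vv = np.meshgrid(np.arange(w, dtype=float), np.arange(h, dtype=float))
    pc = np.array([(w - 1) / 2.0, (h - 1) / 2.0])
    rect_c = np.array([rect.x / ds + (w - 1) / 2.0, rect.y / ds + (h - 1) / 2.0])
    rel_pts = np.column_stack([uu.ravel() - pc[0], vv.ravel() - pc[1]]) + (
        rect_c - np.array([cx, cy])
    )
    slide_pts = rel_pts @ R.T + np.array([cx, cy])
    local = slide_pts - np.array([bx0, by0])

    def interp(chan):
        return ndimage.map_coordinates(
            chan, [local[:, 1], local[:, 0]], order=order, mode="nearest"
        ).reshape(h, w)

    if crop.ndim == 3:
        out = np.stack([interp(crop[..., c]) for c in range(crop.shape[2])], axis=-1)
    else:
        out = interp(crop)
    if np.issubdtype(rr.data.dtype, np.integer):
        info = np.iinfo(rr.data.dtype)
        out = np.clip(np.round(out), info.min, info.max).astype(rr.data.dtype)
    return out, rr.clipped
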
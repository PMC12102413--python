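"""Base-layer refinement of the coarse registration.

Two strategies trade computation against annotation layout:

* Strategy I (clustered annotations): the fixed ROI is divided into a
  row-major grid of equal tiles; each tile containing annotations is
  re-registered (rigid by default) against its coarse-mapped moving
  region, yielding one correction per tile that all annotations in the
  tile share.  The resulting chain is reusable for new point sets.
* Strategy II (sparse annotations): a small square patch (128–256 px,
  default 192) is cut around every single annotation, its coarse-mapped
  counterpart extracted from the moving slide with the coarse rotation
  compensated, and an affine correction registered per annotation.

Both produce correction steps expressed in moving base-layer coordinates
so they slot into a :class:`~wsicoloc.chain.TransformChain` after the
base similarity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .chain import ChainStep
from .pyramid import PyramidImage, Rect, read_region
from .registration import RegistrationConfig, register, to_gray
from .transforms import AffineTransform, SimilarityTransform, rotation_matrix

__all__ = [
    "GridTile",
    "PointCorrection",
    "build_grid",
    "count_registered_pixels",
    "refine_tiles_strategy1",
    "refine_point_strategy2",
    "choose_strategy",
    "refinement_config",
]

PATCH_SIZE_RANGE = (64, 1024)
DEFAULT_PATCH_SIZE = 192  # center of the proposed 128-256 px range
DEFAULT_TILE_SIZE = 2048


def refinement_config(seed: int = 0, tile: bool = False) -> RegistrationConfig:
    """Reduced-budget registration settings for the refinement stages.

    The inputs are already well aligned by the coarse stage, so iteration
    counts, sampling and resolution levels are cut down sharply relative
    to the coarse defaults.
    """
    if tile:
        return RegistrationConfig(
            n_resolutions=2, iterations=150, n_samples=2048,
            polish_iterations=80, polish_samples=4096, seed=seed,
        )
    return RegistrationConfig(
        n_resolutions=2, iterations=100, n_samples=1024,
        polish_iterations=80, polish_samples=2048, seed=seed,
    )


@dataclass
class GridTile:
    """One fixed-side grid tile and its refinement state."""

    index: int  # row-major
    rect: Rect  # fixed base coordinates (T_I)
    moving_rect: Rect | None = None  # coarse-mapped bounding rect (T_M)
    correction: AffineTransform | None = None  # on moving base coords
    status: str = "pending"  # pending | ok | failed | low-overlap | empty
    metric: float = 0.0
    annotation_indices: list = field(default_factory=list)


@dataclass
class PointCorrection:
    """Per-annotation correction produced by Strategy II."""

    annotation_id: int
    patch_size: int
    correction: AffineTransform | None  # on moving base coords
    corrected_point: np.ndarray  # final moving base coordinate (continuous)
    metric: float = 0.0
    status: str = "ok"  # ok | out-of-bounds | failed


def build_grid(
    roi: Rect,
    tile_size: float | None = None,
    n_tiles: int | None = None,
    annotations: np.ndarray | None = None,
) -> list[GridTile]:
    """Row-major grid of equal tiles covering the ROI.

    Exactly one of ``tile_size`` (edge length) or ``n_tiles`` (approximate
    target count, converted to an edge length) must be given.  Tiles in
    the last row/column may extend past the ROI and are clipped at read
    time.  When ``annotations`` is supplied, only tiles containing at
    least one annotation are retained; a point on a tile boundary belongs
    to the tile whose half-open rect contains it (the lower row-major
    index).
    """
    if (tile_size is None) == (n_tiles is None):
        raise ValueError("give exactly one of tile_size or n_tiles")
    if n_tiles is not None:
        if n_tiles < 1:
            raise ValueError("n_tiles must be >= 1")
        tile_size = math.ceil(math.sqrt(roi.w * roi.h / n_tiles))
    if tile_size <= 0:
        raise ValueError("tile_size must be positive")
    if tile_size > max(roi.w, roi.h):
        import warnings

        warnings.warn("tile_size exceeds the ROI; using a single tile", stacklevel=2)
    nx = max(1, math.ceil(roi.w / tile_size))
    ny = max(1, math.ceil(roi.h / tile_size))
    tiles = []
    for iy in range(ny):
        for ix in range(nx):
            rect = Rect(roi.x + ix * tile_size, roi.y + iy * tile_size, tile_size, tile_size)
            tiles.append(GridTile(index=iy * nx + ix, rect=rect))
    if annotations is not None:
        pts = np.atleast_2d(np.asarray(annotations, dtype=float))
        for tile in tiles:
            r = tile.rect
            mask = (
                (pts[:, 0] >= r.x) & (pts[:, 0] < r.x2)
                & (pts[:, 1] >= r.y) & (pts[:, 1] < r.y2)
            )
            tile.annotation_indices = list(np.flatnonzero(mask))
        tiles = [t for t in tiles if t.annotation_indices]
    return tiles


def count_registered_pixels(n_tiles: int, tile_size: int) -> int:
    """Total pixels registered by ``n_tiles`` square tiles (logs report
    this in millions with two decimals)."""
    if n_tiles < 1:
        raise ValueError("n_tiles must be >= 1")
    return int(n_tiles) * int(tile_size) ** 2


def _patch_frame(
    base_transform: SimilarityTransform,
    origin_fixed: np.ndarray,
    px_spacing: float = 1.0,
) -> AffineTransform:
    """Map patch-frame coords -> moving base coords.

    The fixed patch pixel u sits at base coordinate
    ``origin_fixed + u * px_spacing`` (``px_spacing`` = downsample factor
    of the level the fixed patch was read from), so its coarse-mapped
    position is ``G(u) = T(origin_fixed) + s * px_spacing * R(theta) @ u``.
    Using the actual read-grid origin avoids any sub-pixel center
    convention.
    """
    q_o = base_transform.apply(origin_fixed)
    M = base_transform.scale * px_spacing * rotation_matrix(base_transform.angle_deg)
    return AffineTransform(matrix=M, tx=q_o[0], ty=q_o[1], cx=0.0, cy=0.0)


def _extract_moving_patch(
    moving: PyramidImage,
    G: AffineTransform,
    patch_dims: tuple[int, int],
    level: int = 0,
    order: int = 3,
    background: float = 255.0,
):
    """Moving-side patch on the fixed patch grid through the base transform.

    Extracts the coarse-mapped region with the coarse rotation compensated
    (bounding-box read + counter-rotation folded into one resampling) and
    the coarse scale absorbed by sampling at the fixed grid spacing:
    ``patch(u) = moving(G(u))`` for every patch pixel u, with ``G`` the
    patch-frame map from :func:`_patch_frame`.
    """
    from scipy import ndimage as ndi

    w, h = patch_dims
    ds = moving.downsample_factors[level]
    uu, vv = np.meshgrid(np.arange(w, dtype=float), np.arange(h, dtype=float))
    pts = G.apply(np.column_stack([uu.ravel(), vv.ravel()])) / ds

    margin = order + 1
    bx0 = np.floor(pts[:, 0].min()) - margin
    by0 = np.floor(pts[:, 1].min()) - margin
    bx1 = np.ceil(pts[:, 0].max()) + margin
    by1 = np.ceil(pts[:, 1].max()) + margin
    bbox = Rect(bx0 * ds, by0 * ds, (bx1 - bx0) * ds, (by1 - by0) * ds)
    if bbox.intersection(moving.base_rect) is None:
        raise ValueError(f"mapped patch bounding box {bbox} is outside the moving slide")
    rr = read_region(moving, level, bbox, background=background)
    crop = to_gray(rr.data)
    local = pts - np.array([bx0, by0])
    out = ndi.map_coordinates(crop, [local[:, 1], local[:, 0]], order=order, mode="nearest")
    return out.reshape(h, w), rr.clipped


def _plausible(correction: AffineTransform, patch_dims: tuple[int, int], limit_frac: float = 0.25) -> bool:
    """Reject corrections displacing the patch by more than a fraction of
    its size — the coarse alignment guarantees residuals are small."""
    w, h = patch_dims
    pc = np.array([(w - 1) / 2.0, (h - 1) / 2.0])
    shift = np.linalg.norm(correction.apply(pc) - pc)
    return shift <= limit_frac * max(w, h)


def refine_tiles_strategy1(
    grid: list[GridTile],
    base_transform: SimilarityTransform,
    fixed: PyramidImage,
    moving: PyramidImage,
    config: RegistrationConfig | None = None,
    level_fixed: int = 0,
    level_moving: int = 0,
    model: str = "rigid",
    audit: list | None = None,
) -> list[GridTile]:
    """Register every retained grid tile against its coarse-mapped region.

    Per-tile failures never abort the run: a failed tile keeps
    ``correction=None`` and falls back to the base transform.  The
    correction is an affine step on moving base coordinates, valid for
    points in the tile's fixed-frame rect.
    """
    cfg = config or refinement_config(tile=True)
    dsf = fixed.downsample_factors[level_fixed]
    for tile in grid:
        w = int(round(tile.rect.w / dsf))
        h = int(round(tile.rect.h / dsf))
        # actual read-grid origin of the fixed tile (read_region rounds)
        origin_fixed = np.array(
            [round(tile.rect.x / dsf) * dsf, round(tile.rect.y / dsf) * dsf], float
        )
        G = _patch_frame(base_transform, origin_fixed, px_spacing=dsf)
        q0 = base_transform.apply(np.array(tile.rect.center))
        s = base_transform.scale
        tile.moving_rect = Rect(
            q0[0] - tile.rect.w * s / 2.0, q0[1] - tile.rect.h * s / 2.0,
            tile.rect.w * s, tile.rect.h * s,
        )
        try:
            fixed_patch = to_gray(read_region(fixed, level_fixed, tile.rect).data)
            moving_patch, clipped = _extract_moving_patch(
                moving, G, (w, h), level=level_moving,
            )
        except ValueError:
            tile.status = "low-overlap"
            _audit(audit, "tile", tile.index, tile.status, None, 0.0)
            continue
        res = register(fixed_patch, moving_patch, model=model, config=replace(cfg, seed=cfg.seed + tile.index))
        C = res.transform
        if res.status != "ok" or not _plausible(_as_affine(C), (w, h)):
            tile.status = "failed"
            _audit(audit, "tile", tile.index, tile.status, None, res.metric)
            continue
        C_base = _patch_to_base_correction(C, G)
        tile.correction = C_base
        tile.metric = res.metric
        tile.status = "ok"
        _audit(audit, "tile", tile.index, "ok", C_base, res.metric)
    return grid


def _as_affine(T) -> AffineTransform:
    return AffineTransform(matrix=T.linear, tx=T.tx, ty=T.ty, cx=T.cx, cy=T.cy)


def _patch_to_base_correction(C, G: AffineTransform) -> AffineTransform:
    """Lift a patch-frame correction to moving base coordinates.

    G maps the patch frame into moving base coords (including the fixed
    pixel spacing), so the step acting on coarse-mapped moving coords is
    A = G ∘ C ∘ G^{-1}.
    """
    Gm = G.matrix
    A = Gm @ _as_affine(C).matrix @ np.linalg.inv(Gm)
    return AffineTransform(matrix=A[:2, :2], tx=A[0, 2], ty=A[1, 2], cx=0.0, cy=0.0)


def _audit(audit, kind, ident, status, transform, metric):
    if audit is None:
        return
    from .transforms import transform_to_dict

    audit.append(
        {
            "kind": kind,
            "id": int(ident),
            "status": status,
            "transform": transform_to_dict(transform) if transform is not None else None,
            "metric": float(metric),
        }
    )


def refine_point_strategy2(
    p: np.ndarray,
    base_transform: SimilarityTransform,
    fixed: PyramidImage,
    moving: PyramidImage,
    patch_size: int = DEFAULT_PATCH_SIZE,
    config: RegistrationConfig | None = None,
    level_fixed: int = 0,
    level_moving: int = 0,
    annotation_id: int = 0,
    mapped_point: np.ndarray | None = None,
    audit: list | None = None,
) -> PointCorrection:
    """Affine-correct a single annotation from a small centered patch.

    Reads the fixed patch centered on ``p`` and the coarse-mapped moving
    patch centered on ``base_transform(p)`` (coarse rotation compensated,
    scale absorbed), registers an affine correction, and returns the
    corrected moving base coordinate.  Points too close to a slide edge
    are flagged and keep their coarse-mapped coordinate.

    ``mapped_point`` overrides the coarse-mapped position of ``p`` — used
    when a grid-tile refinement ran first and the correction should start
    from the tile-refined coordinate.
    """
    if not PATCH_SIZE_RANGE[0] <= patch_size <= PATCH_SIZE_RANGE[1]:
        raise ValueError(
            f"patch_size must be in [{PATCH_SIZE_RANGE[0]}, {PATCH_SIZE_RANGE[1]}]"
        )
    cfg = config or refinement_config()
    p = np.asarray(p, dtype=float)
    dsf = fixed.downsample_factors[level_fixed]
    half = patch_size * dsf / 2.0
    q0 = base_transform.apply(p) if mapped_point is None else np.asarray(mapped_point, float)

    fx_ok = half <= p[0] <= fixed.width - half and half <= p[1] <= fixed.height - half
    s = base_transform.scale
    mhalf = patch_size * s * dsf / 2.0
    mv_ok = (
        mhalf <= q0[0] <= moving.width - mhalf and mhalf <= q0[1] <= moving.height - mhalf
    )
    if not (fx_ok and mv_ok):
        pc = PointCorrection(annotation_id, patch_size, None, q0, status="out-of-bounds")
        _audit(audit, "point", annotation_id, pc.status, None, 0.0)
        return pc

    frect = Rect(p[0] - half, p[1] - half, patch_size * dsf, patch_size * dsf)
    origin_fixed = np.array(
        [round(frect.x / dsf) * dsf, round(frect.y / dsf) * dsf], float
    )
    G = _patch_frame(base_transform, origin_fixed, px_spacing=dsf)
    if mapped_point is not None:
        shift = q0 - base_transform.apply(p)
        G = AffineTransform(matrix=G.linear, tx=G.tx + shift[0], ty=G.ty + shift[1])
    fixed_patch = to_gray(read_region(fixed, level_fixed, frect).data)
    moving_patch, _ = _extract_moving_patch(
        moving, G, (patch_size, patch_size), level=level_moving
    )
    res = register(
        fixed_patch, moving_patch, model="affine",
        config=replace(cfg, seed=cfg.seed + annotation_id),
    )
    C = res.transform
    if res.status != "ok" or not _plausible(_as_affine(C), (patch_size, patch_size)):
        pc = PointCorrection(annotation_id, patch_size, None, q0, status="failed", metric=res.metric)
        _audit(audit, "point", annotation_id, pc.status, None, res.metric)
        return pc
    C_base = _patch_to_base_correction(C, G)
    corrected = C_base.apply(q0)
    pc = PointCorrection(
        annotation_id, patch_size, C_base, corrected, metric=res.metric, status="ok"
    )
    _audit(audit, "point", annotation_id, "ok", C_base, res.metric)
    return pc


def strategy1_chain_steps(grid: list[GridTile], start_order: int) -> list[ChainStep]:
    """Chain steps for the successful tiles, in row-major order."""
    steps = []
    order = start_order
    for tile in sorted(grid, key=lambda t: t.index):
        if tile.correction is None:
            continue
        steps.append(
            ChainStep(
                kind="tile", order=order, transform=tile.correction,
                domain=tile.rect, meta={"tile_index": tile.index, "status": tile.status},
            )
        )
        order += 1
    return steps


def strategy2_chain_steps(corrections: list[PointCorrection], start_order: int) -> list[ChainStep]:
    steps = []
    order = start_order
    for pc in corrections:
        if pc.correction is None:
            continue
        steps.append(
            ChainStep(
                kind="point", order=order, transform=pc.correction,
                annotation_id=pc.annotation_id,
                meta={"status": pc.status, "patch_size": pc.patch_size},
            )
        )
        order += 1
    return steps


def choose_strategy(
    points: np.ndarray,
    roi: Rect,
    tile_size: int = DEFAULT_TILE_SIZE,
    patch_size: int = DEFAULT_PATCH_SIZE,
    cost_per_pixel: float = 1.0,
    registration_overhead_px: float = 41_000.0,
) -> str:
    """Advisory choice between the strategies by registered-pixel cost.

    Densely clustered annotations share tiles, so grid refinement
    registers fewer pixels; sparse annotations waste tile area and are
    cheaper patch-by-patch.  Each registration also carries a fixed
    overhead (``registration_overhead_px``, in pixel-equivalents), which
    is what makes many tiny patches slower per pixel than few large
    tiles.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if len(pts) < 1:
        raise ValueError("need at least one point")
    occupied = max(len(build_grid(roi, tile_size=tile_size, annotations=pts)), 1)
    cost1 = cost_per_pixel * (
        count_registered_pixels(occupied, tile_size) + occupied * registration_overhead_px
    )
    cost2 = cost_per_pixel * len(pts) * (patch_size**2 + registration_overhead_px)
    return "strategy1" if cost1 < cost2 else "strategy2"
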
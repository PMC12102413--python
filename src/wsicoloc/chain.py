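"""Ordered transformation chains applied to point sets.

Computing transformation parameters (registration) and applying them to
concrete coordinates (transformation) are decoupled: a chain records the
steps in the order they were created — orientation pre-transform, base
similarity from the coarse stage, then per-tile or per-annotation
corrections with their applicability domains — and can be serialized,
reloaded bit-exactly, and reused on new point sets (grid-tile chains
only; per-annotation corrections are tied to their annotation ids).

Continuous results are discretized to target pixels by rounding
half-to-even.  Optionally, for grid-tile chains, the per-tile correction
displacements sampled at tile centers can be interpolated with a cubic
B-spline across tiles, yielding a smooth correction field instead of the
piecewise-constant per-tile default.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from . import hierarchy
from .pyramid import Rect
from .transforms import transform_from_dict, transform_to_dict

__all__ = [
    "ChainStep",
    "TransformChain",
    "ChainError",
    "NotReusableError",
    "compose_chain",
    "apply_chain",
    "reuse_chain",
]

CHAIN_FORMAT_VERSION = 1


class ChainError(ValueError):
    pass


class NotReusableError(ChainError):
    """Raised when a per-annotation chain is applied to unseen points."""


@dataclass
class ChainStep:
    """One transformation step.

    kind:
      - ``orientation``: exact dihedral remap of the fixed canvas
        (payload: op name + canvas dims).
      - ``global``: base similarity, applies to every point.
      - ``tile``: affine correction on moving coordinates, applicable to
        points whose *original fixed* coordinate lies in ``domain``.
      - ``point``: affine correction on moving coordinates, applicable to
        one annotation id.
    """

    kind: str
    order: int
    transform: object | None = None
    op: str | None = None
    dims: tuple[int, int] | None = None  # (W, H) for orientation steps
    domain: Rect | None = None  # fixed-frame tile rect
    annotation_id: int | None = None
    meta: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {"kind": self.kind, "order": self.order, "meta": self.meta}
        if self.transform is not None:
            d["transform"] = transform_to_dict(self.transform)
        if self.op is not None:
            d["op"] = self.op
            d["dims"] = list(self.dims)
        if self.domain is not None:
            d["domain"] = self.domain.to_dict()
        if self.annotation_id is not None:
            d["annotation_id"] = self.annotation_id
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ChainStep":
        return cls(
            kind=d["kind"],
            order=d["order"],
            transform=transform_from_dict(d["transform"]) if "transform" in d else None,
            op=d.get("op"),
            dims=tuple(d["dims"]) if "dims" in d else None,
            domain=Rect.from_dict(d["domain"]) if "domain" in d else None,
            annotation_id=d.get("annotation_id"),
            meta=d.get("meta", {}),
        )


@dataclass
class TransformChain:
    steps: list[ChainStep]
    provenance: dict = field(default_factory=dict)

    @property
    def has_point_steps(self) -> bool:
        return any(s.kind == "point" for s in self.steps)

    @property
    def known_annotation_ids(self) -> set:
        return {s.annotation_id for s in self.steps if s.kind == "point"}

    def to_json(self) -> str:
        return json.dumps(
            {
                "format_version": CHAIN_FORMAT_VERSION,
                "steps": [s.to_dict() for s in self.steps],
                "provenance": self.provenance,
            },
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, s: str) -> "TransformChain":
        d = json.loads(s)
        if d.get("format_version") != CHAIN_FORMAT_VERSION:
            raise ChainError(f"unsupported chain format {d.get('format_version')!r}")
        return cls(
            steps=[ChainStep.from_dict(sd) for sd in d["steps"]],
            provenance=d.get("provenance", {}),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json())

    @classmethod
    def load(cls, path) -> "TransformChain":
        with open(path) as fh:
            return cls.from_json(fh.read())


def compose_chain(steps: list[ChainStep], provenance: dict | None = None) -> TransformChain:
    """Validate and assemble steps into a chain.

    Steps must be declared in creation order (strictly increasing
    ``order``); two tile steps may not claim overlapping fixed-frame
    domains, and two point steps may not claim the same annotation.
    """
    orders = [s.order for s in steps]
    if orders != sorted(orders) or len(set(orders)) != len(orders):
        raise ChainError("steps must be declared in strictly increasing creation order")
    tiles = [s for s in steps if s.kind == "tile"]
    for i in range(len(tiles)):
        for j in range(i + 1, len(tiles)):
            if tiles[i].domain.intersection(tiles[j].domain) is not None:
                raise ChainError(
                    f"tile domains overlap: {tiles[i].domain} and {tiles[j].domain}"
                )
    pids = [s.annotation_id for s in steps if s.kind == "point"]
    if len(pids) != len(set(pids)):
        raise ChainError("duplicate per-annotation correction steps")
    for s in steps:
        if s.kind not in ("orientation", "global", "tile", "point"):
            raise ChainError(f"unknown step kind {s.kind!r}")
    return TransformChain(list(steps), provenance or {})


def _smooth_tile_field(chain: TransformChain, base_points: np.ndarray) -> np.ndarray | None:
    """Cubic B-spline interpolation of per-tile correction displacements.

    Displacement samples live at tile centers (fixed frame); returns the
    interpolated displacement for each base-transformed point, or None if
    the retained tiles do not form a full grid of at least 4x4 (the spline
    then has no support; callers fall back to per-tile application).
    """
    from scipy.interpolate import RectBivariateSpline

    tiles = [s for s in chain.steps if s.kind == "tile"]
    glob = next((s for s in chain.steps if s.kind == "global"), None)
    if glob is None or len(tiles) < 16:
        return None
    cxs = sorted({s.domain.center[0] for s in tiles})
    cys = sorted({s.domain.center[1] for s in tiles})
    if len(cxs) < 4 or len(cys) < 4 or len(cxs) * len(cys) != len(tiles):
        return None
    lookup = {(s.domain.center[0], s.domain.center[1]): s for s in tiles}
    dx = np.zeros((len(cys), len(cxs)))
    dy = np.zeros((len(cys), len(cxs)))
    for iy, cy in enumerate(cys):
        for ix, cx in enumerate(cxs):
            s = lookup.get((cx, cy))
            if s is None:
                return None
            c = np.array([cx, cy])
            q0 = glob.transform.apply(c)
            disp = s.transform.apply(q0) - q0
            dx[iy, ix], dy[iy, ix] = disp
    sx = RectBivariateSpline(cys, cxs, dx, kx=3, ky=3)
    sy = RectBivariateSpline(cys, cxs, dy, kx=3, ky=3)
    return np.column_stack(
        [sx.ev(base_points[:, 1], base_points[:, 0]), sy.ev(base_points[:, 1], base_points[:, 0])]
    )


def apply_chain_continuous(
    points: np.ndarray,
    chain: TransformChain,
    ids: np.ndarray | None = None,
    smooth_tiles: bool = False,
):
    """Map points through the chain; returns (continuous coords, flags).

    ``flags`` is a string array: "ok", or "base-only" for points outside
    every tile/annotation domain (those are mapped by the orientation +
    global steps only).
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float)).copy()
    n = len(pts)
    if ids is None:
        ids = np.arange(n)
    ids = np.asarray(ids)
    flags = np.array(["ok"] * n, dtype=object)

    fixed_ref = pts.copy()  # fixed-frame coords (after orientation steps)
    tile_done = np.zeros(n, dtype=bool)
    corrected = np.zeros(n, dtype=bool)
    has_local = chain.has_point_steps or any(s.kind == "tile" for s in chain.steps)
    smooth_disp = None
    pre_smooth = None

    for step in chain.steps:
        if step.kind == "orientation":
            pts = hierarchy.map_points(step.op, pts, step.dims)
            fixed_ref = pts.copy()
        elif step.kind == "global":
            fixed_ref = pts.copy()
            pts = step.transform.apply(pts)
            if smooth_tiles:
                pre_smooth = pts.copy()
                smooth_disp = _smooth_tile_field(chain, fixed_ref)
        elif step.kind == "tile":
            if smooth_tiles and smooth_disp is not None:
                continue  # handled by the interpolated field below
            r = step.domain
            mask = (
                (fixed_ref[:, 0] >= r.x)
                & (fixed_ref[:, 0] < r.x2)
                & (fixed_ref[:, 1] >= r.y)
                & (fixed_ref[:, 1] < r.y2)
                & ~tile_done
            )
            if mask.any():
                pts[mask] = step.transform.apply(pts[mask])
                tile_done |= mask
                corrected |= mask
        elif step.kind == "point":
            mask = ids == step.annotation_id
            if mask.any():
                pts[mask] = step.transform.apply(pts[mask])
                corrected |= mask

    if smooth_tiles and smooth_disp is not None:
        pts = pre_smooth + smooth_disp
        corrected[:] = True
    if has_local:
        flags[~corrected] = "base-only"
    return pts, flags


def apply_chain(
    points: np.ndarray,
    chain: TransformChain,
    ids: np.ndarray | None = None,
    smooth_tiles: bool = False,
):
    """Map points through the chain to discrete target coordinates.

    Continuous composition through all applicable steps, then rounding
    half-to-even; discretization error is at most 0.5 px per coordinate.
    """
    cont, flags = apply_chain_continuous(points, chain, ids, smooth_tiles)
    return np.round(cont).astype(np.int64), flags


def reuse_chain(new_points: np.ndarray, chain: TransformChain, smooth_tiles: bool = False):
    """Apply a stored chain to a new point set (grid-tile chains only).

    Per-annotation corrections are exact for their own annotation and
    meaningless for any other point, so chains containing them refuse
    unseen points.
    """
    new_points = np.atleast_2d(np.asarray(new_points, dtype=float))
    if chain.has_point_steps:
        raise NotReusableError(
            "chain contains per-annotation corrections; it cannot be reused "
            "for new points (grid-tile chains are reusable)"
        )
    return apply_chain(new_points, chain, smooth_tiles=smooth_tiles)
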
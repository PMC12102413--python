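"""Parametric 2-D transforms with an explicit rotation center.

Convention block (used package-wide and written into every serialized
transform): coordinates are (x, y) with x rightward and y downward; angles
are in degrees, counter-clockwise positive as seen on screen in this
y-down frame, i.e. the rotation matrix is ``[[cos, sin], [-sin, cos]]``;
transforms map points from the fixed-image domain into the moving-image
domain; the rotation center ``c`` is a fixed (non-optimized) parameter.

All transforms map ``p -> M (p - c) + c + t`` where ``M`` is ``s * R(theta)``
for the similarity model, ``R(theta)`` for the rigid model, and a free
non-singular 2x2 matrix for the affine model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SimilarityTransform",
    "RigidTransform",
    "AffineTransform",
    "transform_point",
    "transform_to_dict",
    "transform_from_dict",
]

CONVENTION = {
    "axes": "x-right, y-down",
    "angle_unit": "degrees, CCW-positive in the y-down frame",
    "direction": "fixed -> moving",
}


def rotation_matrix(angle_deg: float) -> np.ndarray:
    """CCW rotation (y-down screen frame): [[cos, sin], [-sin, cos]]."""
    a = np.deg2rad(angle_deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, s], [-s, c]])


class _LinearTransform:
    """Shared machinery: homogeneous matrix, point application, inverse."""

    @property
    def linear(self) -> np.ndarray:  # 2x2 part, implemented by subclasses
        raise NotImplementedError

    @property
    def translation(self) -> np.ndarray:
        return np.array([self.tx, self.ty], dtype=float)

    @property
    def center(self) -> np.ndarray:
        return np.array([self.cx, self.cy], dtype=float)

    @property
    def matrix(self) -> np.ndarray:
        """3x3 homogeneous matrix equivalent (center folded in)."""
        M = self.linear
        c = self.center
        offset = c + self.translation - M @ c
        H = np.eye(3)
        H[:2, :2] = M
        H[:2, 2] = offset
        return H

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map an (n, 2) array (or a single (2,) point) fixed -> moving."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        M = self.linear
        out = (pts - self.center) @ M.T + self.center + self.translation
        return out[0] if np.asarray(points).ndim == 1 else out

    def inverse(self) -> "AffineTransform":
        H = np.linalg.inv(self.matrix)
        return AffineTransform(matrix=H[:2, :2], tx=H[0, 2], ty=H[1, 2], cx=0.0, cy=0.0)

    def compose(self, inner: "_LinearTransform") -> "AffineTransform":
        """Transform applying ``inner`` first, then ``self``."""
        H = self.matrix @ inner.matrix
        return AffineTransform(matrix=H[:2, :2], tx=H[0, 2], ty=H[1, 2], cx=0.0, cy=0.0)


@dataclass
class SimilarityTransform(_LinearTransform):
    """Rotation + isotropic scale + translation about a fixed center.

    The four free parameters of the coarse registration stage are
    (angle_deg, scale, tx, ty); the center is fixed to the geometric
    center of the fixed ROI.
    """

    angle_deg: float = 0.0
    scale: float = 1.0
    tx: float = 0.0
    ty: float = 0.0
    cx: float = 0.0
    cy: float = 0.0

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError("scale must be positive")

    @property
    def linear(self) -> np.ndarray:
        return self.scale * rotation_matrix(self.angle_deg)

    def inverse(self) -> "SimilarityTransform":
        # inverse of a similarity is a similarity about the same center
        H = np.linalg.inv(self.matrix)
        return similarity_from_matrix(H, cx=self.cx, cy=self.cy)


@dataclass
class RigidTransform(_LinearTransform):
    """Rotation + translation (scale identically 1)."""

    angle_deg: float = 0.0
    tx: float = 0.0
    ty: float = 0.0
    cx: float = 0.0
    cy: float = 0.0

    @property
    def scale(self) -> float:
        return 1.0

    @property
    def linear(self) -> np.ndarray:
        return rotation_matrix(self.angle_deg)


@dataclass
class AffineTransform(_LinearTransform):
    """General non-singular linear map + translation about a center."""

    matrix_: np.ndarray = field(default_factory=lambda: np.eye(2))
    tx: float = 0.0
    ty: float = 0.0
    cx: float = 0.0
    cy: float = 0.0

    def __init__(self, matrix=None, tx=0.0, ty=0.0, cx=0.0, cy=0.0):
        self.matrix_ = np.eye(2) if matrix is None else np.asarray(matrix, dtype=float)
        if self.matrix_.shape != (2, 2):
            raise ValueError("affine matrix must be 2x2")
        if abs(np.linalg.det(self.matrix_)) < 1e-15:
            raise ValueError("affine matrix must be non-singular")
        self.tx, self.ty, self.cx, self.cy = float(tx), float(ty), float(cx), float(cy)

    @property
    def linear(self) -> np.ndarray:
        return self.matrix_


def similarity_from_matrix(H: np.ndarray, cx: float = 0.0, cy: float = 0.0) -> SimilarityTransform:
    """Decompose a homogeneous similarity matrix (det > 0) into parameters.

    The resulting transform uses (cx, cy) as its rotation center; the
    translation is adjusted so the point mapping is identical.
    """
    M = H[:2, :2]
    det = np.linalg.det(M)
    if det <= 0:
        raise ValueError("matrix is not an orientation-preserving similarity")
    s = float(np.sqrt(det))
    angle = float(np.rad2deg(np.arctan2(M[0, 1], M[0, 0])))
    c = np.array([cx, cy])
    # H offset = c + t - M c  =>  t = offset + M c - c
    t = H[:2, 2] + M @ c - c
    return SimilarityTransform(angle_deg=angle, scale=s, tx=float(t[0]), ty=float(t[1]), cx=cx, cy=cy)


def transform_point(T: _LinearTransform, p) -> np.ndarray:
    """Map point(s) ``p`` from the fixed domain into the moving domain."""
    return T.apply(p)


# ---------------------------------------------------------------------------
# JSON serialization with explicit convention block.

def transform_to_dict(T: _LinearTransform) -> dict:
    d: dict = {"convention": CONVENTION}
    if isinstance(T, SimilarityTransform):
        d.update(
            type="similarity", angle_deg=T.angle_deg, scale=T.scale,
            tx=T.tx, ty=T.ty, cx=T.cx, cy=T.cy,
        )
    elif isinstance(T, RigidTransform):
        d.update(type="rigid", angle_deg=T.angle_deg, tx=T.tx, ty=T.ty, cx=T.cx, cy=T.cy)
    elif isinstance(T, AffineTransform):
        d.update(
            type="affine", matrix=T.matrix_.tolist(),
            tx=T.tx, ty=T.ty, cx=T.cx, cy=T.cy,
        )
    else:
        raise TypeError(f"unknown transform type {type(T)}")
    return d


def transform_from_dict(d: dict) -> _LinearTransform:
    kind = d["type"]
    if kind == "similarity":
        return SimilarityTransform(
            angle_deg=d["angle_deg"], scale=d["scale"],
            tx=d["tx"], ty=d["ty"], cx=d["cx"], cy=d["cy"],
        )
    if kind == "rigid":
        return RigidTransform(angle_deg=d["angle_deg"], tx=d["tx"], ty=d["ty"], cx=d["cx"], cy=d["cy"])
    if kind == "affine":
        return AffineTransform(matrix=np.array(d["matrix"]), tx=d["tx"], ty=d["ty"], cx=d["cx"], cy=d["cy"])
    raise ValueError(f"unknown transform type {kind!r}")


def transform_to_json(T: _LinearTransform) -> str:
    return json.dumps(transform_to_dict(T), sort_keys=True)


def transform_from_json(s: str) -> _LinearTransform:
    return transform_from_dict(json.loads(s))
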
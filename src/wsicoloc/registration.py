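"""Multi-resolution parametric intensity registration.

Drives the Mattes-MI metric (:mod:`wsicoloc.metrics`) with the ASGD
optimizer (:mod:`wsicoloc.optimize`) over a Gaussian image pyramid,
coarse to fine, for rigid, similarity, or affine transform models.  The
estimated transform maps fixed-image coordinates into the moving-image
domain — exactly the direction needed to colocalize annotations.

Heterogeneous parameters (angle, scale, translation) are jointly optimized
by rescaling rotation/scale entries so that one optimizer unit induces
roughly one pixel of motion at the ROI corner.  Gradients are central
finite differences of the sampled metric with matched sample sets (common
random numbers) to suppress sampling noise.  After the stochastic phase a
short deterministic polish pass re-runs the optimizer on one frozen,
dense sample set, which removes the residual sampling jitter from the
final sub-pixel estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace

import numpy as np
from scipy import ndimage
from skimage.transform import pyramid_reduce

from .metrics import MattesMIConfig, MattesMIObjective, OverlapError
from .optimize import ASGDConfig, asgd_minimize
from .transforms import AffineTransform, RigidTransform, SimilarityTransform

__all__ = ["RegistrationConfig", "RegistrationResult", "register", "resample_image"]


@dataclass
class RegistrationConfig:
    n_resolutions: int = 3
    iterations: int = 500
    n_bins: int = 32
    n_samples: int = 2048
    seed: int = 0
    # ASGD constants; a=None means auto-scaled from probe gradients
    a: float | None = None
    A: float = 20.0
    alpha: float = 1.0
    delta: float = 1.0
    step_tolerance: float = 1e-3
    min_overlap: float = 0.25
    fd_step: float = 0.5  # finite-difference step, scaled parameter units
    polish_iterations: int = 150
    polish_samples: int = 8192  # frozen-sample budget; exhaustive if image smaller
    background: float = 255.0

    def __post_init__(self) -> None:
        if self.n_resolutions < 1 or self.iterations < 1:
            raise ValueError("counts must be >= 1")
        if self.n_bins < 8:
            raise ValueError("n_bins must be >= 8")

    def mi_config(self) -> MattesMIConfig:
        return MattesMIConfig(
            n_bins=self.n_bins, n_samples=self.n_samples, min_overlap=self.min_overlap
        )

    @classmethod
    def from_param_file(cls, path) -> "RegistrationConfig":
        """Read overrides from a flat ``key = value`` text file."""
        cfg = cls()
        valid = {f.name: f.type for f in fields(cls)}
        with open(path) as fh:
            for line in fh:
                line = line.split("#")[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise ValueError(f"malformed parameter line: {line!r}")
                key, val = (s.strip() for s in line.split("=", 1))
                if key not in valid:
                    raise KeyError(f"unknown registration parameter {key!r}")
                current = getattr(cfg, key)
                if key == "a" and val.lower() in ("none", "auto"):
                    setattr(cfg, key, None)
                elif isinstance(current, int) and not isinstance(current, bool):
                    setattr(cfg, key, int(float(val)))
                else:
                    setattr(cfg, key, float(val))
        cfg.__post_init__()
        return cfg


@dataclass
class RegistrationResult:
    transform: object
    metric: float
    status: str  # "ok" or "diverged"
    n_levels: int
    level_metrics: list = field(default_factory=list)
    traces: list = field(default_factory=list)


def to_gray(img: np.ndarray) -> np.ndarray:
    """Luminance grayscale as float; RGB weights per ITU-R 601."""
    img = np.asarray(img, dtype=float)
    if img.ndim == 2:
        return img
    return img[..., 0] * 0.299 + img[..., 1] * 0.587 + img[..., 2] * 0.114


# ---------------------------------------------------------------------------
# Parameter vector <-> transform, with per-pixel scaling of angle/scale terms.

class _ParamModel:
    def __init__(self, model: str, center: np.ndarray, radius: float):
        if model not in ("rigid", "similarity", "affine"):
            raise ValueError(f"unknown model {model!r}")
        self.model = model
        self.center = center
        self.radius = max(radius, 1.0)

    @property
    def n_params(self) -> int:
        return {"rigid": 3, "similarity": 4, "affine": 6}[self.model]

    def to_transform(self, x: np.ndarray):
        cx, cy = self.center
        r = self.radius
        if self.model == "rigid":
            return RigidTransform(
                angle_deg=np.rad2deg(x[0] / r), tx=x[1], ty=x[2], cx=cx, cy=cy
            )
        if self.model == "similarity":
            return SimilarityTransform(
                angle_deg=np.rad2deg(x[0] / r),
                scale=max(1.0 + x[1] / r, 1e-3),
                tx=x[2], ty=x[3], cx=cx, cy=cy,
            )
        A = np.eye(2) + np.array([[x[0], x[1]], [x[2], x[3]]]) / r
        return AffineTransform(matrix=A, tx=x[4], ty=x[5], cx=cx, cy=cy)

    def from_transform(self, T) -> np.ndarray:
        r = self.radius
        if self.model == "rigid":
            return np.array([np.deg2rad(T.angle_deg) * r, T.tx, T.ty])
        if self.model == "similarity":
            return np.array(
                [np.deg2rad(T.angle_deg) * r, (T.scale - 1.0) * r, T.tx, T.ty]
            )
        M = (T.linear - np.eye(2)) * r
        return np.array([M[0, 0], M[0, 1], M[1, 0], M[1, 1], T.tx, T.ty])


def _init_transform(model: str, fixed_shape, moving_shape, center, init):
    """Center-alignment initialization: translation matching geometric centers."""
    if init is not None:
        return init
    fc = np.array([(fixed_shape[1] - 1) / 2.0, (fixed_shape[0] - 1) / 2.0])
    mc = np.array([(moving_shape[1] - 1) / 2.0, (moving_shape[0] - 1) / 2.0])
    t = mc - fc
    if model == "rigid":
        return RigidTransform(tx=t[0], ty=t[1], cx=center[0], cy=center[1])
    if model == "similarity":
        return SimilarityTransform(tx=t[0], ty=t[1], cx=center[0], cy=center[1])
    return AffineTransform(tx=t[0], ty=t[1], cx=center[0], cy=center[1])


def _rescale_transform(T, factor: float, model: str):
    """Express a transform at coordinates scaled by ``factor`` (pure zoom)."""
    if model == "affine":
        return AffineTransform(
            matrix=T.linear, tx=T.tx * factor, ty=T.ty * factor,
            cx=T.cx * factor, cy=T.cy * factor,
        )
    kwargs = dict(tx=T.tx * factor, ty=T.ty * factor, cx=T.cx * factor, cy=T.cy * factor)
    if model == "similarity":
        return SimilarityTransform(angle_deg=T.angle_deg, scale=T.scale, **kwargs)
    return RigidTransform(angle_deg=T.angle_deg, **kwargs)


def _image_pyramid(img: np.ndarray, n_levels: int) -> list[np.ndarray]:
    levels = [img]
    for _ in range(1, n_levels):
        if min(levels[-1].shape) < 16:
            break
        levels.append(pyramid_reduce(levels[-1], downscale=2, preserve_range=True))
    return levels


def register(
    fixed: np.ndarray,
    moving: np.ndarray,
    model: str = "similarity",
    config: RegistrationConfig | None = None,
    init=None,
) -> RegistrationResult:
    """Estimate the transform mapping ``fixed`` coordinates into ``moving``.

    Both images are 2-D grayscale (RGB inputs are converted to luminance).
    ``init`` optionally supplies a starting transform in the input images'
    coordinates; the default initialization aligns geometric centers.
    """
    cfg = config or RegistrationConfig()
    fixed = to_gray(fixed)
    moving = to_gray(moving)
    if fixed.size == 0 or moving.size == 0:
        raise ValueError("images must be non-empty")

    fpyr = _image_pyramid(fixed, cfg.n_resolutions)
    mpyr = _image_pyramid(moving, cfg.n_resolutions)
    n_levels = min(len(fpyr), len(mpyr))

    center0 = np.array([(fixed.shape[1] - 1) / 2.0, (fixed.shape[0] - 1) / 2.0])
    T_full = _init_transform(model, fixed.shape, moving.shape, center0, init)

    level_metrics: list[float] = []
    traces = []
    worsened = 0
    status = "ok"
    best_T, best_metric = T_full, np.inf
    rng = np.random.default_rng(cfg.seed)

    for li in range(n_levels - 1, -1, -1):
        f_img, m_img = fpyr[li], mpyr[li]
        factor = 2**li
        mi_obj = MattesMIObjective(f_img, m_img, cfg.mi_config())
        if mi_obj.fixed_constant or mi_obj.moving_constant:
            continue
        center_l = center0 / factor
        radius = 0.5 * float(np.hypot(*f_img.shape))
        pm = _ParamModel(model, center_l, radius)
        T_level = _rescale_transform(T_full, 1.0 / factor, model)
        x0 = pm.from_transform(T_level)
        level_seed = int(rng.integers(1 << 30))

        def make_objective(sample_fn, fd_step):
            def objective(x, k):
                samples = sample_fn(k)
                n_par = len(x)
                transforms = [pm.to_transform(x)]
                for i in range(n_par):
                    xp, xm = x.copy(), x.copy()
                    xp[i] += fd_step
                    xm[i] -= fd_step
                    transforms.append(pm.to_transform(xp))
                    transforms.append(pm.to_transform(xm))
                try:
                    vals = mi_obj.values_multi(transforms, samples)
                except OverlapError:
                    return 0.0, np.zeros(n_par)
                g = (vals[1::2] - vals[2::2]) / (2 * fd_step)
                return float(vals[0]), g

            return objective

        # stochastic phase: fresh samples each iteration
        stoch = make_objective(lambda k: mi_obj.sample(level_seed + k), cfg.fd_step)
        res = asgd_minimize(
            stoch,
            x0,
            ASGDConfig(
                max_iterations=cfg.iterations, a=cfg.a, A=cfg.A, alpha=cfg.alpha,
                delta=cfg.delta, step_tolerance=cfg.step_tolerance,
            ),
            seed=level_seed,
        )
        x = res.x
        traces.append(res.trace)

        # deterministic polish at the finest level: one frozen dense sample
        # set, two rounds with shrinking finite-difference steps
        if li == 0 and cfg.polish_iterations > 0:
            if f_img.size <= cfg.polish_samples:
                frozen = mi_obj.sample(None, exhaustive=True)
            else:
                big_cfg = replace(cfg.mi_config(), n_samples=cfg.polish_samples)
                mi_obj = MattesMIObjective(f_img, m_img, big_cfg)
                frozen = mi_obj.sample(level_seed + 10_000_019)
            for round_i, (fd, delta) in enumerate(
                [(cfg.fd_step / 2, 0.5 * cfg.delta), (cfg.fd_step / 8, 0.1 * cfg.delta)]
            ):
                polish = make_objective(lambda k: frozen, fd)
                res2 = asgd_minimize(
                    polish,
                    x,
                    ASGDConfig(
                        max_iterations=cfg.polish_iterations, a=cfg.a, A=cfg.A,
                        alpha=cfg.alpha, delta=delta,
                        step_tolerance=cfg.step_tolerance * 0.01,
                    ),
                    seed=level_seed + 1 + round_i,
                )
                x = res2.x
                traces.append(res2.trace)

        T_level = pm.to_transform(x)
        T_full = _rescale_transform(T_level, float(factor), model)

        try:
            metric = mi_obj.value_at(T_level, mi_obj.sample(level_seed))
        except OverlapError:
            metric = 0.0
        if level_metrics and metric > level_metrics[-1]:
            worsened += 1
        else:
            worsened = 0
        level_metrics.append(metric)
        if metric < best_metric:
            best_metric, best_T = metric, T_full
        if worsened >= 3:
            status = "diverged"
            T_full = best_T
            break

    final_metric = level_metrics[-1] if level_metrics else 0.0
    return RegistrationResult(
        transform=T_full,
        metric=final_metric,
        status=status,
        n_levels=n_levels,
        level_metrics=level_metrics,
        traces=traces,
    )


def resample_image(
    image: np.ndarray,
    transform,
    order: int = 3,
    background: float = 255.0,
) -> np.ndarray:
    """Resample: ``output(p) = image(T(p))`` with B-spline interpolation.

    Out-of-domain samples are filled with the background value.  RGB images
    are resampled channel-wise.
    """
    image = np.asarray(image)
    if image.ndim == 3:
        chans = [
            resample_image(image[..., c], transform, order, background)
            for c in range(image.shape[2])
        ]
        return np.stack(chans, axis=-1)
    h, w = image.shape
    xx, yy = np.meshgrid(np.arange(w, dtype=float), np.arange(h, dtype=float))
    pts = np.column_stack([xx.ravel(), yy.ravel()])
    mapped = transform.apply(pts)
    out = ndimage.map_coordinates(
        image.astype(float),
        [mapped[:, 1], mapped[:, 0]],
        order=order,
        mode="constant",
        cval=background,
    ).reshape(h, w)
    if np.issubdtype(image.dtype, np.integer):
        info = np.iinfo(image.dtype)
        out = np.clip(np.round(out), info.min, info.max)
    return out.astype(image.dtype)
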
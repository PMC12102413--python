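"""End-to-end orchestration: preprocess -> register -> transform -> evaluate.

``register_pair`` is the library entry point operating on in-memory
pyramids; ``run_pipeline`` wraps it with file I/O, configuration,
logging and a reproducible run manifest.  Registration and
transformation stay decoupled: the chain written by one run can be
reloaded in another process and applied to new point sets (Strategy I)
with bit-identical results.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import hierarchy
from .chain import ChainStep, TransformChain, apply_chain, compose_chain
from .hierarchy import coarse_register, extrapolate_to_base
from .pyramid import (
    PyramidImage,
    Rect,
    load_points,
    read_pyramid_tiff,
    select_overview_level,
)
from .refinement import (
    DEFAULT_PATCH_SIZE,
    DEFAULT_TILE_SIZE,
    build_grid,
    choose_strategy,
    refine_point_strategy2,
    refine_tiles_strategy1,
    refinement_config,
    strategy1_chain_steps,
    strategy2_chain_steps,
)
from .registration import RegistrationConfig
from .segmentation import (
    filter_particles,
    override_roi,
    particles_from_mask,
    roi_from_particles,
    segment_tissue,
)

__all__ = ["RunConfig", "register_pair", "run_pipeline", "PipelineResult"]


@dataclass
class RunConfig:
    """Fully serializable run description; a stored RunConfig re-executes
    to identical outputs."""

    fixed: str = ""
    moving: str = ""
    annotations: str = ""
    out_dir: str = "wsicoloc_out"
    strategy: str = "auto"  # auto | 1 | 2
    tile_size: int = DEFAULT_TILE_SIZE
    patch_size: int = DEFAULT_PATCH_SIZE
    orientation: str = "none"  # op making the fixed slide match the moving one
    roi_fixed: list | None = None  # [x, y, w, h] manual override
    roi_moving: list | None = None
    roi_margin: float = 2.0  # overview px added around the segmented tissue
    param_file: str | None = None  # flat key=value RegistrationConfig overrides
    seed: int = 0
    evaluate: bool = False
    smooth_tiles: bool = False

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(**{k: v for k, v in d.items() if k in cls.__dataclass_fields__})

    @classmethod
    def load(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        if str(path).endswith((".yaml", ".yml")):
            import yaml

            return cls.from_dict(yaml.safe_load(text))
        return cls.from_dict(json.loads(text))

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class PipelineResult:
    chain: TransformChain
    points_in: np.ndarray
    points_out: np.ndarray  # discrete target coordinates
    flags: np.ndarray
    strategy: str
    coarse: object
    roi_fixed: Rect
    roi_moving: Rect
    audit: list = field(default_factory=list)
    log: list = field(default_factory=list)
    eval_report: object | None = None
    manifest: dict = field(default_factory=dict)


def _orient_pyramid(pyr: PyramidImage, op: str) -> PyramidImage:
    if op == "none":
        return pyr
    levels = [hierarchy.apply_to_image(op, lvl) for lvl in pyr.levels]
    swap = hierarchy.transformed_dims(op, (2, 1)) == (1, 2)
    return PyramidImage(
        levels=levels,
        downsample_factors=list(pyr.downsample_factors),
        mpp_x=pyr.mpp_y if swap else pyr.mpp_x,
        mpp_y=pyr.mpp_x if swap else pyr.mpp_y,
        magnification=pyr.magnification,
        orientation="none",
    )


def _auto_roi(pyr: PyramidImage, margin: float, log: list) -> Rect:
    level = select_overview_level(pyr.magnification, pyr.n_levels)
    ds = pyr.downsample_factors[level]
    overview = pyr.levels[level]
    seg = segment_tissue(overview)
    if seg.failed:
        log.append({"event": "segmentation_failed", "level": level})
        return pyr.base_rect
    pset = filter_particles(particles_from_mask(seg.mask, downsample=ds))
    roi = roi_from_particles(pset, margin=margin, slide_rect=None)
    roi = roi.intersection(pyr.base_rect) or pyr.base_rect
    log.append({"event": "auto_roi", "level": level, "roi": roi.to_dict()})
    return roi


def register_pair(
    fixed: PyramidImage,
    moving: PyramidImage,
    annotations: np.ndarray,
    strategy: str = "auto",
    tile_size: int = DEFAULT_TILE_SIZE,
    patch_size: int = DEFAULT_PATCH_SIZE,
    orientation: str = "none",
    roi_fixed: Rect | None = None,
    roi_moving: Rect | None = None,
    roi_margin: float = 2.0,
    coarse_config: RegistrationConfig | None = None,
    seed: int = 0,
    smooth_tiles: bool = False,
) -> PipelineResult:
    """Register a fixed/moving slide pair and map the annotations.

    The configured orientation op is applied to the fixed slide (and to
    the annotations) first, the coarse overview similarity is estimated
    on segmented ROIs and extrapolated to the base layer, the selected
    refinement strategy adds per-tile or per-annotation corrections, and
    the resulting chain is applied to the annotations.
    """
    log: list = []
    audit: list = []
    annotations = np.atleast_2d(np.asarray(annotations, dtype=float))
    t_start = time.perf_counter()

    # --- preprocessing: orientation + tissue ROIs ---
    dims0 = (fixed.width, fixed.height)
    fixed_o = _orient_pyramid(fixed, orientation)
    ann_o = (
        hierarchy.map_points(orientation, annotations, dims0)
        if orientation != "none"
        else annotations
    )
    if roi_fixed is not None:
        roi_f = override_roi(roi_fixed, fixed_o.base_rect, log)
    else:
        roi_f = _auto_roi(fixed_o, roi_margin, log)
    if roi_moving is not None:
        roi_m = override_roi(roi_moving, moving.base_rect, log)
    else:
        roi_m = _auto_roi(moving, roi_margin, log)
    log.append({"event": "preprocess_done", "t": time.perf_counter() - t_start})

    # --- coarse stage ---
    cfg = coarse_config or RegistrationConfig()
    cfg.seed = seed
    cr = coarse_register(fixed_o, moving, roi_f, roi_m, config=cfg)
    base_T = extrapolate_to_base(cr)
    log.append(
        {
            "event": "coarse_done",
            "status": cr.status,
            "metric": cr.metric,
            "transform": {
                "angle_deg": base_T.angle_deg, "scale": base_T.scale,
                "tx": base_T.tx, "ty": base_T.ty,
            },
            "t": time.perf_counter() - t_start,
        }
    )

    # --- refinement ---
    if strategy == "auto":
        strategy = {"strategy1": "1", "strategy2": "2"}[
            choose_strategy(ann_o, roi_f, tile_size=tile_size, patch_size=patch_size)
        ]
        log.append({"event": "strategy_selected", "strategy": strategy})
    level_moving = moving.level_for_downsample(max(base_T.scale, 1.0))

    steps = []
    order = 0
    if orientation != "none":
        steps.append(ChainStep(kind="orientation", order=order, op=orientation, dims=dims0))
        order += 1
    steps.append(ChainStep(kind="global", order=order, transform=base_T))
    order += 1

    if strategy not in ("1", "2", "1+2"):
        raise ValueError(f"unknown strategy {strategy!r}")
    if strategy in ("1", "1+2"):
        grid = build_grid(roi_f, tile_size=tile_size, annotations=ann_o)
        grid = refine_tiles_strategy1(
            grid, base_T, fixed_o, moving,
            config=refinement_config(seed=seed, tile=True),
            level_moving=level_moving, audit=audit,
        )
        steps.extend(strategy1_chain_steps(grid, order))
        order = steps[-1].order + 1 if steps else order
    if strategy in ("2", "1+2"):
        if strategy == "1+2":
            # per-annotation correction starts from the tile-refined position
            from .chain import apply_chain_continuous

            partial = compose_chain(steps)
            mapped, _ = apply_chain_continuous(annotations, chain=partial)
        else:
            mapped = [None] * len(ann_o)
        corrections = [
            refine_point_strategy2(
                p, base_T, fixed_o, moving, patch_size=patch_size,
                config=refinement_config(seed=seed), level_moving=level_moving,
                annotation_id=i, mapped_point=mapped[i], audit=audit,
            )
            for i, p in enumerate(ann_o)
        ]
        steps.extend(strategy2_chain_steps(corrections, order))
    log.append({"event": "refinement_done", "t": time.perf_counter() - t_start})

    chain = compose_chain(
        steps,
        provenance={
            "strategy": strategy,
            "tile_size": tile_size,
            "patch_size": patch_size,
            "seed": seed,
            "levels": [cr.level_fixed, cr.level_moving],
            "roi_fixed": cr.roi_fixed.to_dict(),
            "roi_moving": cr.roi_moving.to_dict(),
        },
    )
    pts_out, flags = apply_chain(
        annotations, chain, ids=np.arange(len(annotations)), smooth_tiles=smooth_tiles
    )
    log.append({"event": "transform_done", "t": time.perf_counter() - t_start})
    return PipelineResult(
        chain=chain,
        points_in=annotations,
        points_out=pts_out,
        flags=flags,
        strategy=strategy,
        coarse=cr,
        roi_fixed=roi_f,
        roi_moving=roi_m,
        audit=audit,
        log=log,
    )


def run_pipeline(config: RunConfig) -> PipelineResult:
    """File-based end-to-end run with manifest and outputs on disk."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fixed = read_pyramid_tiff(config.fixed)
    moving = read_pyramid_tiff(config.moving)
    annotations = load_points(config.annotations)
    coarse_cfg = (
        RegistrationConfig.from_param_file(config.param_file)
        if config.param_file
        else RegistrationConfig()
    )
    result = register_pair(
        fixed,
        moving,
        annotations,
        strategy=config.strategy if config.strategy != "auto" else "auto",
        tile_size=config.tile_size,
        patch_size=config.patch_size,
        orientation=config.orientation,
        roi_fixed=Rect(*config.roi_fixed) if config.roi_fixed else None,
        roi_moving=Rect(*config.roi_moving) if config.roi_moving else None,
        roi_margin=config.roi_margin,
        coarse_config=coarse_cfg,
        seed=config.seed,
        smooth_tiles=config.smooth_tiles,
    )

    if config.evaluate:
        from .evaluation import ssim_colocalization_eval

        result.eval_report = ssim_colocalization_eval(
            result.points_in,
            [fixed, moving],
            [result.points_in, result.points_out.astype(float)],
        )

    from . import __version__

    manifest = {
        "package_version": __version__,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "strategy": result.strategy,
        "n_points": len(result.points_in),
        "log": result.log,
    }
    result.manifest = manifest

    result.chain.save(out / "chain.json")
    try:
        from .hierarchy import write_roi_overlay

        fixed_o = _orient_pyramid(fixed, config.orientation)
        write_roi_overlay(fixed_o, moving, result.coarse, out / "roi_overlay.png")
    except Exception as exc:  # diagnostics only, never fail the run
        result.log.append({"event": "overlay_failed", "error": str(exc)})
    with open(out / "points_out.csv", "w") as fh:
        fh.write("x,y,flag\n")
        for (x, y), fl in zip(result.points_out, result.flags):
            fh.write(f"{x},{y},{fl}\n")
    with open(out / "audit.jsonl", "w") as fh:
        for rec in result.audit:
            fh.write(json.dumps(rec, sort_keys=True) + "\n")
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    if result.eval_report is not None:
        result.eval_report.to_csv(out / "evaluation.csv")
        with open(out / "evaluation.json", "w") as fh:
            json.dump(result.eval_report.summary(), fh, indent=2, sort_keys=True)
        result.eval_report.plot_histogram(out / "min_ssim_hist.png")
    return result
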
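"""Colocalization quality evaluation.

Pixel-precise point correspondences cannot be annotated by hand at
nucleus scale, so registration quality is assessed photometrically: for
every mapped annotation a patch is extracted from each slide, all patches
are rescaled to the dimensions of the coarsest-resolution slide, the
first and last rows and columns are cropped (absorbing uneven dimensions
after resizing), and the structural similarity index (SSIM) is computed
per slide pair.  The per-annotation minimum over all pairs is the
headline statistic.  For synthetic pairs with exact ground truth, direct
Euclidean point errors (px and um) are reported as well.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.metrics import structural_similarity
from skimage.transform import resize

from .pyramid import PyramidImage, Rect, read_region
from .registration import to_gray

__all__ = ["ssim", "EvalReport", "ssim_colocalization_eval", "colocalization_error"]


def ssim(
    a: np.ndarray,
    b: np.ndarray,
    data_range: float = 255.0,
    sigma: float = 1.5,
    win_size: int = 11,
    k1: float = 0.01,
    k2: float = 0.03,
) -> float:
    """Mean local SSIM with a Gaussian window; range [-1, 1].

    Standard constants: Gaussian window sigma 1.5, width 11, stabilizers
    K1 = 0.01 and K2 = 0.03 on the declared dynamic range.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"image shapes differ: {a.shape} vs {b.shape}")
    if min(a.shape) < win_size:
        raise ValueError(f"images smaller than the {win_size}-px SSIM window")
    return float(
        structural_similarity(
            a, b, data_range=data_range, gaussian_weights=True, sigma=sigma,
            win_size=win_size, K1=k1, K2=k2, use_sample_covariance=False,
        )
    )


@dataclass
class EvalReport:
    """Per-annotation SSIM matrix and (for synthetic runs) point errors."""

    annotation_ids: list
    pair_names: list  # (slide_i, slide_j) labels
    ssim_matrix: np.ndarray  # (n_annotations, n_pairs); NaN = excluded
    min_ssim: np.ndarray  # per annotation, min over pairs
    excluded: list = field(default_factory=list)  # off-slide annotations
    errors_px: np.ndarray | None = None
    errors_um: np.ndarray | None = None

    @property
    def mean_min_ssim(self) -> float:
        vals = self.min_ssim[~np.isnan(self.min_ssim)]
        return float(vals.mean()) if len(vals) else float("nan")

    def summary(self) -> dict:
        out = {
            "n_annotations": len(self.annotation_ids),
            "n_excluded": len(self.excluded),
            "mean_min_ssim": self.mean_min_ssim,
        }
        if self.errors_um is not None:
            out.update(
                mean_error_um=float(np.mean(self.errors_um)),
                median_error_um=float(np.median(self.errors_um)),
                p95_error_um=float(np.percentile(self.errors_um, 95)),
                max_error_um=float(np.max(self.errors_um)),
            )
        return out

    def plot_histogram(self, path, bins: int = 40) -> None:
        """Histogram of per-annotation minimum SSIM, saved as PNG."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        vals = self.min_ssim[~np.isnan(self.min_ssim)]
        fig, ax = plt.subplots(figsize=(6, 4))
        ax.hist(vals, bins=bins, range=(-1, 1), color="#4060a0")
        ax.set_xlabel("minimum SSIM per annotation")
        ax.set_ylabel("count")
        fig.savefig(path, dpi=100, bbox_inches="tight")
        plt.close(fig)

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            pair_cols = ",".join(f"ssim_{i}_{j}" for i, j in self.pair_names)
            err = ",error_um" if self.errors_um is not None else ""
            fh.write(f"annotation_id,{pair_cols},min_ssim{err}\n")
            for r, aid in enumerate(self.annotation_ids):
                row = ",".join(f"{v:.6g}" for v in self.ssim_matrix[r])
                e = f",{self.errors_um[r]:.6g}" if self.errors_um is not None else ""
                fh.write(f"{aid},{row},{self.ssim_matrix[r].min():.6g}{e}\n")


def _patch_at(pyr: PyramidImage, center: np.ndarray, dims_px: tuple[int, int]):
    w, h = dims_px
    rect = Rect(center[0] - w / 2.0, center[1] - h / 2.0, w, h)
    if rect.intersection(pyr.base_rect) is None:
        return None, True
    rr = read_region(pyr, 0, rect)
    return to_gray(rr.data), rr.clipped


def ssim_colocalization_eval(
    annotations: np.ndarray,
    slides: list[PyramidImage],
    mapped_points: list[np.ndarray],
    patch_size_um: float | None = None,
    patch_size_px: int = 256,
    annotation_ids=None,
) -> EvalReport:
    """Per-annotation SSIM across all slide pairs at mapped coordinates.

    ``mapped_points[k]`` holds each annotation's coordinate on slide k
    (for the annotation's source slide this is the annotation itself).
    Patches cover the same physical extent on every slide: the patch is
    ``patch_size_px`` pixels on the coarsest-mpp slide and correspondingly
    larger on finer slides; all are rescaled to the coarsest slide's patch
    dimensions, then the first/last rows and columns are cropped before
    computing grayscale SSIM.  Annotations whose patch leaves any slide
    are excluded (and counted).
    """
    if len(slides) < 2:
        raise ValueError("need at least two slides")
    annotations = np.atleast_2d(np.asarray(annotations, dtype=float))
    n = len(annotations)
    if annotation_ids is None:
        annotation_ids = list(range(n))
    mpps = [max(s.mpp_x, s.mpp_y) for s in slides]
    ref = int(np.argmax(mpps))  # coarsest-resolution scanner sets patch dims
    if patch_size_um is None:
        patch_size_um = patch_size_px * mpps[ref]
    ref_dims = (int(round(patch_size_um / mpps[ref])), int(round(patch_size_um / mpps[ref])))

    patches: list[list[np.ndarray | None]] = []
    for k, (pyr, pts) in enumerate(zip(slides, mapped_points)):
        per_slide = []
        w = int(round(patch_size_um / pyr.mpp_x))
        h = int(round(patch_size_um / pyr.mpp_y))
        for i in range(n):
            patch, clipped = _patch_at(pyr, pts[i], (w, h))
            if patch is None or clipped:
                per_slide.append(None)
                continue
            if patch.shape != (ref_dims[1], ref_dims[0]):
                patch = resize(patch, (ref_dims[1], ref_dims[0]), order=3, preserve_range=True, anti_aliasing=True)
            per_slide.append(patch[1:-1, 1:-1])  # crop first/last rows+cols
        patches.append(per_slide)

    pair_names = [(i, j) for i in range(len(slides)) for j in range(i + 1, len(slides))]
    mat = np.full((n, len(pair_names)), np.nan)
    excluded = []
    for i in range(n):
        if any(patches[k][i] is None for k in range(len(slides))):
            excluded.append(annotation_ids[i])
            continue
        for c, (a, b) in enumerate(pair_names):
            mat[i, c] = ssim(patches[a][i], patches[b][i])
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows = excluded
        min_ssim = np.nanmin(mat, axis=1) if len(pair_names) else np.full(n, np.nan)
    return EvalReport(
        annotation_ids=list(annotation_ids),
        pair_names=pair_names,
        ssim_matrix=mat,
        min_ssim=min_ssim,
        excluded=excluded,
    )


def colocalization_error(
    predicted: np.ndarray,
    ground_truth: np.ndarray,
    mpp: float,
    ids_predicted=None,
    ids_truth=None,
) -> dict:
    """Euclidean per-point error in px and um with summary statistics."""
    predicted = np.atleast_2d(np.asarray(predicted, dtype=float))
    ground_truth = np.atleast_2d(np.asarray(ground_truth, dtype=float))
    if ids_predicted is not None or ids_truth is not None:
        if list(ids_predicted) != list(ids_truth):
            raise ValueError("annotation id mismatch between predictions and ground truth")
    if predicted.shape != ground_truth.shape:
        raise ValueError("point sets must have equal cardinality")
    err_px = np.hypot(*(predicted - ground_truth).T)
    err_um = err_px * mpp
    return {
        "errors_px": err_px,
        "errors_um": err_um,
        "mean_px": float(err_px.mean()),
        "median_px": float(np.median(err_px)),
        "p95_px": float(np.percentile(err_px, 95)),
        "mean_um": float(err_um.mean()),
        "median_um": float(np.median(err_um)),
        "p95_um": float(np.percentile(err_um, 95)),
        "max_um": float(err_um.max()),
    }
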
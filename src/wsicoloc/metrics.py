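"""Mattes mutual-information similarity metric.

Mutual information compares images through the co-occurrence statistics of
their intensities rather than the intensities themselves, which makes it
robust to the stain- and scanner-induced appearance changes between
re-stained/re-scanned slides.  Following the Mattes formulation, the joint
intensity density is estimated with Parzen windows: a zero-order (box)
kernel on the fixed-image intensities and a cubic B-spline kernel on the
(interpolated, hence continuous) moving-image intensities, evaluated at a
random subset of fixed-image coordinates.

The metric is returned negated so that optimizers minimize it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = ["MattesMIConfig", "mattes_mi", "MattesMIObjective", "OverlapError"]

#: Bins reserved at each end of the histogram so the cubic kernel support
#: never leaves the valid bin range.
_PAD = 2


class OverlapError(RuntimeError):
    """Raised when too few samples map inside the moving image."""


@dataclass
class MattesMIConfig:
    n_bins: int = 32
    n_samples: int = 2048
    min_overlap: float = 0.25  # minimum fraction of samples inside moving

    def __post_init__(self) -> None:
        if self.n_bins < 8:
            raise ValueError("n_bins must be >= 8")
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")


def cubic_bspline_kernel(x: np.ndarray) -> np.ndarray:
    """Cubic B-spline Parzen kernel, support (-2, 2), unit integral."""
    ax = np.abs(x)
    out = np.zeros_like(ax)
    m1 = ax < 1
    m2 = (ax >= 1) & (ax < 2)
    out[m1] = (4 - 6 * ax[m1] ** 2 + 3 * ax[m1] ** 3) / 6.0
    out[m2] = (2 - ax[m2]) ** 3 / 6.0
    return out


def _bin_positions(values: np.ndarray, lo: float, hi: float, n_bins: int) -> np.ndarray:
    """Continuous bin coordinate in [_PAD, n_bins - 1 - _PAD]."""
    span = hi - lo
    if span <= 0:
        raise ValueError("degenerate intensity range")
    return (values - lo) / span * (n_bins - 1 - 2 * _PAD) + _PAD


def joint_parzen_histogram(
    fixed_vals: np.ndarray,
    moving_vals: np.ndarray,
    n_bins: int,
    fixed_range: tuple[float, float],
    moving_range: tuple[float, float],
) -> np.ndarray:
    """Parzen joint density: box kernel on fixed, cubic B-spline on moving."""
    uf = _bin_positions(fixed_vals, *fixed_range, n_bins)
    um = _bin_positions(moving_vals, *moving_range, n_bins)
    f_bin = np.clip(np.round(uf).astype(np.intp), 0, n_bins - 1)
    m_floor = np.floor(um).astype(np.intp)

    hist = np.zeros(n_bins * n_bins)
    for off in (-1, 0, 1, 2):
        m_bin = m_floor + off
        w = cubic_bspline_kernel(um - m_bin)
        np.clip(m_bin, 0, n_bins - 1, out=m_bin)
        hist += np.bincount(f_bin * n_bins + m_bin, weights=w, minlength=n_bins * n_bins)
    hist = hist.reshape(n_bins, n_bins)
    total = hist.sum()
    return hist / total if total > 0 else hist


def mi_from_joint(p_joint: np.ndarray) -> float:
    """Mutual information (nats) of a normalized joint density."""
    pf = p_joint.sum(axis=1, keepdims=True)
    pm = p_joint.sum(axis=0, keepdims=True)
    mask = p_joint > 0
    ratio = p_joint[mask] / (pf @ pm)[mask]
    return float(np.sum(p_joint[mask] * np.log(ratio)))


def _intensity_range(img: np.ndarray) -> tuple[float, float]:
    lo, hi = float(img.min()), float(img.max())
    return lo, hi


def sample_coordinates(
    shape: tuple[int, int],
    n_samples: int | None,
    rng: np.random.Generator | None,
) -> np.ndarray:
    """(n, 2) sample coordinates as (x, y); exhaustive grid if n is None."""
    h, w = shape
    if n_samples is None or rng is None:
        xx, yy = np.meshgrid(np.arange(w, dtype=float), np.arange(h, dtype=float))
        return np.column_stack([xx.ravel(), yy.ravel()])
    x = rng.uniform(0, w - 1, size=n_samples)
    y = rng.uniform(0, h - 1, size=n_samples)
    return np.column_stack([x, y])


class MattesMIObjective:
    """Reusable Mattes-MI evaluator for one fixed/moving image pair.

    Pre-filters the moving image once into B-spline coefficients so that
    repeated metric evaluations (optimizer iterations, finite-difference
    gradients) only pay for interpolation at the sample points.
    """

    def __init__(
        self,
        fixed: np.ndarray,
        moving: np.ndarray,
        config: MattesMIConfig | None = None,
        interp_order: int = 3,
    ):
        self.fixed = np.asarray(fixed, dtype=float)
        self.moving = np.asarray(moving, dtype=float)
        if self.fixed.ndim != 2 or self.moving.ndim != 2:
            raise ValueError("mattes_mi operates on 2-D grayscale arrays")
        self.config = config or MattesMIConfig()
        self.interp_order = interp_order
        self._coeffs = ndimage.spline_filter(self.moving, order=interp_order, mode="mirror")
        self.fixed_range = _intensity_range(self.fixed)
        self.moving_range = _intensity_range(self.moving)
        self.fixed_constant = self.fixed_range[0] == self.fixed_range[1]
        self.moving_constant = self.moving_range[0] == self.moving_range[1]
        self._fbin_cache: tuple | None = None  # (key, f_bin) for reused sample sets

    def sample(self, seed: int | None, exhaustive: bool = False) -> np.ndarray:
        if exhaustive:
            return sample_coordinates(self.fixed.shape, None, None)
        rng = np.random.default_rng(seed)
        return sample_coordinates(self.fixed.shape, self.config.n_samples, rng)

    def value_at(self, transform, samples: np.ndarray) -> float:
        """Negated MI for a given transform at given fixed-domain samples."""
        return float(self.values_multi([transform], samples)[0])

    def values_multi(self, transforms, samples: np.ndarray) -> np.ndarray:
        """Negated MI for several transforms sharing one sample set.

        All mapped coordinates are interpolated in a single call and all
        joint histograms accumulated in one weighted bincount, which is
        what makes finite-difference gradients of the sampled metric
        affordable.
        """
        k = len(transforms)
        if self.fixed_constant or self.moving_constant:
            import warnings

            warnings.warn("constant image: mutual information is 0", stacklevel=2)
            return np.zeros(k)
        n = len(samples)
        b = self.config.n_bins
        h, w = self.moving.shape
        mapped = np.stack([T.apply(samples) for T in transforms])  # (k, n, 2)
        inside = (
            (mapped[..., 0] >= 0)
            & (mapped[..., 0] <= w - 1)
            & (mapped[..., 1] >= 0)
            & (mapped[..., 1] <= h - 1)
        )
        frac = inside.mean(axis=1)
        if np.any(frac < self.config.min_overlap):
            worst = float(frac.min())
            raise OverlapError(
                f"only {worst:.1%} of samples map inside the moving image "
                f"(minimum {self.config.min_overlap:.0%})"
            )
        key = (id(samples), n, samples[0, 0], samples[-1, 1])
        if self._fbin_cache is not None and self._fbin_cache[0] == key:
            f_bin = self._fbin_cache[1]
        else:
            fixed_vals = ndimage.map_coordinates(
                self.fixed, [samples[:, 1], samples[:, 0]], order=1, mode="nearest"
            )
            uf = _bin_positions(fixed_vals, *self.fixed_range, b)
            f_bin = np.clip(np.round(uf).astype(np.intp), 0, b - 1)  # (n,)
            self._fbin_cache = (key, f_bin)

        flat = mapped.reshape(-1, 2)
        moving_vals = ndimage.map_coordinates(
            self._coeffs,
            [flat[:, 1], flat[:, 0]],
            order=self.interp_order,
            prefilter=False,
            mode="mirror",
        )
        np.clip(moving_vals, *self.moving_range, out=moving_vals)
        um = _bin_positions(moving_vals, *self.moving_range, b).reshape(k, n)
        m_floor = np.floor(um).astype(np.intp)
        w_in = inside.astype(float)
        base_idx = np.arange(k, dtype=np.intp)[:, None] * (b * b) + f_bin[None, :] * b

        hist = np.zeros(k * b * b)
        for off in (-1, 0, 1, 2):
            m_bin = m_floor + off
            wgt = cubic_bspline_kernel(um - m_bin) * w_in
            np.clip(m_bin, 0, b - 1, out=m_bin)
            hist += np.bincount(
                (base_idx + m_bin).ravel(), weights=wgt.ravel(), minlength=k * b * b
            )
        hist = hist.reshape(k, b, b)
        totals = hist.sum(axis=(1, 2), keepdims=True)
        joint = hist / np.where(totals > 0, totals, 1.0)
        return -np.array([mi_from_joint(joint[i]) for i in range(k)])

    def __call__(self, transform, seed: int | None = None, exhaustive: bool = False) -> float:
        return self.value_at(transform, self.sample(seed, exhaustive))


def mattes_mi(
    fixed: np.ndarray,
    moving: np.ndarray,
    transform,
    config: MattesMIConfig | None = None,
    seed: int | None = None,
    exhaustive: bool = False,
) -> float:
    """Negated Mattes mutual information (nats) between ``fixed`` and
    ``moving`` under ``transform`` (fixed -> moving).

    With ``exhaustive=True`` every fixed pixel is used as a sample, which
    makes the value deterministic and directly comparable to a dense
    joint-histogram computation.
    """
    return MattesMIObjective(fixed, moving, config)(transform, seed=seed, exhaustive=exhaustive)
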
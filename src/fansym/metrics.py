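"""Image-quality metrics: MSE, PSNR, and global-statistics SSIM.

All three compare a reference image I against a test image K of identical
shape.  SSIM here is the *global* single-window form

    SSIM = (2 mu_x mu_y + c1)(2 sigma_xy + c2)
           / ((mu_x^2 + mu_y^2 + c1)(sigma_x^2 + sigma_y^2 + c2))

with population (1/N) variances/covariance over the whole image and
stabilizers c1 = (k1 * max_val)^2, c2 = (k2 * max_val)^2 (k1 = 0.01,
k2 = 0.03 by convention).  The common sliding-window SSIM is available as an
explicit non-default option (delegated to scikit-image).

``max_val`` (the peak intensity MAX entering PSNR and the SSIM stabilizers)
is always an explicit argument: 255 for 8-bit exports, the data range for
float grids.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from skimage.metrics import structural_similarity as _skimage_ssim

from .phantom import ImageGrid

__all__ = ["QualityReport", "mse", "psnr", "ssim", "evaluate"]


def _as_array(img) -> np.ndarray:
    if isinstance(img, ImageGrid):
        return img.values
    return np.asarray(img, dtype=float)


def _pair(I, K) -> tuple[np.ndarray, np.ndarray]:
    a, b = _as_array(I), _as_array(K)
    if a.shape != b.shape:
        raise ValueError(f"image shapes differ: {a.shape} vs {b.shape}")
    return a, b


def mse(I, K) -> float:
    """Mean squared error, 1/(mn) * sum of squared pixel differences."""
    a, b = _pair(I, K)
    return float(np.mean((a - b) ** 2))


def psnr(I, K, max_val: float) -> float:
    """Peak signal-to-noise ratio 10*log10(max_val^2 / MSE), in decibels.

    Identical images have zero MSE; the defined sentinel ``math.inf`` is
    returned (infinite PSNR), not an error.
    """
    if max_val <= 0:
        raise ValueError("max_val must be positive")
    e = mse(I, K)
    if e == 0.0:
        return math.inf
    return 10.0 * math.log10(max_val * max_val / e)


def ssim(
    I,
    K,
    max_val: float,
    k1: float = 0.01,
    k2: float = 0.03,
    windowed: bool = False,
    window_size: int = 11,
) -> float:
    """Structural similarity index.

    Default: global statistics over the whole image (single window),
    population denominators.  ``windowed=True`` switches to the sliding
    Gaussian-window variant of scikit-image — a deliberately non-default
    alternative, as the global form is this package's evaluation contract.
    """
    a, b = _pair(I, K)
    if max_val <= 0:
        raise ValueError("max_val must be positive")
    if windowed:
        return float(
            _skimage_ssim(
                a, b, data_range=max_val, K1=k1, K2=k2,
                gaussian_weights=True, win_size=window_size, sigma=1.5,
                use_sample_covariance=False,
            )
        )
    c1 = (k1 * max_val) ** 2
    c2 = (k2 * max_val) ** 2
    mu_x, mu_y = a.mean(), b.mean()
    var_x = np.mean((a - mu_x) ** 2)
    var_y = np.mean((b - mu_y) ** 2)
    cov = np.mean((a - mu_x) * (b - mu_y))
    return float(
        (2 * mu_x * mu_y + c1) * (2 * cov + c2)
        / ((mu_x**2 + mu_y**2 + c1) * (var_x + var_y + c2))
    )


@dataclass(frozen=True)
class QualityReport:
    """MSE/PSNR/SSIM of one image pair with the constants used."""

    mse: float
    psnr: float
    ssim: float
    max_val: float
    k1: float
    k2: float

    @property
    def c1(self) -> float:
        return (self.k1 * self.max_val) ** 2

    @property
    def c2(self) -> float:
        return (self.k2 * self.max_val) ** 2

    def as_dict(self) -> dict:
        return {
            "mse": self.mse,
            "psnr": self.psnr,
            "ssim": self.ssim,
            "max_val": self.max_val,
            "k1": self.k1,
            "k2": self.k2,
            "c1": self.c1,
            "c2": self.c2,
        }


def evaluate(I, K, max_val: float, k1: float = 0.01, k2: float = 0.03) -> QualityReport:
    """All three metrics of a pair at once."""
    return QualityReport(
        mse=mse(I, K),
        psnr=psnr(I, K, max_val),
        ssim=ssim(I, K, max_val, k1, k2),
        max_val=max_val,
        k1=k1,
        k2=k2,
    )
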
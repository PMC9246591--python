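"""Fan-beam forward projection: analytic (closed-form ellipse chords) and numeric.

Geometry
--------
Flat, equispaced detector; the detector coordinate ``s`` lives on the
*virtual detector* — the line through the isocenter perpendicular to the
source-isocenter axis — so ``s`` carries object-scale length units.

At view angle ``beta`` (degrees) the source sits at polar angle
``beta + 90°`` at distance ``D`` from the isocenter, i.e. at Cartesian
``D * (-sin beta, cos beta)``, and the detector axis is the unit vector
``(cos beta, sin beta)``.  With this single convention a point at polar
coordinates ``(r, phi)`` projects to detector coordinate

    s' = D * r * cos(beta - phi) / (D + r * sin(beta - phi)),

so that ``phi = beta`` gives ``s' = r`` and ``r = 0`` gives ``s' = 0``.
The view angles are ``beta_k = k * 360 / n_views`` for ``k = 1 .. n_views``
(half-open angular regions ``(0, 90], (90, 180], ...`` as used by the
quadrant-symmetry reconstructor).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import cached_property

import numpy as np
from scipy import ndimage

from .phantom import ImageGrid, PhantomSpec

__all__ = [
    "FanBeamGeometry",
    "Sinogram",
    "ray_for",
    "project_analytic",
    "project_numeric",
    "add_noise",
]


@dataclass(frozen=True)
class FanBeamGeometry:
    """Source distance, uniform full-turn view angles, flat equispaced detector."""

    D: float
    n_views: int
    n_bins: int
    bin_spacing: float

    def __post_init__(self) -> None:
        if self.D <= 0:
            raise ValueError("source distance D must be positive")
        if self.n_views < 4:
            raise ValueError(f"need at least 4 views, got {self.n_views}")
        if self.n_bins < 1 or self.bin_spacing <= 0:
            raise ValueError("detector must have >= 1 bin with positive spacing")

    @cached_property
    def view_angles_deg(self) -> np.ndarray:
        """beta_k = k * 360/n_views, k = 1..n_views (last view is 360°)."""
        return np.arange(1, self.n_views + 1) * (360.0 / self.n_views)

    @cached_property
    def bin_centers(self) -> np.ndarray:
        """Detector bin centers, symmetric about s = 0."""
        return (np.arange(self.n_bins) - (self.n_bins - 1) / 2.0) * self.bin_spacing

    @property
    def delta_beta_rad(self) -> float:
        return 2.0 * math.pi / self.n_views

    @property
    def half_width(self) -> float:
        return self.n_bins * self.bin_spacing / 2.0

    def fan_shadow_half_width(self, radius: float) -> float:
        """Largest |s'| reached by any point within `radius` of the isocenter."""
        if radius >= self.D:
            raise ValueError("object radius must be smaller than D")
        return radius / math.sqrt(1.0 - (radius / self.D) ** 2)

    def covers(self, radius: float) -> bool:
        """Does the detector span the fan shadow of the bounding disk?"""
        return self.fan_shadow_half_width(radius) <= self.half_width * (1 + 1e-12)

    @classmethod
    def for_object(
        cls,
        radius: float,
        n_views: int,
        n_bins: int,
        D: float | None = None,
        margin: float = 1.05,
    ) -> "FanBeamGeometry":
        """Geometry sized so the detector covers the object with a small margin.

        ``D`` defaults to four times the object radius.
        """
        if D is None:
            D = 4.0 * radius
        shadow = radius / math.sqrt(1.0 - (radius / D) ** 2)
        spacing = 2.0 * shadow * margin / n_bins
        return cls(D=D, n_views=n_views, n_bins=n_bins, bin_spacing=spacing)


@dataclass
class Sinogram:
    """n_views x n_bins grid of fan-beam line integrals with its geometry."""

    geometry: FanBeamGeometry
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        expected = (self.geometry.n_views, self.geometry.n_bins)
        if self.values.shape != expected:
            raise ValueError(
                f"sinogram shape {self.values.shape} inconsistent with geometry "
                f"{expected}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("sinogram values must be finite")

    def copy_with(self, values: np.ndarray) -> "Sinogram":
        return Sinogram(self.geometry, values)


def _source_and_axis(beta_deg: float) -> tuple[np.ndarray, np.ndarray]:
    rad = math.radians(beta_deg)
    sb, cb = math.sin(rad), math.cos(rad)
    source = np.array([-sb, cb])
    axis = np.array([cb, sb])
    return source, axis


def ray_for(geometry: FanBeamGeometry, beta_deg: float, s: float):
    """Parametric ray (origin point, unit direction) for one detector coordinate.

    The ray starts at the source and passes through the virtual-detector point
    at coordinate ``s``; it is the exact inverse of the ``s'`` mapping — every
    in-field point ``(r, phi)`` with ``s'(r, phi, beta) = s`` lies on it.
    """
    u, t = _source_and_axis(beta_deg)
    source = geometry.D * u
    direction = s * t - source
    direction = direction / np.linalg.norm(direction)
    return source, direction


def project_analytic(spec: PhantomSpec, geometry: FanBeamGeometry) -> Sinogram:
    """Exact sinogram of an ellipse phantom via closed-form ray/ellipse chords.

    Each entry is sum over ellipses of (chord length of the ray through the
    ellipse) x (ellipse value).  Serves as the independent oracle for the
    numeric projector and as noise-free input for reconstruction tests.
    """
    if spec.bounding_radius >= geometry.D:
        raise ValueError("object extends to or beyond the source: outside field of view")
    if not geometry.covers(spec.bounding_radius):
        raise ValueError(
            "detector half-width does not cover the object's fan shadow "
            f"({geometry.fan_shadow_half_width(spec.bounding_radius):.6g} > "
            f"{geometry.half_width:.6g})"
        )

    betas = np.radians(geometry.view_angles_deg)
    sources = geometry.D * np.stack([-np.sin(betas), np.cos(betas)], axis=1)  # (V, 2)
    axes = np.stack([np.cos(betas), np.sin(betas)], axis=1)                   # (V, 2)
    s = geometry.bin_centers                                                  # (B,)

    det_pts = s[None, :, None] * axes[:, None, :]          # (V, B, 2)
    d = det_pts - sources[:, None, :]
    d /= np.linalg.norm(d, axis=2, keepdims=True)

    out = np.zeros((geometry.n_views, geometry.n_bins))
    for e in spec.ellipses:
        rad = math.radians(e.theta_deg)
        c, sn = math.cos(rad), math.sin(rad)
        rot = np.array([[c, sn], [-sn, c]])  # rotate by -theta into ellipse frame
        scale = np.array([1.0 / e.a, 1.0 / e.b])

        o2 = ((sources - np.array([e.cx, e.cy])) @ rot.T) * scale  # (V, 2)
        d2 = (d @ rot.T) * scale                                    # (V, B, 2)

        A = np.einsum("vbk,vbk->vb", d2, d2)
        B = 2.0 * np.einsum("vbk,vk->vb", d2, o2)
        C = np.einsum("vk,vk->v", o2, o2)[:, None] - 1.0
        disc = B * B - 4.0 * A * C
        chord = np.where(disc > 0.0, np.sqrt(np.maximum(disc, 0.0)) / A, 0.0)
        out += e.value * chord
    return Sinogram(geometry, out)


def project_numeric(grid: ImageGrid, geometry: FanBeamGeometry, step: float) -> Sinogram:
    """Sinogram of a pixel grid by sampled line integrals.

    Rays are sampled at spacing ``step`` with bilinear interpolation of the
    grid (zero outside); converges to the analytic projection of the
    generating phantom as ``step -> 0`` and the grid is refined.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    n, p = grid.n, grid.pixel_size
    half = (n - 1) / 2.0
    grid_radius = n * p * math.sqrt(2.0) / 2.0
    # sample the segment of each ray that can intersect the grid's bounding disk
    lam = np.arange(geometry.D - grid_radius, geometry.D + grid_radius + step, step)

    out = np.empty((geometry.n_views, geometry.n_bins))
    s = geometry.bin_centers
    for k, beta in enumerate(geometry.view_angles_deg):
        source, axis = _source_and_axis(beta)
        source = geometry.D * source
        d = s[:, None] * axis[None, :] - source[None, :]
        d /= np.linalg.norm(d, axis=1, keepdims=True)          # (B, 2)
        pts = source[None, None, :] + lam[None, :, None] * d[:, None, :]  # (B, L, 2)
        cols = pts[..., 0] / p + half
        rows = half - pts[..., 1] / p
        vals = ndimage.map_coordinates(
            grid.values,
            np.stack([rows.ravel(), cols.ravel()]),
            order=1,
            mode="constant",
            cval=0.0,
        ).reshape(geometry.n_bins, lam.size)
        out[k] = vals.sum(axis=1) * step
    return Sinogram(geometry, out)


def add_noise(sino: Sinogram, sigma: float, seed: int) -> Sinogram:
    """Add i.i.d. zero-mean Gaussian noise of standard deviation sigma."""
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if sigma == 0:
        return sino.copy_with(sino.values.copy())
    rng = np.random.default_rng(seed)
    return sino.copy_with(sino.values + rng.normal(0.0, sigma, sino.values.shape))
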
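"""Analytic ellipse phantoms and their rasterization onto centered pixel grids.

A phantom is an ordered list of additive ellipses — the standard stand-in for
a 2-D head section (outer skull ring, brain tissue, small high-contrast
lesions).  Every downstream stage (forward projection, reconstruction,
quality metrics) can therefore be exercised without any external image data.

Conventions
-----------
* Intensities are dimensionless attenuation-like values; overlapping
  ellipses add.
* Rasterization samples each pixel *center* (no area-weighted antialiasing);
  a pixel takes the sum of the values of the ellipses containing its center.
* The pixel grid is centered on the isocenter: pixel ``(i, j)`` of an
  ``n``-pixel grid has its center at
  ``x = (j - (n-1)/2) * pixel_size``, ``y = ((n-1)/2 - i) * pixel_size``.
  With this convention a 90° rotation about the isocenter maps pixel centers
  onto pixel centers exactly, for odd and even ``n`` alike — the property the
  symmetry-accelerated reconstructor relies on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Ellipse",
    "PhantomSpec",
    "ImageGrid",
    "point_in_ellipse",
    "rasterize",
    "default_head_phantom",
    "uniform_disk_phantom",
]


@dataclass(frozen=True)
class Ellipse:
    """One additive ellipse of a phantom.

    Parameters
    ----------
    cx, cy : float
        Center, in physical length units.
    a, b : float
        Semi-axes; ``a`` lies along the local x axis before rotation.
    theta_deg : float
        Counterclockwise rotation angle in degrees.
    value : float
        Additive intensity contributed inside the ellipse.
    """

    cx: float
    cy: float
    a: float
    b: float
    theta_deg: float
    value: float

    def __post_init__(self) -> None:
        if not (self.a > 0 and self.b > 0):
            raise ValueError(f"semi-axes must be positive, got a={self.a}, b={self.b}")
        if not all(math.isfinite(v) for v in
                   (self.cx, self.cy, self.a, self.b, self.theta_deg, self.value)):
            raise ValueError("ellipse parameters must be finite")

    def rotated(self, angle_deg: float) -> "Ellipse":
        """The ellipse rotated counterclockwise about the origin."""
        rad = math.radians(angle_deg)
        c, s = math.cos(rad), math.sin(rad)
        return Ellipse(
            cx=c * self.cx - s * self.cy,
            cy=s * self.cx + c * self.cy,
            a=self.a,
            b=self.b,
            theta_deg=self.theta_deg + angle_deg,
            value=self.value,
        )


@dataclass(frozen=True)
class PhantomSpec:
    """An ordered collection of additive ellipses inside a bounding disk."""

    ellipses: tuple[Ellipse, ...]
    bounding_radius: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "ellipses", tuple(self.ellipses))
        if self.bounding_radius <= 0:
            raise ValueError("bounding_radius must be positive")
        for k, e in enumerate(self.ellipses):
            # conservative containment check: center distance + largest semi-axis
            reach = math.hypot(e.cx, e.cy) + max(e.a, e.b)
            if reach > self.bounding_radius * (1 + 1e-12):
                raise ValueError(
                    f"ellipse {k} reaches {reach:.6g}, outside bounding radius "
                    f"{self.bounding_radius:.6g}"
                )

    def rotated(self, angle_deg: float) -> "PhantomSpec":
        return PhantomSpec(
            tuple(e.rotated(angle_deg) for e in self.ellipses), self.bounding_radius
        )


@dataclass
class ImageGrid:
    """Square n-by-n grid of real values centered on the isocenter."""

    values: np.ndarray
    pixel_size: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError(f"grid must be square 2-D, got shape {self.values.shape}")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("grid values must be finite")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) coordinate arrays of shape (n, n) for all pixel centers."""
        n, p = self.n, self.pixel_size
        half = (n - 1) / 2.0
        cols = (np.arange(n) - half) * p
        rows = (half - np.arange(n)) * p
        x = np.broadcast_to(cols[None, :], (n, n))
        y = np.broadcast_to(rows[:, None], (n, n))
        return x, y

    def rot90(self, k: int = 1) -> "ImageGrid":
        """Rotate the image by k*90° counterclockwise about the isocenter.

        Exact: with the centered-pixel convention the rotation is a pure
        index permutation.
        """
        return ImageGrid(np.rot90(self.values, k=k).copy(), self.pixel_size)


def point_in_ellipse(x: float, y: float, e: Ellipse) -> bool:
    """True iff (x, y) lies inside or on the boundary of the ellipse."""
    rad = math.radians(e.theta_deg)
    c, s = math.cos(rad), math.sin(rad)
    dx, dy = x - e.cx, y - e.cy
    # rotate the offset by -theta into the ellipse's own frame
    xp = c * dx + s * dy
    yp = -s * dx + c * dy
    return (xp / e.a) ** 2 + (yp / e.b) ** 2 <= 1.0


def rasterize(spec: PhantomSpec, n: int, pixel_size: float) -> ImageGrid:
    """Sample the phantom on an n-by-n centered grid (pixel-center containment)."""
    if n < 2:
        raise ValueError(f"n must be >= 2, got {n}")
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    grid = ImageGrid(np.zeros((n, n)), pixel_size)
    x, y = grid.pixel_centers()
    for e in spec.ellipses:
        rad = math.radians(e.theta_deg)
        c, s = math.cos(rad), math.sin(rad)
        dx, dy = x - e.cx, y - e.cy
        xp = c * dx + s * dy
        yp = -s * dx + c * dy
        inside = (xp / e.a) ** 2 + (yp / e.b) ** 2 <= 1.0
        grid.values += np.where(inside, e.value, 0.0)
    return grid


def default_head_phantom() -> PhantomSpec:
    """Deterministic head-like phantom: skull ring, brain tissue, two lesions.

    The outer pair of concentric ellipses (the inner one with a negative
    value) forms a bright "skull" ring of value 2.0 over an interior base of
    0.2; a large tissue ellipse raises the brain to ~1.0; a small rotated
    high-intensity lesion and a small hypointense lesion provide off-center
    contrast.  All values are dimensionless; everything fits inside a unit
    bounding disk.
    """
    return PhantomSpec(
        ellipses=(
            Ellipse(0.0, 0.0, 0.90, 0.95, 0.0, 2.0),    # skull, outer
            Ellipse(0.0, 0.0, 0.82, 0.87, 0.0, -1.8),   # skull, inner (ring)
            Ellipse(0.0, -0.02, 0.72, 0.78, 0.0, 0.8),  # brain tissue
            Ellipse(0.35, 0.25, 0.10, 0.08, 30.0, 0.6),  # hyperintense lesion
            Ellipse(-0.28, -0.30, 0.07, 0.07, 0.0, -0.4),  # hypointense lesion
        ),
        bounding_radius=1.0,
    )


def uniform_disk_phantom(radius: float = 0.5, value: float = 1.0) -> PhantomSpec:
    """A single uniform disk — the classic closed-form reconstruction oracle."""
    return PhantomSpec(
        ellipses=(Ellipse(0.0, 0.0, radius, radius, 0.0, value),),
        bounding_radius=radius,
    )
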
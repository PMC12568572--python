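"""Shared planar geometry primitives.

Coordinate convention used throughout the package: pixel-centered raster
coordinates, origin at the top-left pixel center, x rightward, y downward.
Angles are measured with ``atan2(-dy, dx)`` so that 90 degrees points to the
top of the image (superior retina).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict


@dataclass(frozen=True)
class Ellipse:
    """Ellipse in pixel coordinates.

    Parameters
    ----------
    center : (float, float)
        (x, y) center in pixels.
    semi_axes : (float, float)
        Semi-major and semi-minor axis lengths in pixels (order is not
        enforced; area and equal-area radius are symmetric in the two).
    rotation : float
        Rotation of the first axis in radians, counter-clockwise in the
        mathematical sense (i.e. clockwise on screen with y down).
    """

    center: tuple[float, float]
    semi_axes: tuple[float, float]
    rotation: float = 0.0

    def __post_init__(self) -> None:
        a, b = self.semi_axes
        if not (a > 0 and b > 0):
            raise ValueError(f"ellipse semi-axes must be positive, got {self.semi_axes}")

    @property
    def area(self) -> float:
        """Area in px^2."""
        a, b = self.semi_axes
        return math.pi * a * b

    @property
    def equal_area_radius(self) -> float:
        """Radius of the circle with the same area, in px."""
        a, b = self.semi_axes
        return math.sqrt(a * b)

    def contains_point(self, x: float, y: float, scale: float = 1.0) -> bool:
        """True if (x, y) lies inside the ellipse scaled by ``scale``."""
        cx, cy = self.center
        dx, dy = x - cx, y - cy
        c, s = math.cos(self.rotation), math.sin(self.rotation)
        u = c * dx + s * dy
        v = -s * dx + c * dy
        a, b = self.semi_axes
        return (u / (a * scale)) ** 2 + (v / (b * scale)) ** 2 <= 1.0

    def contains_ellipse(self, other: "Ellipse", n_probe: int = 64) -> bool:
        """Approximate containment test by probing the other ellipse's boundary."""
        a, b = other.semi_axes
        c, s = math.cos(other.rotation), math.sin(other.rotation)
        ox, oy = other.center
        for k in range(n_probe):
            t = 2.0 * math.pi * k / n_probe
            u, v = a * math.cos(t), b * math.sin(t)
            x = ox + c * u - s * v
            y = oy + s * u + c * v
            if not self.contains_point(x, y, scale=1.0 + 1e-9):
                return False
        return True

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "Ellipse":
        return cls(
            center=tuple(d["center"]),
            semi_axes=tuple(d["semi_axes"]),
            rotation=float(d.get("rotation", 0.0)),
        )


def circle(center: tuple[float, float], radius: float) -> Ellipse:
    return Ellipse(center=center, semi_axes=(radius, radius), rotation=0.0)
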
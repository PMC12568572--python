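"""Peripapillary measurement zones: PD-scaled annuli and S/N/I/T quadrants.

Distances are expressed in PD units (one PD = the disc's equal-area circular
diameter) measured from the disc *border* (distance from the disc center
minus the equal-area radius).  Quadrants split the plane along the two 45°
diagonals through the disc center — superior up, inferior down, nasal toward
the nose (+x in right-eye images, -x in left-eye images), temporal opposite —
and are restricted to the 0.5–2.5 PD peripapillary band.  Boundary pixels
belong to half-open intervals (inner-inclusive radially, counter-clockwise-
inclusive angularly), so annuli are pairwise disjoint and the four quadrants
partition the band with no pixel assigned twice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import Ellipse

__all__ = [
    "ZoneSpec",
    "disc_diameter_pd",
    "annulus_region",
    "quadrant_region",
    "default_annuli",
    "QUADRANTS",
    "annulus_label",
    "peripapillary_band",
]

QUADRANTS = ("Superior", "Nasal", "Inferior", "Temporal")
DEFAULT_ANNULI = ((0.5, 1.0), (1.0, 1.5), (1.5, 2.0), (2.0, 2.5))
BAND_PD = (0.5, 2.5)  # the peripapillary band hosting the quadrants


@dataclass(frozen=True)
class ZoneSpec:
    kind: str  # "global" | "annulus" | "quadrant"
    inner_pd: float = 0.0
    outer_pd: float = float("inf")
    quadrant: str | None = None
    eye: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("global", "annulus", "quadrant"):
            raise ValueError(f"unknown zone kind {self.kind!r}")
        if self.kind == "annulus" and not (0 <= self.inner_pd < self.outer_pd):
            raise ValueError("require 0 <= inner < outer for an annulus")
        if self.kind == "quadrant":
            if self.quadrant not in QUADRANTS:
                raise ValueError(f"unknown quadrant {self.quadrant!r}")
            if self.eye not in ("OD", "OS"):
                raise ValueError("quadrant zones require known eye laterality")

    @property
    def label(self) -> str:
        if self.kind == "global":
            return "Global"
        if self.kind == "annulus":
            return annulus_label(self.inner_pd, self.outer_pd)
        return self.quadrant  # type: ignore[return-value]


def annulus_label(inner_pd: float, outer_pd: float) -> str:
    return f"{inner_pd:.1f}–{outer_pd:.1f} PD"  # en dash, e.g. "0.5–1.0 PD"


def disc_diameter_pd(disc_ellipse: Ellipse) -> float:
    """One PD in pixels: diameter of the circle with the disc ellipse's area."""
    return 2.0 * disc_ellipse.equal_area_radius


def _border_distance(disc_ellipse: Ellipse, shape: tuple[int, int]) -> np.ndarray:
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    cx, cy = disc_ellipse.center
    return np.sqrt((xx - cx) ** 2 + (yy - cy) ** 2) - disc_ellipse.equal_area_radius


def annulus_region(
    disc_ellipse: Ellipse,
    inner_pd: float,
    outer_pd: float,
    shape: tuple[int, int],
) -> np.ndarray:
    """Pixels whose distance from the disc border lies in [inner, outer) PD."""
    if not inner_pd < outer_pd:
        raise ValueError("require inner_pd < outer_pd")
    pd_px = disc_diameter_pd(disc_ellipse)
    d = _border_distance(disc_ellipse, shape)
    region = (d >= inner_pd * pd_px) & (d < outer_pd * pd_px)
    if not region.any():
        import warnings

        warnings.warn(f"annulus {annulus_label(inner_pd, outer_pd)} lies fully outside the frame")
    return region


def peripapillary_band(disc_ellipse: Ellipse, shape: tuple[int, int]) -> np.ndarray:
    return annulus_region(disc_ellipse, BAND_PD[0], BAND_PD[1], shape)


def quadrant_region(
    disc_ellipse: Ellipse,
    quadrant: str,
    eye: str,
    shape: tuple[int, int],
    band_pd: tuple[float, float] = BAND_PD,
) -> np.ndarray:
    """One S/N/I/T sector of the peripapillary band (45° diagonal split)."""
    if quadrant not in QUADRANTS:
        raise ValueError(f"unknown quadrant {quadrant!r}")
    if eye not in ("OD", "OS"):
        raise ValueError(f"unknown eye laterality {eye!r}")
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    cx, cy = disc_ellipse.center
    # screen angle: 0 = +x, 90 = up; half-open 90° sectors starting at 45°
    phi = np.degrees(np.arctan2(-(yy - cy), xx - cx)) % 360.0
    sectors = {
        "Superior": (45.0, 135.0),
        "Inferior": (225.0, 315.0),
    }
    nasal_right = eye == "OD"  # nasal retina maps to +x in right-eye images
    if quadrant in sectors:
        lo, hi = sectors[quadrant]
    elif (quadrant == "Nasal") == nasal_right:
        lo, hi = 315.0, 45.0  # the +x sector, wrapping through 0
    else:
        lo, hi = 135.0, 225.0  # the -x sector
    if lo < hi:
        sector = (phi >= lo) & (phi < hi)
    else:
        sector = (phi >= lo) | (phi < hi)
    pd_px = disc_diameter_pd(disc_ellipse)
    d = _border_distance(disc_ellipse, shape)
    band = (d >= band_pd[0] * pd_px) & (d < band_pd[1] * pd_px)
    return sector & band


def default_annuli(eye: str | None = None) -> list[ZoneSpec]:
    return [ZoneSpec("annulus", inner_pd=a, outer_pd=b) for a, b in DEFAULT_ANNULI]


def default_zones(eye: str) -> list[ZoneSpec]:
    """Global + four annuli + four quadrants, in reporting order."""
    zones = [ZoneSpec("global")]
    zones += default_annuli()
    zones += [ZoneSpec("quadrant", quadrant=q, eye=eye) for q in QUADRANTS]
    return zones


def zone_region(
    zone: ZoneSpec, disc_ellipse: Ellipse, shape: tuple[int, int]
) -> np.ndarray | None:
    """Raster region for a zone; None means the whole frame (global scope)."""
    if zone.kind == "global":
        return None
    if zone.kind == "annulus":
        return annulus_region(disc_ellipse, zone.inner_pd, zone.outer_pd, shape)
    return quadrant_region(disc_ellipse, zone.quadrant, zone.eye, shape)
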
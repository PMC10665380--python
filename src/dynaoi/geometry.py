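"""Screen geometry for a flat wide-field display.

The display is modeled as a single coplanar surface (three side-by-side
monitors treated as one 5760x1200 pixel plane) viewed from a fixed distance
with the eyes centered on the screen middle.  All conversions between pixel
coordinates and visual angles use the true arctangent on this flat-plane
model; no small-angle approximation is used, because eccentricities reach
50 degrees at the screen edges.

Pixel coordinate convention: origin at the top-left corner, x increasing
rightward, y increasing downward (image convention).  Angular convention:
horizontal angle positive to the right of the vertical meridian, vertical
angle positive above the horizontal meridian.

Screen regions
--------------
Eight named regions are defined for dwell-ratio bookkeeping:

* ``central10`` / ``central20`` / ``central30`` — discs around the screen
  center whose *diameter* is 10, 20 or 30 degrees of visual angle;
* ``entire_screen`` — the full pixel surface;
* ``left`` / ``right`` and ``top`` / ``bottom`` — half-screen partitions.

Midline ties are assigned to ``right`` and ``bottom`` respectively, so the
two partitions are exact for every on-surface point.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import FrozenSet

import numpy as np

CM_PER_INCH = 2.54

#: Region labels, in nesting/partition order.
REGION_LABELS = (
    "central10",
    "central20",
    "central30",
    "entire_screen",
    "left",
    "right",
    "top",
    "bottom",
)

#: Central-disc diameters (degrees) behind the central10/20/30 regions.
CENTRAL_DIAMETERS_DEG = {"central10": 10.0, "central20": 20.0, "central30": 30.0}


class GeometryError(ValueError):
    """Invalid geometric input (non-finite coordinate, impossible angle)."""


@dataclass(frozen=True)
class ScreenConfig:
    """Physical and pixel geometry of the display surface.

    Defaults describe three 24-inch 1920x1200 monitors side by side
    (5760x1200 px, 94.34 ppi) viewed from 65 cm, which yields a horizontal
    span of ~100 degrees.

    Parameters
    ----------
    width_px, height_px
        Surface size in pixels.
    ppi
        Pixel density (pixels per inch), assumed isotropic.
    viewing_distance_cm
        Perpendicular eye-to-screen distance; the gaze origin is on the
        normal through the screen center.
    """

    width_px: int = 5760
    height_px: int = 1200
    ppi: float = 94.34
    viewing_distance_cm: float = 65.0

    def __post_init__(self) -> None:
        for name in ("width_px", "height_px", "ppi", "viewing_distance_cm"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise GeometryError(f"{name} must be positive and finite, got {v!r}")

    @property
    def px_per_cm(self) -> float:
        return self.ppi / CM_PER_INCH

    @property
    def physical_width_cm(self) -> float:
        return self.width_px / self.px_per_cm

    @property
    def physical_height_cm(self) -> float:
        return self.height_px / self.px_per_cm

    @property
    def center(self) -> tuple[float, float]:
        """Screen center in pixel coordinates."""
        return (self.width_px / 2.0, self.height_px / 2.0)

    @property
    def horizontal_span_deg(self) -> float:
        """Total horizontal visual angle subtended by the surface."""
        half = self.physical_width_cm / 2.0
        return 2.0 * math.degrees(math.atan2(half, self.viewing_distance_cm))


@dataclass(frozen=True)
class AngularOffset:
    """Visual-angle position of a screen point relative to the center.

    ``h_deg`` is signed (positive right), ``v_deg`` is signed (positive up),
    and ``eccentricity_deg`` is the total angle between the gaze ray to the
    point and the ray to the screen center — computed on the flat-plane
    model, not as ``sqrt(h**2 + v**2)``.
    """

    h_deg: float
    v_deg: float
    eccentricity_deg: float


def px_to_angle(x: float, y: float, cfg: ScreenConfig) -> AngularOffset:
    """Convert a pixel coordinate to visual angles from the screen center.

    Off-surface coordinates are converted like any other point (flagging is
    the caller's concern); non-finite coordinates raise :class:`GeometryError`.
    """
    if not (np.isfinite(x) and np.isfinite(y)):
        raise GeometryError(f"non-finite coordinates ({x!r}, {y!r})")
    cx, cy = cfg.center
    dx_cm = (x - cx) / cfg.px_per_cm
    dy_cm = (cy - y) / cfg.px_per_cm  # flip: pixel y grows downward
    d = cfg.viewing_distance_cm
    h = math.degrees(math.atan2(dx_cm, d))
    v = math.degrees(math.atan2(dy_cm, d))
    ecc = math.degrees(math.atan2(math.hypot(dx_cm, dy_cm), d))
    return AngularOffset(h_deg=h, v_deg=v, eccentricity_deg=ecc)


def eccentricity_deg(x, y, cfg: ScreenConfig):
    """Vectorized eccentricity (degrees) of pixel coordinates.

    Accepts scalars or arrays; returns the same shape.
    """
    cx, cy = cfg.center
    dx = (np.asarray(x, dtype=float) - cx) / cfg.px_per_cm
    dy = (np.asarray(y, dtype=float) - cy) / cfg.px_per_cm
    return np.degrees(np.arctan2(np.hypot(dx, dy), cfg.viewing_distance_cm))


def deg_to_px(
    angle_deg: float, cfg: ScreenConfig, at: tuple[float, float] | None = None
) -> float:
    """On-screen pixel length subtending ``angle_deg`` at a given location.

    The length is measured radially outward from the screen center under the
    flat-plane model: a point at eccentricity ``e`` lies ``tan(e)*d`` from
    the center, so the extent covering ``e .. e+angle`` is
    ``(tan(e+angle) - tan(e)) * d`` converted to pixels.  At the screen
    center (the default) this reduces to ``tan(angle)*d``.

    Because the flat plane only intersects rays within 90 degrees of the
    normal, ``angle_deg`` plus the local eccentricity must stay below 90.
    """
    if not np.isfinite(angle_deg) or angle_deg < 0:
        raise GeometryError(f"angle_deg must be finite and >= 0, got {angle_deg!r}")
    ecc = 0.0 if at is None else px_to_angle(at[0], at[1], cfg).eccentricity_deg
    if angle_deg + ecc >= 90.0:
        raise GeometryError(
            f"angle {angle_deg} deg at eccentricity {ecc:.1f} deg does not "
            "intersect the screen plane"
        )
    d = cfg.viewing_distance_cm
    length_cm = (math.tan(math.radians(ecc + angle_deg)) - math.tan(math.radians(ecc))) * d
    return length_cm * cfg.px_per_cm


def central_radius_px(diameter_deg: float, cfg: ScreenConfig) -> float:
    """Pixel radius of the central disc with the given angular *diameter*.

    The disc of eccentricity <= D/2 is an exact circle in pixel space on the
    flat-plane model, of radius ``tan(D/2) * distance``.
    """
    return deg_to_px(diameter_deg / 2.0, cfg)


def on_surface(x, y, cfg: ScreenConfig):
    """Vectorized containment test against the pixel surface (closed bounds)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    return (x >= 0) & (x <= cfg.width_px) & (y >= 0) & (y <= cfg.height_px)


def region_membership(x: float, y: float, cfg: ScreenConfig) -> FrozenSet[str]:
    """Set of region labels containing the point.

    Off-surface points belong to no region.  ``centralD`` membership means
    eccentricity <= D/2.  Midline ties go to ``right`` / ``bottom``.
    """
    if not bool(on_surface(x, y, cfg)):
        return frozenset()
    labels = {"entire_screen"}
    ecc = px_to_angle(x, y, cfg).eccentricity_deg
    for name, diam in CENTRAL_DIAMETERS_DEG.items():
        if ecc <= diam / 2.0:
            labels.add(name)
    cx, cy = cfg.center
    labels.add("right" if x >= cx else "left")
    labels.add("bottom" if y >= cy else "top")
    return frozenset(labels)


def region_masks(x, y, cfg: ScreenConfig) -> dict[str, np.ndarray]:
    """Vectorized region membership for arrays of pixel coordinates.

    Returns a boolean array per region label; used by the dwell-ratio
    computation where per-point set construction would be slow.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    onsurf = on_surface(x, y, cfg)
    ecc = eccentricity_deg(x, y, cfg)
    cx, cy = cfg.center
    masks = {"entire_screen": onsurf}
    for name, diam in CENTRAL_DIAMETERS_DEG.items():
        masks[name] = onsurf & (ecc <= diam / 2.0)
    masks["left"] = onsurf & (x < cx)
    masks["right"] = onsurf & (x >= cx)
    masks["top"] = onsurf & (y < cy)
    masks["bottom"] = onsurf & (y >= cy)
    return masks
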
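"""Tray rectification and pot extraction.

Workflow for turning a raw top-view tray photograph into per-pot crops:

1. **Landmark detection** — the trays carry five white fiducial discs (one at
   the centre, four at the corners).  Lighting is controlled, so a fixed
   intensity threshold plus connected-component filtering finds them.
2. **Orientation estimation** — trays are never perfectly aligned with the
   sensor axes.  The residual angle is the principal axis of the modulus of
   the 2-D Fourier transform, treated as a mass distribution about the
   spectrum centre (the periodic pot grid concentrates spectral energy along
   its own axes).
3. **Rectification** — rotate by the estimated angle about the central
   landmark, then a projective transform maps the four corner landmarks onto
   the corners of an axis-aligned output rectangle.
4. **Pot extraction** — slide a ``pot_size x pot_size`` window with a stride
   of one pot; the crops tile the grid exactly.

A per-pixel HSV colour filter (keep the green hue band, zero everything
else) optionally removes the soil background before classification.

Conventions: 0-based pixel coordinates, x right / y down, half-open pixel
intervals; angles in degrees, counter-clockwise on screen positive.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from skimage.color import rgb2hsv
from skimage.measure import label as cc_label, regionprops
from skimage.transform import ProjectiveTransform, warp

from .errors import (ConfigurationError, GeometryError, LandmarksNotFound,
                     OrientationUndefined, RoleAssignmentAmbiguous)
from .synthgen import rotate_point

__all__ = [
    "LandmarkSet", "detect_landmarks", "assign_landmark_roles",
    "estimate_tray_orientation", "rectify_tray", "extract_pots",
    "remove_background", "DEFAULT_HUE_BAND",
]

#: Hue band (degrees) treated as "plant green", with minimum saturation and
#: value; brown soil sits near 20 deg and white landmarks have S ~ 0.
DEFAULT_HUE_BAND = (70.0, 160.0)
DEFAULT_MIN_SATURATION = 0.2
DEFAULT_MIN_VALUE = 0.15


@dataclasses.dataclass(frozen=True)
class LandmarkSet:
    """Five fiducial points: centre plus TL/TR/BL/BR corners, (x, y) pixels."""

    central: tuple[float, float]
    corners: dict[str, tuple[float, float]]  # keys TL, TR, BL, BR

    def corner_array(self) -> np.ndarray:
        """Corners stacked in TL, TR, BR, BL order (clockwise)."""
        return np.array([self.corners[k] for k in ("TL", "TR", "BR", "BL")])


def detect_landmarks(image: np.ndarray, intensity_threshold: float = 200.0,
                     min_area_px: int = 10) -> LandmarkSet:
    """Locate the five white landmark discs.

    Binarises the value channel (max over RGB) at ``intensity_threshold``
    (8-bit scale), labels connected components, drops those below
    ``min_area_px``, keeps the five largest and assigns their roles.

    Raises ``LandmarksNotFound`` (carrying the count) when fewer than five
    components survive.
    """
    img = np.asarray(image)
    if img.size == 0:
        raise LandmarksNotFound(0)
    value = img.max(axis=2) if img.ndim == 3 else img
    binary = value >= intensity_threshold
    labels = cc_label(binary, connectivity=2)
    props = [p for p in regionprops(labels) if p.area >= min_area_px]
    if len(props) < 5:
        raise LandmarksNotFound(len(props))
    props.sort(key=lambda p: -p.area)
    pts = [(p.centroid[1], p.centroid[0]) for p in props[:5]]  # (x, y)
    h, w = value.shape
    return assign_landmark_roles(pts, ((w - 1) / 2.0, (h - 1) / 2.0))


def assign_landmark_roles(candidates, image_center) -> LandmarkSet:
    """Name five points as central + TL/TR/BL/BR.

    The point nearest the image centre is the central landmark (ties broken
    by row-major scan order of the centroid); the remaining four take the
    quadrant of their angle about it, which tolerates tray rotations up to
    +/-45 deg.  Two candidates in one quadrant raise
    ``RoleAssignmentAmbiguous``.
    """
    pts = [tuple(map(float, p)) for p in candidates]
    if len(pts) != 5:
        raise ValueError(f"expected exactly 5 candidate points, got {len(pts)}")
    cx, cy = image_center
    d2 = [((x - cx) ** 2 + (y - cy) ** 2, y, x, i) for i, (x, y) in enumerate(pts)]
    central_idx = min(d2)[3]
    central = pts[central_idx]
    roles: dict[str, tuple[float, float]] = {}
    for i, (x, y) in enumerate(pts):
        if i == central_idx:
            continue
        dx, dy = x - central[0], y - central[1]
        # y-down raster: TL is dx<0, dy<0 etc.
        role = ("T" if dy < 0 else "B") + ("L" if dx < 0 else "R")
        if role in roles:
            raise RoleAssignmentAmbiguous(
                f"two corner candidates fall in quadrant {role}")
        roles[role] = (x, y)
    return LandmarkSet(central=central, corners=roles)


def _spectral_axis(region: np.ndarray, quantile: float, power: float,
                   anisotropy_tol: float) -> float:
    """Principal axis (deg, on-screen CCW, period 90) of the FFT modulus."""
    side = min(region.shape)
    # central square crop so both frequency axes share the same units
    y0 = (region.shape[0] - side) // 2
    x0 = (region.shape[1] - side) // 2
    region = region[y0:y0 + side, x0:x0 + side]
    region = region * np.hanning(side)[:, None] * np.hanning(side)[None, :]
    spec = np.abs(np.fft.fftshift(np.fft.fft2(region - region.mean())))
    h, w = spec.shape
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    yy, xx = np.mgrid[0:h, 0:w]
    dx, dy = xx - cx, yy - cy
    rr = np.hypot(dx, dy)
    # mid-frequency annulus: the low-frequency disc holds smooth soil
    # texture, and the inscribed circle keeps the domain rotation-symmetric
    # (the square's corners would otherwise bias the fold towards 45 deg)
    base = spec.copy()
    base[(rr < side / 5.0) | (rr >= side / 2.0)] = 0.0
    # principal axis of a 90-deg-symmetric mass distribution: the plain
    # second-moment tensor is degenerate (the two grid arms cancel), so fold
    # the arms onto one axis via the quadruple-angle resultant
    phi = np.arctan2(-dy, dx)                  # y-down raster -> CCW on screen
    resultant = np.abs((base * np.exp(4j * phi)).sum()) / base.sum()
    if resultant < anisotropy_tol:
        raise OrientationUndefined(
            f"spectral anisotropy {resultant:.4f} below tolerance "
            f"{anisotropy_tol}: spectrum is isotropic")
    # the angle itself comes from the prominent peaks only (sharpened mass)
    thr = np.quantile(base[base > 0], quantile)
    mass = np.where(base >= thr, base ** power, 0.0)
    s = (mass * np.exp(4j * phi)).sum()
    return float(np.degrees(np.angle(s)) / 4.0)


def estimate_tray_orientation(tray_region: np.ndarray,
                              anisotropy_tol: float = 0.05,
                              quantile: float = 0.99,
                              power: float = 4.0,
                              refine: bool = True) -> float:
    """Tray rotation angle from the Fourier spectrum, in (-45, 45] degrees.

    The modulus of the 2-D FFT of the (grayscale) tray region is treated as
    a mass distribution about the spectrum centre: the periodic pot grid
    concentrates energy along the grid axes, and the angle of that principal
    axis — folded by the 90-deg symmetry of the grid — is the tray
    orientation.  Only prominent mid/high-frequency peaks (above the given
    ``quantile``, raised to ``power``) enter the mass so that smooth soil
    texture cannot bias the axis.  With ``refine=True`` a second pass
    re-estimates the residual after unrotating by the first estimate.
    Raises ``OrientationUndefined`` when the folded angular resultant falls
    below ``anisotropy_tol`` (isotropic spectrum).
    """
    region = np.asarray(tray_region, dtype=np.float64)
    if region.ndim == 3:
        region = region.mean(axis=2)
    if min(region.shape) < 64:
        raise ValueError("region too small for a meaningful spectrum (< 64 px)")
    angle = _spectral_axis(region, quantile, power, anisotropy_tol)
    if refine:
        from skimage.transform import rotate as _rot
        back = _rot(region, -angle, resize=False, mode="edge")
        angle += _spectral_axis(back, quantile, power, anisotropy_tol)
    angle = (angle + 45.0) % 90.0 - 45.0       # canonical range (-45, 45]
    if angle == -45.0:
        angle = 45.0
    return float(angle)


def rectify_tray(image: np.ndarray, landmarks: LandmarkSet, angle: float,
                 output_shape: tuple[int, int],
                 margin: int = 0) -> np.ndarray:
    """Rotate by ``-angle`` about the central landmark, then project the four
    corner landmarks onto the corners of an axis-aligned output rectangle.

    ``output_shape`` is (height, width) of the corner rectangle; ``margin``
    pads all sides.  Bilinear interpolation.  Raises ``GeometryError`` for a
    degenerate (collinear) corner quadrilateral.
    """
    corners = landmarks.corner_array()
    # collinearity check: area of the quadrilateral via the shoelace formula
    x, y = corners[:, 0], corners[:, 1]
    area = 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
    if area < 1.0:
        raise GeometryError("corner landmarks are (nearly) collinear")

    # step 1: rotation by -angle about the central landmark moves the corner
    # landmarks; track them rather than resampling twice.
    rotated = np.array([rotate_point(p, landmarks.central, -angle)
                        for p in corners])
    oh, ow = output_shape
    # edge-based mapping: when the corner landmarks already sit on the
    # output rectangle's corners the transform is an exact translation
    dst = np.array([[margin, margin], [margin + ow, margin],
                    [margin + ow, margin + oh], [margin, margin + oh]],
                   dtype=np.float64)
    # compose: output coords -> projective^-1 -> rotated frame -> rotate back
    if hasattr(ProjectiveTransform, "from_estimate"):
        proj = ProjectiveTransform.from_estimate(dst, rotated)
    else:  # older scikit-image
        proj = ProjectiveTransform()
        if not proj.estimate(dst, rotated):
            proj = None
    if not proj:
        raise GeometryError("projective estimation failed")
    th = np.deg2rad(-angle)
    c, s = np.cos(th), np.sin(th)
    cx, cy = landmarks.central

    def inverse_map(coords):
        p = proj(coords)                       # output -> rotated frame
        dx, dy = p[:, 0] - cx, p[:, 1] - cy
        # inverse of the on-screen CCW rotation by -angle
        return np.column_stack([cx + dx * c - dy * s, cy + dx * s + dy * c])

    out = warp(np.asarray(image, dtype=np.float64) / 255.0, inverse_map,
               output_shape=(oh + 2 * margin, ow + 2 * margin, 3)
               if np.asarray(image).ndim == 3 else (oh + 2 * margin, ow + 2 * margin),
               order=1, mode="constant", cval=0.0, preserve_range=True)
    return (np.clip(out, 0.0, 1.0) * 255.0).round().astype(np.uint8)


def extract_pots(rectified: np.ndarray, grid_rows: int, grid_cols: int,
                 pot_size_px: int) -> list[dict]:
    """Tile the rectified tray into row-major pot crops.

    Crop (r, c) covers pixels ``[r*s, r*s+s) x [c*s, c*s+s)``; crops are
    disjoint and cover the grid area exactly.
    """
    img = np.asarray(rectified)
    s = pot_size_px
    if img.shape[0] < grid_rows * s or img.shape[1] < grid_cols * s:
        raise GeometryError(
            f"grid {grid_rows}x{grid_cols} at pot size {s} exceeds image "
            f"{img.shape[:2]}")
    crops = []
    for r in range(grid_rows):
        for c in range(grid_cols):
            crops.append({"row": r, "col": c,
                          "pixels": img[r * s:(r + 1) * s, c * s:(c + 1) * s].copy()})
    return crops


def remove_background(crop: np.ndarray,
                      hue_band: tuple[float, float] = DEFAULT_HUE_BAND,
                      min_saturation: float = DEFAULT_MIN_SATURATION,
                      min_value: float = DEFAULT_MIN_VALUE) -> np.ndarray:
    """Keep plant-green pixels, zero everything else.

    A pixel survives when its hue (degrees, [0, 360)) lies in ``hue_band``
    and saturation/value meet the minima; all other pixels become black.
    Purely per-pixel, hence idempotent.
    """
    lo, hi = hue_band
    if not (0.0 <= lo < hi <= 360.0):
        raise ConfigurationError(f"empty or invalid hue band {hue_band}")
    img = np.asarray(crop)
    hsv = rgb2hsv(img.astype(np.float64) / 255.0)
    hue = hsv[..., 0] * 360.0
    keep = ((hue >= lo) & (hue <= hi)
            & (hsv[..., 1] >= min_saturation) & (hsv[..., 2] >= min_value))
    out = img.copy()
    out[~keep] = 0
    return out
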
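"""Mask geometry: polar radius profiles, mirror asymmetry, calibrated dimensions.

All shape descriptors downstream of segmentation are derived from the binary
fruit mask of a single view.  The central representation is the *polar radius
profile*: the distance from the mask centroid to the outer boundary, sampled
at every integer degree.  Angles follow the mathematical convention -- 0 deg
along +x, counter-clockwise, with the image row axis flipped so that "up" in
the image is +y.

Side-view masks are first rotated about their centroid to minimise the mirror
asymmetry index (fruit are rarely placed perfectly upright); the minimising
angle is reported alongside the profile.  Top-view profiles yield the
centroid-based circumcircle / incircle / mean-radius metrics.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage as ndi
from skimage import measure


class EmptyMaskError(ValueError):
    """Raised when an operation receives a mask with no foreground pixels."""


def _as_bool_mask(mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError(f"mask must be 2-D, got shape {mask.shape}")
    mask = mask.astype(bool)
    if not mask.any():
        raise EmptyMaskError("mask is empty")
    return mask


@dataclass
class PolarProfile:
    """Radius (px) at each integer degree around the mask centroid.

    ``centroid_xy`` is (column, row) in image coordinates.  For side views,
    ``symmetry_angle_deg`` records the rotation (degrees, positive =
    counter-clockwise) that was applied to the mask before profiling to
    minimise the mirror asymmetry index.
    """

    radius_deg: np.ndarray
    centroid_xy: tuple[float, float]
    view: str = "side"
    symmetry_angle_deg: Optional[float] = None

    def __post_init__(self) -> None:
        self.radius_deg = np.asarray(self.radius_deg, dtype=float)
        if self.radius_deg.shape != (360,):
            raise ValueError("radius_deg must have exactly 360 entries")
        if not np.all(np.isfinite(self.radius_deg)) or np.any(self.radius_deg <= 0):
            raise ValueError("all radii must be positive and finite")

    def area(self) -> float:
        """Polygon area enclosed by the profile (px^2)."""
        return profile_area(self.radius_deg)

    def scaled(self, factor: float) -> np.ndarray:
        """Radii multiplied by ``factor`` (e.g. a cm-per-px calibration)."""
        return self.radius_deg * float(factor)


@dataclass
class CircleMetrics:
    """Centroid-based circle descriptors of a top-view profile.

    The circumcircle / incircle are taken about the centroid (the largest and
    smallest boundary radius), not the true minimum enclosing circle; for
    near-circular fruit tops the two notions coincide to sub-pixel level.
    ``radius_std_nor`` is the standard deviation of radii after rescaling the
    mean radius to 1, a unitless roundness measure.
    """

    radius_mean_px: float
    radius_in_px: float
    radius_circ_px: float
    radius_std_nor: float

    def __post_init__(self) -> None:
        if not (self.radius_in_px <= self.radius_mean_px <= self.radius_circ_px):
            raise ValueError("circle metrics must satisfy in <= mean <= circ")


def profile_from_polygon(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Radius at integer degrees for a closed polygon around the origin.

    For each integer degree the crossing radius is obtained by linear
    interpolation (in angle) between adjacent polygon vertices; where the
    boundary crosses a direction more than once (non-star-shaped outline) the
    maximum crossing is kept, so the profile always traces the outer boundary.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ang = np.degrees(np.arctan2(y, x)) % 360.0
    rad = np.hypot(x, y)
    radii = np.full(360, -np.inf)
    n = len(x)
    for i in range(n):
        j = (i + 1) % n
        a0, r0 = ang[i], rad[i]
        r1 = rad[j]
        # wrapped angular step in (-180, 180]
        d = (ang[j] - a0 + 180.0) % 360.0 - 180.0
        if abs(d) < 1e-12:
            k = int(round(a0)) % 360
            if abs(a0 - round(a0)) < 1e-9:
                radii[k] = max(radii[k], r0, r1)
            continue
        lo, hi = (a0, a0 + d) if d > 0 else (a0 + d, a0)
        ks = np.arange(np.ceil(lo - 1e-9), np.floor(hi + 1e-9) + 1.0)
        if ks.size == 0:
            continue
        t = np.clip((ks - a0) / d, 0.0, 1.0)
        r = r0 + t * (r1 - r0)
        idx = np.rint(ks).astype(int) % 360
        np.maximum.at(radii, idx, r)
    missing = ~np.isfinite(radii)
    if missing.any():
        # fall back to the nearest vertex sample (degenerate, tiny polygons)
        for k in np.nonzero(missing)[0]:
            dk = np.abs((ang - k + 180.0) % 360.0 - 180.0)
            radii[k] = rad[np.argmin(dk)]
    return radii


def profile_area(radius_deg: np.ndarray) -> float:
    """Area of the polygon spanned by per-degree radii."""
    r = np.asarray(radius_deg, dtype=float)
    r2 = np.roll(r, -1)
    dtheta = np.deg2rad(1.0)
    return float(0.5 * np.sum(r * r2) * np.sin(dtheta))


def to_polar(mask: np.ndarray, view: str = "side",
             symmetry_angle_deg: Optional[float] = None) -> PolarProfile:
    """Convert a filled mask to its 360-degree polar radius profile.

    The boundary is extracted at sub-pixel resolution (0.5-level contour of
    the binary mask) and interpolated to integer degrees around the centroid.
    """
    mask = _as_bool_mask(mask)
    cy, cx = ndi.center_of_mass(mask)
    contours = measure.find_contours(mask.astype(float), 0.5)
    if not contours:
        raise EmptyMaskError("mask has no boundary contour")
    contour = max(contours, key=len)
    x = contour[:, 1] - cx
    y = cy - contour[:, 0]  # flip rows to mathematical orientation
    radii = profile_from_polygon(x, y)
    if np.any(radii <= 0):
        raise ValueError("centroid lies outside the mask; profile undefined")
    return PolarProfile(radii, (cx, cy), view=view,
                        symmetry_angle_deg=symmetry_angle_deg)


def mirror_mask(mask: np.ndarray) -> np.ndarray:
    """Mirror a mask across the vertical axis through its column centroid.

    Columns are mapped to their nearest-integer mirror position; pixels whose
    mirror falls outside the frame are dropped.
    """
    mask = _as_bool_mask(mask)
    cx = ndi.center_of_mass(mask)[1]
    w = mask.shape[1]
    src = np.rint(2.0 * cx - np.arange(w)).astype(int)
    valid = (src >= 0) & (src < w)
    out = np.zeros_like(mask)
    out[:, valid] = mask[:, src[valid]]
    return out


def asymmetry_index(mask: np.ndarray) -> float:
    """Mirror asymmetry: |mask XOR mirrored mask| / (2 * |mask|).

    0 for a pixel-perfect mirror-symmetric mask, approaching 1 for shapes
    with no overlap with their own mirror image.  The frame is padded first
    so the mirrored mask is never clipped at the image border.
    """
    mask = _as_bool_mask(mask)
    w = mask.shape[1]
    padded = np.pad(mask, ((0, 0), (w, w)))
    mirrored = mirror_mask(padded)
    return float(np.logical_xor(padded, mirrored).sum() / (2.0 * mask.sum()))


def rotate_mask(mask: np.ndarray, angle_deg: float,
                center: Optional[tuple[float, float]] = None) -> np.ndarray:
    """Rotate a binary mask about ``center`` (row, col) by nearest neighbour.

    Positive angles are counter-clockwise in mathematical orientation (image
    y flipped).  Nearest-neighbour resampling keeps the mask binary.
    """
    mask = _as_bool_mask(mask)
    if angle_deg == 0:
        return mask.copy()
    if center is None:
        center = ndi.center_of_mass(mask)
    cy, cx = center
    h, w = mask.shape
    rr, cc = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    dx = cc - cx
    dy = cy - rr  # mathematical y
    t = np.deg2rad(angle_deg)
    cos_t, sin_t = np.cos(t), np.sin(t)
    # inverse rotation: where did each output pixel come from
    xs = cos_t * dx + sin_t * dy
    ys = -sin_t * dx + cos_t * dy
    src_r = np.rint(cy - ys).astype(int)
    src_c = np.rint(cx + xs).astype(int)
    ok = (src_r >= 0) & (src_r < h) & (src_c >= 0) & (src_c < w)
    out = np.zeros_like(mask)
    out[ok] = mask[src_r[ok], src_c[ok]]
    return out


def symmetrize(mask: np.ndarray, max_angle_deg: float = 20.0,
               step_deg: float = 0.25) -> tuple[float, np.ndarray, float]:
    """Find the rotation about the centroid that minimises mirror asymmetry.

    A grid search over ``[-max_angle_deg, +max_angle_deg]`` in ``step_deg``
    increments; ties resolved towards the smallest magnitude, negative before
    positive.  Returns ``(angle_deg, rotated_mask, minimal_asymmetry)``.
    """
    mask = _as_bool_mask(mask)
    rows = np.any(mask, axis=1).nonzero()[0]
    cols = np.any(mask, axis=0).nonzero()[0]
    half_diag = 0.5 * float(np.hypot(rows[-1] - rows[0] + 1, cols[-1] - cols[0] + 1))
    pad = int(np.ceil(2.0 * np.sin(np.deg2rad(max_angle_deg) / 2.0) * half_diag)) + 2
    r0, r1 = max(0, rows[0] - pad), min(mask.shape[0], rows[-1] + pad + 1)
    c0, c1 = max(0, cols[0] - pad), min(mask.shape[1], cols[-1] + pad + 1)
    crop = mask[r0:r1, c0:c1]
    center = ndi.center_of_mass(crop)

    n = int(round(max_angle_deg / step_deg))
    angles = np.arange(-n, n + 1) * step_deg
    values = np.empty_like(angles)
    # inlined rotate + mirror + XOR with precomputed grids (the rotation is
    # about the centroid, which nearest-neighbour resampling preserves to
    # sub-pixel level, so the mirror axis is recomputed per rotated mask)
    ch, cw = crop.shape
    rr, cc = np.meshgrid(np.arange(ch), np.arange(cw), indexing="ij")
    dx = cc - center[1]
    dy = center[0] - rr
    cols = np.arange(cw)
    for i, a in enumerate(angles):
        if a == 0:
            rot = crop
        else:
            t = np.deg2rad(a)
            xs = np.cos(t) * dx + np.sin(t) * dy
            ys = -np.sin(t) * dx + np.cos(t) * dy
            src_r = np.rint(center[0] - ys).astype(np.intp)
            src_c = np.rint(center[1] + xs).astype(np.intp)
            ok = (src_r >= 0) & (src_r < ch) & (src_c >= 0) & (src_c < cw)
            rot = np.zeros_like(crop)
            rot[ok] = crop[src_r[ok], src_c[ok]]
        # XOR area = 2*(area - overlap); mirrored pixels falling outside the
        # crop cannot overlap the mask, so in-frame overlap is exact
        area = rot.sum()
        cx = (rot.sum(axis=0) @ cols) / area
        src = np.rint(2.0 * cx - cols).astype(np.intp)
        valid = (src >= 0) & (src < cw)
        overlap = np.logical_and(rot[:, valid], rot[:, src[valid]]).sum()
        values[i] = 1.0 - overlap / area
    best = values.min()
    candidates = angles[values == best]
    angle = min(candidates, key=lambda a: (abs(a), a > 0))
    rotated = rotate_mask(mask, float(angle))
    return float(angle), rotated, float(best)


def dimensions(mask: np.ndarray, cm_per_px: float) -> tuple[float, float]:
    """Calibrated (width_cm, height_cm) from the mask's pixel extents.

    The extent counts occupied pixels inclusively (max - min + 1), so a disk
    of radius r px spans 2r + 1 px.
    """
    mask = _as_bool_mask(mask)
    if cm_per_px <= 0:
        raise ValueError("cm_per_px must be positive")
    rows = np.any(mask, axis=1).nonzero()[0]
    cols = np.any(mask, axis=0).nonzero()[0]
    width = (cols[-1] - cols[0] + 1) * cm_per_px
    height = (rows[-1] - rows[0] + 1) * cm_per_px
    return float(width), float(height)


def top_circles(profile: PolarProfile | np.ndarray) -> CircleMetrics:
    """Circumcircle, incircle, mean radius and normalised radial SD.

    All quantities are taken about the centroid of the top-view contour:
    circumcircle = largest boundary radius, incircle = smallest.  The radial
    SD is computed on radii scaled to mean 1 (sample SD, n-1 denominator).
    """
    r = profile.radius_deg if isinstance(profile, PolarProfile) else np.asarray(profile, float)
    mean = float(np.mean(r))
    std_nor = float(np.std(r / mean, ddof=1)) if r.size > 1 else 0.0
    return CircleMetrics(
        radius_mean_px=mean,
        radius_in_px=float(np.min(r)),
        radius_circ_px=float(np.max(r)),
        radius_std_nor=std_nor,
    )


def contour_xy(profile: PolarProfile) -> np.ndarray:
    """Cartesian boundary coordinates (x, y) in px, centroid at the origin."""
    theta = np.deg2rad(np.arange(360))
    return np.column_stack([profile.radius_deg * np.cos(theta),
                            profile.radius_deg * np.sin(theta)])
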
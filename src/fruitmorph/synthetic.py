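"""Synthetic five-view fruit renderer with known ground truth.

Renders the image set an imaging chamber would produce for one fruit -- four
side views and one top view at 1296 x 1080 px, 16 bit/channel RGB -- from a
parametric description (:class:`FruitSpec`): 360-degree polar radius
profiles for the side and top outlines (cm), a peel color mixture in HSV, a
weight and an asymmetry shear.  The renderer returns per-view ground-truth
masks, so every downstream stage (segmentation, shape, color, records) can
be validated without real images.

The background is a uniform neutral gray (S = 0.05, V = 0.9), chosen so the
HSV threshold mask excludes it with a wide margin in both conditions.  Side
view k is sheared horizontally by ``asymmetry_skew * k/4``, producing a
known, monotonically controllable asymmetry.  Rendering is done in floating
point and quantised to 16 bit at the end.

A separate trait-level simulator (:func:`simulate_records`) generates
per-fruit record tables (weight, width, height, shape index, asymmetry) for
cultivar-scale statistical studies where rendering thousands of full-frame
images would be pointless.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, timedelta
from pathlib import Path

import numpy as np
import pandas as pd
from skimage import color as skcolor

from . import io as fio

__all__ = [
    "FruitSpec",
    "RenderedSample",
    "render_fruit",
    "write_sample",
    "write_backgrounds",
    "background_image",
    "ellipse_profile",
    "constant_profile",
    "random_fruit_spec",
    "simulate_records",
    "read_spec_file",
    "write_spec_file",
    "FRAME_SHAPE",
]

#: Sensor frame (rows, cols) of each camera.
FRAME_SHAPE = (1080, 1296)

#: Background panel color in HSV: bright, nearly unsaturated gray.
BACKGROUND_HSV = (0.0, 0.05, 0.9)


@dataclass
class FruitSpec:
    """Ground-truth description of one synthetic fruit.

    Radius profiles are in cm at integer degrees (0 deg = +x, counter-
    clockwise); ``peel_hue_mixture`` is a list of ``(hue, saturation, value,
    weight)`` components with weights summing to 1; ``asymmetry_skew`` is a
    dimensionless horizontal shear applied per side view.
    """

    side_radius_profile: np.ndarray
    top_radius_profile: np.ndarray
    peel_hue_mixture: list[tuple[float, float, float, float]]
    weight_g: float
    asymmetry_skew: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.side_radius_profile = np.asarray(self.side_radius_profile, float)
        self.top_radius_profile = np.asarray(self.top_radius_profile, float)
        for name, prof in (("side", self.side_radius_profile),
                           ("top", self.top_radius_profile)):
            if prof.shape != (360,):
                raise ValueError(f"{name} profile must have 360 radii")
            if np.any(prof <= 0) or not np.all(np.isfinite(prof)):
                raise ValueError(f"{name} profile radii must be positive and finite")
        w = sum(c[3] for c in self.peel_hue_mixture)
        if abs(w - 1.0) > 1e-9:
            raise ValueError(f"hue mixture weights sum to {w}, expected 1")
        for h, s, v, wt in self.peel_hue_mixture:
            if not (0 <= h < 1 and 0 < s <= 1 and 0 < v <= 1 and wt >= 0):
                raise ValueError("hue mixture component out of range")
        if self.weight_g <= 0:
            raise ValueError("weight must be positive")
        if self.asymmetry_skew < 0:
            raise ValueError("asymmetry_skew must be >= 0")


@dataclass
class RenderedSample:
    """Five rendered views, empty-chamber references and ground truth."""

    images: dict[int, np.ndarray]        # camera -> uint16 RGB
    backgrounds: dict[int, np.ndarray]   # camera -> uint16 RGB
    truth_masks: dict[int, np.ndarray]   # camera -> bool
    spec: FruitSpec
    calibration: dict[int, float]        # camera -> cm per px


def _as_calibration(calibration) -> dict[int, float]:
    if np.isscalar(calibration):
        calibration = {cam: float(calibration) for cam in range(1, 6)}
    calibration = {int(k): float(v) for k, v in calibration.items()}
    if sorted(calibration) != [1, 2, 3, 4, 5]:
        raise ValueError("calibration must cover cameras 1-5")
    if any(v <= 0 for v in calibration.values()):
        raise ValueError("calibration must be positive")
    return calibration


def background_image(frame_shape: tuple[int, int] = FRAME_SHAPE) -> np.ndarray:
    """The uniform empty-chamber reference frame, 16-bit RGB."""
    rgb = skcolor.hsv2rgb(np.array(BACKGROUND_HSV)[None, None, :])[0, 0]
    img = np.empty(frame_shape + (3,), dtype=np.uint16)
    img[...] = np.round(rgb * 65535.0).astype(np.uint16)
    return img


def _view_mask(radii_px: np.ndarray, shear: float,
               frame_shape: tuple[int, int]) -> np.ndarray:
    """Rasterise a sheared star-shaped outline centred in the frame.

    A pixel belongs to the fruit iff its centre, mapped back through the
    shear, lies within the outline radius at its polar angle (linear
    interpolation between the integer-degree radii).
    """
    theta = np.deg2rad(np.arange(360))
    vx = radii_px * np.cos(theta) + shear * radii_px * np.sin(theta)
    vy = radii_px * np.sin(theta)
    cy = (frame_shape[0] - 1) / 2.0
    cx = (frame_shape[1] - 1) / 2.0
    if (cy - vy.max() < 1 or cy - vy.min() > frame_shape[0] - 2
            or cx + vx.min() < 1 or cx + vx.max() > frame_shape[1] - 2):
        raise ValueError("fruit larger than the camera frame at this calibration")
    r0 = int(np.floor(cy - vy.max())); r1 = int(np.ceil(cy - vy.min())) + 1
    c0 = int(np.floor(cx + vx.min())); c1 = int(np.ceil(cx + vx.max())) + 1
    rr, cc = np.meshgrid(np.arange(r0, r1), np.arange(c0, c1), indexing="ij")
    y = cy - rr
    x = (cc - cx) - shear * y  # invert the shear
    ang = np.degrees(np.arctan2(y, x)) % 360.0
    rlim = np.interp(ang, np.arange(361), np.append(radii_px, radii_px[0]))
    mask = np.zeros(frame_shape, dtype=bool)
    mask[r0:r1, c0:c1] = np.hypot(x, y) <= rlim
    return mask


def render_fruit(spec: FruitSpec, calibration,
                 frame_shape: tuple[int, int] = FRAME_SHAPE) -> RenderedSample:
    """Render the five views of one fruit with ground-truth masks.

    Cameras 1-4 render the side profile (camera k sheared by
    ``asymmetry_skew * k/4``); camera 5 renders the top profile unsheared.
    Peel pixels draw their HSV color independently from the mixture with the
    spec's seed, so renders are bit-reproducible.
    """
    calibration = _as_calibration(calibration)
    rng = np.random.default_rng(spec.rng_seed)
    mix = np.array([c[:3] for c in spec.peel_hue_mixture])
    weights = np.array([c[3] for c in spec.peel_hue_mixture])
    weights = weights / weights.sum()

    images, backgrounds, masks = {}, {}, {}
    for cam in range(1, 6):
        profile = spec.top_radius_profile if cam == 5 else spec.side_radius_profile
        shear = 0.0 if cam == 5 else spec.asymmetry_skew * cam / 4.0
        radii_px = profile / calibration[cam]
        mask = _view_mask(radii_px, shear, frame_shape)
        n_px = int(mask.sum())

        comp = rng.choice(len(mix), size=n_px, p=weights)
        hsv = mix[comp][None, :, :]
        peel = np.round(skcolor.hsv2rgb(hsv)[0] * 65535.0).astype(np.uint16)
        img = background_image(frame_shape)
        img[mask] = peel
        images[cam] = img
        backgrounds[cam] = background_image(frame_shape)
        masks[cam] = mask
    return RenderedSample(images=images, backgrounds=backgrounds,
                          truth_masks=masks, spec=spec,
                          calibration=calibration)


def write_sample(sample: RenderedSample, root, sample_id: str, index: int,
                 timestamp: datetime) -> list[Path]:
    """Write the five views to the acquisition directory layout.

    Files go to ``images/<ID>/cam<N>/`` with the standard filename dialect,
    16-bit packbits-compressed TIFF, the fruit weight embedded in the image
    description metadata.  Existing files are never overwritten.
    """
    root = Path(root)
    paths = []
    for cam in range(1, 6):
        directory = root / "images" / sample_id / f"cam{cam}"
        directory.mkdir(parents=True, exist_ok=True)
        name = fio.format_name(sample_id, cam, index, timestamp)
        path = directory / name
        if path.exists():
            raise FileExistsError(f"refusing to overwrite {path}")
        fio.write_tiff(path, sample.images[cam], weight_g=sample.spec.weight_g)
        paths.append(path)
    return paths


def write_backgrounds(sample: RenderedSample, root) -> list[Path]:
    """Write the per-camera empty-chamber references to ``background/``."""
    root = Path(root)
    out = []
    directory = root / "background"
    directory.mkdir(parents=True, exist_ok=True)
    for cam in range(1, 6):
        path = directory / f"cam{cam}.tif"
        if not path.exists():
            fio.write_tiff(path, sample.backgrounds[cam])
        out.append(path)
    return out


# ---------------------------------------------------------------------------
# profile and spec helpers
# ---------------------------------------------------------------------------

def constant_profile(radius_cm: float) -> np.ndarray:
    return np.full(360, float(radius_cm))


def ellipse_profile(a_cm: float, b_cm: float) -> np.ndarray:
    """Polar radius profile of an axis-aligned ellipse (semi-axes a, b in cm)."""
    theta = np.deg2rad(np.arange(360))
    return a_cm * b_cm / np.sqrt((b_cm * np.cos(theta)) ** 2
                                 + (a_cm * np.sin(theta)) ** 2)


#: Hue anchors for common apple peel colors (fraction of the color circle).
PEEL_HUES = {"red": 0.0, "orange": 0.06, "yellow": 0.13, "green": 0.26}


def random_fruit_spec(rng: np.random.Generator, base_radius_cm: float = 3.0,
                      irregularity: float = 0.03, asymmetry_skew: float = 0.0,
                      weight_g: float | None = None) -> FruitSpec:
    """A plausible random fruit: smooth star-shaped outline, apple-like peel.

    The outline perturbs a circle with low-order harmonics (amplitude
    ``irregularity``); the peel mixes two or three of the red / orange /
    yellow / green hue anchors with random proportions.
    """
    theta = np.deg2rad(np.arange(360))
    side = np.ones(360)
    top = np.ones(360)
    for k in (2, 3, 4):
        side += irregularity / k * rng.standard_normal() * np.cos(k * theta) \
            + irregularity / k * rng.standard_normal() * np.sin(k * theta)
        top += 0.5 * irregularity / k * rng.standard_normal() * np.cos(k * theta)
    side_r = base_radius_cm * side
    top_r = base_radius_cm * top
    n_colors = rng.integers(2, 4)
    hues = rng.choice(list(PEEL_HUES.values()), size=n_colors, replace=False)
    w = rng.dirichlet(np.ones(n_colors))
    mixture = [(float(h), float(rng.uniform(0.55, 0.95)),
                float(rng.uniform(0.45, 0.85)), float(wi))
               for h, wi in zip(hues, w)]
    if weight_g is None:
        # sphere-volume heuristic with apple-like density ~0.8 g/cm^3
        weight_g = 0.8 * 4.0 / 3.0 * np.pi * base_radius_cm ** 3
    return FruitSpec(side_r, top_r, mixture, weight_g=float(weight_g),
                     asymmetry_skew=asymmetry_skew,
                     rng_seed=int(rng.integers(2 ** 31)))


# ---------------------------------------------------------------------------
# spec files (key = value text, for CLI-driven generation)
# ---------------------------------------------------------------------------

def write_spec_file(spec: FruitSpec, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("side_radius_profile = " + " ".join(f"{r:.9g}" for r in spec.side_radius_profile) + "\n")
        fh.write("top_radius_profile = " + " ".join(f"{r:.9g}" for r in spec.top_radius_profile) + "\n")
        for i, (h, s, v, w) in enumerate(spec.peel_hue_mixture):
            fh.write(f"peel_color_{i} = {h:.9g} {s:.9g} {v:.9g} {w:.9g}\n")
        fh.write(f"weight_g = {spec.weight_g:.9g}\n")
        fh.write(f"asymmetry_skew = {spec.asymmetry_skew:.9g}\n")
        fh.write(f"rng_seed = {spec.rng_seed}\n")


def read_spec_file(path) -> FruitSpec:
    values: dict[str, str] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, val = line.partition("=")
            values[key.strip()] = val.strip()
    mixture = []
    for i in range(64):
        key = f"peel_color_{i}"
        if key not in values:
            break
        mixture.append(tuple(float(x) for x in values[key].split()))
    return FruitSpec(
        side_radius_profile=np.array([float(x) for x in values["side_radius_profile"].split()]),
        top_radius_profile=np.array([float(x) for x in values["top_radius_profile"].split()]),
        peel_hue_mixture=mixture,
        weight_g=float(values["weight_g"]),
        asymmetry_skew=float(values.get("asymmetry_skew", "0")),
        rng_seed=int(values.get("rng_seed", "0")),
    )


# ---------------------------------------------------------------------------
# trait-level study simulator
# ---------------------------------------------------------------------------

def simulate_records(n_cultivars: int = 15, n_fruit: int = 100, seed: int = 0,
                     mean_weight_g: np.ndarray | None = None,
                     weight_cv: float = 0.16,
                     mean_width_cm: np.ndarray | None = None,
                     width_cv: float = 0.056,
                     height_cv: float = 0.066) -> pd.DataFrame:
    """Simulate per-fruit trait records for a multi-cultivar study.

    Trait values are drawn per fruit from normal distributions with
    cultivar-specific means.  Default coefficients of variation are realistic
    for dessert apples: weight varies far more than the linear dimensions
    (~16% vs ~6%) because weight tracks volume, which scales cubically with
    the linear size.  Default cultivar means are evenly spaced over typical
    apple ranges (120-260 g, 6.5-8.5 cm width), giving well-separated
    cultivars.

    Returns a DataFrame with one row per fruit: cultivar, sample_id,
    fruit_index, weight_g, width_mean_cm, height_mean_cm, shape_index,
    asymmetry.
    """
    rng = np.random.default_rng(seed)
    if mean_weight_g is None:
        mean_weight_g = np.linspace(120.0, 260.0, n_cultivars)
    if mean_width_cm is None:
        mean_width_cm = np.linspace(6.5, 8.5, n_cultivars)
    mean_weight_g = np.asarray(mean_weight_g, float)
    mean_width_cm = np.asarray(mean_width_cm, float)
    shape_idx = np.linspace(0.85, 1.1, n_cultivars)
    rows = []
    for c in range(n_cultivars):
        cultivar = f"CV{c + 1:02d}"
        weight = rng.normal(mean_weight_g[c], weight_cv * mean_weight_g[c], n_fruit)
        width = rng.normal(mean_width_cm[c], width_cv * mean_width_cm[c], n_fruit)
        height = rng.normal(shape_idx[c] * mean_width_cm[c],
                            height_cv * shape_idx[c] * mean_width_cm[c], n_fruit)
        asym = np.clip(rng.normal(0.019, 0.004, n_fruit), 1e-4, 1.0)
        for i in range(n_fruit):
            rows.append({
                "cultivar": cultivar,
                "sample_id": f"T{c + 1:03d}",
                "fruit_index": i + 1,
                "weight_g": max(weight[i], 1.0),
                "width_mean_cm": max(width[i], 0.1),
                "height_mean_cm": max(height[i], 0.1),
                "asymmetry": asym[i],
            })
    df = pd.DataFrame(rows)
    df["shape_index"] = df["height_mean_cm"] / df["width_mean_cm"]
    return df
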
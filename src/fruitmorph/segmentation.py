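"""Fruit/background segmentation for single camera views.

Two independent cues are combined:

* ``m1`` -- an HSV threshold: a pixel belongs to the fruit iff the
  saturation-to-value ratio exceeds 0.2 *and* saturation exceeds 0.19.  The
  imaging chamber background is a bright low-saturation panel, which fails
  both conditions.
* ``m2`` -- background differencing: the per-camera empty-chamber reference
  is subtracted from the image and the difference magnitude is thresholded
  with Otsu's method.

The final fruit mask is the post-processed set union of the two: largest
8-connected component, holes filled.  Both component masks are retained for
auditing.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage import color as skcolor
from skimage import filters, measure

__all__ = [
    "SegmentationResult",
    "NoFruitError",
    "hsv_mask",
    "background_diff_mask",
    "segment_fruit",
    "normalize_image",
]

#: HSV thresholds for mask m1 (strict inequalities).
SV_RATIO_THRESHOLD = 0.2
SATURATION_THRESHOLD = 0.19


class NoFruitError(RuntimeError):
    """Raised when the union of both masks contains no pixels."""


@dataclass
class SegmentationResult:
    """Binary fruit mask plus its two component masks and provenance."""

    mask: np.ndarray
    m1: np.ndarray
    m2: np.ndarray
    source_image_id: str = ""
    warnings: list[str] = field(default_factory=list)

    @property
    def area_px(self) -> int:
        return int(self.mask.sum())


def normalize_image(image: np.ndarray) -> np.ndarray:
    """Return a float RGB image scaled to [0, 1].

    Accepts uint8, uint16 or float input (floats assumed already in [0, 1]).
    """
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected an RGB image, got shape {image.shape}")
    if image.dtype == np.uint8:
        return image.astype(np.float64) / 255.0
    if image.dtype == np.uint16:
        return image.astype(np.float64) / 65535.0
    out = image.astype(np.float64)
    if out.max() > 1.0 + 1e-9:
        raise ValueError("float images must be scaled to [0, 1]")
    return out


def hsv_mask(image: np.ndarray) -> np.ndarray:
    """HSV-threshold component m1: S/V > 0.2 AND S > 0.19.

    Pixels with V = 0 (pure black) have an undefined ratio and are False.
    """
    rgb = normalize_image(image)
    hsv = skcolor.rgb2hsv(rgb)
    s, v = hsv[..., 1], hsv[..., 2]
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(v > 0, s / np.where(v > 0, v, 1.0), 0.0)
    return (ratio > SV_RATIO_THRESHOLD) & (s > SATURATION_THRESHOLD)


def difference_magnitude(image: np.ndarray, background: np.ndarray,
                         method: str = "max") -> np.ndarray:
    """Per-pixel magnitude of the image-background difference.

    ``max`` (default) takes the maximum absolute difference over channels,
    which is robust when the fruit matches the background in one channel;
    ``luminance`` and ``norm`` are provided as alternatives.
    """
    img = normalize_image(image)
    bg = normalize_image(background)
    if img.shape != bg.shape:
        raise ValueError(f"image {img.shape} and background {bg.shape} differ in shape")
    diff = np.abs(img - bg)
    if method == "max":
        return diff.max(axis=2)
    if method == "norm":
        return np.sqrt((diff ** 2).sum(axis=2))
    if method == "luminance":
        return np.abs(skcolor.rgb2gray(img) - skcolor.rgb2gray(bg))
    raise ValueError(f"unknown difference method {method!r}")


def background_diff_mask(image: np.ndarray, background: np.ndarray,
                         method: str = "max", nbins: int = 256) -> np.ndarray:
    """Background-difference component m2: Otsu threshold on the difference.

    The threshold maximises the between-class variance of a 256-bin histogram
    over the observed difference range (ties resolved to the lowest
    threshold).  Identical image and background yield an empty mask with a
    warning, not an error.
    """
    d = difference_magnitude(image, background, method=method)
    if d.max() == d.min():
        warnings.warn("image and background are identical; m2 is empty",
                      stacklevel=2)
        return np.zeros(d.shape, dtype=bool)
    threshold = filters.threshold_otsu(d, nbins=nbins)
    return d > threshold


def _postprocess(union: np.ndarray) -> np.ndarray:
    labels = measure.label(union, connectivity=2)
    largest = np.argmax(np.bincount(labels.ravel())[1:]) + 1
    return ndi.binary_fill_holes(labels == largest)


def segment_fruit(image: np.ndarray, background: np.ndarray,
                  image_id: str = "", method: str = "max",
                  postprocess: bool = True) -> SegmentationResult:
    """Full single-view segmentation: union of m1 and m2, post-processed.

    Post-processing keeps the largest 8-connected component of the union and
    fills its holes; it can be disabled for debugging.  Raises
    :class:`NoFruitError` (naming the image) when the union is empty.
    """
    notes: list[str] = []
    m1 = hsv_mask(image)
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        m2 = background_diff_mask(image, background, method=method)
    notes.extend(str(w.message) for w in caught)
    union = m1 | m2
    if not union.any():
        raise NoFruitError(f"no fruit detected in image {image_id or '<unnamed>'}")
    mask = _postprocess(union) if postprocess else union.copy()
    return SegmentationResult(mask=mask, m1=m1, m2=m2,
                              source_image_id=image_id, warnings=notes)
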
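"""Peel color description: hue and saturation density histograms.

Pixels from the four segmented side views of one fruit are pooled and
converted to HSV.  Hue is normalised so [0, 1] spans 0-360 degrees; the
histogram covers the full circle but reporting and plotting conventionally
restrict to [0, 0.5] (yellow, red and green -- the informative range for
apple peel; cyan-to-magenta hues do not occur).  Densities integrate to 1
over their support.

Pixels with zero saturation have undefined hue and are excluded from the hue
histogram (they still contribute to the saturation histogram).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import color as skcolor

from .segmentation import normalize_image

__all__ = ["ColorHistogram", "fruit_histogram", "cultivar_histogram",
           "DEFAULT_N_BINS"]

#: Default number of histogram bins over the hue / saturation range.
DEFAULT_N_BINS = 64


@dataclass
class ColorHistogram:
    """Marginal hue and saturation density histograms of one fruit."""

    hue_bin_edges: np.ndarray   # n_bins + 1 edges over [0, 1)
    hue_density: np.ndarray     # n_bins densities, integrates to 1
    sat_bin_edges: np.ndarray
    sat_density: np.ndarray
    n_pixels: int

    @property
    def n_bins(self) -> int:
        return len(self.hue_density)

    def hue_bin_mass(self) -> np.ndarray:
        """Per-bin probability mass (density times bin width)."""
        return self.hue_density * np.diff(self.hue_bin_edges)

    def header(self) -> list[str]:
        """Flat column names for text export (Table-style colhist header)."""
        return [f"hue_{i:02d}" for i in range(self.n_bins)] + \
               [f"sat_{i:02d}" for i in range(self.n_bins)]

    def values(self) -> np.ndarray:
        return np.concatenate([self.hue_density, self.sat_density])


def fruit_histogram(images, masks, n_bins: int = DEFAULT_N_BINS) -> ColorHistogram:
    """Pool masked pixels across the side views and histogram hue/saturation.

    ``images`` and ``masks`` are paired sequences (typically the four side
    views); shapes must match pairwise.  Raises when all masks are empty.
    """
    if len(images) != len(masks):
        raise ValueError("images and masks must be paired")
    hues, sats = [], []
    n_pixels = 0
    for img, mask in zip(images, masks):
        mask = np.asarray(mask, dtype=bool)
        rgb = normalize_image(img)
        if mask.shape != rgb.shape[:2]:
            raise ValueError("image and mask shapes differ")
        if not mask.any():
            continue
        hsv = skcolor.rgb2hsv(rgb[mask][None, :, :])[0]
        h, s = hsv[:, 0], hsv[:, 1]
        hues.append(h[s > 0])  # hue undefined at zero saturation
        sats.append(s)
        n_pixels += int(mask.sum())
    if n_pixels == 0:
        raise ValueError("all masks are empty; no fruit pixels to histogram")
    hue = np.concatenate(hues) if hues else np.empty(0)
    sat = np.concatenate(sats)
    hue_density, hue_edges = np.histogram(hue, bins=n_bins, range=(0.0, 1.0),
                                          density=True)
    sat_density, sat_edges = np.histogram(sat, bins=n_bins, range=(0.0, 1.0),
                                          density=True)
    return ColorHistogram(hue_edges, hue_density, sat_edges, sat_density,
                          n_pixels=n_pixels)


def cultivar_histogram(histograms: list[ColorHistogram]) -> tuple[ColorHistogram, ColorHistogram]:
    """Per-bin mean and sample SD of fruit histograms, as two histograms.

    Returns ``(mean, sd)``; all inputs must share identical binning.  The
    mean histogram still integrates to 1 (the mean of densities is a
    density); the SD object reuses the histogram container for its per-bin
    spread and does not integrate to 1.
    """
    if not histograms:
        raise ValueError("need at least one histogram")
    ref = histograms[0]
    for h in histograms[1:]:
        if not (np.array_equal(h.hue_bin_edges, ref.hue_bin_edges)
                and np.array_equal(h.sat_bin_edges, ref.sat_bin_edges)):
            raise ValueError("histograms have mismatched binning")
    hue = np.stack([h.hue_density for h in histograms])
    sat = np.stack([h.sat_density for h in histograms])
    n = len(histograms)
    ddof = 1 if n > 1 else 0
    mean = ColorHistogram(ref.hue_bin_edges, hue.mean(axis=0),
                          ref.sat_bin_edges, sat.mean(axis=0),
                          n_pixels=sum(h.n_pixels for h in histograms))
    sd = ColorHistogram(ref.hue_bin_edges,
                        hue.std(axis=0, ddof=ddof) if n > 1 else np.zeros_like(ref.hue_density),
                        ref.sat_bin_edges,
                        sat.std(axis=0, ddof=ddof) if n > 1 else np.zeros_like(ref.sat_density),
                        n_pixels=mean.n_pixels)
    return mean, sd
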
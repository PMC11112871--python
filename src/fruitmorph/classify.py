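"""Shape classification against a reference-outline library, shape averaging
and k-means shape clustering.

A fruit's side (or top) outline is summarised by its 360-degree polar radius
profile.  Classification assigns the profile to the reference outline with
the highest Pearson correlation between the two 360-vectors (profiles are
rotation-registered by the symmetry correction beforehand, so zero angular
lag is used by default; a max-over-lags mode exists for unregistered input).

The shipped default library is a parametric superellipse/ovoid family of 13
outlines named after standard pomological shape descriptors.  It is a
synthetic stand-in for digitised manual reference outlines and is fully
replaceable via :func:`load_reference_library`.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .geometry import PolarProfile, profile_from_polygon

__all__ = [
    "ReferenceShape",
    "ReferenceShapeLibrary",
    "ShapeClassification",
    "AverageShape",
    "default_side_library",
    "default_top_library",
    "load_reference_library",
    "save_reference_library",
    "classify",
    "average_shape",
    "cluster_shapes",
]


@dataclass
class ReferenceShape:
    class_id: int
    name: str
    radius_profile: np.ndarray  # 360 radii, mean 1

    def __post_init__(self) -> None:
        self.radius_profile = np.asarray(self.radius_profile, dtype=float)
        if self.radius_profile.shape != (360,):
            raise ValueError(f"reference {self.name!r}: need 360 radii")
        if np.any(self.radius_profile <= 0):
            raise ValueError(f"reference {self.name!r}: radii must be positive")
        self.radius_profile = self.radius_profile / self.radius_profile.mean()


@dataclass
class ReferenceShapeLibrary:
    entries: list[ReferenceShape]
    view: str = "side"

    def __post_init__(self) -> None:
        ids = [e.class_id for e in self.entries]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate class_id in reference library")

    def __len__(self) -> int:
        return len(self.entries)

    def matrix(self) -> np.ndarray:
        return np.stack([e.radius_profile for e in self.entries])

    def names(self) -> list[str]:
        return [e.name for e in self.entries]


@dataclass
class ShapeClassification:
    shape_class: int
    corr: float
    per_class_corr: np.ndarray
    class_name: str = ""


@dataclass
class AverageShape:
    """Per-degree mean and SD of a set of radius profiles (sample SD)."""

    mean_radius_deg: np.ndarray
    sd_radius_deg: np.ndarray
    n_fruit: int


# ---------------------------------------------------------------------------
# default reference library
# ---------------------------------------------------------------------------

def _outline_profile(a: float, b: float, q_bot: float = 2.0,
                     q_top: float | None = None, taper: float = 0.0,
                     waist: float = 0.0, n: int = 1440) -> np.ndarray:
    """Mean-1 polar profile of a parametric fruit outline.

    The outline has half-width ``a * (1 - |u|^q)^(1/q)`` at normalised height
    ``u`` in [-1, 1] (superellipse exponent ``q``, separately for the bottom
    and top half), multiplied by a linear taper ``(1 - taper*u)`` (positive
    taper narrows the top, as in conical fruit) and a mid-height waist factor
    ``(1 - waist*(1 - u^2))``.  The profile is taken about the area centroid.
    """
    if q_top is None:
        q_top = q_bot
    u = np.linspace(-1.0, 1.0, n)
    q = np.where(u >= 0, q_top, q_bot)
    base = np.power(np.clip(1.0 - np.abs(u) ** q, 0.0, None), 1.0 / q)
    w = a * base * (1.0 - taper * u) * (1.0 - waist * (1.0 - u * u))
    y_half = b * u
    # closed polygon: right side bottom->top, left side top->bottom
    x = np.concatenate([w, -w[::-1][1:-1]])
    y = np.concatenate([y_half, y_half[::-1][1:-1]])
    # area centroid (shoelace); cx = 0 by symmetry
    x2, y2 = np.roll(x, -1), np.roll(y, -1)
    cross = x * y2 - x2 * y
    area = 0.5 * cross.sum()
    cy = np.sum((y + y2) * cross) / (6.0 * area)
    radii = profile_from_polygon(x, y - cy)
    return radii / radii.mean()


# (name, a, b, q_bot, q_top, taper, waist) -- chosen so the 13 classes are
# mutually distinguishable under Pearson correlation of their profiles.
_SIDE_SHAPES: list[tuple[str, float, float, float, float, float, float]] = [
    # "spherical" uses a slightly superelliptic outline: a perfect circle has a
    # constant radius profile with zero variance, which Pearson correlation
    # cannot match; real spherical fruit deviate from a circle anyway.
    ("spherical",            1.00, 1.00, 2.35, 2.35, 0.00, 0.00),
    ("flattened spherical",  1.00, 0.70, 2.0, 2.0, 0.00, 0.00),
    ("ellipsoid",            0.70, 1.00, 2.0, 2.0, 0.00, 0.00),
    ("ovoid",                0.90, 1.00, 2.0, 2.0, 0.30, 0.00),
    ("obovoid",              0.90, 1.00, 2.0, 2.0, -0.30, 0.00),
    ("conical",              1.00, 0.95, 2.2, 1.5, 0.55, 0.00),
    ("truncate conical",     1.00, 0.90, 3.5, 5.0, 0.50, 0.00),
    ("rectangular",          0.85, 1.00, 4.5, 4.5, 0.00, 0.00),
    ("rectangular conical",  0.90, 0.95, 4.0, 4.0, 0.30, 0.00),
    ("cylindrical",          0.62, 1.10, 6.0, 6.0, 0.00, 0.00),
    ("cylindrical waisted",  0.75, 1.05, 5.0, 5.0, 0.00, 0.30),
    ("oblong",               1.10, 0.68, 4.0, 4.0, 0.00, 0.00),
    ("turbinate",            0.95, 0.95, 1.5, 2.5, 0.70, 0.00),
]


def default_side_library() -> ReferenceShapeLibrary:
    """The built-in 13-class side-view reference library."""
    entries = [
        ReferenceShape(i + 1, name,
                       _outline_profile(a, b, qb, qt, taper, waist))
        for i, (name, a, b, qb, qt, taper, waist) in enumerate(_SIDE_SHAPES)
    ]
    return ReferenceShapeLibrary(entries, view="side")


def default_top_library() -> ReferenceShapeLibrary:
    """A minimal 3-class top-view library (circular and ribbed outlines)."""
    # the three classes differ in harmonic content (not just amplitude, to
    # which mean-normalised Pearson correlation is blind): near-circular with
    # faint ellipticity, sinusoidal ribbing, and sharper ribbing with a
    # second-harmonic component
    theta = np.deg2rad(np.arange(360))
    circ = 1.0 + 0.005 * np.cos(2 * theta)
    weak = 1.0 + 0.02 * np.cos(5 * theta)
    strong = 1.0 + 0.06 * np.cos(5 * theta) + 0.04 * np.cos(10 * theta)
    entries = [
        ReferenceShape(1, "circular", circ),
        ReferenceShape(2, "weakly ribbed", weak),
        ReferenceShape(3, "strongly ribbed", strong),
    ]
    return ReferenceShapeLibrary(entries, view="top")


# ---------------------------------------------------------------------------
# library file I/O
# ---------------------------------------------------------------------------

def save_reference_library(library: ReferenceShapeLibrary, path) -> None:
    """Write a library as delimited text: class_id, name, 360 radii."""
    with open(path, "w", encoding="utf-8") as fh:
        cols = " ".join(f"r{i}" for i in range(360))
        fh.write(f"class_id name {cols}\n")
        for e in library.entries:
            radii = " ".join(f"{r:.9g}" for r in e.radius_profile)
            fh.write(f"{e.class_id} {e.name.replace(' ', '_')} {radii}\n")


def load_reference_library(path=None, view: str = "side") -> ReferenceShapeLibrary:
    """Load a reference library from text, or the built-in default.

    Expected format: a header line, then one row per class with class_id,
    name (underscores for spaces) and 360 positive radii, whitespace- or
    comma-delimited.  Radii are renormalised to mean 1 on load.
    """
    if path is None:
        return default_side_library() if view == "side" else default_top_library()
    entries: list[ReferenceShape] = []
    seen: set[int] = set()
    with open(path, "r", encoding="utf-8") as fh:
        for row_no, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or row_no == 1:
                continue
            parts = line.replace(",", " ").split()
            if len(parts) != 362:
                raise ValueError(
                    f"{path}: row {row_no}: expected 362 columns "
                    f"(class_id, name, 360 radii), got {len(parts)}")
            class_id = int(parts[0])
            if class_id in seen:
                raise ValueError(f"{path}: row {row_no}: duplicate class_id {class_id}")
            seen.add(class_id)
            radii = np.array([float(p) for p in parts[2:]])
            if np.any(radii <= 0):
                raise ValueError(f"{path}: row {row_no}: non-positive radius")
            entries.append(ReferenceShape(class_id, parts[1].replace("_", " "), radii))
    return ReferenceShapeLibrary(entries, view=view)


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    sx, sy = x.std(), y.std()
    if sx < 1e-12 or sy < 1e-12:
        warnings.warn("zero-variance profile in correlation; using equality rule",
                      stacklevel=3)
        return 1.0 if np.allclose(x, y, atol=1e-9) else 0.0
    return float(np.corrcoef(x, y)[0, 1])


def classify(profile: PolarProfile | np.ndarray,
             library: ReferenceShapeLibrary,
             max_over_lags: bool = False) -> ShapeClassification:
    """Assign a profile to the best-correlated reference outline.

    The candidate is normalised to mean radius 1 (classification is therefore
    scale-free) and correlated with each reference at zero angular lag; ties
    resolve to the lowest class id.  With ``max_over_lags=True`` each
    reference correlation is maximised over all 360 cyclic shifts.
    """
    r = profile.radius_deg if isinstance(profile, PolarProfile) else np.asarray(profile, float)
    if r.shape != (360,):
        raise ValueError("profile must have 360 radii")
    if len(library) == 0:
        raise ValueError("reference library is empty")
    cand = r / r.mean()
    corrs = np.empty(len(library))
    for i, entry in enumerate(library.entries):
        if max_over_lags:
            corrs[i] = max(_pearson(np.roll(cand, lag), entry.radius_profile)
                           for lag in range(360))
        else:
            corrs[i] = _pearson(cand, entry.radius_profile)
    best = int(np.argmax(corrs))  # argmax returns the first (lowest id) on ties
    entry = library.entries[best]
    return ShapeClassification(shape_class=entry.class_id,
                               corr=float(corrs[best]),
                               per_class_corr=corrs,
                               class_name=entry.name)


def average_shape(profiles: list[np.ndarray] | np.ndarray,
                  view: str | None = None) -> AverageShape:
    """Per-degree mean and sample SD over a set of radius profiles.

    Accepts raw 360-vectors (typically already calibrated to cm) or
    :class:`PolarProfile` objects, which must then share a view.
    """
    arrays = []
    views = set()
    for p in profiles:
        if isinstance(p, PolarProfile):
            views.add(p.view)
            arrays.append(p.radius_deg)
        else:
            arrays.append(np.asarray(p, dtype=float))
    if view is not None:
        views.add(view)
    if len(views) > 1:
        raise ValueError(f"profiles mix views: {sorted(views)}")
    if not arrays:
        raise ValueError("need at least one profile")
    stack = np.stack(arrays)
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1) if len(arrays) > 1 else np.zeros(360)
    return AverageShape(mean, sd, n_fruit=len(arrays))


def cluster_shapes(profiles: np.ndarray, k: int = 6, seed: int = 0,
                   n_init: int = 10, cultivars=None):
    """k-means clustering of mean-1-normalised 360-dim shape profiles.

    Returns ``(labels, centroids, counts)`` where ``counts`` is a cultivar x
    cluster contingency table (None when no cultivar labels are given).
    ``k`` between 3 and 8 spans the useful granularity for fruit outlines;
    the default of 6 gives a readable cross-tabulation.
    """
    from sklearn.cluster import KMeans

    profiles = np.asarray(profiles, dtype=float)
    if profiles.ndim != 2 or profiles.shape[1] != 360:
        raise ValueError("profiles must be an (n, 360) array")
    n = profiles.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds number of profiles ({n})")
    norm = profiles / profiles.mean(axis=1, keepdims=True)
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    labels = km.fit_predict(norm)
    counts = None
    if cultivars is not None:
        import pandas as pd
        counts = pd.crosstab(pd.Series(list(cultivars), name="cultivar"),
                             pd.Series(labels, name="cluster"))
    return labels, km.cluster_centers_, counts
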
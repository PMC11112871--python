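"""Per-fruit records, cultivar summaries and between-cultivar statistics.

A :class:`FruitRecord` gathers everything the pipeline measures for one
fruit across its five views: shape class and correlation, weight, top-view
circle metrics, calibrated per-view widths/heights and their means, the
symmetry-corrected asymmetry, and the peel color histograms.  The shape
index is height/width (a unitless elongation measure, > 1 for fruit taller
than wide).

Cultivar-level functions compute descriptive trait summaries, one-way ANOVA
with Tukey HSD post-hoc letters, and delegate average shapes / mean color
histograms to the shape and color modules.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .classify import (ReferenceShapeLibrary, classify as classify_profile,
                       default_side_library, default_top_library)
from . import color as col
from . import geometry as geo
from .segmentation import SegmentationResult

__all__ = [
    "FruitRecord",
    "build_fruit_record",
    "records_to_frame",
    "summarize_cultivar",
    "significance_groups",
    "compact_letters",
    "TRAITS",
]

#: Trait name -> record column used in summaries and ANOVA.
TRAITS = {
    "height": "height_mean_cm",
    "width": "width_mean_cm",
    "weight": "weight_g",
    "shape_index": "shape_index",
    "asymmetry": "asymmetry",
}

SIDE_CAMERAS = (1, 2, 3, 4)
TOP_CAMERA = 5


@dataclass
class FruitRecord:
    """The per-fruit output row of the feature-extraction pipeline."""

    sample_id: str
    fruit_index: int
    shape_class: int
    corr_side: float
    shape_class_top: int
    weight_g: Optional[float]
    radius_mean_pix: float
    radius_in_pix: float
    radius_circ_pix: float
    radius_std_nor: float
    width_cm: list[float]          # four per-view values, cameras 1-4
    height_cm: list[float]
    symmetry_angle_deg: list[float]
    asymmetry: float               # mean of the four per-view minima
    colhist: col.ColorHistogram
    per_class_corr: np.ndarray = field(default_factory=lambda: np.empty(0))
    side_profile_cm: np.ndarray = field(default_factory=lambda: np.empty(0))
    top_profile_px: np.ndarray = field(default_factory=lambda: np.empty(0))
    weight_flag: str = ""

    @property
    def width_mean_cm(self) -> float:
        return float(np.mean(self.width_cm))

    @property
    def height_mean_cm(self) -> float:
        return float(np.mean(self.height_cm))

    @property
    def shape_index(self) -> float:
        return self.height_mean_cm / self.width_mean_cm

    def to_series(self) -> pd.Series:
        data = {
            "sample_id": self.sample_id,
            "fruit_index": self.fruit_index,
            "ShapeClass": self.shape_class,
            "Corr_side": self.corr_side,
            "ShapeClass_top": self.shape_class_top,
            "weight_g": np.nan if self.weight_g is None else self.weight_g,
            "radius_mean_pix": self.radius_mean_pix,
            "radius_in_pix": self.radius_in_pix,
            "radius_circ_pix": self.radius_circ_pix,
            "radius_std_nor_pix": self.radius_std_nor,
        }
        for cam, w in zip(SIDE_CAMERAS, self.width_cm):
            data[f"width_cm_cam{cam}"] = w
        data["width_mean_cm"] = self.width_mean_cm
        for cam, h in zip(SIDE_CAMERAS, self.height_cm):
            data[f"height_cm_cam{cam}"] = h
        data["height_mean_cm"] = self.height_mean_cm
        data["asymmetry"] = self.asymmetry
        for cam, a in zip(SIDE_CAMERAS, self.symmetry_angle_deg):
            data[f"symmetry_angle_deg_cam{cam}"] = a
        data["shape_index"] = self.shape_index
        for name, value in zip(self.colhist.header(), self.colhist.values()):
            data[name] = value
        return pd.Series(data)


def build_fruit_record(sample_id: str, fruit_index: int,
                       segmentations: dict[int, SegmentationResult],
                       images: dict[int, np.ndarray],
                       calibration: dict[int, float],
                       weight_g: Optional[float],
                       side_library: Optional[ReferenceShapeLibrary] = None,
                       top_library: Optional[ReferenceShapeLibrary] = None,
                       max_angle_deg: float = 20.0,
                       step_deg: float = 0.25) -> FruitRecord:
    """Assemble the full per-fruit record from its five segmented views.

    Side views are symmetry-corrected before measuring; the side shape class
    is computed on the per-fruit average of the four calibrated side
    profiles (averaging suppresses single-view noise), with per-view
    correlations available through ``per_class_corr``.  The per-fruit
    asymmetry is the mean of the four per-view minimal asymmetry values.
    """
    missing = sorted({*SIDE_CAMERAS, TOP_CAMERA} - set(segmentations))
    if missing:
        raise ValueError(f"{sample_id} fruit {fruit_index}: missing view(s) "
                         f"cam {','.join(map(str, missing))}")
    side_library = side_library or default_side_library()
    top_library = top_library or default_top_library()

    widths, heights, angles, asyms, side_profiles_cm = [], [], [], [], []
    for cam in SIDE_CAMERAS:
        seg = segmentations[cam]
        angle, rotated, min_asym = geo.symmetrize(
            seg.mask, max_angle_deg=max_angle_deg, step_deg=step_deg)
        w, h = geo.dimensions(rotated, calibration[cam])
        profile = geo.to_polar(rotated, view="side", symmetry_angle_deg=angle)
        widths.append(w)
        heights.append(h)
        angles.append(angle)
        asyms.append(min_asym)
        side_profiles_cm.append(profile.scaled(calibration[cam]))

    avg_side = np.mean(np.stack(side_profiles_cm), axis=0)
    side_cls = classify_profile(avg_side, side_library)

    top_profile = geo.to_polar(segmentations[TOP_CAMERA].mask, view="top")
    circles = geo.top_circles(top_profile)
    top_cls = classify_profile(top_profile, top_library)

    histogram = col.fruit_histogram(
        [images[cam] for cam in SIDE_CAMERAS],
        [segmentations[cam].mask for cam in SIDE_CAMERAS])

    return FruitRecord(
        sample_id=sample_id,
        fruit_index=fruit_index,
        shape_class=side_cls.shape_class,
        corr_side=side_cls.corr,
        shape_class_top=top_cls.shape_class,
        weight_g=weight_g,
        radius_mean_pix=circles.radius_mean_px,
        radius_in_pix=circles.radius_in_px,
        radius_circ_pix=circles.radius_circ_px,
        radius_std_nor=circles.radius_std_nor,
        width_cm=widths,
        height_cm=heights,
        symmetry_angle_deg=angles,
        asymmetry=float(np.mean(asyms)),
        colhist=histogram,
        per_class_corr=side_cls.per_class_corr,
        side_profile_cm=avg_side,
        top_profile_px=top_profile.radius_deg,
        weight_flag="missing" if weight_g is None else "",
    )


def records_to_frame(records: Sequence[FruitRecord],
                     cultivars: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Stack records into the flat per-fruit feature table."""
    df = pd.DataFrame([r.to_series() for r in records])
    if cultivars is not None:
        df.insert(0, "cultivar", list(cultivars))
    return df


# ---------------------------------------------------------------------------
# cultivar summaries
# ---------------------------------------------------------------------------

def summarize_cultivar(df: pd.DataFrame,
                       traits: dict[str, str] = TRAITS) -> pd.DataFrame:
    """Descriptive statistics per trait for one cultivar's records.

    Returns one row per trait: n, mean, median, sd, min, max.  With a single
    record the SD is reported as 0 and the n = 1 condition is left visible
    in the n column.
    """
    rows = []
    for trait, column in traits.items():
        if column not in df.columns:
            continue
        values = df[column].dropna().to_numpy(dtype=float)
        if values.size == 0:
            continue
        rows.append({
            "trait": trait,
            "n": int(values.size),
            "mean": float(values.mean()),
            "median": float(np.median(values)),
            "sd": float(values.std(ddof=1)) if values.size > 1 else 0.0,
            "min": float(values.min()),
            "max": float(values.max()),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# ANOVA + Tukey compact letter display
# ---------------------------------------------------------------------------

def compact_letters(groups: Sequence[str],
                    significant_pairs: set[tuple[str, str]]) -> dict[str, str]:
    """Compact letter display by the insert-and-absorb algorithm.

    Two groups share a letter iff their pair is not in ``significant_pairs``.
    Letters are assigned in the sort order of the groups.
    """
    groups = sorted(set(groups))
    sig = {tuple(sorted(p)) for p in significant_pairs}
    columns: list[set[str]] = [set(groups)]
    for a, b in sorted(sig):
        for colset in [c for c in columns if a in c and b in c]:
            columns.remove(colset)
            columns.append(colset - {a})
            columns.append(colset - {b})
        # absorb: drop columns contained in another column
        columns = [c for c in columns
                   if c and not any(c < d for d in columns)]
        # deduplicate
        unique: list[set[str]] = []
        for c in columns:
            if c not in unique:
                unique.append(c)
        columns = unique
    columns.sort(key=lambda c: [groups.index(g) for g in sorted(c, key=groups.index)])
    letters = {g: "" for g in groups}
    for i, colset in enumerate(columns):
        letter = chr(ord("a") + i) if i < 26 else f"z{i - 25}"
        for g in sorted(colset):
            letters[g] += letter
    return letters


def significance_groups(df: pd.DataFrame, trait_column: str,
                        group_column: str = "cultivar",
                        alpha: float = 0.05):
    """One-way ANOVA across groups plus Tukey HSD significance letters.

    Returns ``(letters, f_stat, p_value, tukey_frame)`` where ``letters``
    maps each group to its compact letter display and ``tukey_frame`` holds
    the pairwise comparisons (group1, group2, meandiff, p-adj, reject).
    Requires at least two groups with at least two records each.
    """
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    data = df[[group_column, trait_column]].dropna()
    counts = data.groupby(group_column).size()
    if len(counts) < 2:
        raise ValueError("need at least two groups for ANOVA")
    small = counts[counts < 2]
    if not small.empty:
        raise ValueError(f"groups with fewer than two records: {list(small.index)}")
    samples = [g[trait_column].to_numpy(dtype=float)
               for _, g in data.groupby(group_column)]
    f_stat, p_value = stats.f_oneway(*samples)

    tukey = pairwise_tukeyhsd(data[trait_column].to_numpy(dtype=float),
                              data[group_column].to_numpy(), alpha=alpha)
    tukey_frame = pd.DataFrame(tukey.summary().data[1:],
                               columns=tukey.summary().data[0])
    sig_pairs = {
        (str(row["group1"]), str(row["group2"]))
        for _, row in tukey_frame.iterrows() if bool(row["reject"])
    }
    letters = compact_letters(data[group_column].unique(), sig_pairs)
    return letters, float(f_stat), float(p_value), tukey_frame


def format_p(p: float) -> str:
    """Report very small ANOVA p-values the way statistics software prints
    them (below double precision resolution: '< 2e-16')."""
    return "< 2e-16" if p < 2e-16 else f"{p:.3g}"
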
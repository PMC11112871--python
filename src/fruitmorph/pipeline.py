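"""End-to-end feature extraction over an acquisition directory.

``run_extract`` walks the acquisition layout, segments every complete fruit
(four side views + one top view), builds the per-fruit record, groups fruit
by cultivar via the field plan, and writes the per-cultivar feature tables
and plain-text exports (average shape in polar and Cartesian coordinates,
raw color histograms, reference-shape correlations, weight and caliber).
Per-fruit failures are logged and skipped; re-running on unchanged inputs
reproduces the outputs byte for byte.
"""
from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .classify import (ReferenceShapeLibrary, average_shape,
                       default_side_library, default_top_library)
from . import color as col
from . import io as fio
from . import records as rec
from . import segmentation as seg

__all__ = ["run_extract", "export_cultivar", "FLOAT_FORMAT"]

log = logging.getLogger("fruitmorph")

#: All text exports use 6 significant digits.
FLOAT_FORMAT = "%.6g"


def _load_backgrounds(root: Path) -> dict[int, np.ndarray]:
    backgrounds = {}
    for cam in range(1, 6):
        path = root / "background" / f"cam{cam}.tif"
        if not path.exists():
            raise FileNotFoundError(
                f"missing empty-chamber reference {path}; expected one per camera")
        backgrounds[cam], _ = fio.read_tiff(path)
    return backgrounds


def run_extract(root, calibration: dict[int, float],
                field_plan: Optional[pd.DataFrame] = None,
                out: Optional[Path] = None,
                side_library: Optional[ReferenceShapeLibrary] = None,
                top_library: Optional[ReferenceShapeLibrary] = None,
                max_angle_deg: float = 20.0, step_deg: float = 0.25):
    """Run the full pipeline over every complete fruit under ``root``.

    Returns ``(table, failures, anomalies)``: the per-fruit feature table
    (with a ``cultivar`` column mapped from the field plan, or the sample id
    when no plan is given), a list of per-fruit failure messages, and the
    acquisition-scan anomalies.  When ``out`` is given, per-cultivar tables
    and exports are written there.
    """
    root = Path(root)
    complete, anomalies = fio.scan_acquisitions(root)
    for a in anomalies:
        log.warning("scan: %s", a)
    backgrounds = _load_backgrounds(root)
    side_library = side_library or default_side_library()
    top_library = top_library or default_top_library()
    id_to_cultivar = {}
    if field_plan is not None:
        id_to_cultivar = dict(zip(field_plan["tree_id"].astype(str),
                                  field_plan["cultivar"].astype(str)))

    records: list[rec.FruitRecord] = []
    cultivars: list[str] = []
    failures: list[str] = []
    for (sample_id, fruit_index), cams in complete.items():
        try:
            images, segmentations = {}, {}
            weight = None
            for cam, item in cams.items():
                image, w, _meta = fio.read_image_with_weight(item.path)
                images[cam] = image
                if w is not None and weight is None:
                    weight = w
                segmentations[cam] = seg.segment_fruit(
                    image, backgrounds[cam], image_id=item.path.name)
            record = rec.build_fruit_record(
                sample_id, fruit_index, segmentations, images, calibration,
                weight, side_library=side_library, top_library=top_library,
                max_angle_deg=max_angle_deg, step_deg=step_deg)
            records.append(record)
            cultivars.append(id_to_cultivar.get(sample_id, sample_id))
            log.info("extracted %s fruit %d", sample_id, fruit_index)
        except Exception as exc:  # per-fruit failures are logged, not fatal
            failures.append(f"{sample_id} fruit {fruit_index}: {exc}")
            log.error("failed %s fruit %d: %s", sample_id, fruit_index, exc)

    table = rec.records_to_frame(records, cultivars) if records else pd.DataFrame()
    if out is not None and records:
        out = Path(out)
        out.mkdir(parents=True, exist_ok=True)
        for cultivar, group in table.groupby("cultivar", sort=True):
            idx = group.index
            export_cultivar(
                str(cultivar), group,
                [records[i] for i in idx], out, side_library)
    return table, failures, anomalies


def export_cultivar(cultivar: str, table: pd.DataFrame,
                    records: list[rec.FruitRecord], out: Path,
                    side_library: Optional[ReferenceShapeLibrary] = None) -> list[Path]:
    """Write one cultivar's feature table and companion text exports."""
    out = Path(out)
    side_library = side_library or default_side_library()
    written = []

    def _write(df: pd.DataFrame, name: str) -> None:
        path = out / f"{cultivar}_{name}.tsv"
        df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)
        written.append(path)

    _write(table.drop(columns=["cultivar"], errors="ignore"), "records")

    avg = average_shape([r.side_profile_cm for r in records])
    theta = np.deg2rad(np.arange(360))
    _write(pd.DataFrame({
        "degree": np.arange(360),
        "radius_mean_cm": avg.mean_radius_deg,
        "radius_sd_cm": avg.sd_radius_deg,
    }), "avg_shape_polar")
    _write(pd.DataFrame({
        "x_cm": avg.mean_radius_deg * np.cos(theta),
        "y_cm": avg.mean_radius_deg * np.sin(theta),
    }), "avg_shape_cartesian")

    hist_rows = pd.DataFrame(
        [r.colhist.values() for r in records],
        columns=records[0].colhist.header())
    hist_rows.insert(0, "fruit_index", [r.fruit_index for r in records])
    _write(hist_rows, "colhist")

    corr = pd.DataFrame(
        [r.per_class_corr for r in records],
        columns=[f"corr_{e.class_id}_{e.name.replace(' ', '_')}"
                 for e in side_library.entries])
    corr.insert(0, "fruit_index", [r.fruit_index for r in records])
    _write(corr, "shape_correlations")

    _write(pd.DataFrame({
        "fruit_index": [r.fruit_index for r in records],
        "weight_g": [np.nan if r.weight_g is None else r.weight_g for r in records],
        "caliber_cm": [r.width_mean_cm for r in records],
    }), "weight_caliber")
    return written
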
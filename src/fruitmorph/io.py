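"""Acquisition-directory dialect, TIFF I/O with weight metadata, field plan
and calibration files.

The acquisition layout mirrors what the imaging chamber software writes::

    <root>/images/<ID>/cam<N>/<ID>_cam<N>_<index>_<YYYYMMDD>_<HHMMSS>.tif
    <root>/background/cam<N>.tif          (empty-chamber references)

``<ID>`` is the barcode / tree identifier, cameras 1-4 are side views and 5
the top view, and the index is a per-fruit running number (zero-padded to 4
digits).  The fruit weight in grams travels in the TIFF image-description
tag as ``weight_g=<decimal>``; a tab-separated ``manifest.tsv`` (columns
``filename``, ``weight_g``) can serve as fallback.  The filename pattern is
regex-configurable for datasets using a different dialect.
"""
from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "AcquisitionItem",
    "format_name",
    "parse_name",
    "write_tiff",
    "read_tiff",
    "read_image_with_weight",
    "scan_acquisitions",
    "read_field_plan",
    "write_field_plan",
    "read_calibration",
    "write_calibration",
    "read_config",
    "DEFAULT_FILENAME_RE",
]

log = logging.getLogger("fruitmorph")

DEFAULT_FILENAME_RE = re.compile(
    r"^(?P<id>.+)_cam(?P<cam>[1-5])_(?P<index>\d+)_"
    r"(?P<date>\d{8})_(?P<time>\d{6})\.tiff?$", re.IGNORECASE)


@dataclass
class AcquisitionItem:
    """One parsed image file of the acquisition layout."""

    path: Path
    sample_id: str
    camera: int
    fruit_index: int
    timestamp: datetime


def format_name(sample_id: str, camera: int, index: int,
                timestamp: datetime) -> str:
    """Canonical image filename: ID_camN_index_date_time.tif."""
    return (f"{sample_id}_cam{camera}_{index:04d}_"
            f"{timestamp:%Y%m%d}_{timestamp:%H%M%S}.tif")


def parse_name(name: str, pattern: re.Pattern = DEFAULT_FILENAME_RE):
    """Parse a filename into its fields, or None if it does not match."""
    m = pattern.match(name)
    if not m:
        return None
    ts = datetime.strptime(m.group("date") + m.group("time"), "%Y%m%d%H%M%S")
    return {
        "sample_id": m.group("id"),
        "camera": int(m.group("cam")),
        "fruit_index": int(m.group("index")),
        "timestamp": ts,
    }


# ---------------------------------------------------------------------------
# TIFF with weight metadata
# ---------------------------------------------------------------------------

def write_tiff(path, image: np.ndarray, weight_g: float | None = None) -> None:
    """Write a lossless packbits-compressed RGB TIFF.

    When given, the fruit weight is embedded in the image-description tag as
    ``weight_g=<decimal>`` (full repr precision, so read-back is exact).
    """
    description = f"weight_g={weight_g!r}" if weight_g is not None else ""
    tifffile.imwrite(path, image, compression="packbits",
                     photometric="rgb", description=description)


def read_tiff(path) -> tuple[np.ndarray, str]:
    """Read a TIFF and its image-description string."""
    try:
        with tifffile.TiffFile(path) as tif:
            page = tif.pages[0]
            image = page.asarray()
            description = page.tags.get("ImageDescription")
            text = description.value if description is not None else ""
    except (tifffile.TiffFileError, OSError) as exc:
        raise OSError(f"cannot read TIFF {path}: {exc}") from exc
    return image, text


_WEIGHT_RE = re.compile(r"weight_g\s*=\s*([0-9.eE+-]+)")


def _load_manifest(path: Path) -> dict[str, float]:
    manifest = path.parent / "manifest.tsv"
    for candidate in (manifest, *[p / "manifest.tsv" for p in path.parents[1:3]]):
        if candidate.exists():
            df = pd.read_csv(candidate, sep="\t")
            return dict(zip(df["filename"].astype(str), df["weight_g"].astype(float)))
    return {}


def read_image_with_weight(path) -> tuple[np.ndarray, float | None, dict]:
    """Read an image and its fruit weight.

    Weight precedence: image-description metadata, then a ``manifest.tsv``
    sidecar next to the file (or up to two directories above).  If both are
    present and disagree, metadata wins and a warning is logged.  A missing
    weight is returned as None and flagged in the metadata dict.
    """
    path = Path(path)
    image, description = read_tiff(path)
    meta: dict = {"path": str(path), "weight_source": None}
    m = _WEIGHT_RE.search(description or "")
    weight = float(m.group(1)) if m else None
    if weight is not None:
        meta["weight_source"] = "metadata"
    manifest = _load_manifest(path)
    if path.name in manifest:
        manifest_weight = manifest[path.name]
        if weight is None:
            weight = manifest_weight
            meta["weight_source"] = "manifest"
        elif abs(manifest_weight - weight) > 1e-9:
            log.warning("%s: metadata weight %.6g disagrees with manifest %.6g; "
                        "using metadata", path.name, weight, manifest_weight)
    if weight is None:
        meta["weight_missing"] = True
    parsed = parse_name(path.name)
    if parsed:
        meta.update(parsed)
    return image, weight, meta


# ---------------------------------------------------------------------------
# acquisition scanning
# ---------------------------------------------------------------------------

def scan_acquisitions(root, pattern: re.Pattern = DEFAULT_FILENAME_RE):
    """Group acquisition images into complete fruit.

    Returns ``(complete, anomalies)`` where ``complete`` maps
    ``(sample_id, fruit_index)`` to a dict ``camera -> AcquisitionItem`` with
    all five cameras present, and ``anomalies`` is a list of human-readable
    problems: unparseable filenames, duplicate (ID, camera, index) and
    incomplete fruit.
    """
    root = Path(root)
    if not root.exists():
        raise FileNotFoundError(f"acquisition root {root} does not exist")
    images_dir = root / "images" if (root / "images").exists() else root
    groups: dict[tuple[str, int], dict[int, AcquisitionItem]] = {}
    anomalies: list[str] = []
    for path in sorted(images_dir.rglob("*.tif")) + sorted(images_dir.rglob("*.tiff")):
        parsed = parse_name(path.name, pattern)
        if parsed is None:
            anomalies.append(f"unparseable filename: {path}")
            continue
        item = AcquisitionItem(path=path, **parsed)
        key = (item.sample_id, item.fruit_index)
        cams = groups.setdefault(key, {})
        if item.camera in cams:
            anomalies.append(
                f"duplicate image for {key[0]} fruit {key[1]} cam{item.camera}: {path}")
            continue
        cams[item.camera] = item
    complete = {}
    for key in sorted(groups):
        cams = groups[key]
        missing = sorted(set(range(1, 6)) - set(cams))
        if missing:
            anomalies.append(
                f"incomplete fruit {key[0]} #{key[1]}: missing cam "
                + ",".join(map(str, missing)))
        else:
            complete[key] = cams
    return complete, anomalies


# ---------------------------------------------------------------------------
# field plan / calibration / config
# ---------------------------------------------------------------------------

def read_field_plan(path) -> pd.DataFrame:
    """Field plan TSV with header tree_id, cultivar, row, position."""
    df = pd.read_csv(path, sep="\t", dtype={"tree_id": str, "cultivar": str})
    required = {"tree_id", "cultivar", "row", "position"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"field plan {path} missing columns: {sorted(missing)}")
    if df["tree_id"].duplicated().any():
        dupes = df.loc[df["tree_id"].duplicated(), "tree_id"].tolist()
        raise ValueError(f"field plan {path}: duplicate tree_id {dupes}")
    return df


def write_field_plan(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_calibration(path) -> dict[int, float]:
    """Calibration file: one ``cam<N> = <cm_per_px>`` line per camera."""
    values = read_config(path)
    calibration = {}
    for cam in range(1, 6):
        key = f"cam{cam}"
        if key not in values:
            raise ValueError(f"calibration {path} missing {key}")
        v = float(values[key])
        if v <= 0:
            raise ValueError(f"calibration {path}: {key} must be positive")
        calibration[cam] = v
    return calibration


def write_calibration(calibration: dict[int, float], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for cam in range(1, 6):
            fh.write(f"cam{cam} = {calibration[cam]!r}\n")


def read_config(path) -> dict[str, str]:
    """Parse a simple ``key = value`` text file (``#`` comments allowed)."""
    values: dict[str, str] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, sep, val = line.partition("=")
            if not sep:
                raise ValueError(f"{path}: malformed config line {line!r}")
            values[key.strip()] = val.strip()
    return values
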
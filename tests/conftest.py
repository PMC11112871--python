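"""Shared fixtures: random blob masks and rendered synthetic fruit."""
from __future__ import annotations

import numpy as np
import pytest
from scipy import ndimage as ndi

import fruitmorph as fm


def random_blob(rng: np.random.Generator, size: int = 64,
                sigma: float = 6.0) -> np.ndarray:
    """A random single-component filled blob mask (for oracle tests)."""
    field = ndi.gaussian_filter(rng.standard_normal((size, size)), sigma)
    mask = field > np.quantile(field, 0.7)
    labels, n = ndi.label(mask)
    if n == 0:
        return random_blob(rng, size, sigma)
    largest = np.argmax(np.bincount(labels.ravel())[1:]) + 1
    return ndi.binary_fill_holes(labels == largest)


def disk_mask(size: int, radius: float, center=None) -> np.ndarray:
    if center is None:
        center = ((size - 1) / 2.0, (size - 1) / 2.0)
    rr, cc = np.meshgrid(np.arange(size), np.arange(size), indexing="ij")
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius ** 2


def edge_band(mask: np.ndarray, width: int = 1) -> np.ndarray:
    """Pixels within ``width`` px of the mask boundary (excluded from IoU)."""
    boundary = mask ^ ndi.binary_erosion(mask)
    return ndi.binary_dilation(boundary, iterations=width,
                               structure=np.ones((3, 3), bool))


def iou_excluding_edge(mask: np.ndarray, truth: np.ndarray) -> float:
    keep = ~edge_band(truth)
    union = ((mask | truth) & keep).sum()
    return ((mask & truth & keep).sum() / union) if union else 1.0


@pytest.fixture(scope="session")
def two_tone_fruit() -> fm.RenderedSample:
    """A full-frame rendered ellipsoidal fruit with a red/yellow peel."""
    spec = fm.FruitSpec(
        side_radius_profile=fm.ellipse_profile(3.5, 2.8),
        top_radius_profile=fm.constant_profile(3.0),
        peel_hue_mixture=[(0.0, 0.9, 0.8, 0.7), (0.13, 0.8, 0.7, 0.3)],
        weight_g=182.4, asymmetry_skew=0.0, rng_seed=7)
    return fm.render_fruit(spec, 0.01)


@pytest.fixture(scope="session")
def small_study(tmp_path_factory) -> dict:
    """A small rendered acquisition on disk: 2 cultivars x 2 fruit.

    Fruit are kept small (~1.5 cm radius at 0.01 cm/px) so the full
    pipeline, including the rotation search, stays fast.
    """
    from datetime import datetime, timedelta
    import pandas as pd
    from fruitmorph import io as fio

    root = tmp_path_factory.mktemp("study")
    rng = np.random.default_rng(11)
    calibration = {cam: 0.01 for cam in range(1, 6)}
    plan = []
    specs: dict[tuple[str, int], fm.FruitSpec] = {}
    base = datetime(2021, 9, 1, 9, 0, 0)
    for c, cultivar in enumerate(["CVA", "CVB"]):
        sample_id = f"T{c + 1:03d}"
        plan.append({"tree_id": sample_id, "cultivar": cultivar,
                     "row": 1, "position": c + 1})
        for i in range(2):
            spec = fm.random_fruit_spec(
                rng, base_radius_cm=1.5, irregularity=0.02,
                asymmetry_skew=0.02,
                weight_g=float(rng.normal(150 + 40 * c, 5)))
            sample = fm.render_fruit(spec, calibration)
            fm.write_sample(sample, root, sample_id, i + 1,
                            base + timedelta(minutes=2 * c + i))
            fm.write_backgrounds(sample, root)
            specs[(sample_id, i + 1)] = spec
    fio.write_field_plan(pd.DataFrame(plan), root / "field_plan.tsv")
    fio.write_calibration(calibration, root / "calibration.txt")
    return {"root": root, "calibration": calibration, "specs": specs}
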
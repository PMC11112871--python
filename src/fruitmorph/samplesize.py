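"""Sample-size determination by resampled relative margins of error.

How many fruit must be measured to describe a cultivar's mean trait value
with a given confidence?  The procedure: for each candidate sample size n,
repeatedly (default 200 times) draw a random subset of n fruit *without
replacement* from the cultivar's full record set, compute the subset mean,
and take the 2.5% and 97.5% quantiles of those subset means.  Half the
quantile range, divided by the full-sample mean, is the *relative margin of
error* -- the radius of the empirical 95% confidence interval expressed as a
fraction of the mean.

Running this over a grid of sample sizes (default 5..50) per trait and
cultivar yields margin-of-error curves from which a minimal n for a target
margin can be read off.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = ["MOEResult", "margin_of_error", "moe_curve", "recommend_n",
           "DEFAULT_N_GRID", "DEFAULT_REPS"]

DEFAULT_N_GRID = tuple(range(5, 51))
DEFAULT_REPS = 200
QUANTILES = (0.025, 0.975)


@dataclass
class MOEResult:
    """Relative margin of error of one trait at one sample size."""

    cultivar: str
    trait: str
    n: int
    reps: int
    rel_moe: float
    q_low: float
    q_high: float
    full_mean: float
    seed: int

    def as_dict(self) -> dict:
        return {
            "cultivar": self.cultivar, "trait": self.trait, "n": self.n,
            "reps": self.reps, "q_low": self.q_low, "q_high": self.q_high,
            "full_mean": self.full_mean, "rel_moe": self.rel_moe,
            "seed": self.seed,
        }


def margin_of_error(values: Sequence[float], n: int, reps: int = DEFAULT_REPS,
                    seed: int = 0, rng: Optional[np.random.Generator] = None,
                    cultivar: str = "", trait: str = "",
                    replace: bool = False) -> MOEResult:
    """Relative margin of error of the mean of n-fruit subsamples.

    Subsets are drawn without replacement (``replace=True`` switches to a
    conventional bootstrap for comparison).  Quantiles use linear
    interpolation between order statistics.  ``full_mean`` is the mean of
    *all* values, so at n = len(values) every subset mean equals it and the
    margin is exactly 0.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least two values")
    if not 1 <= n <= values.size:
        raise ValueError(f"n={n} outside 1..{values.size}")
    if reps < 2:
        raise ValueError("reps must be >= 2")
    if rng is None:
        rng = np.random.default_rng(seed)
    means = np.empty(reps)
    for r in range(reps):
        subset = rng.choice(values, size=n, replace=replace)
        means[r] = subset.mean()
    q_low, q_high = np.quantile(means, QUANTILES)
    full_mean = float(values.mean())
    rel_moe = float((q_high - q_low) / (2.0 * full_mean))
    return MOEResult(cultivar=cultivar, trait=trait, n=int(n), reps=int(reps),
                     rel_moe=rel_moe, q_low=float(q_low), q_high=float(q_high),
                     full_mean=full_mean, seed=int(seed))


def moe_curve(df: pd.DataFrame, traits: dict[str, str],
              group_column: str = "cultivar",
              n_grid: Iterable[int] = DEFAULT_N_GRID,
              reps: int = DEFAULT_REPS, seed: int = 0,
              replace: bool = False) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Margin-of-error curves per trait and cultivar over a sample-size grid.

    ``traits`` maps trait names to record columns (e.g. ``{"weight":
    "weight_g"}``).  Cultivars with fewer records than the largest grid value
    get a truncated grid (with a warning in the returned curve's metadata
    column ``truncated``).  Returns ``(curves, cross_means)``: the full grid
    of per-cultivar results and the per-n cross-cultivar mean rel_moe per
    trait.  A single seeded generator drives all resampling, so results are
    bit-reproducible for a given seed.
    """
    if df.empty:
        raise ValueError("empty record set")
    n_grid = sorted(set(int(n) for n in n_grid))
    rng = np.random.default_rng(seed)
    rows = []
    for cultivar, group in df.groupby(group_column, sort=True):
        for trait, column in traits.items():
            values = group[column].dropna().to_numpy(dtype=float)
            truncated = values.size < max(n_grid)
            for n in n_grid:
                if n > values.size:
                    continue
                res = margin_of_error(values, n, reps=reps, rng=rng, seed=seed,
                                      cultivar=str(cultivar), trait=trait)
                row = res.as_dict()
                row["truncated"] = truncated
                rows.append(row)
    curves = pd.DataFrame(rows)
    cross = (curves.groupby(["trait", "n"], as_index=False)["rel_moe"]
             .mean().rename(columns={"rel_moe": "mean_rel_moe"}))
    return curves, cross


def recommend_n(cross_means: pd.DataFrame, target_rel_moe: float,
                trait: Optional[str] = None) -> Optional[int]:
    """Smallest grid n whose cross-cultivar mean margin meets the target.

    With ``trait=None`` the n must meet the target for every trait present.
    Returns None when no grid value qualifies.
    """
    data = cross_means if trait is None else cross_means[cross_means["trait"] == trait]
    if data.empty:
        return None
    ok_by_n = data.groupby("n")["mean_rel_moe"].max() <= target_rel_moe
    qualifying = ok_by_n[ok_by_n].index
    return int(qualifying.min()) if len(qualifying) else None
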
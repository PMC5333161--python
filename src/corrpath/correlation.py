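"""All-pairs Pearson correlation of time-course profiles.

Each profile is reduced to its per-time replicate mean and treated as a
vector; the Pearson correlation coefficient

    r = sum((x_i - xbar) (y_i - ybar)) / sqrt(sum((x_i - xbar)^2) sum((y_i - ybar)^2))

is computed on the two profiles' *shared* time points, so entity sets
measured on different day grids (metabolites on days 0-5, genes on days
0-3) correlate on the intersection with no interpolation.  A profile that
is constant on the shared grid has undefined correlation and yields NaN,
never +/-1.  No p-values are attached: downstream display uses r magnitudes
only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InputError, LookupError_
from .io import Dataset, TimeSeriesProfile, mean_profile

logger = logging.getLogger(__name__)

#: minimum number of shared time points admitted for a correlation
DEFAULT_MIN_POINTS = 3


def common_grid(a: TimeSeriesProfile, b: TimeSeriesProfile) -> list[float]:
    """Ascending list of time points present in both profiles (may be empty)."""
    return sorted(set(a.times) & set(b.times))


def pearson(x: np.ndarray, y: np.ndarray,
            min_points: int = DEFAULT_MIN_POINTS) -> float:
    """Pearson r of two equal-length vectors; NaN if either has zero variance."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InputError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < min_points:
        raise InputError(f"need >= {min_points} points, got {x.size}")
    dx = x - x.mean()
    dy = y - y.mean()
    sx = float(dx @ dx)
    sy = float(dy @ dy)
    if sx == 0.0 or sy == 0.0:
        return float("nan")
    r = float(dx @ dy) / np.sqrt(sx * sy)
    # float round-off can overshoot |r| = 1 by ~1e-16
    return float(np.clip(r, -1.0, 1.0))


@dataclass
class CorrelationMatrix:
    """Labelled matrix of Pearson r between two (possibly equal) entity sets."""

    row_ids: list[str]
    col_ids: list[str]
    values: np.ndarray
    grid: list[float] | None = None  # shared grid if uniform across pairs

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.row_ids), len(self.col_ids)):
            raise InputError(
                f"matrix shape {self.values.shape} does not match labels "
                f"({len(self.row_ids)}, {len(self.col_ids)})"
            )

    @property
    def is_square(self) -> bool:
        return self.row_ids == self.col_ids

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.row_ids, columns=self.col_ids)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, na_rep="NA")

    @classmethod
    def from_csv(cls, path) -> "CorrelationMatrix":
        df = pd.read_csv(path, index_col=0, na_values=["NA"])
        return cls(row_ids=[str(i) for i in df.index],
                   col_ids=[str(c) for c in df.columns],
                   values=df.to_numpy(dtype=float))


def _resolve_entities(d: Dataset, condition: str,
                      selector, include_culture: bool) -> list[str]:
    """Selector is an entity-kind name, an explicit id list, or None (all
    omics entities).  Culture metrics are appended after the omics ids."""
    if isinstance(selector, str):
        ids = d.entities(kind=selector, condition=condition)
    elif selector is None:
        ids = sorted(
            set(d.entities("metabolite", condition))
            | set(d.entities("gene", condition))
        )
    else:
        ids = list(selector)
    if include_culture:
        ids = ids + [e for e in d.entities("culture_metric", condition)
                     if e not in ids]
    return ids


def correlation_matrix(d: Dataset, condition: str,
                       rows: str | list[str] | None = None,
                       cols: str | list[str] | None = None,
                       include_culture: bool = False,
                       min_points: int = DEFAULT_MIN_POINTS) -> CorrelationMatrix:
    """All-pairs Pearson matrix between two entity selections.

    ``rows``/``cols`` may be an entity kind (``"metabolite"``, ``"gene"``),
    an explicit id list, or None for all omics entities.  With
    ``include_culture`` the culture metrics (cell number, extracellular
    glucose and lactate) are appended to BOTH axes.  Pairs whose shared
    grid is shorter than ``min_points`` get NaN with a logged warning.
    """
    if condition not in d.conditions():
        raise LookupError_(f"condition {condition!r} not in dataset "
                           f"(have {d.conditions()})")
    row_ids = _resolve_entities(d, condition, rows, include_culture)
    col_ids = _resolve_entities(d, condition, cols, include_culture)

    means: dict[str, tuple[TimeSeriesProfile, np.ndarray]] = {}
    for eid in set(row_ids) | set(col_ids):
        p = d.get(eid, condition)
        means[eid] = (p, mean_profile(p)[0])

    values = np.full((len(row_ids), len(col_ids)), np.nan)
    grids: set[tuple[float, ...]] = set()
    for i, ri in enumerate(row_ids):
        for j, ci in enumerate(col_ids):
            pa, ma = means[ri]
            pb, mb = means[ci]
            grid = common_grid(pa, pb)
            if len(grid) < min_points:
                logger.warning(
                    "pair (%s, %s): only %d shared time points (< %d); NA",
                    ri, ci, len(grid), min_points,
                )
                continue
            grids.add(tuple(grid))
            ia = [pa.times.index(t) for t in grid]
            ib = [pb.times.index(t) for t in grid]
            values[i, j] = pearson(ma[ia], mb[ib], min_points=min_points)

    shared = list(grids.pop()) if len(grids) == 1 else None
    return CorrelationMatrix(row_ids=row_ids, col_ids=col_ids,
                             values=values, grid=shared)
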
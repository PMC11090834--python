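"""Gridded utilization distributions, core ranges and habitat similarity.

Home ranges are estimated as fixed-bandwidth Gaussian kernel densities on
logger coordinates weighted by detection counts, discretized on a regular
grid (one cell defaults to 10 m x 10 m). Pairwise range overlap uses the
Bhattacharyya coefficient on full utilization distributions; the 75% core
range is used only to extract habitat (ground-cover) profiles, which are
compared with Bray-Curtis similarity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._metrics import bray_curtis_similarity

logger = logging.getLogger(__name__)

#: Default cell side in metres.
DEFAULT_CELL_SIZE = 10.0
#: Minimum detections required for a utilization distribution.
MIN_DETECTIONS = 10


class TooFewDetections(ValueError):
    """Individual excluded: not enough detections for a stable range."""


@dataclass(frozen=True)
class GridSpec:
    """Regular grid: ``shape`` (ny, nx) cells of side ``cell_size`` from ``origin``."""

    shape: tuple
    cell_size: float = DEFAULT_CELL_SIZE
    origin: tuple = (0.0, 0.0)

    def cell_centres(self):
        ny, nx = self.shape
        ys = self.origin[1] + (np.arange(ny) + 0.5) * self.cell_size
        xs = self.origin[0] + (np.arange(nx) + 0.5) * self.cell_size
        return np.meshgrid(xs, ys)  # (X, Y) each (ny, nx)


@dataclass
class UtilizationDistribution:
    grid: GridSpec
    p: np.ndarray  # (ny, nx), non-negative, sums to 1

    def __post_init__(self):
        if (self.p < 0).any():
            raise ValueError("UD probabilities must be non-negative")
        total = self.p.sum()
        if not np.isclose(total, 1.0, atol=1e-9):
            raise ValueError(f"UD must sum to 1, got {total}")

    def entropy(self) -> float:
        q = self.p[self.p > 0]
        return float(-(q * np.log(q)).sum())


@dataclass
class CoreRange:
    """Minimal cell set whose cumulative probability reaches ``level``."""

    cells: list  # [(row, col), ...]
    level: float
    grid: GridSpec

    @property
    def area(self) -> float:
        return len(self.cells) * self.grid.cell_size ** 2


def estimate_ud(detections: pd.DataFrame, individual, grid: GridSpec,
                bandwidth: float, logger_coords: pd.DataFrame = None,
                min_detections: int = MIN_DETECTIONS) -> UtilizationDistribution:
    """Kernel-smoothed space-use distribution for one individual.

    Detection counts per logger are placed at the logger coordinates and
    smoothed with an isotropic Gaussian kernel of standard deviation
    ``bandwidth`` (same units as the grid), then renormalized on the grid.

    ``logger_coords`` maps logger id to (x, y); if None, the detections
    frame must carry ``x``/``y`` columns directly.
    """
    sub = detections[detections["individual"] == individual]
    if len(sub) < min_detections:
        raise TooFewDetections(
            f"{individual}: {len(sub)} detections < {min_detections}")
    counts = sub.groupby("logger").size()
    if logger_coords is not None:
        coords = logger_coords.loc[counts.index]
        lx, ly = coords["x"].to_numpy(float), coords["y"].to_numpy(float)
    else:
        first = sub.groupby("logger")[["x", "y"]].first().loc[counts.index]
        lx, ly = first["x"].to_numpy(float), first["y"].to_numpy(float)
    w = counts.to_numpy(float)

    X, Y = grid.cell_centres()
    if bandwidth <= 0:
        # degenerate limit: all mass at the nearest cell to each logger
        p = np.zeros(grid.shape)
        for xi, yi, wi in zip(lx, ly, w):
            d2 = (X - xi) ** 2 + (Y - yi) ** 2
            r, c = np.unravel_index(np.argmin(d2), grid.shape)
            p[r, c] += wi
    else:
        d2 = (X[..., None] - lx) ** 2 + (Y[..., None] - ly) ** 2
        p = (np.exp(-0.5 * d2 / bandwidth ** 2) * w).sum(axis=-1)
    total = p.sum()
    if total == 0:
        raise ValueError(f"{individual}: all kernel mass fell outside the grid")
    return UtilizationDistribution(grid, p / total)


def estimate_all_uds(detections: pd.DataFrame, grid: GridSpec, bandwidth: float,
                     logger_coords: pd.DataFrame = None,
                     min_detections: int = MIN_DETECTIONS):
    """UDs for every individual; returns (dict id -> UD, excluded ids)."""
    uds, excluded = {}, []
    for ind in sorted(detections["individual"].unique()):
        try:
            uds[ind] = estimate_ud(detections, ind, grid, bandwidth,
                                   logger_coords, min_detections)
        except TooFewDetections:
            excluded.append(ind)
    if excluded:
        logger.info("excluded %d/%d individuals with < %d detections",
                    len(excluded), len(excluded) + len(uds), min_detections)
    return uds, excluded


def bhattacharyya(p: UtilizationDistribution, q: UtilizationDistribution) -> float:
    """Bhattacharyya coefficient sum(sqrt(p*q)) in [0, 1]."""
    if p.grid != q.grid:
        raise ValueError("utilization distributions are on different grids")
    return float(np.sqrt(p.p * q.p).sum())


def core_range(ud: UtilizationDistribution, level: float = 0.75) -> CoreRange:
    """Smallest cell set reaching ``level`` cumulative probability.

    Cells are taken in descending probability order; ties break by
    row-major cell index.
    """
    flat = ud.p.ravel()
    # stable sort on (-p, index) gives descending p with row-major tie-break
    order = np.argsort(-flat, kind="stable")
    cum = np.cumsum(flat[order])
    k = int(np.searchsorted(cum, level - 1e-12) + 1)
    k = min(k, flat.size)
    cells = [tuple(np.unravel_index(i, ud.p.shape)) for i in order[:k]]
    return CoreRange(cells=cells, level=level, grid=ud.grid)


def habitat_profile(core: CoreRange, survey: pd.DataFrame) -> pd.Series:
    """Normalized cover-type abundance over a core range.

    ``survey`` is long-format with columns cell_x, cell_y, cover_type,
    percent (cell_x = column index, cell_y = row index). For each cover
    type: sum of (percent/100 * cell area) over core cells, divided by
    the core area.
    """
    table = survey.pivot_table(index=["cell_y", "cell_x"], columns="cover_type",
                               values="percent", aggfunc="first")
    rows = []
    for (r, c) in core.cells:
        if (r, c) not in table.index:
            raise KeyError(f"core cell (row={r}, col={c}) missing from habitat survey")
        rows.append(table.loc[(r, c)])
    cover = pd.concat(rows, axis=1).T.fillna(0.0) / 100.0
    cell_area = core.grid.cell_size ** 2
    return cover.sum(axis=0) * cell_area / core.area


def habitat_similarity_matrix(profiles: dict) -> tuple:
    """Pairwise Bray-Curtis similarity over habitat profiles.

    Returns (ids, matrix) with unit diagonal.
    """
    ids = sorted(profiles)
    aligned = pd.DataFrame({i: profiles[i] for i in ids}).fillna(0.0).T
    n = len(ids)
    m = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            m[i, j] = m[j, i] = bray_curtis_similarity(
                aligned.iloc[i].to_numpy(), aligned.iloc[j].to_numpy())
    return ids, m


def overlap_matrix(uds: dict) -> tuple:
    """Pairwise Bhattacharyya coefficients; returns (ids, matrix)."""
    ids = sorted(uds)
    n = len(ids)
    m = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            m[i, j] = m[j, i] = bhattacharyya(uds[ids[i]], uds[ids[j]])
    return ids, m
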
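"""Occurrence filtering, spatial thinning, background sampling and
checkerboard spatial cross-validation folds.

Occurrence tables are plain :class:`pandas.DataFrame` objects with columns
``id, x, y, year, uncertainty_m`` (projected metres). All distances are
planar Euclidean; swap in great-circle distances before applying any of this
to unprojected lon/lat data.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .grid import Grid

__all__ = [
    "OCCURRENCE_COLUMNS",
    "validate_occurrences",
    "filter_uncertainty",
    "thin",
    "sample_background",
    "checkerboard2",
]

OCCURRENCE_COLUMNS = ("id", "x", "y", "year", "uncertainty_m")

DEFAULT_MAX_UNCERTAINTY_M = 250.0
DEFAULT_N_BACKGROUND = 10_000
DEFAULT_THIN_REPS = 100


def validate_occurrences(occ: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in OCCURRENCE_COLUMNS if c not in occ.columns]
    if missing:
        raise ValueError(f"occurrence table missing columns: {missing}")
    if occ["id"].duplicated().any():
        raise ValueError("occurrence ids must be unique")
    if not np.isfinite(occ[["x", "y"]].to_numpy(float)).all():
        raise ValueError("occurrence coordinates must be finite")
    return occ


def filter_uncertainty(
    occ: pd.DataFrame, max_radius_m: float = DEFAULT_MAX_UNCERTAINTY_M
) -> pd.DataFrame:
    """Keep records whose positional uncertainty is *strictly* below the cutoff."""
    if not max_radius_m > 0:
        raise ValueError("max_radius_m must be positive")
    validate_occurrences(occ)
    return occ.loc[occ["uncertainty_m"] < max_radius_m].reset_index(drop=True)


def thin(
    occ: pd.DataFrame,
    min_dist_m: float,
    reps: int = DEFAULT_THIN_REPS,
    seed: int | None = None,
) -> pd.DataFrame:
    """Spatially thin records so no retained pair is closer than ``min_dist_m``.

    Multi-start removal heuristic: each rep repeatedly deletes one member of
    the closest conflicting pair (uniform tie-break among members of all
    closest pairs) until no conflicts remain; the rep retaining the most
    records wins. Deterministic for a given seed.
    """
    if not min_dist_m > 0:
        raise ValueError("min_dist_m must be positive")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    validate_occurrences(occ)
    n = len(occ)
    if n <= 1:
        return occ.reset_index(drop=True)

    coords = occ[["x", "y"]].to_numpy(float)
    dist = squareform(pdist(coords))
    np.fill_diagonal(dist, np.inf)
    rng = np.random.default_rng(seed)

    best_keep: np.ndarray | None = None
    for _ in range(reps):
        d = dist.copy()
        alive = np.ones(n, dtype=bool)
        while True:
            dmin = d.min()
            if dmin >= min_dist_m:
                break
            ii, jj = np.where(d == dmin)
            members = np.unique(np.concatenate([ii, jj]))
            victim = int(rng.choice(members))
            alive[victim] = False
            d[victim, :] = np.inf
            d[:, victim] = np.inf
        if best_keep is None or alive.sum() > best_keep.sum():
            best_keep = alive
    assert best_keep is not None
    return occ.loc[best_keep].reset_index(drop=True)


def sample_background(
    accessible_mask: Grid,
    n: int = DEFAULT_N_BACKGROUND,
    seed: int | None = None,
) -> pd.DataFrame:
    """Place exactly ``n`` points uniformly within the accessible cells.

    Cells are sampled with replacement and each point jittered uniformly
    within its cell, so points may share a cell.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    mask = np.asarray(accessible_mask.values) == 1
    cells = np.flatnonzero(mask)
    if cells.size == 0:
        raise ValueError("accessible mask has no cells set")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(cells, size=n, replace=True)
    rows, cols = np.unravel_index(chosen, accessible_mask.shape)
    x0, y0 = accessible_mask.origin_xy
    cell = accessible_mask.cell_size_m
    xs = x0 + (cols + rng.random(n)) * cell
    ys = y0 + (rows + rng.random(n)) * cell
    return pd.DataFrame(
        {
            "id": [f"bg{i:06d}" for i in range(n)],
            "x": xs,
            "y": ys,
            "year": np.zeros(n, dtype=int),
            "uncertainty_m": np.zeros(n),
        }
    )


def checkerboard2(
    points: pd.DataFrame,
    grid: Grid,
    coarse_cells: int,
    fine_cells: int,
) -> pd.Series:
    """Four-fold spatial partition from two nested checkerboard grids.

    fold = 2 * parity(coarse block) + parity(fine block), where a block's
    parity is ``(block_x + block_y) % 2`` and block indices come from
    floor-dividing cell-space coordinates by the block edge length (half-open
    blocks, boundary points belong to the right/upper block).

    Returns a Series indexed by record id with integer folds in {0,1,2,3}.
    """
    if not (coarse_cells > fine_cells >= 1):
        raise ValueError("need coarse_cells > fine_cells >= 1")
    validate_occurrences(points)
    x0, y0 = grid.origin_xy
    xs = (points["x"].to_numpy(float) - x0) / grid.cell_size_m
    ys = (points["y"].to_numpy(float) - y0) / grid.cell_size_m
    outside = (
        (xs < 0) | (xs >= grid.n_cols) | (ys < 0) | (ys >= grid.n_rows)
    )
    if outside.any():
        bad = points.loc[outside, "id"].tolist()
        raise ValueError(f"points outside grid extent: {bad}")

    def parity(edge: int) -> np.ndarray:
        bx = np.floor(xs / edge).astype(int)
        by = np.floor(ys / edge).astype(int)
        return (bx + by) % 2

    fold = 2 * parity(coarse_cells) + parity(fine_cells)
    return pd.Series(fold, index=pd.Index(points["id"], name="id"), name="fold")
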
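"""Dispersal-constrained range projection as a deterministic cellular
automaton with reproductive maturity and barrier rules.

Each step: (1) occupied cells that became unsuitable are decolonized;
(2) cells occupied for at least ``maturity_steps`` act as colonization
sources; (3) unoccupied suitable cells within the dispersal distance of an
admissible source are colonized at age 1; (4) surviving occupied cells age
by one. Barrier modes restrict which (source, target) pairs are admissible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .grid import Grid
from .rangemetrics import BinaryRange

__all__ = [
    "DispersalConfig",
    "OccupancyState",
    "SimulationResult",
    "clip_initial_range",
    "simulate",
    "unlimited_projection",
]

BARRIER_MODES = ("none", "cells_block", "basins_and_dams")


@dataclass(frozen=True)
class DispersalConfig:
    dispersal_distance_m: float
    maturity_steps: int = 1
    n_steps: int = 1
    barrier_mode: str = "none"
    colonization_prob: float = 1.0  # < 1 enables the optional stochastic mode
    seed: int | None = None

    def __post_init__(self) -> None:
        if not self.dispersal_distance_m > 0:
            raise ValueError("dispersal_distance_m must be positive")
        if self.maturity_steps < 1:
            raise ValueError("maturity_steps must be >= 1")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        if self.barrier_mode not in BARRIER_MODES:
            raise ValueError(f"barrier_mode must be one of {BARRIER_MODES}")
        if not 0 < self.colonization_prob <= 1:
            raise ValueError("colonization_prob must be in (0, 1]")


@dataclass
class OccupancyState:
    occupied: np.ndarray  # bool
    age: np.ndarray  # int; steps since colonization, 0 where unoccupied

    def __post_init__(self) -> None:
        if ((self.age > 0) != self.occupied).any():
            raise ValueError("age > 0 must hold exactly on occupied cells")


@dataclass
class SimulationResult:
    final: BinaryRange
    history: pd.DataFrame  # step, occupied_cells, colonized, decolonized
    state: OccupancyState


def clip_initial_range(current_binary: BinaryRange, range_mask: Grid) -> BinaryRange:
    """Cellwise AND of the binary prediction with a known-range mask."""
    current_binary.grid.require_aligned(range_mask, "binary range and mask")
    cur = current_binary.occupied
    mask = np.asarray(range_mask.values) == 1
    vals = np.where(
        current_binary.grid.valid_mask(), (cur & mask).astype(float), np.nan
    )
    return BinaryRange(
        grid=current_binary.grid.like(vals, nodata=np.nan),
        threshold_used=current_binary.threshold_used,
        method=current_binary.method,
    )


def unlimited_projection(future_binary: BinaryRange) -> BinaryRange:
    """No-dispersal-limit comparator: the future map passes through."""
    return future_binary


# ---------------------------------------------------------------------------
# Barrier admissibility
# ---------------------------------------------------------------------------


def _river_components(river_mask: Grid, dam_mask: Grid) -> np.ndarray:
    """Label 4-connected river components after cutting dam cells.

    Two cells on the same label are connected by a river path with no dam on
    it. Non-river (and dam) cells get label 0.
    """
    river = (np.asarray(river_mask.values) == 1) & (
        np.asarray(dam_mask.values) != 1
    )
    labels, _ = ndimage.label(river, structure=np.array(
        [[0, 1, 0], [1, 1, 1], [0, 1, 0]]
    ))
    return labels


def _segment_crosses(
    barrier: np.ndarray, r0: int, c0: int, r1: int, c1: int
) -> bool:
    """True if the straight segment between two cell centres passes through a
    barrier cell (dense sampling along the segment)."""
    n = max(abs(r1 - r0), abs(c1 - c0)) * 4 + 1
    t = np.linspace(0.0, 1.0, n)
    rr = np.rint(r0 + (r1 - r0) * t).astype(int)
    cc = np.rint(c0 + (c1 - c0) * t).astype(int)
    # endpoints themselves do not block
    inner = slice(1, -1) if n > 2 else slice(0, 0)
    return bool(barrier[rr[inner], cc[inner]].any())


# ---------------------------------------------------------------------------
# The automaton
# ---------------------------------------------------------------------------


def simulate(
    initial: BinaryRange,
    suitability_steps: list[BinaryRange],
    config: DispersalConfig,
    basin_id: Grid | None = None,
    dam_mask: Grid | None = None,
    river_mask: Grid | None = None,
    barrier_cells: Grid | None = None,
) -> SimulationResult:
    """Run the automaton for ``config.n_steps`` steps.

    ``suitability_steps`` supplies the suitable/unsuitable map per step; a
    single map is reused for every step (constant-future convention). With
    ``barrier_mode="basins_and_dams"`` a source can colonize a target only if
    they share a basin, or a dam-free river path connects them; with
    ``"cells_block"`` the straight segment between the two cell centres must
    not cross a barrier cell (``barrier_cells``, defaulting to dams).
    """
    if not suitability_steps:
        raise ValueError("at least one suitability map is required")
    for s in suitability_steps:
        initial.grid.require_aligned(s.grid, "initial and suitability maps")
    if config.barrier_mode == "basins_and_dams":
        if basin_id is None or dam_mask is None or river_mask is None:
            raise ValueError(
                "basins_and_dams mode needs basin_id, dam_mask and river_mask"
            )
        initial.grid.require_aligned(basin_id, "grids")
        basins = np.asarray(basin_id.values)
        river_comp = _river_components(river_mask, dam_mask)
    elif config.barrier_mode == "cells_block":
        blocker = barrier_cells if barrier_cells is not None else dam_mask
        if blocker is None:
            raise ValueError("cells_block mode needs barrier_cells (or dam_mask)")
        initial.grid.require_aligned(blocker, "grids")
        barrier = np.asarray(blocker.values) == 1
    rng = np.random.default_rng(config.seed)

    cell = initial.grid.cell_size_m
    occupied = initial.occupied.copy()
    age = np.where(occupied, config.maturity_steps, 0).astype(int)

    records = []
    for step in range(1, config.n_steps + 1):
        suit = suitability_steps[min(step - 1, len(suitability_steps) - 1)]
        suitable = suit.occupied

        # 1. decolonize
        gone = occupied & ~suitable
        occupied[gone] = False
        age[gone] = 0
        decolonized = int(gone.sum())

        # 2. mature sources
        sources = occupied & (age >= config.maturity_steps)
        src_rc = np.argwhere(sources)

        # 3. colonize
        new_cells = np.zeros_like(occupied)
        if len(src_rc) > 0:
            cand_rc = np.argwhere(~occupied & suitable)
            if len(cand_rc) > 0:
                tree = cKDTree((src_rc + 0.5) * cell)
                reach = tree.query_ball_point(
                    (cand_rc + 0.5) * cell, r=config.dispersal_distance_m
                )
                for (r, c), src_idx in zip(cand_rc, reach):
                    if not src_idx:
                        continue
                    ok = False
                    if config.barrier_mode == "none":
                        ok = True
                    elif config.barrier_mode == "basins_and_dams":
                        for i in src_idx:
                            sr, sc = src_rc[i]
                            if basins[sr, sc] == basins[r, c]:
                                ok = True
                                break
                            if (
                                river_comp[sr, sc] > 0
                                and river_comp[sr, sc] == river_comp[r, c]
                            ):
                                ok = True
                                break
                    else:  # cells_block
                        for i in src_idx:
                            sr, sc = src_rc[i]
                            if not _segment_crosses(barrier, sr, sc, r, c):
                                ok = True
                                break
                    if ok and (
                        config.colonization_prob >= 1.0
                        or rng.random() < config.colonization_prob
                    ):
                        new_cells[r, c] = True
        colonized = int(new_cells.sum())

        # 4. age survivors; newcomers start at age 1
        age[occupied] += 1
        occupied |= new_cells
        age[new_cells] = 1

        records.append(
            {
                "step": step,
                "occupied_cells": int(occupied.sum()),
                "colonized": colonized,
                "decolonized": decolonized,
            }
        )

    valid = initial.grid.valid_mask()
    for s in suitability_steps:
        valid |= s.grid.valid_mask()
    vals = np.where(valid, occupied.astype(float), np.nan)
    final = BinaryRange(grid=initial.grid.like(vals, nodata=np.nan))
    return SimulationResult(
        final=final,
        history=pd.DataFrame(records),
        state=OccupancyState(occupied=occupied, age=age),
    )
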
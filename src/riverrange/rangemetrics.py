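"""Suitability binarization under four threshold rules, and range
net-change, geographical-shift and interspecific-overlap metrics."""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ensemble import _check_two_class, _confusion_curve, _threshold_candidates
from .grid import Grid

__all__ = [
    "ThresholdMethod",
    "BinaryRange",
    "ChangeSummary",
    "find_threshold",
    "binarize",
    "net_change",
    "shift",
    "shift_of_current",
    "species_overlap",
    "change_map",
    "summarize_across",
]


class ThresholdMethod(str, enum.Enum):
    SENS_EQ_SPEC = "SENS_EQ_SPEC"
    MAX_TSS = "MAX_TSS"
    MEAN_OCC_PROB = "MEAN_OCC_PROB"
    MIN_ROC_DIST = "MIN_ROC_DIST"


@dataclass
class BinaryRange:
    """0/1/nodata range map plus the rule and cutoff that produced it."""

    grid: Grid
    threshold_used: float = float("nan")
    method: ThresholdMethod | None = None

    def __post_init__(self) -> None:
        vals = np.asarray(self.grid.values, float)
        valid = self.grid.valid_mask()
        ok = np.isin(vals[valid], (0.0, 1.0))
        if not ok.all():
            raise ValueError("binary range values must be 0, 1 or nodata")

    @property
    def occupied(self) -> np.ndarray:
        """Boolean occupancy array (nodata counts as unoccupied)."""
        return (np.asarray(self.grid.values, float) == 1.0) & self.grid.valid_mask()

    def count(self) -> int:
        return int(self.occupied.sum())


@dataclass
class ChangeSummary:
    gain_cells: int
    loss_cells: int
    stable_cells: int
    current_cells: int
    future_cells: int
    net_change_pct: float
    shift_pct: float

    def __post_init__(self) -> None:
        assert self.current_cells == self.stable_cells + self.loss_cells
        assert self.future_cells == self.stable_cells + self.gain_cells


def find_threshold(
    scores_presence: np.ndarray,
    scores_background: np.ndarray,
    method: ThresholdMethod | str,
) -> float:
    """Pick a binarization cutoff from presence/background scores.

    Candidates are the midpoints of the sorted unique pooled scores; ties
    resolve to the lowest threshold. MEAN_OCC_PROB ignores the candidates and
    returns the arithmetic mean of the presence scores.
    """
    method = ThresholdMethod(method)
    sp = np.asarray(scores_presence, float)
    sb = np.asarray(scores_background, float)
    if sp.size == 0 or sb.size == 0:
        raise ValueError("both presence and background scores are required")
    if method is ThresholdMethod.MEAN_OCC_PROB:
        return float(sp.mean())

    pooled = np.concatenate([sp, sb])
    labels = np.concatenate([np.ones(sp.size), np.zeros(sb.size)])
    pos, neg = _check_two_class(labels)
    thresholds = _threshold_candidates(pooled)
    sens, spec = _confusion_curve(pooled, pos, neg, thresholds)
    if method is ThresholdMethod.MAX_TSS:
        crit = -(sens + spec - 1.0)  # argmin of negated TSS
    elif method is ThresholdMethod.SENS_EQ_SPEC:
        crit = np.abs(sens - spec)
    else:  # MIN_ROC_DIST
        crit = np.sqrt((1.0 - sens) ** 2 + (1.0 - spec) ** 2)
    best = int(np.argmin(crit))  # first minimizer = lowest threshold
    return float(thresholds[best])


def binarize(
    suitability: Grid,
    threshold: float,
    method: ThresholdMethod | str | None = None,
) -> BinaryRange:
    """Cell = 1 iff suitability >= threshold; nodata propagates."""
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    vals = np.asarray(suitability.values, float)
    valid = suitability.valid_mask()
    out = np.where(valid, (vals >= threshold).astype(float), np.nan)
    grid = suitability.like(out, nodata=np.nan)
    return BinaryRange(
        grid=grid,
        threshold_used=float(threshold),
        method=None if method is None else ThresholdMethod(method),
    )


def _require_aligned(a: BinaryRange, b: BinaryRange) -> None:
    a.grid.require_aligned(b.grid, "binary ranges")


def net_change(current: BinaryRange, future: BinaryRange) -> ChangeSummary:
    """Gain/loss/stable cell counts plus net-change and shift percentages.

    ``net_change_pct`` uses the current range size as denominator (bounded
    below by -100); ``shift_pct`` is the fraction of the future range lying
    outside the current range.
    """
    _require_aligned(current, future)
    cur, fut = current.occupied, future.occupied
    stable = int((cur & fut).sum())
    loss = int((cur & ~fut).sum())
    gain = int((~cur & fut).sum())
    n_cur, n_fut = stable + loss, stable + gain
    if n_cur == 0:
        raise ValueError("current range is empty; net change undefined")
    return ChangeSummary(
        gain_cells=gain,
        loss_cells=loss,
        stable_cells=stable,
        current_cells=n_cur,
        future_cells=n_fut,
        net_change_pct=100.0 * (gain - loss) / n_cur,
        shift_pct=0.0 if n_fut == 0 else 100.0 * (1.0 - stable / n_fut),
    )


def shift(current: BinaryRange, future: BinaryRange) -> float:
    """Percent of the future range lying outside the current range."""
    _require_aligned(current, future)
    fut = future.occupied
    n_fut = int(fut.sum())
    if n_fut == 0:
        raise ValueError("future range is empty; shift undefined")
    stable = int((current.occupied & fut).sum())
    return 100.0 * (1.0 - stable / n_fut)


def shift_of_current(current: BinaryRange, future: BinaryRange) -> float:
    """Mirror definition: percent of the *current* range not retained."""
    _require_aligned(current, future)
    cur = current.occupied
    n_cur = int(cur.sum())
    if n_cur == 0:
        raise ValueError("current range is empty")
    stable = int((cur & future.occupied).sum())
    return 100.0 * (1.0 - stable / n_cur)


def species_overlap(range_a: BinaryRange, range_b: BinaryRange) -> float:
    """Percent of range A's cells that fall inside range B."""
    _require_aligned(range_a, range_b)
    a, b = range_a.occupied, range_b.occupied
    n_a = int(a.sum())
    if n_a == 0:
        raise ValueError("range A is empty; overlap undefined")
    return 100.0 * int((a & b).sum()) / n_a


def change_map(current: BinaryRange, future: BinaryRange) -> Grid:
    """Four-class map: 0 stable-unsuitable, 1 loss, 2 stable-suitable, 3 gain."""
    _require_aligned(current, future)
    cur, fut = current.occupied, future.occupied
    out = np.zeros(cur.shape, dtype=float)
    out[cur & ~fut] = 1
    out[cur & fut] = 2
    out[~cur & fut] = 3
    nodata = current.grid.nodata_mask() & future.grid.nodata_mask()
    out[nodata] = np.nan
    return current.grid.like(out, nodata=np.nan)


def summarize_across(
    runs: pd.DataFrame,
    value_col: str = "value",
    group_cols: tuple[str, ...] = ("species", "scenario", "metric"),
) -> pd.DataFrame:
    """Median and SD of a metric over the GCM x threshold factorial.

    ``runs`` is a tidy table with one row per factorial cell; rows are
    grouped by ``group_cols`` and summarized with the median and the
    population standard deviation (a single run has SD 0).
    """
    cols = [c for c in group_cols if c in runs.columns]
    if runs.empty:
        warnings.warn("summarize_across: empty input", stacklevel=2)
        return pd.DataFrame(columns=[*cols, "n_runs", "median", "sd"])
    grouped = runs.groupby(list(cols), sort=True)[value_col]
    out = grouped.agg(
        n_runs="size", median="median", sd=lambda v: float(np.std(v))
    ).reset_index()
    return out
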
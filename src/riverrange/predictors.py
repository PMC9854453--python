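"""Predictor engineering: distance-to-class layers, terrain derivatives,
the river-buffer analysis mask, feature extraction at points, and iterative
VIF-based variable selection."""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .grid import Grid

__all__ = [
    "PredictorStack",
    "distance_to_class",
    "terrain_slope",
    "terrain_roughness",
    "river_buffer",
    "extract_features",
    "vif_select",
    "compute_vifs",
]

logger = logging.getLogger(__name__)

DEFAULT_VIF_THRESHOLD = 5.0
DEFAULT_BUFFER_RADIUS_M = 1000.0

#: The variable set retained in the reference configuration after
#: collinearity screening: six bioclim-style layers, terrain, and the six
#: land-use distance layers.
REFERENCE_VARIABLES = (
    "bio3", "bio4", "bio8", "bio9", "bio15", "bio19",
    "slope", "elevation",
    "dist_forest", "dist_grassland", "dist_farmland",
    "dist_urban", "dist_water", "dist_barren",
)


@dataclass
class PredictorStack:
    """Named, mutually aligned predictor layers plus the analysis mask."""

    layers: dict[str, Grid]
    mask: Grid

    def __post_init__(self) -> None:
        names = list(self.layers)
        if len(set(names)) != len(names):
            raise ValueError("layer names must be unique")
        for name, layer in self.layers.items():
            self.mask.require_aligned(layer, f"mask and layer {name!r}")

    def subset(self, names) -> "PredictorStack":
        return PredictorStack(
            layers={n: self.layers[n] for n in names}, mask=self.mask
        )


def distance_to_class(landuse: Grid, class_code: int) -> Grid:
    """Euclidean distance (metres, centre-to-centre) to the nearest cell of
    the given land-use class; zero on cells of that class."""
    is_class = np.asarray(landuse.values) == class_code
    if not is_class.any():
        raise ValueError(f"class {class_code} absent from land-use raster")
    dist = ndimage.distance_transform_edt(
        ~is_class, sampling=landuse.cell_size_m
    )
    return landuse.like(dist, nodata=-9999.0)


def terrain_slope(elev: Grid) -> Grid:
    """Slope in degrees from Horn's 3x3 stencil (edge rows/cols replicated)."""
    z = np.pad(np.asarray(elev.values, float), 1, mode="edge")
    cell = elev.cell_size_m
    # neighbours named for a compass window; row+1 is "north" (y up)
    nw, n_, ne = z[2:, :-2], z[2:, 1:-1], z[2:, 2:]
    w_, e_ = z[1:-1, :-2], z[1:-1, 2:]
    sw, s_, se = z[:-2, :-2], z[:-2, 1:-1], z[:-2, 2:]
    dzdx = ((ne + 2 * e_ + se) - (nw + 2 * w_ + sw)) / (8 * cell)
    dzdy = ((nw + 2 * n_ + ne) - (sw + 2 * s_ + se)) / (8 * cell)
    slope = np.degrees(np.arctan(np.hypot(dzdx, dzdy)))
    return elev.like(slope, nodata=-9999.0)


def terrain_roughness(elev: Grid) -> Grid:
    """Roughness: max minus min elevation over the 3x3 neighbourhood."""
    z = np.asarray(elev.values, float)
    hi = ndimage.maximum_filter(z, size=3, mode="nearest")
    lo = ndimage.minimum_filter(z, size=3, mode="nearest")
    return elev.like(hi - lo, nodata=-9999.0)


def river_buffer(
    river_mask: Grid, radius_m: float = DEFAULT_BUFFER_RADIUS_M
) -> Grid:
    """0/1 mask of cells whose centre lies within ``radius_m`` of a river
    cell centre."""
    if radius_m < 0:
        raise ValueError("radius_m must be >= 0")
    river = np.asarray(river_mask.values) == 1
    if not river.any():
        raise ValueError("river mask is empty")
    dist = ndimage.distance_transform_edt(~river, sampling=river_mask.cell_size_m)
    return river_mask.like((dist <= radius_m).astype(np.int8), nodata=-1)


def extract_features(
    stack: PredictorStack,
    presences: pd.DataFrame,
    background: pd.DataFrame,
) -> pd.DataFrame:
    """Build the presence/background design table by sampling every layer at
    each point's containing cell.

    Points falling on masked or nodata cells are dropped (a warning reports
    how many). Columns: ``record_id``, ``label`` (1 presence / 0 background),
    then one column per layer.
    """
    frames = []
    for label, table in ((1, presences), (0, background)):
        rows, cols = stack.mask.cells_of(
            table["x"].to_numpy(float), table["y"].to_numpy(float)
        )
        inside = rows >= 0
        inside[inside] &= (
            np.asarray(stack.mask.values)[rows[inside], cols[inside]] == 1
        )
        dropped = int((~inside).sum())
        if dropped:
            warnings.warn(
                f"extract_features: dropped {dropped} of {len(table)} "
                f"{'presence' if label else 'background'} points outside the "
                "analysis mask",
                stacklevel=2,
            )
        data = {"record_id": table["id"].to_numpy()[inside], "label": label}
        r, c = rows[inside], cols[inside]
        for name, layer in stack.layers.items():
            vals = np.asarray(layer.values, float)[r, c]
            data[name] = vals
        frames.append(pd.DataFrame(data))
    out = pd.concat(frames, ignore_index=True)
    feature_cols = list(stack.layers)
    bad = out[feature_cols].isna().any(axis=1)
    if bad.any():
        warnings.warn(
            f"extract_features: dropped {int(bad.sum())} points on nodata cells",
            stacklevel=2,
        )
        out = out.loc[~bad].reset_index(drop=True)
    return out


def _vif_one(X: np.ndarray, j: int) -> float:
    """VIF of column j: 1 / (1 - R^2) of OLS of column j on the others."""
    y = X[:, j]
    others = np.delete(X, j, axis=1)
    A = np.column_stack([np.ones(len(y)), others])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ coef
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0:
        return np.inf
    r2 = 1.0 - ss_res / ss_tot
    if r2 >= 1.0:
        return np.inf
    return 1.0 / (1.0 - r2)


def compute_vifs(table: pd.DataFrame, names: list[str]) -> dict[str, float]:
    """Current VIF of each named column computed against the others."""
    X = table[names].to_numpy(float)
    return {name: _vif_one(X, j) for j, name in enumerate(names)}


def vif_select(
    table: pd.DataFrame,
    threshold: float = DEFAULT_VIF_THRESHOLD,
    candidates: list[str] | None = None,
) -> list[str]:
    """Iteratively drop the layer with the highest variance inflation factor
    until all remaining VIFs are <= threshold.

    Constant columns are dropped first (infinite-VIF convention); ties break
    toward the earlier-listed column. Returns survivors in input order.
    """
    if candidates is None:
        candidates = [
            c for c in table.columns if c not in ("record_id", "label")
        ]
    if len(candidates) < 2:
        raise ValueError("need at least two candidate layers")
    if len(table) <= len(candidates):
        raise ValueError("need more rows than candidate layers")

    retained = list(candidates)
    for name in list(retained):
        if table[name].nunique() <= 1:
            warnings.warn(f"vif_select: dropping constant layer {name!r}", stacklevel=2)
            retained.remove(name)

    while len(retained) >= 2:
        vifs = compute_vifs(table, retained)
        worst = max(retained, key=lambda nm: (vifs[nm], -retained.index(nm)))
        if vifs[worst] <= threshold:
            break
        logger.info("vif_select: dropping %s (VIF=%.2f)", worst, vifs[worst])
        retained.remove(worst)
    return retained
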
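"""Seeded synthetic landscapes with known ground truth.

Generates correlated continuous predictors, a six-class land-use layer, a
linear river network, basin/dam barrier layers, presence-only occurrences
drawn from a known logistic suitability surface, and deterministic future
scenario layers — everything the downstream modelling stages consume, with
the generating model retained so recovery can be verified.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .grid import Grid
from .predictors import river_buffer

__all__ = [
    "LandscapeConfig",
    "LandscapeBundle",
    "Scenario",
    "SCENARIO_CLIMATES",
    "SCENARIO_LANDUSES",
    "SCENARIO_GCMS",
    "make_landscape",
    "simulate_truth",
    "sample_occurrences",
    "make_future",
]

N_LANDUSE_CLASSES = 6
LANDUSE_NAMES = {
    1: "forest",
    2: "grassland",
    3: "farmland",
    4: "urban",
    5: "water",
    6: "barren",
}

SCENARIO_CLIMATES = ("RCP2.6", "RCP8.5")
SCENARIO_LANDUSES = ("B1", "A2")
SCENARIO_GCMS = ("CCSM4", "IPSL-CM5A-LR", "MIROC-ESM-CHEM")

# Severity multipliers for the additive climate perturbation.
_CLIMATE_SEVERITY = {"RCP2.6": 1.0, "RCP8.5": 2.5}
# Fraction of cells whose land-use class is reassigned.
_LANDUSE_SEVERITY = {"B1": 0.05, "A2": 0.15}

# Default predictor value ranges the smoothed fields are rescaled to.
DEFAULT_PREDICTOR_RANGES: dict[str, tuple[float, float]] = {
    "temperature": (0.0, 25.0),
    "temp_seasonality": (10.0, 80.0),
    "precipitation": (300.0, 1800.0),
    "precip_seasonality": (5.0, 60.0),
    "elevation": (0.0, 2500.0),
}


@dataclass(frozen=True)
class Scenario:
    """One cell of the climate x land-use x GCM projection factorial."""

    climate: str = "RCP2.6"
    landuse: str = "B1"
    gcm: str = "CCSM4"
    magnitude: float = 1.0  # overall perturbation scale; 0 => identity

    def __post_init__(self) -> None:
        if self.climate not in SCENARIO_CLIMATES:
            raise ValueError(f"unknown climate scenario {self.climate!r}")
        if self.landuse not in SCENARIO_LANDUSES:
            raise ValueError(f"unknown land-use scenario {self.landuse!r}")
        if self.gcm not in SCENARIO_GCMS:
            raise ValueError(f"unknown GCM label {self.gcm!r}")

    @property
    def label(self) -> str:
        return f"{self.climate}-{self.landuse}-{self.gcm}"


@dataclass
class LandscapeConfig:
    n_rows: int = 32
    n_cols: int = 32
    cell_size_m: float = 1000.0
    origin_xy: tuple[float, float] = (0.0, 0.0)
    seed: int | None = None
    correlation_length: float = 4.0  # Gaussian kernel sigma, in cells
    predictor_ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_PREDICTOR_RANGES)
    )
    n_dams: int = 2
    truth_beta: dict[str, float] = field(
        default_factory=lambda: {
            "intercept": -1.0,
            "temperature": 2.0,
            "precipitation": -1.5,
        }
    )
    buffer_radius_m: float = 1000.0

    def __post_init__(self) -> None:
        if self.n_rows < 8 or self.n_cols < 8:
            raise ValueError("landscape must be at least 8x8 cells")
        if self.seed is None:
            raise ValueError("a seed is required for reproducible landscapes")
        if self.correlation_length < 0:
            raise ValueError("correlation_length must be >= 0")


@dataclass
class LandscapeBundle:
    """All aligned layers of one synthetic world plus its generating model."""

    predictors: dict[str, Grid]
    landuse: Grid
    river_mask: Grid
    basin_id: Grid
    dam_mask: Grid
    truth_beta: dict[str, float]
    seed: int
    buffer_radius_m: float = 1000.0

    def __post_init__(self) -> None:
        ref = self.landuse
        for name, grid in self.all_grids().items():
            ref.require_aligned(grid, f"landuse and {name}")
        for name in self.truth_beta:
            if name != "intercept" and name not in self.predictors:
                raise ValueError(f"truth_beta references unknown predictor {name!r}")

    def all_grids(self) -> dict[str, Grid]:
        grids = dict(self.predictors)
        grids.update(
            landuse=self.landuse,
            river_mask=self.river_mask,
            basin_id=self.basin_id,
            dam_mask=self.dam_mask,
        )
        return grids

    @property
    def shape(self) -> tuple[int, int]:
        return self.landuse.shape

    def analysis_mask(self) -> Grid:
        """The river-buffer analysis region used throughout the pipeline."""
        return river_buffer(self.river_mask, self.buffer_radius_m)


def _smooth_field(rng: np.random.Generator, shape, sigma: float) -> np.ndarray:
    """White noise convolved with a Gaussian kernel, re-standardized."""
    noise = rng.standard_normal(shape)
    if sigma <= 0:
        return noise
    smoothed = ndimage.gaussian_filter(noise, sigma=sigma, mode="reflect")
    sd = smoothed.std()
    if sd > 0:
        smoothed = (smoothed - smoothed.mean()) / sd
    return smoothed


def _rescale(values: np.ndarray, lo: float, hi: float) -> np.ndarray:
    vmin, vmax = values.min(), values.max()
    if vmax == vmin:
        return np.full_like(values, (lo + hi) / 2.0)
    return lo + (values - vmin) * (hi - lo) / (vmax - vmin)


def _river_path(rng: np.random.Generator, n_rows: int, n_cols: int) -> np.ndarray:
    """A connected 1-cell-wide left-to-right path (4-connected random walk)."""
    mask = np.zeros((n_rows, n_cols), dtype=np.int8)
    row = int(rng.integers(n_rows // 4, 3 * n_rows // 4))
    col = 0
    mask[row, col] = 1
    while col < n_cols - 1:
        step = rng.choice(3, p=[0.5, 0.25, 0.25])  # 0: right, 1: up, 2: down
        if step == 0:
            col += 1
        elif step == 1 and row < n_rows - 2:
            row += 1
        elif step == 2 and row > 1:
            row -= 1
        else:
            col += 1
        mask[row, col] = 1
    return mask


def _basin_partition(rng: np.random.Generator, n_rows: int, n_cols: int) -> np.ndarray:
    """Split the grid into two contiguous basins along a wiggly ridge line."""
    basin = np.ones((n_rows, n_cols), dtype=np.int32)
    split = n_cols // 2 + int(rng.integers(-n_cols // 8, n_cols // 8 + 1))
    split = int(np.clip(split, 2, n_cols - 3))
    boundary = split
    for r in range(n_rows):
        if rng.random() < 0.3:
            boundary += int(rng.integers(-1, 2))
            boundary = int(np.clip(boundary, 2, n_cols - 3))
        basin[r, boundary:] = 2
    return basin


def make_landscape(config: LandscapeConfig) -> LandscapeBundle:
    """Generate a fully aligned synthetic landscape bundle.

    All layers are deterministic functions of ``config`` (including its
    seed); running twice with the same configuration yields bit-identical
    bundles.
    """
    rng = np.random.default_rng(config.seed)
    shape = (config.n_rows, config.n_cols)
    geo = dict(cell_size_m=config.cell_size_m, origin_xy=config.origin_xy)

    predictors: dict[str, Grid] = {}
    for name, (lo, hi) in config.predictor_ranges.items():
        fld = _smooth_field(rng, shape, config.correlation_length)
        predictors[name] = Grid(values=_rescale(fld, lo, hi), **geo)

    landuse_field = _smooth_field(rng, shape, max(config.correlation_length, 1.0))
    edges = np.quantile(landuse_field, np.linspace(0, 1, N_LANDUSE_CLASSES + 1)[1:-1])
    landuse = Grid(
        values=(np.digitize(landuse_field, edges) + 1).astype(np.int32), **geo
    )

    river = Grid(values=_river_path(rng, *shape), **geo)
    basins = Grid(values=_basin_partition(rng, *shape), **geo)

    dam = np.zeros(shape, dtype=np.int8)
    river_cells = np.argwhere(river.values == 1)
    if config.n_dams > 0 and len(river_cells) > 2:
        # dams never on the first/last river cell so the network stays usable
        candidates = river_cells[1:-1]
        take = min(config.n_dams, len(candidates))
        idx = rng.choice(len(candidates), size=take, replace=False)
        for r, c in candidates[idx]:
            dam[r, c] = 1
    dam_mask = Grid(values=dam, **geo)

    return LandscapeBundle(
        predictors=predictors,
        landuse=landuse,
        river_mask=river,
        basin_id=basins,
        dam_mask=dam_mask,
        truth_beta=dict(config.truth_beta),
        seed=config.seed,
        buffer_radius_m=config.buffer_radius_m,
    )


def _standardize_within(values: np.ndarray, mask: np.ndarray) -> np.ndarray:
    sel = values[mask]
    sd = sel.std()
    if sd == 0:
        return np.zeros_like(values, dtype=float)
    return (values - sel.mean()) / sd


def simulate_truth(bundle: LandscapeBundle) -> Grid:
    """True suitability: logistic(intercept + sum beta_j * z(predictor_j)).

    Predictors are standardized over the river-buffer analysis region; cells
    outside the buffer are nodata.
    """
    for name in bundle.truth_beta:
        if name != "intercept" and name not in bundle.predictors:
            raise ValueError(f"truth_beta references unknown predictor {name!r}")
    buffer = bundle.analysis_mask()
    inside = buffer.values.astype(bool)
    eta = np.full(bundle.shape, float(bundle.truth_beta.get("intercept", 0.0)))
    for name, beta in bundle.truth_beta.items():
        if name == "intercept":
            continue
        z = _standardize_within(np.asarray(bundle.predictors[name].values, float), inside)
        eta += beta * z
    suit = 1.0 / (1.0 + np.exp(-eta))
    suit[~inside] = np.nan
    out = bundle.landuse.like(suit, nodata=np.nan)
    return out


def sample_occurrences(
    truth: Grid,
    n: int,
    uncertainty_model: tuple[float, float] = (100.0, 500.0),
    seed: int | None = None,
    year_range: tuple[int, int] = (2013, 2020),
) -> pd.DataFrame:
    """Draw presence-only records with probability proportional to suitability.

    Each record gets a point jittered uniformly within its cell, a collection
    year, and a positional-uncertainty radius drawn from an exponential with
    the given mean, truncated at the given maximum — deliberately letting a
    fraction exceed the 250 m filter cutoff so the filter has work to do.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    vals = np.asarray(truth.values, float)
    weight = np.where(truth.valid_mask(), vals, 0.0)
    weight = np.where(np.isnan(weight), 0.0, weight)
    positive = int((weight > 0).sum())
    if n > positive:
        raise ValueError(
            f"requested {n} occurrences but only {positive} cells have "
            "positive suitability"
        )
    flat = weight.ravel()
    p = flat / flat.sum()
    # cells are drawn with replacement: real presence datasets revisit cells,
    # and with-replacement draws keep P(cell) proportional to suitability
    # regardless of how n compares to the number of cells
    cells = rng.choice(flat.size, size=n, replace=True, p=p)
    rows, cols = np.unravel_index(cells, truth.shape)
    x0, y0 = truth.origin_xy
    xs = x0 + (cols + rng.random(n)) * truth.cell_size_m
    ys = y0 + (rows + rng.random(n)) * truth.cell_size_m
    mean_m, max_m = uncertainty_model
    unc = np.minimum(rng.exponential(mean_m, size=n), max_m)
    years = rng.integers(year_range[0], year_range[1] + 1, size=n)
    return pd.DataFrame(
        {
            "id": [f"occ{i:05d}" for i in range(n)],
            "x": xs,
            "y": ys,
            "year": years,
            "uncertainty_m": unc,
        }
    )


def _gcm_direction(gcm: str) -> float:
    """A stable per-GCM gradient orientation derived from the label."""
    digest = hashlib.sha256(gcm.encode()).digest()
    return 2 * np.pi * int.from_bytes(digest[:4], "big") / 2**32


def make_future(bundle: LandscapeBundle, scenario: Scenario) -> LandscapeBundle:
    """Deterministically perturb a landscape into its scenario future.

    Continuous predictors receive an additive shift plus a planar spatial
    gradient whose magnitude scales with scenario severity (RCP8.5 > RCP2.6)
    and whose orientation depends on the GCM label; a scenario-dependent
    fraction of land-use cells is reassigned. Zero magnitude reproduces the
    current bundle exactly.
    """
    severity = scenario.magnitude * _CLIMATE_SEVERITY[scenario.climate]
    n_rows, n_cols = bundle.shape
    theta = _gcm_direction(scenario.gcm)
    rr, cc = np.meshgrid(np.arange(n_rows), np.arange(n_cols), indexing="ij")
    # planar gradient in the GCM direction, range [-0.5, 0.5]
    proj = (np.cos(theta) * cc / max(n_cols - 1, 1)) + (
        np.sin(theta) * rr / max(n_rows - 1, 1)
    )
    if proj.max() > proj.min():
        proj = (proj - proj.min()) / (proj.max() - proj.min()) - 0.5
    else:  # pragma: no cover - degenerate 1-cell grid
        proj = np.zeros_like(proj, dtype=float)

    future_predictors: dict[str, Grid] = {}
    for name, grid in bundle.predictors.items():
        vals = np.asarray(grid.values, float)
        scale = vals.std() if vals.std() > 0 else 1.0
        shifted = vals + severity * scale * (0.08 + 0.12 * proj)
        future_predictors[name] = grid.like(shifted)

    landuse_vals = bundle.landuse.values.copy()
    frac = scenario.magnitude * _LANDUSE_SEVERITY[scenario.landuse]
    if frac > 0:
        rng = np.random.default_rng(
            np.random.SeedSequence(
                [bundle.seed, int(hashlib.sha256(scenario.label.encode()).hexdigest()[:8], 16)]
            )
        )
        n_cells = landuse_vals.size
        n_change = int(round(min(frac, 1.0) * n_cells))
        if n_change > 0:
            idx = rng.choice(n_cells, size=n_change, replace=False)
            new_classes = rng.integers(1, N_LANDUSE_CLASSES + 1, size=n_change)
            flat = landuse_vals.ravel()
            flat[idx] = new_classes
            landuse_vals = flat.reshape(bundle.shape)
    future_landuse = bundle.landuse.like(landuse_vals)

    return LandscapeBundle(
        predictors=future_predictors,
        landuse=future_landuse,
        river_mask=bundle.river_mask.copy(),
        basin_id=bundle.basin_id.copy(),
        dam_mask=bundle.dam_mask.copy(),
        truth_beta=dict(bundle.truth_beta),
        seed=bundle.seed,
        buffer_radius_m=bundle.buffer_radius_m,
    )
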
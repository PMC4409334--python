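"""Seeded synthetic landscapes with closed-form ground truth.

Generates a spatially autocorrelated covariate stack (elevation with an
anticorrelated temperature field, population density, tree cover, land
cover, roads, cities, distance layers), a protection mask whose
assignment can be confounded with elevation and population, and a
Bernoulli fire process

    fire ~ Bernoulli(sigmoid(b0 + b.z(X) + delta * T))

on standardised covariates.  The generator emits the true ATT over
treated cells in closed form so downstream estimators can be tested
against known truth.  Every output is a pure function of (config, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import ndimage

from firescape.grid import (
    BINARY,
    CONTINUOUS,
    CATEGORICAL,
    GridGeometry,
    GridStack,
    Raster,
    euclidean_distance,
    slope_aspect,
)


@dataclass
class LandscapeConfig:
    n_rows: int = 100
    n_cols: int = 100
    cell_size: float = 1.0
    smoothing_scale: float = 5.0  # cells

    elevation_range: tuple[float, float] = (0.0, 2500.0)
    lapse_rate: float = 0.0065  # degC per m
    base_temperature: float = 28.0
    temperature_noise_sd: float = 0.5
    population_noise_sd: float = 0.4
    n_landcover_classes: int = 8
    n_roads: int = 4
    n_cities: int = 3
    forest_cover_threshold: float = 60.0  # percent, defines the forest mask

    n_protected_patches: int = 5
    protected_fraction: float = 0.25
    confound_elevation: float = 1.0  # protection odds up with elevation
    confound_population: float = -1.0  # protection odds down with population

    fire_intercept: float = -1.0
    fire_coefficients: dict = field(
        default_factory=lambda: {
            "temperature": 0.8,
            "population_density": 0.6,
            "tree_cover": -0.3,
            "dist_road": -0.4,
            "elevation": -0.5,
        }
    )
    protection_effect: float = -0.6  # delta on the logit

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "LandscapeConfig":
        d = json.loads(text)
        if "elevation_range" in d:
            d["elevation_range"] = tuple(d["elevation_range"])
        return cls(**d)


@dataclass
class LandscapeTruth:
    """Closed-form generator truth for downstream estimator tests."""

    true_att: float
    protected_expected_density: float
    nonprotected_expected_density: float
    factor_effects: dict

    def as_dict(self) -> dict:
        return {
            "true_att": self.true_att,
            "protected_expected_density": self.protected_expected_density,
            "nonprotected_expected_density": self.nonprotected_expected_density,
            "factor_effects": dict(self.factor_effects),
        }


def _smooth_field(rng: np.random.Generator, shape, scale: float) -> np.ndarray:
    """Standardised Gaussian random field (smoothed white noise)."""
    white = rng.standard_normal(shape)
    if scale > 0:
        f = ndimage.gaussian_filter(white, sigma=scale, mode="reflect")
    else:
        f = white
    f = f - f.mean()
    sd = f.std()
    return f / sd if sd > 0 else f


def _unit01(f: np.ndarray) -> np.ndarray:
    lo, hi = f.min(), f.max()
    return (f - lo) / (hi - lo) if hi > lo else np.zeros_like(f)


def _random_lines(rng: np.random.Generator, shape, n: int) -> np.ndarray:
    """Binary mask of n random straight cell paths crossing the grid."""
    nr, nc = shape
    mask = np.zeros(shape, dtype=np.uint8)
    for _ in range(n):
        if rng.random() < 0.5:
            r0, r1 = rng.integers(0, nr, size=2)
            cols = np.arange(nc)
            rows = np.round(np.linspace(r0, r1, nc)).astype(int)
        else:
            c0, c1 = rng.integers(0, nc, size=2)
            rows = np.arange(nr)
            cols = np.round(np.linspace(c0, c1, nr)).astype(int)
        mask[rows, cols] = 1
    return mask


def generate_covariates(config: LandscapeConfig, seed: int = 0) -> GridStack:
    """Build the full covariate stack plus confounded protection mask."""
    if config.n_rows < 3 or config.n_cols < 3:
        raise ValueError("landscape must be at least 3x3")
    rng = np.random.default_rng(seed)
    geom = GridGeometry(config.n_rows, config.n_cols, config.cell_size)
    shape = geom.shape

    # elevation: smoothed Gaussian field scaled to the configured range
    e0, e1 = config.elevation_range
    elev = e0 + (e1 - e0) * _unit01(_smooth_field(rng, shape, config.smoothing_scale))
    elevation = Raster(geom, elev, kind=CONTINUOUS, name="elevation")
    slope, aspect = slope_aspect(elevation)

    # temperature anticorrelated with elevation through the lapse rate
    temp = (
        config.base_temperature
        - config.lapse_rate * elev
        + config.temperature_noise_sd * rng.standard_normal(shape)
    )
    temperature = Raster(geom, temp, kind=CONTINUOUS, name="temperature")

    # log-normal population density decreasing with elevation
    pop_field = _smooth_field(rng, shape, config.smoothing_scale)
    log_pop = (
        3.0
        - 1.5 * (elev - elev.mean()) / max(elev.std(), 1e-9)
        + 0.8 * pop_field
        + config.population_noise_sd * rng.standard_normal(shape)
    )
    population = Raster(geom, np.exp(log_pop), kind=CONTINUOUS, name="population_density")

    # tree cover: smooth field mapped into [25, 100]
    tree = 25.0 + 75.0 * _unit01(_smooth_field(rng, shape, config.smoothing_scale))
    tree_cover = Raster(geom, tree, kind=CONTINUOUS, name="tree_cover")

    # categorical land cover from quantile-thresholded latent field
    latent = _smooth_field(rng, shape, config.smoothing_scale / 2)
    qs = np.quantile(latent, np.linspace(0, 1, config.n_landcover_classes + 1)[1:-1])
    lc = np.digitize(latent, qs).astype(np.int16)
    land_cover = Raster(geom, lc, kind=CATEGORICAL, nodata=-1, name="land_cover")

    # roads and cities -> distance and travel-time layers
    roads = _random_lines(rng, shape, config.n_roads)
    road_raster = Raster(geom, roads, kind=BINARY, nodata=255, name="roads")
    dist_road = euclidean_distance(road_raster)
    dist_road.name = "dist_road"

    cities = np.zeros(shape, dtype=np.uint8)
    ci = rng.integers(0, config.n_rows, size=config.n_cities)
    cj = rng.integers(0, config.n_cols, size=config.n_cities)
    cities[ci, cj] = 1
    dist_city = euclidean_distance(Raster(geom, cities, kind=BINARY, nodata=255, name="cities"))
    # crude travel-time: off-road speed 5 km/h plus road proximity discount
    travel = dist_city.values / 5.0 + dist_road.values / 25.0
    travel_time = Raster(geom, travel, kind=CONTINUOUS, name="travel_time")

    # forest mask from tree cover; distance to forest edge = distance to
    # the nearest cell on the other side of the forest boundary
    forest = (tree >= config.forest_cover_threshold).astype(np.uint8)
    if forest.any() and (forest == 0).any():
        inside = ndimage.distance_transform_edt(forest) * config.cell_size
        outside = ndimage.distance_transform_edt(1 - forest) * config.cell_size
        dist_edge_vals = np.where(forest == 1, inside, outside)
    else:
        dist_edge_vals = np.zeros(shape)
    dist_forest_edge = Raster(geom, dist_edge_vals, kind=CONTINUOUS, name="dist_forest_edge")

    protection = _protection_mask(rng, config, geom, elev, population.values)

    covs = {
        r.name: r
        for r in (
            tree_cover,
            land_cover,
            elevation,
            slope,
            aspect,
            temperature,
            population,
            travel_time,
            dist_road,
            dist_forest_edge,
        )
    }
    return GridStack(geometry=geom, covariates=covs, protection=protection)


def _protection_mask(
    rng: np.random.Generator,
    config: LandscapeConfig,
    geom: GridGeometry,
    elev: np.ndarray,
    pop: np.ndarray,
) -> Raster:
    """Contiguous protected patches, seeded with confounded odds.

    Patch seed cells are drawn with probability proportional to
    exp(c_e * z(elevation) + c_p * z(log population)); patches grow as
    disks until roughly ``protected_fraction`` of the grid is covered.
    With both coefficients at 0 the seeds are uniform.
    """
    shape = geom.shape
    z_e = (elev - elev.mean()) / max(elev.std(), 1e-9)
    lp = np.log(pop)
    z_p = (lp - lp.mean()) / max(lp.std(), 1e-9)
    score = config.confound_elevation * z_e + config.confound_population * z_p
    w = np.exp(score - score.max())
    p = (w / w.sum()).ravel()
    n_cells = shape[0] * shape[1]
    target = config.protected_fraction * n_cells
    radius = max(1.0, np.sqrt(target / (np.pi * config.n_protected_patches)))
    seeds = rng.choice(n_cells, size=config.n_protected_patches, replace=False, p=p)
    rr, cc = np.indices(shape)
    mask = np.zeros(shape, dtype=np.uint8)
    for s in seeds:
        sr, sc = divmod(int(s), shape[1])
        r_jit = radius * rng.uniform(0.7, 1.3)
        mask[(rr - sr) ** 2 + (cc - sc) ** 2 <= r_jit**2] = 1
    return Raster(geom, mask, kind=BINARY, nodata=255, name="protection")


def _fire_logits(stack: GridStack, config: LandscapeConfig) -> np.ndarray:
    """Deterministic logit field without the protection term."""
    geom = stack.geometry
    logit = np.full(geom.shape, config.fire_intercept, dtype=float)
    for name, beta in config.fire_coefficients.items():
        if beta == 0:
            continue
        vals = stack.covariates[name].values.astype(float)
        sd = vals.std()
        z = (vals - vals.mean()) / sd if sd > 0 else np.zeros_like(vals)
        logit += beta * z
    if not np.all(np.isfinite(logit)):
        raise ValueError("non-finite fire logits")
    return logit


def landscape_truth(stack: GridStack, config: LandscapeConfig) -> LandscapeTruth:
    """Recompute the closed-form truth record from a stack and config."""
    logit = _fire_logits(stack, config)
    T = stack.protection.values == 1
    delta = config.protection_effect

    def sig(x):
        return 1.0 / (1.0 + np.exp(-x))

    p_treat = sig(logit + delta)
    p_ctrl = sig(logit)
    att = float((p_treat[T] - p_ctrl[T]).mean()) if T.any() else 0.0
    dens_p = float(p_treat[T].mean()) if T.any() else float("nan")
    dens_np = float(p_ctrl[~T].mean()) if (~T).any() else float("nan")
    return LandscapeTruth(
        true_att=att,
        protected_expected_density=dens_p,
        nonprotected_expected_density=dens_np,
        factor_effects={k: abs(v) for k, v in config.fire_coefficients.items()},
    )


def generate_fires(
    stack: GridStack, config: LandscapeConfig, seed: int = 0
) -> tuple[Raster, LandscapeTruth]:
    """Draw Bernoulli fire occurrence and return it with the truth record."""
    rng = np.random.default_rng(seed)
    logit = _fire_logits(stack, config)
    T = (stack.protection.values == 1).astype(float)
    p = 1.0 / (1.0 + np.exp(-(logit + config.protection_effect * T)))
    fire_vals = (rng.random(stack.geometry.shape) < p).astype(np.uint8)
    fire = Raster(stack.geometry, fire_vals, kind=BINARY, nodata=255, name="fire")
    return fire, landscape_truth(stack, config)


def emit_fire_csv(
    fire: Raster,
    geometry: GridGeometry,
    seed: int = 0,
    confidence_values: tuple[int, int] = (80, 100),
    high_confidence_prob: float = 0.7,
) -> pd.DataFrame:
    """One MCD14ML-dialect detection row per fire cell, at the cell center.

    Confidence is drawn from a two-point distribution so the confidence
    filter path is exercised; at ``min_confidence=0`` rasterising the
    output reproduces the input raster exactly.  Synthetic grid-km
    coordinates are carried both as x_km/y_km and mirrored into the
    longitude/latitude columns of the standard dialect.
    """
    rng = np.random.default_rng(seed)
    rows_idx, cols_idx = np.nonzero(fire.values == 1)
    xs, ys = geometry.cell_centers()
    n = rows_idx.size
    lo, hi = confidence_values
    conf = np.where(rng.random(n) < high_confidence_prob, hi, lo).astype(int)
    df = pd.DataFrame(
        {
            "latitude": ys[rows_idx],
            "longitude": xs[cols_idx],
            "brightness": np.round(300 + 40 * rng.random(n), 1),
            "scan": np.ones(n),
            "track": np.ones(n),
            "acq_date": "2006-03-15",
            "acq_time": "0630",
            "satellite": "T",
            "confidence": conf,
            "version": "5.1",
            "x_km": xs[cols_idx],
            "y_km": ys[rows_idx],
        }
    )
    return df
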
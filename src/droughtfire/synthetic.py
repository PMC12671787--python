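"""Seeded synthetic inputs for the drought-to-fire pipeline.

The generators emulate the statistical structure the analysis assumes — a
lon/lat grid partitioned into contiguous regions, monthly climate with a
seasonal cycle, a persistent (AR(1)) wetness anomaly so multi-month droughts
occur, spatially smooth static covariates, spatially varying logistic
coefficient surfaces, and per-cell-per-year Bernoulli fire occurrence — so
every downstream stage has a self-contained, reproducible test surface.

One master seed spawns independent per-stream seeds (grid, climate,
covariates, truth, fires) via numpy's SeedSequence spawn keys, so stages can
be regenerated independently without perturbing each other.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from scipy.special import expit, ndtr
from scipy.stats import gamma as sps_gamma

__all__ = ["GridSpec", "TrueModel", "gen_grid", "gen_climate",
           "gen_covariates", "gen_true_model", "gen_fire_records"]

# stream identifiers for the master-seed spawn protocol
_STREAM_GRID, _STREAM_CLIMATE, _STREAM_COVARIATES, _STREAM_TRUTH, _STREAM_FIRES = range(5)

REGION_LABELS = ("NE", "N", "NW", "C", "E", "S", "SW")


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stream,)))


@dataclass(frozen=True)
class GridSpec:
    """A regular lon/lat grid of square cells with region labels.

    ``cells`` has one row per cell: cell_id, ix, iy, lon, lat (cell centres),
    region, forest_fraction.
    """

    n_lon: int
    n_lat: int
    lon0: float
    lat0: float
    cell_size: float
    cells: pd.DataFrame

    @property
    def n_cells(self) -> int:
        return self.n_lon * self.n_lat


@dataclass(frozen=True)
class TrueModel:
    """Ground-truth coefficient surfaces for recovery tests.

    ``intercept`` and each entry of ``surfaces`` are per-cell coefficient
    arrays on normalized predictors, deterministic functions of (lon, lat)
    for a fixed seed.
    """

    predictors: list[str]
    intercept: np.ndarray
    surfaces: dict[str, np.ndarray]

    def linear_predictor(self, X: pd.DataFrame) -> np.ndarray:
        eta = self.intercept.copy()
        for name in self.predictors:
            eta += self.surfaces[name] * X[name].to_numpy(dtype=float)
        return eta

    def probability(self, X: pd.DataFrame) -> np.ndarray:
        return expit(self.linear_predictor(X))


def gen_grid(n_lon: int, n_lat: int, seed: int, lon0: float = 100.0,
             lat0: float = 35.0, cell_size: float = 0.5) -> GridSpec:
    """Generate a grid whose cells are partitioned into contiguous
    rectangular region blocks (up to seven, shrinking with grid size)."""
    if n_lon < 2 or n_lat < 2:
        raise ValueError(f"grid must be at least 2x2, got {n_lon}x{n_lat}")
    rng = _rng(seed, _STREAM_GRID)

    ix, iy = np.meshgrid(np.arange(n_lon), np.arange(n_lat), indexing="ij")
    ix, iy = ix.ravel(), iy.ravel()
    lon = lon0 + (ix + 0.5) * cell_size
    lat = lat0 + (iy + 0.5) * cell_size

    # two latitude bands, up to 4 (north) + 3 (south) longitude blocks
    lat_split = n_lat // 2
    north = iy >= lat_split
    n_top = min(4, n_lon)
    n_bot = min(3, n_lon)
    top_block = np.minimum(ix * n_top // n_lon, n_top - 1)
    bot_block = np.minimum(ix * n_bot // n_lon, n_bot - 1)
    region_idx = np.where(north, top_block, n_top + bot_block)
    labels = np.array([REGION_LABELS[i % len(REGION_LABELS)] for i in range(n_top + n_bot)])
    region = labels[region_idx]

    forest = np.clip(
        0.55 + 0.25 * np.sin(2.0 * np.pi * ix / max(n_lon, 3))
        * np.cos(2.0 * np.pi * iy / max(n_lat, 3))
        + rng.normal(0.0, 0.08, ix.size),
        0.0, 1.0)

    cells = pd.DataFrame({
        "cell_id": np.arange(ix.size), "ix": ix, "iy": iy,
        "lon": lon, "lat": lat, "region": region, "forest_fraction": forest,
    })
    return GridSpec(n_lon=n_lon, n_lat=n_lat, lon0=lon0, lat0=lat0,
                    cell_size=cell_size, cells=cells)


def gen_climate(
    grid: GridSpec,
    years: int,
    trend: float = 0.0,
    seed: int = 0,
    start_year: int = 2000,
    ar1: float = 0.8,
    scenario: str = "historical",
    model: str = "synthetic",
    temp_noise_sd: float = 1.5,
) -> pd.DataFrame:
    """Monthly temperature (degC) and precipitation (mm) per cell.

    Temperature is a latitude-dependent baseline plus a sinusoidal seasonal
    cycle (July peak), a linear trend (``trend`` degC per decade), and
    Gaussian noise; northern winters go below 0 degC so the frozen-month PET
    branch is exercised.  Precipitation is seasonal gamma draws modulated by
    a cell-specific AR(1) wetness anomaly (coefficient ``ar1``), giving the
    multi-month wet/dry spells run-theory needs; a positive ``trend`` also
    dries precipitation by 3% per decade per unit trend.

    The returned long-format frame has one row per cell-month with columns
    cell_id, lon, lat, year, month, tas, pr, wetness, scenario, model.
    """
    if years < 1:
        raise ValueError(f"years must be >= 1, got {years}")
    rng = _rng(seed, _STREAM_CLIMATE)
    n_cells = grid.n_cells
    n_months = years * 12
    t_dec = (np.arange(n_months) / 12.0) / 10.0  # decades since series start
    month = np.tile(np.arange(1, 13), years)
    year = start_year + np.repeat(np.arange(years), 12)

    lat = grid.cells["lat"].to_numpy()
    # continental mid-latitude climate: annual mean ~16 degC at the southern
    # edge, strong winter so the frozen-PET branch is reachable northward
    baseline = 16.0 - 1.2 * (lat - grid.lat0)
    seasonal = 14.0 * np.cos(2.0 * np.pi * (month - 7) / 12.0)

    tas = (baseline[:, None] + seasonal[None, :]
           + trend * t_dec[None, :]
           + rng.normal(0.0, temp_noise_sd, (n_cells, n_months)))

    # AR(1) wetness anomaly, stationary unit variance
    eps = rng.normal(0.0, 1.0, (n_cells, n_months))
    z = np.empty((n_cells, n_months))
    z[:, 0] = eps[:, 0]
    innov_sd = np.sqrt(1.0 - ar1**2) if abs(ar1) < 1.0 else 0.0
    for t in range(1, n_months):
        z[:, t] = ar1 * z[:, t - 1] + innov_sd * eps[:, t]

    # precipitation: gamma marginals driven through a latent-Gaussian copula,
    # so the AR(1) anomaly supplies persistence without distorting the
    # marginal shape (monthly-total skew ~ 2/sqrt(shape))
    pr_season = 18.0 + 95.0 * np.exp(-0.5 * ((month - 7.0) / 1.8) ** 2)  # monsoon peak
    shape = 2.2
    mix = np.sqrt(0.7) * z + np.sqrt(0.3) * rng.normal(0.0, 1.0, (n_cells, n_months))
    u = ndtr(mix)
    dry_factor = np.clip(1.0 - 0.03 * trend * t_dec, 0.05, None)
    pr = (sps_gamma.ppf(u, a=shape) / shape) * pr_season[None, :] * dry_factor[None, :]

    cells = grid.cells
    return pd.DataFrame({
        "cell_id": np.repeat(cells["cell_id"].to_numpy(), n_months),
        "lon": np.repeat(cells["lon"].to_numpy(), n_months),
        "lat": np.repeat(lat, n_months),
        "year": np.tile(year, n_cells),
        "month": np.tile(month, n_cells),
        "tas": tas.ravel(),
        "pr": pr.ravel(),
        "wetness": z.ravel(),
        "scenario": scenario,
        "model": model,
    })


def _smooth_field(grid: GridSpec, rng: np.random.Generator, n_waves: int = 5) -> np.ndarray:
    """A smooth random surface on the grid: a low-order random Fourier sum,
    scaled to zero mean and unit SD."""
    x = grid.cells["ix"].to_numpy() / max(grid.n_lon - 1, 1)
    y = grid.cells["iy"].to_numpy() / max(grid.n_lat - 1, 1)
    f = np.zeros(grid.n_cells)
    for _ in range(n_waves):
        a = rng.normal()
        wx, wy = rng.uniform(0.5, 2.5, 2)
        phx, phy = rng.uniform(0.0, 2.0 * np.pi, 2)
        f += a * np.sin(2.0 * np.pi * wx * x + phx) * np.sin(2.0 * np.pi * wy * y + phy)
    sd = f.std()
    return (f - f.mean()) / (sd if sd > 0 else 1.0)


def gen_covariates(grid: GridSpec, seed: int = 0) -> pd.DataFrame:
    """Spatially smooth static covariates per cell (unnormalized units)."""
    rng = _rng(seed, _STREAM_COVARIATES)
    elev = 800.0 + 700.0 * _smooth_field(grid, rng) + 0.0
    elev = np.clip(elev, 0.0, None)
    slope = np.clip(8.0 + 6.0 * _smooth_field(grid, rng), 0.0, 45.0)
    tree = np.clip(0.5 + 0.2 * _smooth_field(grid, rng), 0.0, 1.0)
    rough = np.clip(120.0 + 100.0 * _smooth_field(grid, rng), 0.0, None)
    road = np.clip(0.4 + 0.3 * _smooth_field(grid, rng), 0.0, None)
    river = np.clip(0.25 + 0.15 * _smooth_field(grid, rng), 0.0, None)
    pop = np.exp(3.0 + 1.2 * _smooth_field(grid, rng))
    return pd.DataFrame({
        "cell_id": grid.cells["cell_id"].to_numpy(),
        "elevation": elev, "slope": slope, "tree_cover": tree,
        "roughness": rough, "road_density": road, "river_density": river,
        "population_density": pop,
    })


def gen_true_model(
    grid: GridSpec,
    predictors: list[str],
    seed: int = 0,
    drought_predictor: str | None = None,
    drought_amplitude: float = 2.5,
    intercept: float = -1.0,
    static_scale: float = 1.0,
    gradient_axis: str = "lat",
    profile: str = "tanh",
) -> TrueModel:
    """Ground-truth coefficient surfaces on normalized predictors.

    The designated ``drought_predictor`` (default: the first predictor) gets a
    coefficient that flips sign at the domain midline along ``gradient_axis``
    — positive (fire-promoting) on the low side, negative (inhibiting) on the
    high side, mirroring a south-promoting / north-inhibiting drought effect.
    ``profile='tanh'`` (default) is a smooth two-regime flip, the analogue of
    distinct southern/northern drought-fire regimes; ``profile='linear'``
    varies the coefficient linearly across the domain instead.  Other
    predictors get constant coefficients drawn once from the truth stream.
    """
    rng = _rng(seed, _STREAM_TRUTH)
    if drought_predictor is None:
        drought_predictor = predictors[0]
    if drought_predictor not in predictors:
        raise ValueError(f"'{drought_predictor}' not among predictors")
    axis = grid.cells["lat" if gradient_axis == "lat" else "lon"].to_numpy()
    centred = axis - 0.5 * (axis.min() + axis.max())
    half_range = max(np.max(np.abs(centred)), 1e-12)
    surfaces: dict[str, np.ndarray] = {}
    frac = centred / half_range
    if profile == "tanh":
        flip = np.tanh(3.0 * frac)
    elif profile == "linear":
        flip = frac
    else:
        raise ValueError(f"unknown profile '{profile}'")
    for name in predictors:
        if name == drought_predictor:
            surfaces[name] = -drought_amplitude * flip
        else:
            surfaces[name] = np.full(grid.n_cells, rng.normal(0.0, 0.4) * static_scale)
    return TrueModel(predictors=list(predictors),
                     intercept=np.full(grid.n_cells, float(intercept)),
                     surfaces=surfaces)


def gen_fire_records(
    grid: GridSpec,
    fp_true: np.ndarray,
    years: int,
    seed: int = 0,
    start_year: int = 2000,
) -> pd.DataFrame:
    """Point fire records from per-cell annual occurrence probabilities.

    Each cell-year is a fire-year with probability ``fp_true``; a fire-year
    emits one or more point records with coordinates uniform inside the cell.
    Returns a frame with columns lon, lat, year, month, day.
    """
    fp = np.asarray(fp_true, dtype=float)
    if fp.shape != (grid.n_cells,):
        raise ValueError(f"fp_true must have one value per cell ({grid.n_cells})")
    if np.any(fp < 0.0) or np.any(fp > 1.0):
        raise ValueError("fire probabilities must lie in [0, 1]")
    if years < 1:
        raise ValueError(f"years must be >= 1, got {years}")
    rng = _rng(seed, _STREAM_FIRES)

    fire_year = rng.random((grid.n_cells, years)) < fp[:, None]
    cells, yrs = np.nonzero(fire_year)
    n_extra = rng.poisson(0.5, cells.size)
    rows = []
    west = grid.lon0 + grid.cells["ix"].to_numpy() * grid.cell_size
    south = grid.lat0 + grid.cells["iy"].to_numpy() * grid.cell_size
    for c, y, extra in zip(cells, yrs, n_extra):
        k = 1 + extra
        rows.append(pd.DataFrame({
            "lon": west[c] + rng.random(k) * grid.cell_size,
            "lat": south[c] + rng.random(k) * grid.cell_size,
            "year": start_year + y,
            "month": rng.integers(1, 13, k),
            "day": rng.integers(1, 29, k),
        }))
    if not rows:
        return pd.DataFrame(columns=["lon", "lat", "year", "month", "day"])
    return pd.concat(rows, ignore_index=True)
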
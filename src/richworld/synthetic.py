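"""Synthetic gridded worlds with known driver -> richness structure.

Real global analyses of species richness rest on compiled range maps,
occurrence archives and remote-sensing driver layers.  This module builds
statistical stand-ins for those inputs on an equal-area grid so that every
downstream stage (screening, feature engineering, model fitting,
interpretation) can be exercised against a known generative truth:

* spatially autocorrelated driver fields (Gaussian-kernel smoothed white
  noise, scaled to [0, 1]);
* monthly driver series with 12- and 6-month sinusoidal components,
  per-cell phase, on top of a smooth spatial base field;
* species ranges as the cell sets satisfying randomly drawn environmental
  niche intervals, stacked into a richness layer;
* per-species point occurrence records with log-uniform record counts in
  [1, 1000], carrying latitude and a thermal value;
* a richness response defined as a known additive function of drivers
  (plus optional pairwise interactions) with Gaussian noise.

Everything is a pure function of (config, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .grids import (
    EXCLUDED,
    LAND,
    OCEAN,
    GenerationError,
    GridSpec,
    InvalidInputError,
    RasterLayer,
    RasterTimeSeries,
    make_grid,
)

# fixed per-stage offsets so adding a stage never perturbs earlier randomness
_SEED_FIELDS, _SEED_RANGES, _SEED_OCC, _SEED_NOISE = 11, 13, 17, 19


# ---------------------------------------------------------------------------
# richness functions


@dataclass
class RichnessTerm:
    """One additive component of the true richness function.

    ``shape`` maps the (0-1 scaled) driver value through a named response
    curve; the term contributes ``weight * shape(x)``.
    """

    driver: str
    shape: str = "linear"  # linear | quadratic | bump | sigmoid | sinus
    weight: float = 1.0
    center: float = 0.5
    width: float = 0.2

    def evaluate(self, x: np.ndarray) -> np.ndarray:
        if self.shape == "linear":
            f = x
        elif self.shape == "quadratic":
            f = x**2
        elif self.shape == "bump":
            f = np.exp(-(((x - self.center) / self.width) ** 2))
        elif self.shape == "sigmoid":
            f = 1.0 / (1.0 + np.exp(-(x - self.center) / max(self.width, 1e-9)))
        elif self.shape == "sinus":
            f = np.sin(np.pi * x)
        else:
            raise InvalidInputError(f"unknown term shape {self.shape!r}")
        return self.weight * f


@dataclass
class InteractionTerm:
    """Pairwise product interaction ``weight * x_a * x_b``."""

    drivers: tuple[str, str]
    weight: float = 1.0

    def evaluate(self, xa: np.ndarray, xb: np.ndarray) -> np.ndarray:
        return self.weight * xa * xb


@dataclass
class RichnessFunction:
    """Symbolic true driver->richness map: intercept + terms + interactions.

    The function is defined on the ln(richness + 1) response scale; with the
    ``expm1`` link the generated richness layer is ``expm1(f + noise)``,
    which is non-negative and right-skewed like real richness counts, and
    the downstream ln(x+1) transform recovers ``f + noise`` exactly.
    """

    intercept: float = 0.2
    terms: list[RichnessTerm] = field(default_factory=list)
    interactions: list[InteractionTerm] = field(default_factory=list)

    def referenced_drivers(self) -> list[str]:
        names = [t.driver for t in self.terms]
        for it in self.interactions:
            names.extend(it.drivers)
        return sorted(set(names))

    def evaluate(self, values: dict[str, np.ndarray]) -> np.ndarray:
        for name in self.referenced_drivers():
            if name not in values:
                raise InvalidInputError(f"richness function references unknown driver {name!r}")
        out = None
        for t in self.terms:
            c = t.evaluate(values[t.driver])
            out = c if out is None else out + c
        if out is None:
            shape = next(iter(values.values())).shape if values else ()
            out = np.zeros(shape)
        for it in self.interactions:
            out = out + it.evaluate(values[it.drivers[0]], values[it.drivers[1]])
        return out + self.intercept

    def component(self, driver: str, x: np.ndarray) -> np.ndarray:
        """Sum of this driver's additive term responses at values ``x``
        (interactions excluded); used to check partial-dependence recovery."""
        out = np.zeros_like(np.asarray(x, dtype=float))
        for t in self.terms:
            if t.driver == driver:
                out = out + t.evaluate(np.asarray(x, dtype=float))
        return out


def default_richness_function(n_true_drivers: int = 3) -> RichnessFunction:
    """Additive function over the first ``n_true_drivers`` true drivers with
    decreasing weights and varied shapes (monotone, unimodal, convex)."""
    shapes = ["linear", "bump", "quadratic", "sigmoid", "sinus"]
    weights = [1.0, 0.8, 0.6, 0.5, 0.4]
    terms = [
        RichnessTerm(
            driver=f"driver_{i + 1:02d}",
            shape=shapes[i % len(shapes)],
            weight=weights[i % len(weights)],
        )
        for i in range(n_true_drivers)
    ]
    return RichnessFunction(intercept=0.2, terms=terms)


# ---------------------------------------------------------------------------
# configuration


@dataclass
class SyntheticWorldConfig:
    """Full description of a synthetic world; ``seed`` determines all output.

    Defaults emulate the statistical shape of the real compiled inputs:
    30 drivers (3 causal + 27 distractors), 0-1 scaled fields, ten years of
    monthly series with annual and semi-annual harmonics, species record
    counts log-uniform on [1, 1000], and a non-negative right-skewed
    richness response.
    """

    seed: int = 0
    n_species: int = 200
    n_true_drivers: int = 3
    n_distractor_drivers: int = 27
    spatial_correlation_length: float = 5.0  # cells (Gaussian kernel sd)
    n_months: int = 120
    # per-series (12-month, 6-month) sinusoid amplitudes
    seasonal_amplitudes: dict = field(
        default_factory=lambda: {
            "temperature": (0.8, 0.1),
            "production": (0.5, 0.4),
            "insolation": (1.0, 0.0),
        }
    )
    series_noise_sd: float = 0.05
    noise_sd: float = 0.05  # response-scale sd added to the richness function
    richness_function: RichnessFunction | None = None
    richness_link: str = "expm1"  # expm1 | identity
    ocean_fraction: float = 0.5  # area fraction assigned to the ocean mask
    species_domain: str = "both"  # ocean | land | both
    records_per_species: tuple = ("loguniform", 1, 1000)
    n_niche_drivers: int = 2
    niche_width_range: tuple[float, float] = (0.08, 0.3)
    range_retry_cap: int = 20

    def __post_init__(self) -> None:
        if self.n_true_drivers < 1:
            raise InvalidInputError("n_true_drivers must be >= 1")
        if self.noise_sd < 0:
            raise InvalidInputError("noise_sd must be >= 0")
        if self.richness_function is None:
            self.richness_function = default_richness_function(self.n_true_drivers)

    def rng(self, stage_offset: int, extra: int | None = None) -> np.random.Generator:
        key = [self.seed, stage_offset]
        if extra is not None:
            key.append(extra)
        return np.random.default_rng(key)


@dataclass
class DriverFieldSet:
    """Named static layers and monthly series sharing one grid."""

    grid: GridSpec
    static_layers: dict[str, RasterLayer]
    monthly_series: dict[str, RasterTimeSeries]

    def __post_init__(self) -> None:
        for layer in self.static_layers.values():
            if layer.grid is not self.grid:
                raise InvalidInputError("static layer on a different grid")
        lengths = {s.n_months for s in self.monthly_series.values()}
        if len(lengths) > 1:
            raise InvalidInputError(f"monthly series lengths differ: {lengths}")
        for s in self.monthly_series.values():
            if s.grid is not self.grid:
                raise InvalidInputError("monthly series on a different grid")

    @property
    def driver_names(self) -> list[str]:
        return sorted(self.static_layers) + sorted(self.monthly_series)

    def driver_values(self, name: str) -> np.ndarray:
        """2-D values of a driver: static layer, or temporal mean of a series."""
        if name in self.static_layers:
            return self.static_layers[name].values
        if name in self.monthly_series:
            return self.monthly_series[name].values.mean(axis=0)
        raise InvalidInputError(f"unknown driver {name!r}")


@dataclass
class SpeciesRange:
    species_id: str
    domain: str
    cells: np.ndarray  # flat cell ids
    niche: dict[str, tuple[float, float]]


@dataclass
class SpeciesRangeSet:
    grid: GridSpec
    species: list[SpeciesRange]

    def range_sizes(self) -> np.ndarray:
        return np.array([len(s.cells) for s in self.species])


@dataclass
class SpeciesOccurrenceSet:
    """Point occurrence records: one row per record.

    Columns: species_id, lon, lat, month_index, thermal_value.
    """

    table: pd.DataFrame

    REQUIRED = ("species_id", "lon", "lat", "month_index", "thermal_value")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise InvalidInputError(f"occurrence table missing columns {missing}")

    @property
    def species_ids(self) -> list[str]:
        return sorted(self.table["species_id"].unique())

    def counts(self) -> pd.Series:
        return self.table.groupby("species_id").size()

    def species_values(self, species_id: str, axis: str) -> np.ndarray:
        col = {"latitudinal": "lat", "thermal": "thermal_value"}.get(axis, axis)
        sub = self.table.loc[self.table["species_id"] == species_id, col]
        return sub.to_numpy(dtype=float)

    def subset(self, species_ids) -> "SpeciesOccurrenceSet":
        keep = self.table["species_id"].isin(list(species_ids))
        return SpeciesOccurrenceSet(self.table.loc[keep].reset_index(drop=True))

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "SpeciesOccurrenceSet":
        return cls(pd.read_csv(path))


# ---------------------------------------------------------------------------
# generators


def _random_field(rng: np.random.Generator, shape, corr_len: float) -> np.ndarray:
    """Spatially autocorrelated field in [0, 1]: Gaussian-smoothed white noise.

    The correlation length is the smoothing kernel sd in cell units; the
    grid wraps in longitude (axis 1) and reflects at the poles.
    """
    if corr_len <= 0:
        raise InvalidInputError("spatial correlation length must be > 0")
    white = rng.standard_normal(shape)
    smooth = gaussian_filter(white, sigma=corr_len, mode=("reflect", "wrap"))
    lo, hi = smooth.min(), smooth.max()
    if hi - lo < 1e-12:  # pathological (tiny grid); keep deterministic
        return np.full(shape, 0.5)
    return (smooth - lo) / (hi - lo)


def simulate_driver_fields(grid: GridSpec, config: SyntheticWorldConfig) -> DriverFieldSet:
    """Generate all driver fields and set the grid's land/ocean mask.

    Static layers: ``elevation`` plus ``driver_01..`` (causal) and
    ``distractor_01..`` fields, each an autocorrelated [0, 1] field.
    Monthly series: per :attr:`SyntheticWorldConfig.seasonal_amplitudes`,
    each cell is a smooth base value plus 12- and 6-month sinusoids with a
    spatially smooth phase field and white observation noise.

    The ocean mask is the lowest ``ocean_fraction`` of the elevation field
    (the world's "sea level"), so terrestrial and marine pipelines can run
    side by side.
    """
    rng = config.rng(_SEED_FIELDS)
    cl = config.spatial_correlation_length

    static: dict[str, RasterLayer] = {}
    elev = _random_field(rng, grid.shape, cl)
    static["elevation"] = RasterLayer(grid, elev, "elevation")
    for i in range(config.n_true_drivers):
        name = f"driver_{i + 1:02d}"
        static[name] = RasterLayer(grid, _random_field(rng, grid.shape, cl), name)
    for i in range(config.n_distractor_drivers):
        name = f"distractor_{i + 1:02d}"
        static[name] = RasterLayer(grid, _random_field(rng, grid.shape, cl), name)

    t = np.arange(config.n_months, dtype=float)
    series: dict[str, RasterTimeSeries] = {}
    for name in sorted(config.seasonal_amplitudes):
        a12, a6 = config.seasonal_amplitudes[name]
        base = _random_field(rng, grid.shape, cl)
        phase12 = 2 * np.pi * _random_field(rng, grid.shape, cl)
        phase6 = 2 * np.pi * _random_field(rng, grid.shape, cl)
        cyc = a12 * np.cos(2 * np.pi * t[:, None, None] / 12.0 + phase12[None]) + a6 * np.cos(
            2 * np.pi * t[:, None, None] / 6.0 + phase6[None]
        )
        noise = (
            rng.standard_normal((config.n_months,) + grid.shape) * config.series_noise_sd
            if config.series_noise_sd > 0
            else 0.0
        )
        series[name] = RasterTimeSeries(grid, base[None] + cyc + noise, name)

    sea_level = np.quantile(elev, config.ocean_fraction)
    grid.mask = np.where(elev < sea_level, OCEAN, LAND).astype(np.int8)
    return DriverFieldSet(grid, static, series)


def simulate_species_ranges(
    drivers: DriverFieldSet,
    config: SyntheticWorldConfig,
) -> SpeciesRangeSet:
    """Draw a niche (driver intervals) per species; range = cells satisfying it.

    Niche centres are the driver values at a random cell of the species'
    domain, so ranges are never empty by construction unless the interval
    is extremely narrow; empty draws are retried up to ``range_retry_cap``.
    """
    grid = drivers.grid
    rng = config.rng(_SEED_RANGES)
    niche_pool = [n for n in sorted(drivers.static_layers) if n != "elevation"]
    if not niche_pool:
        raise InvalidInputError("no niche drivers available")
    k = min(config.n_niche_drivers, len(niche_pool))

    species: list[SpeciesRange] = []
    for i in range(config.n_species):
        if config.species_domain == "both":
            domain = "ocean" if i < config.n_species // 2 else "land"
        else:
            domain = config.species_domain
        dom_mask = grid.domain_mask(domain)
        dom_cells = np.flatnonzero(dom_mask.ravel())
        if dom_cells.size == 0:
            raise GenerationError(f"species {i}: domain {domain!r} has no cells")
        for attempt in range(config.range_retry_cap):
            chosen = list(rng.choice(niche_pool, size=k, replace=False))
            centre_cell = rng.choice(dom_cells)
            r, c = divmod(int(centre_cell), grid.n_cols)
            niche: dict[str, tuple[float, float]] = {}
            ok = np.array(dom_mask)
            for name in chosen:
                vals = drivers.static_layers[name].values
                centre = vals[r, c]
                half = rng.uniform(*config.niche_width_range)
                lo, hi = centre - half, centre + half
                niche[name] = (float(lo), float(hi))
                ok &= (vals >= lo) & (vals <= hi)
            cells = np.flatnonzero(ok.ravel())
            if cells.size > 0:
                species.append(
                    SpeciesRange(f"sp_{i + 1:04d}", domain, cells, niche)
                )
                break
        else:
            raise GenerationError(
                f"species {i}: empty range after {config.range_retry_cap} retries"
            )
    return SpeciesRangeSet(grid, species)


def stack_ranges_to_richness(
    ranges: SpeciesRangeSet, grid: GridSpec, domain: str | None = None
) -> RasterLayer:
    """Cell value = number of species whose range contains the cell.

    Cells outside ``domain`` (or excluded cells) are NaN.
    """
    if ranges.grid is not grid:
        raise InvalidInputError("ranges were built on a different grid")
    counts = np.zeros(grid.n_cells, dtype=float)
    for sp in ranges.species:
        if domain is not None and sp.domain != domain:
            continue
        counts[sp.cells] += 1
    values = counts.reshape(grid.shape)
    values = np.where(grid.domain_mask(domain), values, np.nan)
    return RasterLayer(grid, values, "richness")


def _record_counts(rng: np.random.Generator, spec, n_species: int) -> np.ndarray:
    if isinstance(spec, (list, tuple)) and spec and spec[0] == "loguniform":
        lo, hi = int(spec[1]), int(spec[2])
        u = rng.uniform(math.log(lo), math.log(hi + 1), size=n_species)
        return np.clip(np.floor(np.exp(u)).astype(int), lo, hi)
    if np.isscalar(spec):
        return np.full(n_species, int(spec))
    arr = np.asarray(spec, dtype=int)
    if arr.size != n_species:
        raise InvalidInputError("records_per_species array length != n_species")
    return arr


def simulate_occurrences(
    ranges: SpeciesRangeSet,
    drivers: DriverFieldSet,
    records_per_species=None,
    seed: int | None = None,
    config: SyntheticWorldConfig | None = None,
) -> SpeciesOccurrenceSet:
    """Sample point records uniformly over each species' range cells.

    Each record gets a position jittered uniformly inside its cell, a random
    month index, and as thermal value the temporal mean of the temperature
    series at its cell (how thermal values attach to records is a package
    convention; see docs/methods.md).
    """
    grid = ranges.grid
    if config is not None:
        records_per_species = records_per_species or config.records_per_species
        rng = config.rng(_SEED_OCC)
    else:
        rng = np.random.default_rng(0 if seed is None else seed)
        records_per_species = records_per_species or ("loguniform", 1, 1000)
    if "temperature" not in drivers.monthly_series:
        raise InvalidInputError("drivers must include a 'temperature' monthly series")
    temp_mean = drivers.monthly_series["temperature"].values.mean(axis=0).ravel()
    n_months = drivers.monthly_series["temperature"].n_months

    counts = _record_counts(rng, records_per_species, len(ranges.species))
    if np.any(counts < 1):
        raise InvalidInputError("record counts must be >= 1")

    rows = []
    for sp, n in zip(ranges.species, counts):
        if sp.cells.size == 0:
            raise GenerationError(f"species {sp.species_id} has an empty range")
        cells = rng.choice(sp.cells, size=int(n), replace=True)
        r, c = np.divmod(cells, grid.n_cols)
        lat_lo, lat_hi, lon_lo, lon_hi = grid.cell_bounds(r, c)
        lat = rng.uniform(lat_lo, lat_hi)
        lon = rng.uniform(lon_lo, lon_hi)
        month = rng.integers(0, n_months, size=int(n))
        rows.append(
            pd.DataFrame(
                {
                    "species_id": sp.species_id,
                    "lon": lon,
                    "lat": lat,
                    "month_index": month,
                    "thermal_value": temp_mean[cells],
                }
            )
        )
    table = pd.concat(rows, ignore_index=True)
    return SpeciesOccurrenceSet(table)


def true_richness_function(
    drivers: DriverFieldSet,
    config: SyntheticWorldConfig,
    include_noise: bool = True,
    link: str | None = None,
) -> RasterLayer:
    """Evaluate the configured driver->richness function on the grid.

    Gaussian noise with sd ``config.noise_sd`` is added on the response
    (pre-link) scale; pass ``include_noise=False`` for the noiseless truth.
    ``link='expm1'`` maps the response to a count-like richness scale;
    ``'identity'`` returns the function value itself.
    """
    grid = drivers.grid
    link = link or config.richness_link
    values = {name: drivers.driver_values(name) for name in drivers.driver_names}
    eta = config.richness_function.evaluate(values)
    if include_noise and config.noise_sd > 0:
        eta = eta + config.rng(_SEED_NOISE).standard_normal(grid.shape) * config.noise_sd
    if link == "identity":
        out = eta
    elif link == "expm1":
        out = np.expm1(np.maximum(eta, 0.0))
    else:
        raise InvalidInputError(f"unknown richness link {link!r}")
    out = np.where(grid.domain_mask(None), out, np.nan)
    return RasterLayer(grid, out, "richness")


# ---------------------------------------------------------------------------
# bundled world


@dataclass
class SyntheticWorld:
    config: SyntheticWorldConfig
    grid: GridSpec
    drivers: DriverFieldSet
    ranges: SpeciesRangeSet
    occurrences: SpeciesOccurrenceSet
    richness: RasterLayer  # function-derived, with noise, link applied
    richness_noiseless: RasterLayer


def generate_world(
    config: SyntheticWorldConfig, grid: GridSpec | None = None
) -> SyntheticWorld:
    """Generate a full world (drivers, mask, ranges, occurrences, richness)."""
    if grid is None:
        grid = make_grid((-65.0, 65.0, -180.0, 180.0), cell_km=250.0)
    drivers = simulate_driver_fields(grid, config)
    ranges = simulate_species_ranges(drivers, config)
    occurrences = simulate_occurrences(ranges, drivers, config=config)
    richness = true_richness_function(drivers, config, include_noise=True)
    noiseless = true_richness_function(drivers, config, include_noise=False)
    return SyntheticWorld(config, grid, drivers, ranges, occurrences, richness, noiseless)


# ---------------------------------------------------------------------------
# I/O


def write_drivers_netcdf(drivers: DriverFieldSet, path) -> None:
    """Write static layers and monthly series to one NetCDF3 file."""
    import xarray as xr

    arrays = {name: layer.to_xarray() for name, layer in drivers.static_layers.items()}
    arrays.update({name: s.to_xarray() for name, s in drivers.monthly_series.items()})
    xr.Dataset(arrays).to_netcdf(path, engine="scipy")


def config_to_yaml(config: SyntheticWorldConfig, path) -> None:
    import yaml

    d = asdict(config)
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=True)
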
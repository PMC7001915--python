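"""Feature engineering: series summaries, quantile truncation, 0-1 scaling,
and Morlet-wavelet seasonal-intensity metrics.

Driver layers and monthly stacks become one model-ready table with a row
per grid cell.  Summaries follow the intra-/inter-annual convention:
intra-annual statistics see only the 12-month climatology (per-cell monthly
means across years, ``sub`` prefix), inter-annual statistics act across
annual aggregates (``ann`` prefix).  Seasonal phenology intensity is the
time-averaged continuous-wavelet (Morlet, omega0 = 6) power at the 6- and
12-month periods.  All features are truncated to the 1%/99% quantiles
(elevation/depth exempt), affinely rescaled to [0, 1], and the response is
0-1 rescaled ln(richness + 1); every transform parameter is kept so
predictions can be mapped back to the original richness scale.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pywt

from .grids import GridSpec, InvalidInputError, RasterLayer, RasterTimeSeries
from .synthetic import DriverFieldSet

logger = logging.getLogger(__name__)

# Morlet parameters: omega0 = 6 (standard), geometric scales, 12 sub-octaves
MORLET_OMEGA0 = 6.0
_FC = MORLET_OMEGA0 / (2.0 * np.pi)  # centre frequency in cycles/sample at scale 1
_WAVELET = f"cmor2.0-{_FC}"  # bandwidth 2.0 reproduces exp(-t^2/2) envelope
SUBOCTAVES = 12
BAND_HALFWIDTH_MONTHS = 1.0
# e-folding (cone-of-influence) extent in samples per unit Fourier period
_COI_FACTOR = np.sqrt(2.0) * (MORLET_OMEGA0 + np.sqrt(2.0 + MORLET_OMEGA0**2)) / (4.0 * np.pi)

STATISTICS = ("mean", "sd", "range", "cv", "wavelet_intensity_6", "wavelet_intensity_12", "annual_sum", "identity")
SCOPES = ("intra-annual", "inter-annual", "static")


@dataclass
class FeatureDefinition:
    """One feature: a statistic of a driver at a temporal scope."""

    source: str
    statistic: str = "identity"
    scope: str = "static"

    def __post_init__(self) -> None:
        if self.statistic not in STATISTICS:
            raise InvalidInputError(f"unknown statistic {self.statistic!r}")
        if self.scope not in SCOPES:
            raise InvalidInputError(f"unknown scope {self.scope!r}")
        if self.scope == "static" and self.statistic != "identity":
            raise InvalidInputError("static sources admit only the identity statistic")
        if self.statistic.startswith("wavelet") and self.scope == "static":
            raise InvalidInputError("wavelet statistics require a monthly series source")

    @property
    def name(self) -> str:
        if self.statistic == "identity":
            return self.source
        if self.statistic == "wavelet_intensity_6":
            return f"{self.source}_amp6"
        if self.statistic == "wavelet_intensity_12":
            return f"{self.source}_amp12"
        prefix = "sub" if self.scope == "intra-annual" else "ann"
        return f"{prefix}_{self.source}_{self.statistic}"


# ---------------------------------------------------------------------------
# temporal summaries


def _apply_stat(values: np.ndarray, statistic: str) -> np.ndarray:
    """Statistic across axis 0 (months-of-climatology or years)."""
    if statistic == "mean":
        return values.mean(axis=0)
    if statistic == "sd":
        return values.std(axis=0, ddof=1)
    if statistic == "range":
        return values.max(axis=0) - values.min(axis=0)
    if statistic == "cv":
        m = values.mean(axis=0)
        s = values.std(axis=0, ddof=1)
        out = np.zeros_like(m)
        ok = np.abs(m) > 1e-9
        out[ok] = s[ok] / m[ok]
        if not ok.all():
            logger.warning("cv: %d cells with |mean| < 1e-9 set to 0", int((~ok).sum()))
        return out
    raise InvalidInputError(f"unknown statistic {statistic!r}")


def summarize_series(
    series: RasterTimeSeries, statistic: str, scope: str = "intra-annual"
) -> RasterLayer:
    """Per-cell temporal summary of a monthly stack.

    intra-annual: statistic of the 12 climatology values (monthly means
    across years); inter-annual: statistic across annual means;
    annual_sum: mean across years of the 12-month sums.
    """
    T = series.n_months
    if T % 12 != 0:
        raise InvalidInputError(f"series length {T} is not a multiple of 12")
    years = series.values.reshape(T // 12, 12, *series.grid.shape)
    if statistic == "annual_sum":
        out = years.sum(axis=1).mean(axis=0)
    elif scope == "intra-annual":
        clim = years.mean(axis=0)  # (12, rows, cols)
        out = _apply_stat(clim, statistic)
    elif scope == "inter-annual":
        annual = years.mean(axis=1)  # (n_years, rows, cols)
        if annual.shape[0] < 2 and statistic in ("sd", "range", "cv"):
            raise InvalidInputError("inter-annual variability needs >= 2 years")
        out = _apply_stat(annual, statistic)
    else:
        raise InvalidInputError(f"unknown scope {scope!r}")
    prefix = "sub" if scope == "intra-annual" else "ann"
    return RasterLayer(series.grid, out, f"{prefix}_{series.name}_{statistic}")


# ---------------------------------------------------------------------------
# wavelet seasonal intensity


def _band_scales(periods_target, max_period: float | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Geometric scale grid (12 sub-octaves) and corresponding Fourier periods."""
    top = max(max(periods_target) + 2.0, max_period or 0.0)
    n = int(np.ceil(SUBOCTAVES * np.log2(top / 2.0))) + 1
    periods = 2.0 * 2.0 ** (np.arange(n + 1) / SUBOCTAVES)
    scales = periods * _FC  # pywt: Fourier period = scale / fc
    return scales, periods


def _coi_valid(T: int, period: float) -> np.ndarray:
    """Time indices outside the cone of influence for a given period."""
    margin = int(np.ceil(_COI_FACTOR * period))
    t = np.arange(T)
    return (t >= margin) & (t <= T - 1 - margin)


def _band_power(power: np.ndarray, periods: np.ndarray, target: float, T: int) -> np.ndarray:
    """Scale-rectified average power over band scales and COI-valid times.

    ``power`` has shape (n_scales, ..., T); returns shape (...,).  Raw
    wavelet power grows with scale for equal-amplitude oscillations, so
    each scale's power is divided by its scale (standard spectral-bias
    rectification) before averaging — this makes the 6- and 12-month
    intensities comparable.
    """
    in_band = np.abs(periods - target) <= BAND_HALFWIDTH_MONTHS
    if not in_band.any():
        in_band = np.isclose(periods, periods[np.argmin(np.abs(periods - target))])
    valid = _coi_valid(T, target)
    if not valid.any():
        valid = np.ones(T, dtype=bool)  # COI-dominated; caller warned
    scales = (periods[in_band] * _FC).reshape((-1,) + (1,) * (power.ndim - 1))
    return (power[in_band] / scales)[..., valid].mean(axis=(0, -1))


def morlet_power(series_1cell, periods=(6.0, 12.0), return_flags: bool = False):
    """Time-averaged Morlet wavelet power at the requested periods (months).

    The series is mean-removed; power outside the cone of influence is
    excluded from the time average.  Returns ``{period: power}`` (and a
    ``{period: coi_dominated}`` flag map when ``return_flags``).
    """
    x = np.asarray(series_1cell, dtype=float)
    if x.ndim != 1 or x.size < 48:
        raise InvalidInputError("morlet_power needs a 1-D series of >= 48 months")
    T = x.size
    flags = {}
    for p in periods:
        flags[p] = bool(T < 4 * p or not _coi_valid(T, p).any())
        if flags[p]:
            warnings.warn(
                f"series length {T} < 4x period {p}: power is cone-of-influence dominated",
                stacklevel=2,
            )
    scales, all_periods = _band_scales(periods)
    coef, _ = pywt.cwt(x - x.mean(), scales, _WAVELET, sampling_period=1.0)
    power = np.abs(coef) ** 2
    out = {p: float(_band_power(power, all_periods, p, T)) for p in periods}
    if return_flags:
        return out, flags
    return out


def seasonal_intensity(
    series: RasterTimeSeries, period: float, chunk_cells: int = 4096
) -> RasterLayer:
    """Per-cell mean wavelet power in the band around ``period`` (6 or 12 months)."""
    T = series.n_months
    if T < 48:
        raise InvalidInputError("seasonal_intensity needs >= 48 months")
    if T < 4 * period:
        warnings.warn(
            f"series length {T} < 4x period {period}: power is cone-of-influence dominated",
            stacklevel=2,
        )
    scales, all_periods = _band_scales([period])
    in_band = np.abs(all_periods - period) <= BAND_HALFWIDTH_MONTHS
    scales, all_periods = scales[in_band], all_periods[in_band]

    flat = series.values.reshape(T, -1).T  # (cells, T)
    flat = flat - flat.mean(axis=1, keepdims=True)
    out = np.empty(flat.shape[0])
    for start in range(0, flat.shape[0], chunk_cells):
        block = flat[start : start + chunk_cells]
        coef, _ = pywt.cwt(block, scales, _WAVELET, sampling_period=1.0, axis=-1)
        power = np.abs(coef) ** 2  # (n_scales, cells, T)
        out[start : start + block.shape[0]] = _band_power(power, all_periods, period, T)
    name = f"{series.name}_amp{int(period)}"
    return RasterLayer(series.grid, out.reshape(series.grid.shape), name)


# ---------------------------------------------------------------------------
# truncation and scaling


def truncate_quantiles(layer: RasterLayer, lo: float = 0.01, hi: float = 0.99) -> RasterLayer:
    """Clamp values below/above the lo/hi quantiles to those quantiles."""
    finite = layer.values[np.isfinite(layer.values)]
    if finite.size == 0:
        raise InvalidInputError(f"layer {layer.name!r} has no finite values")
    if np.all(finite == finite[0]):
        logger.warning("truncate_quantiles: layer %r is constant, returned unchanged", layer.name)
        return layer.copy_with(layer.values.copy())
    qlo, qhi = np.nanquantile(layer.values, [lo, hi])
    return layer.copy_with(np.clip(layer.values, qlo, qhi))


def rescale_unit(layer: RasterLayer) -> tuple[RasterLayer, tuple[float, float]]:
    """Affine map of a layer to [0, 1]; returns the (min, max) provenance."""
    finite = layer.values[np.isfinite(layer.values)]
    if finite.size == 0:
        raise InvalidInputError(f"layer {layer.name!r} has no finite values")
    vmin, vmax = float(finite.min()), float(finite.max())
    if vmax - vmin < 1e-12:
        raise InvalidInputError(f"layer {layer.name!r} is constant; 0-1 scaling undefined")
    return layer.copy_with((layer.values - vmin) / (vmax - vmin)), (vmin, vmax)


# ---------------------------------------------------------------------------
# feature table


@dataclass
class FeatureTable:
    """Model-ready table: one row per in-mask grid cell.

    ``data`` holds cell_id, lon, lat, the 0-1 scaled features and the 0-1
    scaled ln(x+1) response; ``provenance`` stores every transform
    parameter (per-feature quantiles and min/max, response min/max) needed
    to invert predictions back to raw richness.
    """

    data: pd.DataFrame
    feature_names: list[str]
    provenance: dict
    grid: GridSpec | None = None

    @property
    def n_rows(self) -> int:
        return len(self.data)

    @property
    def X(self) -> np.ndarray:
        return self.data[self.feature_names].to_numpy(dtype=float)

    @property
    def y(self) -> np.ndarray:
        return self.data["response"].to_numpy(dtype=float)

    def inverse_response(self, y_scaled) -> np.ndarray:
        """Map scaled predictions back to the raw richness scale."""
        lo, hi = self.provenance["response"]["min"], self.provenance["response"]["max"]
        return np.expm1(np.asarray(y_scaled) * (hi - lo) + lo)

    def select_rows(self, idx) -> "FeatureTable":
        return FeatureTable(
            self.data.iloc[idx].reset_index(drop=True),
            list(self.feature_names),
            self.provenance,
            self.grid,
        )

    def to_csv(self, path, sidecar: bool = True) -> None:
        self.data.to_csv(path, index=False)
        if sidecar:
            with open(str(path) + ".provenance.json", "w") as fh:
                json.dump(self.provenance, fh, indent=1, sort_keys=True)

    @classmethod
    def from_csv(cls, path) -> "FeatureTable":
        data = pd.read_csv(path)
        try:
            with open(str(path) + ".provenance.json") as fh:
                provenance = json.load(fh)
        except FileNotFoundError:
            provenance = {"features": {}, "response": {"min": 0.0, "max": 1.0}}
        reserved = {"cell_id", "lon", "lat", "response"}
        names = [c for c in data.columns if c not in reserved]
        return cls(data, names, provenance)


def build_feature_table(
    layers: dict[str, RasterLayer],
    richness: RasterLayer,
    mask: np.ndarray | None = None,
    truncate: bool = True,
    truncation_exempt: tuple = ("elevation", "depth"),
    lo: float = 0.01,
    hi: float = 0.99,
) -> FeatureTable:
    """Assemble the scaled feature table and ln(x+1) response.

    ``mask`` selects the cells (rows); by default every cell where the
    richness layer is finite.  Quantile truncation and 0-1 scaling are
    computed over the masked domain only.  Constant features are dropped
    with a warning (their 0-1 scaling is undefined).
    """
    grid = richness.grid
    for name, layer in layers.items():
        if layer.grid is not grid:
            raise InvalidInputError(f"layer {name!r} is on a different grid")
    if mask is None:
        mask = np.isfinite(richness.values)
    mask = np.asarray(mask, dtype=bool) & np.isfinite(richness.values)

    rich = richness.values[mask]
    if np.any(rich < 0):
        raise InvalidInputError("richness must be non-negative")

    flat_ids = grid.cell_ids()[mask]
    data = {
        "cell_id": flat_ids,
        "lon": grid.lon_grid()[mask],
        "lat": grid.lat_grid()[mask],
    }
    provenance: dict = {"features": {}, "truncation_quantiles": [lo, hi]}
    feature_names: list[str] = []
    for name in layers:
        sub = RasterLayer(grid, np.where(mask, layers[name].values, np.nan), name)
        truncated = truncate and name not in truncation_exempt
        if truncated:
            qlo, qhi = np.nanquantile(sub.values, [lo, hi])
            sub = sub.copy_with(np.clip(sub.values, qlo, qhi))
        else:
            qlo = qhi = None
        try:
            scaled, (vmin, vmax) = rescale_unit(sub)
        except InvalidInputError:
            logger.warning("feature %r is constant over the mask; dropped", name)
            continue
        data[name] = scaled.values[mask]
        feature_names.append(name)
        provenance["features"][name] = {
            "truncated": truncated,
            "q_lo": None if qlo is None else float(qlo),
            "q_hi": None if qhi is None else float(qhi),
            "min": vmin,
            "max": vmax,
        }

    log_rich = np.log1p(rich)
    rmin, rmax = float(log_rich.min()), float(log_rich.max())
    if rmax - rmin < 1e-12:
        logger.warning("response is constant (all-equal richness); emitted as all-zero")
        response = np.zeros_like(log_rich)
        rmax = rmin + 1.0
    else:
        response = (log_rich - rmin) / (rmax - rmin)
    data["response"] = response
    provenance["response"] = {"min": rmin, "max": rmax, "transform": "ln(x+1) then 0-1"}

    table = pd.DataFrame(data)
    return FeatureTable(table, feature_names, provenance, grid)


def default_feature_definitions(drivers: DriverFieldSet) -> list[FeatureDefinition]:
    """Identity features for static layers; for each monthly series the
    intra-annual mean/sd/range/cv, inter-annual mean/sd, and 6-/12-month
    wavelet intensities."""
    defs = [FeatureDefinition(n) for n in sorted(drivers.static_layers)]
    for n in sorted(drivers.monthly_series):
        defs += [
            FeatureDefinition(n, "mean", "intra-annual"),
            FeatureDefinition(n, "sd", "intra-annual"),
            FeatureDefinition(n, "range", "intra-annual"),
            FeatureDefinition(n, "cv", "intra-annual"),
            FeatureDefinition(n, "mean", "inter-annual"),
            FeatureDefinition(n, "sd", "inter-annual"),
            FeatureDefinition(n, "wavelet_intensity_6", "intra-annual"),
            FeatureDefinition(n, "wavelet_intensity_12", "intra-annual"),
        ]
    return defs


def compute_features(
    drivers: DriverFieldSet, definitions: list[FeatureDefinition] | None = None
) -> dict[str, RasterLayer]:
    """Evaluate feature definitions into named raw (unscaled) layers."""
    if definitions is None:
        definitions = default_feature_definitions(drivers)
    out: dict[str, RasterLayer] = {}
    for d in definitions:
        if d.statistic == "identity":
            out[d.name] = drivers.static_layers[d.source]
        elif d.statistic == "wavelet_intensity_6":
            out[d.name] = seasonal_intensity(drivers.monthly_series[d.source], 6.0)
        elif d.statistic == "wavelet_intensity_12":
            out[d.name] = seasonal_intensity(drivers.monthly_series[d.source], 12.0)
        else:
            out[d.name] = summarize_series(drivers.monthly_series[d.source], d.statistic, d.scope)
    return out
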
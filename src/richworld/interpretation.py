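"""Model interrogation: bootstrapped noise-perturbation importance,
partial dependence, loess curve ensembles, residual maps, zonal profiles,
and empirical semivariograms.

Variable importance is estimated by an ensemble of retrained networks:
each rep trains a fresh model on a random subset of the rows, records a
baseline held-out R^2, then replaces one feature column at a time with
resampled noise (the feature's own values sampled with replacement, which
breaks the association while preserving the marginal) and records the drop
in R^2.  The resulting per-feature Delta-R^2 densities are ranked by their
medians.

Partial dependence sweeps one or two features over their range while the
remaining features follow the data distribution (every row is evaluated at
each grid point and predictions averaged).  Residual diagnostics follow
the convention residual = observed - predicted (positive = underpredicted).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ann import AnnConfig, TrainedRichnessModel, predict, train_ann
from .features import FeatureTable
from .grids import InvalidInputError, RasterLayer

# ---------------------------------------------------------------------------
# bootstrapped noise-perturbation importance


@dataclass
class ImportanceDistribution:
    """Per-feature Delta-R^2 samples across bootstrap-retrained models."""

    reps: pd.DataFrame  # columns: feature, rep, delta_r2, baseline_r2
    n_reps: int
    subset_fraction: float
    noise: str

    def features(self) -> list[str]:
        return sorted(self.reps["feature"].unique())

    def summary(self) -> pd.DataFrame:
        g = self.reps.groupby("feature")["delta_r2"]
        out = g.median().to_frame("median")
        out["q025"] = g.quantile(0.025)
        out["q975"] = g.quantile(0.975)
        return out.reset_index()


def permutation_importance(
    table: FeatureTable,
    config: AnnConfig,
    n_reps: int = 500,
    subset_fraction: float = 0.8,
    seed: int = 0,
    noise: str = "bootstrap",
    inner_test_fraction: float = 0.2,
    features: list[str] | None = None,
) -> ImportanceDistribution:
    """Delta-R^2 importance over ``n_reps`` retrained models.

    Per rep: draw ``subset_fraction`` of the rows without replacement,
    train a fresh network on 80% of the subset, measure baseline R^2 on
    the remaining 20%, then perturb one feature at a time on those
    held-out rows and record Delta-R^2 = baseline - perturbed.

    ``noise='bootstrap'`` resamples the feature's own column with
    replacement; ``'uniform'`` draws Uniform(0, 1) values.
    """
    if noise not in ("bootstrap", "uniform"):
        raise InvalidInputError(f"unknown noise kind {noise!r}")
    feats = features or list(table.feature_names)
    n = table.n_rows
    n_sub = int(round(subset_fraction * n))
    n_test = int(round(inner_test_fraction * n_sub))
    if n_sub - n_test < config.batch_size or n_test < 2:
        raise InvalidInputError("subset too small to train and evaluate")
    X_all, y_all = table.X, table.y
    col = {f: i for i, f in enumerate(table.feature_names)}

    rows = []
    for rep in range(n_reps):
        rng = np.random.default_rng([seed, rep])
        sub = rng.choice(n, size=n_sub, replace=False)
        test_idx = sub[:n_test]
        train_idx = sub[n_test:]
        rep_config = AnnConfig(**{**config.__dict__, "seed": int(rng.integers(2**31))})
        model = train_ann(table, rep_config, row_indices=train_idx)

        X_test, y_test = X_all[test_idx], y_all[test_idx]
        sst = float(np.sum((y_test - y_test.mean()) ** 2))
        if sst <= 0:
            raise InvalidInputError("zero-variance held-out response in importance rep")

        def r2(Xm):
            sse = float(np.sum((y_test - predict(model, Xm)) ** 2))
            return 1.0 - sse / sst

        baseline = r2(X_test)
        for f in feats:
            Xp = X_test.copy()
            if noise == "bootstrap":
                Xp[:, col[f]] = rng.choice(X_all[:, col[f]], size=n_test, replace=True)
            else:
                Xp[:, col[f]] = rng.random(n_test)
            rows.append(
                {
                    "feature": f,
                    "rep": rep,
                    "delta_r2": baseline - r2(Xp),
                    "baseline_r2": baseline,
                }
            )
    return ImportanceDistribution(pd.DataFrame(rows), n_reps, subset_fraction, noise)


def rank_importance(dist: ImportanceDistribution) -> pd.DataFrame:
    """Features ordered by descending median Delta-R^2 (ties alphabetical)."""
    s = dist.summary().sort_values(
        ["median", "feature"], ascending=[False, True], kind="mergesort"
    )
    s = s.reset_index(drop=True)
    s.insert(0, "rank", np.arange(1, len(s) + 1))
    return s


# ---------------------------------------------------------------------------
# partial dependence


@dataclass
class PDSurface:
    var_x: str
    var_y: str
    grid_x: np.ndarray
    grid_y: np.ndarray
    surface: np.ndarray  # (len(grid_y), len(grid_x)) mean prediction
    covered: np.ndarray  # same shape; joint data coverage flags

    def to_dataframe(self) -> pd.DataFrame:
        gx, gy = np.meshgrid(self.grid_x, self.grid_y)
        return pd.DataFrame(
            {
                self.var_x: gx.ravel(),
                self.var_y: gy.ravel(),
                "mean_prediction": self.surface.ravel(),
                "covered": self.covered.ravel(),
            }
        )


def partial_dependence(
    model: TrainedRichnessModel,
    table: FeatureTable,
    variables,
    resolution: int = 25,
    mode: str = "data",
):
    """Partial dependence of the model on one or two features.

    ``mode='data'`` (default): at every grid point all table rows are
    evaluated with the swept feature(s) pinned and predictions averaged,
    so the remaining inputs co-vary as in the data.  ``mode='mean-pin'``
    pins all other features at their means instead.

    Returns a DataFrame (one variable) or a :class:`PDSurface` (two).
    Coverage flags mark grid points supported by observed data (marginal
    range for curves; occupied joint histogram bins for surfaces).
    """
    if isinstance(variables, str):
        variables = [variables]
    if not (1 <= len(variables) <= 2):
        raise InvalidInputError("partial dependence takes 1 or 2 features")
    for v in variables:
        if v not in model.feature_names:
            raise InvalidInputError(f"unknown feature {v!r}")
    col = {f: i for i, f in enumerate(model.feature_names)}
    X = table.X
    if mode == "mean-pin":
        X_base = X.mean(axis=0, keepdims=True)
    elif mode == "data":
        X_base = X
    else:
        raise InvalidInputError(f"unknown mode {mode!r}")

    def grid_for(v):
        vals = X[:, col[v]]
        return np.linspace(vals.min(), vals.max(), resolution)

    if len(variables) == 1:
        v = variables[0]
        g = grid_for(v)
        means = np.empty(resolution)
        for i, x0 in enumerate(g):
            Xs = X_base.copy()
            Xs[:, col[v]] = x0
            means[i] = predict(model, Xs).mean()
        vals = X[:, col[v]]
        covered = (g >= vals.min()) & (g <= vals.max())
        return pd.DataFrame({v: g, "mean_prediction": means, "covered": covered})

    vx, vy = variables
    gx, gy = grid_for(vx), grid_for(vy)
    surface = np.empty((resolution, resolution))
    for j, y0 in enumerate(gy):
        for i, x0 in enumerate(gx):
            Xs = X_base.copy()
            Xs[:, col[vx]] = x0
            Xs[:, col[vy]] = y0
            surface[j, i] = predict(model, Xs).mean()
    hist, _, _ = np.histogram2d(
        X[:, col[vx]],
        X[:, col[vy]],
        bins=[_edges_from_centres(gx), _edges_from_centres(gy)],
    )
    covered = hist.T > 0
    return PDSurface(vx, vy, gx, gy, surface, covered)


def _edges_from_centres(centres: np.ndarray) -> np.ndarray:
    step = centres[1] - centres[0] if centres.size > 1 else 1.0
    return np.concatenate([centres - step / 2, [centres[-1] + step / 2]])


# ---------------------------------------------------------------------------
# loess curve ensembles


@dataclass
class CurveEnsemble:
    feature: str
    grid: np.ndarray
    median: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    n_reps: int
    subsample_size: int

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                self.feature: self.grid,
                "median": self.median,
                "lower95": self.lower,
                "upper95": self.upper,
            }
        )


def pairwise_loess_ensemble(
    table: FeatureTable,
    feature: str,
    n_sub: int = 10000,
    n_reps: int = 100,
    span: float = 0.75,
    grid_size: int = 50,
    seed: int = 0,
) -> CurveEnsemble:
    """Median and 95% quantile band of local-regression fits over resamples.

    Each rep subsamples ``n_sub`` rows uniformly (clamped to the table size
    with a warning when smaller), fits a lowess smoother of the response on
    the feature, and evaluates it on a fixed grid; pointwise medians and
    2.5%/97.5% quantiles are taken across reps.
    """
    import warnings

    from statsmodels.nonparametric.smoothers_lowess import lowess

    if feature not in table.feature_names:
        raise InvalidInputError(f"unknown feature {feature!r}")
    x = table.data[feature].to_numpy(dtype=float)
    y = table.y
    if np.ptp(x) < 1e-12:
        raise InvalidInputError(f"feature {feature!r} is constant")
    if n_sub > x.size:
        warnings.warn(f"n_sub {n_sub} > {x.size} rows; clamped", stacklevel=2)
        n_sub = x.size
    grid = np.linspace(x.min(), x.max(), grid_size)
    rng = np.random.default_rng(seed)
    curves = np.empty((n_reps, grid_size))
    for r in range(n_reps):
        idx = rng.choice(x.size, size=n_sub, replace=False)
        curves[r] = lowess(y[idx], x[idx], frac=span, xvals=grid)
    return CurveEnsemble(
        feature=feature,
        grid=grid,
        median=np.median(curves, axis=0),
        lower=np.quantile(curves, 0.025, axis=0),
        upper=np.quantile(curves, 0.975, axis=0),
        n_reps=n_reps,
        subsample_size=n_sub,
    )


# ---------------------------------------------------------------------------
# residual diagnostics


@dataclass
class ResidualMap:
    """observed - predicted on the scaled response (positive = underpredicted)."""

    layer: RasterLayer
    summary: dict = field(default_factory=dict)


def residual_map(observed: RasterLayer, predicted: RasterLayer) -> ResidualMap:
    if observed.grid is not predicted.grid:
        raise InvalidInputError("observed and predicted are on different grids")
    res = observed.values - predicted.values
    finite = res[np.isfinite(res)]
    summary = {
        "n": int(finite.size),
        "mean": float(finite.mean()) if finite.size else np.nan,
        "sd": float(finite.std()) if finite.size else np.nan,
        "min": float(finite.min()) if finite.size else np.nan,
        "max": float(finite.max()) if finite.size else np.nan,
    }
    return ResidualMap(RasterLayer(observed.grid, res, "residual"), summary)


def zonal_profile(layer: RasterLayer, bin_deg: float = 2.0) -> pd.DataFrame:
    """Mean of a layer in half-open latitude bins [b, b + bin_deg) over [-90, 90).

    Empty bins carry NaN and n_cells = 0; the cell-weighted recombination
    of bin means equals the layer's global mean (cells have equal area).
    """
    edges = np.arange(-90.0, 90.0 + bin_deg, bin_deg)
    lat = layer.grid.lat_grid().ravel()
    vals = layer.values.ravel()
    ok = np.isfinite(vals)
    which = np.clip(np.digitize(lat, edges, right=False) - 1, 0, edges.size - 2)
    rows = []
    for b in range(edges.size - 1):
        sel = ok & (which == b)
        rows.append(
            {
                "bin_low": edges[b],
                "bin_mid": edges[b] + bin_deg / 2,
                "mean": float(vals[sel].mean()) if sel.any() else np.nan,
                "n_cells": int(sel.sum()),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class Semivariogram:
    lag_km: np.ndarray  # bin midpoints
    semivariance: np.ndarray
    pair_counts: np.ndarray
    exhaustive: bool

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "lag_km": self.lag_km,
                "semivariance": self.semivariance,
                "pair_counts": self.pair_counts,
            }
        )


def empirical_semivariogram(
    res: ResidualMap | RasterLayer,
    lag_edges_km: np.ndarray | None = None,
    max_pairs: int = 1_000_000,
    seed: int = 0,
) -> Semivariogram:
    """gamma(h) = mean of 0.5*(z_i - z_j)^2 over pairs at plane distance h.

    Distances are taken on the equal-area plane (cell units x cell size).
    All pairs are used when their count fits ``max_pairs`` (always the case
    below ~1400 cells); otherwise ``max_pairs`` random pairs are sampled.
    Empty bins are reported with NaN semivariance, not errored.
    """
    layer = res.layer if isinstance(res, ResidualMap) else res
    grid = layer.grid
    ok = np.isfinite(layer.values)
    if ok.sum() < 2:
        raise InvalidInputError("semivariogram needs >= 2 non-missing cells")
    x, y = grid.plane_coords()
    xs, ys, zs = x[ok], y[ok], layer.values[ok]
    m = zs.size
    n_all = m * (m - 1) // 2
    exhaustive = n_all <= max_pairs
    if exhaustive:
        ii, jj = np.triu_indices(m, k=1)
    else:
        rng = np.random.default_rng(seed)
        ii = rng.integers(0, m, size=max_pairs)
        jj = rng.integers(0, m, size=max_pairs)
        keep = ii != jj
        ii, jj = ii[keep], jj[keep]
    d = np.hypot(xs[ii] - xs[jj], ys[ii] - ys[jj])
    sq = 0.5 * (zs[ii] - zs[jj]) ** 2
    if lag_edges_km is None:
        lag_edges_km = np.arange(0.0, 20.5 * grid.cell_km, grid.cell_km)
    lag_edges_km = np.asarray(lag_edges_km, dtype=float)
    which = np.digitize(d, lag_edges_km) - 1
    nbins = lag_edges_km.size - 1
    gamma = np.full(nbins, np.nan)
    counts = np.zeros(nbins, dtype=int)
    for b in range(nbins):
        sel = which == b
        counts[b] = int(sel.sum())
        if counts[b]:
            gamma[b] = float(sq[sel].mean())
    mids = 0.5 * (lag_edges_km[:-1] + lag_edges_km[1:])
    return Semivariogram(mids, gamma, counts, exhaustive)
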
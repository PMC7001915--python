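"""End-to-end orchestration: generate -> screen -> featurize -> fit -> interpret.

One :class:`PipelineConfig` (YAML-serialisable) drives the whole analysis.
Terrestrial and marine domains are modelled by two independent networks
sharing one world; record-sufficiency screening applies to the marine
point records only (terrestrial richness comes from stacked ranges).
Every stage seed is derived by hashing (global_seed, stage name), so adding
a stage never perturbs earlier randomness, and a completed run writes a
manifest (config echo, seeds, versions, artifact checksums) from which any
stage can be reproduced exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .ann import AnnConfig, evaluate, predict_surface, split_train_test, train_ann
from .features import FeatureDefinition, build_feature_table, compute_features
from .grids import GridSpec, InvalidInputError, RasterLayer, make_grid
from .interpretation import (
    empirical_semivariogram,
    pairwise_loess_ensemble,
    partial_dependence,
    permutation_importance,
    rank_importance,
    residual_map,
    zonal_profile,
)
from .screening import screen_species, screening_report
from .synthetic import (
    SyntheticWorldConfig,
    simulate_driver_fields,
    simulate_occurrences,
    simulate_species_ranges,
    stack_ranges_to_richness,
    true_richness_function,
)

logger = logging.getLogger(__name__)

STAGES = ("generate", "screen", "featurize", "fit", "interpret")


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class PipelineConfig:
    """Everything one run needs; nested sections mirror the stage order."""

    global_seed: int = 0
    output_dir: str = "richworld_run"
    domains: tuple = ("land", "ocean")
    # grid + synthetic world
    grid: dict = field(
        default_factory=lambda: {"extent": [-65.0, 65.0, -180.0, 180.0], "cell_km": 130.0}
    )
    world: dict = field(default_factory=dict)  # SyntheticWorldConfig overrides
    response: str = "function"  # function | stacked
    # screening (marine point records only)
    screening: dict = field(
        default_factory=lambda: {"enabled": True, "threshold": 41, "sufficiency": False}
    )
    # feature definitions: "default" or a list of FeatureDefinition dicts
    features: object = "default"
    # model
    model: dict = field(default_factory=dict)  # AnnConfig overrides
    cv_candidates: list = field(default_factory=list)  # optional CV sweep
    split_fraction: float = 0.8
    # interpretation
    interpretation: dict = field(
        default_factory=lambda: {
            "importance_reps": 20,
            "subset_fraction": 0.8,
            "loess_reps": 25,
            "loess_subsample": 2000,
            "pd_resolution": 15,
        }
    )

    def to_dict(self) -> dict:
        return _listify(asdict(self))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 16), b""):
            h.update(block)
    return h.hexdigest()


def _layer_to_csv(layer: RasterLayer, path: Path) -> None:
    layer.to_dataframe().to_csv(path, index=False, float_format="%.10g")


def layer_from_csv(grid: GridSpec, path, column: str) -> RasterLayer:
    df = pd.read_csv(path)
    values = np.full(grid.n_cells, np.nan)
    values[df["cell_id"].to_numpy(dtype=int)] = df[column].to_numpy(dtype=float)
    return RasterLayer(grid, values.reshape(grid.shape), column)


class PipelineRun:
    """State holder for one run; stages populate attributes and artifacts.

    Stages are deterministic functions of the config, so a stage invoked in
    isolation first rebuilds its (cheap, seeded) upstream state and then
    recomputes only itself; re-running any completed stage rewrites
    byte-identical artifacts.
    """

    def __init__(self, config: PipelineConfig):
        self.config = config
        self.out = Path(config.output_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.artifacts: dict[str, dict[str, str]] = {}
        self.grid = None
        self.world_config = None
        self.drivers = None
        self.ranges = None
        self.occurrences = None
        self.screened = None
        self.feature_layers = None
        self.richness: dict[str, RasterLayer] = {}
        self.tables: dict = {}
        self.models: dict = {}
        self.metrics: dict = {}

    # -- helpers -----------------------------------------------------------

    def _write(self, stage: str, name: str, writer) -> None:
        path = self.out / name
        writer(path)
        self.artifacts.setdefault(stage, {})[name] = _sha256(path)

    def _ensure_world(self) -> None:
        if self.drivers is not None:
            return
        cfg = self.config
        extent = tuple(cfg.grid.get("extent", (-65.0, 65.0, -180.0, 180.0)))
        self.grid = make_grid(extent, cell_km=float(cfg.grid.get("cell_km", 130.0)))
        world_kwargs = dict(cfg.world)
        world_kwargs.setdefault("seed", stage_seed(cfg.global_seed, "generate"))
        self.world_config = SyntheticWorldConfig(**world_kwargs)
        self.drivers = simulate_driver_fields(self.grid, self.world_config)
        self.ranges = simulate_species_ranges(self.drivers, self.world_config)
        self.occurrences = simulate_occurrences(
            self.ranges, self.drivers, config=self.world_config
        )

    # -- stages ------------------------------------------------------------

    def generate(self) -> None:
        self._ensure_world()
        logger.info("generate: %d cells, %d species", self.grid.n_cells, len(self.ranges.species))
        self._write("generate", "occurrences.csv", lambda p: self.occurrences.to_csv(p))
        self._write(
            "generate",
            "world_config.yaml",
            lambda p: Path(p).write_text(
                yaml.safe_dump(_world_config_dict(self.world_config), sort_keys=True)
            ),
        )
        for domain in self.config.domains:
            obs = self._observed_richness(domain, screened=False)
            self._write(
                "generate", f"richness_observed_{domain}.csv", lambda p, o=obs: _layer_to_csv(o, p)
            )

    def _observed_richness(self, domain: str, screened: bool) -> RasterLayer:
        if self.config.response == "function":
            layer = true_richness_function(self.drivers, self.world_config, include_noise=True)
            values = np.where(self.grid.domain_mask(domain), layer.values, np.nan)
            return RasterLayer(self.grid, values, "richness")
        if self.config.response != "stacked":
            raise InvalidInputError(f"unknown response kind {self.config.response!r}")
        if screened and domain == "ocean" and self.screened is not None:
            keep = set(self.screened.species_ids)
            sub = [s for s in self.ranges.species if s.species_id in keep or s.domain != "ocean"]
            ranges = type(self.ranges)(self.grid, sub)
            return stack_ranges_to_richness(ranges, self.grid, domain)
        return stack_ranges_to_richness(self.ranges, self.grid, domain)

    def screen(self) -> None:
        self._ensure_world()
        scfg = self.config.screening
        if not scfg.get("enabled", True):
            logger.info("screen: disabled, skipping")
            self.screened = None
            return
        marine_ids = [s.species_id for s in self.ranges.species if s.domain == "ocean"]
        marine = self.occurrences.subset(marine_ids)
        self.screened, results = screen_species(
            marine,
            threshold=int(scfg.get("threshold", 41)),
            compute_sufficiency=bool(scfg.get("sufficiency", False)),
            reps=int(scfg.get("reps", 1000)),
            coverage=float(scfg.get("coverage", 0.95)),
            seed=stage_seed(self.config.global_seed, "screen"),
        )
        logger.info("screen: retained %d / %d marine species", len(self.screened.species_ids), len(marine_ids))
        self._write(
            "screen",
            "screening_report.csv",
            lambda p: screening_report(results).to_csv(p, index=False, float_format="%.10g"),
        )
        self._write("screen", "occurrences_retained.csv", lambda p: self.screened.to_csv(p))

    def featurize(self) -> None:
        self._ensure_world()
        if self.config.screening.get("enabled", True) and self.screened is None:
            self.screen()
        defs = None
        if self.config.features != "default":
            defs = [FeatureDefinition(**d) for d in self.config.features]
        self.feature_layers = compute_features(self.drivers, defs)
        for domain in self.config.domains:
            obs = self._observed_richness(domain, screened=True)
            mask = self.grid.domain_mask(domain) & np.isfinite(obs.values)
            table = build_feature_table(self.feature_layers, obs, mask=mask)
            self.richness[domain] = obs
            self.tables[domain] = table
            logger.info("featurize[%s]: %d rows x %d features", domain, table.n_rows, len(table.feature_names))
            self._write(
                "featurize",
                f"features_{domain}.csv",
                lambda p, t=table: t.data.to_csv(p, index=False, float_format="%.10g"),
            )
            self._write(
                "featurize",
                f"features_{domain}.provenance.json",
                lambda p, t=table: Path(p).write_text(
                    json.dumps(t.provenance, indent=1, sort_keys=True)
                ),
            )

    def fit(self) -> None:
        if not self.tables:
            self.featurize()
        seed = stage_seed(self.config.global_seed, "fit")
        for domain in self.config.domains:
            table = self.tables[domain]
            split = split_train_test(table, self.config.split_fraction, seed=seed)
            model_kwargs = dict(self.config.model)
            model_kwargs.setdefault("seed", seed + 1)
            config = AnnConfig(**model_kwargs)
            if self.config.cv_candidates:
                from .ann import cross_validate

                candidates = [AnnConfig(**{**model_kwargs, **c}) for c in self.config.cv_candidates]
                config, fold_table = cross_validate(table, candidates, split=split, seed=seed + 2)
                self._write(
                    "fit",
                    f"cv_folds_{domain}.csv",
                    lambda p, t=fold_table: t.to_csv(p, index=False, float_format="%.10g"),
                )
            model = train_ann(table, config, split=split)
            self.models[domain] = model
            m = {
                scope: asdict(evaluate(model, table, scope)) for scope in ("train", "test")
            }
            self.metrics[domain] = m
            logger.info("fit[%s]: test R2=%.3f RMSE=%.3f", domain, m["test"]["r2"], m["test"]["rmse"])
            self._write("fit", f"model_{domain}.json", lambda p, mo=model: mo.to_json(p))
            self._write(
                "fit",
                f"metrics_{domain}.json",
                lambda p, mm=m: Path(p).write_text(json.dumps(mm, indent=1, sort_keys=True)),
            )
            predicted = predict_surface(model, table, self.grid)
            res = residual_map(_as_response_layer(self.richness[domain], table), predicted)
            self._write(
                "fit", f"predicted_{domain}.csv", lambda p, la=predicted: _layer_to_csv(la, p)
            )
            self._write(
                "fit", f"residuals_{domain}.csv", lambda p, la=res.layer: _layer_to_csv(la, p)
            )

    def interpret(self) -> None:
        if not self.models:
            self.fit()
        icfg = self.config.interpretation
        seed = stage_seed(self.config.global_seed, "interpret")
        for domain in self.config.domains:
            table = self.tables[domain]
            model = self.models[domain]
            dist = permutation_importance(
                table,
                model.config,
                n_reps=int(icfg.get("importance_reps", 20)),
                subset_fraction=float(icfg.get("subset_fraction", 0.8)),
                seed=seed,
            )
            ranking = rank_importance(dist)
            self._write(
                "interpret",
                f"importance_reps_{domain}.csv",
                lambda p, d=dist: d.reps.to_csv(p, index=False, float_format="%.10g"),
            )
            self._write(
                "interpret",
                f"importance_ranking_{domain}.json",
                lambda p, r=ranking: Path(p).write_text(
                    r.to_json(orient="records", indent=1)
                ),
            )
            top = list(ranking["feature"].head(3))
            res = int(icfg.get("pd_resolution", 15))
            for f in top:
                curve = partial_dependence(model, table, f, resolution=res)
                self._write(
                    "interpret",
                    f"pd_{domain}_{f}.csv",
                    lambda p, c=curve: c.to_csv(p, index=False, float_format="%.10g"),
                )
            if len(top) >= 2:
                surf = partial_dependence(model, table, top[:2], resolution=res)
                self._write(
                    "interpret",
                    f"pd_surface_{domain}.csv",
                    lambda p, s=surf: s.to_dataframe().to_csv(p, index=False, float_format="%.10g"),
                )
            ens = pairwise_loess_ensemble(
                table,
                top[0],
                n_sub=int(icfg.get("loess_subsample", 2000)),
                n_reps=int(icfg.get("loess_reps", 25)),
                seed=seed + 1,
            )
            self._write(
                "interpret",
                f"loess_{domain}_{top[0]}.csv",
                lambda p, e=ens: e.to_dataframe().to_csv(p, index=False, float_format="%.10g"),
            )
            observed = _as_response_layer(self.richness[domain], table)
            predicted = predict_surface(model, table, self.grid)
            res_map = residual_map(observed, predicted)
            for name, layer in (("observed", observed), ("predicted", predicted)):
                prof = zonal_profile(layer)
                self._write(
                    "interpret",
                    f"zonal_{name}_{domain}.csv",
                    lambda p, pr=prof: pr.to_csv(p, index=False, float_format="%.10g"),
                )
            vario = empirical_semivariogram(res_map, seed=seed + 2)
            self._write(
                "interpret",
                f"semivariogram_{domain}.csv",
                lambda p, v=vario: v.to_dataframe().to_csv(p, index=False, float_format="%.10g"),
            )

    # -- driver ------------------------------------------------------------

    def run(self, stages=None) -> dict:
        stages = list(stages or STAGES)
        unknown = set(stages) - set(STAGES)
        if unknown:
            raise InvalidInputError(f"unknown stages {sorted(unknown)}")
        config_echo = self.config.to_dict()
        config_echo.pop("output_dir", None)  # run location, not an analysis input
        manifest = {
            "package_version": __version__,
            "config": config_echo,
            "stage_seeds": {s: stage_seed(self.config.global_seed, s) for s in STAGES},
            "stages": {},
        }
        try:
            for s in STAGES:
                if s not in stages:
                    continue
                if s == "screen" and not self.config.screening.get("enabled", True):
                    manifest["stages"][s] = {"status": "skipped", "outputs": {}}
                    continue
                getattr(self, s)()
                manifest["stages"][s] = {
                    "status": "complete",
                    "outputs": self.artifacts.get(s, {}),
                }
        except Exception:
            for s in STAGES:
                manifest["stages"].setdefault(
                    s, {"status": "not-run", "outputs": self.artifacts.get(s, {})}
                )
            self._write_manifest(manifest)
            raise
        self._write_manifest(manifest)
        return manifest

    def _write_manifest(self, manifest: dict) -> None:
        with open(self.out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)


def _as_response_layer(richness: RasterLayer, table) -> RasterLayer:
    """Observed richness mapped onto the scaled-response scale of the table."""
    prov = table.provenance["response"]
    lo, hi = prov["min"], prov["max"]
    with np.errstate(invalid="ignore"):
        vals = (np.log1p(richness.values) - lo) / (hi - lo)
    return RasterLayer(richness.grid, vals, "observed_response")


def _listify(obj):
    """Recursively turn tuples into lists so yaml.safe_dump accepts the tree."""
    if isinstance(obj, (list, tuple)):
        return [_listify(v) for v in obj]
    if isinstance(obj, dict):
        return {k: _listify(v) for k, v in obj.items()}
    return obj


def _world_config_dict(cfg: SyntheticWorldConfig) -> dict:
    return _listify(asdict(cfg))


def run_pipeline(config: PipelineConfig, stages=None) -> dict:
    """Execute the pipeline; returns (and writes) the run manifest."""
    return PipelineRun(config).run(stages)
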
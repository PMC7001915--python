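import numpy as np
import pytest

from richworld import (
    SyntheticWorldConfig,
    build_feature_table,
    make_grid,
    simulate_driver_fields,
    true_richness_function,
)


@pytest.fixture(scope="session")
def small_world():
    """A small deterministic world shared by read-only tests."""
    config = SyntheticWorldConfig(
        seed=5,
        n_species=40,
        n_true_drivers=3,
        n_distractor_drivers=3,
        spatial_correlation_length=3.0,
        noise_sd=0.05,
    )
    grid = make_grid((-60.0, 60.0, -180.0, 180.0), cell_km=300.0)
    drivers = simulate_driver_fields(grid, config)
    return config, grid, drivers


@pytest.fixture(scope="session")
def driver_table(small_world):
    """Feature table of the causal + distractor static drivers vs noisy richness."""
    config, grid, drivers = small_world
    richness = true_richness_function(drivers, config, include_noise=True)
    layers = {n: l for n, l in drivers.static_layers.items() if n != "elevation"}
    return build_feature_table(layers, richness, mask=grid.domain_mask(None))


def lag1_moran(values: np.ndarray) -> float:
    """Correlation between horizontally adjacent cells (simple Moran-type stat)."""
    a, b = values[:, :-1].ravel(), values[:, 1:].ravel()
    return float(np.corrcoef(a, b)[0, 1])
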
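import numpy as np
import pytest

from supergrid import (
    CellTable,
    FallbackBackbone,
    SuperpixelGrid,
    SyntheticConfig,
    build_feature_map,
    make_benchmark,
)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_grid():
    return SuperpixelGrid(n_rows=10, n_cols=12)


@pytest.fixture(scope="session")
def random_cells():
    """500 cells with random square footprints inside a 10x12 superpixel grid."""
    r = np.random.default_rng(42)
    n = 500
    centroids = np.stack(
        [r.uniform(5, 91, size=n), r.uniform(5, 75, size=n)], axis=1
    )  # grid extent is 96 x 80 µm; margin keeps footprints inside
    sides = r.uniform(2.0, 8.0, size=n)
    expr = r.gamma(2.0, 2.0, size=(n, 5))
    return CellTable(
        cell_expression=expr,
        centroids_um=centroids,
        areas_um2=sides**2,
        gene_names=tuple(f"g{i}" for i in range(5)),
    )


@pytest.fixture(scope="session")
def benchmark():
    """The default synthetic benchmark (96x96 grid, 25 genes, seed 0)."""
    return make_benchmark(SyntheticConfig())


@pytest.fixture(scope="session")
def benchmark_fmap(benchmark):
    return build_feature_map(
        benchmark.image,
        benchmark.config.pixel_size_um,
        FallbackBackbone(feature_dim=32, seed=0),
    )
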
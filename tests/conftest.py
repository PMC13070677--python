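import numpy as np
import pytest

import spotae


@pytest.fixture(scope="session")
def tiny_ref():
    """Small labeled reference: 3 types, 30 cells each, 60 genes, 5 markers/type."""
    return spotae.generate_reference(
        k=3, n_per_type=30, ng=60, n_markers_per_type=5, fold=8.0, seed=11
    )


@pytest.fixture(scope="session")
def tiny_sim(tiny_ref):
    return spotae.simulate_spots(
        tiny_ref, grid=(6, 5), cells_per_spot=8, domain_layout="stripes", purity=5.0, seed=12
    )


@pytest.fixture(scope="session")
def benchmark_run():
    """The strong-signal benchmark: 4 types x 20 markers at 10x fold,
    800-cell reference, 20x10 grid of 10-cell spots in 4 stripe domains,
    Dirichlet purity 5, trained with default settings. Shared across the
    tests that score it (training takes about a minute)."""
    return spotae.run_benchmark(seed=0)


@pytest.fixture(scope="session")
def benchmark_score(benchmark_run):
    run = benchmark_run
    return spotae.evaluate(
        run.result.proportions,
        run.sim_raw.P,
        coords=run.sim_raw.st.coords,
        type_names=run.sim.type_names,
    )
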
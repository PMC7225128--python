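import numpy as np
import pandas as pd
import pytest

from statekinetics import synthkit
from statekinetics.containers import EmbeddingState, LayeredCountMatrix


@pytest.fixture(scope="session")
def small_expression():
    """200 cells/group, default gene panel, fixed seed."""
    genes = synthkit.default_gene_panel(seed=0)
    pop = synthkit.SimPopulationConfig(n_cells_per_group=200, seed=0)
    return synthkit.simulate_expression(genes, pop)


@pytest.fixture(scope="session")
def small_tracks():
    cfg = synthkit.TrackSimConfig(n_cells_per_group=60, seed=0)
    return synthkit.simulate_tracks(cfg)


@pytest.fixture()
def tiny_matrix():
    rng = np.random.default_rng(0)
    spliced = rng.poisson(5.0, (20, 30))
    unspliced = rng.poisson(2.0, (20, 30))
    genes = [f"g{i}" for i in range(20)]
    meta = pd.DataFrame(
        {
            "age": ["young"] * 15 + ["aged"] * 15,
            "lrc": ["LRC", "nonLRC"] * 15,
            "timepoint": ["quiescent"] * 30,
        }
    )
    return LayeredCountMatrix(spliced, unspliced, genes, meta)


@pytest.fixture()
def line_embedding():
    """1-D manifold along the first axis with pseudotime = 2 * x."""
    x = np.linspace(0.0, 10.0, 201)
    coords = np.column_stack([x, np.zeros_like(x)])
    return EmbeddingState(
        coordinates=coords,
        loadings=np.eye(2),
        gene_means=np.zeros(2),
        gene_ids=["axis_0", "axis_1"],
        pseudotime=2.0 * x,
    )
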
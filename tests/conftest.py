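import numpy as np
import pytest

from spothet import (
    CountMatrix,
    PipelineConfig,
    PipelineInputs,
    SimConfig,
    make_reference,
    make_spot_counts,
    make_tissue,
    run_pipeline,
)


def small_sim_config(seed: int = 0, **overrides) -> SimConfig:
    """A fast, fully-featured study: 2 sections, 6 glomeruli each."""
    kw = dict(
        n_genes=120,
        n_cells_per_type=40,
        lattice_rows=16,
        lattice_cols=12,
        n_glomeruli=6,
        conditions={"Ctrl": 1, "Losa": 1},
        seed=seed,
    )
    kw.update(overrides)
    return SimConfig(**kw)


#: pipeline thresholds matched to the synthetic gene-panel scale
def small_pipeline_config(**overrides) -> PipelineConfig:
    kw = dict(min_genes=50)
    kw.update(overrides)
    return PipelineConfig(**kw)


@pytest.fixture(scope="session")
def small_dataset():
    cfg = small_sim_config(seed=7)
    ref, labels = make_reference(cfg)
    lattice, truth = make_tissue(cfg)
    spots = make_spot_counts(lattice, truth, cfg)
    return cfg, ref, labels, lattice, truth, spots


@pytest.fixture(scope="session")
def small_pipeline_result(small_dataset):
    cfg, ref, labels, lattice, truth, spots = small_dataset
    pconf = small_pipeline_config()
    result = run_pipeline(pconf, PipelineInputs(ref, labels, spots, lattice))
    return cfg, truth, lattice, result


def toy_counts(values, gene_ids=None, sample_ids=None, modality="single_cell"):
    arr = np.asarray(values)
    genes = gene_ids or [f"g{i}" for i in range(arr.shape[0])]
    cells = sample_ids or [f"c{j}" for j in range(arr.shape[1])]
    return CountMatrix(genes, cells, arr, modality=modality)
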
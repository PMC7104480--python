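import numpy as np
import pytest

from epitensor import EpiTensorModel, ModelConfig, TrainingConfig
from epitensor.grid import GenomicGrid
from epitensor import synthetic, training


@pytest.fixture
def grid():
    return GenomicGrid(("chr1", "chr2"), (10_000, 5_010))


@pytest.fixture
def tiny_model(grid):
    """Small random-initialized model over the two-chromosome grid."""
    config = ModelConfig(n_cell_factors=3, n_assay_factors=4, n_g25=5,
                         n_g250=2, n_g5k=2, n_hidden_layers=2,
                         n_hidden_units=7)
    model = EpiTensorModel(config, grid, ["E001", "E002"],
                           ["H3K4me3", "H3K27me3", "DNase"])
    return training.initialize(model, seed=11)


@pytest.fixture(scope="session")
def small_compendium():
    """4 cells x 3 assays over a 200-kbp chromosome."""
    spec = synthetic.SyntheticSpec(n_cells=4, n_assays=3,
                                   chrom_lengths=(("chrS", 200_000),), seed=5)
    return synthetic.make_compendium(spec)


@pytest.fixture(scope="session")
def trained_model(small_compendium):
    """Two-stage-trained desk model on the small compendium (shared)."""
    comp = small_compendium
    model = EpiTensorModel(ModelConfig.desk(), comp.grid, comp.cells,
                           comp.assays)
    training.initialize(model, seed=5)
    regions = training.sample_pilot_regions(comp.grid, fraction=0.1, seed=5)
    training.fit_stage1(comp.observed_tracks(), regions, model,
                        TrainingConfig(batch_size=10_000, dropout=0.2,
                                       epochs_stage1=300, seed=5))
    training.fit_stage2(comp.observed_tracks(), "chrS", model,
                        TrainingConfig(batch_size=10_000, epochs_stage2=300,
                                       seed=5))
    return model
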
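import numpy as np
import pytest

from epiedit import features, models, synthetic, tracks_io


@pytest.fixture(scope="session")
def small_sim() -> synthetic.Simulation:
    """A small but fully structured linear-mode simulation: 60 genes,
    3 chromosomes, 3 cell types."""
    cfg = synthetic.SimConfig(
        n_genes=60, n_chroms=3, chrom_length=500_000, n_cell_types=3,
        expression_function="linear", seed=7,
    )
    return synthetic.simulate(cfg)


@pytest.fixture(scope="session")
def small_dataset(small_sim) -> features.Dataset:
    cfg = small_sim.config
    log_tracks = {ct: small_sim.log_tracks(ct) for ct in cfg.cell_type_names}
    return features.build_dataset(small_sim.annotation, log_tracks, small_sim.expression)


@pytest.fixture(scope="session")
def small_ridge(small_dataset) -> models.ExpressionModel:
    train, _ = features.split_by_chromosome(small_dataset, ["chr1"])
    return models.train_ridge(train, models.ModelConfig(seed=0))


def make_track(values_by_chrom, assay="H3K27ac", cell_type="ctA",
               scale="neglog10p", bin_size=25, imputed=False) -> tracks_io.BinnedTrack:
    vals = {c: np.asarray(v, dtype=float) for c, v in values_by_chrom.items()}
    return tracks_io.BinnedTrack(assay=assay, cell_type=cell_type, values=vals,
                                 scale=scale, bin_size=bin_size, imputed=imputed)
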
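import numpy as np
import pandas as pd
import pytest

from tcrvae.encoding import build_encoded_batch
from tcrvae.model import ArchitectureConfig
from tcrvae.simulate import SimulationConfig, simulate_paired_dataset

TINY_ARCH = ArchitectureConfig(rna_proj_dim=32, vj_embed_dim=8,
                               cnn_feature_maps=(8, 16, 32),
                               encoder_hidden=64, latent_dim=16,
                               decoder_hidden=64)


@pytest.fixture(scope="session")
def small_dataset():
    ds, truth = simulate_paired_dataset(
        SimulationConfig(n_cells=60, n_genes=30, n_clonotypes=8, seed=42))
    return ds, truth


@pytest.fixture(scope="session")
def small_batch(small_dataset):
    ds, _ = small_dataset
    return build_encoded_batch(ds)


@pytest.fixture
def tiny_arch():
    return TINY_ARCH


def make_contig_frame(rows):
    """Build a 10x-dialect contig table from (barcode, chain, cdr3, v, j,
    productive, umis) tuples."""
    return pd.DataFrame(rows, columns=["barcode", "chain", "cdr3", "v_gene",
                                       "j_gene", "productive", "umis"])


@pytest.fixture
def contig_csv(tmp_path):
    def _write(rows, name="contigs.csv"):
        path = tmp_path / name
        make_contig_frame(rows).to_csv(path, index=False)
        return path
    return _write


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
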
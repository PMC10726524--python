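"""Network contracts: shapes, determinism, training behaviour."""

import numpy as np
import pytest

from tcrvae.encoding import build_encoded_batch
from tcrvae.errors import ConfigError
from tcrvae.model import (ArchitectureConfig, LossWeights, ModelDims,
                          MultimodalVAE, TrainingConfig,
                          embed_for_visualization, extract_latent, load_model,
                          save_model, train_vae)
from tcrvae.simulate import SimulationConfig, simulate_paired_dataset


@pytest.fixture(scope="module")
def model_and_batch(tiny_arch_module, small_batch_module):
    model = MultimodalVAE(tiny_arch_module, ModelDims.from_batch(small_batch_module),
                          seed=0)
    return model, small_batch_module


@pytest.fixture(scope="module")
def tiny_arch_module():
    return ArchitectureConfig(rna_proj_dim=32, vj_embed_dim=8,
                              cnn_feature_maps=(8, 16, 32),
                              encoder_hidden=64, latent_dim=16,
                              decoder_hidden=64)


@pytest.fixture(scope="module")
def small_sim_module():
    return simulate_paired_dataset(
        SimulationConfig(n_cells=60, n_genes=30, n_clonotypes=8, seed=42))


@pytest.fixture(scope="module")
def small_batch_module(small_sim_module):
    return build_encoded_batch(small_sim_module[0])


class TestEncodeDecode:
    def test_latent_shapes(self, model_and_batch):
        model, batch = model_and_batch
        lat = model.encode(batch)
        n, d = batch.n_cells, model.arch.latent_dim
        assert lat.mu.shape == (n, d)
        assert lat.sigma.shape == (n, d)
        assert np.all(lat.sigma > 0)

    def test_identical_cells_get_identical_posteriors(self, model_and_batch):
        model, batch = model_and_batch
        dup = batch.subset(np.array([0, 0, 1]))
        lat = model.encode(dup)
        assert np.array_equal(lat.mu[0], lat.mu[1])
        assert not np.array_equal(lat.mu[0], lat.mu[2])

    def test_sampled_z_reproducible_with_seed(self, model_and_batch):
        model, batch = model_and_batch
        z1 = model.encode(batch, rng=np.random.default_rng(9)).z
        z2 = model.encode(batch, rng=np.random.default_rng(9)).z
        assert np.array_equal(z1, z2)
        z3 = model.encode(batch, rng=np.random.default_rng(10)).z
        assert not np.array_equal(z1, z3)

    def test_decoder_head_shapes(self, model_and_batch):
        model, batch = model_and_batch
        out = model.decode(np.zeros((3, model.arch.latent_dim)))
        assert out["rna"].shape == (3, batch.rna.shape[1])
        assert out["v_alpha"].shape == (3, batch.v_alpha.shape[1])
        assert out["cdr3_alpha"].shape == (3, batch.cdr3_alpha.shape[1], 21)
        assert out["cdr3_beta"].shape == (3, batch.cdr3_beta.shape[1], 21)

    def test_shape_mismatch_is_a_config_error(self, model_and_batch):
        model, batch = model_and_batch
        bad = batch.subset(np.arange(4))
        bad.rna = bad.rna[:, :-1]
        with pytest.raises(ConfigError, match="rna"):
            model.encode(bad)

    def test_tcr_only_mode_has_no_rna_branch(self, small_batch_module):
        arch = ArchitectureConfig(rna_proj_dim=32, vj_embed_dim=8,
                                  cnn_feature_maps=(8, 16, 32),
                                  encoder_hidden=64, latent_dim=16,
                                  decoder_hidden=64, include_rna=False)
        model = MultimodalVAE(arch, ModelDims.from_batch(small_batch_module), seed=1)
        out = model.decode(np.zeros((2, 16)))
        assert "rna" not in out
        lat = model.encode(small_batch_module)
        assert lat.mu.shape == (small_batch_module.n_cells, 16)


class TestTraining:
    def test_zero_epochs_returns_initial_parameters_and_empty_trace(
            self, small_batch_module, tiny_arch_module):
        model, trace = train_vae(small_batch_module, tiny_arch_module,
                                 cfg=TrainingConfig(epochs=0, seed=0))
        ref = MultimodalVAE(tiny_arch_module,
                            ModelDims.from_batch(small_batch_module),
                            seed=int(np.random.default_rng(0).integers(2 ** 31)))
        assert trace == []
        for (k, p), (_, q) in zip(sorted(model.named_parameters().items()),
                                  sorted(ref.named_parameters().items())):
            assert np.array_equal(p.data, q.data), k

    def test_loss_decreases_on_small_dataset(self, small_batch_module,
                                             tiny_arch_module):
        _, trace = train_vae(small_batch_module, tiny_arch_module,
                             cfg=TrainingConfig(epochs=50, batch_size=32, seed=0))
        assert trace[-1].total < trace[0].total

    def test_same_seed_gives_identical_traces(self, small_batch_module,
                                              tiny_arch_module):
        cfg = TrainingConfig(epochs=5, batch_size=32, seed=3)
        _, t1 = train_vae(small_batch_module, tiny_arch_module, cfg=cfg)
        _, t2 = train_vae(small_batch_module, tiny_arch_module, cfg=cfg)
        assert [b.total for b in t1] == [b.total for b in t2]

    def test_trace_decomposition_matches_weighted_sum(self, small_batch_module,
                                                      tiny_arch_module):
        w = LossWeights(0.3, 0.2, 0.1)
        _, trace = train_vae(small_batch_module, tiny_arch_module, w,
                             TrainingConfig(epochs=3, batch_size=32, seed=0))
        for bd in trace:
            ref = (w.alpha_latent * bd.v_loss + w.alpha_gene * bd.r_gene
                   + w.alpha_seq * bd.r_cdr3 + bd.r_rna)
            assert bd.total == pytest.approx(ref, rel=1e-6)

    def test_extreme_inputs_warn(self, small_batch_module, tiny_arch_module):
        loud = small_batch_module.subset(np.arange(small_batch_module.n_cells))
        loud.rna = loud.rna * 1e4
        with pytest.warns(UserWarning, match="extreme"):
            train_vae(loud, tiny_arch_module, cfg=TrainingConfig(epochs=0))


class TestLatentExtraction:
    def test_shape_determinism_and_duplication(self, small_sim_module,
                                               tiny_arch_module):
        ds, _ = small_sim_module
        model, _ = train_vae(ds, tiny_arch_module,
                             cfg=TrainingConfig(epochs=2, batch_size=32, seed=0))
        lat1 = extract_latent(model, ds)
        lat2 = extract_latent(model, ds)
        assert lat1.shape == (len(ds), tiny_arch_module.latent_dim)
        assert np.array_equal(lat1, lat2)  # no sampling involved
        dup = ds.subset([0, 0, 5])
        lat3 = extract_latent(model, dup)
        assert np.array_equal(lat3[0], lat3[1])
        assert np.allclose(lat3[0], lat1[0], atol=1e-10)


class TestCheckpoint:
    def test_save_load_roundtrip(self, model_and_batch, tmp_path):
        model, batch = model_and_batch
        save_model(model, tmp_path / "m.npz", extra={"hvg_genes": ["gene0001"]})
        back = load_model(tmp_path / "m.npz")
        assert back.checkpoint_extra == {"hvg_genes": ["gene0001"]}
        lat1 = model.encode(batch).mu
        lat2 = back.encode(batch).mu
        assert np.allclose(lat1, lat2)


class TestVisualization:
    def test_shape_and_seed_determinism(self, rng):
        lat = np.vstack([rng.standard_normal((40, 8)),
                         rng.standard_normal((40, 8)) + 8.0])
        c1 = embed_for_visualization(lat, n_pcs=5, seed=1)
        c2 = embed_for_visualization(lat, n_pcs=5, seed=1)
        assert c1.shape == (80, 2)
        assert np.allclose(c1, c2)
        with pytest.raises(ValueError):
            embed_for_visualization(lat, n_pcs=9)

    def test_separated_types_keep_positive_silhouette(self, rng):
        from tcrvae.metrics import normalized_asw
        lat = np.vstack([rng.standard_normal((40, 8)),
                         rng.standard_normal((40, 8)) + 8.0])
        coords = embed_for_visualization(lat, n_pcs=5, seed=0)
        labels = ["a"] * 40 + ["b"] * 40
        rep = normalized_asw(coords, labels)
        assert (rep.per_cell.mean()) > 0  # raw silhouette positive
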
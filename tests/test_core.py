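"""Model core: posterior contracts, PoE closed form vs density-product
oracle, fusion dimension contracts, discriminators, checkpoint round-trip."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from omicsfuse import (FusionModel, GaussianPosterior, ModalitySpec,
                       fuse_modality_embedding, poe_fuse, reparameterize)


@pytest.fixture(scope="module")
def model():
    specs = [ModalitySpec("a", 12, latent_dim=4, hidden_dims=[16]),
             ModalitySpec("b", 9, latent_dim=4, hidden_dims=[16]),
             ModalitySpec("mut", 7, latent_dim=4, hidden_dims=[16],
                          likelihood="bernoulli")]
    return FusionModel(specs, disc_hidden=8, seed=42)


@pytest.fixture(scope="module")
def batch(model):
    rng = np.random.default_rng(0)
    return {"a": rng.standard_normal((6, 12)),
            "b": rng.standard_normal((6, 9)),
            "mut": (rng.random((6, 7)) < 0.4).astype(float)}


class TestEncoders:
    def test_posterior_shapes_and_positivity(self, model, rng):
        post = model.encode_self(rng.standard_normal(12), "a")
        assert post.mean.shape == (4,) and post.scale.shape == (4,)
        assert (post.scale > 0).all()

    def test_encoding_deterministic(self, model, rng):
        x = rng.standard_normal(12)
        p1, p2 = model.encode_self(x, "a"), model.encode_self(x, "a")
        np.testing.assert_array_equal(p1.mean, p2.mean)
        np.testing.assert_array_equal(p1.scale, p2.scale)

    def test_batched_equals_rowwise(self, model, batch):
        full = model.encode_self(batch["a"], "a")
        for i in range(batch["a"].shape[0]):
            row = model.encode_self(batch["a"][i], "a")
            np.testing.assert_allclose(full.mean[i], row.mean, atol=1e-12)
            np.testing.assert_allclose(full.scale[i], row.scale, atol=1e-12)

    def test_dimension_mismatch_rejected(self, model, rng):
        with pytest.raises(ValueError, match="features|dimension"):
            model.encode_self(rng.standard_normal(5), "a")

    def test_cross_encoder_pair_combinatorics(self, model):
        # 3 modalities -> 6 ordered cross encoders; none for self-pairs
        assert len(model.cross_enc) == 6
        with pytest.raises(ValueError, match="source != target"):
            model.encode_cross(np.zeros(12), "a", "a")

    def test_cross_encoder_targets_target_latent(self, model, rng):
        post = model.encode_cross(rng.standard_normal(12), "a", "b")
        assert post.mean.shape == (4,)


class TestReparameterize:
    def test_eps_zero_returns_mean(self):
        p = GaussianPosterior(np.array([1.0, -2.0]), np.array([0.5, 2.0]))
        np.testing.assert_array_equal(reparameterize(p, np.zeros(2)), p.mean)

    def test_monte_carlo_moments(self, rng):
        p = GaussianPosterior(np.array([0.7]), np.array([1.3]))
        draws = np.array([reparameterize(p, rng.standard_normal(1)) for _ in range(10 ** 5)])
        se_mean = 1.3 / np.sqrt(10 ** 5)
        assert abs(draws.mean() - 0.7) < 3 * se_mean
        assert abs(draws.std() - 1.3) < 3 * se_mean


class TestDecode:
    def test_output_length_and_determinism(self, model, rng):
        z = rng.standard_normal(4)
        out1, out2 = model.decode(z, "a"), model.decode(z, "a")
        assert out1.shape == (12,)
        np.testing.assert_array_equal(out1, out2)

    def test_bernoulli_decoder_in_unit_interval(self, model, rng):
        out = model.decode(rng.standard_normal((5, 4)), "mut")
        assert ((out > 0) & (out < 1)).all()

    def test_latent_dim_mismatch_rejected(self, model):
        with pytest.raises(ValueError, match="latent"):
            model.decode(np.zeros(7), "a")


class TestPoE:
    def test_single_expert_identity(self, rng):
        e = GaussianPosterior(rng.standard_normal(3), rng.random(3) + 0.1)
        out = poe_fuse([e])
        np.testing.assert_allclose(out.mean, e.mean, atol=1e-12)
        np.testing.assert_allclose(out.scale, e.scale, atol=1e-12)

    def test_symmetric_unit_experts(self):
        a = GaussianPosterior(np.zeros(2), np.ones(2))
        b = GaussianPosterior(np.full(2, 2.0), np.ones(2))
        out = poe_fuse([a, b])
        np.testing.assert_allclose(out.mean, [1.0, 1.0])
        np.testing.assert_allclose(out.scale**2, [0.5, 0.5])

    def test_k_identical_experts_shrink_variance(self):
        e = GaussianPosterior(np.array([1.5]), np.array([0.8]))
        out = poe_fuse([e] * 5)
        np.testing.assert_allclose(out.mean, [1.5])
        np.testing.assert_allclose(out.scale**2, [0.8**2 / 5])

    def test_matches_grid_density_product(self, rng):
        """1-D PoE equals a renormalized numerical product of Gaussian
        densities on a fine grid."""
        for _ in range(10):
            experts = [GaussianPosterior(rng.uniform(-1, 1, 1), rng.uniform(0.3, 1.5, 1))
                       for _ in range(rng.integers(2, 5))]
            out = poe_fuse(experts)
            grid = np.linspace(-8, 8, 200001)
            log_prod = sum(-0.5 * ((grid - e.mean[0]) / e.scale[0]) ** 2
                           - np.log(e.scale[0]) for e in experts)
            dens = np.exp(log_prod - log_prod.max())
            dens /= np.trapezoid(dens, grid)
            mean = np.trapezoid(grid * dens, grid)
            var = np.trapezoid((grid - mean) ** 2 * dens, grid)
            assert abs(mean - out.mean[0]) < 1e-6
            assert abs(var - out.scale[0] ** 2) < 1e-6

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 10 ** 6))
    def test_permutation_invariance(self, seed):
        rng = np.random.default_rng(seed)
        experts = [GaussianPosterior(rng.standard_normal(3), rng.random(3) + 0.2)
                   for _ in range(4)]
        a = poe_fuse(experts)
        b = poe_fuse(experts[::-1])
        np.testing.assert_allclose(a.mean, b.mean, atol=1e-12)
        np.testing.assert_allclose(a.scale, b.scale, atol=1e-12)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            poe_fuse([])


class TestFusion:
    def test_present_modality_concatenates(self, rng):
        zs, zc = rng.standard_normal(4), rng.standard_normal(4)
        out = fuse_modality_embedding(zs, zc)
        np.testing.assert_array_equal(out, np.concatenate([zs, zc]))

    def test_missing_modality_duplicates_cross(self, rng):
        zc = rng.standard_normal(4)
        out = fuse_modality_embedding(None, zc)
        assert out.shape == (8,)
        np.testing.assert_array_equal(out[:4], out[4:])

    def test_both_absent_rejected(self):
        with pytest.raises(ValueError):
            fuse_modality_embedding(None, None)

    def test_joint_embedding_dimension_mask_independent(self, model, batch):
        full = model.joint_embedding(batch, np.ones((6, 3)))
        mask = np.ones((6, 3))
        mask[:, 1] = 0
        partial = model.joint_embedding(batch, mask)
        assert full.joint_embedding.shape == partial.joint_embedding.shape == (6, 24)

    def test_single_source_cross_equals_encoder_posterior(self, model, batch):
        """With only modality a present (of a 2-modality view), z_cross for b
        is exactly the a->b cross posterior (PoE identity)."""
        mask = np.ones((6, 3))
        mask[:, 1] = 0  # b missing
        mask[:, 2] = 0  # mut missing
        state = model.joint_embedding(batch, mask)
        expected = model.encode_cross(batch["a"], "a", "b")
        np.testing.assert_allclose(state.z_cross["b"], expected.mean, atol=1e-10)

    def test_deterministic_mode_repeatable(self, model, batch):
        m = np.ones((6, 3))
        e1 = model.joint_embedding(batch, m).joint_embedding
        e2 = model.joint_embedding(batch, m).joint_embedding
        np.testing.assert_array_equal(e1, e2)

    def test_zero_present_modalities_rejected(self, model, batch):
        with pytest.raises(ValueError):
            model.joint_embedding(batch, np.zeros((6, 3)))


class TestDiscriminators:
    def test_probability_in_unit_interval(self, model, rng):
        p = model.discriminate_reconstruction(rng.standard_normal(12), "a")
        assert 0 < p < 1

    def test_untrained_near_half_on_average(self):
        probs = []
        for seed in range(20):
            m = FusionModel([ModalitySpec("a", 10, latent_dim=2, hidden_dims=[8]),
                             ModalitySpec("b", 10, latent_dim=2, hidden_dims=[8])],
                            disc_hidden=8, seed=seed)
            rng = np.random.default_rng(seed)
            probs.append(model_mean := m.discriminate_reconstruction(
                rng.standard_normal((50, 10)), "a").mean())
        assert abs(np.mean(probs) - 0.5) < 0.1

    def test_source_probabilities_normalized(self, model, rng):
        p = model.discriminate_source_modality(rng.standard_normal((5, 9)), "b")
        assert p.shape == (5, 2)  # n_modalities - 1 sources
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)

    def test_dimension_mismatch_rejected(self, model):
        with pytest.raises(ValueError):
            model.discriminate_reconstruction(np.zeros(5), "a")


class TestCheckpoint:
    def test_round_trip_bitwise_forward(self, model, batch, tmp_path):
        path = tmp_path / "ckpt.npz"
        model.save(path)
        restored = FusionModel.load(path)
        m = np.ones((6, 3))
        e1 = model.joint_embedding(batch, m).joint_embedding
        e2 = restored.joint_embedding(batch, m).joint_embedding
        np.testing.assert_array_equal(e1, e2)

    def test_spec_mismatch_detected(self, model, tmp_path):
        path = tmp_path / "ckpt.npz"
        model.save(path)
        import json
        import numpy as np_
        with np_.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
        assert meta["config_hash"] == model.config_hash()
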
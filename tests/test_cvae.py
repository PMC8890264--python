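"""CVAE: losses, KL schedule, architecture contracts, training dynamics."""

import numpy as np
import pytest

from gridmol import nn
from gridmol.cvae import (
    GridCVAE, LatentDistribution, LossWeights, ModelConfig, TrainConfig,
    kl_divergence, kl_weight, load_checkpoint, reconstruction_loss,
    save_checkpoint, total_loss, train,
)
from gridmol.data import FixtureSpec, make_fixture_complex
from gridmol.grids import DensityGrid, GridSpec, molecule_to_grid

TINY = ModelConfig(grid_points=8, lig_channels=2, rec_channels=2, latent_dim=3,
                   block_widths=(3, 4), rng_seed=0)


def _tiny_grids(seed=0, channels=2, points=8):
    rng = np.random.default_rng(seed)
    spec = GridSpec(side=float(points - 1), resolution=1.0, n_channels=channels)
    rec = DensityGrid(rng.random((channels, points, points, points)), spec)
    lig = DensityGrid(rng.random((channels, points, points, points)), spec)
    return rec, lig


class TestKL:
    def test_standard_normal_is_zero(self):
        assert kl_divergence(LatentDistribution(np.zeros(7), np.ones(7))) == 0.0

    def test_unit_mean_half_per_dim(self):
        assert kl_divergence(LatentDistribution(np.ones(1), np.ones(1))) == pytest.approx(0.5)

    def test_nonpositive_std_rejected(self):
        with pytest.raises(ValueError):
            LatentDistribution(np.zeros(2), np.array([1.0, 0.0]))

    def test_matches_monte_carlo(self):
        """Closed form vs E[ln q - ln p] estimated from 1e5 samples (4 dims)."""
        rng = np.random.default_rng(12)
        mu = rng.normal(size=4)
        sigma = np.abs(rng.normal(size=4)) + 0.3
        closed = kl_divergence(LatentDistribution(mu, sigma))
        n = 100_000
        x = mu + sigma * rng.standard_normal((n, 4))
        log_q = -0.5 * (((x - mu) / sigma) ** 2 + np.log(2 * np.pi)) - np.log(sigma)
        log_p = -0.5 * (x**2 + np.log(2 * np.pi))
        samples = (log_q - log_p).sum(axis=1)
        se = samples.std(ddof=1) / np.sqrt(n)
        assert abs(closed - samples.mean()) < 3 * se


class TestReconstruction:
    def test_identical_grids_zero(self):
        rec, _ = _tiny_grids()
        assert reconstruction_loss(rec, rec) == 0.0

    def test_single_voxel_difference(self):
        rec, _ = _tiny_grids()
        other = DensityGrid(rec.values.copy(), rec.spec)
        other.values[0, 1, 2, 3] += 1.0
        assert reconstruction_loss(other, rec) == pytest.approx(1.0)

    def test_matches_bruteforce_loop(self):
        a, b = _tiny_grids(3)
        brute = 0.0
        for c in range(a.values.shape[0]):
            for i in range(8):
                for j in range(8):
                    for k in range(8):
                        brute += (a.values[c, i, j, k] - b.values[c, i, j, k]) ** 2
        assert reconstruction_loss(a, b) == pytest.approx(brute)

    def test_shape_mismatch(self):
        rec, _ = _tiny_grids()
        with pytest.raises(ValueError):
            reconstruction_loss(rec.values, rec.values[:1])


class TestSchedule:
    def test_ramp_endpoints_and_midpoint(self):
        w = LossWeights()
        assert kl_weight(w, 0) == 0.1
        assert kl_weight(w, 449_999) == 0.1
        assert kl_weight(w, 550_000) == pytest.approx(0.85)
        assert kl_weight(w, 650_000) == 1.6
        assert kl_weight(w, 2_000_000) == 1.6

    def test_negative_iteration_rejected(self):
        with pytest.raises(ValueError):
            kl_weight(LossWeights(), -1)

    def test_total_loss_weighted_sum(self):
        rec, lig = _tiny_grids()
        gen = DensityGrid(lig.values + 1.0, lig.spec)
        latent = LatentDistribution(np.ones(2), np.ones(2))
        value, parts = total_loss(lig, gen, rec, latent, LossWeights(), iteration=0)
        assert value == pytest.approx(
            4.0 * parts["recon"] + 0.1 * parts["kl"] + 1.0 * parts["steric"]
        )
        assert parts["kl"] == pytest.approx(1.0)

    def test_zero_weights_zero_loss(self):
        rec, lig = _tiny_grids()
        latent = LatentDistribution(np.ones(2), np.ones(2))
        w = LossWeights(recon=0.0, kl_initial=0.0, kl_final=0.0, steric=0.0)
        value, _ = total_loss(lig, rec, rec, latent, w, iteration=0)
        assert value == 0.0

    def test_arbitrary_term_arithmetic(self):
        # weighted sum with terms (1, 2, 3) at the reference weights
        assert 4.0 * 1 + 0.1 * 2 + 1.0 * 3 == pytest.approx(7.2)


class TestArchitecture:
    def test_posterior_std_positive_and_shapes(self):
        model = GridCVAE(TINY)
        rec, lig = _tiny_grids()
        latent = model.encode_input(rec, lig)
        assert latent.mean.shape == (3,)
        assert np.all(latent.std > 0)

    def test_encoder_determinism(self):
        model = GridCVAE(TINY)
        rec, lig = _tiny_grids()
        a = model.encode_input(rec, lig)
        b = model.encode_input(rec, lig)
        assert np.array_equal(a.mean, b.mean) and np.array_equal(a.std, b.std)

    def test_conditional_code_skip_shapes(self):
        model = GridCVAE(TINY)
        rec, _ = _tiny_grids()
        code = model.encode_condition(rec)
        assert code.vector.shape == (3,)
        assert [s.shape for s in code.skip_features] == [(3, 8, 8, 8), (4, 4, 4, 4)]

    def test_zero_receptor_finite(self):
        model = GridCVAE(TINY)
        spec = GridSpec(side=7.0, resolution=1.0, n_channels=2)
        code = model.encode_condition(DensityGrid(np.zeros(spec.shape), spec))
        assert np.all(np.isfinite(code.vector))

    def test_decode_shape_nonnegativity_determinism(self):
        model = GridCVAE(TINY)
        rec, _ = _tiny_grids()
        code = model.encode_condition(rec)
        z = np.random.default_rng(0).standard_normal(3)
        a = model.decode(z, code)
        b = model.decode(z, code)
        assert a.values.shape == (2, 8, 8, 8)
        assert np.all(a.values >= 0)
        assert np.array_equal(a.values, b.values)

    def test_latent_dimension_mismatch(self):
        model = GridCVAE(TINY)
        rec, _ = _tiny_grids()
        code = model.encode_condition(rec)
        with pytest.raises(ValueError):
            model.decode(np.zeros(5), code)

    def test_grid_points_must_match_levels(self):
        with pytest.raises(ValueError):
            ModelConfig(grid_points=12, block_widths=(2, 2, 2))


def test_end_to_end_gradients_match_finite_differences():
    """Reparameterized decode is differentiable end to end: analytic grads of
    the full loss agree with central differences at 1e-3 relative tolerance."""
    model = GridCVAE(TINY)
    rng = np.random.default_rng(1)
    rec = rng.random((1, 2, 8, 8, 8))
    lig = rng.random((1, 2, 8, 8, 8))
    eps = rng.standard_normal((1, 3))

    def loss():
        mu, log_std = model._encode_input_t(rec, lig)
        sigma = nn.exp(log_std)
        z = mu + sigma * nn.Tensor(eps)
        cvec, skips = model._encode_cond_t(rec)
        gen = model._decode_t(z, cvec, skips)
        diff = gen - nn.Tensor(lig)
        kl = (mu * mu + sigma * sigma - 2.0 * log_std + (-1.0)).sum() * 0.5
        steric = (gen.sum_axis(1) * nn.Tensor(rec.sum(axis=1, keepdims=True))).sum()
        return 4.0 * (diff * diff).sum() + 0.1 * kl + steric

    with nn.frozen_power_iteration():
        L = loss()
        L.backward()
        check_rng = np.random.default_rng(2)
        for p in model.parameters():
            idx = tuple(check_rng.integers(s) for s in p.data.shape)
            h = 1e-5 * max(1.0, abs(p.data[idx]))
            old = p.data[idx]
            p.data[idx] = old + h
            lp = loss().data
            p.data[idx] = old - h
            lm = loss().data
            p.data[idx] = old
            fd = (lp - lm) / (2 * h)
            assert p.grad[idx] == pytest.approx(fd, rel=1e-3, abs=1e-6)


@pytest.fixture(scope="module")
def complexes():
    return [
        make_fixture_complex(FixtureSpec(n_atoms=(3, 5), box=4.0, rng_seed=s))
        for s in range(3)
    ]


class TestTraining:
    def test_zero_learning_rate_keeps_weights(self, complexes):
        cfg = ModelConfig(grid_points=8, latent_dim=4, block_widths=(4,), rng_seed=1)
        model = GridCVAE(cfg)
        before = {k: v.copy() for k, v in model.state_arrays().items()}
        tc = TrainConfig(learning_rate=0.0, batch_size=2, augment=False, rng_seed=0)
        train(complexes, model, tc, grid_spec=GridSpec(side=7.0, resolution=1.0),
              max_iterations=3)
        after = model.state_arrays()
        for k in before:
            assert np.array_equal(before[k], after[k])

    def test_loss_history_is_logged(self, complexes, tmp_path):
        cfg = ModelConfig(grid_points=8, latent_dim=4, block_widths=(4,), rng_seed=1)
        model = GridCVAE(cfg)
        log = tmp_path / "log.csv"
        tc = TrainConfig(learning_rate=1e-3, batch_size=2, augment=False,
                         rng_seed=0, log_path=str(log))
        hist = train(complexes, model, tc, grid_spec=GridSpec(side=7.0, resolution=1.0),
                     max_iterations=5)
        assert len(hist) == 5
        assert {"iteration", "loss", "recon", "kl", "steric", "lambda_kl"} <= set(hist[0])
        assert log.exists() and len(log.read_text().splitlines()) == 6

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            train([], GridCVAE(TINY))

    def test_steric_term_matches_grid_functional(self, complexes):
        """The training steric term equals steric_overlap on (rec, gen)."""
        from gridmol.grids import steric_overlap

        cfg = ModelConfig(grid_points=8, latent_dim=4, block_widths=(4,), rng_seed=1)
        model = GridCVAE(cfg)
        spec = GridSpec(side=7.0, resolution=1.0, n_channels=18)
        rec_s, lig_s = complexes[0]
        center = tuple(lig_s.centroid)
        sp = GridSpec(center=center, side=7.0, resolution=1.0, n_channels=18)
        rec = molecule_to_grid(rec_s, sp)
        lig = molecule_to_grid(lig_s, sp)
        latent = model.encode_input(rec, lig)
        code = model.encode_condition(rec)
        gen = model.decode(latent.mean, code, spec=sp)
        _, parts = total_loss(lig, gen, rec, latent, LossWeights(), 0)
        assert parts["steric"] == pytest.approx(steric_overlap(rec, gen))


def test_checkpoint_roundtrip(tmp_path):
    model = GridCVAE(TINY)
    rec, lig = _tiny_grids()
    before = model.encode_input(rec, lig)
    path = tmp_path / "ckpt.npz"
    save_checkpoint(model, path, iteration=17)
    restored, iteration = load_checkpoint(path)
    assert iteration == 17
    after = restored.encode_input(rec, lig)
    assert np.allclose(before.mean, after.mean)
    assert np.allclose(before.std, after.std)
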
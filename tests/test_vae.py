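"""KL divergence, encoder/decoder contracts, Phi pair construction, and
checkpoint round-trips for the shape VAE."""

import numpy as np
import pytest

from cephaloseed.landmarks import FrameError, LandmarkSet
from cephaloseed.vae import (LatentCode, TrainConfig, kl_divergence,
                             load_checkpoint, local_to_global, make_phi_pairs,
                             save_checkpoint, train_phi, train_vae)


def _tiny_cfg(**kw):
    base = dict(epochs=300, learning_rate=1e-3, latent_dim=3,
                hidden_widths=(32, 16, 8), seed=0)
    base.update(kw)
    return TrainConfig(**base)


class TestKLDivergence:
    def test_standard_normal_gives_zero_both_forms(self):
        for form in ("standard", "as_printed"):
            assert kl_divergence(np.zeros(5), np.ones(5), form) == pytest.approx(0.0)

    def test_hand_evaluated_unit_case(self):
        # mu=1, sigma=1, d=1: (1/2)(1 + 1 - 0 - 1) = 0.5 in both forms
        assert kl_divergence([1.0], [1.0], "standard") == pytest.approx(0.5)
        assert kl_divergence([1.0], [1.0], "as_printed") == pytest.approx(0.5)

    def test_forms_differ_by_half_log_sigma(self):
        mu, sigma = np.array([0.3, -0.2]), np.array([0.5, 2.0])
        gap = kl_divergence(mu, sigma, "standard") - kl_divergence(mu, sigma, "as_printed")
        assert gap == pytest.approx(-0.5 * np.sum(np.log(sigma)))

    def test_standard_form_matches_monte_carlo(self):
        rng = np.random.default_rng(0)
        mu = rng.normal(size=4)
        sigma = np.exp(rng.normal(scale=0.4, size=4))
        z = mu + sigma * rng.standard_normal((200_000, 4))
        log_q = -0.5 * (((z - mu) / sigma) ** 2 + np.log(2 * np.pi)
                        + 2 * np.log(sigma)).sum(axis=1)
        log_p = -0.5 * (z ** 2 + np.log(2 * np.pi)).sum(axis=1)
        mc = float(np.mean(log_q - log_p))
        assert kl_divergence(mu, sigma, "standard") == pytest.approx(mc, rel=0.02)

    def test_standard_form_nonnegative_on_random_inputs(self):
        rng = np.random.default_rng(1)
        for _ in range(300):
            mu = rng.normal(scale=2, size=6)
            sigma = np.exp(rng.normal(scale=1, size=6))
            assert kl_divergence(mu, sigma, "standard") >= 0.0

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError):
            kl_divergence([0.0], [0.0])
        with pytest.raises(ValueError):
            LatentCode(z=np.zeros(1), mu=np.zeros(1), sigma=np.array([-1.0]))


@pytest.fixture(scope="module")
def toy_vae(registry):
    """VAE memorizing a tiny low-rank family of full landmark vectors."""
    rng = np.random.default_rng(9)
    base = rng.normal(scale=30, size=270)
    mode = rng.normal(size=270)
    mode /= np.linalg.norm(mode)
    data = np.stack([base + a * mode for a in rng.normal(scale=20, size=20)])
    vae = train_vae(data, _tiny_cfg(epochs=800), registry.names, registry)
    return vae, data


class TestEncodeDecode:
    def test_same_noise_seed_gives_identical_latents(self, toy_vae):
        vae, data = toy_vae
        z1 = vae.encode(data[0], noise_seed=5)
        z2 = vae.encode(data[0], noise_seed=5)
        np.testing.assert_array_equal(z1.z, z2.z)
        assert np.all(z1.sigma > 0)

    def test_deterministic_mode_returns_mu(self, toy_vae):
        vae, data = toy_vae
        code = vae.encode(data[0])
        np.testing.assert_array_equal(code.z, code.mu)

    def test_reconstruction_error_small_on_training_family(self, toy_vae):
        vae, data = toy_vae
        errs = []
        for r in data:
            diff = (vae.reconstruct(r) - r).reshape(-1, 3)
            errs.append(np.linalg.norm(diff, axis=1).mean())
        assert np.mean(errs) < 2.0  # mm; rank-1 family, d=3

    def test_dimension_mismatch_rejected(self, toy_vae):
        vae, _ = toy_vae
        with pytest.raises(ValueError):
            vae.encode(np.zeros(100))
        with pytest.raises(ValueError):
            vae.decode(np.zeros(7))


class TestTrainVae:
    def test_two_runs_same_seed_identical_weights(self, registry):
        rng = np.random.default_rng(2)
        data = rng.normal(scale=30, size=(8, 270))
        v1 = train_vae(data, _tiny_cfg(epochs=50), registry.names, registry)
        v2 = train_vae(data, _tiny_cfg(epochs=50), registry.names, registry)
        for a, b in zip(v1.params(), v2.params()):
            np.testing.assert_array_equal(a.value, b.value)
        assert v1.loss_curve == v2.loss_curve

    def test_repeated_vector_memorized(self, registry):
        data = np.tile(np.random.default_rng(3).normal(scale=40, size=270), (6, 1))
        vae = train_vae(data, _tiny_cfg(epochs=600, latent_dim=2),
                        registry.names, registry)
        diff = (vae.reconstruct(data[0]) - data[0]).reshape(-1, 3)
        assert np.linalg.norm(diff, axis=1).mean() < 1.0

    def test_as_printed_kl_form_trains(self, registry):
        rng = np.random.default_rng(4)
        data = rng.normal(scale=30, size=(8, 270))
        vae = train_vae(data, _tiny_cfg(epochs=50, kl_form="as_printed"),
                        registry.names, registry)
        assert np.isfinite(vae.loss_curve[-1])

    def test_needs_two_vectors(self, registry):
        with pytest.raises(ValueError):
            train_vae(np.zeros((1, 270)), _tiny_cfg(), registry.names, registry)


class TestPhi:
    def test_pair_counts_paired_plus_unpaired(self, toy_vae, registry):
        vae, data = toy_vae
        full = [vae.set_of(r) for r in data]
        refs = [lm.subset(registry.reference_names) for lm in full]
        x, z = make_phi_pairs(refs[:5], full[:5], full[5:], vae,
                              registry.reference_names)
        assert x.shape == (20, 30)
        assert z.shape == (20, vae.latent_dim)

    def test_no_paired_data_uses_subsampling_only(self, toy_vae, registry):
        vae, data = toy_vae
        full = [vae.set_of(r) for r in data]
        x, z = make_phi_pairs(None, None, full, vae, registry.reference_names)
        assert x.shape[0] == len(full)
        np.testing.assert_allclose(
            x[0], full[0].to_vector(registry.reference_names))

    def test_targets_deterministic(self, toy_vae, registry):
        vae, data = toy_vae
        full = [vae.set_of(r) for r in data[:4]]
        _, z1 = make_phi_pairs(None, None, full, vae, registry.reference_names)
        _, z2 = make_phi_pairs(None, None, full, vae, registry.reference_names)
        np.testing.assert_array_equal(z1, z2)

    def test_wrong_frame_rejected(self, toy_vae, registry):
        vae, data = toy_vae
        bad = [vae.set_of(r).with_frame("raw") for r in data[:2]]
        with pytest.raises(FrameError):
            make_phi_pairs(None, None, bad, vae, registry.reference_names)

    def test_constant_latent_target_is_learned(self, toy_vae, registry):
        vae, data = toy_vae
        rng = np.random.default_rng(5)
        x = rng.normal(scale=40, size=(12, 30))
        z = np.tile([0.7, -1.2, 0.4], (12, 1))
        phi = train_phi((x, z), vae,
                        TrainConfig(epochs=2000, learning_rate=1e-3,
                                    latent_dim=3, seed=0),
                        registry.reference_names)
        pred = phi.predict(x[3])
        np.testing.assert_allclose(pred, z[0], atol=0.05)
        assert phi.loss_curve[-1] < 1e-3

    def test_local_to_global_shape_and_determinism(self, toy_vae, registry):
        vae, data = toy_vae
        full = [vae.set_of(r) for r in data]
        pairs = make_phi_pairs(None, None, full, vae, registry.reference_names)
        phi = train_phi(pairs, vae, _tiny_cfg(epochs=300, learning_rate=1e-3),
                        registry.reference_names)
        est1 = local_to_global(phi, vae, full[0].subset(registry.reference_names))
        est2 = local_to_global(phi, vae, full[0].subset(registry.reference_names))
        assert len(est1) == 90
        for n in est1.names_in_order():
            np.testing.assert_array_equal(est1[n], est2[n])


class TestCheckpoint:
    def test_round_trip_preserves_predictions(self, toy_vae, registry, tmp_path):
        vae, data = toy_vae
        full = [vae.set_of(r) for r in data]
        pairs = make_phi_pairs(None, None, full, vae, registry.reference_names)
        phi = train_phi(pairs, vae, _tiny_cfg(epochs=100, learning_rate=1e-3),
                        registry.reference_names)
        p = tmp_path / "ckpt.npz"
        save_checkpoint(p, vae, phi)
        vae2, phi2 = load_checkpoint(p, registry)
        r = data[2]
        np.testing.assert_allclose(vae2.reconstruct(r), vae.reconstruct(r))
        np.testing.assert_allclose(phi2.predict(pairs[0][0]),
                                   phi.predict(pairs[0][0]))

    def test_registry_mismatch_refused(self, toy_vae, registry, tmp_path):
        from cephaloseed.registry import LandmarkRegistry, RegistryEntry

        vae, _ = toy_vae
        p = tmp_path / "ckpt.npz"
        save_checkpoint(p, vae)
        entries = list(registry.entries)
        e = entries[0]
        entries[0] = RegistryEntry(e.index, e.name, e.region, e.laterality, "x")
        other = LandmarkRegistry(entries)
        with pytest.raises(ValueError, match="registry"):
            load_checkpoint(p, other)
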
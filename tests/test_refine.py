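"""Patch datasets, flip augmentation, refinement contracts, and the
reference detector's translation equivariance."""

import numpy as np
import pytest

from cephaloseed.landmarks import LandmarkSet
from cephaloseed.refine import (GroupSpec, RegressorConfig, RenderConfig,
                                build_regressor, group_center,
                                jitter_radius_mm, make_patch_training_set,
                                make_patch_training_set_2d, mandibular_groups,
                                midsagittal_groups, refine_cranium,
                                refine_mandible, refine_midsagittal,
                                train_group_regressor,
                                train_reference_detector)
from cephaloseed.volume import binarize, extract_patch_3d, segment_components


class TestGroups:
    def test_nine_mandibular_groups_with_mirrors(self, registry):
        groups = mandibular_groups(registry)
        assert len(groups) == 9
        by_id = {g.group_id: g for g in groups}
        assert by_id["condyle_L"].mirror_group_id == "condyle_R"
        assert by_id["symphysis"].mirror_group_id == "symphysis"
        assert len(by_id["condyle_L"].members) == 6
        assert by_id["condyle_L"].output_dim == 18

    def test_midsagittal_groups_are_2d_singletons(self, registry):
        groups = midsagittal_groups(registry)
        assert [g.members[0] for g in groups] == registry.midsagittal_names
        assert all(g.output_dim == 2 for g in groups)

    def test_flip_member_order_is_involution(self, registry):
        by_id = {g.group_id: g for g in mandibular_groups(registry)}
        g, m = by_id["condyle_L"], by_id["condyle_R"]
        fwd = g.flipped_member_order(m)
        back = m.flipped_member_order(g)
        assert [fwd[i] for i in back] == list(range(6))

    def test_jitter_rule_doubles_max_error(self, registry):
        est = LandmarkSet({"Menton": (3.0, 0.0, 0.0), "Na": (0, 0, 0)},
                          frame="raw", registry=registry)
        lab = LandmarkSet({"Menton": (0.0, 0.0, 0.0), "Na": (0, 1, 0)},
                          frame="raw", registry=registry)
        assert jitter_radius_mm([est], [lab]) == pytest.approx(6.0)


@pytest.fixture(scope="module")
def mandible_case(rasterized_subject):
    s = rasterized_subject
    _, md = segment_components(binarize(s.volume))
    return md, s.landmarks_raw


class TestPatchTrainingSet:
    def test_zero_jitter_truth_centered_targets(self, mandible_case, registry):
        md, truth = mandible_case
        g = GroupSpec("one", ("Menton",), "mandible_mask")
        x, y = make_patch_training_set([(md, truth)], [truth], g,
                                       jitter_mm=0.0, n_jitter=0, eta=16)
        assert x.shape == (1, 16, 16, 16)
        # target = truth - snapped patch center: within half a voxel per axis
        assert np.all(np.abs(y[0]) <= md.spacing[0] / 2 + 1e-9)

    def test_flip_doubles_bilateral_group_data(self, mandible_case, registry):
        md, truth = mandible_case
        by_id = {g.group_id: g for g in mandibular_groups(registry)}
        x, y = make_patch_training_set(
            [(md, truth)], [truth], by_id["condyle_L"], 0.0, 2, 16, seed=0,
            mirror_group=by_id["condyle_R"], mirror_coarse=[truth])
        assert x.shape[0] == 6  # (1 + 2 jitters) direct + same flipped

    def test_double_flip_recovers_original_sample(self, mandible_case, registry):
        md, truth = mandible_case
        by_id = {g.group_id: g for g in mandibular_groups(registry)}
        g, m = by_id["condyle_L"], by_id["condyle_R"]
        x_l, y_l = make_patch_training_set([(md, truth)], [truth], g, 0.0, 0, 16)
        x_r, y_r = make_patch_training_set([(md, truth)], [truth], m, 0.0, 0, 16)
        # flip R's sample into L's frame, then back into R's: identity
        order_lr = g.flipped_member_order(m)
        order_rl = m.flipped_member_order(g)
        t = y_r[0].reshape(-1, 3)[order_lr].copy()
        t[:, 0] *= -1
        t2 = t[order_rl].copy()
        t2[:, 0] *= -1
        np.testing.assert_array_equal(t2.reshape(-1), y_r[0])
        data2 = x_r[0][::-1][::-1]
        np.testing.assert_array_equal(data2, x_r[0])

    def test_2d_dataset_targets_in_plane(self, mandible_case, registry):
        md, truth = mandible_case
        img = np.zeros(md.shape[1:], dtype=np.int64)
        img[40:60, 40:60] = 3
        g = midsagittal_groups(registry)[0]
        x, y = make_patch_training_set_2d([(img, md, truth)], [truth], g,
                                          jitter_mm=0.0, n_jitter=1, eta=16)
        assert x.shape[1:] == (16, 16)
        assert y.shape[1] == 2


class _StubRegressor:
    """Predicts fixed offsets regardless of patch content."""

    def __init__(self, offsets, eta):
        self._off = np.asarray(offsets, dtype=float).reshape(-1)
        self.cfg = RegressorConfig(epochs=0, learning_rate=0, eta=eta)

    def predict(self, patch_data):
        return self._off.copy()


class TestRefine:
    def test_identity_regressor_reproduces_coarse(self, mandible_case, registry):
        md, truth = mandible_case
        coarse = truth
        regs = {}
        for g in mandibular_groups(registry):
            patch = extract_patch_3d(md, group_center(coarse, g), 16)
            offs = np.concatenate([coarse[m] - patch.center_mm for m in g.members])
            regs[g.group_id] = _StubRegressor(offs, 16)
        fine = refine_mandible(md, coarse, regs, eta=16)
        assert set(fine.mask) == set(registry.mandibular_names)
        for n in fine.names_in_order():
            np.testing.assert_allclose(fine[n], coarse[n], atol=1e-9)

    def test_member_order_matches_group_spec(self, mandible_case, registry):
        md, truth = mandible_case
        by_id = {g.group_id: g for g in mandibular_groups(registry)}
        g = by_id["condyle_L"]
        offsets = np.arange(18, dtype=float).reshape(6, 3)
        regs = {gid: _StubRegressor(np.zeros(3 * len(spec.members)), 16)
                for gid, spec in by_id.items()}
        regs["condyle_L"] = _StubRegressor(offsets, 16)
        fine = refine_mandible(md, truth, regs, eta=16)
        patch = extract_patch_3d(md, group_center(truth, g), 16)
        for i, m in enumerate(g.members):
            np.testing.assert_allclose(fine[m], patch.center_mm + offsets[i])

    def test_missing_group_regressor_raises(self, mandible_case, registry):
        md, truth = mandible_case
        with pytest.raises(KeyError):
            refine_mandible(md, truth, {}, eta=16)

    def test_midsagittal_v1_pinned_to_plane(self, mandible_case, registry):
        md, truth = mandible_case
        img = np.random.default_rng(0).integers(0, 5, size=md.shape[1:])
        regs = {n: _StubRegressor(np.zeros(2), 16)
                for n in registry.midsagittal_names}
        plane = 1.25
        out = refine_midsagittal(img, md, truth, regs, plane_v1=plane, eta=16)
        assert set(out.mask) == set(registry.midsagittal_names)
        for n in out.names_in_order():
            assert out[n][0] == plane

    def test_patch_local_global_round_trip_within_voxel(self, mandible_case):
        md, _ = mandible_case
        rng = np.random.default_rng(1)
        for _ in range(10):
            c = md.origin + rng.uniform(20, 80, size=3)
            patch = extract_patch_3d(md, c, 16)
            assert np.all(np.abs(patch.center_mm - c) <= np.asarray(md.spacing) / 2)


@pytest.fixture(scope="module")
def cranial_stage(registry, shape_model):
    """Quick cranial VAE + Phi fitted on a small synthetic cohort."""
    from cephaloseed.experiments import normalize_cohort
    from cephaloseed.synth import sample_subjects
    from cephaloseed.vae import (TrainConfig, make_phi_pairs, train_phi,
                                 train_vae)

    subs = sample_subjects(shape_model, 30, seed=21)
    norm, _ = normalize_cohort(subs)
    cr_names = registry.cranial_names
    vae = train_vae([lm.to_vector(cr_names) for lm in norm],
                    TrainConfig(epochs=200, learning_rate=1e-3,
                                latent_dim=3, hidden_widths=(48, 24, 12),
                                seed=0),
                    cr_names, registry)
    in_names = registry.ordered(registry.cranial_reference_names
                                + registry.midsagittal_names)
    pairs = make_phi_pairs(None, None, norm, vae, in_names)
    phi = train_phi(pairs, vae,
                    TrainConfig(epochs=200, learning_rate=1e-3,
                                latent_dim=3, seed=0), in_names)
    return vae, phi, norm, in_names


class TestRefineCranium:

    def test_output_is_the_46_cranial_names(self, cranial_stage, registry):
        vae, phi, norm, in_names = cranial_stage
        lm = norm[0]
        out = refine_cranium(lm.subset(registry.cranial_reference_names),
                             lm.subset(registry.midsagittal_names), vae, phi)
        assert set(out.mask) == set(registry.cranial_names)

    def test_known_landmarks_pass_through_unchanged(self, cranial_stage, registry):
        vae, phi, norm, in_names = cranial_stage
        lm = norm[0]
        out = refine_cranium(lm.subset(registry.cranial_reference_names),
                             lm.subset(registry.midsagittal_names), vae, phi)
        for n in in_names:
            np.testing.assert_array_equal(out[n], lm[n])

    def test_missing_inputs_rejected(self, cranial_stage, registry):
        vae, phi, norm, _ = cranial_stage
        lm = norm[0]
        from cephaloseed.landmarks import MissingLandmarkError

        with pytest.raises(MissingLandmarkError):
            refine_cranium(lm.subset(["Na", "ANS"]),
                           lm.subset(registry.midsagittal_names), vae, phi)


@pytest.fixture(scope="module")
def tiny_detector(rasterized_subject, registry):
    from cephaloseed.landmarks import subsample_reference

    s = rasterized_subject
    xb = binarize(s.volume)
    cfg = RegressorConfig(epochs=30, learning_rate=1e-3, eta=32,
                          channels=(4, 8), fc_width=16, seed=0)
    det = train_reference_detector(
        [(xb, subsample_reference(s.landmarks_raw))], cfg,
        render=RenderConfig(), registry=registry, n_aug=1)
    return det, xb


class TestReferenceDetector:

    def test_identical_input_identical_output(self, tiny_detector, registry):
        det, xb = tiny_detector
        a = det.predict(xb, registry)
        b = det.predict(xb, registry)
        for n in a.names_in_order():
            np.testing.assert_array_equal(a[n], b[n])
        assert len(a) == 10

    def test_whole_voxel_translation_equivariance(self, tiny_detector, registry):
        det, xb = tiny_detector
        shift_vox = np.array([2, 3, -2])
        shifted = xb.like(np.roll(xb.data, shift_vox, axis=(0, 1, 2)))
        a = det.predict(xb, registry)
        b = det.predict(shifted, registry)
        delta = shift_vox * np.asarray(xb.spacing)
        # silhouette-edge gradients couple weakly to the along-view shift, so
        # equivariance is exact only up to a fraction of a voxel
        for n in a.names_in_order():
            np.testing.assert_allclose(b[n], a[n] + delta,
                                       atol=0.5 * xb.spacing[0])


def test_trained_singleton_regressor_memorizes(mandible_case, registry):
    md, truth = mandible_case
    g = GroupSpec("one", ("Menton",), "mandible_mask")
    x, y = make_patch_training_set([(md, truth)], [truth], g, 4.0, 3, 16, seed=2)
    cfg = RegressorConfig(epochs=300, learning_rate=1e-3, eta=16,
                          channels=(4, 8), fc_width=16, seed=0)
    reg = train_group_regressor((x, y), g, cfg)
    assert reg.loss_curve[-1] < reg.loss_curve[0]
    pred = reg.predict(x[0])
    assert np.linalg.norm(pred - y[0]) < 2.0  # mm, memorization regime


def test_same_seed_same_weights(mandible_case, registry):
    from cephaloseed import nn

    md, truth = mandible_case
    g = GroupSpec("one", ("Menton",), "mandible_mask")
    ds = make_patch_training_set([(md, truth)], [truth], g, 2.0, 2, 16, seed=3)
    cfg = RegressorConfig(epochs=20, learning_rate=1e-3, eta=16,
                          channels=(4, 8), fc_width=16, seed=5)
    r1 = train_group_regressor(ds, g, cfg)
    r2 = train_group_regressor(ds, g, cfg)
    for a, b in zip(nn.get_weights(r1.net), nn.get_weights(r2.net)):
        np.testing.assert_array_equal(a, b)
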
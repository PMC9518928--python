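"""Reference experiments on the synthetic benchmark.

Two study designs exercise the method end to end without any external data:

* :func:`vae_recovery_experiment` — the local-to-global core in isolation.
  Landmark sets from a known low-rank shape family are normalized, a shape
  VAE is trained per latent dimension, and the Phi map is fitted from the
  10-landmark reference subvector.  Reported: held-out reconstruction MDE per
  latent dimension, the held-out local-to-global MDE, and the MDE of the
  constant mean-shape baseline that any useful estimator must beat.
* :func:`coarse_to_fine_experiment` — the full pipeline.  A benchmark bundle
  (paired volumes, unpaired landmark sets, held-out test volumes) is
  generated, all stages are trained, and test subjects are pushed through the
  detect flow.  Reported: coarse and final MDEs overall and per region, the
  reference-detector error, and the in-plane midsagittal error before and
  after 2D refinement.

Both run at desk scale in minutes on one CPU and are fully seeded.
"""

from __future__ import annotations

import numpy as np

from .config import PipelineConfig
from .landmarks import (LandmarkSet, build_frame, cranial_volume,
                        normalize_scale, subsample_reference)
from .metrics import mde
from .pipeline import run_detect, run_train_all
from .synth import ShapeModel, make_benchmark, sample_subjects
from .vae import TrainConfig, local_to_global, make_phi_pairs, train_phi, train_vae


def normalize_cohort(subjects, target_volume: float | None = None
                     ) -> tuple[list[LandmarkSet], float]:
    """Canonicalize each subject on its own true references and fix scale.

    The normalization target defaults to the cohort's mean cranial volume.
    """
    canon = []
    for s in subjects:
        frame = build_frame(subsample_reference(s.landmarks_raw))
        canon.append(frame.to_canonical(s.landmarks_raw))
    if target_volume is None:
        target_volume = float(np.mean([cranial_volume(c) for c in canon]))
    return [normalize_scale(c, target_volume)[0] for c in canon], target_volume


def vae_recovery_experiment(seed: int = 0, n_unpaired: int = 229,
                            n_test: int = 24,
                            d_sweep: tuple[int, ...] = (1, 3, 5, 7, 9),
                            d_phi: int = 9,
                            config: PipelineConfig | None = None,
                            shape_model: ShapeModel | None = None) -> dict:
    """Parameter recovery of a k-mode family through the VAE + Phi stage."""
    config = config or PipelineConfig.desk(seed)
    model = shape_model or ShapeModel()
    registry = model.registry
    names = registry.names
    ref_names = registry.reference_names

    train_subj = sample_subjects(model, n_unpaired, seed=seed * 2 + 1)
    test_subj = sample_subjects(model, n_test, seed=seed * 2 + 2)
    train_norm, target = normalize_cohort(train_subj)
    test_norm, _ = normalize_cohort(test_subj, target_volume=target)
    x_train = np.stack([lm.to_vector(names) for lm in train_norm])
    x_test = np.stack([lm.to_vector(names) for lm in test_norm])

    def recon_mde(vae) -> float:
        per = []
        for r in x_test:
            diff = (vae.reconstruct(r) - r).reshape(-1, 3)
            per.append(np.linalg.norm(diff, axis=1).mean())
        return float(np.mean(per))

    recon = {}
    vaes = {}
    for d in sorted(set(d_sweep) | {d_phi}):
        cfg = TrainConfig(epochs=config.vae_coarse.epochs,
                          learning_rate=config.vae_coarse.learning_rate,
                          latent_dim=d, seed=seed * 100 + d,
                          kl_form=config.vae_coarse.kl_form,
                          hidden_widths=config.vae_coarse.hidden_widths)
        vaes[d] = train_vae(x_train, cfg, names, registry)
        recon[d] = recon_mde(vaes[d])

    vae = vaes[d_phi]
    pairs = make_phi_pairs(None, None, train_norm, vae, ref_names)
    phi_cfg = TrainConfig(epochs=config.phi_coarse.epochs,
                          learning_rate=config.phi_coarse.learning_rate,
                          latent_dim=d_phi, seed=seed * 100 + 77)
    phi = train_phi(pairs, vae, phi_cfg, ref_names)

    est = [local_to_global(phi, vae, lm.subset(ref_names)) for lm in test_norm]
    rep = mde(est, test_norm)

    mean_vec = x_train.mean(axis=0)
    baseline = [LandmarkSet.from_vector(mean_vec, names, "normalized", registry)
                for _ in test_norm]
    rep_base = mde(baseline, test_norm)

    return {
        "recon_mde_by_dim": recon,
        "l2g_mde": rep.mde_all,
        "l2g_mde_cranial": rep.mde_cranial,
        "l2g_mde_mandibular": rep.mde_mandibular,
        "baseline_mde": rep_base.mde_all,
        "improvement_pct": 100.0 * (1.0 - rep.mde_all / rep_base.mde_all),
        "noise_sigma": model.noise_sigma,
        "n_train": n_unpaired,
        "n_test": n_test,
    }


def coarse_to_fine_experiment(seed: int = 0,
                              config: PipelineConfig | None = None,
                              shape_model: ShapeModel | None = None) -> dict:
    """Train the full pipeline on a tiny benchmark; evaluate held-out subjects."""
    config = config or PipelineConfig.tiny(seed)
    model = shape_model or ShapeModel()
    bundle = make_benchmark(model, config.split.n_paired, config.split.n_unpaired,
                            config.split.n_test, seed=config.stage_seed("benchmark"))
    models = run_train_all(bundle, config)

    results = [run_detect(s.volume, models) for s in bundle.test]
    labels = [s.landmarks_raw for s in bundle.test]
    finals = [r.final for r in results]
    coarses = [r.coarse for r in results]
    rep_f = mde(finals, labels)
    rep_c = mde(coarses, labels)

    refs_err, mid_before, mid_after = [], [], []
    registry = model.registry
    for s, r in zip(bundle.test, results):
        truth = subsample_reference(s.landmarks_raw)
        for n in truth.names_in_order():
            refs_err.append(float(np.linalg.norm(r.refs[n] - truth[n])))
        for n in registry.midsagittal_names:
            mid_before.append(float(np.linalg.norm(
                r.coarse[n][1:] - s.landmarks_raw[n][1:])))
            mid_after.append(float(np.linalg.norm(
                r.mid3[n][1:] - s.landmarks_raw[n][1:])))

    return {
        "coarse_mde": rep_c.mde_all,
        "coarse_mde_cranial": rep_c.mde_cranial,
        "coarse_mde_mandibular": rep_c.mde_mandibular,
        "final_mde": rep_f.mde_all,
        "final_mde_cranial": rep_f.mde_cranial,
        "final_mde_mandibular": rep_f.mde_mandibular,
        "reference_detector_mde": float(np.mean(refs_err)),
        "midsagittal_inplane_before": float(np.mean(mid_before)),
        "midsagittal_inplane_after": float(np.mean(mid_after)),
        "jitter_mm": models.jitter_mm,
        "n_paired": config.split.n_paired,
        "n_unpaired": config.split.n_unpaired,
        "n_test": config.split.n_test,
        "manifest": models.manifest,
        "_models": models,
        "_bundle": bundle,
        "_results": results,
    }
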
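"""End-to-end orchestration: train all stages, detect, evaluate.

The detect flow mirrors the three-step method: binarize -> reference
detection -> pose/scale normalization -> coarse VAE/Phi estimate of all 90
landmarks -> mandible/cranium segmentation -> mandibular 3D patch refinement
+ midsagittal 2D refinement -> cranial fine VAE stage -> denormalization back
to scanner coordinates.  The final output always prefers the CNN-detected
positions for the 10 reference and the 3 midsagittal landmarks over decoded
(VAE) positions.

Training order follows the stage dependencies: reference detector first (its
outputs normalize the paired data), then the coarse VAE on the pooled
unpaired + paired landmark vectors, the coarse Phi on reference/latent pairs,
patch regressors on coarse-estimate-centered patches (jitter radius = 2x the
maximum coarse training error), and finally the cranial VAE + Phi.  All
stages are full-batch Adam with seeds derived from the pipeline seed, so a
rerun reproduces the same models bit for bit.
"""

from __future__ import annotations

import json
import logging
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .config import PipelineConfig
from .landmarks import (LandmarkSet, RigidFrame, build_frame, cranial_volume,
                        normalize_scale, subsample_reference)
from .metrics import mde
from .refine import (PatchRegressor, ReferenceDetector,
                     RegressorConfig, jitter_radius_mm, make_patch_training_set,
                     make_patch_training_set_2d, mandibular_groups,
                     midsagittal_groups, refine_cranium, refine_mandible,
                     refine_midsagittal, train_group_regressor,
                     train_reference_detector)
from .registry import LandmarkRegistry
from .synth import BenchmarkBundle
from .vae import (PhiModel, TrainConfig, VaeModel, make_phi_pairs, train_phi,
                  train_vae)
from .volume import VolumeGrid, binarize, integrate_midsagittal, segment_components

log = logging.getLogger(__name__)


def _scaled(lm: LandmarkSet, s: float) -> LandmarkSet:
    """canonical -> normalized by a known scale factor."""
    return LandmarkSet({k: v * s for k, v in lm.coords.items()},
                       frame="normalized", registry=lm.registry)


def _unscaled(lm: LandmarkSet, s: float) -> LandmarkSet:
    return LandmarkSet({k: v / s for k, v in lm.coords.items()},
                       frame="canonical", registry=lm.registry)


@dataclass
class SubjectFrame:
    """Per-subject normalization state derived from detected references."""

    frame: RigidFrame
    scale: float

    def normalize(self, lm_raw: LandmarkSet) -> LandmarkSet:
        return _scaled(self.frame.to_canonical(lm_raw), self.scale)

    def denormalize(self, lm_norm: LandmarkSet) -> LandmarkSet:
        return self.frame.to_raw(_unscaled(lm_norm, self.scale))


@dataclass
class TrainedModels:
    config: PipelineConfig
    registry: LandmarkRegistry
    detector: ReferenceDetector
    vae_coarse: VaeModel
    phi_coarse: PhiModel
    vae_cranial: VaeModel
    phi_cranial: PhiModel
    regressors_3d: dict[str, PatchRegressor]
    regressors_2d: dict[str, PatchRegressor]
    target_volume: float
    jitter_mm: float
    manifest: dict = field(default_factory=dict)


def subject_frame_from_refs(refs_raw: LandmarkSet, target_volume: float) -> SubjectFrame:
    frame = build_frame(refs_raw)
    refs_canon = frame.to_canonical(refs_raw)
    _, s = normalize_scale(refs_canon, target_volume)
    return SubjectFrame(frame=frame, scale=s)


def phi_input_names_cranial(registry: LandmarkRegistry) -> list[str]:
    return registry.ordered(registry.cranial_reference_names
                            + registry.midsagittal_names)


def run_train_all(bundle: BenchmarkBundle, config: PipelineConfig) -> TrainedModels:
    """Train every stage on a benchmark bundle, in dependency order."""
    registry = bundle.model.registry
    stages: list[dict] = []

    def record(stage, t0, **extra):
        stages.append({"stage": stage, "wall_s": round(time.time() - t0, 2), **extra})
        log.info("stage %s done in %.1fs", stage, time.time() - t0)

    # 1. reference detector on the paired subjects
    t0 = time.time()
    xbs = [binarize(s.volume, config.rho_hu) for s in bundle.paired]
    det_cfg = RegressorConfig(
        epochs=config.detector.epochs, learning_rate=config.detector.learning_rate,
        eta=config.render.crop_px, channels=config.detector.channels,
        fc_width=config.detector.fc_width, seed=config.stage_seed("detector"))
    detector = train_reference_detector(
        [(xb, subsample_reference(s.landmarks_raw))
         for xb, s in zip(xbs, bundle.paired)],
        det_cfg, render=config.render, registry=registry)
    record("detector", t0, epochs=det_cfg.epochs, seed=det_cfg.seed,
           final_loss=detector.loss_curve[-1])

    # 2. normalization target: mean cranial volume over all training landmarks
    t0 = time.time()
    vols = []
    for s in bundle.unpaired + bundle.paired:
        frame = build_frame(subsample_reference(s.landmarks_raw))
        vols.append(cranial_volume(frame.to_canonical(s.landmarks_raw)))
    target_volume = float(np.mean(vols))

    # per-paired-subject frames from *detected* references (pipeline-consistent)
    det_refs = [detector.predict(xb, registry) for xb in xbs]
    paired_frames = [subject_frame_from_refs(r, target_volume) for r in det_refs]
    paired_full_norm = [f.normalize(s.landmarks_raw)
                        for f, s in zip(paired_frames, bundle.paired)]
    paired_refs_norm = [f.normalize(r) for f, r in zip(paired_frames, det_refs)]

    unpaired_norm = []
    for s in bundle.unpaired:
        frame = build_frame(subsample_reference(s.landmarks_raw))
        canon = frame.to_canonical(s.landmarks_raw)
        lm, _ = normalize_scale(canon, target_volume)
        unpaired_norm.append(lm)
    record("normalize", t0, target_volume=target_volume)

    # 3. coarse VAE over all 90 landmarks
    t0 = time.time()
    all_norm = unpaired_norm + paired_full_norm
    vae_cfg = TrainConfig(**{**config.vae_coarse.__dict__,
                             "seed": config.stage_seed("vae_coarse")})
    vae_coarse = train_vae([lm.to_vector(registry.names) for lm in all_norm],
                           vae_cfg, registry.names, registry)
    record("vae_coarse", t0, epochs=vae_cfg.epochs, seed=vae_cfg.seed,
           final_loss=vae_coarse.loss_curve[-1])

    # 4. coarse Phi from 10-landmark reference vectors
    t0 = time.time()
    ref_names = registry.reference_names
    pairs = make_phi_pairs(paired_refs_norm, paired_full_norm, unpaired_norm,
                           vae_coarse, ref_names)
    phi_cfg = TrainConfig(**{**config.phi_coarse.__dict__,
                             "seed": config.stage_seed("phi_coarse")})
    phi_coarse = train_phi(pairs, vae_coarse, phi_cfg, ref_names)
    record("phi_coarse", t0, epochs=phi_cfg.epochs, seed=phi_cfg.seed,
           n_pairs=pairs[0].shape[0], final_loss=phi_coarse.loss_curve[-1])

    # 5. coarse estimates for the paired subjects -> jitter radius
    t0 = time.time()
    from .vae import local_to_global
    coarse_raw = []
    for f, refs in zip(paired_frames, paired_refs_norm):
        est_norm = local_to_global(phi_coarse, vae_coarse,
                                   refs.subset(ref_names))
        coarse_raw.append(f.denormalize(est_norm))
    jitter = jitter_radius_mm(coarse_raw, [s.landmarks_raw for s in bundle.paired])
    # the 2x-max-error rule assumes the patch still sees its target; cap the
    # jitter at half the patch extent so training offsets stay inside the
    # field of view
    spacing = bundle.paired[0].volume.spacing[0]
    jitter_cap = 0.5 * config.eta_3d * spacing
    jitter = min(jitter, jitter_cap)
    record("coarse_estimates", t0, jitter_mm=jitter, jitter_cap_mm=jitter_cap)

    # 6. mandibular 3D patch regressors (9 groups)
    t0 = time.time()
    masks = [segment_components(xb) for xb in xbs]
    md_subjects = [(md, s.landmarks_raw)
                   for (_, md), s in zip(masks, bundle.paired)]
    groups = {g.group_id: g for g in mandibular_groups(registry)}
    regressors_3d: dict[str, PatchRegressor] = {}
    for gid, g in groups.items():
        mirror = groups.get(g.mirror_group_id)
        ds = make_patch_training_set(
            md_subjects, coarse_raw, g, jitter, config.n_jitter, config.eta_3d,
            seed=config.stage_seed("cnn_3d") + zlib.crc32(gid.encode()) % 1000,
            mirror_group=mirror, mirror_coarse=coarse_raw)
        cfg3 = RegressorConfig(**{**config.cnn_3d.__dict__,
                                  "eta": config.eta_3d,
                                  "seed": config.stage_seed("cnn_3d")})
        regressors_3d[gid] = train_group_regressor(ds, g, cfg3)
    record("cnn_3d", t0, groups=len(regressors_3d),
           epochs=config.cnn_3d.epochs)

    # 7. midsagittal 2D regressors (3 landmarks)
    t0 = time.time()
    mid_subjects = []
    planes = []
    for (cr, _), refs, s in zip(masks, det_refs, bundle.paired):
        plane_v1 = 0.5 * (refs["Po(L)"][0] + refs["Po(R)"][0])
        planes.append(plane_v1)
        img = integrate_midsagittal(cr, plane_v1, config.half_width_mm)
        mid_subjects.append((img, cr, s.landmarks_raw))
    regressors_2d: dict[str, PatchRegressor] = {}
    for g in midsagittal_groups(registry):
        name = g.members[0]
        ds = make_patch_training_set_2d(
            mid_subjects, coarse_raw, g, jitter, config.n_jitter, config.eta_2d,
            seed=config.stage_seed("cnn_2d") + zlib.crc32(name.encode()) % 1000)
        cfg2 = RegressorConfig(**{**config.cnn_2d.__dict__,
                                  "eta": config.eta_2d,
                                  "seed": config.stage_seed("cnn_2d")})
        regressors_2d[name] = train_group_regressor(ds, g, cfg2)
    record("cnn_2d", t0, epochs=config.cnn_2d.epochs)

    # 8. cranial VAE + Phi (driven by refs + finely detected midsagittal)
    t0 = time.time()
    cr_names = registry.cranial_names
    vae_cr_cfg = TrainConfig(**{**config.vae_cranial.__dict__,
                                "seed": config.stage_seed("vae_cranial")})
    vae_cranial = train_vae([lm.to_vector(cr_names) for lm in all_norm],
                            vae_cr_cfg, cr_names, registry)
    record("vae_cranial", t0, epochs=vae_cr_cfg.epochs,
           final_loss=vae_cranial.loss_curve[-1])

    t0 = time.time()
    in_names = phi_input_names_cranial(registry)
    paired_mid_norm = []
    for (img, cr, _), f, c_raw, plane_v1, refs in zip(
            mid_subjects, paired_frames, coarse_raw, planes, det_refs):
        mid3 = refine_midsagittal(img, cr, c_raw, regressors_2d, plane_v1,
                                  eta=config.eta_2d)
        known = f.normalize(refs).updated(f.normalize(mid3))
        paired_mid_norm.append(known.subset(in_names))
    pairs_cr = make_phi_pairs(paired_mid_norm, paired_full_norm, unpaired_norm,
                              vae_cranial, in_names)
    phi_cr_cfg = TrainConfig(**{**config.phi_cranial.__dict__,
                                "seed": config.stage_seed("phi_cranial")})
    phi_cranial = train_phi(pairs_cr, vae_cranial, phi_cr_cfg, in_names)
    record("phi_cranial", t0, epochs=phi_cr_cfg.epochs,
           final_loss=phi_cranial.loss_curve[-1])

    manifest = {
        "stages": stages,
        "seed": config.seed,
        "preset": config.preset,
        "target_volume": target_volume,
        "jitter_mm": jitter,
        "benchmark": bundle.manifest,
    }
    return TrainedModels(
        config=config, registry=registry, detector=detector,
        vae_coarse=vae_coarse, phi_coarse=phi_coarse, vae_cranial=vae_cranial,
        phi_cranial=phi_cranial, regressors_3d=regressors_3d,
        regressors_2d=regressors_2d, target_volume=target_volume,
        jitter_mm=jitter, manifest=manifest)


@dataclass
class DetectResult:
    final: LandmarkSet
    coarse: LandmarkSet
    refs: LandmarkSet
    mid3: LandmarkSet
    fine_mandible: LandmarkSet
    fine_cranial_raw: LandmarkSet
    plane_v1: float
    timings: dict[str, float] = field(default_factory=dict)


def run_detect(volume: VolumeGrid, models: TrainedModels) -> DetectResult:
    """Full detect flow on one HU volume; deterministic given the models."""
    cfg = models.config
    registry = models.registry
    timings = {}

    t0 = time.time()
    xb = binarize(volume, cfg.rho_hu)
    refs = models.detector.predict(xb, registry)
    timings["detect_reference"] = time.time() - t0

    t0 = time.time()
    sf = subject_frame_from_refs(refs, models.target_volume)
    refs_norm = sf.normalize(refs)
    from .vae import local_to_global
    coarse_norm = local_to_global(models.phi_coarse, models.vae_coarse,
                                  refs_norm.subset(registry.reference_names))
    coarse_raw = sf.denormalize(coarse_norm)
    timings["coarse"] = time.time() - t0

    t0 = time.time()
    cr_mask, md_mask = segment_components(xb)
    fine_md = refine_mandible(md_mask, coarse_raw, models.regressors_3d,
                              eta=cfg.eta_3d)
    timings["refine_mandible"] = time.time() - t0

    t0 = time.time()
    plane_v1 = 0.5 * (refs["Po(L)"][0] + refs["Po(R)"][0])
    x_mid = integrate_midsagittal(cr_mask, plane_v1, cfg.half_width_mm)
    mid3 = refine_midsagittal(x_mid, cr_mask, coarse_raw, models.regressors_2d,
                              plane_v1, eta=cfg.eta_2d)
    timings["refine_midsagittal"] = time.time() - t0

    t0 = time.time()
    ref_cr_norm = refs_norm.subset(registry.cranial_reference_names)
    mid3_norm = sf.normalize(mid3)
    fine_cr_norm = refine_cranium(ref_cr_norm, mid3_norm,
                                  models.vae_cranial, models.phi_cranial)
    fine_cr_raw = sf.denormalize(fine_cr_norm)
    timings["refine_cranium"] = time.time() - t0

    # assemble: cranial from the fine cranial stage, mandibular from the 3D
    # patch stage; detector/2D-CNN outputs win for the 13 known landmarks
    final = fine_cr_raw.updated(fine_md).updated(refs).updated(mid3)
    return DetectResult(final=final, coarse=coarse_raw, refs=refs, mid3=mid3,
                        fine_mandible=fine_md, fine_cranial_raw=fine_cr_raw,
                        plane_v1=plane_v1, timings=timings)


def run_eval(est: list[LandmarkSet], label: list[LandmarkSet],
             initial: list[LandmarkSet] | None = None) -> dict:
    """Aggregate detection errors; optionally compare against initial estimates."""
    common = [e.subset(l.mask & e.mask) for e, l in zip(est, label)]
    labels = [l.subset(c.mask) for l, c in zip(label, common)]
    report = mde(common, labels)
    out = {"final": report.to_dict()}
    if initial is not None:
        init_common = [i.subset(l.mask & i.mask) for i, l in zip(initial, label)]
        init_labels = [l.subset(c.mask) for l, c in zip(label, init_common)]
        out["initial"] = mde(init_common, init_labels).to_dict()
    return out


def kfold_indices(n: int, k: int, seed: int = 0) -> list[tuple[np.ndarray, np.ndarray]]:
    """Shuffled k-fold (train_idx, val_idx) splits, e.g. 15-fold for image
    stages and 5-fold for the VAE stages."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    folds = np.array_split(perm, k)
    out = []
    for i in range(k):
        val = folds[i]
        train = np.concatenate([folds[j] for j in range(k) if j != i]) \
            if k > 1 else val
        out.append((np.sort(train), np.sort(val)))
    return out


def plot_initial_vs_final(eval_out: dict, path) -> None:
    """Bar chart of per-subject initial vs final errors (saved to file)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 3.5))
    fin = eval_out["final"]["per_subject"]
    x = np.arange(len(fin))
    w = 0.38
    if "initial" in eval_out:
        ini = eval_out["initial"]["per_subject"]
        ax.bar(x - w / 2, ini, w, label="initial", color="#4878a8")
        ax.bar(x + w / 2, fin, w, label="final", color="#c44e52")
        ax.axhline(float(np.mean(ini)), color="#4878a8", ls="--", lw=1)
    else:
        ax.bar(x, fin, w, label="final", color="#c44e52")
    ax.axhline(float(np.mean(fin)), color="#c44e52", ls="--", lw=1)
    ax.set_xlabel("test subject")
    ax.set_ylabel("mean detection error (mm)")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def write_manifest(models: TrainedModels, path) -> None:
    Path(path).write_text(json.dumps(models.manifest, indent=1, sort_keys=True))


# -- model persistence -----------------------------------------------------

def save_models(models: TrainedModels, out_dir) -> None:
    """Persist every trained stage to a directory of checkpoint files."""
    from . import nn
    from .vae import save_checkpoint

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.yaml").write_text(models.config.dump_yaml())
    meta = dict(models.manifest)
    meta["registry_hash"] = models.registry.content_hash()
    (out / "manifest.json").write_text(json.dumps(meta, indent=1, sort_keys=True))

    save_checkpoint(out / "coarse.npz", models.vae_coarse, models.phi_coarse)
    save_checkpoint(out / "cranial.npz", models.vae_cranial, models.phi_cranial)

    def save_net(path, net, cfg: RegressorConfig, extra=None):
        arrays = {f"w_{i}": p.value for i, p in enumerate(net.params())}
        info = {"cfg": {"epochs": cfg.epochs, "learning_rate": cfg.learning_rate,
                        "eta": cfg.eta, "channels": list(cfg.channels),
                        "fc_width": cfg.fc_width, "seed": cfg.seed,
                        "input_scale": cfg.input_scale}}
        if extra:
            info.update(extra)
        np.savez(path, meta=json.dumps(info), **arrays)

    for gid, reg in models.regressors_3d.items():
        save_net(out / f"cnn3d_{gid}.npz", reg.net, reg.cfg)
    for name, reg in models.regressors_2d.items():
        save_net(out / f"cnn2d_{name}.npz", reg.net, reg.cfg)
    rc = models.detector.render
    save_net(out / "detector.npz", models.detector.net, models.detector.cfg,
             extra={"render": {"views": [list(v) for v in rc.views],
                               "light_tilt": list(rc.light_tilt),
                               "crop_px": rc.crop_px, "downsample": rc.downsample,
                               "depth_scale_mm": rc.depth_scale_mm},
                    "ref_names": models.detector.ref_names})


def load_models(models_dir, registry: LandmarkRegistry | None = None) -> TrainedModels:
    """Load a directory written by :func:`save_models`."""
    from . import nn
    from .config import PipelineConfig
    from .refine import (RenderConfig, build_regressor, midsagittal_groups)
    from .vae import load_checkpoint

    d = Path(models_dir)
    registry = registry or LandmarkRegistry.default()
    config = PipelineConfig.from_yaml((d / "config.yaml").read_text())
    manifest = json.loads((d / "manifest.json").read_text())
    if manifest.get("registry_hash") not in (None, registry.content_hash()):
        raise ValueError("models were trained against a different registry")

    vae_coarse, phi_coarse = load_checkpoint(d / "coarse.npz", registry)
    vae_cranial, phi_cranial = load_checkpoint(d / "cranial.npz", registry)

    def load_net(path):
        with np.load(path, allow_pickle=False) as f:
            meta = json.loads(str(f["meta"]))
            weights = []
            i = 0
            while f"w_{i}" in f:
                weights.append(f[f"w_{i}"].copy())
                i += 1
        c = meta["cfg"]
        cfg = RegressorConfig(epochs=c["epochs"], learning_rate=c["learning_rate"],
                              eta=c["eta"], channels=tuple(c["channels"]),
                              fc_width=c["fc_width"], seed=c["seed"],
                              input_scale=c["input_scale"])
        return meta, weights, cfg

    groups = {g.group_id: g for g in mandibular_groups(registry)}
    regressors_3d = {}
    for gid, g in groups.items():
        meta, weights, cfg = load_net(d / f"cnn3d_{gid}.npz")
        reg = build_regressor(g, cfg)
        nn.set_weights(reg.net, weights)
        regressors_3d[gid] = reg
    regressors_2d = {}
    for g in midsagittal_groups(registry):
        name = g.members[0]
        meta, weights, cfg = load_net(d / f"cnn2d_{name}.npz")
        reg = build_regressor(g, cfg)
        nn.set_weights(reg.net, weights)
        regressors_2d[name] = reg

    meta, weights, det_cfg = load_net(d / "detector.npz")
    rcm = meta["render"]
    render = RenderConfig(views=tuple(tuple(v) for v in rcm["views"]),
                          light_tilt=tuple(rcm["light_tilt"]),
                          crop_px=rcm["crop_px"], downsample=rcm["downsample"],
                          depth_scale_mm=rcm["depth_scale_mm"])
    net = nn.conv_regressor(2, render.crop_px, render.n_channels,
                            3 * len(meta["ref_names"]),
                            list(det_cfg.channels), det_cfg.fc_width,
                            np.random.default_rng(det_cfg.seed))
    nn.set_weights(net, weights)
    detector = ReferenceDetector(net=net, render=render,
                                 ref_names=meta["ref_names"], cfg=det_cfg)

    return TrainedModels(
        config=config, registry=registry, detector=detector,
        vae_coarse=vae_coarse, phi_coarse=phi_coarse, vae_cranial=vae_cranial,
        phi_cranial=phi_cranial, regressors_3d=regressors_3d,
        regressors_2d=regressors_2d,
        target_volume=float(manifest["target_volume"]),
        jitter_mm=float(manifest["jitter_mm"]), manifest=manifest)
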
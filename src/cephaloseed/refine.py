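"""Coarse-to-fine refinement and reference-landmark detection.

Refinement strategy by region:

* **Mandible** — nine group regressors, each a small 3D CNN that reads a
  binary-mask cube centered at the group's coarse position and regresses the
  member landmark offsets (mm, patch frame).  Groups bundle landmarks that
  co-vary: the six condyle landmarks per side are detected at once, bilateral
  groups mirror each other, and horizontal-flip augmentation swaps L/R labels
  and negates the v1 offset.
* **Midsagittal cranial landmarks** (MxDML, Od, PNS) — per-landmark 2D CNNs
  on square patches of the partially integrated midsagittal image regress
  (v2, v3); v1 is fixed to the midsagittal plane.
* **Remaining cranial landmarks** — a second VAE/Phi stage driven by the 8
  cranial references plus the 3 finely detected midsagittal landmarks (see
  :mod:`cephaloseed.vae`), assembled in :func:`refine_cranium`.

Reference detection renders a configurable set of illuminated orthographic
views of the binarized skull, crops them around the foreground centroid, and
regresses all 10 reference landmarks as offsets from that centroid — which
makes the detector translation-equivariant by construction.  The renderer +
centroid-offset regressor is a documented simplification of illuminated-image
landmarking; the network bodies are small configurable conv stacks rather
than any fixed published architecture.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .landmarks import LandmarkSet, MissingLandmarkError
from .registry import LandmarkRegistry, mirror_name
from .vae import PhiModel, VaeModel, local_to_global
from .volume import (VolumeGrid, _extract_nd, extract_patch_2d,
                     extract_patch_3d, render_depth, render_illuminated)

log = logging.getLogger(__name__)

DEFAULT_ETA_3D = 80
DEFAULT_ETA_2D = 80


@dataclass(frozen=True)
class GroupSpec:
    """One jointly regressed landmark group."""

    group_id: str
    members: tuple[str, ...]
    patch_source: str              # "mandible_mask" | "midsagittal_image"
    mirror_group_id: str | None = None

    @property
    def n_dim(self) -> int:
        return 2 if self.patch_source == "midsagittal_image" else 3

    @property
    def output_dim(self) -> int:
        return self.n_dim * len(self.members)

    def flipped_member_order(self, mirror: "GroupSpec") -> list[int]:
        """Index into ``mirror.members`` giving this group's members mirrored."""
        idx = []
        for m in self.members:
            idx.append(mirror.members.index(mirror_name(m)))
        return idx


def mandibular_groups(registry: LandmarkRegistry) -> list[GroupSpec]:
    """The 9 mandibular patch groups declared in the registry."""
    specs = []
    for gid in registry.mandibular_group_ids:
        if gid.endswith("_L"):
            mirror = gid[:-2] + "_R"
        elif gid.endswith("_R"):
            mirror = gid[:-2] + "_L"
        else:
            mirror = gid  # midline group mirrors itself
        specs.append(GroupSpec(gid, tuple(registry.group_members(gid)),
                               "mandible_mask", mirror))
    return specs


def midsagittal_groups(registry: LandmarkRegistry) -> list[GroupSpec]:
    """Per-landmark 2D groups for the midsagittal refinement stage."""
    return [GroupSpec(f"mid_{n}", (n,), "midsagittal_image", None)
            for n in registry.midsagittal_names]


@dataclass
class RegressorConfig:
    epochs: int
    learning_rate: float
    eta: int
    channels: tuple[int, ...] = (4, 8, 16)
    fc_width: int = 32
    seed: int = 0
    input_scale: float = 1.0   # patch values divided by this before the net


@dataclass
class PatchRegressor:
    """Small conv net regressing member offsets (mm) from a patch."""

    net: nn.Sequential
    group: GroupSpec
    cfg: RegressorConfig
    loss_curve: list[float] = field(default_factory=list)

    def predict(self, patch_data: np.ndarray) -> np.ndarray:
        x = np.asarray(patch_data, dtype=nn.net_dtype(self.net))[None, None]
        return self.net.forward(x / self.cfg.input_scale)[0].astype(float)


def build_regressor(group: GroupSpec, cfg: RegressorConfig) -> PatchRegressor:
    rng = np.random.default_rng(cfg.seed)
    net = nn.conv_regressor(group.n_dim, cfg.eta, 1, group.output_dim,
                            list(cfg.channels), cfg.fc_width, rng)
    return PatchRegressor(net=net, group=group, cfg=cfg)


def jitter_radius_mm(coarse: list[LandmarkSet], truth: list[LandmarkSet]) -> float:
    """Patch-center jitter radius: 2x the maximum coarse error (training data)."""
    worst = 0.0
    for c, t in zip(coarse, truth):
        for n in c.names_in_order():
            if n in t.mask:
                worst = max(worst, float(np.linalg.norm(c[n] - t[n])))
    return 2.0 * worst


def group_center(lm: LandmarkSet, group: GroupSpec) -> np.ndarray:
    return np.mean([lm[m] for m in group.members], axis=0)


def _sample_3d(source: VolumeGrid, truth: LandmarkSet, group: GroupSpec,
               center: np.ndarray, eta: int):
    try:
        patch = extract_patch_3d(source, center, eta)
    except ValueError:
        log.warning("patch at %s fully outside volume; skipped", center)
        return None
    target = np.concatenate([truth[m] - patch.center_mm for m in group.members])
    return patch.data.astype(float), target


def make_patch_training_set(subjects: list[tuple[VolumeGrid, LandmarkSet]],
                            coarse: list[LandmarkSet], group: GroupSpec,
                            jitter_mm: float, n_jitter: int, eta: int,
                            seed: int = 0,
                            mirror_group: GroupSpec | None = None,
                            mirror_coarse: list[LandmarkSet] | None = None
                            ) -> tuple[np.ndarray, np.ndarray]:
    """3D patch dataset for one mandibular group.

    Patches are cubes of the mandible mask centered at the group's coarse
    position plus uniform jitter in ``[-jitter_mm, jitter_mm]^3`` (one
    unjittered sample plus ``n_jitter`` jittered ones per subject); targets
    are the true member positions in patch-frame mm.  When ``mirror_group``
    is given, every sample of the mirror group is added flipped along v1 with
    the member order swapped L/R, doubling the data of bilateral groups.
    """
    rng = np.random.default_rng(seed)
    xs, ys = [], []

    def gather(g: GroupSpec, coarse_sets: list[LandmarkSet], flip: bool):
        order = group.flipped_member_order(g) if flip else None
        for (vol, truth), c in zip(subjects, coarse_sets):
            center0 = group_center(c, g)
            jitters = [np.zeros(3)] + [rng.uniform(-jitter_mm, jitter_mm, 3)
                                       for _ in range(n_jitter)]
            for j in jitters:
                sample = _sample_3d(vol, truth, g, center0 + j, eta)
                if sample is None:
                    continue
                data, target = sample
                if flip:
                    data = data[::-1].copy()
                    t = target.reshape(-1, 3)[order].copy()
                    t[:, 0] *= -1.0
                    target = t.reshape(-1)
                xs.append(data)
                ys.append(target)

    gather(group, coarse, flip=False)
    if mirror_group is not None:
        gather(mirror_group, mirror_coarse if mirror_coarse is not None else coarse,
               flip=True)
    if not xs:
        raise ValueError(f"no usable patches for group {group.group_id}")
    return np.stack(xs), np.stack(ys)


def make_patch_training_set_2d(subjects: list[tuple[np.ndarray, VolumeGrid, LandmarkSet]],
                               coarse: list[LandmarkSet], group: GroupSpec,
                               jitter_mm: float, n_jitter: int, eta: int,
                               seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """2D patch dataset for a midsagittal landmark (translation augmentation).

    ``subjects`` holds (midsagittal image, source grid, truth landmarks);
    targets are true (v2, v3) in patch-frame mm.
    """
    rng = np.random.default_rng(seed)
    xs, ys = [], []
    name = group.members[0]
    for (img, grid, truth), c in zip(subjects, coarse):
        center0 = c[name][1:]
        jitters = [np.zeros(2)] + [rng.uniform(-jitter_mm, jitter_mm, 2)
                                   for _ in range(n_jitter)]
        for j in jitters:
            try:
                patch = extract_patch_2d(img, grid, center0 + j, eta)
            except ValueError:
                log.warning("2D patch at %s outside image; skipped", center0 + j)
                continue
            xs.append(patch.data.astype(float))
            ys.append(truth[name][1:] - patch.center_mm)
    if not xs:
        raise ValueError(f"no usable patches for group {group.group_id}")
    return np.stack(xs), np.stack(ys)


def train_group_regressor(dataset: tuple[np.ndarray, np.ndarray],
                          group: GroupSpec, cfg: RegressorConfig) -> PatchRegressor:
    """Full-batch Adam on squared coordinate error; seeded and reproducible."""
    x, y = dataset
    if x.shape[0] == 0:
        raise ValueError("empty dataset")
    reg = build_regressor(group, cfg)
    xin = x[:, None] / cfg.input_scale
    reg.loss_curve = nn.train_regressor(reg.net, xin, y, cfg.epochs,
                                        cfg.learning_rate)
    return reg


def refine_mandible(xb_md: VolumeGrid, coarse: LandmarkSet,
                    regressors: dict[str, PatchRegressor],
                    eta: int | None = None) -> LandmarkSet:
    """Replace the 44 mandibular coarse positions with patch-regressed ones."""
    registry = coarse.registry
    out: dict[str, np.ndarray] = {}
    for spec in mandibular_groups(registry):
        reg = regressors.get(spec.group_id)
        if reg is None:
            raise KeyError(f"no regressor for group {spec.group_id!r}")
        e = eta or reg.cfg.eta
        patch = extract_patch_3d(xb_md, group_center(coarse, spec), e)
        offsets = reg.predict(patch.data).reshape(-1, 3)
        for m, off in zip(spec.members, offsets):
            out[m] = patch.center_mm + off
    return LandmarkSet(out, frame=coarse.frame, registry=registry)


def refine_midsagittal(x_mid: np.ndarray, grid: VolumeGrid, coarse: LandmarkSet,
                       regressors: dict[str, PatchRegressor], plane_v1: float,
                       eta: int | None = None) -> LandmarkSet:
    """Refine MxDML, Od, PNS in-plane; their v1 is the midsagittal plane."""
    registry = coarse.registry
    out: dict[str, np.ndarray] = {}
    for name in registry.midsagittal_names:
        if name not in coarse.mask:
            raise MissingLandmarkError([name])
        reg = regressors.get(name)
        if reg is None:
            raise KeyError(f"no regressor for midsagittal landmark {name!r}")
        e = eta or reg.cfg.eta
        patch = extract_patch_2d(x_mid, grid, coarse[name][1:], e)
        v23 = patch.center_mm + reg.predict(patch.data)
        out[name] = np.array([plane_v1, v23[0], v23[1]])
    return LandmarkSet(out, frame=coarse.frame, registry=registry)


def refine_cranium(ref_cr: LandmarkSet, mid3: LandmarkSet,
                   vae_cr: VaeModel, phi_cr: PhiModel) -> LandmarkSet:
    """Fine cranial estimate from the 8 references + 3 midsagittal landmarks.

    The known 11 landmarks pass through unchanged in the output: detector
    outputs are preferred over decoded ones.
    """
    registry = ref_cr.registry
    known = ref_cr.updated(mid3)
    known.require(phi_cr.input_names)
    est = local_to_global(phi_cr, vae_cr, known.subset(phi_cr.input_names))
    if set(est.mask) != set(registry.cranial_names):
        raise ValueError("cranial stage must produce the 46 cranial landmarks")
    return est.updated(known.subset(phi_cr.input_names))


# -- reference-landmark detection ------------------------------------------

@dataclass
class RenderConfig:
    """Illuminated-view rendering for the reference detector."""

    views: tuple[tuple[float, float, float], ...] = ((0, 1, 0), (1, 0, 0), (0, 0, 1))
    light_tilt: tuple[float, float, float] = (0.35, 0.25, 0.45)
    crop_px: int = 32
    downsample: int = 3
    depth_scale_mm: float = 50.0

    @property
    def n_channels(self) -> int:
        return 2 * len(self.views)


def _view_features(xb: VolumeGrid, rc: RenderConfig,
                   centroid_mm: np.ndarray,
                   crop_jitter_px: tuple[int, int] = (0, 0)) -> np.ndarray:
    """Per-view (shade, depth) channels cropped around the centroid."""
    channels = []
    for view in rc.views:
        view = np.asarray(view, dtype=float)
        light = view + np.asarray(rc.light_tilt)
        shade = render_illuminated(xb, view, light / np.linalg.norm(light))
        depth, hit = render_depth(xb, view)
        axis = int(np.argmax(np.abs(view)))
        plane_axes = [a for a in range(3) if a != axis]
        cidx = [(centroid_mm[a] - xb.origin[a]) / xb.spacing[a] for a in plane_axes]
        cidx = np.rint(cidx).astype(int) + np.asarray(crop_jitter_px)
        window = rc.crop_px * rc.downsample
        for img, scale in ((shade, 1.0), (depth, None)):
            crop = _extract_nd(np.ascontiguousarray(img, dtype=float), cidx, window)
            if crop is None:
                crop = np.zeros((window, window))
            if scale is None:  # depth channel: center and scale
                ref = np.median(crop[crop > 0]) if np.any(crop > 0) else 0.0
                crop = np.where(crop > 0, (crop - ref) / rc.depth_scale_mm, 0.0)
            ds = rc.downsample
            crop = crop.reshape(rc.crop_px, ds, rc.crop_px, ds).mean(axis=(1, 3))
            channels.append(crop)
    return np.stack(channels)


def foreground_centroid_mm(xb: VolumeGrid) -> np.ndarray:
    idx = np.argwhere(xb.data > 0)
    if idx.size == 0:
        raise ValueError("empty volume has no centroid")
    return xb.origin + idx.mean(axis=0) * np.asarray(xb.spacing)


@dataclass
class ReferenceDetector:
    """Multi-view CNN regressing the 10 reference landmarks.

    Outputs are offsets (mm) from the binarized volume's foreground centroid,
    which makes predictions equivariant to whole-voxel translations.
    """

    net: nn.Sequential
    render: RenderConfig
    ref_names: list[str]
    cfg: RegressorConfig
    loss_curve: list[float] = field(default_factory=list)

    def predict(self, xb: VolumeGrid, registry: LandmarkRegistry) -> LandmarkSet:
        centroid = foreground_centroid_mm(xb)
        feats = _view_features(xb, self.render, centroid)
        feats = feats.astype(nn.net_dtype(self.net))
        offsets = self.net.forward(feats[None])[0].astype(float).reshape(-1, 3)
        coords = {n: centroid + off for n, off in zip(self.ref_names, offsets)}
        return LandmarkSet(coords, frame="raw", registry=registry)


def detect_reference(xb: VolumeGrid, detector: ReferenceDetector,
                     registry: LandmarkRegistry) -> LandmarkSet:
    """Detect the 10 reference landmarks on a binarized volume (raw frame)."""
    if detector is None:
        raise ValueError("reference detector has not been trained")
    return detector.predict(xb, registry)


def train_reference_detector(subjects: list[tuple[VolumeGrid, LandmarkSet]],
                             cfg: RegressorConfig,
                             render: RenderConfig | None = None,
                             registry: LandmarkRegistry | None = None,
                             n_aug: int = 2) -> ReferenceDetector:
    """Train the multi-view detector on (binarized volume, labels) pairs.

    Augmentation jitters the crop window by up to +-2 px per view, emulating
    centroid-estimate noise (translation augmentation).
    """
    registry = registry or subjects[0][1].registry
    render = render or RenderConfig()
    ref_names = registry.reference_names
    rng = np.random.default_rng(cfg.seed)
    xs, ys = [], []
    for xb, truth in subjects:
        centroid = foreground_centroid_mm(xb)
        target = np.concatenate([truth[n] - centroid for n in ref_names])
        jitters = [(0, 0)] + [tuple(rng.integers(-2, 3, size=2)) for _ in range(n_aug)]
        for j in jitters:
            xs.append(_view_features(xb, render, centroid, crop_jitter_px=j))
            ys.append(target)
    x = np.stack(xs)
    y = np.stack(ys)
    net_rng = np.random.default_rng(cfg.seed)
    net = nn.conv_regressor(2, render.crop_px, render.n_channels,
                            3 * len(ref_names), list(cfg.channels),
                            cfg.fc_width, net_rng)
    det = ReferenceDetector(net=net, render=render, ref_names=ref_names, cfg=cfg)
    det.loss_curve = nn.train_regressor(net, x, y, cfg.epochs, cfg.learning_rate)
    return det
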
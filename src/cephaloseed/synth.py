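"""Synthetic skull generator: statistical landmark shape model + rasterizer.

Every stage of the pipeline can be trained and evaluated without any external
data.  The generator emulates the statistical structure the method relies on,
not anatomy: a bilaterally symmetric 90-landmark template, low-rank correlated
shape variation (a few orthonormal deformation modes with given standard
deviations, one of them a deliberately asymmetric mandibular deviation mode to
mimic a dentofacial-deformity cohort), isotropic landmark noise, and a random
similarity pose (small rotation, translation, uniform scale).

Rasterized subjects are HU-valued volumes in which bone is ~1200 HU on a
-1000 HU background, so a 500 HU threshold separates bone cleanly.  The
cranium is an ellipsoidal shell plus struts connecting every cranial landmark
to the shell; the mandible is a tube network swept along a minimum spanning
tree of the mandibular landmarks.  By construction the binarized volume has
exactly two 26-connected components, the cranium strictly larger, and every
ground-truth landmark lies on the surface of its region's component.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial.distance import squareform, pdist

from .landmarks import LandmarkSet
from .registry import LandmarkRegistry
from .volume import VolumeGrid

BONE_HU = 1200.0
AIR_HU = -1000.0

# Stylized skull template, canonical frame (mm): origin at CFM, +v1 toward the
# right porion, +v2 anterior, +v3 superior.  Bilateral pairs are stored for
# the right side and mirrored.
_MIDLINE = {
    "Bregma": (0, 10, 118), "CFM": (0, 0, 0), "Na": (0, 82, 48),
    "ANS": (0, 92, 22), "MxDML": (0, 90, 8), "Od": (0, 8, -12),
    "PNS": (0, 42, 14), "Sella": (0, 28, 42), "Basion": (0, 12, -2),
    "Opisthion": (0, -14, 0), "Glabella": (0, 80, 62), "Rhinion": (0, 88, 38),
    "A-point": (0, 92, 12), "Prosthion": (0, 93, 2), "SC": (0, 20, 119),
    "Staphylion": (0, 40, 10), "Lambda": (0, -55, 95),
    "Opisthocranion": (0, -68, 60), "Inion": (0, -66, 35), "Vomer": (0, 50, 20),
    "Menton": (0, 78, -44), "Pogonion": (0, 84, -36), "B-point": (0, 86, -28),
    "Gnathion": (0, 81, -41), "Infradentale": (0, 88, -24), "IDML": (0, 88, -20),
}
_RIGHT = {
    "Or": (32, 76, 40), "Po": (58, -2, 28), "Zygion": (65, 45, 28),
    "FZ": (48, 65, 52), "Jugale": (52, 52, 38), "IOF": (26, 80, 30),
    "Ek": (44, 70, 42), "KeyRidge": (38, 58, 18), "Mastoidale": (64, -30, 18),
    "Pterygoid": (28, 45, 8), "Euryon": (64, -10, 70), "U1Tip": (4, 94, 2),
    "U6MB": (30, 60, -2),
    "MF": (24, 72, -28), "COR": (46, 18, 6), "MCP": (46, 0, 8),
    "LCP": (58, 0, 8), "Cp": (52, -7, 6), "Ct-in": (48, 2, 12),
    "Ct-out": (56, 2, 12), "Go": (50, -2, -26), "Sigmoid": (48, 8, -6),
    "MandF": (44, 6, -12), "Ag": (48, 8, -28), "RamusPost": (51, -3, -16),
    "L6MB": (28, 58, -20), "MT": (14, 80, -40), "BodyInf": (34, 48, -26),
    "L1Tip": (4, 90, -22), "L3Tip": (12, 86, -22), "ArchMid": (16, 78, -22),
    "AlvCrest": (22, 70, -24),
}

# Cranial vault ellipsoid (canonical frame): center and semi-axes, and the
# normalized-radius band forming the shell.
SHELL_CENTER = np.array([0.0, 15.0, 55.0])
SHELL_AXES = np.array([62.0, 82.0, 62.0])
SHELL_BAND = (0.88, 1.0)
#: The shell is cut off below this template-frame height: the skull base is
#: carried by the landmark struts instead, keeping the temporomandibular
#: region clear of the mandibular condyles.
SHELL_MIN_Z = 25.0

# The v1 axis has an odd voxel count with a center exactly on x = 0, so the
# midsagittal plane is a voxel-center plane and mirror-symmetric
# configurations rasterize to mirror-symmetric voxel grids.
DEFAULT_GRID_ORIGIN = (-96.0, -88.0, -80.0)
DEFAULT_GRID_SHAPE = (97, 112, 124)
DEFAULT_GRID_SPACING = 2.0

#: Latent draws are truncated at +-3 sigma so every subject stays inside the
#: default grid; the variance shrink this causes is ~3%.
LATENT_CLIP_SIGMA = 3.0


def template_coords() -> dict[str, np.ndarray]:
    """The symmetric mean landmark configuration (canonical frame, mm)."""
    out = {k: np.array(v, dtype=float) for k, v in _MIDLINE.items()}
    for base, (x, y, z) in _RIGHT.items():
        out[f"{base}(R)"] = np.array([x, y, z], dtype=float)
        out[f"{base}(L)"] = np.array([-x, y, z], dtype=float)
    return out


@dataclass(frozen=True)
class Similarity:
    """p -> scale * R @ p + t."""

    rotation: np.ndarray
    translation: np.ndarray
    scale: float = 1.0

    def apply(self, p: np.ndarray) -> np.ndarray:
        return self.scale * (np.asarray(p, dtype=float) @ self.rotation.T) \
            + self.translation

    def invert(self, p: np.ndarray) -> np.ndarray:
        return ((np.asarray(p, dtype=float) - self.translation) / self.scale) \
            @ self.rotation

    @classmethod
    def identity(cls) -> "Similarity":
        return cls(np.eye(3), np.zeros(3), 1.0)


def _rotation_xyz(angles) -> np.ndarray:
    ax, ay, az = angles
    cx, sx = np.cos(ax), np.sin(ax)
    cy, sy = np.cos(ay), np.sin(ay)
    cz, sz = np.cos(az), np.sin(az)
    rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return rz @ ry @ rx


@dataclass
class ShapeModel:
    """Generator parameters: template, deformation modes, noise, pose ranges.

    ``mode_std`` is expressed in the coordinates of the unit-norm 270-dim
    modes, so a mode concentrated on m landmarks displaces each by roughly
    ``std / sqrt(m)`` mm per standard deviation.
    """

    registry: LandmarkRegistry = field(default_factory=LandmarkRegistry.default)
    n_modes: int = 3
    mode_std: tuple[float, ...] = (40.0, 30.0, 20.0)
    noise_sigma: float = 0.5        # mm, isotropic per coordinate
    rot_max_rad: float = 0.05
    trans_max_mm: float = 5.0
    scale_range: tuple[float, float] = (0.95, 1.05)
    grid_origin: tuple[float, float, float] = DEFAULT_GRID_ORIGIN
    grid_shape: tuple[int, int, int] = DEFAULT_GRID_SHAPE
    grid_spacing: float = DEFAULT_GRID_SPACING
    ball_radius_mm: float = 5.0
    tube_radius_mm: float = 4.0

    def __post_init__(self):
        if not (1 <= self.n_modes <= 15):
            raise ValueError("n_modes must be in 1..15")
        if len(self.mode_std) < self.n_modes:
            raise ValueError("need a std per mode")
        self.template = template_coords()
        self.names = self.registry.names
        self.mean_vector = np.concatenate([self.template[n] for n in self.names])
        self.modes = self._build_modes()

    def _build_modes(self) -> np.ndarray:
        names = self.names
        reg = self.registry
        z_coord = {n: self.template[n][2] for n in names}
        raw = []
        # mode 1: anterior-posterior shift of the whole mandible (symmetric)
        m = np.zeros((len(names), 3))
        for i, n in enumerate(names):
            if reg[n].region == "mandibular":
                m[i, 1] = 1.0
        raw.append(m.reshape(-1))
        # mode 2: vertical stretch about z = 30 (global, symmetric)
        m = np.zeros((len(names), 3))
        for i, n in enumerate(names):
            m[i, 2] = (z_coord[n] - 30.0) / 50.0
        raw.append(m.reshape(-1))
        # mode 3: lateral mandibular deviation, stronger toward the chin
        # (asymmetric: emulates dentofacial deformity)
        m = np.zeros((len(names), 3))
        for i, n in enumerate(names):
            if reg[n].region == "mandibular":
                m[i, 0] = np.clip((10.0 - z_coord[n]) / 40.0, 0.0, 1.0)
        raw.append(m.reshape(-1))
        # further modes, if requested: smooth seeded random fields
        rng = np.random.default_rng(20220928)
        while len(raw) < self.n_modes:
            raw.append(rng.normal(size=3 * len(names)))
        basis, _ = np.linalg.qr(np.stack(raw[: self.n_modes]).T)
        return basis.T  # (k, 270), orthonormal rows

    def analytic_covariance(self) -> np.ndarray:
        std = np.asarray(self.mode_std[: self.n_modes])
        cov = (self.modes.T * std ** 2) @ self.modes
        return cov + self.noise_sigma ** 2 * np.eye(self.modes.shape[1])


@dataclass
class SyntheticSubject:
    subject_id: str
    landmarks_raw: LandmarkSet
    landmarks_canonical: LandmarkSet
    latent_true: np.ndarray
    pose: Similarity
    volume: VolumeGrid | None = None


def sample_subjects(model: ShapeModel, n: int, seed: int,
                    with_volumes: bool = False,
                    with_poses: bool = True) -> list[SyntheticSubject]:
    """Draw n subjects: latent ~ N(0, diag(std^2)), plus noise and pose."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    std = np.asarray(model.mode_std[: model.n_modes])
    subjects = []
    for i in range(n):
        latent = np.clip(rng.normal(size=model.n_modes),
                         -LATENT_CLIP_SIGMA, LATENT_CLIP_SIGMA) * std
        vec = model.mean_vector + latent @ model.modes
        vec = vec + rng.normal(scale=model.noise_sigma, size=vec.shape)
        canonical = LandmarkSet.from_vector(vec, model.names, frame="canonical",
                                            registry=model.registry)
        if with_poses:
            angles = rng.uniform(-model.rot_max_rad, model.rot_max_rad, size=3)
            t = rng.uniform(-model.trans_max_mm, model.trans_max_mm, size=3)
            s = rng.uniform(*model.scale_range)
            pose = Similarity(_rotation_xyz(angles), t, float(s))
        else:
            pose = Similarity.identity()
        raw = LandmarkSet({k: pose.apply(v) for k, v in canonical.coords.items()},
                          frame="raw", registry=model.registry)
        subj = SyntheticSubject(
            subject_id=f"synth{seed}_{i:04d}",
            landmarks_raw=raw, landmarks_canonical=canonical,
            latent_true=latent, pose=pose)
        if with_volumes:
            subj.volume = rasterize_skull(raw, model, pose=pose)
        subjects.append(subj)
    return subjects


def _stamp_balls(mask: np.ndarray, centers_vox: np.ndarray, r_vox: float) -> None:
    """Set a sphere of radius r_vox around each center (voxel units)."""
    r_int = int(np.ceil(r_vox))
    span = np.arange(-r_int, r_int + 1)
    di, dj, dk = np.meshgrid(span, span, span, indexing="ij")
    ball = (di ** 2 + dj ** 2 + dk ** 2) <= r_vox ** 2
    shape = mask.shape
    for c in np.atleast_2d(centers_vox):
        # quantize before rounding so mirrored centers round to mirrored
        # voxels despite float noise at half-integer boundaries
        ci = np.rint(np.round(c, 6)).astype(int)
        lo = ci - r_int
        hi = ci + r_int + 1
        s_lo = np.maximum(lo, 0)
        s_hi = np.minimum(hi, shape)
        if np.any(s_lo >= s_hi):
            continue
        b = ball[tuple(slice(a - l, a - l + (bnd - a))
                       for a, l, bnd in zip(s_lo, lo, s_hi))]
        region = mask[tuple(slice(a, bnd) for a, bnd in zip(s_lo, s_hi))]
        region |= b


def _segment_points(p: np.ndarray, q: np.ndarray, step_mm: float) -> np.ndarray:
    n = max(2, int(np.ceil(np.linalg.norm(q - p) / step_mm)) + 1)
    t = np.linspace(0.0, 1.0, n)[:, None]
    return p[None, :] * (1 - t) + q[None, :] * t


def _mandible_edges(lm: LandmarkSet, md_names: list[str]) -> list[tuple[str, str]]:
    """Mirror-symmetric tube topology for the mandible.

    A minimum spanning tree is built over the left + midline landmarks only
    and mirrored to the right by name, so a bilaterally symmetric
    configuration rasterizes to a voxel-symmetric mandible (a plain MST over
    all 44 points breaks ties asymmetrically).  Both halves share the midline
    nodes, keeping the union connected.
    """
    from .registry import mirror_name

    half = [n for n in md_names if not n.endswith("(R)")]
    pts = np.array([lm[n] for n in half])
    mst = minimum_spanning_tree(squareform(pdist(pts))).tocoo()
    edges = []
    for a, b in zip(mst.row, mst.col):
        na, nb = half[a], half[b]
        edges.append((na, nb))
        mirrored = (mirror_name(na), mirror_name(nb))
        if mirrored != (na, nb):
            edges.append(mirrored)
    return edges


def rasterize_skull(lm: LandmarkSet, model: ShapeModel,
                    pose: Similarity | None = None) -> VolumeGrid:
    """Rasterize a subject's landmarks into an HU-valued volume.

    ``pose`` positions the rigid cranial shell (identity for canonical-frame
    landmarks); tubes and landmark balls follow the landmark coordinates
    themselves.  Raises if any landmark falls outside the configured grid.
    """
    pose = pose or Similarity.identity()
    spacing = model.grid_spacing
    origin = np.asarray(model.grid_origin)
    shape = tuple(model.grid_shape)
    grid = VolumeGrid(np.zeros(shape, dtype=np.int16), spacing=(spacing,) * 3,
                      origin=origin)

    upper = origin + (np.asarray(shape) - 1) * spacing
    for n, p in lm.coords.items():
        if np.any(p < origin) or np.any(p > upper):
            raise ValueError(f"landmark {n} at {p} mm is outside the configured grid")

    # world coordinates of all voxel centers, mapped back through the pose
    idx = np.indices(shape, dtype=float)
    world = origin.reshape(3, 1, 1, 1) + idx * spacing
    template_pts = pose.invert(world.reshape(3, -1).T)
    q = (template_pts - SHELL_CENTER) / SHELL_AXES
    r = np.sqrt((q ** 2).sum(axis=1)).reshape(shape)
    lo, hi = SHELL_BAND
    z_t = template_pts[:, 2].reshape(shape)
    cranium = (r >= lo) & (r <= hi) & (z_t >= SHELL_MIN_Z)

    ball_r = model.ball_radius_mm * pose.scale / spacing
    tube_r = model.tube_radius_mm * pose.scale / spacing
    step = spacing * 0.75

    reg = lm.registry
    cr_names = [n for n in lm.names_in_order() if reg[n].region == "cranial"]
    md_names = [n for n in lm.names_in_order() if reg[n].region == "mandibular"]

    shell_center_world = pose.apply(SHELL_CENTER)
    for n in cr_names:
        p = lm[n]
        pts = _segment_points(p, shell_center_world, step)
        _stamp_balls(cranium, grid.mm_to_voxel(pts[0])[None], ball_r)
        _stamp_balls(cranium, np.array([grid.mm_to_voxel(x) for x in pts[1:]]),
                     tube_r)

    mandible = np.zeros(shape, dtype=bool)
    pts_md = np.array([lm[n] for n in md_names])
    _stamp_balls(mandible, np.array([grid.mm_to_voxel(p) for p in pts_md]), ball_r)
    for a, b in _mandible_edges(lm, md_names):
        pts = _segment_points(lm[a], lm[b], step)
        _stamp_balls(mandible, np.array([grid.mm_to_voxel(x) for x in pts]), tube_r)

    hu = np.full(shape, AIR_HU, dtype=np.float32)
    hu[cranium | mandible] = BONE_HU
    return grid.like(hu)


@dataclass
class BenchmarkBundle:
    """Paired (volume + landmarks), unpaired (landmarks only), held-out test."""

    paired: list[SyntheticSubject]
    unpaired: list[SyntheticSubject]
    test: list[SyntheticSubject]
    model: ShapeModel
    manifest: dict

    def manifest_hash(self) -> str:
        return self.manifest["hash"]


def make_benchmark(model: ShapeModel, n_paired: int = 15, n_unpaired: int = 229,
                   n_test: int = 9, seed: int = 7,
                   with_volumes: bool = True) -> BenchmarkBundle:
    """Sample the three disjoint cohorts the training procedure expects."""
    for k, v in (("n_paired", n_paired), ("n_unpaired", n_unpaired), ("n_test", n_test)):
        if v < 1:
            raise ValueError(f"{k} must be >= 1")
    ss = np.random.SeedSequence(seed)
    s_paired, s_unpaired, s_test = (int(s.generate_state(1)[0] % (2 ** 31))
                                    for s in ss.spawn(3))
    paired = sample_subjects(model, n_paired, s_paired, with_volumes=with_volumes)
    unpaired = sample_subjects(model, n_unpaired, s_unpaired, with_volumes=False)
    test = sample_subjects(model, n_test, s_test, with_volumes=with_volumes)
    for group, tag in ((paired, "paired"), (unpaired, "unpaired"), (test, "test")):
        for s in group:
            s.subject_id = f"{tag}_{s.subject_id}"

    h = hashlib.sha256()
    for s in paired + unpaired + test:
        h.update(s.subject_id.encode())
        h.update(np.ascontiguousarray(s.landmarks_raw.to_vector()).tobytes())
    manifest = {
        "seed": seed,
        "sub_seeds": {"paired": s_paired, "unpaired": s_unpaired, "test": s_test},
        "counts": {"paired": n_paired, "unpaired": n_unpaired, "test": n_test},
        "noise_sigma": model.noise_sigma,
        "n_modes": model.n_modes,
        "mode_std": list(model.mode_std[: model.n_modes]),
        "hash": h.hexdigest(),
    }
    return BenchmarkBundle(paired, unpaired, test, model, manifest)


def load_benchmark(in_dir, registry: LandmarkRegistry | None = None,
                   model: ShapeModel | None = None) -> BenchmarkBundle:
    """Load a benchmark directory written by :func:`write_benchmark`.

    Latent codes and poses are not stored on disk; loaded subjects carry
    them as empty placeholders (training only needs landmarks and volumes).
    """
    from pathlib import Path

    from .landmarks import read_csv

    d = Path(in_dir)
    model = model or ShapeModel(registry=registry or LandmarkRegistry.default())
    groups: dict[str, list[SyntheticSubject]] = {}
    for group in ("paired", "unpaired", "test"):
        subs = []
        for csv_path in sorted((d / group).glob("*_landmarks.csv")):
            sid = csv_path.name[: -len("_landmarks.csv")]
            lm = read_csv(csv_path, frame="raw", registry=model.registry)
            vol_path = d / group / f"{sid}.nii.gz"
            vol = VolumeGrid.from_nifti(vol_path) if vol_path.exists() else None
            subs.append(SyntheticSubject(
                subject_id=sid, landmarks_raw=lm,
                landmarks_canonical=lm.with_frame("canonical"),
                latent_true=np.zeros(model.n_modes),
                pose=Similarity.identity(), volume=vol))
        groups[group] = subs
    manifest = json.loads((d / "manifest.json").read_text())
    return BenchmarkBundle(groups["paired"], groups["unpaired"], groups["test"],
                           model, manifest)


def write_benchmark(bundle: BenchmarkBundle, out_dir) -> None:
    """Write NIfTI volumes, landmark CSVs, and the manifest JSON."""
    from pathlib import Path

    from .landmarks import write_csv

    out = Path(out_dir)
    for group, subjects in (("paired", bundle.paired), ("unpaired", bundle.unpaired),
                            ("test", bundle.test)):
        d = out / group
        d.mkdir(parents=True, exist_ok=True)
        for s in subjects:
            write_csv(s.landmarks_raw, d / f"{s.subject_id}_landmarks.csv")
            if s.volume is not None:
                s.volume.to_nifti(d / f"{s.subject_id}.nii.gz")
    (out / "manifest.json").write_text(json.dumps(bundle.manifest, indent=1))
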
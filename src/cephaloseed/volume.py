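"""Volume-domain primitives.

A :class:`VolumeGrid` is a 3D scalar grid (HU-valued CT or a {0,1} bone mask)
with voxel spacing and a world origin; ``data[i1, i2, i3]`` indexes the grid
so that index axis 0 runs along v1, the midsagittal-plane normal.  World
coordinates are ``origin + index * spacing`` (mm), 0-based indices.

Operations: HU thresholding (bone at >= 500 HU by default), 26-connected
component labeling that yields the cranium (largest component) and mandible
(second largest), the partially integrated midsagittal image (sum of a +-7.5
mm slab of the bone mask along v1), an orthographic illuminated-view
renderer, and zero-padded cubic/square patch extraction around landmarks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
from scipy import ndimage

DEFAULT_RHO_HU = 500.0
DEFAULT_HALF_WIDTH_MM = 7.5
DEFAULT_SPACING_MM = 0.5  # so an 80-voxel patch spans ~4 cm

_CARDINALS = {
    (1.0, 0.0, 0.0): (0, +1), (-1.0, 0.0, 0.0): (0, -1),
    (0.0, 1.0, 0.0): (1, +1), (0.0, -1.0, 0.0): (1, -1),
    (0.0, 0.0, 1.0): (2, +1), (0.0, 0.0, -1.0): (2, -1),
}


class SegmentationError(RuntimeError):
    """Connected-component segmentation could not find cranium + mandible."""


@dataclass
class VolumeGrid:
    data: np.ndarray
    spacing: tuple[float, float, float] = (DEFAULT_SPACING_MM,) * 3
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("VolumeGrid data must be 3D")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def is_binary(self) -> bool:
        return bool(np.isin(self.data, (0, 1)).all())

    def mm_to_voxel(self, p_mm) -> np.ndarray:
        return (np.asarray(p_mm, dtype=float) - self.origin) / np.asarray(self.spacing)

    def voxel_to_mm(self, idx) -> np.ndarray:
        return self.origin + np.asarray(idx, dtype=float) * np.asarray(self.spacing)

    def like(self, data: np.ndarray) -> "VolumeGrid":
        return VolumeGrid(data, spacing=self.spacing, origin=self.origin.copy())

    # -- NIfTI I/O --------------------------------------------------------

    def to_nifti(self, path) -> None:
        affine = np.eye(4)
        affine[:3, :3] = np.diag(self.spacing)
        affine[:3, 3] = self.origin
        dtype = np.uint8 if self.is_binary() else np.float32
        nib.save(nib.Nifti1Image(self.data.astype(dtype), affine), str(path))

    @classmethod
    def from_nifti(cls, path) -> "VolumeGrid":
        img = nib.load(str(path))
        affine = img.affine
        spacing = tuple(float(np.linalg.norm(affine[:3, i])) for i in range(3))
        return cls(np.asarray(img.dataobj), spacing=spacing, origin=affine[:3, 3])


def binarize(x: VolumeGrid, rho: float = DEFAULT_RHO_HU) -> VolumeGrid:
    """Threshold a HU volume into a bone mask: 1 where x >= rho (inclusive)."""
    return x.like((x.data >= rho).astype(np.uint8))


def segment_components(xb: VolumeGrid) -> tuple[VolumeGrid, VolumeGrid]:
    """Split a bone mask into (cranium, mandible) by 26-connected CCL.

    The cranium is the largest component and the mandible the second largest.
    Ties on size are broken by the lower minimum linear voxel index, for
    determinism.  Raises :class:`SegmentationError` below two components.
    """
    if not xb.is_binary():
        raise ValueError("segment_components requires a binary volume")
    structure = np.ones((3, 3, 3), dtype=int)  # 26-connectivity
    labels, n = ndimage.label(xb.data, structure=structure)
    if n < 2:
        raise SegmentationError(f"found {n} connected component(s); need >= 2")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    flat = labels.reshape(-1)
    first_idx = np.full(n + 1, flat.size, dtype=np.int64)
    nz = np.flatnonzero(flat)
    # first occurrence per label (nz is sorted ascending)
    np.minimum.at(first_idx, flat[nz], nz)
    order = sorted(range(1, n + 1), key=lambda l: (-sizes[l - 1], first_idx[l]))
    cranium = xb.like((labels == order[0]).astype(np.uint8))
    mandible = xb.like((labels == order[1]).astype(np.uint8))
    return cranium, mandible


def integrate_midsagittal(xb: VolumeGrid, plane_v1: float,
                          half_width_mm: float = DEFAULT_HALF_WIDTH_MM) -> np.ndarray:
    """Partially integrated 2D image: sum the bone mask over a v1 slab.

    The slab covers ``plane_v1 +- half_width_mm`` (world mm along axis 0);
    voxels whose centers fall inside the closed interval are summed.  Returns
    an integer image indexed by (v2, v3) voxel indices.  A slab wholly
    outside the grid extent is an error; a slab inside the grid but too thin
    to contain a voxel center yields an all-zero image.
    """
    if not xb.is_binary():
        raise ValueError("integrate_midsagittal requires a binary volume")
    s1 = xb.spacing[0]
    lo_mm = plane_v1 - half_width_mm
    hi_mm = plane_v1 + half_width_mm
    extent_hi = xb.origin[0] + (xb.shape[0] - 1) * s1
    if hi_mm < xb.origin[0] - 1e-9 or lo_mm > extent_hi + 1e-9:
        raise ValueError(
            f"midsagittal slab [{lo_mm}, {hi_mm}] mm lies outside the grid")
    a = max(int(np.ceil((lo_mm - xb.origin[0]) / s1 - 1e-9)), 0)
    b = min(int(np.floor((hi_mm - xb.origin[0]) / s1 + 1e-9)), xb.shape[0] - 1)
    if a > b:  # inside the grid, but between voxel centers
        return np.zeros(xb.shape[1:], dtype=np.int64)
    return xb.data[a:b + 1].sum(axis=0).astype(np.int64)


def render_illuminated(xb: VolumeGrid, view_dir, light_dir) -> np.ndarray:
    """Orthographic illuminated view of a bone mask.

    ``view_dir`` must be one of the six cardinal unit vectors (the renderer is
    a deliberate axis-aligned simplification); ``light_dir`` is any unit
    vector pointing from the scene toward the light source, so ``light ==
    view`` lights the visible surface head-on.  The surface depth along the
    view axis gives per-pixel normals via depth gradients, shaded by the
    Lambertian term max(0, n . light) plus a small ambient floor.  Background
    pixels are exactly 0; every hit pixel is > 0, so the silhouette depends
    only on the mask, not the light.
    """
    view_dir = np.asarray(view_dir, dtype=float)
    light_dir = np.asarray(light_dir, dtype=float)
    for d in (view_dir, light_dir):
        n = np.linalg.norm(d)
        if n < 1e-12:
            raise ValueError("zero direction vector")
    view_dir = view_dir / np.linalg.norm(view_dir)
    light_dir = light_dir / np.linalg.norm(light_dir)
    key = tuple(np.round(view_dir, 6))
    if key not in _CARDINALS:
        raise ValueError("view_dir must be a cardinal unit vector (+-e1, +-e2, +-e3)")
    axis, sign = _CARDINALS[key]

    data = xb.data
    if sign > 0:
        data = np.flip(data, axis=axis)  # view from +axis: first hit at far end
    mask = np.moveaxis(data, axis, 0).astype(bool)
    hit = mask.any(axis=0)
    depth = np.argmax(mask, axis=0).astype(float) * xb.spacing[axis]

    # in-plane world axes for gradient spacing
    plane_axes = [a for a in range(3) if a != axis]
    gu, gv = np.gradient(depth, xb.spacing[plane_axes[0]], xb.spacing[plane_axes[1]])
    # surface height toward the viewer is -depth, so the outward normal is
    # proportional to (d depth/du, d depth/dv, 1) in (u, v, toward-viewer)
    norm = np.sqrt(gu ** 2 + gv ** 2 + 1.0)
    lu = light_dir[plane_axes[0]]
    lv = light_dir[plane_axes[1]]
    lw = sign * light_dir[axis]  # toward-viewer component of the light
    shade = (gu * lu + gv * lv + lw) / norm
    ambient = 0.05
    img = np.where(hit, ambient + (1.0 - ambient) * np.maximum(shade, 0.0), 0.0)
    return img


def render_depth(xb: VolumeGrid, view_dir) -> tuple[np.ndarray, np.ndarray]:
    """Depth map (mm from the viewing side) and hit mask for a cardinal view."""
    view_dir = np.asarray(view_dir, dtype=float)
    view_dir = view_dir / np.linalg.norm(view_dir)
    key = tuple(np.round(view_dir, 6))
    if key not in _CARDINALS:
        raise ValueError("view_dir must be a cardinal unit vector")
    axis, sign = _CARDINALS[key]
    data = xb.data
    if sign > 0:
        data = np.flip(data, axis=axis)
    mask = np.moveaxis(data, axis, 0).astype(bool)
    hit = mask.any(axis=0)
    depth = np.argmax(mask, axis=0).astype(float) * xb.spacing[axis]
    return np.where(hit, depth, 0.0), hit


@dataclass
class Patch3D:
    data: np.ndarray
    center_mm: np.ndarray
    center_voxel: tuple[int, int, int]
    provenance: str = ""

    @property
    def eta(self) -> int:
        return self.data.shape[0]


@dataclass
class Patch2D:
    data: np.ndarray
    center_mm: np.ndarray          # (v2, v3) mm
    center_pixel: tuple[int, int]
    provenance: str = ""

    @property
    def eta(self) -> int:
        return self.data.shape[0]


def _extract_nd(data: np.ndarray, center_idx, eta: int):
    """Zero-padded eta^nd crop centered on a voxel index."""
    nd = data.ndim
    half = eta // 2
    out = np.zeros((eta,) * nd, dtype=data.dtype)
    src, dst = [], []
    for ax in range(nd):
        c = center_idx[ax]
        lo = c - half
        hi = lo + eta
        s_lo, s_hi = max(lo, 0), min(hi, data.shape[ax])
        if s_lo >= s_hi:
            return None
        src.append(slice(s_lo, s_hi))
        dst.append(slice(s_lo - lo, s_hi - lo))
    out[tuple(dst)] = data[tuple(src)]
    return out


def extract_patch_3d(x: VolumeGrid, center_mm, eta_vox: int = 80,
                     provenance: str = "") -> Patch3D:
    """Cube of ``eta_vox`` voxels centered at the voxel nearest ``center_mm``.

    Voxels outside the grid are zero-filled; a center that puts the whole
    patch outside the grid is an error.
    """
    center_mm = np.asarray(center_mm, dtype=float)
    cidx = np.rint(x.mm_to_voxel(center_mm)).astype(int)
    out = _extract_nd(x.data, cidx, eta_vox)
    if out is None:
        raise ValueError(f"patch center {center_mm} mm maps outside padded bounds")
    return Patch3D(out, center_mm=x.voxel_to_mm(cidx), center_voxel=tuple(cidx),
                   provenance=provenance)


def extract_patch_2d(image: np.ndarray, grid: VolumeGrid, center_mm_23,
                     eta_px: int = 80, provenance: str = "") -> Patch2D:
    """Square patch from a (v2, v3)-indexed image, e.g. the midsagittal image.

    ``center_mm_23`` gives (v2, v3) world mm; pixel spacing and origin come
    from axes 1 and 2 of ``grid``.
    """
    center = np.asarray(center_mm_23, dtype=float)
    spacing = np.array(grid.spacing[1:])
    origin = grid.origin[1:]
    cidx = np.rint((center - origin) / spacing).astype(int)
    out = _extract_nd(np.asarray(image), cidx, eta_px)
    if out is None:
        raise ValueError(f"patch center {center} mm maps outside padded bounds")
    snapped = origin + cidx * spacing
    return Patch2D(out, center_mm=snapped, center_pixel=tuple(cidx), provenance=provenance)
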
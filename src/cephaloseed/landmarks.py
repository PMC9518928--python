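"""Landmark sets, the head coordinate frame, and cranial-volume normalization.

Coordinates are always stored in millimetres.  A :class:`LandmarkSet` carries a
``frame`` tag describing which coordinate frame the numbers live in:

``raw``
    scanner/world coordinates of the source volume;
``canonical``
    the head frame built from the five frame landmarks (CFM origin, v1 the
    midsagittal-plane normal from Po(L) to Po(R), v3 toward Bregma);
``normalized``
    canonical coordinates after the uniform scaling that fixes the cranial
    volume to a common target, so that shape — not size — is what a model sees.

The cranial volume is the product of three reference distances: |v1(PoL) -
v1(PoR)| (width) x |v2(PoL) - v2(Na)| (depth) x |v3(CFM) - v3(Bregma)|
(height), all measured in the canonical frame.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .registry import FRAME_NAMES, REFERENCE_NAMES, LandmarkRegistry

FRAMES = ("raw", "canonical", "normalized")

_FLOAT_FMT = "%.6f"


class DegenerateGeometryError(ValueError):
    """Frame or volume construction hit a degenerate landmark configuration."""


class FrameError(ValueError):
    """An operation received a LandmarkSet in the wrong coordinate frame."""


class MissingLandmarkError(KeyError):
    """A required landmark name is absent from the set."""

    def __init__(self, missing):
        self.missing = sorted(missing)
        super().__init__(f"missing landmarks: {self.missing}")


@dataclass
class LandmarkSet:
    """Named 3D points (mm) with a coordinate-frame tag."""

    coords: dict[str, np.ndarray]
    frame: str = "raw"
    registry: LandmarkRegistry = field(default_factory=LandmarkRegistry.default, repr=False)

    def __post_init__(self):
        if self.frame not in FRAMES:
            raise FrameError(f"unknown frame {self.frame!r}")
        clean = {}
        for k, v in self.coords.items():
            a = np.asarray(v, dtype=float).reshape(3)
            if not np.all(np.isfinite(a)):
                raise ValueError(f"non-finite coordinates for {k!r}")
            clean[k] = a
        self.coords = clean

    # -- basic access -----------------------------------------------------

    @property
    def mask(self) -> set[str]:
        return set(self.coords)

    def __len__(self) -> int:
        return len(self.coords)

    def __getitem__(self, name: str) -> np.ndarray:
        try:
            return self.coords[name]
        except KeyError:
            raise MissingLandmarkError([name]) from None

    def names_in_order(self) -> list[str]:
        return [n for n in self.registry.names if n in self.coords]

    def require(self, names) -> None:
        missing = [n for n in names if n not in self.coords]
        if missing:
            raise MissingLandmarkError(missing)

    def to_vector(self, names=None) -> np.ndarray:
        """Concatenate coordinates (registry order) into a flat vector."""
        names = self.names_in_order() if names is None else list(names)
        self.require(names)
        return np.concatenate([self.coords[n] for n in names])

    @classmethod
    def from_vector(cls, vec, names, frame, registry=None) -> "LandmarkSet":
        vec = np.asarray(vec, dtype=float).reshape(-1)
        names = list(names)
        if vec.size != 3 * len(names):
            raise ValueError(f"vector length {vec.size} != 3*{len(names)}")
        kw = {} if registry is None else {"registry": registry}
        return cls({n: vec[3 * i:3 * i + 3] for i, n in enumerate(names)}, frame=frame, **kw)

    def subset(self, names) -> "LandmarkSet":
        self.require(names)
        order = [n for n in self.registry.names if n in set(names)]
        return LandmarkSet({n: self.coords[n].copy() for n in order},
                           frame=self.frame, registry=self.registry)

    def with_frame(self, frame: str) -> "LandmarkSet":
        return LandmarkSet({k: v.copy() for k, v in self.coords.items()},
                           frame=frame, registry=self.registry)

    def updated(self, other: "LandmarkSet") -> "LandmarkSet":
        """Return a copy with coordinates overridden by ``other`` (same frame)."""
        if other.frame != self.frame:
            raise FrameError(f"cannot merge frame {other.frame!r} into {self.frame!r}")
        coords = {k: v.copy() for k, v in self.coords.items()}
        coords.update({k: v.copy() for k, v in other.coords.items()})
        return LandmarkSet(coords, frame=self.frame, registry=self.registry)


@dataclass(frozen=True)
class RigidFrame:
    """Head coordinate frame: rows of ``axes`` are the v1, v2, v3 directions."""

    origin: np.ndarray
    axes: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "origin", np.asarray(self.origin, dtype=float).reshape(3))
        object.__setattr__(self, "axes", np.asarray(self.axes, dtype=float).reshape(3, 3))
        if not np.allclose(self.axes @ self.axes.T, np.eye(3), atol=1e-8):
            raise DegenerateGeometryError("frame axes are not orthonormal")
        if np.linalg.det(self.axes) < 0:
            raise DegenerateGeometryError("frame axes must be right-handed")

    def to_canonical(self, lm: LandmarkSet) -> LandmarkSet:
        """Map a raw-frame set into canonical head coordinates."""
        coords = {k: self.axes @ (v - self.origin) for k, v in lm.coords.items()}
        return LandmarkSet(coords, frame="canonical", registry=lm.registry)

    def to_raw(self, lm: LandmarkSet) -> LandmarkSet:
        coords = {k: self.axes.T @ v + self.origin for k, v in lm.coords.items()}
        return LandmarkSet(coords, frame="raw", registry=lm.registry)

    def point_to_canonical(self, p) -> np.ndarray:
        return self.axes @ (np.asarray(p, dtype=float) - self.origin)

    def point_to_raw(self, p) -> np.ndarray:
        return self.axes.T @ np.asarray(p, dtype=float) + self.origin


def build_frame(ref5: LandmarkSet) -> RigidFrame:
    """Build the head frame from CFM, Bregma, Na, Po(L), Po(R).

    v1 is the unit vector from Po(L) to Po(R) (midsagittal-plane normal), v3
    is Bregma - CFM orthogonalized against v1, v2 = v3 x v1, and the origin
    is CFM.  Raises :class:`DegenerateGeometryError` when Bregma - CFM is
    (near-)collinear with the Po axis or either direction vanishes.
    """
    ref5.require(FRAME_NAMES)
    po_l, po_r = ref5["Po(L)"], ref5["Po(R)"]
    cfm, bregma = ref5["CFM"], ref5["Bregma"]
    d1 = po_r - po_l
    n1 = np.linalg.norm(d1)
    if n1 < 1e-9:
        raise DegenerateGeometryError("Po(L) and Po(R) coincide")
    v1 = d1 / n1
    d3 = bregma - cfm
    d3 = d3 - (d3 @ v1) * v1
    n3 = np.linalg.norm(d3)
    if n3 < 1e-9:
        raise DegenerateGeometryError("Bregma-CFM direction collinear with Po axis")
    v3 = d3 / n3
    v2 = np.cross(v3, v1)
    return RigidFrame(origin=cfm, axes=np.stack([v1, v2, v3]))


def cranial_volume(refs: LandmarkSet) -> float:
    """Cranial volume (mm^3): width x depth x height product in canonical frame."""
    if refs.frame != "canonical":
        raise FrameError("cranial_volume requires canonical-frame landmarks")
    refs.require(FRAME_NAMES)
    width = abs(refs["Po(L)"][0] - refs["Po(R)"][0])
    depth = abs(refs["Po(L)"][1] - refs["Na"][1])
    height = abs(refs["CFM"][2] - refs["Bregma"][2])
    vol = width * depth * height
    if vol <= 0.0:
        raise DegenerateGeometryError(
            f"degenerate cranial volume (width={width}, depth={depth}, height={height})")
    return float(vol)


def normalize_scale(lm: LandmarkSet, target_volume: float) -> tuple[LandmarkSet, float]:
    """Uniformly scale about the frame origin so the cranial volume hits target.

    Returns the scaled set (frame tag ``normalized``) and the scale factor s =
    (target / volume)^(1/3); dividing by s recovers the canonical input.
    """
    if lm.frame != "canonical":
        raise FrameError("normalize_scale requires canonical-frame landmarks")
    if target_volume <= 0:
        raise ValueError("target_volume must be positive")
    s = float((target_volume / cranial_volume(lm)) ** (1.0 / 3.0))
    coords = {k: v * s for k, v in lm.coords.items()}
    return LandmarkSet(coords, frame="normalized", registry=lm.registry), s


def denormalize_scale(lm: LandmarkSet, scale_factor: float) -> LandmarkSet:
    """Invert :func:`normalize_scale` back to the canonical frame."""
    if lm.frame != "normalized":
        raise FrameError("denormalize_scale requires normalized-frame landmarks")
    coords = {k: v / scale_factor for k, v in lm.coords.items()}
    return LandmarkSet(coords, frame="canonical", registry=lm.registry)


def subsample_reference(lm: LandmarkSet) -> LandmarkSet:
    """The Sub operator: keep exactly the 10 reference landmarks, registry order."""
    lm.require(REFERENCE_NAMES)
    return lm.subset(REFERENCE_NAMES)


# -- I/O -------------------------------------------------------------------

def write_csv(lm: LandmarkSet, path: str | Path) -> None:
    """Write `name,index,region,v1_mm,v2_mm,v3_mm` with fixed float formatting."""
    rows = []
    for n in lm.names_in_order():
        e = lm.registry[n]
        v = lm.coords[n]
        rows.append((n, e.index, e.region,
                     _FLOAT_FMT % v[0], _FLOAT_FMT % v[1], _FLOAT_FMT % v[2]))
    df = pd.DataFrame(rows, columns=["name", "index", "region", "v1_mm", "v2_mm", "v3_mm"])
    df.to_csv(path, index=False)


def read_csv(path: str | Path, frame: str = "raw",
             registry: LandmarkRegistry | None = None) -> LandmarkSet:
    df = pd.read_csv(path)
    for col in ("name", "v1_mm", "v2_mm", "v3_mm"):
        if col not in df.columns:
            raise ValueError(f"landmark CSV missing column {col!r}")
    coords = {str(r["name"]): np.array([r["v1_mm"], r["v2_mm"], r["v3_mm"]], dtype=float)
              for _, r in df.iterrows()}
    kw = {} if registry is None else {"registry": registry}
    return LandmarkSet(coords, frame=frame, **kw)


def write_json(lm: LandmarkSet, path: str | Path) -> None:
    payload = {
        "frame": lm.frame,
        "landmarks": {n: [float(_FLOAT_FMT % x) for x in lm.coords[n]]
                      for n in lm.names_in_order()},
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def read_json(path: str | Path, registry: LandmarkRegistry | None = None) -> LandmarkSet:
    payload = json.loads(Path(path).read_text())
    kw = {} if registry is None else {"registry": registry}
    return LandmarkSet({k: np.asarray(v, dtype=float) for k, v in payload["landmarks"].items()},
                       frame=payload.get("frame", "raw"), **kw)
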
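"""Canonical 90-landmark registry.

The skull landmark set comprises 46 cranial and 44 mandibular named points.
Ten of them are the easy-to-find *reference* landmarks (Bregma, CFM, Na, ANS,
Or(L/R), Po(L/R) on the cranium; the mental foramina MF(L/R) on the mandible)
that anchor the coordinate frame, the scale normalization, and the
local-to-global estimation.  Three further cranial landmarks near the
midsagittal plane (MxDML, Od, PNS) are refined on the partially integrated 2D
image.

The registry shipped in ``data/registry_90.csv`` contains every name required
by the method; names outside that required set are repo-defined picks from
standard cephalometric nomenclature (Sella, Basion, Gonion, Menton, ...) and
are editable — the code treats the CSV, not any hard-coded index range, as
authoritative for landmark order, regions, and refinement groups.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

#: The 10 reference landmark names (8 cranial + 2 mandibular).
REFERENCE_NAMES = (
    "Bregma", "CFM", "Na", "ANS", "Or(L)", "Or(R)", "Po(L)", "Po(R)",
    "MF(L)", "MF(R)",
)
#: The 5 names used to build the head coordinate frame.
FRAME_NAMES = ("CFM", "Bregma", "Na", "Po(L)", "Po(R)")
#: Midsagittal landmarks refined on the partially integrated 2D image.
MIDSAGITTAL_FINE_NAMES = ("MxDML", "Od", "PNS")
#: The six condyle landmarks detected jointly, per side (base names).
CONDYLE_BASE_NAMES = ("COR", "MCP", "LCP", "Cp", "Ct-in", "Ct-out")


class RegistryError(ValueError):
    """Raised when a registry file violates the 90-landmark contract."""


def mirror_name(name: str) -> str:
    """Swap the (L)/(R) laterality tag of a landmark name (midline: no-op)."""
    if name.endswith("(L)"):
        return name[:-3] + "(R)"
    if name.endswith("(R)"):
        return name[:-3] + "(L)"
    return name


@dataclass(frozen=True)
class RegistryEntry:
    index: int
    name: str
    region: str        # "cranial" | "mandibular"
    laterality: str    # "L" | "R" | "midline"
    group_id: str


class LandmarkRegistry:
    """Ordered table of the 90 named skull landmarks.

    Defines the canonical concatenation order of landmark vectors: the full
    configuration lives in R^270 (90 x 3), the cranial block in R^138
    (46 x 3) and the mandibular block in R^132 (44 x 3), always in registry
    order.
    """

    def __init__(self, entries: list[RegistryEntry]):
        self.entries = list(entries)
        self._by_name = {e.name: e for e in self.entries}
        self._validate()

    # -- construction -----------------------------------------------------

    @classmethod
    def from_csv(cls, path: str | Path) -> "LandmarkRegistry":
        df = pd.read_csv(path)
        entries = [
            RegistryEntry(int(r["index"]), str(r["name"]), str(r["region"]),
                          str(r["laterality"]), str(r["group_id"]))
            for _, r in df.iterrows()
        ]
        return cls(entries)

    @classmethod
    def default(cls) -> "LandmarkRegistry":
        with resources.as_file(
            resources.files("cephaloseed.data") / "registry_90.csv"
        ) as p:
            return cls.from_csv(p)

    def _validate(self) -> None:
        if len(self.entries) != 90:
            raise RegistryError(f"registry must have 90 entries, got {len(self.entries)}")
        names = [e.name for e in self.entries]
        if len(set(names)) != 90:
            raise RegistryError("registry names must be unique")
        n_cr = sum(e.region == "cranial" for e in self.entries)
        n_md = sum(e.region == "mandibular" for e in self.entries)
        if (n_cr, n_md) != (46, 44):
            raise RegistryError(f"expected 46 cranial / 44 mandibular, got {n_cr}/{n_md}")
        missing = [n for n in REFERENCE_NAMES if n not in self._by_name]
        if missing:
            raise RegistryError(f"missing reference landmarks: {missing}")
        for n in MIDSAGITTAL_FINE_NAMES:
            e = self._by_name.get(n)
            if e is None or e.region != "cranial":
                raise RegistryError(f"midsagittal landmark {n} missing or not cranial")
        for side in ("L", "R"):
            want = {f"{b}({side})" for b in CONDYLE_BASE_NAMES}
            got = {e.name for e in self.entries
                   if e.group_id == f"condyle_{side}"}
            if got != want:
                raise RegistryError(f"condyle_{side} group must be exactly {sorted(want)}")

    # -- queries ----------------------------------------------------------

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def __getitem__(self, name: str) -> RegistryEntry:
        return self._by_name[name]

    @property
    def names(self) -> list[str]:
        return [e.name for e in self.entries]

    def names_of_region(self, region: str) -> list[str]:
        return [e.name for e in self.entries if e.region == region]

    @property
    def cranial_names(self) -> list[str]:
        return self.names_of_region("cranial")

    @property
    def mandibular_names(self) -> list[str]:
        return self.names_of_region("mandibular")

    @property
    def reference_names(self) -> list[str]:
        """The 10 reference names, in registry order."""
        return [n for n in self.names if n in set(REFERENCE_NAMES)]

    @property
    def cranial_reference_names(self) -> list[str]:
        return [n for n in self.reference_names if self[n].region == "cranial"]

    @property
    def midsagittal_names(self) -> list[str]:
        return [n for n in self.names if n in set(MIDSAGITTAL_FINE_NAMES)]

    @property
    def mandibular_group_ids(self) -> list[str]:
        """The patch-refinement groups partitioning the 44 mandibular names."""
        seen: list[str] = []
        for e in self.entries:
            if e.region == "mandibular" and e.group_id not in seen:
                seen.append(e.group_id)
        return seen

    def group_members(self, group_id: str) -> list[str]:
        return [e.name for e in self.entries if e.group_id == group_id]

    def ordered(self, names) -> list[str]:
        """Return the given names sorted into registry order."""
        want = set(names)
        unknown = want - set(self.names)
        if unknown:
            raise RegistryError(f"unknown landmark names: {sorted(unknown)}")
        return [n for n in self.names if n in want]

    def content_hash(self) -> str:
        """Stable hash of the registry contents (guards model checkpoints)."""
        h = hashlib.sha256()
        for e in self.entries:
            h.update(f"{e.index},{e.name},{e.region},{e.laterality},{e.group_id}\n".encode())
        return h.hexdigest()

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            [(e.index, e.name, e.region, e.laterality, e.group_id) for e in self.entries],
            columns=["index", "name", "region", "laterality", "group_id"],
        )
        df.to_csv(path, index=False)
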
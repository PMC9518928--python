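"""Detection-error metrics.

The mean detection error (MDE) of a set of estimated landmark configurations
is the average, over evaluated subjects, of the per-subject error; the
per-subject error is the average, over its landmarks, of the Euclidean
distance (mm) between estimate and ground truth.  Region aggregates
(cranial/mandibular) average per-landmark errors uniformly within the region,
so with full 90-landmark masks ``mde_all = (46*mde_cranial + 44*mde_mandibular)/90``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .landmarks import LandmarkSet


@dataclass
class DetectionReport:
    per_landmark: dict[str, float]
    mde_all: float
    mde_cranial: float
    mde_mandibular: float
    n_eval: int
    per_subject: list[float] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "n_eval": self.n_eval,
            "mde_all": self.mde_all,
            "mde_cranial": self.mde_cranial,
            "mde_mandibular": self.mde_mandibular,
            "per_subject": list(self.per_subject),
            "per_landmark": dict(self.per_landmark),
        }


def pair_errors(est: LandmarkSet, label: LandmarkSet) -> dict[str, float]:
    """Per-landmark Euclidean distances (mm) for one estimate/label pair."""
    if est.mask != label.mask:
        raise ValueError(
            f"landmark mask mismatch: est-only={sorted(est.mask - label.mask)}, "
            f"label-only={sorted(label.mask - est.mask)}")
    return {n: float(np.linalg.norm(est[n] - label[n])) for n in est.names_in_order()}


def mde(est: list[LandmarkSet], label: list[LandmarkSet],
        region_filter: str | None = None) -> DetectionReport:
    """Mean detection error over subject pairs, with region splits.

    ``region_filter`` restricts evaluation to "cranial" or "mandibular"
    landmarks before any averaging.
    """
    if len(est) != len(label):
        raise ValueError(f"est/label length mismatch: {len(est)} vs {len(label)}")
    if not est:
        raise ValueError("empty evaluation set")

    registry = est[0].registry
    per_subject: list[float] = []
    sums: dict[str, float] = {}
    counts: dict[str, int] = {}
    for e, l in zip(est, label):
        errs = pair_errors(e, l)
        if region_filter is not None:
            errs = {n: v for n, v in errs.items()
                    if registry[n].region == region_filter}
            if not errs:
                raise ValueError(f"no {region_filter} landmarks in pair")
        per_subject.append(float(np.mean(list(errs.values()))))
        for n, v in errs.items():
            sums[n] = sums.get(n, 0.0) + v
            counts[n] = counts.get(n, 0) + 1

    per_landmark = {n: sums[n] / counts[n] for n in sums}

    def _region_mean(region: str) -> float:
        vals = [v for n, v in per_landmark.items() if registry[n].region == region]
        return float(np.mean(vals)) if vals else float("nan")

    return DetectionReport(
        per_landmark=per_landmark,
        mde_all=float(np.mean(per_subject)),
        mde_cranial=_region_mean("cranial"),
        mde_mandibular=_region_mean("mandibular"),
        n_eval=len(est),
        per_subject=per_subject,
    )
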
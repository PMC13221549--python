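"""Contour-agreement metrics on binary masks: DSC, Hausdorff distance, MDA.

The Dice similarity coefficient measures volume overlap,

    DSC(A, B) = 2 |A ∩ B| / (|A| + |B|),

and is computed by voxel counting. The Hausdorff distance and mean
distance to agreement are surface metrics over the two boundary point
sets: with the directed distance h(A, B) = max_{a∈∂A} min_{b∈∂B} ||a − b||,

    HD(A, B) = max(h(A, B), h(B, A)),

and MDA replaces the maximum with a mean. "Replace max with mean" is
ambiguous about symmetrization; the default here pools every boundary
point of both surfaces into one mean (weighted by point counts), with the
mean-of-directed-means variant available via ``symmetrization``.

Boundary semantics: a boundary voxel is a mask voxel with at least one of
its 6 face-neighbours outside the mask (out-of-lattice counts as outside);
distances are Euclidean in mm between voxel centers, honouring anisotropic
spacing. HD is the exact 100th-percentile Hausdorff, not a 95% variant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .config import ToleranceCriteria
from .errors import UndefinedMetricError
from .grids import OrganMask, validate_alignment

_FACE_STRUCT = ndimage.generate_binary_structure(3, 1)


@dataclass
class BoundaryPointSet:
    """World coordinates (mm) of the 6-connectivity boundary voxel centers."""

    points: np.ndarray  # (n, 3) float64, mm

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=np.float64).reshape(-1, 3)
        if len(self.points) == 0:
            raise UndefinedMetricError("boundary point set is empty")


@dataclass
class MetricResult:
    """DSC/HD/MDA for one (candidate, reference) pair plus tolerance flags."""

    dsc: float
    hd_mm: float
    mda_mm: float
    dsc_ok: bool
    hd_ok: bool
    mda_ok: bool

    @property
    def all_ok(self) -> bool:
        return self.dsc_ok and self.hd_ok and self.mda_ok


def boundary_points(mask: OrganMask) -> BoundaryPointSet:
    """Extract the boundary voxel centers of a non-empty mask, in mm."""
    if not mask.values.any():
        raise UndefinedMetricError(f"mask for {mask.organ} is empty")
    eroded = ndimage.binary_erosion(
        mask.values, structure=_FACE_STRUCT, border_value=0
    )
    boundary = mask.values & ~eroded
    idx = np.argwhere(boundary)
    return BoundaryPointSet(points=idx * np.asarray(mask.spacing))


def dice(a: OrganMask, b: OrganMask) -> float:
    """Dice similarity coefficient by voxel counting."""
    validate_alignment(a, b)
    na, nb = int(a.values.sum()), int(b.values.sum())
    if na + nb == 0:
        raise UndefinedMetricError("both masks are empty")
    inter = int(np.logical_and(a.values, b.values).sum())
    return 2.0 * inter / (na + nb)


def _nearest_distances(a: OrganMask, b: OrganMask):
    validate_alignment(a, b)
    pa = boundary_points(a).points
    pb = boundary_points(b).points
    d_ab = cKDTree(pb).query(pa, workers=-1)[0]
    d_ba = cKDTree(pa).query(pb, workers=-1)[0]
    return d_ab, d_ba


def hausdorff(a: OrganMask, b: OrganMask) -> float:
    """Exact symmetric Hausdorff distance between boundary point sets, mm."""
    d_ab, d_ba = _nearest_distances(a, b)
    return float(max(d_ab.max(), d_ba.max()))


def mda(a: OrganMask, b: OrganMask, symmetrization: str = "pooled") -> float:
    """Mean distance to agreement between boundary point sets, mm.

    symmetrization : "pooled" (default) averages all nearest-neighbour
        distances of both boundaries together; "directed_mean" averages
        the two directed means.
    """
    d_ab, d_ba = _nearest_distances(a, b)
    if symmetrization == "pooled":
        return float((d_ab.sum() + d_ba.sum()) / (len(d_ab) + len(d_ba)))
    if symmetrization == "directed_mean":
        return float((d_ab.mean() + d_ba.mean()) / 2.0)
    raise ValueError(f"unknown symmetrization {symmetrization!r}")


def evaluate_contour(
    candidate: OrganMask,
    reference: OrganMask,
    criteria: ToleranceCriteria | None = None,
    symmetrization: str = "pooled",
) -> MetricResult | None:
    """All three metrics plus tolerance flags for one contour pair.

    Absent-organ pairs (either mask flagged absent) yield ``None`` — a
    skipped record — mirroring the exclusion of post-surgical spleens from
    cohort analysis. Empty masks *not* flagged absent raise.
    """
    if candidate.absent or reference.absent:
        return None
    criteria = criteria or ToleranceCriteria()
    d = dice(candidate, reference)
    hd = hausdorff(candidate, reference)
    m = mda(candidate, reference, symmetrization=symmetrization)
    return MetricResult(
        dsc=d,
        hd_mm=hd,
        mda_mm=m,
        dsc_ok=d >= criteria.dsc_min,
        hd_ok=hd <= criteria.hd_max_mm,
        mda_ok=m <= criteria.mda_max_mm,
    )


def criteria_rate(flags) -> tuple[float, int, int]:
    """Percentage of passing cases, one-decimal rounded, with (passing, total).

    ``flags`` is a sequence of booleans (one per case). 22/23 → (95.7, 22, 23).
    """
    flags = list(flags)
    if not flags:
        raise ValueError("criteria_rate needs at least one result")
    passing = sum(bool(f) for f in flags)
    total = len(flags)
    return round(100.0 * passing / total, 1), passing, total
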
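"""Voxel lattices with physical spacing: scalar volumes and binary organ masks.

Conventions used throughout the package:

* axis order is (slice, row, column);
* the world position of voxel ``(i, j, k)`` is its center, at
  ``(i * s0, j * s1, k * s2)`` mm, i.e. the origin sits at the center of
  voxel ``(0, 0, 0)``;
* spacing is anisotropic and always carried alongside the data; mismatched
  grids are an error, never silently resampled.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import AlignmentError, QuantityError

#: physical quantities a VolumeGrid may carry
QUANTITIES = ("HU", "cps", "MBq", "Gy_per_s", "Gy", "g_per_cm3")

ORGANS = ("liver", "spleen", "kidney_right", "kidney_left")
SOURCES = ("reference", "manual", "ai")

SPACING_ATOL_MM = 1e-6


def _as_spacing(spacing) -> tuple[float, float, float]:
    s = tuple(float(x) for x in spacing)
    if len(s) != 3:
        raise ValueError(f"spacing must have 3 entries, got {len(s)}")
    if any(x <= 0 for x in s):
        raise ValueError(f"spacing must be positive, got {s}")
    return s


@dataclass
class VolumeGrid:
    """A 3-D scalar lattice with per-axis voxel size in mm.

    Parameters
    ----------
    values : ndarray
        3-D array of voxel values (converted to float64).
    spacing : (float, float, float)
        Voxel size in mm along (slice, row, column).
    quantity : str
        One of ``HU, cps, MBq, Gy_per_s, Gy, g_per_cm3`` — the physical
        quantity the voxels carry. Operations check this tag and refuse
        physically meaningless inputs.
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    quantity: str

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError(f"expected a 3-D lattice, got ndim={self.values.ndim}")
        if min(self.values.shape) < 1:
            raise ValueError("lattice must have at least one voxel per axis")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("lattice contains non-finite values")
        self.spacing = _as_spacing(self.spacing)
        if self.quantity not in QUANTITIES:
            raise QuantityError(
                f"unknown quantity {self.quantity!r}; expected one of {QUANTITIES}"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_ml(self) -> float:
        """Volume of one voxel in mL (spacing is mm, 1 mL = 1000 mm^3)."""
        return float(np.prod(self.spacing)) / 1000.0

    def like(self, values: np.ndarray, quantity: str) -> "VolumeGrid":
        """A new grid on this grid's lattice carrying different values."""
        return VolumeGrid(values=values, spacing=self.spacing, quantity=quantity)

    def require(self, quantity: str) -> None:
        if self.quantity != quantity:
            raise QuantityError(
                f"expected a {quantity} grid, got {self.quantity}"
            )


@dataclass
class OrganMask:
    """A binary lattice aligned to a companion :class:`VolumeGrid`.

    ``absent`` flags organs that are genuinely missing (e.g. post-surgical
    spleens); an absent mask is empty by construction and is skipped, not
    compared, by cohort code.
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    organ: str
    source: str = "reference"
    absent: bool = False

    def __post_init__(self):
        self.values = np.asarray(self.values).astype(bool)
        if self.values.ndim != 3:
            raise ValueError(f"expected a 3-D mask, got ndim={self.values.ndim}")
        self.spacing = _as_spacing(self.spacing)
        if self.organ not in ORGANS:
            raise ValueError(f"unknown organ {self.organ!r}; expected one of {ORGANS}")
        if self.source not in SOURCES:
            raise ValueError(f"unknown source {self.source!r}; expected one of {SOURCES}")
        if not self.absent and not self.values.any():
            raise ValueError(
                f"mask for {self.organ} is empty but not flagged absent"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_count(self) -> int:
        return int(self.values.sum())

    @property
    def volume_ml(self) -> float:
        return self.voxel_count * float(np.prod(self.spacing)) / 1000.0

    def with_values(self, values: np.ndarray, source: str | None = None) -> "OrganMask":
        return replace(
            self,
            values=values,
            source=self.source if source is None else source,
            absent=not np.asarray(values).any(),
        )


def validate_alignment(a, b) -> None:
    """Check that two lattices share shape and spacing.

    Returns silently iff shapes are equal and per-axis spacings agree to
    within 1e-6 mm; otherwise raises :class:`AlignmentError` naming the
    first differing axis. Symmetric in its arguments.
    """
    sa, sb = a.values.shape, b.values.shape
    for ax in range(3):
        if sa[ax] != sb[ax]:
            raise AlignmentError(
                f"shape mismatch on axis {ax}: {sa[ax]} vs {sb[ax]}"
            )
    for ax in range(3):
        if abs(a.spacing[ax] - b.spacing[ax]) > SPACING_ATOL_MM:
            raise AlignmentError(
                f"spacing mismatch on axis {ax}: "
                f"{a.spacing[ax]} vs {b.spacing[ax]} mm"
            )
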
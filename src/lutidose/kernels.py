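"""Voxel S-value dose kernels.

A dose kernel tabulates the dose rate delivered to surrounding voxels per
unit activity in the central source voxel (Gy/s per MBq), on the same
lattice spacing as the activity map it will be convolved with. Published
voxel S-value tables have exactly this shape; :func:`make_test_kernel`
builds a physically plausible synthetic stand-in with a dominant self-dose
term and an exponentially decaying cross-dose tail, which is convenient
because its integral properties are known in closed form.

File dialect (plain text, single file): the first line is a JSON header
``{"spacing_mm": [s, r, c], "units": "Gy_s_per_MBq", "shape": [a, b, c]}``;
the remaining lines are the table values in row-major order, one
comma-separated row of the last axis per line.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import KernelError
from .grids import SPACING_ATOL_MM, _as_spacing

KERNEL_UNITS = "Gy_s_per_MBq"


@dataclass
class DoseKernel:
    """Odd-sided 3-D dose-rate table, Gy/s per MBq in the center voxel."""

    values: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise KernelError(f"kernel must be 3-D, got ndim={self.values.ndim}")
        if any(n % 2 == 0 for n in self.values.shape):
            raise KernelError(
                f"kernel extents must all be odd, got {self.values.shape}"
            )
        if np.any(self.values < 0):
            raise KernelError("kernel entries must be non-negative")
        if not np.all(np.isfinite(self.values)):
            raise KernelError("kernel contains non-finite entries")
        c = self.center_index
        if self.values[c] < self.values.max():
            raise KernelError(
                "center entry (self-dose) must be the maximum kernel entry"
            )
        self.spacing = _as_spacing(self.spacing)

    @property
    def center_index(self) -> tuple[int, int, int]:
        return tuple(n // 2 for n in self.values.shape)

    @property
    def total(self) -> float:
        """Sum of all entries: whole-lattice dose rate per MBq (Gy/s/MBq)."""
        return float(self.values.sum())

    def check_spacing(self, spacing) -> None:
        for ax in range(3):
            if abs(self.spacing[ax] - spacing[ax]) > SPACING_ATOL_MM:
                raise KernelError(
                    f"kernel spacing {self.spacing[ax]} mm differs from grid "
                    f"spacing {spacing[ax]} mm on axis {ax}"
                )


#: default whole-kernel dose-rate total: 7.5e-4 Gy/s per MBq at a 27 mm^3
#: voxel, scaled inversely with voxel volume (dose is energy per mass, so
#: voxel S-value totals shrink as voxels grow)
REFERENCE_TOTAL_GY_S_PER_MBQ = 7.5e-4
REFERENCE_VOXEL_MM3 = 27.0


def make_test_kernel(
    spacing,
    self_fraction: float = 0.7,
    range_mm: float = 4.0,
    total: float | None = None,
) -> DoseKernel:
    """Synthetic voxel S-value kernel with known integral properties.

    The center voxel carries ``self_fraction`` of the total kernel mass
    (the self-dose term); the remainder decays as ``exp(-r / range_mm)``
    with radial distance r, truncated at 3 * range_mm. The kernel sums to
    ``total`` Gy/s per MBq exactly; when ``total`` is None it defaults to
    ``REFERENCE_TOTAL_GY_S_PER_MBQ`` rescaled by 27 mm^3 / voxel volume.

    ``self_fraction = 1`` yields the pure local-deposition (1x1x1) kernel,
    for which dose maps are analytically trivial — used by the recovery
    tests.
    """
    if not (0 < self_fraction <= 1):
        raise ValueError("self_fraction must lie in (0, 1]")
    if range_mm <= 0:
        raise ValueError("range_mm must be > 0")
    spacing = _as_spacing(spacing)
    if total is None:
        total = REFERENCE_TOTAL_GY_S_PER_MBQ * REFERENCE_VOXEL_MM3 / (
            spacing[0] * spacing[1] * spacing[2]
        )
    if total <= 0:
        raise ValueError("total must be > 0")
    if self_fraction == 1.0:
        return DoseKernel(values=np.full((1, 1, 1), total), spacing=spacing)

    cutoff = 3.0 * range_mm
    half = [max(1, int(np.ceil(cutoff / s))) for s in spacing]
    ax = [np.arange(-h, h + 1) * s for h, s in zip(half, spacing)]
    r = np.sqrt(
        ax[0][:, None, None] ** 2 + ax[1][None, :, None] ** 2 + ax[2][None, None, :] ** 2
    )
    tail = np.where((r > 0) & (r <= cutoff), np.exp(-r / range_mm), 0.0)
    tail *= (1.0 - self_fraction) * total / tail.sum()
    values = tail
    values[tuple(half)] = self_fraction * total
    return DoseKernel(values=values, spacing=spacing)


def save_kernel(kernel: DoseKernel, path) -> None:
    """Write a kernel in the JSON-header + CSV-body dialect."""
    path = Path(path)
    header = {
        "spacing_mm": list(kernel.spacing),
        "units": KERNEL_UNITS,
        "shape": list(kernel.values.shape),
    }
    rows = kernel.values.reshape(-1, kernel.values.shape[2])
    body = "\n".join(",".join(repr(float(v)) for v in row) for row in rows)
    path.write_text(json.dumps(header) + "\n" + body + "\n")


def load_kernel(path) -> DoseKernel:
    """Read a kernel file; structural contracts are re-verified on load."""
    path = Path(path)
    lines = path.read_text().strip().splitlines()
    if not lines:
        raise KernelError(f"{path}: empty kernel file")
    try:
        header = json.loads(lines[0])
        spacing = header["spacing_mm"]
        shape = tuple(int(n) for n in header["shape"])
    except (json.JSONDecodeError, KeyError, TypeError, ValueError) as exc:
        raise KernelError(f"{path}: bad kernel header: {exc}") from exc
    if header.get("units") != KERNEL_UNITS:
        raise KernelError(
            f"{path}: kernel units must be {KERNEL_UNITS!r}, got {header.get('units')!r}"
        )
    try:
        flat = np.array(
            [float(v) for line in lines[1:] for v in line.split(",") if v.strip()]
        )
        values = flat.reshape(shape)
    except ValueError as exc:
        raise KernelError(f"{path}: kernel body does not match shape {shape}: {exc}") from exc
    return DoseKernel(values=values, spacing=spacing)
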
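"""NIfTI readers/writers for volumes and masks, with JSON sidecars.

Volumes are float64 NIfTI with a diagonal affine built from the spacing;
masks are uint8 {0,1}. Labels that NIfTI has no standard slot for
(quantity, organ, source, absent flag) live in a JSON sidecar next to the
image: ``case_ct.nii`` ↔ ``case_ct.json``.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import nibabel as nib
import numpy as np

from .errors import FormatError
from .grids import OrganMask, VolumeGrid


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".json")
    return path.with_suffix(".json")


def _read_sidecar(path: Path) -> dict:
    sc = _sidecar_path(path)
    if sc.exists():
        return json.loads(sc.read_text())
    return {}


def _write_sidecar(path: Path, meta: dict) -> None:
    _sidecar_path(path).write_text(json.dumps(meta, indent=1, sort_keys=True) + "\n")


def _load_nifti(path: Path):
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several unrelated types
        raise FormatError(f"{path}: not a readable NIfTI image: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise FormatError(f"{path}: expected a 3-D image, got ndim={data.ndim}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    if any(s <= 0 for s in spacing):
        raise FormatError(f"{path}: non-positive voxel spacing {spacing}")
    return data, spacing


def write_volume(volume: VolumeGrid, path) -> None:
    path = Path(path)
    affine = np.diag(list(volume.spacing) + [1.0])
    nib.save(nib.Nifti1Image(volume.values, affine), str(path))
    _write_sidecar(path, {"quantity": volume.quantity})


def read_volume(path, quantity: str | None = None) -> VolumeGrid:
    """Read a scalar volume; quantity comes from the sidecar unless given."""
    path = Path(path)
    data, spacing = _load_nifti(path)
    if quantity is None:
        quantity = _read_sidecar(path).get("quantity")
    if quantity is None:
        raise FormatError(
            f"{path}: no quantity in sidecar and none supplied"
        )
    return VolumeGrid(values=data.astype(np.float64), spacing=spacing, quantity=quantity)


def write_mask(mask: OrganMask, path) -> None:
    path = Path(path)
    affine = np.diag(list(mask.spacing) + [1.0])
    nib.save(nib.Nifti1Image(mask.values.astype(np.uint8), affine), str(path))
    _write_sidecar(
        path, {"organ": mask.organ, "source": mask.source, "absent": mask.absent}
    )


def read_mask(
    path, organ: str | None = None, source: str | None = None
) -> OrganMask:
    """Read a binary mask, thresholding any probabilistic map at 0.5.

    An all-zero mask without an ``absent`` sidecar flag is returned
    absent-flagged with a warning rather than an error.
    """
    path = Path(path)
    data, spacing = _load_nifti(path)
    meta = _read_sidecar(path)
    organ = organ if organ is not None else meta.get("organ")
    source = source if source is not None else meta.get("source", "reference")
    if organ is None:
        raise FormatError(f"{path}: no organ label in sidecar and none supplied")
    values = np.asarray(data, dtype=np.float64) > 0.5
    absent = bool(meta.get("absent", False))
    if not values.any() and not absent:
        warnings.warn(
            f"{path}: mask for {organ} is empty but not flagged absent; "
            "treating the organ as absent",
            stacklevel=2,
        )
        absent = True
    return OrganMask(
        values=values, spacing=spacing, organ=organ, source=source, absent=absent
    )
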
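"""Seeded synthetic phantom cohort generator.

Emulates the *statistical structure* of a single-time-point ¹⁷⁷Lu-DOTATATE
SPECT/CT cohort — not realistic anatomy. Each case carries:

* a CT volume (HU) with an elliptical body, liver (optionally enlarged by
  a second inferior–anterior lobe under hepatomegaly, with hot lesions),
  spleen (absent in a configurable fraction of cases, emulating
  post-surgical patients), and two kidneys whose reference masks exclude
  a cold renal-pelvis subregion;
* a true activity map (organ concentration × voxel volume, MBq/voxel);
* a simulated count-rate map (activity × cross-calibration factor,
  Gaussian system blur, Poisson counting noise);
* reference masks plus "manual" and "ai" observer masks produced by
  warping the reference with a smooth random displacement field, with
  rare injected gross failures (plane truncation / bleeding into a
  neighbouring organ) for the AI source in hepatomegaly cases.

Everything is a pure function of (config, seed). Per-case and per-observer
seeds derive from the master seed through a splitmix64-style integer hash,
so cohorts are portable across machines.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy import ndimage

from .config import CalibrationConfig, TimingParams
from .errors import ConstructionError
from .grids import ORGANS, OrganMask, VolumeGrid

FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))

_MASK64 = (1 << 64) - 1


def derive_seed(master: int, *indices: int) -> int:
    """Derive a child seed < 2^31 from a master seed and an index path.

    Splitmix64-style mixing: each index advances the state by the golden
    64-bit constant and passes through two xor-multiply finalization
    rounds. Documented so cohorts regenerate identically anywhere.
    """
    z = int(master) & _MASK64
    for idx in indices:
        z = (z + (int(idx) + 1) * 0x9E3779B97F4A7C15) & _MASK64
        z = ((z ^ (z >> 30)) * 0xBF58476D1CE4E5B9) & _MASK64
        z = ((z ^ (z >> 27)) * 0x94D049BB133111EB) & _MASK64
        z ^= z >> 31
    return int(z % (2**31 - 1))


@dataclass
class OrganSpec:
    """One ellipsoidal organ: center offset from grid center (mm), semi-axes
    (mm), CT number, and activity concentration (MBq/mL)."""

    center_mm: tuple[float, float, float]
    semi_axes_mm: tuple[float, float, float]
    hu: float
    conc_mbq_per_ml: float


def _default_organs() -> dict[str, OrganSpec]:
    # axis order (slice z, row y, column x); offsets relative to grid center
    return {
        "liver": OrganSpec(
            center_mm=(-20.0, 0.0, 45.0),
            semi_axes_mm=(45.0, 45.0, 48.0),
            hu=55.0,
            conc_mbq_per_ml=0.90,
        ),
        "spleen": OrganSpec(
            center_mm=(-15.0, -10.0, -70.0),
            semi_axes_mm=(28.0, 22.0, 18.0),
            hu=50.0,
            conc_mbq_per_ml=0.46,
        ),
        "kidney_right": OrganSpec(
            center_mm=(50.0, 30.0, 38.0),
            semi_axes_mm=(22.0, 13.0, 12.0),
            hu=35.0,
            conc_mbq_per_ml=1.00,
        ),
        "kidney_left": OrganSpec(
            center_mm=(50.0, 30.0, -38.0),
            semi_axes_mm=(22.0, 13.0, 12.0),
            hu=35.0,
            conc_mbq_per_ml=1.00,
        ),
    }


@dataclass
class PhantomConfig:
    """Study conditions of the synthetic cohort.

    Defaults emulate a ~23-patient single-time-point cohort: spleen absent
    with probability 6/23, hepatomegaly (which drives the rare gross AI
    segmentation failures) with probability 4/23, imaging at the cohort
    median 24.49 h post administration.
    """

    shape: tuple[int, int, int] = (80, 80, 80)
    spacing_mm: tuple[float, float, float] = (3.0, 3.0, 3.0)
    body_semi_axes_mm: tuple[float, float, float] = (115.0, 112.0, 112.0)
    body_hu: float = 40.0
    air_hu: float = -1000.0
    background_conc_mbq_per_ml: float = 0.02
    organs: dict[str, OrganSpec] = field(default_factory=_default_organs)

    # liver lesions (always part of the whole-liver mask)
    lesion_count_range: tuple[int, int] = (1, 3)
    lesion_radius_range_mm: tuple[float, float] = (8.0, 15.0)
    lesion_conc_multiplier: float = 2.5
    lesion_hu: float = 45.0

    # hepatomegaly: second liver lobe, scaled by (factor - 1) / 0.35
    hepatomegaly_prob: float = 4.0 / 23.0
    hepatomegaly_factor: float = 1.35
    hepatomegaly_lobe_center_mm: tuple[float, float, float] = (15.0, -25.0, 45.0)
    hepatomegaly_lobe_semi_axes_mm: tuple[float, float, float] = (40.0, 34.0, 40.0)

    spleen_absent_prob: float = 6.0 / 23.0

    # renal pelvis: excluded from the kidney mask, cold in the activity map
    renal_pelvis_semi_axes_mm: tuple[float, float, float] = (10.0, 5.0, 5.0)
    renal_pelvis_offset_mm: tuple[float, float, float] = (0.0, 0.0, 6.0)  # toward midline
    renal_pelvis_hu: float = 15.0

    # case-to-case variability
    semi_axis_jitter: float = 0.05
    conc_jitter_sigma: float = 0.20

    # acquisition
    calibration: CalibrationConfig = field(default_factory=CalibrationConfig)
    poisson: bool = True
    count_time_s: float = 120.0
    t_hours: float = 24.49

    # observer model
    n_manual_observers: int = 4
    manual_sigma_mm: float = 1.8
    ai_sigma_mm: float = 0.7
    displacement_smooth_mm: float = 10.0

    # AI gross failures, conditional on hepatomegaly
    ai_failure_prob_liver: float = 0.8
    ai_failure_prob_spleen: float = 0.55
    liver_truncate_mm: float = 45.0
    spleen_bleed_mm: float = 65.0

    def __post_init__(self):
        if not (0 <= self.spleen_absent_prob <= 1):
            raise ValueError("spleen_absent_prob must lie in [0, 1]")
        if not (0 <= self.hepatomegaly_prob <= 1):
            raise ValueError("hepatomegaly_prob must lie in [0, 1]")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing must be positive")
        if self.hepatomegaly_factor < 1.0:
            raise ValueError("hepatomegaly_factor must be >= 1")


@dataclass
class PhantomCase:
    """One synthetic patient: images, reference masks, observer masks."""

    case_id: str
    seed: int
    ct: VolumeGrid
    activity_true: VolumeGrid
    masks: dict[str, OrganMask]  # reference masks, keyed by organ
    counts: Optional[VolumeGrid] = None
    observer_masks: Optional[dict[str, dict[str, OrganMask]]] = None
    timing_t_hours: float = 24.49
    hepatomegaly: bool = False
    spleen_absent: bool = False
    failures: list = field(default_factory=list)  # (organ, mode) tuples


def _grid_center_mm(shape, spacing) -> np.ndarray:
    return (np.asarray(shape, dtype=float) - 1.0) / 2.0 * np.asarray(spacing)


def _ellipsoid(shape, spacing, center_mm, semi_axes_mm) -> np.ndarray:
    """Binary ellipsoid on the lattice; center_mm is absolute (mm)."""
    if any(a <= 0 for a in semi_axes_mm):
        return np.zeros(shape, dtype=bool)
    grids = np.ogrid[: shape[0], : shape[1], : shape[2]]
    q = np.zeros(shape, dtype=np.float64)
    for ax in range(3):
        q = q + ((grids[ax] * spacing[ax] - center_mm[ax]) / semi_axes_mm[ax]) ** 2
    return q <= 1.0


def build_phantom(config: PhantomConfig, seed: int) -> PhantomCase:
    """Construct CT, true activity, and reference masks for one case.

    Deterministic given (config, seed). Raises ConstructionError if the
    (jittered) organ regions overlap or stick out of the body.
    """
    rng = np.random.default_rng(seed)
    shape, spacing = tuple(config.shape), tuple(config.spacing_mm)
    center = _grid_center_mm(shape, spacing)

    hepatomegaly = bool(rng.random() < config.hepatomegaly_prob)
    spleen_absent = bool(rng.random() < config.spleen_absent_prob)

    # jittered geometry and uptake, in fixed organ order
    regions: dict[str, np.ndarray] = {}
    concs: dict[str, float] = {}
    for organ in ORGANS:
        spec = config.organs[organ]
        scale = 1.0 + rng.uniform(-config.semi_axis_jitter, config.semi_axis_jitter)
        conc = spec.conc_mbq_per_ml * float(
            np.exp(rng.normal(0.0, config.conc_jitter_sigma))
        )
        if organ == "spleen" and spleen_absent:
            regions[organ] = np.zeros(shape, dtype=bool)
            concs[organ] = 0.0
            continue
        region = _ellipsoid(
            shape, spacing, center + np.asarray(spec.center_mm),
            np.asarray(spec.semi_axes_mm) * scale,
        )
        if organ == "liver" and hepatomegaly:
            lobe_scale = (config.hepatomegaly_factor - 1.0) / 0.35
            lobe = _ellipsoid(
                shape, spacing,
                center + np.asarray(config.hepatomegaly_lobe_center_mm),
                np.asarray(config.hepatomegaly_lobe_semi_axes_mm) * lobe_scale * scale,
            )
            region = region | lobe
        regions[organ] = region
        concs[organ] = conc

    body = _ellipsoid(shape, spacing, center, config.body_semi_axes_mm)

    names = [o for o in ORGANS if regions[o].any()]
    for i, a in enumerate(names):
        if (regions[a] & ~body).any():
            raise ConstructionError(f"organ {a} extends outside the body")
        for b in names[i + 1 :]:
            if (regions[a] & regions[b]).any():
                raise ConstructionError(f"organs {a} and {b} overlap")

    # renal pelvis subregions (cold, excluded from kidney reference masks)
    pelvis: dict[str, np.ndarray] = {}
    for organ in ("kidney_right", "kidney_left"):
        spec = config.organs[organ]
        offset = np.asarray(config.renal_pelvis_offset_mm, dtype=float).copy()
        if organ == "kidney_left":
            offset[2] = -offset[2]
        pelvis[organ] = regions[organ] & _ellipsoid(
            shape, spacing, center + np.asarray(spec.center_mm) + offset,
            config.renal_pelvis_semi_axes_mm,
        )

    # liver lesions: hot spheres fully inside the base liver ellipsoid
    liver_spec = config.organs["liver"]
    lo, hi = config.lesion_count_range
    n_lesions = int(rng.integers(lo, hi + 1))
    lesions = np.zeros(shape, dtype=bool)
    for _ in range(n_lesions):
        radius = rng.uniform(*config.lesion_radius_range_mm)
        u = rng.uniform(-0.6, 0.6, size=3)  # stay in the ellipsoid interior
        pos = center + np.asarray(liver_spec.center_mm) + u * np.asarray(
            liver_spec.semi_axes_mm
        )
        lesions |= _ellipsoid(shape, spacing, pos, (radius, radius, radius))
    lesions &= regions["liver"]

    # paint CT
    ct = np.full(shape, config.air_hu, dtype=np.float64)
    ct[body] = config.body_hu
    for organ in ORGANS:
        ct[regions[organ]] = config.organs[organ].hu
    ct[lesions] = config.lesion_hu
    for organ in ("kidney_right", "kidney_left"):
        ct[pelvis[organ]] = config.renal_pelvis_hu

    # paint activity (MBq per voxel = concentration x voxel volume)
    voxel_ml = float(np.prod(spacing)) / 1000.0
    act = np.zeros(shape, dtype=np.float64)
    act[body] = config.background_conc_mbq_per_ml * voxel_ml
    for organ in ORGANS:
        act[regions[organ]] = concs[organ] * voxel_ml
    act[lesions] = concs["liver"] * config.lesion_conc_multiplier * voxel_ml
    for organ in ("kidney_right", "kidney_left"):
        act[pelvis[organ]] = config.background_conc_mbq_per_ml * voxel_ml

    masks = {}
    for organ in ORGANS:
        values = regions[organ].copy()
        if organ in pelvis:
            values &= ~pelvis[organ]
        masks[organ] = OrganMask(
            values=values, spacing=spacing, organ=organ, source="reference",
            absent=not values.any(),
        )

    return PhantomCase(
        case_id=f"case_{seed}",
        seed=seed,
        ct=VolumeGrid(values=ct, spacing=spacing, quantity="HU"),
        activity_true=VolumeGrid(values=act, spacing=spacing, quantity="MBq"),
        masks=masks,
        timing_t_hours=config.t_hours,
        hepatomegaly=hepatomegaly,
        spleen_absent=spleen_absent,
    )


def simulate_spect(
    activity: VolumeGrid,
    cal: CalibrationConfig,
    seed: int | None = None,
    poisson: bool = True,
    count_time_s: float = 120.0,
) -> VolumeGrid:
    """Degrade a true activity map into a reconstructed count-rate map.

    Expected cps = activity × ccf, blurred by an isotropic Gaussian of
    FWHM ``cal.psf_fwhm_mm`` (which conserves total counts away from the
    lattice edge), then Poisson-resampled assuming an effective counting
    time of ``count_time_s`` seconds per voxel.
    """
    activity.require("MBq")
    if np.any(activity.values < 0):
        raise ValueError("activity map contains negative values")
    expected = activity.values * cal.ccf
    if cal.psf_fwhm_mm > 0:
        sigma_vox = [
            cal.psf_fwhm_mm * FWHM_TO_SIGMA / s for s in activity.spacing
        ]
        expected = ndimage.gaussian_filter(expected, sigma=sigma_vox, mode="constant")
        expected = np.clip(expected, 0.0, None)
    if poisson:
        if seed is None:
            raise ValueError("Poisson resampling requires a seed")
        if count_time_s <= 0:
            raise ValueError("count_time_s must be > 0")
        rng = np.random.default_rng(seed)
        expected = rng.poisson(expected * count_time_s).astype(np.float64) / count_time_s
    return activity.like(expected, quantity="cps")


def _crop_slices(mask_values, spacing, margin_mm):
    idx = np.argwhere(mask_values)
    lo = idx.min(axis=0)
    hi = idx.max(axis=0) + 1
    slices = []
    for ax in range(3):
        m = int(np.ceil(margin_mm / spacing[ax])) + 2
        slices.append(slice(max(0, lo[ax] - m), min(mask_values.shape[ax], hi[ax] + m)))
    return tuple(slices)


def perturb_contour(
    mask: OrganMask, sigma_mm: float, seed: int, smooth_mm: float = 10.0
) -> OrganMask:
    """Warp a mask by a smooth random displacement field.

    The field is white Gaussian vector noise smoothed with a Gaussian of
    scale ``smooth_mm`` and rescaled so the RMS displacement magnitude is
    ``sigma_mm``; the mask is pulled back through the field with trilinear
    interpolation and rethresholded at 0.5. Agreement metrics therefore
    degrade continuously with sigma. Topology is not guaranteed.
    """
    if sigma_mm < 0:
        raise ValueError("sigma_mm must be >= 0")
    if mask.absent or not mask.values.any():
        raise ValueError(f"cannot perturb empty mask for {mask.organ}")
    if sigma_mm == 0:
        return mask.with_values(mask.values.copy())

    spacing = mask.spacing
    sl = _crop_slices(mask.values, spacing, margin_mm=3 * sigma_mm + 2 * smooth_mm)
    crop = mask.values[sl].astype(np.float64)

    rng = np.random.default_rng(seed)
    fields = rng.standard_normal((3,) + crop.shape)
    for ax in range(3):
        fields[ax] = ndimage.gaussian_filter(
            fields[ax], sigma=[smooth_mm / s for s in spacing], mode="constant"
        )
    rms = float(np.sqrt((fields**2).sum(axis=0).mean()))
    if rms == 0:
        return mask.with_values(mask.values.copy())
    fields *= sigma_mm / rms  # displacement in mm

    coords = np.meshgrid(*[np.arange(n, dtype=np.float64) for n in crop.shape],
                         indexing="ij")
    sample = [coords[ax] + fields[ax] / spacing[ax] for ax in range(3)]
    warped = ndimage.map_coordinates(crop, sample, order=1, mode="constant", cval=0.0)

    out = np.zeros(mask.values.shape, dtype=bool)
    out[sl] = warped > 0.5
    return mask.with_values(out)


def inject_gross_failure(
    mask: OrganMask,
    mode: str,
    magnitude_mm: float,
    seed: int,
    neighbor: OrganMask | None = None,
) -> OrganMask:
    """Inject a gross segmentation failure into a mask.

    ``truncate_plane`` removes every voxel beyond a random-orientation
    plane placed ``magnitude_mm`` deep from the far pole of the mask —
    the "segmentation stops short" failure seen with enlarged livers.
    ``bleed_into_neighbor`` adds the neighbour-organ voxels lying within
    ``magnitude_mm`` of the mask — the contour swallowing part of an
    adjacent organ.
    """
    if magnitude_mm < 0:
        raise ValueError("magnitude_mm must be >= 0")
    if mask.absent or not mask.values.any():
        raise ValueError(f"cannot inject failure into empty mask for {mask.organ}")
    if magnitude_mm == 0:
        return mask.with_values(mask.values.copy())
    rng = np.random.default_rng(seed)
    spacing = np.asarray(mask.spacing)

    if mode == "truncate_plane":
        normal = rng.standard_normal(3)
        normal /= np.linalg.norm(normal)
        idx = np.argwhere(mask.values)
        proj = (idx * spacing) @ normal
        keep = proj <= proj.max() - magnitude_mm
        if not keep.any():
            raise ValueError(
                f"truncation depth {magnitude_mm} mm exceeds the mask extent"
            )
        out = np.zeros(mask.values.shape, dtype=bool)
        out[tuple(idx[keep].T)] = True
        return mask.with_values(out)

    if mode == "bleed_into_neighbor":
        if neighbor is None or not neighbor.values.any():
            raise ValueError("bleed_into_neighbor requires a non-empty neighbor mask")
        dist = ndimage.distance_transform_edt(~mask.values, sampling=mask.spacing)
        extra = neighbor.values & (dist <= magnitude_mm)
        return mask.with_values(mask.values | extra)

    raise ValueError(f"unknown failure mode {mode!r}")


def generate_cohort(
    config: PhantomConfig, n_cases: int, seed: int
) -> list[PhantomCase]:
    """Generate a full synthetic cohort with observer masks and counts.

    Each case receives ``n_manual_observers`` manual-like observer mask
    sets and one AI-like set per present organ; AI liver/spleen masks in
    hepatomegaly cases may carry an injected gross failure. Per-case and
    per-observer seeds derive from the master seed via :func:`derive_seed`.
    """
    if n_cases < 1:
        raise ValueError("n_cases must be >= 1")
    cases = []
    for i in range(n_cases):
        case_seed = derive_seed(seed, i)
        case = build_phantom(config, case_seed)
        case.case_id = f"case_{i:02d}"
        case.counts = simulate_spect(
            case.activity_true,
            config.calibration,
            seed=derive_seed(case_seed, 1),
            poisson=config.poisson,
            count_time_s=config.count_time_s,
        )

        observers: dict[str, dict[str, OrganMask]] = {}
        present = [o for o in ORGANS if not case.masks[o].absent]
        for j in range(config.n_manual_observers):
            name = f"manual_{j + 1}"
            observers[name] = {}
            for k, organ in enumerate(present):
                m = perturb_contour(
                    case.masks[organ],
                    config.manual_sigma_mm,
                    seed=derive_seed(case_seed, 10 + j, k),
                    smooth_mm=config.displacement_smooth_mm,
                )
                observers[name][organ] = m.with_values(m.values, source="manual")

        ai: dict[str, OrganMask] = {}
        for k, organ in enumerate(present):
            m = perturb_contour(
                case.masks[organ],
                config.ai_sigma_mm,
                seed=derive_seed(case_seed, 99, k),
                smooth_mm=config.displacement_smooth_mm,
            )
            ai[organ] = m.with_values(m.values, source="ai")

        if case.hepatomegaly:
            fail_rng = np.random.default_rng(derive_seed(case_seed, 7))
            if fail_rng.random() < config.ai_failure_prob_liver:
                ai["liver"] = inject_gross_failure(
                    ai["liver"], "truncate_plane", config.liver_truncate_mm,
                    seed=derive_seed(case_seed, 7, 0),
                )
                case.failures.append(("liver", "truncate_plane"))
            if "spleen" in ai and fail_rng.random() < config.ai_failure_prob_spleen:
                ai["spleen"] = inject_gross_failure(
                    ai["spleen"], "bleed_into_neighbor", config.spleen_bleed_mm,
                    seed=derive_seed(case_seed, 7, 1),
                    neighbor=case.masks["liver"],
                )
                case.failures.append(("spleen", "bleed_into_neighbor"))
        observers["ai"] = ai

        case.observer_masks = observers
        cases.append(case)
    return cases
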
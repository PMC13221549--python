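"""End-to-end pipeline: simulate → evaluate → dose → report.

Stages hand data off through plain files (uncompressed NIfTI plus
JSON/CSV) so each one is independently testable, and the run manifest
lists every artifact with its SHA-256 hash — identical (config, seed)
reruns produce identical manifests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

from .cohort import analyze_cohort, build_report
from .config import CalibrationConfig, ToleranceCriteria
from .errors import LutidoseError, StageError
from .grids import ORGANS
from .io import write_mask, write_volume
from .kernels import load_kernel, make_test_kernel, save_kernel
from .phantom import PhantomConfig, generate_cohort


@dataclasses.dataclass
class RunConfig:
    """Run-level configuration: cohort size, seed, kernel, output layout."""

    out_dir: str
    n_cases: int = 3
    seed: int = 0
    phantom: PhantomConfig = dataclasses.field(default_factory=PhantomConfig)
    criteria: ToleranceCriteria = dataclasses.field(default_factory=ToleranceCriteria)
    kernel_path: str | None = None  # None -> synthetic test kernel
    density_correction: bool = False
    write_images: bool = True

    def __post_init__(self):
        if self.seed < 0:
            raise ValueError("seed must be a non-negative integer")
        if self.n_cases < 1:
            raise ValueError("n_cases must be >= 1")


def demo_config(out_dir, n_cases: int = 3, seed: int = 0) -> RunConfig:
    """Small, fast demonstration run: 3 cases on a 48^3 grid at 4 mm."""
    phantom = PhantomConfig(
        shape=(48, 48, 48),
        spacing_mm=(4.0, 4.0, 4.0),
        body_semi_axes_mm=(92.0, 90.0, 90.0),
    )
    # shrink the default anatomy by 20% so it fits the demo grid
    for spec in phantom.organs.values():
        spec.center_mm = tuple(0.8 * c for c in spec.center_mm)
        spec.semi_axes_mm = tuple(0.8 * s for s in spec.semi_axes_mm)
    phantom.hepatomegaly_lobe_center_mm = tuple(
        0.8 * c for c in phantom.hepatomegaly_lobe_center_mm
    )
    phantom.hepatomegaly_lobe_semi_axes_mm = tuple(
        0.8 * s for s in phantom.hepatomegaly_lobe_semi_axes_mm
    )
    phantom.liver_truncate_mm = 36.0
    return RunConfig(out_dir=str(out_dir), n_cases=n_cases, seed=seed, phantom=phantom)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run all four stages; returns the manifest (also written to disk).

    Any stage failure raises :class:`StageError` carrying the stage name;
    no artifacts of later stages are produced after a failure.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: list[Path] = []

    try:
        cases = generate_cohort(config.phantom, config.n_cases, config.seed)
        if config.write_images:
            for case in cases:
                case_dir = out / case.case_id
                case_dir.mkdir(exist_ok=True)
                write_volume(case.ct, case_dir / "ct.nii")
                write_volume(case.counts, case_dir / "counts.nii")
                artifacts += [case_dir / "ct.nii", case_dir / "counts.nii"]
                for organ in ORGANS:
                    p = case_dir / f"{organ}_reference.nii"
                    write_mask(case.masks[organ], p)
                    artifacts.append(p)
                    for obs, masks in case.observer_masks.items():
                        if organ in masks:
                            p = case_dir / f"{organ}_{obs}.nii"
                            write_mask(masks[organ], p)
                            artifacts.append(p)
    except (LutidoseError, OSError) as exc:
        raise StageError("simulate", str(exc)) from exc

    try:
        if config.kernel_path is not None:
            kernel = load_kernel(config.kernel_path)
        else:
            kernel = make_test_kernel(config.phantom.spacing_mm)
            save_kernel(kernel, out / "kernel.vsv")
            artifacts.append(out / "kernel.vsv")
        metrics_df, dose_df = analyze_cohort(
            cases,
            cal=config.phantom.calibration,
            kernel=kernel,
            criteria=config.criteria,
            density_correction=config.density_correction,
        )
    except (LutidoseError, OSError) as exc:
        raise StageError("dose", str(exc)) from exc

    try:
        metrics_df.to_csv(out / "metrics.csv", index=False)
        dose_df.to_csv(out / "dose.csv", index=False)
        artifacts += [out / "metrics.csv", out / "dose.csv"]
        report = build_report(metrics_df, dose_df, config.criteria)
        for name, table in report.items():
            p = out / f"report_{name}.csv"
            table.to_csv(p, index=False)
            artifacts.append(p)
    except (LutidoseError, OSError) as exc:
        raise StageError("report", str(exc)) from exc

    manifest = {
        "seed": config.seed,
        "n_cases": config.n_cases,
        "artifacts": {
            str(p.relative_to(out)): _sha256(p) for p in sorted(artifacts)
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
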
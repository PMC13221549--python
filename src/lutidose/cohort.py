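"""Cohort-level aggregation: per-case metric and dose tables, and the
accuracy / criteria-rate / dose report with paired Wilcoxon comparisons.

Each case contributes several manual observer contours; for paired
per-case statistics the manual value is the per-case median across
observers (one manual value per patient, as a cohort table needs). The
"median relative difference" of mean dose is reported under both readings
of that phrase: the relative difference of the cohort medians, and the
median of the per-case relative differences.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import CalibrationConfig, TimingParams, ToleranceCriteria
from .dosimetry import compute_dose_map, dose_stats
from .grids import ORGANS
from .kernels import DoseKernel, make_test_kernel
from .metrics import criteria_rate, evaluate_contour
from .stats import PairedSample, median_iqr, relative_difference, wilcoxon_signed_rank

_METRICS = ("dsc", "hd_mm", "mda_mm")
_DOSE_STATS = ("d_mean", "d_max", "d_min")


def analyze_cohort(
    cases,
    cal: CalibrationConfig | None = None,
    kernel: DoseKernel | None = None,
    criteria: ToleranceCriteria | None = None,
    density_correction: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-case, per-organ, per-observer metric and dose tables.

    Returns (metrics_df, dose_df). Absent organs are skipped (not rows).
    """
    cal = cal or CalibrationConfig()
    criteria = criteria or ToleranceCriteria()
    metric_rows = []
    dose_rows = []
    for case in cases:
        if case.observer_masks is None:
            raise ValueError(f"{case.case_id}: case has no observer masks")
        if kernel is None:
            kernel = make_test_kernel(case.counts.spacing)
        timing = TimingParams(t_hours=case.timing_t_hours)
        dose = compute_dose_map(
            case.counts, cal, kernel, timing,
            ct=case.ct, density_correction=density_correction,
        )
        failures = {organ for organ, _ in case.failures}
        for organ in ORGANS:
            ref = case.masks[organ]
            if ref.absent:
                continue
            ds = dose_stats(dose, ref)
            dose_rows.append(
                dict(case=case.case_id, organ=organ, source="reference",
                     observer="reference", d_mean=ds.d_mean, d_max=ds.d_max,
                     d_min=ds.d_min, volume_ml=ds.volume_ml)
            )
            for observer in sorted(case.observer_masks):
                mask = case.observer_masks[observer].get(organ)
                if mask is None or mask.absent:
                    continue
                res = evaluate_contour(mask, ref, criteria)
                if res is not None:
                    metric_rows.append(
                        dict(case=case.case_id, organ=organ, source=mask.source,
                             observer=observer, dsc=res.dsc, hd_mm=res.hd_mm,
                             mda_mm=res.mda_mm, dsc_ok=res.dsc_ok,
                             hd_ok=res.hd_ok, mda_ok=res.mda_ok,
                             gross_failure=(mask.source == "ai" and organ in failures))
                    )
                ds = dose_stats(dose, mask)
                dose_rows.append(
                    dict(case=case.case_id, organ=organ, source=mask.source,
                         observer=observer, d_mean=ds.d_mean, d_max=ds.d_max,
                         d_min=ds.d_min, volume_ml=ds.volume_ml)
                )
    return pd.DataFrame(metric_rows), pd.DataFrame(dose_rows)


def _per_case(df: pd.DataFrame, value: str, source: str) -> pd.Series:
    """One value per case for a source; manual observers collapse to their
    per-case median."""
    sub = df[df["source"] == source]
    return sub.groupby("case")[value].median()


def build_report(
    metrics_df: pd.DataFrame,
    dose_df: pd.DataFrame,
    criteria: ToleranceCriteria | None = None,
) -> dict[str, pd.DataFrame]:
    """Assemble the cohort report tables.

    Returns a dict with:
      ``accuracy`` — per organ x metric: median (IQR) for manual and AI,
        paired two-sided Wilcoxon p (manual vs AI), n;
      ``criteria_rates`` — per organ x metric x method: percentage and
        (passing, total) of cases meeting the tolerance;
      ``dose`` — per organ x dose statistic x method: median (IQR) and
        paired Wilcoxon p against the reference contour;
      ``dose_relative_difference`` — D_mean relative differences vs the
        reference under both readings.
    """
    criteria = criteria or ToleranceCriteria()
    thresholds = {
        "dsc": (criteria.dsc_min, "ge"),
        "hd_mm": (criteria.hd_max_mm, "le"),
        "mda_mm": (criteria.mda_max_mm, "le"),
    }

    accuracy_rows, rate_rows = [], []
    for organ in ORGANS:
        sub = metrics_df[metrics_df["organ"] == organ]
        if sub.empty:
            continue
        for metric in _METRICS:
            man = _per_case(sub, metric, "manual")
            ai = _per_case(sub, metric, "ai")
            cases = man.index.intersection(ai.index)
            if len(cases) == 0:
                continue
            m_med, m_q1, m_q3 = median_iqr(man.loc[cases])
            a_med, a_q1, a_q3 = median_iqr(ai.loc[cases])
            test = wilcoxon_signed_rank(
                PairedSample(man.loc[cases].values, ai.loc[cases].values)
            )
            accuracy_rows.append(
                dict(organ=organ, metric=metric, n=len(cases),
                     manual_median=m_med, manual_q1=m_q1, manual_q3=m_q3,
                     ai_median=a_med, ai_q1=a_q1, ai_q3=a_q3,
                     p_value=test.p_value)
            )
            threshold, sense = thresholds[metric]
            for method, series in (("manual", man.loc[cases]), ("ai", ai.loc[cases])):
                flags = series >= threshold if sense == "ge" else series <= threshold
                rate, passing, total = criteria_rate(flags.tolist())
                rate_rows.append(
                    dict(organ=organ, metric=metric, method=method,
                         rate_percent=rate, passing=passing, total=total)
                )

    dose_rows, reldiff_rows = [], []
    for organ in ORGANS:
        sub = dose_df[dose_df["organ"] == organ]
        if sub.empty:
            continue
        ref = _per_case(sub, "d_mean", "reference")  # index of cases with the organ
        for stat in _DOSE_STATS:
            ref_vals = _per_case(sub, stat, "reference")
            r_med, r_q1, r_q3 = median_iqr(ref_vals)
            dose_rows.append(
                dict(organ=organ, quantity=stat, method="reference",
                     n=len(ref_vals), median=r_med, q1=r_q1, q3=r_q3,
                     p_vs_reference=np.nan)
            )
            for method in ("manual", "ai"):
                vals = _per_case(sub, stat, method)
                cases = vals.index.intersection(ref_vals.index)
                med, q1, q3 = median_iqr(vals.loc[cases])
                test = wilcoxon_signed_rank(
                    PairedSample(vals.loc[cases].values, ref_vals.loc[cases].values)
                )
                dose_rows.append(
                    dict(organ=organ, quantity=stat, method=method,
                         n=len(cases), median=med, q1=q1, q3=q3,
                         p_vs_reference=test.p_value)
                )
                if stat == "d_mean":
                    per_case_rd = [
                        relative_difference(vals.loc[c], ref_vals.loc[c])
                        for c in cases if ref_vals.loc[c] != 0
                    ]
                    reldiff_rows.append(
                        dict(organ=organ, method=method,
                             difference_of_medians_percent=relative_difference(
                                 med, median_iqr(ref_vals.loc[cases])[0]),
                             median_of_differences_percent=float(np.median(per_case_rd)))
                    )

    return {
        "accuracy": pd.DataFrame(accuracy_rows),
        "criteria_rates": pd.DataFrame(rate_rows),
        "dose": pd.DataFrame(dose_rows),
        "dose_relative_difference": pd.DataFrame(reldiff_rows),
    }
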
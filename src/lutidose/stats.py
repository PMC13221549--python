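"""Cohort statistics: median (IQR), paired Wilcoxon signed-rank, relative
differences.

The Wilcoxon signed-rank test follows the classic recipe: zero differences
are discarded, ties among the remaining |differences| are mid-ranked, and
the two-sided p-value is twice the smaller tail, capped at 1. Three
evaluation paths:

* ``exact`` with tie-free ranks: the null distribution of W+ is built by
  dynamic programming over the 2^n equiprobable sign assignments;
* ``exact`` with ties: seeded Monte-Carlo over 10^5 random sign flips
  (the DP null is no longer a simple integer lattice walk);
* ``normal_approx``: Gaussian approximation with continuity correction
  and the usual tie correction of the variance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm, rankdata

MC_SIGN_FLIPS = 100_000
MC_DEFAULT_SEED = 20_21


def median_iqr(values) -> tuple[float, float, float]:
    """(median, q1, q3) with quartiles by linear interpolation between order
    statistics (quantile q sits at position (n-1)*q)."""
    values = np.asarray(values, dtype=np.float64)
    if values.size == 0:
        raise ValueError("median_iqr needs at least one value")
    med, q1, q3 = np.percentile(values, [50, 25, 75])
    return float(med), float(q1), float(q3)


def relative_difference(a: float, b_reference: float) -> float:
    """Signed percent difference 100 * (a - b) / b of a against a reference."""
    if b_reference == 0:
        raise ValueError("reference value must be nonzero")
    return 100.0 * (a - b_reference) / b_reference


@dataclass
class PairedSample:
    """Per-case value pairs (method_a, method_b) for one organ and quantity."""

    a: np.ndarray
    b: np.ndarray
    case_ids: tuple = ()

    def __post_init__(self):
        self.a = np.asarray(self.a, dtype=np.float64)
        self.b = np.asarray(self.b, dtype=np.float64)
        if self.a.shape != self.b.shape or self.a.ndim != 1:
            raise ValueError("paired sample needs two equal-length 1-D arrays")
        if self.a.size < 1:
            raise ValueError("paired sample needs at least one pair")

    @property
    def differences(self) -> np.ndarray:
        return self.a - self.b


@dataclass
class WilcoxonResult:
    statistic: float  # W+ (sum of ranks of positive differences)
    p_value: float
    n_used: int  # pairs remaining after discarding zero differences
    degenerate: bool
    method_used: str


def _exact_null_pmf(n: int) -> np.ndarray:
    """PMF of W+ over 0..n(n+1)/2 for tie-free integer ranks 1..n, by DP."""
    counts = np.zeros(n * (n + 1) // 2 + 1, dtype=np.float64)
    counts[0] = 1.0
    for r in range(1, n + 1):
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[:-r] if r > 0 else counts
        counts = counts + shifted
    return counts / 2.0**n


def _two_sided_from_tails(p_low: float, p_high: float) -> float:
    return float(min(1.0, 2.0 * min(p_low, p_high)))


def wilcoxon_signed_rank(
    sample: PairedSample,
    method: str = "exact",
    mc_seed: int = MC_DEFAULT_SEED,
) -> WilcoxonResult:
    """Two-sided paired Wilcoxon signed-rank test.

    If every difference is zero the sample is degenerate: p = 1.0 with the
    ``degenerate`` flag set, by convention.
    """
    if method not in ("exact", "normal_approx"):
        raise ValueError(f"unknown method {method!r}")
    d = sample.differences
    d = d[d != 0.0]
    n = d.size
    if n == 0:
        return WilcoxonResult(
            statistic=0.0, p_value=1.0, n_used=0, degenerate=True, method_used="degenerate"
        )
    ranks = rankdata(np.abs(d))  # midranks under ties
    w_plus = float(ranks[d > 0].sum())
    tie_free = np.unique(np.abs(d)).size == n

    if method == "exact" and tie_free:
        pmf = _exact_null_pmf(n)
        w = int(round(w_plus))
        p = _two_sided_from_tails(pmf[: w + 1].sum(), pmf[w:].sum())
        return WilcoxonResult(w_plus, p, n, False, "exact")

    if method == "exact":
        # ties: Monte-Carlo over random sign assignments of the midranks
        rng = np.random.default_rng(mc_seed)
        signs = rng.integers(0, 2, size=(MC_SIGN_FLIPS, n)).astype(bool)
        w_sim = signs @ ranks
        p_low = float((w_sim <= w_plus + 1e-12).mean())
        p_high = float((w_sim >= w_plus - 1e-12).mean())
        return WilcoxonResult(
            w_plus, _two_sided_from_tails(p_low, p_high), n, False, "monte_carlo"
        )

    # normal approximation with continuity and tie corrections
    mean = n * (n + 1) / 4.0
    _, tie_counts = np.unique(np.abs(d), return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum())) / 48.0
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    if var <= 0:
        return WilcoxonResult(w_plus, 1.0, n, True, "degenerate")
    delta = w_plus - mean
    z = (delta - 0.5 * np.sign(delta)) / np.sqrt(var)
    p = float(min(1.0, 2.0 * norm.sf(abs(z))))
    return WilcoxonResult(w_plus, p, n, False, "normal_approx")
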
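"""Exact paired Wilcoxon signed-rank testing and cohort summaries.

The exact test enumerates all 2^n sign assignments of the rank vector
(midranks for tied absolute differences, zero differences dropped), so small
cohorts get exact two-sided p-values: with n = 10 pairs whose differences
all share one sign, p = 2/1024 ≈ 0.0020.  For n > 20 a normal approximation
with tie correction is used and flagged in the result.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

EXACT_ENUMERATION_LIMIT = 20


@dataclass
class PairedSample:
    metric: str
    values_standard: np.ndarray
    values_sparing: np.ndarray
    patient_ids: list | None = None

    def __post_init__(self) -> None:
        self.values_standard = np.asarray(self.values_standard, dtype=float)
        self.values_sparing = np.asarray(self.values_sparing, dtype=float)
        if self.values_standard.shape != self.values_sparing.shape:
            raise ValueError("paired arms must have equal length")
        if self.values_standard.size < 1:
            raise ValueError("need at least one pair")

    @property
    def differences(self) -> np.ndarray:
        return self.values_sparing - self.values_standard


@dataclass
class WilcoxonResult:
    statistic: float  # W+ = sum of ranks of positive differences
    p_two_sided: float
    n_nonzero: int
    exact: bool
    all_zero: bool = False


def _midranks(abs_d: np.ndarray) -> np.ndarray:
    order = np.argsort(abs_d, kind="stable")
    ranks = np.empty(abs_d.size, dtype=float)
    sorted_vals = abs_d[order]
    i = 0
    while i < sorted_vals.size:
        j = i
        while j + 1 < sorted_vals.size and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def wilcoxon_exact(paired: PairedSample | np.ndarray) -> WilcoxonResult:
    """Two-sided paired Wilcoxon signed-rank test.

    Accepts a :class:`PairedSample` or a raw array of paired differences.
    Zero differences are dropped before ranking (the classic treatment); if
    all differences are zero the result is degenerate with p = 1.
    Two-sided p = min(1, 2 * min(P(W <= w), P(W >= w))) under the exact
    enumeration null for n <= 20.
    """
    d = paired.differences if isinstance(paired, PairedSample) else np.asarray(paired, float)
    d = d[d != 0]
    if d.size == 0:
        return WilcoxonResult(0.0, 1.0, 0, exact=True, all_zero=True)
    ranks = _midranks(np.abs(d))
    w_pos = float(ranks[d > 0].sum())
    n = d.size
    if n <= EXACT_ENUMERATION_LIMIT:
        # enumerate all sign assignments; 2*rank is integral even with midranks
        r2 = np.rint(2 * ranks).astype(np.int64)
        sums = np.zeros(1, dtype=np.int64)
        for r in r2:
            sums = np.concatenate([sums, sums + r])
        w2 = int(round(2 * w_pos))
        p_le = np.count_nonzero(sums <= w2) / sums.size
        p_ge = np.count_nonzero(sums >= w2) / sums.size
        p = min(1.0, 2.0 * min(p_le, p_ge))
        return WilcoxonResult(w_pos, p, n, exact=True)
    # normal approximation with tie correction
    mu = n * (n + 1) / 4.0
    _, counts = np.unique(np.abs(d), return_counts=True)
    tie_term = float(((counts**3 - counts)).sum()) / 48.0
    sigma = np.sqrt(n * (n + 1) * (2 * n + 1) / 24.0 - tie_term)
    from scipy.stats import norm

    z = (w_pos - mu) / sigma
    p = min(1.0, 2.0 * norm.sf(abs(z)))
    return WilcoxonResult(w_pos, p, n, exact=False)


def median_iqr(values) -> dict:
    """Median and quartiles by linear interpolation between order statistics
    (the common 'type 7' convention)."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty sample")
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    return {"median": float(med), "q1": float(q1), "q3": float(q3)}


@dataclass
class ComparisonReport:
    """Per-metric cohort comparison between the two planning arms."""

    table: pd.DataFrame
    n_patients: int
    notes: dict = field(default_factory=dict)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def compare_cohort(samples: list[PairedSample]) -> ComparisonReport:
    """One comparison row per (structure, quantity) paired metric.

    Each row carries median (IQR) per arm, the exact Wilcoxon p-value and
    the mean paired difference (sparing - standard).  With a single patient
    the p-value column is NaN and flagged not-applicable.
    """
    if not samples:
        raise ValueError("no paired samples")
    n = samples[0].values_standard.size
    ids = samples[0].patient_ids
    rows = []
    for s in samples:
        if s.values_standard.size != n:
            raise ValueError("mismatched patient sets across metrics")
        if ids is not None and s.patient_ids is not None and list(s.patient_ids) != list(ids):
            raise ValueError("mismatched patient ids across metrics")
        ms, mp = median_iqr(s.values_standard), median_iqr(s.values_sparing)
        if n >= 2:
            res = wilcoxon_exact(s)
            p, w, exact = res.p_two_sided, res.statistic, res.exact
        else:
            p, w, exact = float("nan"), float("nan"), False
        rows.append(
            {
                "metric": s.metric,
                "median_standard": ms["median"],
                "q1_standard": ms["q1"],
                "q3_standard": ms["q3"],
                "median_sparing": mp["median"],
                "q1_sparing": mp["q1"],
                "q3_sparing": mp["q3"],
                "mean_difference": float(s.differences.mean()),
                "W": w,
                "p_value": p,
                "exact": exact,
            }
        )
    notes = {"p_values_not_applicable": n < 2}
    return ComparisonReport(pd.DataFrame(rows), n_patients=n, notes=notes)
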
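"""Relative quantification arithmetic for real-time qPCR.

Implements the comparative-Ct family with amplification efficiency
fixed at 2 (one cycle = one doubling): fold change by 2^-ddCt against a
reference gene and a calibrator sample, relative expression by 2^-dCt,
and replicate summaries (mean +/- SEM, two-tailed t-test, star tiers).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


def ddct_fold_change(ct_target_test: float, ct_ref_test: float,
                     ct_target_cal: float, ct_ref_cal: float) -> float:
    """Fold change of the target in the test sample vs the calibrator,
    normalized to the reference gene: 2^-((dCt_test) - (dCt_cal))."""
    ddct = (ct_target_test - ct_ref_test) - (ct_target_cal - ct_ref_cal)
    return float(2.0 ** (-ddct))


def dct_expression(ct_target: float, ct_ref: float) -> float:
    """Expression of the target relative to the reference gene in one
    sample: 2^-(Ct_target - Ct_ref)."""
    return float(2.0 ** (-(ct_target - ct_ref)))


def significance_tier(p: float) -> str:
    """Map a p-value to the conventional star annotation
    (ns > 0.05, * <= 0.05, ** <= 0.01, *** <= 0.001; inclusive)."""
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return "ns"


@dataclass(frozen=True)
class ReplicateSummary:
    mean_a: float
    sem_a: float
    mean_b: float
    sem_b: float
    p: float
    tier: str


def replicate_summary(values: list[float], other: list[float],
                      equal_var: bool = False) -> ReplicateSummary:
    """Mean +/- SEM per replicate group and a two-tailed two-sample t-test.

    Welch's test by default; set ``equal_var=True`` for the pooled
    variant.  SEM is sd / sqrt(n) with the n-1 (sample) sd.
    """
    a = np.asarray(values, dtype=float)
    b = np.asarray(other, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 replicates per group")
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    p = 1.0 if np.isnan(res.pvalue) else float(res.pvalue)
    return ReplicateSummary(
        mean_a=float(a.mean()), sem_a=float(a.std(ddof=1) / np.sqrt(a.size)),
        mean_b=float(b.mean()), sem_b=float(b.std(ddof=1) / np.sqrt(b.size)),
        p=p, tier=significance_tier(p),
    )
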
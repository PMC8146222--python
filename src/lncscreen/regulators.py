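"""Time-course regulator screen.

Candidate regulators (typically transcription factors) are correlated
with a target gene across a short synthesis-rate time course; the
significance of each Pearson correlation comes from the exact t-test
with n - 2 degrees of freedom.  With n = 6 time points the two-sided
p-value has the closed form 1 - (3/2)|r| + (1/2)|r|^3, which the exact
t-CDF path reproduces.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

STRONG_POSITIVE = "strong_positive"
STRONG_NEGATIVE = "strong_negative"
NONE = "none"


def correlation_pvalue(r: float, n: int) -> float:
    """Two-sided p for a Pearson correlation from n paired observations.

    t = r * sqrt(n - 2) / sqrt(1 - r^2) referred to Student's t with
    n - 2 degrees of freedom (exact under bivariate normality);
    |r| = 1 gives p = 0.
    """
    if n < 3:
        raise ValueError("need at least 3 observations")
    if not np.isfinite(r) or abs(r) > 1:
        raise ValueError("correlation must lie in [-1, 1]")
    if abs(r) == 1:
        return 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def correlate_with_target(timecourse: pd.DataFrame, target: str,
                          candidates: list[str]) -> pd.DataFrame:
    """Pearson correlation of each candidate with the target profile.

    ``timecourse`` is genes x time points (>= 3 strictly increasing time
    points).  Returns one record per gene — the target itself first with
    r = 1, p = 0 — sorted by descending |r|.  A zero-variance candidate
    is kept but flagged (``r`` NaN) and excluded from classification.
    """
    _validate_timecourse(timecourse)
    if target not in timecourse.index:
        raise ValueError(f"target {target!r} absent from time course")
    missing = [g for g in candidates if g not in timecourse.index]
    if missing:
        raise ValueError(f"candidate(s) absent from time course: {missing[:5]}")
    n = timecourse.shape[1]
    y = timecourse.loc[target].to_numpy(dtype=float)
    if y.std() == 0:
        raise ValueError("target profile has zero variance")
    rows = [(target, 1.0, 0.0, False)]
    for g in candidates:
        if g == target:
            continue
        x = timecourse.loc[g].to_numpy(dtype=float)
        if x.std() == 0:
            rows.append((g, np.nan, np.nan, True))
            continue
        r = float(np.corrcoef(x, y)[0, 1])
        rows.append((g, r, correlation_pvalue(r, n), False))
    out = pd.DataFrame(rows, columns=["gene_id", "r", "p", "zero_variance"]
                       ).set_index("gene_id")
    order = (-out["r"].abs()).fillna(np.inf)
    return out.loc[order.sort_values(kind="mergesort").index]


def classify_regulators(records: pd.DataFrame, pos_cut: float = 0.95,
                        neg_cut: float = -0.95) -> pd.DataFrame:
    """Label strong positive / strong negative correlations (inclusive cuts).

    r >= pos_cut -> ``strong_positive``; r <= neg_cut ->
    ``strong_negative``; anything else (including flagged zero-variance
    records) -> ``none``.
    """
    out = records.copy()
    r = out["r"]
    out["class"] = np.select(
        [r >= pos_cut, r <= neg_cut], [STRONG_POSITIVE, STRONG_NEGATIVE], NONE
    )
    out.loc[r.isna(), "class"] = NONE
    return out


def _validate_timecourse(tc: pd.DataFrame) -> None:
    if tc.shape[1] < 3:
        raise ValueError("time course needs at least 3 time points")
    times = pd.to_numeric(pd.Index(tc.columns), errors="coerce")
    if times.isna().any():
        raise ValueError("time-course columns must be numeric hours")
    if not (np.diff(times.to_numpy()) > 0).all():
        raise ValueError("time points must be strictly increasing")


def read_timecourse(path) -> pd.DataFrame:
    """Read a gene x time-point TSV (columns labeled by hour)."""
    tc = pd.read_csv(path, sep="\t", index_col=0, comment="#").astype(float)
    tc.index = tc.index.astype(str)
    _validate_timecourse(tc)
    return tc
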
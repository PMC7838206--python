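"""Pearson product-moment correlation with explicit variance explained."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    r_squared: float
    n: int
    p: float
    undefined: bool = False


def pearson_with_r2(x, y) -> CorrelationResult:
    """Pearson r, r^2 and the two-sided p (t transform) on complete pairs.

    Non-finite pairs are dropped.  Zero variance in either variable leaves
    the correlation undefined; the result is flagged rather than coerced.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = len(x)
    if n < 3:
        raise ValueError(f"need at least 3 complete pairs, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(np.nan, np.nan, n, np.nan, undefined=True)
    res = sps.pearsonr(x, y)
    r = float(res.statistic)
    return CorrelationResult(r, r * r, n, float(res.pvalue))
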
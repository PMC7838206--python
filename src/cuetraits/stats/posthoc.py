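"""Tukey HSD pairwise comparisons.

Adjusted p-values come from the studentized range distribution with the
Tukey-Kramer standard error for unequal group sizes.  The pooled error
variance and its degrees of freedom are supplied by the caller, so the
probe can use whichever ANOVA error stratum matches the probed term
(between vs within)."""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import studentized_range

_PAIR_COLUMNS = ["group1", "group2", "mean_diff", "se", "q", "p_adj", "reject"]


def tukey_hsd(means, ns, ms_error: float, df_error: float,
              labels=None, alpha: float = 0.05) -> pd.DataFrame:
    """Pairwise studentized-range comparisons of k group means.

    ``ms_error``/``df_error`` are the pooled error mean square and df of the
    matching ANOVA stratum.  With a single group the table is empty.
    """
    means = np.asarray(means, dtype=float)
    ns = np.asarray(ns, dtype=float)
    k = len(means)
    if labels is None:
        labels = [str(i) for i in range(k)]
    if k < 2:
        return pd.DataFrame(columns=_PAIR_COLUMNS)
    rows = []
    for i, j in combinations(range(k), 2):
        diff = means[i] - means[j]
        se = np.sqrt(ms_error / 2.0 * (1.0 / ns[i] + 1.0 / ns[j]))
        q = abs(diff) / se
        p = float(studentized_range.sf(q, k, df_error))
        rows.append({"group1": labels[i], "group2": labels[j],
                     "mean_diff": float(diff), "se": float(se),
                     "q": float(q), "p_adj": p, "reject": p < alpha})
    return pd.DataFrame(rows, columns=_PAIR_COLUMNS)


def tukey_from_samples(groups: dict, alpha: float = 0.05) -> pd.DataFrame:
    """Convenience wrapper pooling the within-group variance from raw samples."""
    labels = list(groups)
    samples = [np.asarray(groups[g], dtype=float) for g in labels]
    ns = np.array([len(s) for s in samples], dtype=float)
    if (ns < 2).any():
        raise ValueError("every group needs at least 2 observations")
    sse = sum(((s - s.mean()) ** 2).sum() for s in samples)
    df_error = float(ns.sum() - len(samples))
    ms_error = sse / df_error
    means = [s.mean() for s in samples]
    return tukey_hsd(means, ns, ms_error, df_error, labels=labels, alpha=alpha)
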
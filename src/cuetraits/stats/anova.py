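"""Univariate mixed-design repeated-measures ANOVA.

The model is the conventional univariate mixed ANOVA: between-subjects
factors crossed with fully-within repeated factors, subjects nested in the
between-group cells.  Sums of squares are Type III (sum-to-zero contrasts,
partial SS), so unbalanced between-group sizes — e.g. unequal phenotype
groups — are handled; within-factor cells must be complete per subject, and
subjects with any missing within cell are excluded casewise (the count is
reported).  No sphericity correction is applied: plain univariate F with
integer degrees of freedom.

Error strata follow the classical decomposition: between-subject terms are
tested against subjects-within-groups; any term involving a within-factor
combination w is tested against the subject x w interaction within groups.
The computation projects each subject's within-cell vector onto orthonormal
contrast subspaces (one per within-factor combination) and runs a Type III
between-subjects regression on each projected score, which reproduces the
classical summation formulas exactly on balanced designs.

Effect size is classical eta-squared, SS_term / SS_total (partial
eta-squared is also reported).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations, product

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.linalg import helmert


@dataclass
class AnovaResult:
    """Fixed-effect table, error strata, and bookkeeping for one model."""

    table: pd.DataFrame
    errors: pd.DataFrame
    ss_total: float
    n_subjects: int
    excluded_subjects: list

    @property
    def n_excluded(self) -> int:
        return len(self.excluded_subjects)

    def term(self, label: str) -> pd.Series:
        hit = self.table[self.table["term"] == label]
        if hit.empty:
            raise KeyError(f"no ANOVA term '{label}'")
        return hit.iloc[0]


def _effect_coding(labels: np.ndarray, levels: list) -> np.ndarray:
    """Sum-to-zero (deviation) coding: k levels -> k-1 columns."""
    k = len(levels)
    idx = {lev: i for i, lev in enumerate(levels)}
    M = np.zeros((len(labels), k - 1))
    for r, lab in enumerate(labels):
        i = idx[lab]
        if i < k - 1:
            M[r, i] = 1.0
        else:
            M[r, :] = -1.0
    return M


def _interaction(blocks) -> np.ndarray:
    out = blocks[0]
    for b in blocks[1:]:
        out = np.einsum("ij,ik->ijk", out, b).reshape(out.shape[0], -1)
    return out


def _rss(X: np.ndarray, U: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, U, rcond=None)
    R = U - X @ beta
    return float((R * R).sum())


def _label(within_part, between_part) -> str:
    return " × ".join(list(within_part) + list(between_part))


def mixed_rm_anova(data: pd.DataFrame, dv: str, subject: str,
                   between=(), within=()) -> AnovaResult:
    """Fit the mixed RM-ANOVA of ``dv`` and return the full F table.

    ``data`` is long-format with one row per subject x within-cell.  Raises
    on duplicate observations, inconsistent between labels within a subject,
    or a singular between-subjects design (e.g. an empty group cell).
    """
    between, within = list(between), list(within)
    cols = [subject, dv] + between + within
    missing = [c for c in cols if c not in data.columns]
    if missing:
        raise ValueError(f"missing column(s) {missing}")
    d = data[cols].copy()

    key = [subject] + within
    if d.duplicated(subset=key).any():
        raise ValueError("duplicate observation for a subject within-cell")

    wlevels = [sorted(d[f].dropna().unique().tolist()) for f in within]
    if within:
        wide = d.pivot(index=subject, columns=within, values=dv)
        full = (pd.MultiIndex.from_product(wlevels, names=within)
                if len(within) > 1 else pd.Index(wlevels[0], name=within[0]))
        wide = wide.reindex(columns=full)
    else:
        wide = d.set_index(subject)[[dv]]

    if between:
        nun = d.groupby(subject)[between].nunique()
        if (nun > 1).any().any():
            raise ValueError("between-subjects labels vary within a subject")
        bmeta = d.groupby(subject)[between].first().reindex(wide.index)
    else:
        bmeta = pd.DataFrame(index=wide.index)

    complete = wide.notna().all(axis=1)
    if between:
        complete &= bmeta.notna().all(axis=1)
    excluded = sorted(map(str, wide.index[~complete]))
    Y = wide.loc[complete].to_numpy(dtype=float)
    bmeta = bmeta.loc[complete]
    S, m = Y.shape
    if S < 3:
        raise ValueError(f"only {S} complete subjects; cannot fit model")

    blevels = [sorted(bmeta[f].unique().tolist()) for f in between]
    if between:
        cells = bmeta.groupby(between, observed=True).size()
        n_cells = int(np.prod([len(l) for l in blevels]))
        if len(cells) < n_cells:
            raise ValueError("empty between-subjects cell: singular design")
    else:
        n_cells = 1

    # between-subjects design, sum-to-zero, grouped in labeled column blocks
    codings = {f: _effect_coding(bmeta[f].to_numpy(), lv)
               for f, lv in zip(between, blevels)}
    blocks = [("Intercept", np.ones((S, 1)))]
    for r in range(1, len(between) + 1):
        for combo in combinations(between, r):
            blocks.append((combo, _interaction([codings[f] for f in combo])))
    X = np.hstack([b for _, b in blocks])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("singular between-subjects design")
    spans, start = {}, 0
    for name, b in blocks:
        spans[name] = (start, start + b.shape[1])
        start += b.shape[1]

    def _without(name):
        lo, hi = spans[name]
        return np.delete(X, np.s_[lo:hi], axis=1)

    # orthonormal within bases: mean vector and Helmert contrast columns
    bases = {}
    for f, lv in zip(within, wlevels):
        l = len(lv)
        bases[f] = (np.full((l, 1), 1.0 / np.sqrt(l)), helmert(l).T)

    grand = Y.mean()
    ss_total = float(((Y - grand) ** 2).sum())

    rows, err_rows = [], []
    strata = [tuple(w) for r in range(len(within) + 1)
              for w in combinations(within, r)]
    for omega in strata:
        C = np.ones((1, 1))
        for f in within:
            C = np.kron(C, bases[f][1] if f in omega else bases[f][0])
        U = Y @ C
        d_omega = C.shape[1]
        rss_full = _rss(X, U)
        df_err = d_omega * (S - n_cells)
        stratum = "Between" if not omega else " × ".join(omega)
        err_rows.append({"stratum": stratum, "ss": rss_full, "df": df_err,
                         "ms": rss_full / df_err if df_err else np.nan})
        droppable = ([("Intercept", 1)] if omega else [])
        droppable += [(combo, int(np.prod([len(lv) - 1 for f2, lv in
                                           zip(between, blevels) if f2 in combo])))
                      for r in range(1, len(between) + 1)
                      for combo in combinations(tuple(between), r)]
        for name, width in droppable:
            ss = _rss(_without(name), U) - rss_full
            df_num = d_omega * width
            ms_err = rss_full / df_err if df_err else np.nan
            F = (ss / df_num) / ms_err if df_err else np.nan
            label = _label(omega, () if name == "Intercept" else name)
            rows.append({
                "term": label, "stratum": stratum,
                "ss": ss, "df_num": df_num, "df_den": df_err,
                "ms": ss / df_num, "F": F,
                "p": float(sps.f.sf(F, df_num, df_err)) if df_err else np.nan,
                "eta_squared": ss / ss_total,
                "eta_squared_partial": ss / (ss + rss_full),
            })
    return AnovaResult(table=pd.DataFrame(rows), errors=pd.DataFrame(err_rows),
                       ss_total=ss_total, n_subjects=S,
                       excluded_subjects=excluded)
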
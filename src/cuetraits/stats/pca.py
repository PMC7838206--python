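"""Principal components with Kaiser retention and normalized varimax rotation.

The decomposition operates on the correlation matrix of complete cases
(variables standardized to unit variance), retains components with
eigenvalue >= 1 (Kaiser criterion), and rotates the retained loading matrix
with Kaiser-normalized varimax: rows are scaled to unit communality,
an orthogonal rotation maximizing the varimax criterion is found
iteratively, and rows are rescaled back.  Communalities are invariant under
the (orthogonal) rotation; loadings with magnitude above a salience cutoff
(0.7 by default) are flagged.  Each factor is sign-oriented so its
largest-magnitude loading is positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class VarimaxConvergenceError(RuntimeError):
    pass


@dataclass
class PCAResult:
    loadings: pd.DataFrame          # variables x retained factors (rotated)
    unrotated: pd.DataFrame
    eigenvalues: np.ndarray         # all eigenvalues, descending
    n_retained: int
    proportion: np.ndarray          # variance proportion per retained factor
    cumulative: np.ndarray
    rotation: str
    salient: pd.DataFrame = field(default=None)
    communalities: pd.Series = field(default=None)
    rotation_matrix: np.ndarray = field(default=None)
    n_iter: int = 0
    n_obs: int = 0


def varimax_criterion(L: np.ndarray) -> float:
    """Sum over factors of the variance of squared loadings (raw criterion)."""
    L2 = np.asarray(L) ** 2
    return float((L2.var(axis=0)).sum())


def varimax(loadings: np.ndarray, normalize: bool = True, tol: float = 1e-6,
            max_iter: int = 500):
    """Kaiser-normalized varimax rotation of a loading matrix.

    Classical pairwise (Jacobi-style) planar rotations: for every factor
    pair the criterion-maximizing angle has a closed form, and sweeps repeat
    until the relative criterion change falls below ``tol`` (and all planar
    angles are negligible).  Returns ``(rotated, rotation_matrix, n_iter)``;
    exceeding ``max_iter`` sweeps raises :class:`VarimaxConvergenceError`
    with diagnostics.
    """
    L = np.asarray(loadings, dtype=float)
    p, k = L.shape
    if k < 2:
        return L.copy(), np.eye(k), 0
    h = np.sqrt((L ** 2).sum(axis=1))
    if normalize:
        if (h == 0).any():
            raise ValueError("zero-communality row; cannot Kaiser-normalize")
        Lam = L / h[:, None]
    else:
        Lam = L.copy()
    R = np.eye(k)
    v_old = varimax_criterion(Lam)
    for it in range(1, max_iter + 1):
        max_phi = 0.0
        for a in range(k - 1):
            for b in range(a + 1, k):
                x, y = Lam[:, a], Lam[:, b]
                u = x * x - y * y
                w = 2.0 * x * y
                num = 2.0 * (u * w).sum() - 2.0 * u.sum() * w.sum() / p
                den = (u * u - w * w).sum() - (u.sum() ** 2
                                               - w.sum() ** 2) / p
                if num == 0.0 and den == 0.0:
                    continue
                phi = 0.25 * np.arctan2(num, den)
                if abs(phi) < 1e-12:
                    continue
                max_phi = max(max_phi, abs(phi))
                c, s = np.cos(phi), np.sin(phi)
                G = np.array([[c, -s], [s, c]])
                Lam[:, [a, b]] = Lam[:, [a, b]] @ G
                R[:, [a, b]] = R[:, [a, b]] @ G
        v_new = varimax_criterion(Lam)
        if (v_new - v_old) <= tol * max(v_old, 1e-12) and max_phi < 1e-6:
            break
        v_old = v_new
    else:
        raise VarimaxConvergenceError(
            f"varimax did not converge in {max_iter} sweeps "
            f"(criterion {v_new:.6e}, last max angle {max_phi:.3e} rad)")
    rotated = Lam * (h[:, None] if normalize else 1.0)
    return rotated, R, it


def _orient_signs(L: np.ndarray) -> np.ndarray:
    flip = np.sign(L[np.abs(L).argmax(axis=0), np.arange(L.shape[1])])
    flip[flip == 0] = 1.0
    return L * flip


def pca_varimax(data: pd.DataFrame, columns=None, min_eigenvalue: float = 1.0,
                salient_cutoff: float = 0.7, rotate: bool = True,
                tol: float = 1e-6, max_iter: int = 500) -> PCAResult:
    """Correlation-matrix PCA with eigenvalue-based retention and varimax.

    ``data`` rows with any missing value among ``columns`` are dropped
    (complete cases).  Raises if fewer than one component reaches
    ``min_eigenvalue`` or if any variable has zero variance.
    """
    if columns is None:
        columns = list(data.columns)
    if len(columns) < 2:
        raise ValueError("need at least 2 variables")
    X = data[list(columns)].dropna().to_numpy(dtype=float)
    n, p = X.shape
    if n <= p:
        raise ValueError(f"need more complete cases ({n}) than variables ({p})")
    if (X.std(axis=0) == 0).any():
        raise ValueError("zero-variance variable")
    corr = np.corrcoef(X, rowvar=False)
    vals, vecs = np.linalg.eigh(corr)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    k = int((vals >= min_eigenvalue).sum())
    if k < 1:
        raise ValueError(
            f"no component reaches the minimum eigenvalue {min_eigenvalue}")
    unrot = vecs[:, :k] * np.sqrt(vals[:k])
    if rotate and k > 1:
        rotated, R, n_iter = varimax(unrot, normalize=True, tol=tol,
                                     max_iter=max_iter)
        rotation = "varimax (normalized)"
    else:
        rotated, R, n_iter = unrot.copy(), np.eye(k), 0
        rotation = "none"
    rotated = _orient_signs(rotated)
    unrot_df = pd.DataFrame(_orient_signs(unrot.copy()), index=columns,
                            columns=[f"F{i + 1}" for i in range(k)])
    load = pd.DataFrame(rotated, index=columns,
                        columns=[f"F{i + 1}" for i in range(k)])
    prop = (rotated ** 2).sum(axis=0) / p
    return PCAResult(
        loadings=load, unrotated=unrot_df, eigenvalues=vals, n_retained=k,
        proportion=prop, cumulative=np.cumsum(vals[:k]) / p,
        rotation=rotation, salient=load.abs() > salient_cutoff,
        communalities=pd.Series((rotated ** 2).sum(axis=1), index=columns),
        rotation_matrix=R, n_iter=n_iter, n_obs=n)
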
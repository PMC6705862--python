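"""Correlation-matrix PCA with varimax rotation and adequacy diagnostics.

The variable-reduction stage mirrors the SPSS-style workflow: Bartlett's
test of sphericity (is the correlation matrix distinguishable from
identity?), the Kaiser-Meyer-Olkin measure of sampling adequacy (raw vs
partial correlations; > .50 acceptable), principal components of the
correlation matrix, Kaiser retention (eigenvalue > 1.0) with a ≥ 60%
cumulative-variance check, varimax rotation with Kaiser row normalization,
and a ±.60 flag for practically significant loadings.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import UsageError

logger = logging.getLogger("matchspace")


@dataclass
class FAConfig:
    eigen_threshold: float = 1.0
    cumvar_threshold_pct: float = 60.0
    loading_threshold: float = 0.60
    kaiser_normalize: bool = True
    max_iter: int = 1000
    tol: float = 1e-8

    def __post_init__(self) -> None:
        if min(self.eigen_threshold, self.cumvar_threshold_pct, self.loading_threshold) <= 0:
            raise UsageError("thresholds must be positive")


@dataclass
class FactorModel:
    """Fitted PCA + varimax model with diagnostics."""

    variables: list[str]
    eigenvalues: np.ndarray
    pct_variance: np.ndarray          # per retained rotated component
    cumulative_pct: np.ndarray
    loadings: pd.DataFrame            # variables × retained components (rotated)
    n_retained: int
    practical_flags: pd.DataFrame     # |loading| ≥ loading_threshold
    bartlett_chi2: float
    bartlett_df: int
    bartlett_p: float
    kmo_overall: float
    kmo_per_variable: pd.Series
    n_observations: int

    def to_frame(self) -> pd.DataFrame:
        """Loadings table with eigenvalue / % variance / cumulative % footer rows."""
        out = self.loadings.copy()
        footer = pd.DataFrame(
            [self.eigenvalues[: self.n_retained], self.pct_variance, self.cumulative_pct],
            index=["eigenvalue", "pct_variance", "cumulative_pct"],
            columns=out.columns,
        )
        return pd.concat([out, footer])


# ---------------------------------------------------------------------------
# adequacy diagnostics
# ---------------------------------------------------------------------------


def bartlett_sphericity(R: np.ndarray, n: int) -> tuple[float, int, float]:
    """Bartlett's test that R is an identity matrix.

    χ² = −(n − 1 − (2p + 5)/6) · ln det R with p(p−1)/2 degrees of freedom.
    """
    R = np.asarray(R, dtype=float)
    p = R.shape[0]
    if p < 2:
        raise UsageError("Bartlett's test needs at least two variables")
    if not np.allclose(R, R.T) or not np.allclose(np.diag(R), 1.0):
        raise UsageError("R must be a symmetric correlation matrix with unit diagonal")
    sign, logdet = np.linalg.slogdet(R)
    if sign <= 0:
        raise UsageError("correlation matrix is singular (non-positive determinant)")
    chi2 = -(n - 1 - (2 * p + 5) / 6.0) * logdet
    df = p * (p - 1) // 2
    return float(chi2), int(df), float(stats.chi2.sf(chi2, df))


def kmo(R: np.ndarray) -> tuple[float, np.ndarray]:
    """Kaiser-Meyer-Olkin sampling adequacy, overall and per variable.

    Anti-image partial correlations come from the inverse of R:
    q_ij = −S_ij / √(S_ii S_jj). KMO = Σ r² / (Σ r² + Σ q²) over
    off-diagonal entries (per-variable versions restrict to one row).
    Returns NaN values for a matrix with no off-diagonal correlation
    (0/0 degenerate case).
    """
    R = np.asarray(R, dtype=float)
    try:
        S = np.linalg.inv(R)
    except np.linalg.LinAlgError as exc:
        raise UsageError("singular correlation matrix") from exc
    d = np.sqrt(np.outer(np.diag(S), np.diag(S)))
    partial = -S / d
    off = ~np.eye(R.shape[0], dtype=bool)
    r2 = R**2 * off
    q2 = partial**2 * off
    denom_overall = r2.sum() + q2.sum()
    if denom_overall == 0:
        logger.info("KMO degenerate: no off-diagonal correlation")
        return float("nan"), np.full(R.shape[0], np.nan)
    overall = float(r2.sum() / denom_overall)
    denom_var = r2.sum(axis=1) + q2.sum(axis=1)
    with np.errstate(invalid="ignore"):
        per_var = np.where(denom_var > 0, r2.sum(axis=1) / denom_var, np.nan)
    return overall, per_var


# ---------------------------------------------------------------------------
# retention and rotation
# ---------------------------------------------------------------------------


def retain_components(eigenvalues: np.ndarray, config: FAConfig | None = None) -> int:
    """Kaiser rule: count of eigenvalues strictly greater than the threshold.

    Warns when the retained components explain less cumulative variance
    than ``cumvar_threshold_pct``.
    """
    config = config or FAConfig()
    ev = np.asarray(eigenvalues, dtype=float)
    if np.any(np.diff(ev) > 1e-12):
        raise UsageError("eigenvalues must be sorted in descending order")
    k = int(np.sum(ev > config.eigen_threshold))
    if k:
        cum = 100.0 * ev[:k].sum() / ev.sum()
        if cum < config.cumvar_threshold_pct:
            warnings.warn(
                f"retained {k} components explain only {cum:.1f}% "
                f"(< {config.cumvar_threshold_pct}%)",
                stacklevel=2,
            )
    return k


def varimax_criterion(loadings: np.ndarray) -> float:
    """The varimax objective: summed per-component variance of squared loadings."""
    L2 = np.asarray(loadings, dtype=float) ** 2
    return float(np.sum(L2.var(axis=0)))


def varimax(loadings: np.ndarray, kaiser_normalize: bool = True,
            max_iter: int = 1000, tol: float = 1e-8) -> tuple[np.ndarray, np.ndarray]:
    """Varimax rotation of a loading matrix (Kaiser's pairwise algorithm).

    Sweeps every pair of components, applying the closed-form planar
    rotation angle that maximizes the varimax criterion for that pair,
    until a full sweep moves by less than ``tol`` radians in total. With
    Kaiser normalization rows are scaled to unit communality during the
    iteration and rescaled afterwards. Returns the rotated loadings and
    the orthogonal rotation matrix.
    """
    L = np.asarray(loadings, dtype=float).copy()
    p, k = L.shape
    if k < 2:
        return L, np.eye(k)
    if kaiser_normalize:
        h = np.sqrt((L**2).sum(axis=1))
        h[h == 0] = 1.0
        L = L / h[:, None]
    T = np.eye(k)
    for sweep in range(max_iter):
        moved = 0.0
        for i in range(k - 1):
            for j in range(i + 1, k):
                a, b = L[:, i], L[:, j]
                u, v = a**2 - b**2, 2 * a * b
                num = 2 * (u * v).sum() - 2 * u.sum() * v.sum() / p
                den = (u**2 - v**2).sum() - (u.sum() ** 2 - v.sum() ** 2) / p
                phi = 0.25 * np.arctan2(num, den)
                if abs(phi) < 1e-14:
                    continue
                c, s = np.cos(phi), np.sin(phi)
                G = np.array([[c, -s], [s, c]])
                L[:, [i, j]] = L[:, [i, j]] @ G
                T[:, [i, j]] = T[:, [i, j]] @ G
                moved += abs(phi)
        if moved < tol:
            break
    else:
        warnings.warn("varimax rotation did not converge; returning last iterate",
                      stacklevel=2)
    if kaiser_normalize:
        L = L * h[:, None]
    return L, T


def _order_and_sign(loadings: np.ndarray) -> np.ndarray:
    """Deterministic presentation: order components by rotated variance
    (descending), make each component's largest-|loading| entry positive."""
    var = (loadings**2).sum(axis=0)
    order = np.argsort(-var, kind="stable")
    out = loadings[:, order]
    for j in range(out.shape[1]):
        i = int(np.argmax(np.abs(out[:, j])))
        if out[i, j] < 0:
            out[:, j] = -out[:, j]
    return out


def pca_varimax(table: pd.DataFrame, config: FAConfig | None = None,
                variables: list[str] | None = None) -> FactorModel:
    """Correlation-matrix PCA with Kaiser retention and varimax rotation.

    Rows with any missing value among the selected variables are dropped
    (listwise deletion) before the correlation matrix is formed. Loadings
    are eigenvectors scaled by √eigenvalue; rotation preserves per-variable
    communalities.
    """
    config = config or FAConfig()
    variables = variables or list(table.columns)
    X = table[variables].astype(float)
    n_before = len(X)
    X = X.dropna()
    if n_before - len(X):
        logger.info("listwise deletion dropped %d of %d rows", n_before - len(X), n_before)
    if len(X) < len(variables) + 1:
        raise UsageError("need at least (number of variables + 1) complete rows")
    sds = X.std(ddof=1)
    constant = sds[sds == 0].index.tolist()
    if constant:
        raise UsageError(f"constant column(s): {constant}")
    R = np.corrcoef(X.to_numpy(), rowvar=False)
    n = len(X)

    # adequacy diagnostics need an invertible R; with exactly collinear
    # variables (e.g. deepest location vs the offensive-space rectangle,
    # which are linear complements by definition) they are undefined and
    # reported as NaN while the PCA itself proceeds on the eigenspectrum
    try:
        chi2, df, p_val = bartlett_sphericity(R, n)
    except UsageError as exc:
        logger.warning("Bartlett diagnostic undefined: %s", exc)
        chi2, df, p_val = float("nan"), len(variables) * (len(variables) - 1) // 2, float("nan")
    try:
        kmo_all, kmo_var = kmo(R)
    except UsageError as exc:
        logger.warning("KMO diagnostic undefined: %s", exc)
        kmo_all, kmo_var = float("nan"), np.full(len(variables), np.nan)

    eigval, eigvec = np.linalg.eigh(R)
    order = np.argsort(-eigval)
    eigval, eigvec = eigval[order], eigvec[:, order]
    k = retain_components(eigval, config)
    if k == 0:
        raise UsageError("no component passes the eigenvalue threshold")
    raw_loadings = eigvec[:, :k] * np.sqrt(eigval[:k])
    rotated, _ = varimax(raw_loadings, config.kaiser_normalize,
                         config.max_iter, config.tol)
    rotated = _order_and_sign(rotated)

    comp_names = [f"PC{j + 1}" for j in range(k)]
    loadings = pd.DataFrame(rotated, index=variables, columns=comp_names)
    pct = 100.0 * (rotated**2).sum(axis=0) / len(variables)
    return FactorModel(
        variables=list(variables),
        eigenvalues=eigval,
        pct_variance=pct,
        cumulative_pct=np.cumsum(pct),
        loadings=loadings,
        n_retained=k,
        practical_flags=loadings.abs() >= config.loading_threshold,
        bartlett_chi2=chi2,
        bartlett_df=df,
        bartlett_p=p_val,
        kmo_overall=kmo_all,
        kmo_per_variable=pd.Series(kmo_var, index=variables),
        n_observations=n,
    )
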
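"""Canonical correspondence analysis with per-factor permutation tests.

ter Braak's algorithm: chi-square standardise the community matrix,
project its row space onto the (weighted-centred) environmental predictors
under row weights, and take the SVD of the fitted matrix. The permutation
test is MARGINAL — one factor at a time, the others ignored — with the
pseudo-F statistic (constrained over residual inertia, each scaled by its
degrees of freedom) recomputed under random row permutations of the
factor. Community rows are expected as relative abundances.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger("gapkit")

_RANK_TOL = 1e-10


@dataclass
class CCAResult:
    constrained_eigenvalues: np.ndarray
    total_inertia: float
    constrained_inertia: float
    pseudo_F: float
    rank: int
    site_scores: pd.DataFrame
    species_scores: pd.DataFrame
    biplot_scores: pd.DataFrame


@dataclass(frozen=True)
class PermutationTestResult:
    factor: str
    F_observed: float
    p_value: float
    n_permutations: int
    seed: int


def dummy_code(X: pd.DataFrame) -> pd.DataFrame:
    """Dummy-code categorical predictors with first-level reference."""
    return pd.get_dummies(X, drop_first=True, dtype=float)


def _chi_square_standardise(Y: np.ndarray):
    total = Y.sum()
    if total <= 0:
        raise ValueError("community matrix has zero total")
    P = Y / total
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    if np.any(r == 0):
        bad = int(np.argmin(r))
        raise ValueError(f"sample row {bad} has zero total abundance")
    if np.any(c == 0):
        bad = int(np.argmin(c))
        raise ValueError(f"cluster column {bad} has zero total abundance")
    expected = np.outer(r, c)
    Q = (P - expected) / np.sqrt(expected)
    return Q, r, float(np.sum(Q * Q))


def _constraint_basis(Z: np.ndarray, r: np.ndarray) -> np.ndarray:
    """Orthonormal basis (in the sqrt(r) metric) of the centred constraint
    space; aliased columns are dropped implicitly by the rank cut."""
    Zc = Z - r @ Z  # weighted column means removed
    Zs = np.sqrt(r)[:, None] * Zc
    U, s, _ = np.linalg.svd(Zs, full_matrices=False)
    keep = s > _RANK_TOL * (s[0] if s.size else 1.0)
    if keep.sum() < Z.shape[1]:
        logger.warning("dropped %d aliased constraint dimension(s)",
                       Z.shape[1] - int(keep.sum()))
    return U[:, keep]


def cca_fit(Y, X) -> CCAResult:
    """Constrained correspondence analysis of community Y on predictors X.

    Y: non-negative samples x clusters matrix (DataFrame or array) with
    positive row and column sums. X: samples x predictors; categorical
    columns are dummy-coded. Eigenvalues are the squared singular values
    of the weighted-least-squares fit of the chi-square-standardised Y.
    """
    y_index = Y.index if isinstance(Y, pd.DataFrame) else None
    y_cols = Y.columns if isinstance(Y, pd.DataFrame) else None
    if isinstance(X, pd.Series):
        X = X.to_frame()
    if isinstance(X, pd.DataFrame):
        if y_index is not None:
            X = X.loc[y_index]
        X = dummy_code(X)
        x_cols = list(X.columns)
        Z = X.to_numpy(dtype=float)
    else:
        Z = np.asarray(X, dtype=float)
        if Z.ndim == 1:
            Z = Z[:, None]
        x_cols = [f"x{i}" for i in range(Z.shape[1])]
    Yv = np.asarray(Y, dtype=float)
    if np.any(Yv < 0):
        raise ValueError("community matrix must be non-negative")
    n, m = Yv.shape
    if Z.shape[0] != n:
        raise ValueError("Y and X disagree on the number of samples")

    Q, r, total = _chi_square_standardise(Yv)
    U = _constraint_basis(Z, r)
    q = U.shape[1]
    proj = U.T @ Q                      # q x m; ||proj||^2 = constrained inertia
    Us, s, Vt = np.linalg.svd(proj, full_matrices=False)
    k = min(q, m - 1)
    eig = (s ** 2)[:k]
    constrained = float(np.sum(proj * proj))
    residual = total - constrained
    if q == 0 or n - q - 1 <= 0 or residual <= 0:
        pseudo_F = np.inf if q > 0 and residual <= 0 else 0.0
    else:
        pseudo_F = (constrained / q) / (residual / (n - q - 1))

    axes = [f"CCA{i + 1}" for i in range(k)]
    sites = (U @ Us[:, :k]) * s[:k]     # linear-combination site scores
    sites = sites / np.sqrt(r)[:, None]
    species = Vt[:k].T
    # biplot scores: weighted correlation of predictors with site axes
    Zc = Z - r @ Z
    Zs = np.sqrt(r)[:, None] * Zc
    ax = U @ Us[:, :k]
    with np.errstate(invalid="ignore", divide="ignore"):
        norm = np.linalg.norm(Zs, axis=0)[:, None]
        biplot = np.where(norm > 0, (Zs.T @ ax) / norm, 0.0)
    idx = y_index if y_index is not None else pd.RangeIndex(n)
    cols = y_cols if y_cols is not None else pd.RangeIndex(m)
    return CCAResult(
        constrained_eigenvalues=eig,
        total_inertia=total,
        constrained_inertia=constrained,
        pseudo_F=float(pseudo_F),
        rank=q,
        site_scores=pd.DataFrame(sites[:, :k], index=idx, columns=axes),
        species_scores=pd.DataFrame(species, index=cols, columns=axes),
        biplot_scores=pd.DataFrame(biplot, index=x_cols, columns=axes),
    )


def _pseudo_F(Q: np.ndarray, r: np.ndarray, total: float,
              Z: np.ndarray) -> float:
    n = Q.shape[0]
    U = _constraint_basis(Z, r)
    q = U.shape[1]
    if q == 0 or n - q - 1 <= 0:
        return 0.0
    proj = U.T @ Q
    constrained = float(np.sum(proj * proj))
    residual = total - constrained
    if residual <= 0:
        return np.inf
    return (constrained / q) / (residual / (n - q - 1))


def permutation_test(Y, x_factor, n_perm: int = 999, seed: int = 0,
                     factor_name: str | None = None) -> PermutationTestResult:
    """Marginal permutation test of one environmental factor.

    F_observed comes from cca_fit(Y, x_factor); the factor's sample rows
    are then permuted ``n_perm`` times (a categorical factor permutes as a
    block of dummy columns) and p = (1 + #{F_perm >= F_obs}) / (1 + n_perm).
    Samples are put in a canonical order (sorted by id) before permuting,
    so the p-value is reproducible regardless of input row order.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    name = factor_name
    if isinstance(x_factor, pd.Series):
        name = name or str(x_factor.name)
        x_factor = x_factor.to_frame()
    if isinstance(Y, pd.DataFrame):
        order = sorted(Y.index.astype(str))
        Y = Y.loc[order]
        if isinstance(x_factor, pd.DataFrame):
            x_factor = x_factor.loc[order]
    if isinstance(x_factor, pd.DataFrame):
        name = name or "+".join(map(str, x_factor.columns))
        Z = dummy_code(x_factor).to_numpy(dtype=float)
    else:
        Z = np.asarray(x_factor, dtype=float)
        if Z.ndim == 1:
            Z = Z[:, None]
        name = name or "factor"

    Yv = np.asarray(Y, dtype=float)
    Q, r, total = _chi_square_standardise(Yv)
    F_obs = _pseudo_F(Q, r, total, Z)
    rng = np.random.default_rng(seed)
    n = Z.shape[0]
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if _pseudo_F(Q, r, total, Z[perm]) >= F_obs:
            exceed += 1
    p = (1 + exceed) / (1 + n_perm)
    return PermutationTestResult(name, float(F_obs), float(p), n_perm, seed)


def env_permutation_tests(Y, env: pd.DataFrame, n_perm: int = 999,
                          seed: int = 0) -> pd.DataFrame:
    """One marginal test per environmental column; returns a tidy table
    (factor, F, p) mirroring a per-factor significance summary."""
    rows = []
    for i, col in enumerate(env.columns):
        res = permutation_test(Y, env[col], n_perm=n_perm, seed=seed + i,
                               factor_name=str(col))
        rows.append({"factor": res.factor, "F": res.F_observed,
                     "p_value": res.p_value})
    return pd.DataFrame(rows).set_index("factor")
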
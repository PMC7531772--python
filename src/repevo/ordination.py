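"""Canonical correspondence analysis (CCA) with a permutation pseudo-F test.

CCA ordains a non-negative response table Y (taxa x orthogroups, gene
counts) in the chi-square metric, constrained to the subspace spanned by
explanatory variables X (taxa x domain counts). The algorithm is the
classical one (ter Braak; as in vegan's ``cca``):

1. relative frequencies p_ij = y_ij / y++; row weights r = p_i+, column
   weights c = p_+j;
2. the chi-square standardized matrix
   Qbar_ij = (p_ij - r_i c_j) / sqrt(r_i c_j), whose total sum of squares is
   the total inertia (= Pearson chi-square of Y / grand total);
3. weighted least-squares projection of Qbar onto [1, X] with row weights r
   (computed via QR of diag(sqrt(r)) [1, X]);
4. SVD of the fitted matrix: squared singular values are the constrained
   eigenvalues; their sum the constrained inertia.

The global association test is the permutation pseudo-F
F = (constrained/q) / (residual/(n - q - 1)), with rows of X permuted
jointly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["CcaResult", "cca_fit", "cca_permutation_test"]


@dataclass
class CcaResult:
    eigenvalues: np.ndarray  # constrained eigenvalues, non-increasing
    total_inertia: float
    constrained_inertia: float
    residual_inertia: float
    site_scores: pd.DataFrame  # linear-combination (LC) taxon scores
    species_scores: pd.DataFrame  # orthogroup scores
    biplot_scores: pd.DataFrame  # constraint (domain) vectors
    pseudo_f: float
    df_num: int
    df_den: int
    dropped_rows: tuple[str, ...] = ()
    dropped_cols: tuple[str, ...] = ()
    dropped_constraints: tuple[str, ...] = ()
    p: float | None = None
    n_perm: int | None = None


def _prepare(Y: pd.DataFrame, X: pd.DataFrame):
    """Validate and align the response and constraint tables."""
    if not set(Y.index) == set(X.index):
        raise ValueError("Y and X must cover the same taxa")
    X = X.loc[Y.index]
    Yv = Y.to_numpy(dtype=float)
    if (Yv < 0).any():
        raise ValueError("response table must be non-negative")
    dropped_rows = tuple(Y.index[Yv.sum(axis=1) == 0])
    dropped_cols = tuple(Y.columns[Yv.sum(axis=0) == 0])
    if dropped_rows:
        logger.warning("dropping all-zero response rows: %s", dropped_rows)
        Y = Y.drop(index=list(dropped_rows))
        X = X.drop(index=list(dropped_rows))
    if dropped_cols:
        logger.warning("dropping all-zero response columns: %s", dropped_cols)
        Y = Y.drop(columns=list(dropped_cols))
    # drop constraint columns that are linear combinations of earlier ones
    # (a lone constant column is kept: it constrains nothing and yields zero
    # constrained inertia, which is well-defined)
    keep: list[str] = []
    dropped_constraints: list[str] = []
    Xv = X.to_numpy(dtype=float)
    for j, name in enumerate(X.columns):
        cand = Xv[:, [X.columns.get_loc(k) for k in keep] + [j]]
        if np.linalg.matrix_rank(cand) == cand.shape[1]:
            keep.append(name)
        else:
            dropped_constraints.append(name)
    if dropped_constraints:
        logger.warning("dropping collinear/constant constraints: %s",
                       dropped_constraints)
    X = X[keep]
    if X.shape[1] == 0:
        raise ValueError("constraint matrix has rank 0 after dropping")
    if Y.shape[0] < X.shape[1] + 2:
        raise ValueError("need at least (number of constraints + 2) taxa")
    return Y, X, dropped_rows, dropped_cols, tuple(dropped_constraints)


def _chi_square_matrix(Yv: np.ndarray):
    total = Yv.sum()
    P = Yv / total
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    E = np.outer(r, c)
    Qbar = (P - E) / np.sqrt(E)
    return Qbar, r, c


def _constrained_fit(Qbar: np.ndarray, r: np.ndarray, Xv: np.ndarray):
    """Project Qbar onto the weighted constraint space; return fitted matrix."""
    B = np.column_stack([np.ones(len(r)), Xv]) * np.sqrt(r)[:, None]
    # rank-aware orthonormal basis: a constant constraint collapses onto the
    # weighted intercept and must not contribute a spurious direction
    U, s, _ = np.linalg.svd(B, full_matrices=False)
    Q = U[:, s > s[0] * 1e-12]
    # the weighted-intercept direction is orthogonal to Qbar by construction,
    # so including it leaves the fit unchanged
    return Q @ (Q.T @ Qbar)


def cca_fit(Y: pd.DataFrame, X: pd.DataFrame) -> CcaResult:
    """Fit CCA of response table Y constrained by X.

    All-zero rows/columns of Y and collinear or constant columns of X are
    dropped with a warning. Returns eigenvalues, inertias, taxon/orthogroup/
    constraint scores and the pseudo-F (no p-value; see
    :func:`cca_permutation_test`).
    """
    Y, X, drows, dcols, dcons = _prepare(Y, X)
    Yv = Y.to_numpy(dtype=float)
    Xv = X.to_numpy(dtype=float)
    n, q = Xv.shape

    Qbar, r, c = _chi_square_matrix(Yv)
    total = float(np.sum(Qbar**2))
    fitted = _constrained_fit(Qbar, r, Xv)
    constrained = float(np.sum(fitted**2))
    residual = total - constrained

    U, s, Vt = np.linalg.svd(fitted, full_matrices=False)
    eig = s**2
    n_axes = min(q, Yv.shape[1] - 1, n - 1)
    eig = eig[:n_axes]
    U, s, Vt = U[:, :n_axes], s[:n_axes], Vt[:n_axes]

    axes = [f"CCA{i+1}" for i in range(n_axes)]
    # LC site scores and species scores in the chi-square metric
    site = (U * s) / np.sqrt(r)[:, None]
    species = Vt.T / np.sqrt(c)[:, None]
    # biplot scores: weighted correlation of constraints with LC axes
    Xc = Xv - (r @ Xv)[None, :]
    wsd = np.sqrt((r[:, None] * Xc**2).sum(axis=0))
    site_c = site - (r @ site)[None, :]
    ssd = np.sqrt((r[:, None] * site_c**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        biplot = (r[:, None] * Xc).T @ site_c / np.outer(wsd, ssd)
    biplot = np.nan_to_num(biplot)

    df_num, df_den = q, n - q - 1
    pseudo_f = (constrained / df_num) / (residual / df_den) if residual > 0 else np.inf
    return CcaResult(
        eigenvalues=eig,
        total_inertia=total,
        constrained_inertia=constrained,
        residual_inertia=residual,
        site_scores=pd.DataFrame(site, index=Y.index, columns=axes),
        species_scores=pd.DataFrame(species, index=Y.columns, columns=axes),
        biplot_scores=pd.DataFrame(biplot, index=X.columns, columns=axes),
        pseudo_f=float(pseudo_f),
        df_num=df_num,
        df_den=df_den,
        dropped_rows=drows,
        dropped_cols=dcols,
        dropped_constraints=dcons,
    )


def cca_permutation_test(
    Y: pd.DataFrame,
    X: pd.DataFrame,
    n_perm: int = 999,
    seed: int | None = None,
) -> CcaResult:
    """Global permutation test of the CCA association.

    Rows of X are permuted jointly ``n_perm`` times (unrestricted);
    p = (#{F* >= F} + 1) / (n_perm + 1). Returns the observed fit with
    ``p`` and ``n_perm`` filled in.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be at least 99")
    result = cca_fit(Y, X)
    # recompute on the aligned/filtered tables the fit actually used
    Yv = Y.loc[result.site_scores.index,
               result.species_scores.index].to_numpy(dtype=float)
    Xv = X.loc[result.site_scores.index,
               result.biplot_scores.index].to_numpy(dtype=float)
    n, q = Xv.shape
    Qbar, r, _ = _chi_square_matrix(Yv)
    total = float(np.sum(Qbar**2))
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        Xp = Xv[rng.permutation(n)]
        fitted = _constrained_fit(Qbar, r, Xp)
        con = float(np.sum(fitted**2))
        res = total - con
        f = (con / q) / (res / (n - q - 1)) if res > 0 else np.inf
        if f >= result.pseudo_f - 1e-12:
            hits += 1
    result.p = (hits + 1) / (n_perm + 1)
    result.n_perm = n_perm
    return result
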
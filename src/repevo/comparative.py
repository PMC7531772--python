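"""Phylogenetic signal (Blomberg's K, Pagel's lambda) and (P)GLS regression.

All estimators operate on the Brownian-motion variance-covariance matrix C
of the tree (see :func:`repevo.phylo.vcv_matrix`): under Brownian motion a
trait's tip values are jointly normal with covariance sigma^2 * C.

* Blomberg's K compares the observed ratio of among-tip to
  phylogenetically-corrected trait variance with its Brownian expectation;
  K = 1 is the BM expectation, smaller K means less signal than BM.
* Pagel's lambda multiplies the off-diagonal of C and is estimated by
  profile maximum likelihood on [0, 1]; lambda = 0 is a star phylogeny
  (no signal), lambda = 1 pure BM.
* PGLS is generalized least squares with error covariance proportional to C
  (statsmodels GLS does the fitting); with no tree it collapses to OLS.

The PGLS *scan* regresses every focal orthogroup's (transformed) gene count
on each domain count plus genome size, adjusting p-values across the whole
scan by Benjamini-Hochberg.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.linalg as sla
import scipy.stats
from scipy.optimize import minimize_scalar
import statsmodels.api as sm

from .phylo import Phylogeny, lambda_transform, vcv_matrix
from .repertoire import CountMatrix

__all__ = [
    "SignalEstimate",
    "PglsFit",
    "phylo_mean",
    "blomberg_k",
    "pagel_lambda",
    "pgls_fit",
    "ols_r2",
    "pgls_scan",
]


@dataclass(frozen=True)
class SignalEstimate:
    """Point estimate of a phylogenetic-signal statistic."""

    statistic: str  # "K" or "lambda"
    estimate: float
    loglik: float | None = None
    loglik_zero: float | None = None  # lambda = 0 endpoint
    loglik_one: float | None = None  # lambda = 1 endpoint
    at_boundary: bool = False
    observed_ratio: float | None = None  # K: observed MSE0/MSE
    expected_ratio: float | None = None  # K: BM expectation of that ratio
    p_value: float | None = None


@dataclass(frozen=True)
class PglsFit:
    """A (phylogenetic) generalized least squares fit."""

    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    sigma2: float
    df_resid: int
    cov_params: pd.DataFrame
    correlation: str  # "brownian" or "identity"
    loglik: float

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        q = scipy.stats.t.ppf(1 - alpha / 2, self.df_resid)
        return pd.DataFrame(
            {"lower": self.params - q * self.bse, "upper": self.params + q * self.bse}
        )


def _as_cov(C: pd.DataFrame | np.ndarray, y: pd.Series | np.ndarray):
    """Align trait and covariance; returns (y array, C array)."""
    if isinstance(C, pd.DataFrame) and isinstance(y, pd.Series):
        if set(y.index) != set(C.index):
            raise ValueError("trait and covariance labels do not match")
        y = y.loc[C.index]
    yv = np.asarray(y, dtype=float)
    Cv = C.to_numpy() if isinstance(C, pd.DataFrame) else np.asarray(C, float)
    if yv.shape[0] != Cv.shape[0]:
        raise ValueError("trait length does not match covariance dimension")
    return yv, Cv


def phylo_mean(y, C) -> float:
    """GLS estimate of the ancestral (root) mean: (1'C^-1 1)^-1 1' C^-1 y."""
    yv, Cv = _as_cov(C, y)
    one = np.ones(len(yv))
    Ci_one = sla.solve(Cv, one, assume_a="pos")
    return float(Ci_one @ yv / (Ci_one @ one))


def blomberg_k(y, tree: Phylogeny | None = None, C=None) -> SignalEstimate:
    """Blomberg's K for a continuous trait on a tree.

    K = [MSE0 / MSE] / E_BM[MSE0 / MSE] with MSE0 the mean squared deviation
    from the phylogenetic mean and MSE its C^-1-weighted counterpart;
    the BM expectation is (tr C - n / (1'C^-1 1)) / (n - 1).
    """
    if C is None:
        if tree is None:
            raise ValueError("provide a tree or a covariance matrix")
        C = vcv_matrix(tree)
    yv, Cv = _as_cov(C, y)
    n = len(yv)
    if n < 4:
        raise ValueError("Blomberg's K needs n >= 4 tips")
    one = np.ones(n)
    Ci_one = sla.solve(Cv, one, assume_a="pos")
    a = float(Ci_one @ yv / (Ci_one @ one))
    r = yv - a
    mse0 = float(r @ r)
    mse = float(r @ sla.solve(Cv, r, assume_a="pos"))
    if mse0 == 0.0 or mse == 0.0:
        raise ValueError("constant trait: K is undefined")
    observed = mse0 / mse
    expected = (np.trace(Cv) - n / float(Ci_one @ one)) / (n - 1)
    return SignalEstimate(
        statistic="K",
        estimate=observed / expected,
        observed_ratio=observed,
        expected_ratio=float(expected),
    )


def _lambda_loglik(lam: float, yv: np.ndarray, Cv: np.ndarray) -> float:
    """Profile log-likelihood of lambda (mean and sigma^2 profiled out)."""
    n = len(yv)
    V = lam * Cv + (1.0 - lam) * np.diag(np.diag(Cv))
    try:
        L = sla.cholesky(V, lower=True)
    except sla.LinAlgError:
        return -np.inf
    logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
    one = np.ones(n)
    Vi_one = sla.cho_solve((L, True), one)
    a = float(Vi_one @ yv / (Vi_one @ one))
    r = yv - a
    rss = float(r @ sla.cho_solve((L, True), r))
    if rss <= 0:
        return -np.inf
    sigma2 = rss / n
    return -0.5 * (n * np.log(2.0 * np.pi * sigma2) + logdet + n)


def pagel_lambda(
    y, tree: Phylogeny | None = None, C=None, *, tol: float = 1e-6
) -> SignalEstimate:
    """Maximum-likelihood Pagel's lambda on [0, 1].

    A 21-point grid seeds a bounded scalar optimization (Brent) in the best
    grid cell; the better of optimizer and grid argmax is reported, so the
    estimate can never fall below the grid. Endpoint log-likelihoods at 0
    and 1 are reported alongside.
    """
    if C is None:
        if tree is None:
            raise ValueError("provide a tree or a covariance matrix")
        C = vcv_matrix(tree)
    yv, Cv = _as_cov(C, y)
    if len(yv) < 4:
        raise ValueError("Pagel's lambda needs n >= 4 tips")
    if np.ptp(yv) == 0:
        raise ValueError("constant trait: lambda is undefined")

    grid = np.linspace(0.0, 1.0, 21)
    ll_grid = np.array([_lambda_loglik(g, yv, Cv) for g in grid])
    i = int(np.argmax(ll_grid))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    best_lam, best_ll = float(grid[i]), float(ll_grid[i])
    if hi > lo:
        res = minimize_scalar(
            lambda lam: -_lambda_loglik(lam, yv, Cv),
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": tol},
        )
        if res.success and -res.fun > best_ll:
            best_lam, best_ll = float(res.x), float(-res.fun)
    ll0 = _lambda_loglik(0.0, yv, Cv)
    ll1 = _lambda_loglik(1.0, yv, Cv)
    # endpoints participate on equal terms
    if ll1 >= best_ll:
        best_lam, best_ll = 1.0, ll1
    if ll0 >= best_ll:
        best_lam, best_ll = 0.0, ll0
    return SignalEstimate(
        statistic="lambda",
        estimate=best_lam,
        loglik=best_ll,
        loglik_zero=ll0,
        loglik_one=ll1,
        at_boundary=best_lam in (0.0, 1.0),
    )


def pgls_fit(
    y,
    X: pd.DataFrame,
    tree: Phylogeny | None = None,
    C=None,
) -> PglsFit:
    """(Phylogenetic) GLS regression of y on the named columns of X.

    With a tree (or explicit covariance C) the error covariance is
    proportional to the Brownian-motion VCV; with neither, the identity is
    used and the fit equals OLS. Rows are aligned to the covariance by label
    when pandas objects are supplied.
    """
    if not isinstance(X, pd.DataFrame):
        raise TypeError("X must be a DataFrame with named columns")
    if C is None and tree is not None:
        C = vcv_matrix(tree)
    correlation = "identity" if C is None else "brownian"
    if C is not None:
        if isinstance(C, pd.DataFrame):
            order = list(C.index)
            if isinstance(y, pd.Series):
                y = y.loc[order]
            if not X.index.equals(pd.Index(order)):
                X = X.loc[order]
        sigma = C.to_numpy() if isinstance(C, pd.DataFrame) else np.asarray(C, float)
    else:
        sigma = None
    yv = np.asarray(y, dtype=float)
    Xv = np.asarray(X, dtype=float)
    n, p = Xv.shape
    if n <= p:
        raise ValueError(f"need more observations ({n}) than predictors ({p})")
    if np.linalg.matrix_rank(Xv) < p:
        raise ValueError("design matrix is rank deficient")
    model = sm.GLS(yv, Xv, sigma=sigma)
    with np.errstate(divide="ignore"):  # llf is -inf for an exact fit
        fit = model.fit()
        llf = float(fit.llf)
    names = list(X.columns)
    return PglsFit(
        params=pd.Series(fit.params, index=names),
        bse=pd.Series(fit.bse, index=names),
        tvalues=pd.Series(fit.tvalues, index=names),
        pvalues=pd.Series(fit.pvalues, index=names),
        sigma2=float(fit.scale),
        df_resid=int(fit.df_resid),
        cov_params=pd.DataFrame(fit.cov_params(), index=names, columns=names),
        correlation=correlation,
        loglik=llf,
    )


def ols_r2(y, x) -> tuple[float, float, float]:
    """Simple linear regression of y on x: (slope, r^2, two-sided p)."""
    xv = np.asarray(x, float)
    yv = np.asarray(y, float)
    if len(xv) < 3:
        raise ValueError("need n >= 3")
    if np.ptp(xv) == 0:
        raise ValueError("x has zero variance")
    res = scipy.stats.linregress(xv, yv)
    return float(res.slope), float(res.rvalue**2), float(res.pvalue)


def pgls_scan(
    matrix: CountMatrix,
    domain_profile: pd.DataFrame,
    tree: Phylogeny,
    *,
    focal: str = "focal",
    covariates: pd.DataFrame | None = None,
    transform: str = "log1p",
    adjust: str = "global",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-orthogroup x per-domain PGLS scan under Brownian correlation.

    For each focal orthogroup g and each domain d, fits
    ``t(count_g) ~ intercept + domain_d [+ covariates]`` by PGLS and records
    the domain coefficient. *transform* is ``log1p`` (default, variance
    stabilization for Poisson-like counts) or ``none``. *adjust* controls
    the BH correction: ``global`` (jointly across the whole scan, default),
    ``per-domain``, or ``none``. An orthogroup counts as significant when
    any of its domain terms has q < alpha.
    """
    from .enrichment import bh_fdr  # local import to avoid a cycle

    if transform not in ("log1p", "none"):
        raise ValueError(f"unknown transform: {transform!r}")
    if adjust not in ("global", "per-domain", "none"):
        raise ValueError(f"unknown adjustment: {adjust!r}")
    order = tree.tip_labels
    C = vcv_matrix(tree, order)
    focal_ogs = sorted(matrix.tagged(focal))
    counts = matrix.data.loc[order, focal_ogs]
    domains = domain_profile.loc[order]
    rows = []
    for og in focal_ogs:
        y = counts[og].astype(float)
        if transform == "log1p":
            y = np.log1p(y)
        for dom in domains.columns:
            X = pd.DataFrame({"intercept": 1.0, dom: domains[dom].astype(float)},
                             index=order)
            if covariates is not None:
                for cname in covariates.columns:
                    X[cname] = covariates.loc[order, cname].astype(float)
            if np.ptp(X[dom].to_numpy()) == 0:
                rows.append((og, dom, np.nan, np.nan, np.nan, np.nan))
                continue
            fit = pgls_fit(y, X, C=C)
            rows.append(
                (og, dom, fit.params[dom], fit.bse[dom], fit.tvalues[dom],
                 fit.pvalues[dom])
            )
    out = pd.DataFrame(rows, columns=["orthogroup", "domain", "beta", "se", "t", "p"])
    out["transform"] = transform
    out["correlation"] = "brownian"
    if adjust == "none":
        out["q"] = out["p"]
    elif adjust == "per-domain":
        out["q"] = np.nan
        for dom in out["domain"].unique():
            mask = (out["domain"] == dom) & out["p"].notna()
            out.loc[mask, "q"] = bh_fdr(out.loc[mask, "p"].to_numpy())
    else:
        mask = out["p"].notna()
        out.loc[mask, "q"] = bh_fdr(out.loc[mask, "p"].to_numpy())
    out["significant"] = out["q"] < alpha
    return out
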
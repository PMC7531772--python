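"""Clade-wise enrichment/depletion of orthogroup copy number.

The paper-scale question: are gene families (orthogroups) systematically
depleted in one clade (Ecdysozoa) relative to another
(Lophotrochozoa + Deuterostomia)? Three pieces:

* a per-orthogroup two-sample Fisher-Pitman permutation test on per-taxon
  gene counts (statistic = difference of clade means; exact enumeration of
  all label assignments when feasible, otherwise seeded Monte Carlo);
* Benjamini-Hochberg FDR across orthogroups (default level 0.1);
* a clade depletion log-ratio d = ln((total_A + c)/(total_B + c)) per
  orthogroup, with a Wilcoxon rank-sum contrast of focal (apoptosis) vs
  background orthogroup d distributions.

Taxa are treated as exchangeable within clades; the permutation null is
over clade-label assignments of taxa.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .phylo import CladePartition
from .repertoire import CountMatrix

__all__ = [
    "EnrichmentResult",
    "DepletionResult",
    "fisher_pitman",
    "bh_fdr",
    "clade_enrichment_scan",
    "depletion_contrast",
    "EXACT_ENUMERATION_LIMIT",
]

#: Exact enumeration of label assignments is used when C(n, n_a) is at most this.
EXACT_ENUMERATION_LIMIT = 20_000

_ABS_TOL = 1e-12


@dataclass(frozen=True)
class EnrichmentResult:
    orthogroup: str
    mean_a: float
    mean_b: float
    statistic: float  # mean_a - mean_b
    p: float
    q: float
    direction: str  # "enriched_in_a" | "depleted_in_a" | "none"
    exact: bool
    all_zero: bool


@dataclass(frozen=True)
class DepletionResult:
    """Depletion log-ratios plus the focal-vs-background Wilcoxon contrast."""

    ratios: pd.DataFrame  # orthogroup, total_a, total_b, d, focal
    w_statistic: float  # rank-sum W of the focal group
    p: float
    n_focal: int
    n_background: int
    exact: bool


def _split_membership(n: int, n_a: int) -> np.ndarray:
    """All C(n, n_a) assignments of n items to group A, as a 0/1 matrix."""
    rows = np.zeros((comb(n, n_a), n), dtype=np.float64)
    for r, ix in enumerate(combinations(range(n), n_a)):
        rows[r, list(ix)] = 1.0
    return rows


def fisher_pitman(
    a: Sequence[float],
    b: Sequence[float],
    n_perm: int = 9_999,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Two-sample Fisher-Pitman permutation test (difference of means).

    Returns (mean(a) - mean(b), two-sided p). Exact when C(n, |a|) is within
    :data:`EXACT_ENUMERATION_LIMIT`; otherwise Monte Carlo over ``n_perm``
    label permutations with the add-one correction
    p = (#{|T*| >= |T|} + 1)/(B + 1).
    """
    av = np.asarray(a, float)
    bv = np.asarray(b, float)
    if len(av) < 2 or len(bv) < 2:
        raise ValueError("each group needs at least 2 observations")
    if n_perm < 99:
        raise ValueError("n_perm must be at least 99")
    pooled = np.concatenate([av, bv])
    n, n_a = len(pooled), len(av)
    obs = float(av.mean() - bv.mean())
    if comb(n, n_a) <= EXACT_ENUMERATION_LIMIT:
        M = _split_membership(n, n_a)
        stats = (M @ pooled) / n_a - ((1.0 - M) @ pooled) / (n - n_a)
        p = float(np.mean(np.abs(stats) >= abs(obs) - _ABS_TOL))
        return obs, p
    if rng is None:
        rng = np.random.default_rng(seed)
    perms = rng.permuted(np.tile(pooled, (n_perm, 1)), axis=1)
    stats = perms[:, :n_a].mean(axis=1) - perms[:, n_a:].mean(axis=1)
    hits = int(np.sum(np.abs(stats) >= abs(obs) - _ABS_TOL))
    return obs, (hits + 1) / (n_perm + 1)


def bh_fdr(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in input order, capped at 1."""
    pv = np.asarray(p, float)
    if pv.size and (np.min(pv) < 0 or np.max(pv) > 1):
        raise ValueError("p-values must lie in [0, 1]")
    if pv.size == 0:
        return pv.copy()
    return multipletests(pv, method="fdr_bh")[1]


def clade_enrichment_scan(
    matrix: CountMatrix,
    partition: CladePartition,
    clade_a: str | Sequence[str],
    clade_b: str | Sequence[str],
    n_perm: int = 9_999,
    seed: int | None = None,
    alpha: float = 0.1,
) -> list[EnrichmentResult]:
    """Fisher-Pitman test per orthogroup, BH-adjusted across orthogroups.

    ``clade_a`` / ``clade_b`` may be single clade names or lists whose tip
    sets are pooled (the paper's main contrast pools Lophotrochozoa and
    Deuterostomia against Ecdysozoa). Orthogroups with all-zero counts in
    both clades are reported with p = 1 and flagged. Tests are vectorized:
    the same set of label assignments (exact) or permutations (Monte Carlo,
    seeded) is applied to every orthogroup.
    """
    tips_a = sorted(partition.tips(clade_a))
    tips_b = sorted(partition.tips(clade_b))
    if set(tips_a) & set(tips_b):
        raise ValueError("clade A and clade B overlap")
    if len(tips_a) < 2 or len(tips_b) < 2:
        raise ValueError("each clade needs at least 2 taxa in the matrix")
    missing = (set(tips_a) | set(tips_b)) - set(matrix.taxa)
    if missing:
        raise ValueError(f"clade taxa missing from matrix: {sorted(missing)}")

    X = matrix.data.loc[tips_a + tips_b].to_numpy(dtype=float)
    n_a, n = len(tips_a), len(tips_a) + len(tips_b)
    n_b = n - n_a
    obs = X[:n_a].mean(axis=0) - X[n_a:].mean(axis=0)
    all_zero = X.sum(axis=0) == 0

    exact = comb(n, n_a) <= EXACT_ENUMERATION_LIMIT
    if exact:
        M = _split_membership(n, n_a)
        stats = (M @ X) / n_a - ((1.0 - M) @ X) / n_b  # splits x orthogroups
        pvals = np.mean(np.abs(stats) >= np.abs(obs)[None, :] - _ABS_TOL, axis=0)
    else:
        rng = np.random.default_rng(seed)
        order = np.argsort(rng.random((n_perm, n)), axis=1)
        M = np.zeros((n_perm, n))
        np.put_along_axis(M, order[:, :n_a], 1.0, axis=1)
        stats = (M @ X) / n_a - ((1.0 - M) @ X) / n_b
        hits = np.sum(np.abs(stats) >= np.abs(obs)[None, :] - _ABS_TOL, axis=0)
        pvals = (hits + 1) / (n_perm + 1)
    pvals = np.where(all_zero, 1.0, pvals)
    qvals = bh_fdr(pvals)

    results = []
    for j, og in enumerate(matrix.orthogroups):
        if qvals[j] < alpha and obs[j] > 0:
            direction = "enriched_in_a"
        elif qvals[j] < alpha and obs[j] < 0:
            direction = "depleted_in_a"
        else:
            direction = "none"
        results.append(
            EnrichmentResult(
                orthogroup=og,
                mean_a=float(X[:n_a, j].mean()),
                mean_b=float(X[n_a:, j].mean()),
                statistic=float(obs[j]),
                p=float(pvals[j]),
                q=float(qvals[j]),
                direction=direction,
                exact=exact,
                all_zero=bool(all_zero[j]),
            )
        )
    return results


def enrichment_table(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])


def depletion_contrast(
    matrix: CountMatrix,
    partition: CladePartition,
    clade_a: str | Sequence[str],
    clade_b: str | Sequence[str],
    focal: str = "focal",
    pseudocount: float = 1.0,
    drop_zeros: bool = False,
) -> DepletionResult:
    """Per-orthogroup depletion log-ratio and the focal/background contrast.

    d = ln((clade-A total + pseudocount) / (clade-B total + pseudocount));
    the pseudocount (default 1, added to both totals) keeps orthogroups
    entirely lost in one clade finite. With ``drop_zeros=True`` and
    pseudocount 0, orthogroups with a zero clade total are excluded instead.
    The focal-vs-background difference in d is tested with a two-sided
    Wilcoxon rank-sum test (exact when both groups are <= 12 and tie-free,
    otherwise normal approximation with tie correction); W is the rank-sum
    of the focal group.
    """
    if pseudocount <= 0 and not drop_zeros:
        raise ValueError("pseudocount must be > 0 (or set drop_zeros=True)")
    tips_a = sorted(partition.tips(clade_a))
    tips_b = sorted(partition.tips(clade_b))
    focal_ogs = matrix.tagged(focal)
    if not focal_ogs:
        raise ValueError("focal orthogroup set is empty")
    missing = (set(tips_a) | set(tips_b)) - set(matrix.taxa)
    if missing:
        raise ValueError(f"clade taxa missing from matrix: {sorted(missing)}")

    tot_a = matrix.data.loc[tips_a].sum(axis=0)
    tot_b = matrix.data.loc[tips_b].sum(axis=0)
    table = pd.DataFrame(
        {
            "orthogroup": matrix.orthogroups,
            "total_a": tot_a.to_numpy(),
            "total_b": tot_b.to_numpy(),
        }
    )
    if drop_zeros and pseudocount == 0:
        table = table[(table.total_a > 0) & (table.total_b > 0)].reset_index(drop=True)
    table["d"] = np.log(
        (table.total_a + pseudocount) / (table.total_b + pseudocount)
    )
    table["focal"] = table.orthogroup.isin(focal_ogs)

    d_focal = table.loc[table.focal, "d"].to_numpy()
    d_back = table.loc[~table.focal, "d"].to_numpy()
    if len(d_back) == 0:
        raise ValueError("no background orthogroups to contrast against")
    tie_free = len(np.unique(np.concatenate([d_focal, d_back]))) == len(d_focal) + len(d_back)
    exact = len(d_focal) <= 12 and len(d_back) <= 12 and tie_free
    method = "exact" if exact else "asymptotic"
    res = scipy.stats.mannwhitneyu(
        d_focal, d_back, alternative="two-sided", method=method
    )
    w = float(res.statistic + len(d_focal) * (len(d_focal) + 1) / 2)
    return DepletionResult(
        ratios=table,
        w_statistic=w,
        p=float(res.pvalue),
        n_focal=int(len(d_focal)),
        n_background=int(len(d_back)),
        exact=exact,
    )
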
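# Methods

This note documents the statistical models implemented in `repevo`, the
assumptions they carry, the defaults and why, what the synthetic-data
generator does and does not emulate, and the numerical choices made where
the design was genuinely open.

## Trees and phylogenetic covariance

Input trees are single rooted Newick strings; the outermost nesting is
interpreted as the root (a rooted polytomy and an "unrooted" basal
trichotomy are indistinguishable in Newick, so no rooting token is
required). Polytomies are allowed everywhere — Dollo reconstruction and the
covariance construction are well defined on them. Branch lengths must be
present and non-negative; `unit_branch_lengths=True` substitutes 1.0 for
missing lengths for topology-only work. Internal nodes without labels
receive deterministic post-order labels `N0, N1, ...` so event tables and
ancestral-state matrices key stably. A stem edge above the root is ignored
in depth calculations: it is not shared evolution among the tips (the same
convention as `ape::vcv`).

The Brownian-motion variance–covariance matrix C has `C[i,i]` = root-to-tip
distance and `C[i,j]` = depth of the MRCA of tips i and j. It is built by a
single post-order sweep writing each pair's entry exactly once, so symmetry
is structural rather than numerical. All matrix-producing operations carry
an explicit tip-label index (sorted labels by default) and reconcile by
label, never by position.

## Dollo parsimony

A binary character (domain presence, orthogroup presence) may originate
once and be lost arbitrarily often, never re-originate. On a rooted tree
the minimum-change reconstruction under this constraint is unique and
closed-form: the gain sits on the branch above the MRCA of the 1-tips, and
the losses are the branches subtending maximal all-0 subtrees inside the
gain clade. No tie-breaking is needed; the test suite verifies minimality
against exhaustive enumeration of all single-gain labelings on random trees
(all 2^n tip patterns, trees up to 8 tips). The state above the gain node
is 0, which keeps outgroup absence representable; characters absent from
every tip yield an empty reconstruction rather than an error, since clade
subsets produce them routinely. Orthogroup presence is binarized at count
≥ 1 (configurable threshold). Ancestral repertoires report the character
set implied at a node with an optional per-character weight (default 1);
weighted totals approximate ancestral gene counts as presence × a chosen
extant summary, since parsimony on presence cannot reconstruct copy
numbers.

Parsimony undercounts true losses when losses nest (a loss below another
loss is unobservable), so simulation comparisons treat the reconstruction
as a lower bound that approaches the truth on bushy trees with ≲1 expected
loss per character.

## Phylogenetic signal

**Blomberg's K** is the ratio of the observed MSE₀/MSE (deviations from the
GLS ancestral mean, unweighted vs C⁻¹-weighted) to its Brownian
expectation `(tr C − n/(1'C⁻¹1))/(n − 1)`. K = 1 exactly on a star tree
and in expectation under Brownian motion; the estimator is exactly
invariant to affine transforms of the trait. A constant trait is an error
(the ratio is undefined). The optional randomization significance test
(999 tip shuffles) is off by default; the analyses this package supports
report point estimates.

**Pagel's λ** multiplies the off-diagonal of C; the profile log-likelihood
(ancestral mean and σ² profiled out analytically, σ̂² = RSS/n) is maximized
over [0, 1]. A 21-point grid seeds bounded Brent optimization in the best
grid cell (tolerance 1e-6), and both endpoints compete on equal terms, so
the reported optimum can never fall below the grid and always dominates
λ = 0 and λ = 1. The search is restricted to [0, 1] rather than the wider
PD-feasible interval: that is the standard interpretation, and reported
estimates in this literature live there. Estimates agree with
`phytools::phylosig` to ~1e-6 on a fixed fixture (frozen in the tests).

## PGLS and the domain scan

`pgls_fit` is generalized least squares with error covariance σ²C
(statsmodels `GLS` does the fitting); with no tree it reduces to OLS
exactly. The Brownian correlation is held fixed rather than jointly
re-estimating λ inside the regression — the analyses this package mirrors
specify a Brownian correlation structure; λ-estimation remains available
separately via `pagel_lambda`.

The scan regresses each focal orthogroup's count on each domain count plus
covariates (genome size). Counts are transformed `log(count + 1)` by
default — variance stabilization for Poisson-like copy numbers — with
`transform="none"` to fit raw counts. The scan's p-values are BH-adjusted
jointly across all orthogroup × domain pairs by default (`global`); the
alternatives `per-domain` and `none` are exposed because the choice is a
genuine degree of freedom in this kind of analysis. An orthogroup counts as
"predicted by domain structure" when any of its domain terms passes
q < 0.05. A domain with zero variance across taxa yields NaN rows rather
than a degenerate fit.

## Enrichment and depletion

Per-orthogroup tests treat taxa as exchangeable within clades — a known
limitation (closely related taxa are not independent), inherited from the
test family itself and documented rather than "fixed". The Fisher–Pitman
statistic is the difference of clade means of per-taxon counts. Exact
enumeration of all `C(n, n_A)` label assignments is used when that count is
≤ 20 000; otherwise 9 999 seeded Monte Carlo permutations with the add-one
correction `p = (hits + 1)/(B + 1)`. Comparisons of permuted to observed
statistics use an absolute tolerance of 1e-12 so ties count as hits.
Orthogroups with all-zero counts in both clades are reported with p = 1 and
flagged. The scan is vectorized: one membership matrix drives every
orthogroup, which also makes exact-mode results independent of orthogroup
order.

The depletion statistic is `d = ln((N_A + c)/(N_B + c))` on clade total
counts with pseudocount c = 1 added to both totals — keeping orthogroups
entirely lost in one clade (the phenomenon of interest) finite —
with `drop_zeros` as the alternative. The focal-vs-background contrast is a
two-sided Wilcoxon rank-sum test: exact when both groups have ≤ 12
observations and no ties, otherwise the normal approximation with tie
correction (scipy's Mann–Whitney implementation); W is reported in the
rank-sum convention, `U + n₁(n₁+1)/2`, for the focal group.

BH FDR uses the step-up formula (via statsmodels), default level 0.1 for
the enrichment scan.

## CCA

Canonical correspondence analysis follows the classical algorithm: the
chi-square standardized matrix `Q̄ = D_r^{-1/2}(P − rc')D_c^{-1/2}` is
projected onto the row-weighted constraint space (orthonormal basis of
`D_r^{1/2}[1, X]` via SVD with rank truncation at `s > s₁·1e-12`), and the
SVD of the fitted matrix gives the constrained eigenvalues. Total inertia
equals the Pearson chi-square of Y divided by its grand total; constrained
plus residual inertia equals total to 1e-9 by construction. Y enters as raw
counts (the chi-square metric is the transform); results are invariant to
positive scaling of Y and affine rescaling of X columns. The global test is
the permutation pseudo-F with unrestricted joint row permutations of X
(999 by default, seeded); degrees of freedom are reported as
(q, n − q − 1). A constant constraint column contributes nothing (zero
constrained inertia) rather than erroring; columns that are linear
combinations of earlier ones are dropped with a warning. Eigenvalues,
inertias and F agree with `vegan::cca` and scikit-bio's CCA on fixed
fixtures to 1e-8.

## Synthetic data

The generator emulates the structure of a ~29-genome comparative study
without reproducing any real dataset:

- **Tree**: ultrametric, height 1, with four named monophyletic groups
  grafted at fixed depths onto the bilaterian backbone
  `(outgroups, (Deuterostomia, (Lophotrochozoa, Ecdysozoa)))`; each crown
  group is an independently simulated Yule subtree rescaled to its crown
  height. Ecdysozoa (9 taxa by default) is the designated loss clade.
  A generic Yule simulator (`simulate_yule_tree`) is also exposed for
  calibration experiments.
- **Counts**: `N_gt ~ Poisson(μ_g · exp(β z_t) · m_gt)` with per-orthogroup
  baselines `μ_g ~ Gamma(2, baseline_mean/2)`, optional log-linear linkage
  β to standardized domain richness z_t (default 0), and `m_gt = δ`
  (default 0.2) for *depleted* focal orthogroups in loss-clade taxa. By
  default half the focal set is depleted (`depleted_fraction = 0.5`):
  depleting every focal orthogroup by the same factor would leave the focal
  table's compositional profiles unchanged and make the CCA association
  undetectable by construction, whereas heterogeneous depletion is what
  such studies actually observe. Setting the fraction to 1 restores uniform
  focal depletion. The truth table records which orthogroups are depleted.
- **Domains**: the DNA-binding domain (p53) is universal; TAD, TET and SAM
  gain at the root and are lost per-branch with probability 0.7 inside the
  loss clade and 0.02 elsewhere; present domains carry 1 + Poisson(0.7)
  occurrences. Locus-level records are emitted greedily (each locus carries
  one copy of every remaining domain) so that tabulating them reproduces
  the profile exactly.
- **Genome size**: log genome size is Brownian motion (σ² = 0.25) plus a
  −0.5 shift in the loss clade, emulating genome reduction co-occurring
  with gene loss.
- **Gene set**: 137 curated genes of which 56 are unmapped and 22 share an
  orthogroup with another gene, mapping onto the 59 focal orthogroups — the
  bookkeeping is structural, so the mapping summary is a fixed property of
  the default profile.

All generators draw from named substreams of one root `SeedSequence`
(append-only registry), so adding a generator never perturbs existing
outputs, and identical (seed, config) pairs serialize byte-identically.

What the generator does **not** emulate: real orthology inference noise
(Orthofinder's graph clustering artifacts), ascertainment bias of
BLAST-based orthogroup assignment toward the reference lineage, correlated
copy-number evolution among functionally linked families beyond the shared
clade effect, domain-call errors from HMM scanning, and non-ultrametric
rate variation. Passing tests therefore demonstrate the statistical
machinery is correct and calibrated under its stated model, not that the
model captures every property of real genomic data.

## Pipeline, determinism and problem sizes

The pipeline derives stage seeds from the root seed by fixed offsets, and
the JSON report contains no timestamp, so a rerun with the same config is
byte-identical. Reported simulation sizes used in tests — a 64-tip Yule
tree with 200–500 replicates for the signal and regression calibrations,
200 matrices/datasets for the error-control checks, 50 seeds for the
full-null pipeline — were chosen so Monte Carlo standard errors are small
relative to the asserted bands (e.g. the PGLS recovery uses error variance
σ² = 0.1 so that three standard errors of the 200-replicate mean intercept
stay inside the ±0.05 band; larger error variance makes the band a
coin-flip regardless of estimator correctness).

## Known limitations

- The enrichment permutation null ignores phylogenetic dependence within
  clades; a phylogenetically corrected count test is out of scope.
- Dollo parsimony is a lower bound on loss counts (nested losses are
  invisible) and assumes no re-origination, appropriate for gene/domain
  presence but not convergent morphology.
- PGLS supports Brownian correlation only (no Ornstein–Uhlenbeck or
  multi-rate structures, no measurement-error model).
- CCA is the global association test only: no partial CCA, no
  axis-specific permutation tests.
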
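# repevo

Phylogenetic comparative analysis of gene-repertoire evolution.

`repevo` asks a question that recurs across comparative genomics: when a
clade of species has lost copies of a functionally related gene set (for
example, the widespread reduction of apoptosis-pathway gene families in
ecdysozoan genomes, contrasted with their retention in lophotrochozoans such
as bivalves and in deuterostomes), is that loss clade-specific and
statistically credible, is it explained by overall genome reduction, and
does it track the domain architecture of a master regulator (p53-family
TAD / p53 / TET / SAM domains)? The package implements the full analysis
chain on a species tree, an orthogroup copy-number matrix, a locus-level
domain-architecture table and a curated gene-set map:

- **Dollo parsimony** histories of binary characters (domain or orthogroup
  presence): a character originates once, on the branch above the MRCA of
  the tips carrying it, and is lost on the branches subtending the maximal
  all-absent subtrees. The reconstruction is closed-form, provably minimal,
  and yields per-branch gain/loss event tables and ancestral repertoires.
- **Clade enrichment/depletion**: per-orthogroup two-sample Fisher–Pitman
  permutation tests on per-taxon counts (statistic `mean_A − mean_B`, exact
  enumeration when `C(n, n_A) ≤ 20 000`), Benjamini–Hochberg FDR across
  orthogroups, and a depletion log-ratio
  `d = ln((N_A + c)/(N_B + c))` per orthogroup with a Wilcoxon rank-sum
  contrast of focal vs background `d` distributions.
- **Phylogenetic signal**: Blomberg's *K* (ratio of observed to
  Brownian-expected MSE ratios; *K* = 1 under Brownian motion) and Pagel's
  λ (profile-ML multiplier on the off-diagonal of the phylogenetic
  covariance matrix C, λ ∈ [0, 1]).
- **PGLS**: generalized least squares with error covariance ∝ C (Brownian
  motion), used both for the genome-size control and for the per-orthogroup
  × per-domain scan `log1p(count_g) ~ domain_d + genome size`.
- **CCA**: canonical correspondence analysis of the orthogroup table
  constrained by the four domain counts, with the permutation pseudo-F test
  `F = (constrained/q)/(residual/(n − q − 1))`.
- **Synthetic data**: a seeded generator producing ultrametric study trees
  with a designated loss clade, clade-depleted count matrices with known
  truth tables, correlated domain-loss profiles, Brownian covariates and
  the curated-gene-set bookkeeping — so every stage is testable end to end
  without any downloads.

## Worked example

Run the whole analysis on the default simulated study (29 taxa, a 9-taxon
loss clade, 59 focal + 500 background orthogroups):

```sh
repevo run --config config.yaml --out results/
```

with `config.yaml` containing:

```yaml
seed: 1
simulate: {}
```

which prints:

```
# Gene-repertoire evolution report

- Gene set: 137 curated genes, 56 unmapped, 81 mapped into 59 distinct orthogroups (22 sharing an orthogroup).
- Enrichment: 25 of 59 focal orthogroups enriched and 1 depleted in clade A at FDR 0.1.
- Depletion contrast: Wilcoxon rank-sum W = 23859, P = 3.985e-10 (focal n=59 vs background n=500).
- Phylogenetic signal of repertoire size: Blomberg's K = 1.03; Pagel's lambda = 0.92.
- Phylogenetic signal of genome size: K = 0.88; lambda = 0.98.
- Genome-size control: repertoire size vs log genome size r^2 = 0.44 (P = 9.66e-05).
- Dollo parsimony: 278 orthogroup losses (124 on loss-clade branches); 4 domain losses.
- CCA: pseudo-F(4,24) = 1.72, P = 0.004.
- PGLS scan: 7 of 59 focal orthogroups predicted by at least one domain (q < 0.05, global adjustment).

Provenance: seed 1, config b03f39a84d0b0913, version 0.1.0, 29 taxa.
```

Reading the numbers: 25 of the 59 focal orthogroups carry significantly
more gene copies outside the loss clade (clade A pools the two non-loss
clades) at FDR < 0.1, while the focal set as a whole is more depleted than
the 500 background orthogroups (Wilcoxon P ≈ 4e-10) — so focal loss is not
explained by the overall gene-loss trend, which the r² = 0.44 genome-size
regression quantifies. Repertoire size carries Brownian-like phylogenetic
signal (K ≈ 1), and the CCA permutation test finds a significant global
association between the domain profile and the orthogroup table
(P = 0.004). Per-stage tables (`enrichment.tsv`, `pgls_scan.tsv`,
`dollo_orthogroups.tsv`, CCA scores, `report.json`) are written to
`results/`.

The same stages are available individually (`repevo simulate | dollo |
signal | enrich | deplete | cca | pgls | report`) and as library functions
(`repevo.dollo_reconstruct`, `repevo.blomberg_k`, `repevo.pgls_fit`,
`repevo.clade_enrichment_scan`, `repevo.cca_permutation_test`, ...).

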
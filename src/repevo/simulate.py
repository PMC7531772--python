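"""Synthetic data with the statistical structure the pipeline assumes.

The generators emulate a 29-genome comparative study: an ultrametric
species tree containing a designated "loss clade" (the ecdysozoan role),
orthogroup count matrices with clade-biased depletion of a labeled focal
(apoptosis-like) gene set, p53-style domain profiles whose loss is
concentrated on the loss clade, Brownian-motion continuous covariates
(log genome size) with an optional clade shift, and the curated-gene-set
bookkeeping (137 genes -> 56 unmapped -> 59 distinct orthogroups).

Every generator is deterministic given a seed. A run derives independent
substreams per generator from a single root :class:`numpy.random.SeedSequence`,
so adding a generator does not perturb the outputs of existing ones.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .phylo import CladePartition, Phylogeny, lambda_transform, parse_newick, vcv_matrix
from .repertoire import (
    DEFAULT_DOMAIN_VOCABULARY,
    CountMatrix,
    DomainArchitectureRecord,
    GeneSetMap,
    UNMAPPED,
)

__all__ = [
    "SimulationConfig",
    "SyntheticDataset",
    "simulate_yule_tree",
    "simulate_bm",
    "simulate_dollo_characters",
    "simulate_count_matrix",
    "simulate_study_tree",
    "simulate_dataset",
]

# substream indices off the root SeedSequence; append-only so that adding a
# generator never changes existing outputs
_STREAMS = {
    "tree": 0,
    "domains": 1,
    "counts": 2,
    "genome_size": 3,
    "bm": 4,
    "dollo": 5,
}


def _rng_for(seed: int, stream: str) -> np.random.Generator:
    ss = np.random.SeedSequence(seed, spawn_key=(_STREAMS[stream],))
    return np.random.default_rng(ss)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the default synthetic dataset.

    The defaults mirror the scale of the motivating study: 29 taxa with a
    9-taxon loss clade, 59 focal plus 500 background orthogroups, and the
    curated gene set mapping 137 genes -> 81 mapped -> 59 distinct focal
    orthogroups (56 unmapped, 22 sharing an orthogroup).
    """

    seed: int
    n_taxa: int = 29
    n_outgroup: int = 2
    loss_clade_size: int = 9
    birth_rate: float = 1.0
    n_focal: int = 59
    n_background: int = 500
    baseline_mean: float = 3.0  # per-orthogroup Poisson mean scale
    depletion: float = 0.2  # delta: loss-clade count multiplier on depleted OGs
    depleted_fraction: float = 0.5  # fraction of focal orthogroups depleted
    domain_loss_prob: float = 0.7  # per loss-clade branch, per accessory domain
    background_domain_loss_prob: float = 0.02
    domain_extra_mean: float = 0.7  # Poisson mean of extra copies per present domain
    domain_linkage: float = 0.0  # beta: log-mean count per sd of domain richness
    bm_sigma2: float = 0.25  # variance rate of log genome size
    bm_lambda: float = 1.0
    genome_size_clade_effect: float = -0.5  # log-scale shift in the loss clade
    log_genome_size_mean: float = 7.0  # ~ 1.1 Gb in ln-Mb units
    n_geneset_unmapped: int = 56
    n_geneset_shared: int = 22

    def __post_init__(self):
        if not 0.0 <= self.depletion <= 1.0:
            raise ValueError("depletion multiplier delta must lie in [0, 1]")
        if not 0.0 <= self.depleted_fraction <= 1.0:
            raise ValueError("depleted_fraction must lie in [0, 1]")
        for name in ("domain_loss_prob", "background_domain_loss_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.bm_sigma2 <= 0:
            raise ValueError("bm_sigma2 must be positive")
        if not 0.0 <= self.bm_lambda <= 1.0:
            raise ValueError("bm_lambda must lie in [0, 1]")
        if self.loss_clade_size + self.n_outgroup + 4 > self.n_taxa:
            raise ValueError("n_taxa too small for the requested clade structure")


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------


def _yule_newick(n_taxa: int, birth_rate: float, rng: np.random.Generator,
                 prefix: str = "t") -> str:
    """Simulate a pure-birth tree; all tips extant (ultrametric)."""
    if n_taxa < 2:
        raise ValueError("need at least 2 tips")
    if birth_rate <= 0:
        raise ValueError("birth rate must be positive")
    parent: dict[int, int] = {}
    children: dict[int, list[int]] = {}
    born: dict[int, float] = {0: 0.0}
    split: dict[int, float] = {}
    active = [0]
    next_id = 1
    t = 0.0
    while len(active) < n_taxa:
        t += rng.exponential(1.0 / (birth_rate * len(active)))
        i = int(rng.integers(len(active)))
        node = active[i]
        split[node] = t
        kids = [next_id, next_id + 1]
        next_id += 2
        for k in kids:
            parent[k] = node
            born[k] = t
        children[node] = kids
        active[i] = kids[0]
        active.append(kids[1])
    t_end = t + rng.exponential(1.0 / (birth_rate * n_taxa))
    width = len(str(n_taxa))
    labels = {node: f"{prefix}{j + 1:0{width}d}" for j, node in enumerate(sorted(active))}

    def render(node: int) -> str:
        end = split.get(node, t_end)
        length = end - born[node]
        if node in children:
            inner = ",".join(render(k) for k in children[node])
            return f"({inner}):{length:.12g}"
        return f"{labels[node]}:{length:.12g}"

    inner = ",".join(render(k) for k in children[0])
    return f"({inner});"


def simulate_yule_tree(
    n_taxa: int,
    birth_rate: float = 1.0,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> Phylogeny:
    """Ultrametric pure-birth (Yule) tree with ``n_taxa`` extant tips."""
    if rng is None:
        rng = np.random.default_rng(seed)
    return parse_newick(_yule_newick(n_taxa, birth_rate, rng))


def _rescaled_subtree(n: int, birth_rate: float, rng, prefix: str,
                      crown_height: float) -> str:
    """Yule subtree rescaled to a fixed crown height, as a Newick fragment.

    The fragment is the parenthesized crown group without a stem length
    (``(a:...,b:...)``), ready for a ``:stem`` suffix when grafted."""
    import dendropy

    nwk = _yule_newick(n, birth_rate, rng, prefix=prefix)
    tree = dendropy.Tree.get(data=nwk, schema="newick",
                             suppress_internal_node_taxa=True,
                             preserve_underscores=True)
    factor = crown_height / tree.max_distance_from_root()
    for edge in tree.preorder_edge_iter():
        if edge.length:
            edge.length *= factor
    frag = tree.as_string(
        schema="newick", suppress_rooting=True, unquoted_underscores=True,
        real_value_format_specifier=".12g",
    ).strip().rstrip(";")
    return frag


def simulate_study_tree(config: SimulationConfig) -> tuple[Phylogeny, CladePartition]:
    """Species tree with named monophyletic clades and a designated loss clade.

    Topology mirrors the bilaterian backbone:
    ``(outgroups, (Deuterostomia, (Lophotrochozoa, Ecdysozoa)))`` with
    Ecdysozoa as the loss clade. Total height 1.0; clade crowns start at
    fixed depths so the tree is ultrametric by construction.
    """
    if config.n_outgroup < 2 or config.loss_clade_size < 2:
        raise ValueError("outgroup and loss clade each need at least 2 taxa")
    rng = _rng_for(config.seed, "tree")
    n_in = config.n_taxa - config.n_outgroup - config.loss_clade_size
    if n_in < 4:
        raise ValueError("need at least 4 taxa outside the outgroup and loss clade")
    n_deut = n_in // 2
    n_loph = n_in - n_deut
    # crown heights chosen so every tip sits at depth 1.0
    ecd = _rescaled_subtree(config.loss_clade_size, config.birth_rate, rng, "ecd", 0.45)
    lop = _rescaled_subtree(n_loph, config.birth_rate, rng, "lop", 0.45)
    deu = _rescaled_subtree(n_deut, config.birth_rate, rng, "deu", 0.6)
    out = _rescaled_subtree(config.n_outgroup, config.birth_rate, rng, "out", 0.7)
    newick = (
        f"({out}:0.3,"
        f"({deu}:0.2,"
        f"({lop}:0.15,{ecd}:0.15):0.2):0.2);"
    )
    tree = parse_newick(newick)
    partition = CladePartition(
        {
            "Ecdysozoa": frozenset(t for t in tree.tip_labels if t.startswith("ecd")),
            "Lophotrochozoa": frozenset(t for t in tree.tip_labels if t.startswith("lop")),
            "Deuterostomia": frozenset(t for t in tree.tip_labels if t.startswith("deu")),
            "Outgroup": frozenset(t for t in tree.tip_labels if t.startswith("out")),
        }
    )
    partition.validate_against(tree)
    return tree, partition


# ---------------------------------------------------------------------------
# traits and characters
# ---------------------------------------------------------------------------


def simulate_bm(
    tree: Phylogeny,
    sigma2: float = 1.0,
    lam: float = 1.0,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    n_reps: int = 1,
) -> pd.Series | pd.DataFrame:
    """Draw traits from Normal(0, sigma2 * lambda-transform(C)) at the tips.

    ``lam=1`` is pure Brownian motion on the tree; ``lam=0`` yields
    independent tips. Returns a Series (or a tips x n_reps DataFrame)."""
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    if rng is None:
        rng = np.random.default_rng(seed)
    C = vcv_matrix(tree)
    V = sigma2 * lambda_transform(C.to_numpy(), lam)
    # tips at depth ~0 give a singular V; jitter-free Cholesky via eigh
    w, Q = np.linalg.eigh(V)
    w = np.clip(w, 0.0, None)
    L = Q * np.sqrt(w)[None, :]
    Z = rng.standard_normal((len(C), n_reps))
    Y = L @ Z
    if n_reps == 1:
        return pd.Series(Y[:, 0], index=C.index)
    return pd.DataFrame(Y, index=C.index)


def simulate_dollo_characters(
    tree: Phylogeny,
    n_chars: int,
    loss_rate: float,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    gain_at_root: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Single-gain characters with exponential per-branch loss.

    Each character gains at the root (or at an internal node sampled
    uniformly when ``gain_at_root=False``) and is lost on each branch below
    a presence with probability ``1 - exp(-loss_rate * branch_length)``;
    descendants of a loss stay absent. Returns the tip matrix and a truth
    table (gain node label, true loss count per character).
    """
    if loss_rate < 0:
        raise ValueError("loss_rate must be >= 0")
    if rng is None:
        rng = np.random.default_rng(seed)
    internal = [nd for nd in tree.tree.preorder_internal_node_iter()]
    tips = tree.tip_labels
    states = np.zeros((len(tips), n_chars), dtype=np.int64)
    tip_index = {lb: i for i, lb in enumerate(tips)}
    truth_rows = []
    for c in range(n_chars):
        gain = tree.root if gain_at_root else internal[int(rng.integers(len(internal)))]
        losses = 0
        stack = [(gain, True)]
        while stack:
            node, present = stack.pop()
            if node.is_leaf():
                states[tip_index[node.taxon.label], c] = int(present)
                continue
            for ch in node.child_nodes():
                child_present = present
                if present:
                    p_loss = 1.0 - np.exp(-loss_rate * (ch.edge.length or 0.0))
                    if rng.random() < p_loss:
                        child_present = False
                        losses += 1
                else:
                    # keep the stream advancing identically below losses
                    pass
                stack.append((ch, child_present))
        truth_rows.append((f"char{c + 1:04d}", tree.node_label(gain), losses))
    chars = pd.DataFrame(states, index=tips,
                         columns=[f"char{c + 1:04d}" for c in range(n_chars)])
    truth = pd.DataFrame(truth_rows, columns=["character", "gain", "true_losses"])
    return chars, truth


def _simulate_domain_profile(
    tree: Phylogeny, partition: CladePartition, config: SimulationConfig
) -> pd.DataFrame:
    """Domain-occurrence profile with loss concentrated on the loss clade.

    The DNA-binding domain (p53) is universal; the accessory domains (TAD,
    TET, SAM) are gained at the root and lost per-branch with probability
    ``domain_loss_prob`` inside the loss clade and
    ``background_domain_loss_prob`` elsewhere. Present domains carry
    1 + Poisson(domain_extra_mean) occurrences.
    """
    rng = _rng_for(config.seed, "domains")
    tips = tree.tip_labels
    loss_tips = partition["Ecdysozoa"]
    profile = pd.DataFrame(0, index=tips, columns=list(DEFAULT_DOMAIN_VOCABULARY),
                           dtype=np.int64)
    loss_root = tree.mrca(loss_tips) if len(loss_tips) > 1 else tree.leaf(next(iter(loss_tips)))
    in_loss_clade = {nd for nd in loss_root.preorder_iter()}
    for dom in DEFAULT_DOMAIN_VOCABULARY:
        if dom == "p53":
            present = {t: True for t in tips}
        else:
            present = {}
            stack = [(tree.root, True)]
            while stack:
                node, here = stack.pop()
                if node.is_leaf():
                    present[node.taxon.label] = here
                    continue
                for ch in node.child_nodes():
                    child_here = here
                    if here:
                        p = (config.domain_loss_prob if ch in in_loss_clade
                             else config.background_domain_loss_prob)
                        if rng.random() < p:
                            child_here = False
                    stack.append((ch, child_here))
        for t in tips:
            if present[t]:
                profile.loc[t, dom] = 1 + rng.poisson(config.domain_extra_mean)
    return profile


def simulate_count_matrix(
    tree: Phylogeny,
    config: SimulationConfig,
    partition: CladePartition | None = None,
    domain_profile: pd.DataFrame | None = None,
) -> tuple[CountMatrix, pd.DataFrame]:
    """Orthogroup count matrix with clade-biased depletion of the focal set.

    ``N_gt ~ Poisson(mu_g * exp(beta * z_t) * m_gt)`` where z_t is the
    standardized domain richness of taxon t (zero when no profile is
    supplied or beta = 0) and ``m_gt = delta`` for *depleted* focal
    orthogroups in loss-clade taxa, 1 otherwise. The depleted subset is a
    random ``depleted_fraction`` of the focal set (default half, reflecting
    that clade-biased loss hits some gene families and spares others; set
    the fraction to 1 for uniform focal depletion). Returns the tagged
    matrix (tag "focal") and the truth table of generating parameters.
    """
    rng = _rng_for(config.seed, "counts")
    tips = tree.tip_labels
    n_og = config.n_focal + config.n_background
    og_ids = [f"OG{j + 1:04d}" for j in range(n_og)]
    focal_ids = og_ids[: config.n_focal]
    mu = rng.gamma(shape=2.0, scale=config.baseline_mean / 2.0, size=n_og)
    n_depleted = int(round(config.depleted_fraction * config.n_focal))
    depleted_idx = np.sort(
        rng.choice(config.n_focal, size=n_depleted, replace=False)
    )
    is_depleted = np.zeros(n_og, dtype=bool)
    is_depleted[depleted_idx] = config.depletion < 1.0

    if domain_profile is not None and config.domain_linkage != 0.0:
        richness = domain_profile.loc[tips].sum(axis=1).to_numpy(dtype=float)
        z = (richness - richness.mean()) / (richness.std() or 1.0)
    else:
        z = np.zeros(len(tips))
    loss_tips = partition["Ecdysozoa"] if partition is not None else frozenset()
    in_loss = np.array([t in loss_tips for t in tips])

    M = np.ones((len(tips), n_og))
    M[np.ix_(in_loss, np.flatnonzero(is_depleted))] = config.depletion
    lam = mu[None, :] * np.exp(config.domain_linkage * z)[:, None] * M
    counts = rng.poisson(lam)
    matrix = CountMatrix(
        pd.DataFrame(counts, index=tips, columns=og_ids),
        tags={"focal": focal_ids},
    )
    truth = pd.DataFrame(
        {
            "orthogroup": og_ids,
            "focal": [og in set(focal_ids) for og in og_ids],
            "depleted": is_depleted,
            "mu": mu,
            "depletion": np.where(is_depleted, config.depletion, 1.0),
        }
    )
    return matrix, truth


def _simulate_gene_set(config: SimulationConfig, focal_ids: list[str]) -> GeneSetMap:
    """Curated gene set reproducing the mapping bookkeeping structurally."""
    entries = []
    g = 0
    for og in focal_ids:
        g += 1
        entries.append((f"gene{g:03d}", og))
    for j in range(config.n_geneset_shared):
        g += 1
        entries.append((f"gene{g:03d}", focal_ids[j % len(focal_ids)]))
    for _ in range(config.n_geneset_unmapped):
        g += 1
        entries.append((f"gene{g:03d}", UNMAPPED))
    return GeneSetMap(tuple(entries))


def _simulate_genome_size(
    tree: Phylogeny, partition: CladePartition, config: SimulationConfig
) -> pd.Series:
    """Log genome size: BM on the tree plus a loss-clade shift."""
    rng = _rng_for(config.seed, "genome_size")
    bm = simulate_bm(tree, config.bm_sigma2, config.bm_lambda, rng=rng)
    log_gs = config.log_genome_size_mean + bm
    loss_tips = partition["Ecdysozoa"]
    log_gs[log_gs.index.isin(loss_tips)] += config.genome_size_clade_effect
    return log_gs.rename("log_genome_size")


def _domain_records(profile: pd.DataFrame) -> list[DomainArchitectureRecord]:
    """Locus-level records whose tabulation reproduces the profile exactly.

    Loci are emitted greedily: each locus carries one occurrence of every
    domain the taxon still has left, so the first locus of a domain-rich
    taxon looks like a full-complement p53 (TAD;p53;TET;SAM)."""
    records = []
    order = list(profile.columns)
    for taxon, row in profile.iterrows():
        remaining = row.to_dict()
        k = 0
        while any(v > 0 for v in remaining.values()):
            k += 1
            doms = tuple(d for d in order if remaining[d] > 0)
            for d in doms:
                remaining[d] -= 1
            records.append(
                DomainArchitectureRecord(taxon=taxon, locus=f"{taxon}_p53L{k}",
                                         domains=doms)
            )
    return records


@dataclass
class SyntheticDataset:
    """A complete simulated study, ready to feed every pipeline stage."""

    config: SimulationConfig
    tree: Phylogeny
    partition: CladePartition
    counts: CountMatrix  # tagged with "focal"
    domain_profile: pd.DataFrame
    domain_records: list[DomainArchitectureRecord]
    gene_set: GeneSetMap
    log_genome_size: pd.Series
    truth: pd.DataFrame

    def write(self, outdir) -> dict[str, Path]:
        """Write the exact file formats the pipeline reads; returns paths."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "tree": outdir / "tree.nwk",
            "counts": outdir / "counts.tsv",
            "domains": outdir / "domains.tsv",
            "clades": outdir / "clades.tsv",
            "geneset": outdir / "geneset.tsv",
            "genome_size": outdir / "genome_size.tsv",
            "truth": outdir / "truth.tsv",
        }
        self.tree.write_newick(paths["tree"])
        self.counts.write_tsv(paths["counts"])
        with open(paths["domains"], "w") as fh:
            for rec in self.domain_records:
                fh.write(f"{rec.taxon}\t{rec.locus}\t{';'.join(rec.domains)}\n")
        with open(paths["clades"], "w") as fh:
            for clade in sorted(self.partition.names()):
                for tip in sorted(self.partition[clade]):
                    fh.write(f"{tip}\t{clade}\n")
        with open(paths["geneset"], "w") as fh:
            for gene, og in self.gene_set.entries:
                fh.write(f"{gene}\t{og}\n")
        self.log_genome_size.sort_index().to_frame().to_csv(
            paths["genome_size"], sep="\t", index_label="taxon"
        )
        self.truth.to_csv(paths["truth"], sep="\t", index=False)
        return paths


def simulate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Generate the full synthetic study under one root seed."""
    tree, partition = simulate_study_tree(config)
    profile = _simulate_domain_profile(tree, partition, config)
    counts, truth = simulate_count_matrix(tree, config, partition, profile)
    gene_set = _simulate_gene_set(config, sorted(counts.tagged("focal")))
    log_gs = _simulate_genome_size(tree, partition, config)
    records = _domain_records(profile)
    return SyntheticDataset(
        config=config,
        tree=tree,
        partition=partition,
        counts=counts,
        domain_profile=profile,
        domain_records=records,
        gene_set=gene_set,
        log_genome_size=log_gs,
        truth=truth,
    )
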
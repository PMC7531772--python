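"""Rooted phylogenies, Newick I/O, clade bookkeeping and phylogenetic covariance.

The tree is the backbone of every downstream analysis: Dollo parsimony walks
it, Blomberg's K / Pagel's lambda and PGLS consume the variance-covariance
matrix it induces, and the clade contrasts (e.g. Ecdysozoa vs
Lophotrochozoa+Deuterostomia) are defined as sets of its tips.

Newick parsing and serialization are delegated to :mod:`dendropy`;
:class:`Phylogeny` is a validated wrapper that fixes the conventions the rest
of the package relies on (rooted interpretation, unique tip labels,
deterministic internal-node labels, sorted tip order for matrices).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "Phylogeny",
    "CladePartition",
    "read_newick",
    "parse_newick",
    "read_clade_partition",
    "vcv_matrix",
    "lambda_transform",
]


class PhylogenyError(ValueError):
    """Raised when a tree violates the package's structural requirements."""


class Phylogeny:
    """A rooted phylogenetic tree with branch lengths.

    Wraps a :class:`dendropy.Tree`. The outermost nesting of the Newick
    string is interpreted as the root; polytomies are allowed everywhere.
    Internal nodes without labels receive deterministic post-order labels
    ``N0, N1, ...`` so that event tables and ancestral-state matrices can be
    keyed stably.

    Parameters
    ----------
    tree:
        A dendropy tree. Ownership is transferred; do not mutate afterwards.
    unit_branch_lengths:
        If True, missing branch lengths are replaced by 1.0 instead of being
        an error. The root edge defaults to length 0 in either mode.
    """

    def __init__(self, tree: dendropy.Tree, *, unit_branch_lengths: bool = False):
        tree.is_rooted = True
        self._tree = tree
        self._validate(unit_branch_lengths)
        self._assign_internal_labels()
        self._index()

    # -- construction helpers -------------------------------------------------

    def _validate(self, unit_branch_lengths: bool) -> None:
        leaves = list(self._tree.leaf_node_iter())
        if len(leaves) < 2:
            raise PhylogenyError(f"tree must have >= 2 tips, got {len(leaves)}")
        labels = [lf.taxon.label if lf.taxon else None for lf in leaves]
        if any(not lb for lb in labels):
            raise PhylogenyError("every tip must carry a non-empty label")
        if len(set(labels)) != len(labels):
            dupes = sorted({lb for lb in labels if labels.count(lb) > 1})
            raise PhylogenyError(f"duplicate tip labels: {dupes}")
        root = self._tree.seed_node
        for node in self._tree.preorder_node_iter():
            if node is root:
                if node.edge.length is None:
                    node.edge.length = 0.0
                continue
            if node.edge.length is None:
                if unit_branch_lengths:
                    node.edge.length = 1.0
                else:
                    raise PhylogenyError(
                        "missing branch length (pass unit_branch_lengths=True "
                        "to substitute 1.0)"
                    )
            if node.edge.length < 0:
                raise PhylogenyError(f"negative branch length {node.edge.length}")

    def _assign_internal_labels(self) -> None:
        used = set(self.tip_labels_unsorted())
        k = 0
        for node in self._tree.postorder_internal_node_iter():
            if not node.label:
                while f"N{k}" in used:
                    k += 1
                node.label = f"N{k}"
                k += 1
            used.add(node.label)

    def _index(self) -> None:
        self._leaf_by_label = {
            lf.taxon.label: lf for lf in self._tree.leaf_node_iter()
        }
        # depth from the root node; a stem edge above the root is not shared
        # evolution among the tips and is ignored (ape's vcv convention)
        self._depth = {}
        for node in self._tree.preorder_node_iter():
            parent = node.parent_node
            edge = node.edge.length or 0.0
            self._depth[node] = 0.0 if parent is None else self._depth[parent] + edge

    # -- basic accessors ------------------------------------------------------

    @property
    def tree(self) -> dendropy.Tree:
        return self._tree

    @property
    def root(self) -> dendropy.Node:
        return self._tree.seed_node

    @property
    def n_tips(self) -> int:
        return len(self._leaf_by_label)

    @property
    def tip_labels(self) -> list[str]:
        """Tip labels in sorted order (the default matrix order)."""
        return sorted(self._leaf_by_label)

    def tip_labels_unsorted(self) -> list[str]:
        return [lf.taxon.label for lf in self._tree.leaf_node_iter()]

    def node_label(self, node: dendropy.Node) -> str:
        return node.taxon.label if node.is_leaf() else node.label

    def depth(self, node: dendropy.Node) -> float:
        """Distance from the root to *node*."""
        return self._depth[node]

    def leaf(self, label: str) -> dendropy.Node:
        try:
            return self._leaf_by_label[label]
        except KeyError:
            raise KeyError(f"unknown tip label: {label!r}") from None

    def mrca(self, tips: Iterable[str]) -> dendropy.Node:
        """Deepest node whose descendant tip set contains all given tips."""
        tips = list(tips)
        if not tips:
            raise ValueError("tips must be non-empty")
        nodes = [self.leaf(t) for t in tips]
        # ancestor path of the first tip (tip -> root); for every other tip,
        # ascend until the path is hit and keep the root-most hit seen so far
        path: list[dendropy.Node] = []
        node = nodes[0]
        while node is not None:
            path.append(node)
            node = node.parent_node
        pos = {n: i for i, n in enumerate(path)}
        mrca_idx = 0
        for other in nodes[1:]:
            node = other
            while node not in pos:
                node = node.parent_node
            mrca_idx = max(mrca_idx, pos[node])
        return path[mrca_idx]

    def tip_set(self, node: dendropy.Node) -> frozenset[str]:
        return frozenset(lf.taxon.label for lf in node.leaf_iter())

    def is_monophyletic(self, tips: Iterable[str]) -> bool:
        tips = frozenset(tips)
        return self.tip_set(self.mrca(tips)) == tips

    # -- serialization --------------------------------------------------------

    def newick_string(self) -> str:
        return self._tree.as_string(
            schema="newick",
            suppress_rooting=True,
            unquoted_underscores=True,
            real_value_format_specifier=".12g",
        ).strip()

    def write_newick(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.newick_string() + "\n")

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"Phylogeny(n_tips={self.n_tips})"


def parse_newick(newick: str, *, unit_branch_lengths: bool = False) -> Phylogeny:
    """Parse a single Newick string into a validated :class:`Phylogeny`.

    Internal node labels after ``)`` are kept as node annotations (support
    values or clade names), never treated as tips; ``[...]`` comments are
    stripped; quoted labels are honored.
    """
    try:
        tree = dendropy.Tree.get(
            data=newick,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:
        raise PhylogenyError(f"could not parse Newick: {exc}") from exc
    return Phylogeny(tree, unit_branch_lengths=unit_branch_lengths)


def read_newick(path, *, unit_branch_lengths: bool = False) -> Phylogeny:
    """Read one rooted Newick tree from *path*."""
    with open(path) as fh:
        text = fh.read()
    if not text.strip():
        raise PhylogenyError(f"empty Newick file: {path}")
    return parse_newick(text, unit_branch_lengths=unit_branch_lengths)


# ---------------------------------------------------------------------------
# clade partitions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CladePartition:
    """Assignment of tree tips to named, disjoint clades.

    The canonical use is the three bilaterian groups contrasted throughout
    the analysis (Ecdysozoa, Lophotrochozoa, Deuterostomia) plus outgroups.
    """

    clades: Mapping[str, frozenset[str]]

    def __post_init__(self):
        seen: dict[str, str] = {}
        for name, tips in self.clades.items():
            for t in tips:
                if t in seen:
                    raise ValueError(
                        f"tip {t!r} assigned to both {seen[t]!r} and {name!r}"
                    )
                seen[t] = name

    def __getitem__(self, name: str) -> frozenset[str]:
        return self.clades[name]

    def names(self) -> list[str]:
        return list(self.clades)

    def tips(self, names: str | Sequence[str]) -> frozenset[str]:
        """Union of tips over one clade name or a list of names."""
        if isinstance(names, str):
            names = [names]
        out: set[str] = set()
        for name in names:
            if name not in self.clades:
                raise KeyError(f"unknown clade: {name!r}")
            out |= self.clades[name]
        return frozenset(out)

    def validate_against(
        self, phylogeny: Phylogeny, *, require_monophyly: bool = True
    ) -> None:
        tipset = set(phylogeny.tip_labels)
        for name, tips in self.clades.items():
            missing = sorted(set(tips) - tipset)
            if missing:
                raise ValueError(f"clade {name!r} lists unknown tips: {missing}")
            if require_monophyly and len(tips) >= 2:
                if not phylogeny.is_monophyletic(tips):
                    raise ValueError(
                        f"clade {name!r} is not monophyletic on the tree "
                        "(pass require_monophyly=False to override)"
                    )


def read_clade_partition(path) -> CladePartition:
    """Read a two-column TSV ``tip_label<TAB>clade_name`` ('#' comments allowed)."""
    clades: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(
                    f"{path}:{lineno}: expected 'tip<TAB>clade', got {raw!r}"
                )
            tip, clade = (p.strip() for p in parts)
            clades.setdefault(clade, set()).add(tip)
    return CladePartition({k: frozenset(v) for k, v in clades.items()})


# ---------------------------------------------------------------------------
# phylogenetic covariance
# ---------------------------------------------------------------------------


def vcv_matrix(
    phylogeny: Phylogeny, order: Sequence[str] | None = None
) -> pd.DataFrame:
    """Phylogenetic variance-covariance matrix C of shared path lengths.

    ``C[i, i]`` is the root-to-tip distance of tip *i*; ``C[i, j]`` the depth
    of the MRCA of tips *i* and *j* — the expected trait covariance under
    Brownian motion with unit rate. Rows/columns follow sorted tip labels
    unless an explicit *order* is supplied.
    """
    labels = list(order) if order is not None else phylogeny.tip_labels
    if set(labels) != set(phylogeny.tip_labels) or len(labels) != phylogeny.n_tips:
        raise ValueError("order must be a permutation of the tree's tip labels")
    idx = {lb: i for i, lb in enumerate(labels)}
    n = len(labels)
    C = np.zeros((n, n))
    # post-order accumulation of tip index sets; a pair's covariance is the
    # depth of the first node joining them, written exactly once
    below: dict[dendropy.Node, list[int]] = {}
    for node in phylogeny.tree.postorder_node_iter():
        if node.is_leaf():
            i = idx[node.taxon.label]
            C[i, i] = phylogeny.depth(node)
            below[node] = [i]
        else:
            d = phylogeny.depth(node)
            child_sets = [below.pop(ch) for ch in node.child_nodes()]
            for a in range(len(child_sets)):
                for b in range(a + 1, len(child_sets)):
                    for i in child_sets[a]:
                        for j in child_sets[b]:
                            C[i, j] = C[j, i] = d
            below[node] = [i for s in child_sets for i in s]
    return pd.DataFrame(C, index=labels, columns=labels)


def lambda_transform(C: pd.DataFrame | np.ndarray, lam: float):
    """Pagel's lambda transform: scale off-diagonal covariances by *lam*.

    lam=1 leaves C unchanged (Brownian motion); lam=0 collapses the tree to a
    star (no phylogenetic covariance). The result is a convex combination of
    C and diag(C) and therefore remains positive semi-definite.
    """
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda must lie in [0, 1], got {lam}")
    values = C.to_numpy() if isinstance(C, pd.DataFrame) else np.asarray(C, float)
    out = lam * values + (1.0 - lam) * np.diag(np.diag(values))
    if isinstance(C, pd.DataFrame):
        return pd.DataFrame(out, index=C.index, columns=C.columns)
    return out
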
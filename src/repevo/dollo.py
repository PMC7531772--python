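"""Dollo parsimony reconstruction of binary characters on a rooted tree.

Under Dollo parsimony a character (a protein domain, or presence of an
orthogroup in a genome) originates exactly once on the tree and may be lost
any number of times, but never re-originates. For a rooted tree this makes
the minimum-change reconstruction unique and closed-form:

* the single gain sits on the branch above the MRCA of all tips carrying the
  character (a gain "at the root" if that MRCA is the root itself);
* the losses are the branches subtending the maximal subtrees, inside the
  gain clade, whose tips all lack the character.

This module computes those histories for whole character matrices, the
per-branch gain/loss event table, and ancestral repertoires (the character
set implied at any internal node, optionally weighted by per-character gene
totals).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

from .phylo import Phylogeny

__all__ = [
    "DolloReconstruction",
    "dollo_reconstruct",
    "ancestral_repertoire",
    "gain_loss_table",
]


@dataclass
class DolloReconstruction:
    """Single-gain / multiple-loss histories for a set of binary characters.

    Attributes
    ----------
    phylogeny:
        The tree the reconstruction lives on.
    characters:
        Character IDs, in input order.
    gain_node:
        Per character, the node whose subtending branch carries the gain
        (the MRCA of the 1-tips), or None for all-absent characters.
    losses:
        Per character, the tuple of child nodes whose subtending branches
        carry a loss.
    states:
        DataFrame (node label x character) of implied 0/1 states.
    """

    phylogeny: Phylogeny
    characters: list[str]
    gain_node: dict[str, dendropy.Node | None]
    losses: dict[str, tuple[dendropy.Node, ...]]
    states: pd.DataFrame

    def loss_count(self, character: str) -> int:
        return len(self.losses[character])

    def gain_label(self, character: str) -> str | None:
        node = self.gain_node[character]
        return None if node is None else self.phylogeny.node_label(node)


def _character_matrix(chars: pd.DataFrame) -> pd.DataFrame:
    values = chars.to_numpy()
    if not np.isin(values, (0, 1)).all():
        raise ValueError("character matrix entries must be 0 or 1")
    return chars.astype(np.int64)


def dollo_reconstruct(phylogeny: Phylogeny, chars: pd.DataFrame) -> DolloReconstruction:
    """Reconstruct every character of a taxa x characters 0/1 matrix.

    The matrix rows must be exactly the tree's tips (any order; matching is
    by label). Characters absent from all tips get an empty reconstruction
    (no gain, no losses), which arises naturally in clade-subset analyses.
    """
    chars = _character_matrix(chars)
    tipset = set(phylogeny.tip_labels)
    if set(chars.index) != tipset:
        raise ValueError(
            "character matrix taxa do not match tree tips "
            f"(missing {sorted(tipset - set(chars.index))[:5]}, "
            f"extra {sorted(set(chars.index) - tipset)[:5]})"
        )
    characters = list(chars.columns)
    k = len(characters)

    nodes = list(phylogeny.tree.postorder_node_iter())
    node_index = {nd: i for i, nd in enumerate(nodes)}
    # any_below[i, c]: does the subtree of node i contain a 1-tip of char c
    any_below = np.zeros((len(nodes), k), dtype=bool)
    tip_rows = chars.loc[:, characters]
    for nd in nodes:
        i = node_index[nd]
        if nd.is_leaf():
            any_below[i] = tip_rows.loc[nd.taxon.label].to_numpy() > 0
        else:
            for ch in nd.child_nodes():
                any_below[i] |= any_below[node_index[ch]]

    # gain node per character = MRCA of 1-tips = shallowest (first in
    # post-order is deepest; we want the node all of whose ancestors also
    # have any_below True). Walk down from root instead.
    root = phylogeny.root
    gain_node: dict[str, dendropy.Node | None] = {}
    for c_idx, char in enumerate(characters):
        if not any_below[node_index[root], c_idx]:
            gain_node[char] = None
            continue
        node = root
        while True:
            carriers = [
                ch for ch in node.child_nodes() if any_below[node_index[ch], c_idx]
            ]
            if node.is_leaf() or len(carriers) != 1:
                break
            node = carriers[0]
        gain_node[char] = node

    # states: 1 iff inside the gain clade and some 1-tip below
    in_clade = np.zeros((len(nodes), k), dtype=bool)
    for c_idx, char in enumerate(characters):
        g = gain_node[char]
        if g is None:
            continue
        stack = [g]
        while stack:
            nd = stack.pop()
            in_clade[node_index[nd], c_idx] = True
            stack.extend(nd.child_nodes())
    state = in_clade & any_below

    losses: dict[str, tuple[dendropy.Node, ...]] = {}
    for c_idx, char in enumerate(characters):
        lost = tuple(
            nd
            for nd in nodes
            if nd.parent_node is not None
            and state[node_index[nd.parent_node], c_idx]
            and not state[node_index[nd], c_idx]
        )
        losses[char] = lost

    labels = [phylogeny.node_label(nd) for nd in nodes]
    states = pd.DataFrame(
        state.astype(np.int64), index=labels, columns=characters
    )
    return DolloReconstruction(phylogeny, characters, gain_node, losses, states)


def ancestral_repertoire(
    recon: DolloReconstruction,
    node: dendropy.Node | str,
    weights: Mapping[str, float] | pd.Series | None = None,
) -> tuple[frozenset[str], float]:
    """Characters implied present at *node*, plus their additive total.

    *weights* assigns a per-character gene total (defaults to 1 each), so
    the additive total of an ancestral apoptotic repertoire can be reported
    either as a character count or as an expected gene count.
    """
    if isinstance(node, str):
        label = node
        if label not in recon.states.index:
            raise KeyError(f"unknown node label: {label!r}")
    else:
        label = recon.phylogeny.node_label(node)
        if label not in recon.states.index:
            raise KeyError(f"node {label!r} not part of the reconstruction")
    row = recon.states.loc[label]
    present = frozenset(row.index[row > 0])
    if weights is None:
        total = float(len(present))
    else:
        total = float(sum(weights[c] for c in present))
    return present, total


def gain_loss_table(recon: DolloReconstruction) -> pd.DataFrame:
    """Event table with one row per gain or loss.

    Columns: character, branch (label of the child node of the branch the
    event sits on), event ('gain' or 'loss'). All-absent characters
    contribute no rows. Per-branch loss totals can be aggregated by clade
    directly from this table.
    """
    rows = []
    for char in recon.characters:
        g = recon.gain_node[char]
        if g is None:
            continue
        rows.append((char, recon.phylogeny.node_label(g), "gain"))
        for nd in recon.losses[char]:
            rows.append((char, recon.phylogeny.node_label(nd), "loss"))
    return pd.DataFrame(rows, columns=["character", "branch", "event"])


def write_event_table(recon: DolloReconstruction, path) -> None:
    gain_loss_table(recon).to_csv(path, sep="\t", index=False)


def write_ancestral_states(recon: DolloReconstruction, path) -> None:
    recon.states.sort_index().to_csv(path, sep="\t", index_label="node")
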
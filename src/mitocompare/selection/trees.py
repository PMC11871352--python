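"""Minimal unrooted-tree scaffolding for codon-model likelihoods.

Newick parsing is delegated to dendropy; internally a tree is flattened
to integer node ids with one branch per non-root node, evaluated by
postorder pruning from an arbitrary internal "root" (the likelihood of a
reversible model does not depend on that choice).
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np


@dataclass
class UnrootedTree:
    taxa: tuple[str, ...]  # leaf ids 0..N-1 in this order
    n_nodes: int
    root: int
    #: (node, parent, edge_index) with children listed before parents;
    #: every node except the root appears exactly once.
    postorder: tuple[tuple[int, int, int], ...]
    branch_lengths: np.ndarray  # initial lengths, one per edge

    @property
    def n_leaves(self) -> int:
        return len(self.taxa)

    @property
    def n_edges(self) -> int:
        return self.n_nodes - 1

    @property
    def preorder(self) -> tuple[tuple[int, int, int], ...]:
        return tuple(reversed(self.postorder))


def from_newick(newick: str, default_branch_length: float = 0.1) -> UnrootedTree:
    """Parse a Newick string into an :class:`UnrootedTree`.

    A rooted (bifurcating-root) topology is derooted so a two-model LRT
    sees 2N−3 free branch lengths; missing branch lengths default to
    `default_branch_length`.
    """
    tree = dendropy.Tree.get(data=newick, schema="newick")
    tree.deroot()  # a bifurcating root would add a redundant branch

    leaves = [lf for lf in tree.leaf_node_iter()]
    taxa = tuple(lf.taxon.label for lf in leaves)
    if len(set(taxa)) != len(taxa):
        raise ValueError("duplicate taxon labels in tree")

    ids: dict[int, int] = {}
    for i, lf in enumerate(leaves):
        ids[id(lf)] = i
    nxt = len(leaves)
    for nd in tree.preorder_node_iter():
        if id(nd) not in ids:
            ids[id(nd)] = nxt
            nxt += 1

    root_nd = tree.seed_node
    post: list[tuple[int, int, int]] = []
    bls: list[float] = []
    edge_of: dict[int, int] = {}
    for nd in tree.postorder_node_iter():
        if nd is root_nd:
            continue
        e = len(bls)
        edge_of[id(nd)] = e
        bls.append(
            nd.edge.length if nd.edge.length is not None else default_branch_length
        )
        post.append((ids[id(nd)], ids[id(nd.parent_node)], e))

    return UnrootedTree(
        taxa=taxa,
        n_nodes=nxt,
        root=ids[id(root_nd)],
        postorder=tuple(post),
        branch_lengths=np.asarray(bls, dtype=float),
    )


def star_tree(taxa: list[str], branch_length: float = 0.1) -> UnrootedTree:
    """A star topology (one internal node) — the minimal unrooted tree."""
    n = len(taxa)
    if n < 2:
        raise ValueError("need at least 2 taxa")
    post = tuple((i, n, i) for i in range(n))
    return UnrootedTree(
        taxa=tuple(taxa), n_nodes=n + 1, root=n, postorder=post,
        branch_lengths=np.full(n, branch_length),
    )
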
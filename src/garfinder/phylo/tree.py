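"""Array-backed phylogeny for fast pruning-likelihood evaluation.

Newick parsing, pruning and rerooting are delegated to dendropy; this class
flattens the result into postorder arrays (parent pointers, branch lengths,
tip rows) that the likelihood engine consumes.
"""

from __future__ import annotations

import io

import dendropy
import numpy as np

__all__ = ["Phylogeny"]


class Phylogeny:
    """A rooted tree with named tips and branch lengths (subs/site)."""

    def __init__(self, dtree: dendropy.Tree) -> None:
        self._dtree = dtree
        nodes = list(dtree.postorder_node_iter())
        self._index = {id(nd): i for i, nd in enumerate(nodes)}
        self.n_nodes = len(nodes)
        self.parent = np.full(self.n_nodes, -1, dtype=int)
        self.branch_lengths = np.zeros(self.n_nodes)
        self.children: list[list[int]] = [[] for _ in nodes]
        self.tip_names: list[str] = []
        self.tip_index: dict[str, int] = {}
        for i, nd in enumerate(nodes):
            if nd.parent_node is not None:
                p = self._index[id(nd.parent_node)]
                self.parent[i] = p
                self.children[p].append(i)
                self.branch_lengths[i] = (
                    nd.edge.length if nd.edge.length is not None else 0.0
                )
            if nd.is_leaf():
                name = nd.taxon.label.replace(" ", "_")
                self.tip_names.append(name)
                self.tip_index[name] = i
        self.root = self.n_nodes - 1

    # -- construction -----------------------------------------------------
    @classmethod
    def from_newick(cls, newick: str) -> "Phylogeny":
        dtree = dendropy.Tree.get(
            data=newick, schema="newick", preserve_underscores=True
        )
        return cls(dtree)

    @classmethod
    def from_file(cls, path) -> "Phylogeny":
        with open(path) as fh:
            return cls.from_newick(fh.read())

    def newick(self) -> str:
        return self._dtree.as_string(schema="newick", suppress_rooting=True).strip()

    # -- manipulation ------------------------------------------------------
    def prune_to(self, taxa: set[str]) -> "Phylogeny":
        """Restrict to a tip subset, suppressing unifurcations."""
        keep = [t for t in self.tip_names if t in taxa]
        if len(keep) < 2:
            raise ValueError(f"cannot prune to {len(keep)} tips")
        dtree = self._dtree.clone(depth=1)
        dtree.retain_taxa_with_labels(keep)
        dtree.suppress_unifurcations()
        return Phylogeny(dtree)

    def with_branch_lengths(self, lengths: np.ndarray) -> "Phylogeny":
        """Copy with per-node branch lengths replaced (postorder indexing)."""
        dtree = self._dtree.clone(depth=1)
        new = Phylogeny(dtree)
        if len(lengths) != new.n_nodes:
            raise ValueError("length vector does not match node count")
        new.branch_lengths = np.asarray(lengths, dtype=float).copy()
        for nd in new._dtree.postorder_node_iter():
            i = new._index[id(nd)]
            if nd.parent_node is not None:
                nd.edge.length = float(new.branch_lengths[i])
        return new

    @property
    def n_tips(self) -> int:
        return len(self.tip_names)

    @property
    def n_edges(self) -> int:
        return self.n_nodes - 1

    def terminal_edge(self, tip_name: str) -> int:
        """Node index whose parent edge is the terminal branch of a tip."""
        if tip_name not in self.tip_index:
            raise KeyError(f"tip {tip_name!r} not in tree")
        return self.tip_index[tip_name]

    def total_length(self) -> float:
        return float(self.branch_lengths.sum())

    def __repr__(self) -> str:
        return f"Phylogeny({self.n_tips} tips, total length {self.total_length():.4g})"
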
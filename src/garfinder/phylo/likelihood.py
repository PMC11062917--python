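"""Felsenstein pruning likelihood under GTR with branch scaling.

The engine evaluates the log-likelihood of an alignment given the neutral
model, a global scale ``lambda`` multiplying every branch, and an extra
foreground scale ``rho`` multiplying one designated branch. Gaps and Ns are
missing data (all-ones partial likelihoods); identical columns are collapsed
into weighted site patterns so each distinct pattern is computed once.
"""

from __future__ import annotations

import numpy as np

from ..msa import OrthologueAlignment
from .model import PhyloModel

__all__ = ["LikelihoodEngine", "log_likelihood"]

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4, "-": 4}
# partial-likelihood row per tip state; state 4 = missing
_TIP_PARTIALS = np.vstack([np.eye(4), np.ones((1, 4))])


def encode_alignment(
    rows: dict[str, str], species_order: list[str]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Collapse columns into unique site patterns.

    Returns (patterns, weights, column_pattern): patterns is (n_species,
    n_patterns) int8 with 0-3 bases / 4 missing; ``column_pattern[c]`` maps
    alignment column c to its pattern index.
    """
    L = len(next(iter(rows.values())))
    mat = np.empty((len(species_order), L), dtype=np.int8)
    for r, sp in enumerate(species_order):
        seq = rows[sp]
        mat[r] = [_CODE[ch] for ch in seq]
    patterns, col_pat, counts = np.unique(
        mat.T, axis=0, return_inverse=True, return_counts=True
    )
    return patterns.T.copy(), counts.astype(float), col_pat


class LikelihoodEngine:
    """Reusable pruning-likelihood evaluator for one alignment + model.

    The model tree is pruned to the species present in the alignment. The
    foreground branch, if any, is the terminal branch of a named tip.
    """

    def __init__(
        self,
        msa: OrthologueAlignment | dict[str, str],
        model: PhyloModel,
        foreground: str | None = None,
    ) -> None:
        rows = msa.rows if isinstance(msa, OrthologueAlignment) else msa
        if not rows:
            raise ValueError("empty alignment")
        shared = [sp for sp in rows if sp in model.tree.tip_index]
        if len(shared) < 2:
            raise ValueError(f"fewer than 2 alignment rows match tree tips: {shared}")
        self.model = (
            model
            if set(shared) == set(model.tree.tip_names)
            else model.pruned_to(set(shared))
        )
        tree = self.model.tree
        self.species = [sp for sp in tree.tip_names]  # tree order
        self.patterns, self.weights, self.column_pattern = encode_alignment(
            {sp: rows[sp] for sp in self.species}, self.species
        )
        self.n_patterns = self.patterns.shape[1]
        self._tree = tree
        self._freqs = self.model.base_freqs
        self._eig = self.model.eigen
        self._t0 = tree.branch_lengths.copy()
        self.foreground_node: int | None = (
            tree.terminal_edge(foreground) if foreground is not None else None
        )

    def branch_lengths(self, lam: float, rho: float = 1.0) -> np.ndarray:
        t = self._t0 * lam
        if rho != 1.0:
            if self.foreground_node is None:
                raise ValueError("rho != 1 requires a foreground branch")
            t[self.foreground_node] *= rho
        return t

    def loglik(self, lam: float, rho: float = 1.0) -> float:
        col = self.pattern_logliks(lam, rho)
        return float(np.dot(self.weights, col))

    def pattern_logliks(self, lam: float, rho: float = 1.0) -> np.ndarray:
        """Per-pattern column log-likelihoods."""
        return _prune(
            self._tree,
            self.patterns,
            self._eig.transition_matrices(self.branch_lengths(lam, rho)),
            self._freqs,
        )


def _prune(tree, patterns: np.ndarray, P: np.ndarray, freqs: np.ndarray) -> np.ndarray:
    n_pat = patterns.shape[1]
    partials: list[np.ndarray | None] = [None] * tree.n_nodes
    tip_row = {node: r for r, node in enumerate(tree.tip_index.values())}
    for node in range(tree.n_nodes):
        kids = tree.children[node]
        if not kids:
            continue
        acc = np.ones((n_pat, 4))
        for child in kids:
            if tree.children[child]:
                child_partial = partials[child]
                partials[child] = None  # free memory
                acc *= child_partial @ P[child].T
            else:
                # tip: look up precomputed (state -> partial) rows through P
                tipP = _TIP_PARTIALS @ P[child].T  # (5, 4)
                acc *= tipP[patterns[tip_row[child]]]
        partials[node] = acc
    site_lik = partials[tree.root] @ freqs
    return np.log(np.maximum(site_lik, 1e-300))


def log_likelihood(
    msa: OrthologueAlignment | dict[str, str],
    model: PhyloModel,
    lam: float = 1.0,
    rho: float = 1.0,
    foreground: str | None = None,
) -> float:
    """One-shot pruning log-likelihood (see :class:`LikelihoodEngine`)."""
    return LikelihoodEngine(msa, model, foreground).loglik(lam, rho)
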
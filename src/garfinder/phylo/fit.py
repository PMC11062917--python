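"""Maximum-likelihood fitting of the neutral GTR model.

Given a fixed topology and an alignment of putatively neutral sites
(fourfold-degenerate codon positions in the motivating design), jointly
optimizes all branch lengths and the five free GTR exchangeabilities (GT
fixed at 1) under the pruning likelihood. Stationary frequencies default to
empirical base counts.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import optimize

from ..msa import OrthologueAlignment
from .likelihood import encode_alignment, _prune
from .model import EigenGTR, PhyloModel, build_rate_matrix
from .tree import Phylogeny

__all__ = ["empirical_base_freqs", "fit_neutral_model"]

_MIN_BL, _MAX_BL = 1e-6, 10.0


def empirical_base_freqs(rows: dict[str, str]) -> np.ndarray:
    counts = np.zeros(4)
    for seq in rows.values():
        for ch, k in (("A", 0), ("C", 1), ("G", 2), ("T", 3)):
            counts[k] += seq.count(ch)
    if counts.sum() == 0:
        raise ValueError("no unambiguous bases in alignment")
    return counts / counts.sum()


def fit_neutral_model(
    alignment: OrthologueAlignment | dict[str, str],
    topology: Phylogeny,
    base_freqs: np.ndarray | None = None,
    maxiter: int = 500,
) -> PhyloModel:
    """Fit branch lengths and GTR exchangeabilities on a fixed topology."""
    rows = alignment.rows if isinstance(alignment, OrthologueAlignment) else alignment
    shared = set(rows) & set(topology.tip_names)
    if len(shared) < 3:
        raise ValueError(f"need >= 3 taxa shared with tree, have {len(shared)}")
    tree = (
        topology
        if shared == set(topology.tip_names)
        else topology.prune_to(shared)
    )
    species = tree.tip_names
    patterns, weights, _ = encode_alignment(
        {sp: rows[sp] for sp in species}, species
    )
    freqs = (
        np.asarray(base_freqs, dtype=float)
        if base_freqs is not None
        else empirical_base_freqs(rows)
    )

    variant = _has_variation(patterns)
    edge_nodes = [i for i in range(tree.n_nodes) if tree.parent[i] >= 0]
    n_edges = len(edge_nodes)

    def unpack(v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        bl = np.exp(v[:n_edges])
        exch = np.concatenate([np.exp(v[n_edges:]), [1.0]])  # GT reference rate
        return bl, exch

    def negll(v: np.ndarray) -> float:
        bl, exch = unpack(v)
        eig = EigenGTR.of(build_rate_matrix(exch, freqs), freqs)
        t = np.zeros(tree.n_nodes)
        t[edge_nodes] = bl
        col = _prune(tree, patterns, eig.transition_matrices(t), freqs)
        return -float(np.dot(weights, col))

    x0 = np.concatenate([np.full(n_edges, np.log(0.05)), np.zeros(5)])
    bounds = [(np.log(_MIN_BL), np.log(_MAX_BL))] * n_edges + [(-7.0, 7.0)] * 5
    res = optimize.minimize(
        negll, x0, method="L-BFGS-B", bounds=bounds,
        options={"maxiter": maxiter, "ftol": 1e-12, "gtol": 1e-6},
    )
    if not res.success and "ITERATIONS" not in str(res.message).upper():
        warnings.warn(f"neutral-model fit did not fully converge: {res.message}")
    if not variant:
        warnings.warn("invariant alignment: branch lengths pinned at ~0")
    bl, exch = unpack(res.x)
    full_bl = np.zeros(tree.n_nodes)
    full_bl[edge_nodes] = bl if variant else _MIN_BL
    fitted_tree = tree.with_branch_lengths(full_bl)
    return PhyloModel(fitted_tree, exch / exch[-1], freqs, label="fitted_neutral")


def _has_variation(patterns: np.ndarray) -> bool:
    for col in patterns.T:
        bases = {int(b) for b in col if b < 4}
        if len(bases) > 1:
            return True
    return False
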
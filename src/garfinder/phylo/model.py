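"""General time-reversible (GTR) substitution model and PHAST-style .mod IO.

The rate matrix is Q[i,j] = s[i,j] * pi[j] for i != j (s the six symmetric
exchangeabilities, pi the stationary base frequencies), diagonal set so rows
sum to zero, and globally rescaled so the expected substitution rate at
stationarity is one — branch lengths are then in expected substitutions per
site. Transition probabilities come from the eigendecomposition of Q in the
pi-symmetrized basis, where Q is similar to a real symmetric matrix.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from .tree import Phylogeny

__all__ = ["GTR_PAIRS", "PhyloModel", "read_mod", "write_mod"]

BASES = "ACGT"
# order of the six exchangeability parameters
GTR_PAIRS = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]  # AC AG AT CG CT GT


def build_rate_matrix(exch: np.ndarray, freqs: np.ndarray) -> np.ndarray:
    """Normalized GTR rate matrix (mean rate 1 at stationarity)."""
    Q = np.zeros((4, 4))
    for k, (i, j) in enumerate(GTR_PAIRS):
        Q[i, j] = exch[k] * freqs[j]
        Q[j, i] = exch[k] * freqs[i]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    mu = -float(np.dot(freqs, np.diag(Q)))
    if mu <= 0:
        raise ValueError("degenerate rate matrix (all exchangeabilities zero?)")
    return Q / mu


@dataclass
class EigenGTR:
    """Cached spectral decomposition: P(t) = A @ diag(exp(w t)) @ B."""

    w: np.ndarray  # eigenvalues (4,)
    A: np.ndarray  # D^{-1/2} U
    B: np.ndarray  # U.T D^{1/2}

    @classmethod
    def of(cls, Q: np.ndarray, freqs: np.ndarray) -> "EigenGTR":
        d = np.sqrt(freqs)
        S = (Q * d[:, None]) / d[None, :]  # symmetric for reversible Q
        w, U = np.linalg.eigh((S + S.T) / 2.0)
        return cls(w=w, A=U / d[:, None], B=U.T * d[None, :])

    def transition_matrices(self, t: np.ndarray) -> np.ndarray:
        """P(t_e) for a vector of branch lengths; shape (n_edges, 4, 4)."""
        E = np.exp(np.outer(t, self.w))  # (n, 4)
        P = np.einsum("ij,ej,jk->eik", self.A, E, self.B)
        np.clip(P, 0.0, 1.0, out=P)
        return P


@dataclass
class PhyloModel:
    """A neutral substitution model: tree + GTR parameters."""

    tree: Phylogeny
    exchangeabilities: np.ndarray  # 6, order AC AG AT CG CT GT
    base_freqs: np.ndarray  # 4, order A C G T
    label: str = "neutral"
    _eig: EigenGTR | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.exchangeabilities = np.asarray(self.exchangeabilities, dtype=float)
        self.base_freqs = np.asarray(self.base_freqs, dtype=float)
        if self.exchangeabilities.shape != (6,):
            raise ValueError("need 6 exchangeabilities (AC AG AT CG CT GT)")
        if abs(self.base_freqs.sum() - 1.0) > 1e-9:
            raise ValueError("base frequencies must sum to 1")
        if np.any(self.base_freqs <= 0) or np.any(self.exchangeabilities < 0):
            raise ValueError("frequencies must be positive, exchangeabilities >= 0")
        if np.any(self.tree.branch_lengths < 0):
            raise ValueError("negative branch length in tree")

    @property
    def rate_matrix(self) -> np.ndarray:
        return build_rate_matrix(self.exchangeabilities, self.base_freqs)

    @property
    def eigen(self) -> EigenGTR:
        if self._eig is None:
            self._eig = EigenGTR.of(self.rate_matrix, self.base_freqs)
        return self._eig

    def pruned_to(self, taxa: set[str]) -> "PhyloModel":
        return PhyloModel(
            self.tree.prune_to(taxa),
            self.exchangeabilities,
            self.base_freqs,
            self.label,
        )

    @classmethod
    def jukes_cantor(cls, tree: Phylogeny) -> "PhyloModel":
        return cls(tree, np.ones(6), np.full(4, 0.25), label="JC69")


def write_mod(model: PhyloModel, path) -> None:
    """Write a PHAST-style .mod file (REV substitution model)."""
    Q = model.rate_matrix
    with open(path, "w") as fh:
        fh.write("ALPHABET: A C G T\n")
        fh.write("ORDER: 0\n")
        fh.write("SUBST_MOD: REV\n")
        fh.write(
            "BACKGROUND: " + " ".join(f"{f:.6f}" for f in model.base_freqs) + "\n"
        )
        fh.write("RATE_MAT:\n")
        for row in Q:
            fh.write("  " + " ".join(f"{x: .6f}" for x in row) + "\n")
        fh.write("TREE: " + model.tree.newick().lstrip("[&R] ").strip() + "\n")


def read_mod(path) -> PhyloModel:
    """Read a PHAST-style .mod (REV); exchangeabilities recovered from Q."""
    text = open(path).read()
    bg = re.search(r"BACKGROUND:\s*([^\n]+)", text)
    tree_m = re.search(r"TREE:\s*([^\n]+)", text)
    mat_m = re.search(r"RATE_MAT:\s*\n((?:\s*[-\d.eE+ ]+\n){4})", text)
    if not (bg and tree_m and mat_m):
        raise ValueError(f"{path}: missing BACKGROUND, TREE or RATE_MAT")
    freqs = np.array([float(x) for x in bg.group(1).split()])
    freqs = freqs / freqs.sum()
    Q = np.array(
        [[float(x) for x in line.split()] for line in mat_m.group(1).strip().splitlines()]
    )
    exch = np.array([Q[i, j] / freqs[j] for i, j in GTR_PAIRS])
    tree = Phylogeny.from_newick(tree_m.group(1).strip())
    return PhyloModel(tree, exch, freqs)
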
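"""PWM motif scanning with exact p-values and cross-species site conservation.

An IUPAC consensus (e.g. the EMX2 motif ATTARCNV) is expanded into a
pseudocount-smoothed position weight matrix; windows are scored by log-odds
against a 0-order background, and each score's p-value is the exact tail
probability of that score among random background words, computed by dynamic
programming over a finely discretized score distribution. Sites found in the
per-species rows of an element alignment are grouped into alignment-column
sites and classified as conserved, glider-specific, or sporadic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .msa import OrthologueAlignment

__all__ = [
    "PWM",
    "MotifHit",
    "iupac_to_pwm",
    "scan_pwm",
    "scan_sequences",
    "call_site_conservation",
]

BASES = "ACGT"
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
# score-grid step (log2 units); small enough that the discretized tail
# differs from full enumeration by < 1e-4 in p for motifs of length <= ~12
SCORE_STEP = 1e-4


@dataclass(frozen=True)
class MotifHit:
    sequence_id: str
    offset: int  # 0-based on the forward strand
    strand: str
    score: float  # log2 odds
    p_value: float


@dataclass
class PWM:
    """Per-position base probabilities plus the scanning background."""

    probs: np.ndarray  # (length, 4)
    background: np.ndarray  # (4,)
    pseudocount: float = 0.01
    name: str = ""
    _tail: "ScoreTail | None" = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("PWM rows must sum to 1")
        if not math.isclose(self.background.sum(), 1.0, abs_tol=1e-9):
            raise ValueError("background must sum to 1")

    def __len__(self) -> int:
        return self.probs.shape[0]

    @property
    def score_matrix(self) -> np.ndarray:
        """Log2-odds scores per (position, base)."""
        return np.log2(self.probs / self.background[None, :])

    @property
    def tail(self) -> "ScoreTail":
        if self._tail is None:
            self._tail = ScoreTail.build(self.score_matrix, self.background)
        return self._tail


def iupac_to_pwm(
    motif: str,
    pseudocount: float = 0.01,
    background: np.ndarray | None = None,
) -> PWM:
    """Expand an IUPAC consensus into a smoothed PWM.

    Each position spreads probability uniformly over the code's allowed
    bases, then adds the pseudocount to every base and renormalizes:
    p = (share + pc) / (1 + 4 pc).
    """
    bg = (
        np.asarray(background, dtype=float)
        if background is not None
        else np.full(4, 0.25)
    )
    probs = np.zeros((len(motif), 4))
    for i, ch in enumerate(motif.upper()):
        allowed = IUPAC.get(ch)
        if allowed is None:
            raise ValueError(f"invalid IUPAC code {ch!r} at position {i + 1}")
        share = 1.0 / len(allowed)
        for b in allowed:
            probs[i, BASES.index(b)] = share
    probs = (probs + pseudocount) / (1.0 + 4.0 * pseudocount)
    return PWM(probs, bg, pseudocount, name=motif.upper())


@dataclass
class ScoreTail:
    """Exact tail distribution of the discretized log-odds score.

    Per-position scores are rounded to a lattice of step ``SCORE_STEP``; the
    distribution of the rounded window score under the background is built by
    convolution, and windows are scored on the same lattice, so the reported
    p-value is the exact tail probability of the rounded score.
    """

    int_scores: np.ndarray  # (length, 4) lattice scores
    offset: int  # lattice index of the minimal achievable sum
    tail: np.ndarray  # tail[k] = P(int score >= offset + k)

    @classmethod
    def build(cls, score_matrix: np.ndarray, background: np.ndarray) -> "ScoreTail":
        ints = np.rint(score_matrix / SCORE_STEP).astype(np.int64)
        dist = np.ones(1)
        base = 0  # lattice value of dist[0]
        for p in range(ints.shape[0]):
            pmin, pmax = int(ints[p].min()), int(ints[p].max())
            new = np.zeros(dist.size + (pmax - pmin))
            for b in range(4):
                if background[b] == 0.0:
                    continue
                sh = int(ints[p, b]) - pmin
                new[sh : sh + dist.size] += background[b] * dist
            dist = new
            base += pmin
        tail = np.cumsum(dist[::-1])[::-1]
        return cls(ints, base, np.minimum(tail, 1.0))

    def p_value(self, window_codes: np.ndarray) -> float:
        k = int(self.int_scores[np.arange(len(window_codes)), window_codes].sum())
        idx = k - self.offset
        if idx <= 0:
            return 1.0
        if idx >= self.tail.size:
            return float(self.tail[-1])
        return float(self.tail[idx])


def _encode(seq: str) -> np.ndarray:
    out = np.full(len(seq), -1, dtype=np.int64)
    for i, ch in enumerate(seq.upper()):
        k = BASES.find(ch)
        out[i] = k  # -1 for N / anything else
    return out


def scan_pwm(
    seq: str,
    pwm: PWM,
    p_threshold: float = 0.01,
    both_strands: bool = True,
    sequence_id: str = "",
) -> list[MotifHit]:
    """All windows with exact p-value <= threshold; N-containing windows skipped."""
    L = len(pwm)
    hits: list[MotifHit] = []
    if len(seq) < L:
        return hits
    sm = pwm.score_matrix
    tail = pwm.tail
    strands = [("+", seq)]
    if both_strands:
        strands.append(("-", str(Seq(seq).reverse_complement())))
    for strand, s in strands:
        codes = _encode(s)
        for off in range(len(s) - L + 1):
            window = codes[off : off + L]
            if (window < 0).any():
                continue
            p = tail.p_value(window)
            if p <= p_threshold:
                score = float(sm[np.arange(L), window].sum())
                fwd_off = off if strand == "+" else len(s) - L - off
                hits.append(MotifHit(sequence_id, fwd_off, strand, score, p))
    hits.sort(key=lambda h: (h.offset, h.strand))
    return hits


def scan_sequences(
    seqs: dict[str, str],
    pwm: PWM,
    p_threshold: float = 0.01,
    both_strands: bool = True,
) -> dict[str, list[MotifHit]]:
    return {
        name: scan_pwm(s, pwm, p_threshold, both_strands, sequence_id=name)
        for name, s in seqs.items()
    }


def empirical_background(seqs: dict[str, str] | list[str]) -> np.ndarray:
    """0-order mononucleotide background of a sequence set."""
    pool = seqs.values() if isinstance(seqs, dict) else seqs
    counts = np.zeros(4)
    for s in pool:
        su = s.upper()
        for k, b in enumerate(BASES):
            counts[k] += su.count(b)
    if counts.sum() == 0:
        raise ValueError("no unambiguous bases")
    return counts / counts.sum()


def _ungapped_to_column(row: str) -> np.ndarray:
    """Map each ungapped base index of a row to its alignment column."""
    return np.flatnonzero(np.frombuffer(row.encode(), dtype="S1") != b"-")


def call_site_conservation(
    msa: OrthologueAlignment,
    hits_per_species: dict[str, list[MotifHit]],
    motif_length: int,
    min_frac: float = 0.5,
    glider_species: set[str] | frozenset[str] = frozenset(),
) -> pd.DataFrame:
    """Group per-species motif hits into alignment-column sites and classify.

    Hits on the same strand whose alignment-column spans overlap by at least
    half the motif length belong to one site. A site present in at least
    ``ceil(min_frac * n_species_in_alignment)`` species is ``conserved``;
    otherwise it is ``glider_specific`` when it covers every glider in the
    alignment and no non-glider, else ``sporadic``.
    """
    if msa.n_species == 0 or msa.length == 0:
        raise ValueError("empty alignment")
    entries = []  # (strand, col_start, col_end, species)
    for sp, hits in hits_per_species.items():
        if sp not in msa.rows:
            continue
        col_of = _ungapped_to_column(msa.rows[sp])
        for h in hits:
            if h.offset + motif_length > col_of.size:
                continue  # hit beyond the filtered row (trimmed away)
            entries.append(
                (h.strand, int(col_of[h.offset]),
                 int(col_of[h.offset + motif_length - 1]) + 1, sp)
            )
    entries.sort(key=lambda e: (e[0], e[1], e[2]))
    min_ov = math.ceil(motif_length / 2)
    clusters: list[dict] = []
    for strand, start, end, sp in entries:
        placed = False
        for cl in clusters:
            if cl["strand"] != strand:
                continue
            ov = min(end, cl["end"]) - max(start, cl["start"])
            if ov >= min_ov:
                cl["species"].add(sp)
                placed = True
                break
        if not placed:
            clusters.append(
                {"strand": strand, "start": start, "end": end, "species": {sp}}
            )
    n_total = msa.n_species
    need = math.ceil(min_frac * n_total)
    gliders_here = set(glider_species) & set(msa.rows)
    rows = []
    for i, cl in enumerate(sorted(clusters, key=lambda c: (c["start"], c["strand"]))):
        spp = cl["species"]
        if len(spp) >= need:
            status = "conserved"
        elif gliders_here and gliders_here <= spp and spp <= gliders_here:
            status = "glider_specific"
        else:
            status = "sporadic"
        rows.append(
            (f"{msa.element_id}_site{i + 1}", cl["strand"], cl["start"], cl["end"],
             len(spp), ",".join(sorted(spp)), status)
        )
    return pd.DataFrame(
        rows,
        columns=["site_id", "strand", "col_start", "col_end", "n_species", "species", "status"],
    )
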
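"""Alignment trimming and element-retention rules.

Substitution-rate estimation is unreliable in gappy alignment regions, but
similarity-based filtering would bias a divergence-based test; the rules here
therefore act on gap structure only, in a fixed order:

1. ``trim_to_reference`` — drop columns outside the reference element bounds
   (lift-over flanks in the target species).
2. ``trim_gappy_ends`` — 20 bp sliding window from each end, advancing until
   at least 75% of rows have <= 5 gap/N characters in the window.
3. ``remove_gappy_columns`` — internal gap columns, either a fixed
   gap-fraction threshold or a gappyout-style data-driven cutoff.
4. ``drop_gappy_sequences`` — rows with > 25% gaps overall or any single gap
   run longer than 10% of the alignment are removed.
5. ``check_retention`` — keep the element only with >= 5 species including a
   complete (glider, sister) pair and every outgroup group represented.

'-' and 'N' both count as gaps throughout. All thresholds are strict
(*greater than*): boundary ties survive.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .msa import GAP_CHARS, OrthologueAlignment, SpeciesRoles

__all__ = [
    "FilterRejection",
    "RetentionRule",
    "trim_to_reference",
    "trim_gappy_ends",
    "remove_gappy_columns",
    "drop_gappy_sequences",
    "check_retention",
    "filter_alignment",
]


class FilterRejection(Exception):
    """An element failed a filtering stage and is removed from the analysis."""

    def __init__(self, element_id: str, stage: str, reason: str) -> None:
        self.element_id, self.stage, self.reason = element_id, stage, reason
        super().__init__(f"{element_id}: rejected at {stage} ({reason})")


@dataclass(frozen=True)
class RetentionRule:
    """Minimum composition an alignment must keep to be testable."""

    min_species: int = 5
    required_pairs: tuple[tuple[str, str], ...] = ()
    outgroup_groups: dict[str, tuple[str, ...]] = field(default_factory=dict)

    @classmethod
    def from_roles(cls, roles: SpeciesRoles, min_species: int = 5) -> "RetentionRule":
        return cls(min_species, roles.pairs, dict(roles.outgroup_groups))


def _is_gap(ch: str) -> bool:
    return ch in GAP_CHARS


def _gap_matrix(msa: OrthologueAlignment) -> np.ndarray:
    """Boolean (n_rows, n_cols) matrix of gap-or-N positions."""
    arr = np.frombuffer(
        "".join(msa.rows[sp] for sp in msa.species).encode(), dtype="S1"
    ).reshape(msa.n_species, msa.length)
    return (arr == b"-") | (arr == b"N")


def trim_to_reference(msa: OrthologueAlignment) -> OrthologueAlignment:
    """Cut columns before/after the reference row's first/last non-gap base."""
    ref = msa.reference_row()
    idx = [i for i, ch in enumerate(ref) if ch != "-"]
    if not idx:
        raise FilterRejection(msa.element_id, "trim_to_reference", "empty_reference")
    return msa.slice_columns(idx[0], idx[-1] + 1)


def trim_gappy_ends(
    msa: OrthologueAlignment,
    window: int = 20,
    species_frac: float = 0.75,
    max_gaps: int = 5,
) -> OrthologueAlignment:
    """Trim each end to the first window where enough rows are gap-poor.

    The window advances inward one column at a time; it stops at the first
    offset where >= ceil(species_frac * n_rows) rows contain <= max_gaps
    gap/N characters within it. Columns strictly outside the two stopped
    windows' span are removed.
    """
    L, n = msa.length, msa.n_species
    if L < window:
        warnings.warn(
            f"{msa.element_id}: alignment shorter than window ({L} < {window}); "
            "end trimming skipped"
        )
        return msa
    need = math.ceil(species_frac * n)
    gaps = _gap_matrix(msa)
    # per-row rolling gap count over every window offset
    csum = np.concatenate(
        [np.zeros((n, 1), dtype=int), np.cumsum(gaps, axis=1)], axis=1
    )
    win_gaps = csum[:, window:] - csum[:, :-window]  # (n, L - window + 1)
    ok = (win_gaps <= max_gaps).sum(axis=0) >= need  # per offset
    qualifying = np.flatnonzero(ok)
    if qualifying.size == 0:
        raise FilterRejection(msa.element_id, "trim_gappy_ends", "all_gappy")
    left = int(qualifying[0])
    right_stop = int(qualifying[-1])  # rightmost qualifying offset
    right = right_stop + window  # exclusive end of that window
    if right <= left:
        raise FilterRejection(msa.element_id, "trim_gappy_ends", "all_gappy")
    return msa.slice_columns(left, right)


def _gappyout_cutoff(gap_frac: np.ndarray) -> float:
    """Data-driven gap-fraction cutoff (gappyout-style).

    Sort the distinct per-column gap fractions and find the largest jump
    (steepest slope) in the sorted curve; the cutoff sits inside that jump so
    the low-gap cluster is kept and the high-gap cluster removed. With a
    single distinct value no column is removed.
    """
    vals = np.unique(gap_frac)
    if vals.size <= 1:
        return 1.0  # nothing exceeds: identity
    jumps = np.diff(vals)
    k = int(np.argmax(jumps))
    if jumps[k] < 0.1:  # no clear two-cluster structure: leave columns alone
        return 1.0
    return float((vals[k] + vals[k + 1]) / 2.0)


def remove_gappy_columns(
    msa: OrthologueAlignment,
    mode: str = "gappyout",
    fixed_threshold: float = 0.9,
) -> OrthologueAlignment:
    """Remove internal high-gap columns; order of survivors preserved."""
    if msa.length == 0:
        raise FilterRejection(msa.element_id, "remove_gappy_columns", "no_columns")
    gaps = _gap_matrix(msa)
    gap_frac = gaps.mean(axis=0)
    if mode == "fixed":
        cutoff = fixed_threshold
    elif mode == "gappyout":
        cutoff = _gappyout_cutoff(gap_frac)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    keep = [i for i, f in enumerate(gap_frac) if f <= cutoff]
    if not keep:
        raise FilterRejection(msa.element_id, "remove_gappy_columns", "no_columns")
    return msa.take_columns(keep)


def _max_gap_run(seq: str) -> int:
    best = run = 0
    for ch in seq:
        if _is_gap(ch):
            run += 1
            best = max(best, run)
        else:
            run = 0
    return best


def drop_gappy_sequences(
    msa: OrthologueAlignment,
    max_gap_frac: float = 0.25,
    max_run_frac: float = 0.10,
) -> OrthologueAlignment:
    """Drop rows with > max_gap_frac gaps or a gap run > max_run_frac * L.

    The reference row is exempt: if it fails, the whole element is rejected.
    """
    L = msa.length
    if L == 0:
        raise FilterRejection(msa.element_id, "drop_gappy_sequences", "no_columns")
    doomed: set[str] = set()
    for sp, seq in msa.rows.items():
        n_gaps = sum(1 for ch in seq if _is_gap(ch))
        fails = (n_gaps / L) > max_gap_frac or _max_gap_run(seq) > max_run_frac * L
        if fails:
            if sp == msa.reference_species:
                raise FilterRejection(
                    msa.element_id, "drop_gappy_sequences", "reference_gappy"
                )
            doomed.add(sp)
    return msa.drop_species(doomed)


def check_retention(
    msa: OrthologueAlignment, rule: RetentionRule
) -> tuple[bool, str]:
    """Final keep/drop decision on species composition."""
    present = set(msa.rows)
    if len(present) < rule.min_species:
        return False, "too_few_species"
    if rule.required_pairs and not any(
        g in present and s in present for g, s in rule.required_pairs
    ):
        return False, "no_glider_sister_pair"
    for label, members in rule.outgroup_groups.items():
        if not present.intersection(members):
            return False, f"missing_outgroup:{label}"
    return True, "retained"


def filter_alignment(
    msa: OrthologueAlignment,
    rule: RetentionRule,
    window: int = 20,
    species_frac: float = 0.75,
    max_gaps: int = 5,
    column_mode: str = "gappyout",
    fixed_threshold: float = 0.9,
    max_gap_frac: float = 0.25,
    max_run_frac: float = 0.10,
) -> OrthologueAlignment:
    """Run the five stages in order; raises FilterRejection on failure."""
    msa = trim_to_reference(msa)
    msa = trim_gappy_ends(msa, window, species_frac, max_gaps)
    msa = remove_gappy_columns(msa, column_mode, fixed_threshold)
    msa = drop_gappy_sequences(msa, max_gap_frac, max_run_frac)
    ok, reason = check_retention(msa, rule)
    if not ok:
        raise FilterRejection(msa.element_id, "check_retention", reason)
    return msa
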
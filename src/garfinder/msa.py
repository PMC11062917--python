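"""Per-element multiple sequence alignments with species-role metadata.

Rows are aligned sequences over {A,C,G,T,N,-}; one row is the reference
species whose element coordinates anchor the alignment. Roles classify each
species for the retention rule: a glider, the non-gliding sister of a glider,
a member of a named outgroup group, or other ingroup.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = ["SpeciesRoles", "OrthologueAlignment", "read_roles", "write_fasta", "read_fasta"]

ALPHABET = set("ACGTN-")
GAP_CHARS = frozenset("-N")  # gaps and Ns count alike in gap filtering


@dataclass(frozen=True)
class SpeciesRoles:
    """Role table: which species are gliders, sisters, and outgroups.

    ``pairs`` lists (glider, sister) couples; ``outgroup_groups`` maps a group
    label to its member species. Everything else is generic ingroup.
    """

    pairs: tuple[tuple[str, str], ...]
    outgroup_groups: dict[str, tuple[str, ...]]

    @property
    def gliders(self) -> tuple[str, ...]:
        return tuple(g for g, _ in self.pairs)

    def role_of(self, species: str) -> str:
        for g, s in self.pairs:
            if species == g:
                return "glider"
            if species == s:
                return f"sister_of:{g}"
        for label, members in self.outgroup_groups.items():
            if species in members:
                return f"outgroup_group:{label}"
        return "other"


@dataclass
class OrthologueAlignment:
    """One element's alignment: species -> equal-length aligned sequence."""

    element_id: str
    rows: dict[str, str]
    reference_species: str

    def __post_init__(self) -> None:
        if self.reference_species not in self.rows:
            raise ValueError(
                f"{self.element_id}: reference {self.reference_species!r} absent"
            )
        lengths = {len(s) for s in self.rows.values()}
        if len(lengths) > 1:
            raise ValueError(f"{self.element_id}: unequal row lengths {lengths}")
        bad = set("".join(self.rows.values()).upper()) - ALPHABET
        if bad:
            raise ValueError(f"{self.element_id}: invalid characters {bad}")
        self.rows = {sp: s.upper() for sp, s in self.rows.items()}

    @property
    def length(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0

    @property
    def n_species(self) -> int:
        return len(self.rows)

    @property
    def species(self) -> list[str]:
        return list(self.rows)

    def reference_row(self) -> str:
        return self.rows[self.reference_species]

    def slice_columns(self, start: int, stop: int) -> "OrthologueAlignment":
        return OrthologueAlignment(
            self.element_id,
            {sp: s[start:stop] for sp, s in self.rows.items()},
            self.reference_species,
        )

    def take_columns(self, keep: list[int]) -> "OrthologueAlignment":
        return OrthologueAlignment(
            self.element_id,
            {sp: "".join(s[i] for i in keep) for sp, s in self.rows.items()},
            self.reference_species,
        )

    def drop_species(self, names: set[str]) -> "OrthologueAlignment":
        return OrthologueAlignment(
            self.element_id,
            {sp: s for sp, s in self.rows.items() if sp not in names},
            self.reference_species,
        )

    def degapped(self, species: str) -> str:
        return self.rows[species].replace("-", "")


def read_roles(path) -> SpeciesRoles:
    """Read a roles TSV with columns: species, role, group.

    role in {glider, sister, outgroup, other}; for sisters ``group`` names the
    glider they pair with, for outgroups it names the outgroup group.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    pairs: dict[str, str] = {}
    groups: dict[str, list[str]] = {}
    for _, r in df.iterrows():
        if r["role"] == "sister":
            pairs[r["group"]] = r["species"]
        elif r["role"] == "outgroup":
            groups.setdefault(r["group"], []).append(r["species"])
    gliders = df.loc[df["role"] == "glider", "species"].tolist()
    return SpeciesRoles(
        pairs=tuple((g, pairs[g]) for g in gliders),
        outgroup_groups={k: tuple(v) for k, v in groups.items()},
    )


def write_fasta(rows: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in rows.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
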
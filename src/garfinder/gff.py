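"""Minimal GFF3 reading/writing for gene models.

Handles the 9-column GFF3 the pipeline itself writes and reads back:
``gene`` / ``mRNA`` / ``exon`` features with ``ID`` and ``Parent`` attributes.
Coordinates are converted between GFF3's 1-based closed dialect and the
package's 0-based half-open internal one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .intervals import GenomicInterval, IntervalSet

__all__ = ["Transcript", "GeneModel", "read_gff3", "write_gff3", "exon_interval_set"]


@dataclass
class Transcript:
    transcript_id: str
    strand: str
    exons: list[GenomicInterval] = field(default_factory=list)  # sorted by start

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def start(self) -> int:
        return min(e.start for e in self.exons)

    @property
    def end(self) -> int:
        return max(e.end for e in self.exons)

    def length(self) -> int:
        return self.end - self.start


@dataclass
class GeneModel:
    gene_id: str
    transcripts: list[Transcript] = field(default_factory=list)

    @property
    def chrom(self) -> str:
        return self.transcripts[0].chrom

    @property
    def strand(self) -> str:
        return self.transcripts[0].strand

    @property
    def start(self) -> int:
        return min(t.start for t in self.transcripts)

    @property
    def end(self) -> int:
        return max(t.end for t in self.transcripts)

    def longest_transcript(self) -> Transcript:
        """Representative transcript: longest genomic span, ties by id."""
        return max(self.transcripts, key=lambda t: (t.length(), t.transcript_id))

    def span(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, self.gene_id, self.strand)


def _parse_attrs(s: str) -> dict[str, str]:
    out = {}
    for part in s.strip().split(";"):
        if "=" in part:
            k, v = part.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def read_gff3(path) -> list[GeneModel]:
    """Parse gene/mRNA/exon features into :class:`GeneModel` records."""
    genes: dict[str, GeneModel] = {}
    transcripts: dict[str, tuple[str, Transcript]] = {}  # tid -> (gene_id, tx)
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) != 9:
                raise ValueError(f"{path}: malformed GFF3 line: {line!r}")
            chrom, _, ftype, start1, end1, _, strand, _, attrs = f
            a = _parse_attrs(attrs)
            start, end = int(start1) - 1, int(end1)
            if ftype == "gene":
                gid = a["ID"]
                genes.setdefault(gid, GeneModel(gid))
            elif ftype in ("mRNA", "transcript"):
                tid, gid = a["ID"], a["Parent"]
                tx = Transcript(tid, strand)
                transcripts[tid] = (gid, tx)
                genes.setdefault(gid, GeneModel(gid)).transcripts.append(tx)
            elif ftype == "exon":
                parent = a["Parent"]
                if parent not in transcripts:
                    # exon attached directly to a gene (single-transcript shorthand)
                    gid = parent
                    tid = f"{gid}.t1"
                    if tid not in transcripts:
                        tx = Transcript(tid, strand)
                        transcripts[tid] = (gid, tx)
                        genes.setdefault(gid, GeneModel(gid)).transcripts.append(tx)
                tx = transcripts[parent][1] if parent in transcripts else transcripts[tid][1]
                tx.exons.append(GenomicInterval(chrom, start, end, strand=strand))
    out = []
    for g in genes.values():
        g.transcripts = [t for t in g.transcripts if t.exons]
        for t in g.transcripts:
            t.exons.sort(key=lambda e: e.start)
        if g.transcripts:
            out.append(g)
    out.sort(key=lambda g: (g.chrom, g.start, g.gene_id))
    return out


def write_gff3(genes: list[GeneModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.chrom, g.start, g.gene_id)):
            fh.write(
                f"{g.chrom}\tgarfinder\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\tID={g.gene_id}\n"
            )
            for t in g.transcripts:
                fh.write(
                    f"{g.chrom}\tgarfinder\tmRNA\t{t.start + 1}\t{t.end}\t.\t"
                    f"{t.strand}\t.\tID={t.transcript_id};Parent={g.gene_id}\n"
                )
                for e in t.exons:
                    fh.write(
                        f"{g.chrom}\tgarfinder\texon\t{e.start + 1}\t{e.end}\t.\t"
                        f"{t.strand}\t.\tParent={t.transcript_id}\n"
                    )


def exon_interval_set(genes: list[GeneModel]) -> IntervalSet:
    """All exons of all transcripts, as an IntervalSet labelled ``exons``."""
    ivs = [
        GenomicInterval(e.chrom, e.start, e.end, id=g.gene_id, strand=t.strand)
        for g in genes
        for t in g.transcripts
        for e in t.exons
    ]
    return IntervalSet(ivs, source_label="exons")
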
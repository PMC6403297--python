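"""Gene models (gene → transcript → exon/CDS) and GFF3 input/output.

Intervals are 0-based half-open internally; GFF3 files are 1-based inclusive.
"""

from __future__ import annotations

import dataclasses
import tempfile
from pathlib import Path

import gffutils


@dataclasses.dataclass(frozen=True)
class Transcript:
    transcript_id: str
    exons: tuple[tuple[int, int], ...]  # genomic order, 0-based half-open
    cds: tuple[tuple[int, int], ...]  # genomic order, subset of exons

    def __post_init__(self) -> None:
        for ivs in (self.exons, self.cds):
            prev_end = -1
            for s, e in ivs:
                if s >= e:
                    raise ValueError(f"empty interval in {self.transcript_id}")
                if s < prev_end:
                    raise ValueError(f"overlapping intervals in {self.transcript_id}")
                prev_end = e

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds)

    def introns(self) -> list[tuple[int, int]]:
        return [
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
            if self.exons[i + 1][0] > self.exons[i][1]
        ]


@dataclasses.dataclass(frozen=True)
class GeneModel:
    gene_id: str
    chromosome: str
    strand: str  # '+' or '-'
    transcripts: tuple[Transcript, ...]
    span: tuple[int, int] | None = None  # explicit span for transcript-less genes

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r} for {self.gene_id}")
        if not self.transcripts and self.span is None:
            raise ValueError(f"gene {self.gene_id} has no transcripts and no span")

    @property
    def bounds(self) -> tuple[int, int]:
        if self.transcripts:
            starts, ends = zip(*(t.span for t in self.transcripts))
            return min(starts), max(ends)
        return self.span  # type: ignore[return-value]


def write_gff3(path: str | Path, genes: list[GeneModel]) -> None:
    """Write gene models as GFF3 (1-based inclusive coordinates)."""
    lines = ["##gff-version 3"]
    for g in sorted(genes, key=lambda g: (g.chromosome, g.bounds)):
        gs, ge = g.bounds
        lines.append(
            f"{g.chromosome}\tbridgemark\tgene\t{gs + 1}\t{ge}\t.\t{g.strand}\t.\t"
            f"ID={g.gene_id}"
        )
        for t in g.transcripts:
            ts, te = t.span
            lines.append(
                f"{g.chromosome}\tbridgemark\tmRNA\t{ts + 1}\t{te}\t.\t{g.strand}\t.\t"
                f"ID={t.transcript_id};Parent={g.gene_id}"
            )
            for i, (s, e) in enumerate(t.exons, 1):
                lines.append(
                    f"{g.chromosome}\tbridgemark\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                    f"ID={t.transcript_id}.exon{i};Parent={t.transcript_id}"
                )
            # CDS phase: number of bases to skip before the first full codon,
            # accumulated along the coding strand
            cds = list(t.cds) if g.strand == "+" else list(reversed(t.cds))
            done = 0
            phases = []
            for s, e in cds:
                phases.append((s, e, (3 - done % 3) % 3))
                done += e - s
            for s, e, phase in sorted(phases):
                lines.append(
                    f"{g.chromosome}\tbridgemark\tCDS\t{s + 1}\t{e}\t.\t{g.strand}\t"
                    f"{phase}\tID={t.transcript_id}.cds;Parent={t.transcript_id}"
                )
    Path(path).write_text("\n".join(lines) + "\n")


def read_gff3(path: str | Path) -> list[GeneModel]:
    """Load gene models from GFF3 via gffutils (in-memory database)."""
    db = gffutils.create_db(
        str(path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    genes: list[GeneModel] = []
    for g in db.features_of_type("gene"):
        transcripts = []
        for t in db.children(g, featuretype="mRNA"):
            exons = tuple(
                sorted((f.start - 1, f.end) for f in db.children(t, featuretype="exon"))
            )
            cds = tuple(
                sorted((f.start - 1, f.end) for f in db.children(t, featuretype="CDS"))
            )
            transcripts.append(Transcript(t.id, exons, cds))
        genes.append(
            GeneModel(
                gene_id=g.id,
                chromosome=g.seqid,
                strand=g.strand,
                transcripts=tuple(transcripts),
                span=(g.start - 1, g.end) if not transcripts else None,
            )
        )
    return genes
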
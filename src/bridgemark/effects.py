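"""Functional classification of InDels against gene models.

Each InDel receives exactly one primary category, the most severe of its
per-transcript effects. Coding effects are decided at codon level by
rebuilding the spliced CDS with and without the variant, so that a
classification like "codon insertion" versus "codon change plus codon
insertion" reflects the actual protein-level consequence rather than raw
coordinate geometry (an in-frame insertion inside a homopolymer codon run can
spell out a pure codon insertion even though it straddles a codon boundary).

Severity order, highest first: StartLost > StopGained > StopLost >
FrameShift > CodonChangePlusCodonInsertion/Deletion > CodonInsertion/
CodonDeletion > SpliceSiteAcceptor/Donor > Intron > Upstream5kb >
Downstream5kb > IntragenicNoTranscript > Intergenic. ``Other`` is a sink for
unclassifiable records and ranks lowest.
"""

from __future__ import annotations

import dataclasses
import enum
import warnings
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio.Seq import Seq
from intervaltree import IntervalTree

from .genes import GeneModel, Transcript
from .variants import InDelVariant

SPLICE_WINDOW = 2  # bp at either intron end treated as splice site
DEFAULT_FLANK_BP = 5_000


class EffectCategory(enum.IntEnum):
    """Functional categories; the integer value encodes severity (higher =
    more severe)."""

    Other = 0
    Intergenic = 1
    IntragenicNoTranscript = 2
    Downstream5kb = 3
    Upstream5kb = 4
    Intron = 5
    SpliceSiteDonor = 6
    SpliceSiteAcceptor = 7
    CodonDeletion = 8
    CodonInsertion = 9
    CodonChangePlusCodonDeletion = 10
    CodonChangePlusCodonInsertion = 11
    FrameShift = 12
    StopLost = 13
    StopGained = 14
    StartLost = 15


#: categories counted as lying inside a gene (transcript span or
#: transcript-less gene body); used for the genic fraction
GENIC_CATEGORIES = frozenset(
    {
        EffectCategory.IntragenicNoTranscript,
        EffectCategory.Intron,
        EffectCategory.SpliceSiteDonor,
        EffectCategory.SpliceSiteAcceptor,
        EffectCategory.CodonDeletion,
        EffectCategory.CodonInsertion,
        EffectCategory.CodonChangePlusCodonDeletion,
        EffectCategory.CodonChangePlusCodonInsertion,
        EffectCategory.FrameShift,
        EffectCategory.StopLost,
        EffectCategory.StopGained,
        EffectCategory.StartLost,
    }
)

STOP_CODONS = {"TAA", "TAG", "TGA"}


@dataclasses.dataclass(frozen=True)
class EffectAnnotation:
    variant: InDelVariant
    per_transcript: tuple[tuple[str, EffectCategory], ...]
    primary: EffectCategory
    gene_id: str | None


class GeneModelIndex:
    """Interval index over gene bodies (plus flanks) for fast lookup."""

    def __init__(self, genes: Iterable[GeneModel], flank_bp: int = DEFAULT_FLANK_BP):
        self.flank_bp = flank_bp
        self._trees: dict[str, IntervalTree] = {}
        for g in genes:
            s, e = g.bounds
            self._trees.setdefault(g.chromosome, IntervalTree()).addi(
                max(0, s - flank_bp), e + flank_bp, g
            )

    def candidates(self, chromosome: str, start0: int, end0: int) -> list[GeneModel]:
        tree = self._trees.get(chromosome)
        if tree is None:
            return []
        return sorted((iv.data for iv in tree.overlap(start0, end0)),
                      key=lambda g: g.gene_id)

    def has_chromosome(self, chromosome: str) -> bool:
        return chromosome in self._trees


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def _splice_cds(chrom_seq: str, t: Transcript, strand: str) -> str:
    s = "".join(chrom_seq[a:b] for a, b in t.cds)
    return s if strand == "+" else _revcomp(s)


def _mutant_cds(chrom_seq: str, t: Transcript, strand: str, v: InDelVariant) -> str:
    """Spliced CDS with the variant applied (coding-strand orientation).

    A deletion removes the intersection of its deleted span with the CDS; an
    insertion adds its bases at the mapped coding coordinate of its anchor
    point (insertions at an exon boundary attach to the exonic side).
    """
    pieces: list[str] = []
    if v.is_insertion:
        gap = v.start0 + 1  # 0-based index the inserted bases precede
        for a, b in t.cds:
            seg = chrom_seq[a:b]
            if a < gap <= b:
                off = gap - a
                seg = seg[:off] + v.inserted + seg[off:]
            pieces.append(seg)
    else:
        ds, de = v.start0 + 1, v.end0  # deleted genomic span
        for a, b in t.cds:
            lo, hi = max(a, ds), min(b, de)
            if lo < hi:
                pieces.append(chrom_seq[a:lo] + chrom_seq[hi:b])
            else:
                pieces.append(chrom_seq[a:b])
    s = "".join(pieces)
    return s if strand == "+" else _revcomp(s)


def _translate(cds: str) -> str:
    """Translate up to (not including) the first stop codon."""
    prot = []
    for i in range(0, len(cds) - len(cds) % 3, 3):
        aa = str(Seq(cds[i : i + 3]).translate())
        if aa == "*":
            break
        prot.append(aa)
    return "".join(prot)


def _classify_coding(wild: str, mut: str) -> EffectCategory:
    """Decide the coding-effect category from wild and mutant spliced CDS."""
    if (len(mut) - len(wild)) % 3 != 0:
        return EffectCategory.FrameShift
    if wild[:3] == "ATG" and mut[:3] != "ATG":
        return EffectCategory.StartLost
    wild_has_stop = wild[-3:] in STOP_CODONS
    # premature stop: a stop codon strictly before the mutant's last codon
    body = mut[:-3] if wild_has_stop else mut
    if any(body[i : i + 3] in STOP_CODONS for i in range(0, len(body) - 2, 3)):
        # only "gained" if the wild body was stop-free
        wbody = wild[:-3] if wild_has_stop else wild
        if not any(wbody[i : i + 3] in STOP_CODONS for i in range(0, len(wbody) - 2, 3)):
            return EffectCategory.StopGained
    if wild_has_stop and mut[-3:] not in STOP_CODONS:
        return EffectCategory.StopLost
    # pure codon indel vs codon change plus indel, at protein level
    p = _translate(wild)
    q = _translate(mut)
    insertion = len(mut) > len(wild)
    short, long_ = (p, q) if insertion else (q, p)
    pre = 0
    while pre < len(short) and short[pre] == long_[pre]:
        pre += 1
    suf = 0
    while suf < len(short) - pre and short[-1 - suf] == long_[-1 - suf]:
        suf += 1
    pure = pre + suf >= len(short)
    if insertion:
        return (
            EffectCategory.CodonInsertion
            if pure
            else EffectCategory.CodonChangePlusCodonInsertion
        )
    return (
        EffectCategory.CodonDeletion
        if pure
        else EffectCategory.CodonChangePlusCodonDeletion
    )


def _overlaps_cds(v: InDelVariant, t: Transcript) -> bool:
    if v.is_insertion:
        gap = v.start0 + 1
        # anchor-in-CDS rule: an insertion whose anchor base is the last base
        # of a CDS segment attaches to the exonic side of the boundary
        return any(a < gap <= b for a, b in t.cds)
    ds, de = v.start0 + 1, v.end0
    return any(max(a, ds) < min(b, de) for a, b in t.cds)


def _splice_site_category(
    v: InDelVariant, t: Transcript, strand: str
) -> EffectCategory | None:
    """Splice-site check: variant touching the first/last SPLICE_WINDOW bases
    of an intron (donor = transcription-5' end, acceptor = 3' end)."""
    if v.is_insertion:
        lo, hi = v.start0 + 1, v.start0 + 1  # point insertion
    else:
        lo, hi = v.start0 + 1, v.end0
    for is_, ie in t.introns():
        donor = (is_, is_ + SPLICE_WINDOW) if strand == "+" else (ie - SPLICE_WINDOW, ie)
        acceptor = (ie - SPLICE_WINDOW, ie) if strand == "+" else (is_, is_ + SPLICE_WINDOW)
        if v.is_insertion:
            # insertion disrupts the motif only if it lands strictly inside it
            if donor[0] < lo < donor[1]:
                return EffectCategory.SpliceSiteDonor
            if acceptor[0] < lo < acceptor[1]:
                return EffectCategory.SpliceSiteAcceptor
        else:
            if max(lo, donor[0]) < min(hi, donor[1]):
                return EffectCategory.SpliceSiteDonor
            if max(lo, acceptor[0]) < min(hi, acceptor[1]):
                return EffectCategory.SpliceSiteAcceptor
    return None


def classify_transcript(
    v: InDelVariant, t: Transcript, strand: str, chrom_seq: str
) -> EffectCategory | None:
    """Category of the variant with respect to one transcript, or None when
    the variant lies outside the transcript span."""
    ts, te = t.span
    if v.is_insertion:
        inside = ts <= v.start0 < te
    else:
        inside = max(ts, v.start0 + 1) < min(te, v.end0)
    if t.cds and _overlaps_cds(v, t):
        wild = _splice_cds(chrom_seq, t, strand)
        if len(wild) % 3 != 0:  # malformed model: skip transcript
            warnings.warn(f"CDS length of {t.transcript_id} not divisible by 3; skipped")
            return None
        mut = _mutant_cds(chrom_seq, t, strand, v)
        cat = _classify_coding(wild, mut)
        # a frameshifting deletion can simultaneously hit a splice site; the
        # coding call is the more severe and wins
        return cat
    splice = _splice_site_category(v, t, strand)
    if splice is not None:
        return splice
    if inside:
        return EffectCategory.Intron
    return None


def classify(
    variant: InDelVariant,
    index: GeneModelIndex,
    reference: Mapping[str, str],
    flank_bp: int = DEFAULT_FLANK_BP,
) -> EffectAnnotation:
    """Assign the primary functional category of one InDel.

    Looks at every transcript of every gene whose flanked span covers the
    variant; the primary category is the most severe per-transcript call.
    Variants outside all transcripts but within ``flank_bp`` of one are
    Upstream5kb/Downstream5kb of the nearest gene (ties resolve to the
    upstream relation); inside a transcript-less gene body the category is
    IntragenicNoTranscript; otherwise Intergenic.
    """
    if not index.has_chromosome(variant.chromosome):
        warnings.warn(f"chromosome {variant.chromosome} absent from gene models")
        return EffectAnnotation(variant, (), EffectCategory.Intergenic, None)

    vlo, vhi = variant.start0, variant.end0
    # changed region: deleted span, or the zero-width insertion gap
    if variant.is_insertion:
        c_lo = c_hi = variant.start0 + 1
    else:
        c_lo, c_hi = variant.start0 + 1, variant.end0
    per_transcript: list[tuple[str, EffectCategory]] = []
    best: tuple[EffectCategory, str | None] = (EffectCategory.Intergenic, None)
    flank_hits: list[tuple[int, int, EffectCategory, str]] = []  # (dist, pref, cat, gene)

    for gene in index.candidates(variant.chromosome, vlo, vhi):
        chrom_seq = reference[variant.chromosome]
        gs, ge = gene.bounds
        in_body = max(gs, vlo) < min(ge, vhi) or (variant.is_insertion and gs <= vlo < ge)
        if not gene.transcripts:
            if in_body and best[0] < EffectCategory.IntragenicNoTranscript:
                best = (EffectCategory.IntragenicNoTranscript, gene.gene_id)
            continue
        hit_transcript = False
        for t in gene.transcripts:
            cat = classify_transcript(variant, t, gene.strand, chrom_seq)
            if cat is not None:
                hit_transcript = True
                per_transcript.append((t.transcript_id, cat))
                if cat > best[0]:
                    best = (cat, gene.gene_id)
        if not hit_transcript:
            # flanking relation, strand-aware; distance of the changed
            # region from the nearer gene edge
            if c_hi <= gs:
                dist = gs - c_hi
                upstream = gene.strand == "+"
            elif c_lo >= ge:
                dist = c_lo - ge
                upstream = gene.strand == "-"
            else:
                continue  # inside gene body but between transcripts: skip
            if dist <= flank_bp:
                cat = EffectCategory.Upstream5kb if upstream else EffectCategory.Downstream5kb
                flank_hits.append((dist, 0 if upstream else 1, cat, gene.gene_id))

    if best[0] <= EffectCategory.IntragenicNoTranscript and flank_hits:
        if best[0] < EffectCategory.Upstream5kb:
            flank_hits.sort(key=lambda h: (h[0], h[1], h[3]))
            dist, _, cat, gid = flank_hits[0]
            best = (cat, gid)
    return EffectAnnotation(variant, tuple(per_transcript), best[0], best[1])


def classify_all(
    variants: Sequence[InDelVariant],
    genes: Iterable[GeneModel],
    reference: Mapping[str, str],
    flank_bp: int = DEFAULT_FLANK_BP,
) -> list[EffectAnnotation]:
    index = GeneModelIndex(genes, flank_bp)
    return [classify(v, index, reference, flank_bp) for v in variants]


def summarize_effects(annotations: Iterable[EffectAnnotation]) -> pd.DataFrame:
    """Counts per category plus the genic fraction (percent of variants in
    gene bodies: coding, splice, intron or transcript-less gene categories)."""
    counts = {cat.name: 0 for cat in EffectCategory}
    total = 0
    genic = 0
    for a in annotations:
        counts[a.primary.name] += 1
        total += 1
        if a.primary in GENIC_CATEGORIES:
            genic += 1
    df = pd.DataFrame(
        {"count": pd.Series(counts, dtype=int)},
    )
    df.attrs["total"] = total
    df.attrs["genic_count"] = genic
    df.attrs["genic_fraction_pct"] = round(100 * genic / total, 1) if total else 0.0
    return df


def genic_fraction_pct(genic_count: int, total: int) -> float:
    """Percent of InDels in gene regions, 1 decimal (half-even)."""
    return round(100 * genic_count / total, 1)
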
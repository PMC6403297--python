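"""Anchored InDel representation, normalization and VCF/BED input-output.

Coordinate conventions
----------------------
Variants are stored VCF-style: ``position`` is the 1-based coordinate of the
anchor base, and REF/ALT share that single leading reference base. Interval
arithmetic (identity intervals, variant footprints) is 0-based half-open
internally; BED files are written 0-based half-open, VCF 1-based.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Mapping

import pysam
from intervaltree import IntervalTree


class UnsupportedRecordError(ValueError):
    """Raised for records that are not simple bi-allelic InDels."""


@dataclasses.dataclass(frozen=True, order=True)
class InDelVariant:
    """One anchored insertion or deletion against a named reference chromosome.

    ``ref_allele`` and ``alt_allele`` share their first (anchor) base; the
    variant is a deletion when REF is longer and an insertion when ALT is
    longer. ``size`` is the absolute length difference in bp.
    """

    chromosome: str
    position: int  # 1-based anchor coordinate
    ref_allele: str
    alt_allele: str

    def __post_init__(self) -> None:
        if len(self.ref_allele) == len(self.alt_allele):
            raise ValueError(
                f"not an InDel: REF={self.ref_allele} ALT={self.alt_allele}"
            )
        if not self.ref_allele or not self.alt_allele:
            raise ValueError("empty allele")
        if self.ref_allele[0] != self.alt_allele[0]:
            raise ValueError(
                f"alleles not anchored: REF={self.ref_allele} ALT={self.alt_allele}"
            )
        if self.position < 1:
            raise ValueError("position must be 1-based and positive")

    @property
    def size(self) -> int:
        return abs(len(self.ref_allele) - len(self.alt_allele))

    @property
    def kind(self) -> str:
        return "deletion" if len(self.ref_allele) > len(self.alt_allele) else "insertion"

    @property
    def is_insertion(self) -> bool:
        return len(self.alt_allele) > len(self.ref_allele)

    @property
    def start0(self) -> int:
        """0-based start of the reference footprint (the anchor base)."""
        return self.position - 1

    @property
    def end0(self) -> int:
        """0-based half-open end of the reference footprint."""
        return self.position - 1 + len(self.ref_allele)

    @property
    def inserted(self) -> str:
        """Bases added by an insertion (empty for deletions)."""
        return self.alt_allele[1:] if self.is_insertion else ""

    @property
    def deleted(self) -> str:
        """Bases removed by a deletion (empty for insertions)."""
        return self.ref_allele[1:] if not self.is_insertion else ""

    def key(self) -> tuple:
        return (self.chromosome, self.position, self.ref_allele, self.alt_allele)


def normalize_variant(
    chromosome: str,
    position: int,
    ref: str,
    alt: str,
    reference: Mapping[str, str],
) -> InDelVariant:
    """Left-align and anchor a raw VCF-style InDel record.

    The record is first trimmed of shared trailing and (all but one) shared
    leading bases, then shifted left while the base preceding the event equals
    the last base of the varying allele — the standard left-alignment used by
    variant normalizers. Idempotent. SNPs/MNPs and symbolic or multi-allelic
    ALTs must be filtered by the caller and raise :class:`UnsupportedRecordError`.
    """
    ref = ref.upper()
    alt = alt.upper()
    if not ref or not alt or "," in alt:
        raise UnsupportedRecordError(f"unsupported record at {chromosome}:{position}")
    if any(c not in "ACGTN" for c in ref + alt):
        raise UnsupportedRecordError(f"symbolic allele at {chromosome}:{position}")
    if len(ref) == len(alt):
        raise UnsupportedRecordError(f"not an InDel at {chromosome}:{position}")

    seq = reference[chromosome]
    # truncate shared trailing bases, extending left through repeats whenever
    # an allele would become empty (standard left-alignment)
    while ref[-1] == alt[-1] and (len(ref) > 1 or len(alt) > 1):
        tail = ref[-1]
        ref, alt = ref[:-1], alt[:-1]
        if not ref or not alt:
            if position == 1:  # at chromosome start: cannot extend further
                ref, alt = ref + tail, alt + tail
                break
            prev = seq[position - 2].upper()
            ref, alt = prev + ref, prev + alt
            position -= 1
    # trim shared leading bases down to a single anchor
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        position += 1
    if min(len(ref), len(alt)) != 1 or ref[0] != alt[0]:
        raise UnsupportedRecordError(f"complex substitution at {chromosome}:{position}")
    return InDelVariant(chromosome, position, ref, alt)


@dataclasses.dataclass
class VariantCallSet:
    """All InDels of one accession versus a named reference, with optional
    intervals where the accession is confirmed identical to the reference."""

    accession_id: str
    reference_id: str
    variants: list[InDelVariant]
    identity_intervals: dict[str, IntervalTree] = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        self.variants = sorted(self.variants, key=InDelVariant.key)
        prev: InDelVariant | None = None
        for v in self.variants:
            if prev and prev.chromosome == v.chromosome and v.start0 < prev.end0:
                raise ValueError(
                    f"overlapping variants in {self.accession_id}: "
                    f"{prev.chromosome}:{prev.position} and {v.position}"
                )
            prev = v

    def variant_tree(self) -> dict[str, IntervalTree]:
        """Interval tree of variant footprints per chromosome (0-based)."""
        trees: dict[str, IntervalTree] = {}
        for v in self.variants:
            trees.setdefault(v.chromosome, IntervalTree()).addi(v.start0, v.end0, v)
        return trees

    def confirmed(self, chromosome: str, start0: int, end0: int) -> bool:
        """True when [start0, end0) lies entirely inside identity intervals."""
        tree = self.identity_intervals.get(chromosome)
        if tree is None:
            return False
        pos = start0
        for iv in sorted(tree.overlap(start0, end0)):
            if iv.begin > pos:
                return False
            pos = max(pos, iv.end)
        return pos >= end0


# ---------------------------------------------------------------------------
# file I/O


def write_vcf(
    path: str | Path,
    variants: Iterable[InDelVariant],
    contigs: Mapping[str, int],
    sample_id: str,
    info_tags: Mapping[tuple, str] | None = None,
) -> None:
    """Write anchored InDels as minimal VCF v4.2 (deterministic text)."""
    lines = ["##fileformat=VCFv4.2", "##source=bridgemark"]
    for name, length in contigs.items():
        lines.append(f"##contig=<ID={name},length={length}>")
    if info_tags is not None:
        lines.append(
            '##INFO=<ID=CARRIER,Number=1,Type=String,'
            'Description="Accession carrying the InDel">'
        )
    lines.append(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    for v in sorted(variants, key=InDelVariant.key):
        info = "."
        if info_tags is not None:
            tag = info_tags.get(v.key())
            info = f"CARRIER={tag}" if tag else "."
        lines.append(
            f"{v.chromosome}\t{v.position}\t.\t{v.ref_allele}\t{v.alt_allele}"
            f"\t.\tPASS\t{info}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_vcf(path: str | Path, reference: Mapping[str, str]) -> list[InDelVariant]:
    """Read InDels from a VCF, normalizing each record; non-InDel records
    (SNPs, multi-allelic or symbolic ALTs) are skipped."""
    out: list[InDelVariant] = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            if rec.alts is None or len(rec.alts) != 1:
                continue
            try:
                out.append(
                    normalize_variant(rec.chrom, rec.pos, rec.ref, rec.alts[0], reference)
                )
            except UnsupportedRecordError:
                continue
    return out


def write_bed(path: str | Path, intervals: Mapping[str, IntervalTree]) -> None:
    """Write identity intervals as BED (0-based half-open)."""
    lines = []
    for chrom in sorted(intervals):
        for iv in sorted(intervals[chrom]):
            lines.append(f"{chrom}\t{iv.begin}\t{iv.end}")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_bed(path: str | Path) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        chrom, start, end = line.split("\t")[:3]
        trees.setdefault(chrom, IntervalTree()).addi(int(start), int(end))
    return trees
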
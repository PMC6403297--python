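"""Reference-bridged InDel comparison between two resequenced accessions.

Each accession is described by its InDels versus a shared reference plus
intervals where it is confirmed identical to that reference. An InDel of
accession A is accepted as a real A-vs-B difference only when B carries no
variant near the locus AND B is confirmed reference-identical across the
locus plus a small symmetric window (default 10 bp) — the operational
reading of "identical sequences around the InDel". Variants shared
identically by both accessions are not differences; loci where the two
accessions carry different overlapping variants are emitted once, tagged
``both-different``.
"""

from __future__ import annotations

import dataclasses
from collections import Counter
from typing import Mapping, Sequence

import pandas as pd

from .variants import InDelVariant, VariantCallSet

DEFAULT_WINDOW = 10  # bp of confirmed identity required either side of a locus

CARRIER_BOTH = "both-different"


@dataclasses.dataclass
class BridgeResult:
    pair: tuple[str, str]
    indels: list[tuple[InDelVariant, str]]  # (variant, carrier)
    excluded_shared: int
    excluded_unconfirmed: int

    @property
    def variants(self) -> list[InDelVariant]:
        return [v for v, _ in self.indels]


def bridge_compare(
    set_a: VariantCallSet, set_b: VariantCallSet, window_w: int = DEFAULT_WINDOW
) -> BridgeResult:
    """Infer the InDel differences between two accessions via the reference.

    For each InDel v of A with footprint [s, e) the window [s-w, e+w) must be
    free of B variants and fully inside B's identity intervals for v to be
    emitted with carrier A (and symmetrically for B). Shared identical
    variants count in ``excluded_shared`` (once per shared locus); windows
    that fail identity confirmation count in ``excluded_unconfirmed``.
    """
    if set_a.reference_id != set_b.reference_id:
        raise ValueError(
            f"call sets are against different references: "
            f"{set_a.reference_id!r} vs {set_b.reference_id!r}"
        )
    keys = {set_a.accession_id: {v.key() for v in set_a.variants},
            set_b.accession_id: {v.key() for v in set_b.variants}}
    trees = {set_a.accession_id: set_a.variant_tree(),
             set_b.accession_id: set_b.variant_tree()}
    emitted: list[tuple[InDelVariant, str]] = []
    shared = 0
    unconfirmed = 0
    both_seen: set[tuple] = set()
    for own, other in ((set_a, set_b), (set_b, set_a)):
        first_pass = own is set_a
        other_keys = keys[other.accession_id]
        other_tree = trees[other.accession_id]
        for v in own.variants:
            if v.key() in other_keys:
                if first_pass:
                    shared += 1
                continue
            lo, hi = v.start0 - window_w, v.end0 + window_w
            hits = other_tree.get(v.chromosome)
            overlapping = hits.overlap(lo, hi) if hits is not None else set()
            touching = [iv for iv in overlapping if iv.begin < v.end0 and iv.end > v.start0]
            if touching:
                # different variants at the same locus
                locus = (v.chromosome, min(v.start0, min(iv.begin for iv in touching)))
                if first_pass:
                    emitted.append((v, CARRIER_BOTH))
                    both_seen.add(locus)
                elif locus not in both_seen:
                    emitted.append((v, CARRIER_BOTH))
                    both_seen.add(locus)
                continue
            if overlapping:
                # a nearby variant of the other accession spoils the window
                unconfirmed += 1
                continue
            if not other.confirmed(v.chromosome, max(0, lo), hi):
                unconfirmed += 1
                continue
            emitted.append((v, own.accession_id))
    emitted.sort(key=lambda t: t[0].key())
    return BridgeResult(
        pair=(set_a.accession_id, set_b.accession_id),
        indels=emitted,
        excluded_shared=shared,
        excluded_unconfirmed=unconfirmed,
    )


# ---------------------------------------------------------------------------
# summaries (per-chromosome density table and size histogram)


@dataclasses.dataclass
class IndelSummary:
    per_chromosome: pd.DataFrame  # index chromosome; count, length_mb, density
    size_histogram: dict[int, int]  # full 1..49 detail
    total_count: int
    total_length_mb: float
    overall_density: float

    def table_bins(self) -> pd.DataFrame:
        """Histogram in presentation bins 1..10 and >=11, with percentages."""
        rows = []
        for s in range(1, 11):
            rows.append((str(s), self.size_histogram.get(s, 0)))
        rows.append((">=11", sum(c for s, c in self.size_histogram.items() if s >= 11)))
        df = pd.DataFrame(rows, columns=["size_bp", "count"]).set_index("size_bp")
        total = self.total_count
        df["ratio_pct"] = [
            round(100 * c / total, 1) if total else 0.0 for c in df["count"]
        ]
        return df


def _density(count: int, length_mb: float) -> float:
    if length_mb <= 0:
        raise ValueError("chromosome length must be positive")
    return round(count / length_mb, 1)  # round-half-even, 1 decimal


def summarize(
    indels: Sequence[InDelVariant] | Mapping[str, int],
    chromosome_lengths_mb: Mapping[str, float],
    size_histogram: Mapping[int, int] | None = None,
) -> IndelSummary:
    """Per-chromosome counts and densities (InDels/Mb, 1 decimal) plus the
    size histogram. Accepts either a variant list or precomputed
    per-chromosome counts (then ``size_histogram`` supplies sizes)."""
    if isinstance(indels, Mapping):
        counts = dict(indels)
        hist = Counter(
            {int(s): int(c) for s, c in (size_histogram or {}).items()}
        )
    else:
        counts = Counter(v.chromosome for v in indels)
        hist = Counter(v.size for v in indels)
    for chrom in counts:
        if chrom not in chromosome_lengths_mb:
            raise ValueError(f"no length provided for chromosome {chrom}")
    rows = {}
    for chrom in chromosome_lengths_mb:
        n = counts.get(chrom, 0)
        length = chromosome_lengths_mb[chrom]
        rows[chrom] = {"count": n, "length_mb": length, "density": _density(n, length)}
    per_chrom = pd.DataFrame.from_dict(rows, orient="index")
    total = int(per_chrom["count"].sum())
    total_len = float(per_chrom["length_mb"].sum())
    return IndelSummary(
        per_chromosome=per_chrom,
        size_histogram=dict(sorted(hist.items())),
        total_count=total,
        total_length_mb=total_len,
        overall_density=_density(total, total_len),
    )


def size_fraction(
    summary: IndelSummary | Mapping[int, int], max_size_inclusive: int
) -> float:
    """Percent of InDels of size <= max_size_inclusive, 1 decimal."""
    hist = summary.size_histogram if isinstance(summary, IndelSummary) else summary
    total = sum(hist.values())
    if total == 0:
        raise ValueError("empty size histogram")
    le = sum(c for s, c in hist.items() if s <= max_size_inclusive)
    return round(100 * le / total, 1)
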
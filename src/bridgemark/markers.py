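"""PCR marker design from InDels: uniform selection, flank extraction,
primer-pair constraint search, in-silico product-size prediction and outcome
classification.

Primers satisfy length 19-22 nt, melting temperature 52-60 deg C, GC 40-60%,
reference product 80-250 bp and a pair Tm difference of at most 3 deg C. The
melting temperature uses the GC-count formula Tm = 64.9 + 41 x (nGC - 16.4)/N,
standard for primers of this length; the formula is pluggable. A marker is
codominant between two accessions when both amplify and the product sizes
differ by at least the gel's resolvable minimum (3 bp for 10% PAGE).
"""

from __future__ import annotations

import dataclasses
from typing import Callable, Mapping, Sequence

import numpy as np

from .variants import InDelVariant, VariantCallSet

_COMP = bytes.maketrans(b"ACGT", b"TGCA")


def revcomp(seq: str) -> str:
    return seq.encode().translate(_COMP)[::-1].decode()


def wallace_tm(n_gc: int, length: int) -> float:
    """GC-count melting temperature for 19-22-mers."""
    return 64.9 + 41.0 * (n_gc - 16.4) / length


@dataclasses.dataclass(frozen=True)
class PrimerConstraints:
    min_length: int = 19
    max_length: int = 22
    tm_min: float = 52.0
    tm_max: float = 60.0
    gc_min: float = 0.40
    gc_max: float = 0.60
    product_min: int = 80
    product_max: int = 250
    product_target: int = 150
    max_tm_diff: float = 3.0
    tm_formula: Callable[[int, int], float] = wallace_tm


@dataclasses.dataclass(frozen=True)
class PrimerPair:
    forward: str
    reverse: str  # reverse-complement strand, 5'->3'
    tm_forward: float
    tm_reverse: float
    gc_forward: float
    gc_reverse: float
    product_size: int  # on the reference
    forward_offset: int  # 0-based start of forward primer within the left flank
    reverse_end: int  # end (exclusive) of the reverse binding site in the right flank


@dataclasses.dataclass(frozen=True)
class DesignFailure:
    reason: str


@dataclasses.dataclass(frozen=True)
class Flanks:
    left: str  # up to `flank` bp ending at (and including) the anchor base
    right: str  # up to `flank` bp starting after the REF allele
    left_truncated: bool
    right_truncated: bool


@dataclasses.dataclass(frozen=True)
class MarkerCandidate:
    marker_id: str
    variant: InDelVariant
    flanks: Flanks
    primers: PrimerPair
    # genomic binding sites (0-based half-open on the reference)
    forward_site: tuple[int, int]
    reverse_site: tuple[int, int]
    products: dict[str, int | None] = dataclasses.field(default_factory=dict)
    outcome: str | None = None


@dataclasses.dataclass
class SelectionPlan:
    quotas: dict[str, int]
    bin_width: dict[str, float]
    picks: list[InDelVariant]


def select_uniform(
    indels: Sequence[InDelVariant],
    n_target: int,
    chromosome_lengths: Mapping[str, int],
    size_min: int = 3,
    size_max: int = 49,
) -> SelectionPlan:
    """Pick up to ``n_target`` size-eligible InDels spread evenly along the
    genome: per-chromosome quotas proportional to length (largest-remainder
    rounding), each chromosome cut into quota equal-width bins, and in each
    bin the eligible InDel nearest the bin midpoint chosen (leftmost on tie).
    Bins without an eligible InDel are skipped."""
    if n_target < len(chromosome_lengths):
        raise ValueError("n_target must be at least the number of chromosomes")
    total = sum(chromosome_lengths.values())
    raw = {c: n_target * length / total for c, length in chromosome_lengths.items()}
    quotas = {c: int(raw[c]) for c in chromosome_lengths}
    short = n_target - sum(quotas.values())
    for c in sorted(raw, key=lambda c: (-(raw[c] - int(raw[c])), c))[:short]:
        quotas[c] += 1
    eligible: dict[str, list[InDelVariant]] = {c: [] for c in chromosome_lengths}
    for v in indels:
        if size_min <= v.size <= size_max and v.chromosome in eligible:
            eligible[v.chromosome].append(v)
    picks: list[InDelVariant] = []
    widths: dict[str, float] = {}
    for chrom, quota in quotas.items():
        if quota == 0:
            continue
        length = chromosome_lengths[chrom]
        width = length / quota
        widths[chrom] = width
        cands = sorted(eligible[chrom], key=lambda v: v.position)
        positions = np.array([v.position for v in cands])
        for b in range(quota):
            lo, hi = b * width, (b + 1) * width
            mid = (lo + hi) / 2
            in_bin = [
                (abs(v.position - mid), v.position, v)
                for v, pos in zip(cands, positions)
                if lo < pos <= hi
            ]
            if not in_bin:
                continue
            picks.append(min(in_bin)[2])
    return SelectionPlan(quotas=quotas, bin_width=widths, picks=picks)


def extract_flanks(
    reference: Mapping[str, str], variant: InDelVariant, flank: int = 150
) -> Flanks:
    """Flanking reference sequence: ``left`` ends at the anchor base (inclusive),
    ``right`` starts after the REF allele; truncated (and flagged) at
    chromosome ends. left + REF[1:] + right reproduces the reference slice."""
    seq = reference[variant.chromosome]
    left_start = max(0, variant.start0 + 1 - flank)
    left = seq[left_start : variant.start0 + 1]
    right = seq[variant.end0 : variant.end0 + flank]
    return Flanks(
        left=left,
        right=right,
        left_truncated=len(left) < flank,
        right_truncated=len(right) < flank,
    )


def _candidates(seq: str, c: PrimerConstraints):
    """All substrings meeting length/Tm/GC constraints.

    Returns arrays (start, length, tm) for starts in ``seq``.
    """
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    is_gc = ((arr == ord("G")) | (arr == ord("C"))).astype(np.int32)
    cum = np.concatenate([[0], np.cumsum(is_gc)])
    starts_all, lens_all, tms_all = [], [], []
    for n in range(c.min_length, c.max_length + 1):
        if len(seq) < n:
            continue
        starts = np.arange(0, len(seq) - n + 1)
        gc = cum[starts + n] - cum[starts]
        tm = c.tm_formula(gc, n)
        frac = gc / n
        ok = (tm >= c.tm_min) & (tm <= c.tm_max) & (frac >= c.gc_min) & (frac <= c.gc_max)
        starts_all.append(starts[ok])
        lens_all.append(np.full(ok.sum(), n))
        tms_all.append(tm[ok])
    if not starts_all:
        return (np.array([], int), np.array([], int), np.array([], float))
    return (
        np.concatenate(starts_all),
        np.concatenate(lens_all),
        np.concatenate(tms_all),
    )


def design_primers(
    left: str,
    right: str,
    variant: InDelVariant,
    constraints: PrimerConstraints = PrimerConstraints(),
) -> PrimerPair | DesignFailure:
    """Exhaustive constraint search over forward primers (substrings of the
    left flank) and reverse primers (reverse complements of right-flank
    substrings). Feasible pairs need a reference product of 80-250 bp and a
    Tm difference of at most 3 deg C; the returned pair minimizes the Tm
    difference, then the distance of the product from 150 bp, then the
    leftmost forward and reverse positions. Deterministic."""
    c = constraints
    f_start, f_len, f_tm = _candidates(left, c)
    r_start, r_len, r_tm = _candidates(right, c)
    if len(f_start) == 0 or len(r_start) == 0:
        return DesignFailure(reason="no_tm_feasible")
    # reference amplicon: from forward start through REF allele to the end of
    # the reverse binding site in the right flank
    f_span = len(left) - f_start  # bases contributed left of/including anchor
    r_end = r_start + r_len
    inner = len(variant.ref_allele) - 1
    prod = f_span[:, None] + inner + r_end[None, :]
    dtm = np.abs(f_tm[:, None] - r_tm[None, :])
    ok = (prod >= c.product_min) & (prod <= c.product_max) & (dtm <= c.max_tm_diff)
    if not ok.any():
        return DesignFailure(reason="no_product_feasible")
    fi, ri = np.nonzero(ok)
    order = np.lexsort(
        (r_start[ri], f_start[fi], np.abs(prod[fi, ri] - c.product_target), dtm[fi, ri])
    )
    fi, ri = fi[order[0]], ri[order[0]]
    fwd = left[f_start[fi] : f_start[fi] + f_len[fi]]
    rev_site = right[r_start[ri] : r_end[ri]]
    gc = lambda s: (s.count("G") + s.count("C")) / len(s)
    return PrimerPair(
        forward=fwd,
        reverse=revcomp(rev_site),
        tm_forward=float(f_tm[fi]),
        tm_reverse=float(r_tm[ri]),
        gc_forward=gc(fwd),
        gc_reverse=gc(rev_site),
        product_size=int(prod[fi, ri]),
        forward_offset=int(f_start[fi]),
        reverse_end=int(r_end[ri]),
    )


def predict_products(
    marker: MarkerCandidate, call_sets: Mapping[str, VariantCallSet]
) -> dict[str, int | None]:
    """Predicted amplicon size per accession: the reference product adjusted
    by the net size of the accession's InDels that fall strictly between the
    primer 3' ends; an InDel overlapping a primer binding site abolishes
    amplification (None)."""
    f_lo, f_hi = marker.forward_site
    r_lo, r_hi = marker.reverse_site
    out: dict[str, int | None] = {}
    for acc, cs in call_sets.items():
        delta = 0
        dead = False
        for v in cs.variants:
            if v.chromosome != marker.variant.chromosome:
                continue
            if v.is_insertion:
                g = v.start0 + 1  # gap index the inserted bases precede
                if f_lo < g < f_hi or r_lo < g < r_hi:
                    dead = True  # insertion interrupts a primer binding site
                    break
                if f_hi <= g <= r_lo:
                    delta += v.size
            else:
                lo, hi = v.start0 + 1, v.end0  # deleted reference span
                if max(lo, f_lo) < min(hi, f_hi) or max(lo, r_lo) < min(hi, r_hi):
                    dead = True
                    break
                if lo >= f_hi and hi <= r_lo:
                    delta -= v.size
        out[acc] = None if dead else marker.primers.product_size + delta
    return out


def classify_outcome(
    size_a: int | None, size_b: int | None, min_resolvable: int = 3
) -> str:
    """codominant / monomorphic / dominant / failed from two product sizes."""
    if size_a is None and size_b is None:
        return "failed"
    if size_a is None or size_b is None:
        return "dominant"
    return "codominant" if abs(size_a - size_b) >= min_resolvable else "monomorphic"


def design_markers(
    reference: Mapping[str, str],
    indels: Sequence[InDelVariant],
    n_target: int,
    call_sets: Mapping[str, VariantCallSet] | None = None,
    chromosome_lengths: Mapping[str, int] | None = None,
    constraints: PrimerConstraints = PrimerConstraints(),
    flank: int = 150,
    size_min: int = 3,
    size_max: int = 49,
    min_resolvable: int = 3,
) -> tuple[list[MarkerCandidate], list[tuple[InDelVariant, str]]]:
    """Full marker panel: uniform selection, flanks, primer design, product
    prediction and outcome classification between two accessions.

    Marker ids follow the InDel-<chromosome 2-digit>-<size>b-<serial> scheme,
    with serials per chromosome and size class. Returns (markers, failures).
    """
    if chromosome_lengths is None:
        chromosome_lengths = {c: len(s) for c, s in reference.items()}
    plan = select_uniform(indels, n_target, chromosome_lengths, size_min, size_max)
    markers: list[MarkerCandidate] = []
    failures: list[tuple[InDelVariant, str]] = []
    serials: dict[tuple[str, int], int] = {}
    for v in plan.picks:
        flanks = extract_flanks(reference, v, flank)
        result = design_primers(flanks.left, flanks.right, v, constraints)
        if isinstance(result, DesignFailure):
            failures.append((v, result.reason))
            continue
        key = (v.chromosome, v.size)
        serials[key] = serials.get(key, 0) + 1
        chrom_num = "".join(ch for ch in v.chromosome if ch.isdigit()) or "00"
        marker_id = f"InDel-{int(chrom_num):02d}-{v.size}b-{serials[key]}"
        left_start = v.start0 + 1 - len(flanks.left)
        f_lo = left_start + result.forward_offset
        f_hi = f_lo + len(result.forward)
        r_hi = v.end0 + result.reverse_end
        r_lo = r_hi - len(result.reverse)
        marker = MarkerCandidate(
            marker_id=marker_id,
            variant=v,
            flanks=flanks,
            primers=result,
            forward_site=(f_lo, f_hi),
            reverse_site=(r_lo, r_hi),
        )
        if call_sets is not None:
            products = predict_products(marker, call_sets)
            accs = list(call_sets)
            outcome = (
                classify_outcome(products[accs[0]], products[accs[1]], min_resolvable)
                if len(accs) == 2
                else None
            )
            marker = dataclasses.replace(marker, products=products, outcome=outcome)
        markers.append(marker)
    return markers, failures


def outcome_counts(markers: Sequence[MarkerCandidate]) -> dict[str, int]:
    counts = {"codominant": 0, "monomorphic": 0, "dominant": 0, "failed": 0}
    for m in markers:
        if m.outcome is not None:
            counts[m.outcome] += 1
    return counts
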
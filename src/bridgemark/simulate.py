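"""Synthetic study system: reference genome, gene models, resequenced
accessions with known InDel truth, and species-structured band-score panels.

The generator emulates the shape of a two-accession pepper resequencing
comparison: InDel sizes follow the observed genome-wide distribution
(~68% single-base, ~89% at 5 bp or less, maximum 49 bp), counts per
chromosome are Poisson with a configurable density per Mb, genes occupy a
small minority of the genome, and the accession panel has five species whose
within-species band divergence is far below the between-species divergence.
Everything is deterministic given the seed.
"""

from __future__ import annotations

import dataclasses
import zlib
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from intervaltree import Interval, IntervalTree

from .diversity import GenotypeMatrix
from .genes import GeneModel, Transcript, write_gff3
from .variants import InDelVariant, VariantCallSet, normalize_variant, write_bed, write_vcf

MAX_INDEL_SIZE = 49
PLACEMENT_MARGIN = 60  # bp kept free of variants at chromosome ends
MASK_WINDOW = 500  # bp granularity of unconfirmed-coverage masking


class SimulationError(RuntimeError):
    pass


def default_size_pmf(tail_decay: float = 0.85) -> dict[int, float]:
    """Size distribution matching the observed genome-wide histogram for the
    two-accession comparison: exact fractions for 1-10 bp, and the >=11 bp
    mass spread geometrically (ratio ``tail_decay``) out to 49 bp."""
    counts = {
        1: 1129627, 2: 186832, 3: 79602, 4: 49560, 5: 27140,
        6: 25056, 7: 15470, 8: 16107, 9: 15547, 10: 13361,
    }
    tail_count = 93554
    total = sum(counts.values()) + tail_count
    pmf = {s: c / total for s, c in counts.items()}
    weights = np.array([tail_decay ** (s - 11) for s in range(11, MAX_INDEL_SIZE + 1)])
    weights *= (tail_count / total) / weights.sum()
    for s, w in zip(range(11, MAX_INDEL_SIZE + 1), weights):
        pmf[s] = float(w)
    return pmf


def default_panel_spec() -> list[tuple[str, int, float, float]]:
    """Five domesticated species with a 9/13/22/14/5 accession panel;
    between-species divergence far above within-species divergence."""
    return [
        ("C.annuum", 9, 0.02, 0.9),
        ("C.frutescens", 13, 0.02, 0.9),
        ("C.chinense", 22, 0.02, 0.9),
        ("C.baccatum", 14, 0.02, 0.9),
        ("C.pubescens", 5, 0.02, 0.9),
    ]


@dataclasses.dataclass
class SimulationConfig:
    seed: int = 0
    n_chromosomes: int = 2
    chromosome_lengths: Sequence[int] = (500_000, 500_000)
    gc_fraction: float = 0.35
    indel_density_per_mb: float = 600.0
    indel_size_pmf: Mapping[int, float] = dataclasses.field(default_factory=default_size_pmf)
    insertion_fraction: float = 0.5
    n_genes_per_chromosome: int = 18
    mean_exons_per_gene: int = 3
    identity_masked_fraction: float = 0.05
    panel_spec: Sequence[tuple[str, int, float, float]] = dataclasses.field(
        default_factory=default_panel_spec
    )
    panel_alleles_per_locus: Sequence[int] = (5, 6, 5)

    def __post_init__(self) -> None:
        if len(self.chromosome_lengths) != self.n_chromosomes:
            raise ValueError("chromosome_lengths must have n_chromosomes entries")
        if any(length <= 0 for length in self.chromosome_lengths):
            raise ValueError("chromosome lengths must be positive")
        if not 0 <= self.gc_fraction <= 1:
            raise ValueError("gc_fraction must be in [0, 1]")
        if self.indel_density_per_mb < 0:
            raise ValueError("indel_density_per_mb must be non-negative")
        total = sum(self.indel_size_pmf.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"indel_size_pmf sums to {total}, not 1")
        if any(not 1 <= s <= MAX_INDEL_SIZE for s in self.indel_size_pmf):
            raise ValueError(f"InDel sizes must be 1..{MAX_INDEL_SIZE}")
        if not 0 <= self.insertion_fraction <= 1:
            raise ValueError("insertion_fraction must be in [0, 1]")
        for label, n, within, between in self.panel_spec:
            if n < 1:
                raise ValueError(f"species {label} has no accessions")
            if not within < between:
                raise ValueError(
                    f"species {label}: within-species divergence must be below "
                    "between-species divergence"
                )

    @property
    def chromosome_names(self) -> list[str]:
        return [f"Chr{i + 1:02d}" for i in range(self.n_chromosomes)]


@dataclasses.dataclass
class SimulatedTruth:
    """Ground truth of one simulation: reference, gene models, per-accession
    variants/sequences/identity intervals, and the species band panel."""

    config: SimulationConfig
    reference: dict[str, str]
    genes: list[GeneModel]
    accession_sequences: dict[str, dict[str, str]]
    variants: dict[str, list[InDelVariant]]
    identity_intervals: dict[str, dict[str, IntervalTree]]
    panel: GenotypeMatrix | None = None

    def call_set(self, accession: str) -> VariantCallSet:
        return VariantCallSet(
            accession_id=accession,
            reference_id="reference",
            variants=list(self.variants[accession]),
            identity_intervals=self.identity_intervals[accession],
        )

    def true_pairwise_indels(self, a: str, b: str) -> list[InDelVariant]:
        return true_pairwise_indels(self, a, b)


def _accession_rng(seed: int, accession_id: str, salt: int = 0) -> np.random.Generator:
    return np.random.default_rng([seed, zlib.crc32(accession_id.encode()), salt])


def simulate_reference(config: SimulationConfig) -> dict[str, str]:
    """Random multi-chromosome reference with the configured base composition."""
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    gc = config.gc_fraction
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    out: dict[str, str] = {}
    for i, (name, length) in enumerate(zip(config.chromosome_names, config.chromosome_lengths)):
        rng = np.random.default_rng([config.seed, i])
        codes = rng.choice(4, size=length, p=p)
        out[name] = bases[codes].tobytes().decode()
    return out


def apply_variants(sequence: str, variants: Sequence[InDelVariant]) -> str:
    """Apply sorted, non-overlapping anchored variants to one chromosome."""
    pieces = []
    cursor = 0
    for v in sorted(variants, key=lambda v: v.position):
        if v.start0 < cursor:
            raise ValueError("variants overlap or are unsorted")
        pieces.append(sequence[cursor : v.start0])
        pieces.append(v.alt_allele)
        cursor = v.end0
    pieces.append(sequence[cursor:])
    return "".join(pieces)


def simulate_accession(
    reference: Mapping[str, str],
    config: SimulationConfig,
    accession_id: str,
) -> tuple[list[InDelVariant], dict[str, str], dict[str, IntervalTree]]:
    """Draw one accession's InDels against the reference.

    Counts are Poisson(density x Mb) per chromosome, sizes follow the size
    pmf, variants are placed non-overlapping with a 1-bp spacer and stored
    left-aligned. Identity intervals are the unmutated complement minus a
    masked fraction emulating unconfirmed read coverage.
    """
    if not reference:
        raise ValueError("empty reference")
    sizes = np.array(sorted(config.indel_size_pmf), dtype=int)
    probs = np.array([config.indel_size_pmf[s] for s in sizes])
    variants: list[InDelVariant] = []
    mutated: dict[str, str] = {}
    identity: dict[str, IntervalTree] = {}
    for ci, (chrom, seq) in enumerate(reference.items()):
        rng = _accession_rng(config.seed, accession_id, ci)
        length = len(seq)
        n = int(rng.poisson(config.indel_density_per_mb * length / 1e6))
        occupied = IntervalTree()
        placed: list[InDelVariant] = []
        attempts = 0
        max_attempts = 50 * max(n, 1)
        while len(placed) < n:
            attempts += 1
            if attempts > max_attempts:
                raise SimulationError(
                    f"cannot place {n} non-overlapping InDels on {chrom} "
                    f"({length} bp) after {max_attempts} attempts"
                )
            size = int(rng.choice(sizes, p=probs))
            insertion = bool(rng.random() < config.insertion_fraction)
            hi = length - size - PLACEMENT_MARGIN
            if hi <= PLACEMENT_MARGIN:
                raise SimulationError(f"chromosome {chrom} too short for placement")
            anchor = int(rng.integers(PLACEMENT_MARGIN, hi))
            if insertion:
                ins = "".join("ACGT"[c] for c in rng.integers(0, 4, size))
                ref_a, alt_a = seq[anchor], seq[anchor] + ins
            else:
                ref_a, alt_a = seq[anchor : anchor + size + 1], seq[anchor]
            v = normalize_variant(chrom, anchor + 1, ref_a, alt_a, reference)
            if occupied.overlap(v.start0 - 1, v.end0 + 1):
                continue
            occupied.addi(v.start0 - 1, v.end0 + 1)
            placed.append(v)
        placed.sort(key=InDelVariant.key)
        variants.extend(placed)
        mutated[chrom] = apply_variants(seq, placed)
        tree = IntervalTree([Interval(0, length)])
        for v in placed:
            tree.chop(v.start0, v.end0)
        if config.identity_masked_fraction > 0:
            n_windows = (length + MASK_WINDOW - 1) // MASK_WINDOW
            masked = rng.random(n_windows) < config.identity_masked_fraction
            for w in np.nonzero(masked)[0]:
                tree.chop(int(w) * MASK_WINDOW, min((int(w) + 1) * MASK_WINDOW, length))
        tree.merge_overlaps(strict=False)
        identity[chrom] = tree
    return variants, mutated, identity


# ---------------------------------------------------------------------------
# gene models


def _patch(seq: bytearray, start: int, replacement: str) -> None:
    seq[start : start + len(replacement)] = replacement.encode()


_COMP = bytes.maketrans(b"ACGT", b"TGCA")


def _rc(s: str) -> str:
    return s.encode().translate(_COMP)[::-1].decode()


def simulate_genes(
    reference: dict[str, str], config: SimulationConfig
) -> tuple[dict[str, str], list[GeneModel]]:
    """Place non-overlapping multi-exon genes and rewrite the reference so
    every model is a valid ORF (ATG start, stop-free body, TAA stop, GT/AG
    splice sites). Returns the patched reference and the models."""
    STOPS = {"TAA", "TAG", "TGA"}
    genes: list[GeneModel] = []
    patched: dict[str, str] = {}
    for ci, (chrom, seq) in enumerate(reference.items()):
        rng = np.random.default_rng([config.seed, 10_000 + ci])
        buf = bytearray(seq.encode())
        length = len(seq)
        occupied = IntervalTree()
        for gi in range(config.n_genes_per_chromosome):
            for _ in range(200):  # placement retries
                n_exons = int(rng.integers(1, 2 * config.mean_exons_per_gene))
                exon_lens = [int(3 * rng.integers(20, 100)) for _ in range(n_exons)]
                intron_lens = [int(rng.integers(100, 500)) for _ in range(n_exons - 1)]
                span = sum(exon_lens) + sum(intron_lens)
                start = int(rng.integers(200, max(201, length - span - 200)))
                if occupied.overlap(start - 200, start + span + 200):
                    continue
                occupied.addi(start - 200, start + span + 200)
                break
            else:
                break  # chromosome saturated; accept fewer genes
            strand = "+" if rng.random() < 0.5 else "-"
            exons = []
            pos = start
            for k, el in enumerate(exon_lens):
                exons.append((pos, pos + el))
                if k < n_exons - 1:
                    intron_start, intron_end = pos + el, pos + el + intron_lens[k]
                    if strand == "+":
                        _patch(buf, intron_start, "GT")
                        _patch(buf, intron_end - 2, "AG")
                    else:
                        _patch(buf, intron_start, "CT")
                        _patch(buf, intron_end - 2, "AC")
                    pos = intron_end
                else:
                    pos += el
            # make the spliced CDS a clean ORF on the coding strand
            genomic = "".join(str(buf[a:b], "ascii") for a, b in exons)
            cds = genomic if strand == "+" else _rc(genomic)
            codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
            codons[0] = "ATG"
            for k in range(1, len(codons) - 1):
                if codons[k] in STOPS:
                    codons[k] = "C" + codons[k][1:]
            codons[-1] = "TAA"
            fixed = "".join(codons)
            genomic_fixed = fixed if strand == "+" else _rc(fixed)
            off = 0
            for a, b in exons:
                _patch(buf, a, genomic_fixed[off : off + (b - a)])
                off += b - a
            tid = f"{chrom}g{gi + 1:03d}.t1"
            genes.append(
                GeneModel(
                    gene_id=f"{chrom}g{gi + 1:03d}",
                    chromosome=chrom,
                    strand=strand,
                    transcripts=(Transcript(tid, tuple(exons), tuple(exons)),),
                )
            )
        patched[chrom] = str(buf, "ascii")
    return patched, genes


# ---------------------------------------------------------------------------
# pairwise truth


def true_pairwise_indels(truth: SimulatedTruth, a: str, b: str) -> list[InDelVariant]:
    """Exact InDel differences between accessions a and b by coordinate
    bookkeeping of the two known variant sets (no re-alignment): variants
    carried by exactly one of the two, with identical shared variants removed."""
    for acc in (a, b):
        if acc not in truth.variants:
            raise KeyError(f"unknown accession {acc!r}")
    keys_a = {v.key() for v in truth.variants[a]}
    keys_b = {v.key() for v in truth.variants[b]}
    out = [v for v in truth.variants[a] if v.key() not in keys_b]
    out += [v for v in truth.variants[b] if v.key() not in keys_a]
    return sorted(out, key=InDelVariant.key)


def pairwise_with_carriers(
    truth: SimulatedTruth, a: str, b: str
) -> list[tuple[InDelVariant, str]]:
    keys_a = {v.key() for v in truth.variants[a]}
    keys_b = {v.key() for v in truth.variants[b]}
    tagged = [(v, a) for v in truth.variants[a] if v.key() not in keys_b]
    tagged += [(v, b) for v in truth.variants[b] if v.key() not in keys_a]
    return sorted(tagged, key=lambda t: t[0].key())


# ---------------------------------------------------------------------------
# species band panel


def simulate_panel(reference: Mapping[str, str], config: SimulationConfig) -> GenotypeMatrix:
    """Band-score matrix for a species-structured accession panel.

    Per locus each species carries an ancestral band: its private allele with
    probability ``between_species_divergence``, otherwise a panel-wide shared
    allele. Each accession keeps the ancestral band except with probability
    ``within_species_divergence``, where it switches to another allele of the
    locus pool; the replacement never coincides with another species'
    ancestral band (band homoplasy between species is not modelled).
    """
    if not config.panel_spec:
        raise ValueError("panel_spec is empty")
    rng = np.random.default_rng([config.seed, 777])
    n_species = len(config.panel_spec)
    loci = [f"L{i + 1:02d}" for i in range(len(config.panel_alleles_per_locus))]
    accessions: list[str] = []
    species_of: dict[str, str] = {}
    for label, n, _, _ in config.panel_spec:
        for j in range(n):
            acc = f"{label}-{j + 1:02d}"
            accessions.append(acc)
            species_of[acc] = label
    scores: dict[str, dict[str, int]] = {acc: {} for acc in accessions}
    for locus, k in zip(loci, config.panel_alleles_per_locus):
        shared = n_species if k > n_species else 0
        ancestral = []
        for si, (label, n, within, between) in enumerate(config.panel_spec):
            private = si % k
            ancestral.append(private if rng.random() < between else shared)
        for si, (label, n, within, between) in enumerate(config.panel_spec):
            others = {ancestral[sj] for sj in range(n_species) if sj != si}
            free = [al for al in range(k) if al not in others]
            for j in range(n):
                allele = ancestral[si]
                if rng.random() < within and free:
                    allele = int(free[int(rng.integers(0, len(free)))])
                acc = f"{label}-{j + 1:02d}"
                for al in range(k):
                    scores[acc][f"{locus}:a{al}"] = int(al == allele)
    import pandas as pd

    frame = pd.DataFrame.from_dict(scores, orient="index").loc[accessions]
    species = pd.Series(species_of, name="species").loc[accessions]
    return GenotypeMatrix(frame, species=species)


# ---------------------------------------------------------------------------
# orchestration and file output


def simulate_truth(
    config: SimulationConfig, accessions: Sequence[str] = ("PBC688", "G29")
) -> SimulatedTruth:
    """Full synthetic study: patched reference with genes, per-accession
    variant truth, and the species panel."""
    reference = simulate_reference(config)
    reference, genes = simulate_genes(reference, config)
    seqs: dict[str, dict[str, str]] = {}
    variants: dict[str, list[InDelVariant]] = {}
    identity: dict[str, dict[str, IntervalTree]] = {}
    for acc in accessions:
        v, m, ident = simulate_accession(reference, config, acc)
        variants[acc], seqs[acc], identity[acc] = v, m, ident
    panel = simulate_panel(reference, config)
    return SimulatedTruth(config, reference, genes, seqs, variants, identity, panel)


def write_fasta(path: str | Path, sequences: Mapping[str, str], width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_truth(truth: SimulatedTruth, outdir: str | Path) -> dict[str, Path]:
    """Write every simulated input in its standard text format."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    contigs = {c: len(s) for c, s in truth.reference.items()}
    paths["reference"] = outdir / "reference.fa"
    write_fasta(paths["reference"], truth.reference)
    paths["genes"] = outdir / "genes.gff3"
    write_gff3(paths["genes"], truth.genes)
    for acc in truth.variants:
        paths[f"vcf:{acc}"] = outdir / f"{acc}.indels.vcf"
        write_vcf(paths[f"vcf:{acc}"], truth.variants[acc], contigs, acc)
        paths[f"bed:{acc}"] = outdir / f"{acc}.identity.bed"
        write_bed(paths[f"bed:{acc}"], truth.identity_intervals[acc])
    if truth.panel is not None:
        paths["bands"] = outdir / "bands.tsv"
        truth.panel.to_tsv(paths["bands"])
    truth_rows = ["accession\tchromosome\tposition\tref\talt\tsize\tkind"]
    for acc, vs in truth.variants.items():
        for v in vs:
            truth_rows.append(
                f"{acc}\t{v.chromosome}\t{v.position}\t{v.ref_allele}\t{v.alt_allele}"
                f"\t{v.size}\t{v.kind}"
            )
    paths["truth"] = outdir / "truth_variants.tsv"
    paths["truth"].write_text("\n".join(truth_rows) + "\n")
    return paths
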
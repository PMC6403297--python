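"""InDel effect classification: toy-transcript examples, the exhaustive
translate-and-diff oracle, strand reflection, and summary bookkeeping."""

import numpy as np
import pytest
from Bio.Seq import Seq

from bridgemark import EffectCategory, GeneModelIndex, classify, classify_all
from bridgemark.effects import summarize_effects
from bridgemark.genes import GeneModel, Transcript
from bridgemark.simulate import apply_variants
from bridgemark.variants import InDelVariant

STOPS = {"TAA", "TAG", "TGA"}


def make_toy(cds: str, strand: str = "+", pad: int = 60, seed: int = 0):
    """Single-exon gene with the given coding sequence embedded in random
    stop-free-irrelevant flanking sequence."""
    rng = np.random.default_rng(seed)
    flank5 = "".join(rng.choice(list("ACGT"), pad))
    flank3 = "".join(rng.choice(list("ACGT"), pad))
    genomic = cds if strand == "+" else str(Seq(cds).reverse_complement())
    chrom = flank5 + genomic + flank3
    t = Transcript("t1", ((pad, pad + len(genomic)),), ((pad, pad + len(genomic)),))
    gene = GeneModel("g1", "c", strand, (t,))
    return {"c": chrom}, gene, pad


def classify_one(ref, gene, variant):
    return classify(variant, GeneModelIndex([gene]), ref).primary


class TestCodingExamples:
    CDS = "ATG" + "GCT GGA AAG CTT CCA GTC GAC".replace(" ", "") + "TAA"

    def test_non_triplet_deletion_is_frameshift(self):
        ref, gene, pad = make_toy(self.CDS)
        # 4-bp deletion fully inside the CDS
        a = pad + 5
        v = InDelVariant("c", a + 1, ref["c"][a : a + 5], ref["c"][a])
        assert classify_one(ref, gene, v) == EffectCategory.FrameShift

    def test_inframe_insertion_at_codon_boundary(self):
        ref, gene, pad = make_toy(self.CDS)
        a = pad + 5  # anchor = last base of codon 2: gap falls on a boundary
        v = InDelVariant("c", a + 1, ref["c"][a], ref["c"][a] + "CAC")
        assert classify_one(ref, gene, v) == EffectCategory.CodonInsertion

    def test_codon_straddling_insertion_changes_a_codon(self):
        ref, gene, pad = make_toy(self.CDS)
        a = pad + 3  # mid-codon: GCT -> G|AAA|CT spells Glu+Thr, not Ala
        v = InDelVariant("c", a + 1, ref["c"][a], ref["c"][a] + "AAA")
        assert classify_one(ref, gene, v) == EffectCategory.CodonChangePlusCodonInsertion

    def test_deleting_the_start_codon(self):
        ref, gene, pad = make_toy(self.CDS)
        a = pad - 1  # anchor just before the CDS, deleting ATG
        v = InDelVariant("c", a + 1, ref["c"][a : a + 4], ref["c"][a])
        assert classify_one(ref, gene, v) == EffectCategory.StartLost

    def test_inframe_deletion_creating_stop(self):
        # ATG | TAC AAG | TAA: deleting codon "TAC"+.. chosen so that the
        # junction spells TAA in frame before the terminal stop
        cds = "ATG" + "TCG" + "ATA" + "AGG" + "TAA"
        # delete 3 bp straddling codons 3-4 so the junction reads TAA early
        ref, gene, pad = make_toy(cds)
        a = pad + 6  # wild: ATG TCG A|TA AG|G TAA; remove TAA -> ATG TCG AGG..
        v = InDelVariant("c", a + 1, ref["c"][a : a + 4], ref["c"][a])
        mutant = cds[: a - pad + 1] + cds[a - pad + 4 :]
        assert classify_one(ref, gene, v) == translation_oracle(cds, mutant)

    def test_inframe_codon_deletion(self):
        ref, gene, pad = make_toy(self.CDS)
        a = pad + 2  # anchor = last base of ATG; deletes codon 2 exactly
        v = InDelVariant("c", a + 1, ref["c"][a : a + 4], ref["c"][a])
        assert classify_one(ref, gene, v) == EffectCategory.CodonDeletion


class TestNonCoding:
    def _two_exon_gene(self, strand="+"):
        rng = np.random.default_rng(4)
        chrom = "".join(rng.choice(list("ACGT"), 400))
        exons = ((100, 130), (190, 220))
        chrom = chrom[:130] + ("GT" if strand == "+" else "CT") + chrom[132:]
        chrom = chrom[:188] + ("AG" if strand == "+" else "AC") + chrom[190:]
        # CDS content irrelevant for splice/intron categories; keep frame valid
        t = Transcript("t1", exons, exons)
        gene = GeneModel("g1", "c", strand, (t,))
        return {"c": chrom}, gene

    @pytest.mark.parametrize(
        "strand,pos0,expected",
        [
            ("+", 130, EffectCategory.SpliceSiteDonor),
            ("+", 188, EffectCategory.SpliceSiteAcceptor),
            ("-", 130, EffectCategory.SpliceSiteAcceptor),
            ("-", 188, EffectCategory.SpliceSiteDonor),
            ("+", 150, EffectCategory.Intron),
        ],
    )
    def test_splice_and_intron(self, strand, pos0, expected):
        ref, gene = self._two_exon_gene(strand)
        v = InDelVariant(
            "c", pos0, ref["c"][pos0 - 1 : pos0 + 1], ref["c"][pos0 - 1]
        )  # 1-bp deletion removing base at pos0
        assert classify_one(ref, gene, v) == expected

    def test_upstream_downstream_and_intergenic(self):
        ref, gene = self._two_exon_gene("+")
        up = InDelVariant("c", 50, ref["c"][49:51], ref["c"][49])
        down = InDelVariant("c", 300, ref["c"][299:301], ref["c"][299])
        assert classify_one(ref, gene, up) == EffectCategory.Upstream5kb
        assert classify_one(ref, gene, down) == EffectCategory.Downstream5kb
        index = GeneModelIndex([gene], flank_bp=50)
        far = InDelVariant("c", 350, ref["c"][349:351], ref["c"][349])
        assert classify(far, index, ref, flank_bp=50).primary == EffectCategory.Intergenic

    def test_transcript_less_gene(self):
        ref, gene = self._two_exon_gene("+")
        bare = GeneModel("g2", "c", "+", (), span=(100, 220))
        v = InDelVariant("c", 150, ref["c"][149:151], ref["c"][149])
        assert classify_one(ref, bare, v) == EffectCategory.IntragenicNoTranscript

    def test_missing_chromosome_warns_intergenic(self):
        ref, gene = self._two_exon_gene("+")
        v = InDelVariant("other", 10, "AC", "A")
        with pytest.warns(UserWarning, match="absent"):
            assert classify_one(ref, gene, v) == EffectCategory.Intergenic


# ---------------------------------------------------------------------------
# the independent translate-and-diff oracle


def translation_oracle(wild: str, mut: str) -> EffectCategory:
    """Category from full-sequence translation diffs (independent of the
    classifier's codon bookkeeping)."""
    if (len(mut) - len(wild)) % 3 != 0:
        return EffectCategory.FrameShift
    if mut[:3] != "ATG":
        return EffectCategory.StartLost
    wp = str(Seq(wild).translate())
    mp = str(Seq(mut).translate())
    assert wp.count("*") == 1 and wp.endswith("*")
    if "*" in mp[:-1]:
        return EffectCategory.StopGained
    if not mp.endswith("*"):
        return EffectCategory.StopLost
    p, q = wp[:-1], mp[:-1]
    short, long_ = (p, q) if len(q) > len(p) else (q, p)
    pre = 0
    while pre < len(short) and short[pre] == long_[pre]:
        pre += 1
    suf = 0
    while suf < len(short) - pre and short[len(short) - 1 - suf] == long_[len(long_) - 1 - suf]:
        suf += 1
    pure = pre + suf >= len(short)
    if len(q) > len(p):
        return (
            EffectCategory.CodonInsertion if pure
            else EffectCategory.CodonChangePlusCodonInsertion
        )
    return (
        EffectCategory.CodonDeletion if pure
        else EffectCategory.CodonChangePlusCodonDeletion
    )


def random_orf(rng, n_codons: int) -> str:
    body_codons = [
        c
        for c in ("".join(p) for p in __import__("itertools").product("ACGT", repeat=3))
        if c not in STOPS and c != "ATG"
    ]
    body = "".join(rng.choice(body_codons) for _ in range(n_codons - 2))
    return "ATG" + body + "TAA"


def enumerate_cases(cds: str, strand: str, pad: int, ref, rng):
    """All 1-6 bp deletions inside the CDS and a sample of insertions."""
    chrom = ref["c"]
    L = len(cds)
    cases = []
    for size in range(1, 7):
        for cpos in range(0, L - size):
            # deletion of coding bases [cpos+1, cpos+1+size)
            if strand == "+":
                a = pad + cpos
            else:
                a = pad + (L - 2 - cpos) - size
            mut = cds[: cpos + 1] + cds[cpos + 1 + size :]
            v = InDelVariant("c", a + 1, chrom[a : a + size + 1], chrom[a])
            cases.append((v, mut))
    for size in range(1, 7):
        for cpos in range(0, L):  # insertion after cds base cpos-1.. gap=cpos
            ins = "".join(rng.choice(list("ACGT"), size))
            if strand == "+":
                a = pad + cpos - 1
                if a < 0:
                    continue
                gins = ins
            else:
                a = pad + (L - 1 - cpos)
                gins = str(Seq(ins).reverse_complement())
            if cpos == 0:
                continue  # insertion before the CDS start is non-coding
            v = InDelVariant("c", a + 1, chrom[a], chrom[a] + gins)
            mut = cds[:cpos] + ins + cds[cpos:]
            cases.append((v, mut))
    return cases


class TestTranslationOracle:
    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_exhaustive_agreement_on_random_toys(self, strand):
        rng = np.random.default_rng(17 if strand == "+" else 18)
        for toy in range(6):
            n_codons = int(rng.integers(4, 11))
            cds = random_orf(rng, n_codons)
            ref, gene, pad = make_toy(cds, strand=strand, seed=int(rng.integers(1 << 30)))
            index = GeneModelIndex([gene])
            for v, mut in enumerate_cases(cds, strand, pad, ref, rng):
                got = classify(v, index, ref).primary
                want = translation_oracle(cds, mut)
                assert got == want, (strand, cds, v, mut)

    def test_oracle_via_genome_application(self):
        """Cross-check the coordinate math: the mutant CDS equals what the
        mutated chromosome spells at the shifted CDS location."""
        rng = np.random.default_rng(3)
        cds = random_orf(rng, 8)
        ref, gene, pad = make_toy(cds, strand="+", seed=5)
        for v, mut in enumerate_cases(cds, "+", pad, ref, rng):
            net = v.size if v.is_insertion else -v.size
            mutated = apply_variants(ref["c"], [v])
            region = mutated[pad : pad + len(cds) + net]
            assert region == mut


class TestStrandReflection:
    def test_categories_invariant_under_reflection(self):
        rng = np.random.default_rng(9)
        cds = random_orf(rng, 9)
        ref, gene, pad = make_toy(cds, strand="+", seed=6)
        chrom = ref["c"]
        L = len(chrom)
        mchrom = str(Seq(chrom).reverse_complement())
        mt = Transcript(
            "t1",
            ((L - gene.transcripts[0].exons[0][1], L - gene.transcripts[0].exons[0][0]),),
            ((L - gene.transcripts[0].cds[0][1], L - gene.transcripts[0].cds[0][0]),),
        )
        mgene = GeneModel("g1", "c", "-", (mt,))
        mref = {"c": mchrom}
        idx, midx = GeneModelIndex([gene]), GeneModelIndex([mgene])
        for _ in range(300):
            a = int(rng.integers(5, L - 12))
            if rng.random() < 0.5:
                size = int(rng.integers(1, 7))
                v = InDelVariant("c", a + 1, chrom[a : a + size + 1], chrom[a])
                # mirrored deleted span [L-end0, L-start0-1); anchor just before
                ma = L - v.end0 - 1
                mv = InDelVariant("c", ma + 1, mchrom[ma : ma + size + 1], mchrom[ma])
            else:
                size = int(rng.integers(1, 7))
                ins = "".join(rng.choice(list("ACGT"), size))
                v = InDelVariant("c", a + 1, chrom[a], chrom[a] + ins)
                g = v.start0 + 1
                ts, te = gene.transcripts[0].span
                if g in (ts, te):
                    continue  # boundary insertions are a side convention,
                    # not a strand property
                ma = L - g - 1
                mv = InDelVariant(
                    "c", ma + 1, mchrom[ma], mchrom[ma] + str(Seq(ins).reverse_complement())
                )
            assert (
                classify(v, idx, ref).primary == classify(mv, midx, mref).primary
            ), (v, mv)


class TestSummary:
    def test_partition_and_counts(self, truth):
        variants = truth.variants["PBC688"][:300]
        anns = classify_all(variants, truth.genes, truth.reference)
        assert len(anns) == len(variants)
        table = summarize_effects(anns)
        assert table["count"].sum() == len(variants)

    def test_empty_input(self):
        table = summarize_effects([])
        assert table["count"].sum() == 0
        assert table.attrs["genic_fraction_pct"] == 0.0

    def test_uniform_placement_recovers_gene_span_fraction(self, truth):
        """1-bp deletions placed uniformly hit gene bodies at the genomic
        gene-span fraction (binomial check at n=50,000)."""
        index = GeneModelIndex(truth.genes)
        spans = sum(g.bounds[1] - g.bounds[0] for g in truth.genes)
        genome = sum(len(s) for s in truth.reference.values())
        expected = spans / genome
        rng = np.random.default_rng(12)
        genic_cats = {
            EffectCategory.Intron,
            EffectCategory.SpliceSiteDonor,
            EffectCategory.SpliceSiteAcceptor,
            EffectCategory.FrameShift,
            EffectCategory.CodonInsertion,
            EffectCategory.CodonDeletion,
            EffectCategory.CodonChangePlusCodonInsertion,
            EffectCategory.CodonChangePlusCodonDeletion,
            EffectCategory.StartLost,
            EffectCategory.StopGained,
            EffectCategory.StopLost,
            EffectCategory.IntragenicNoTranscript,
        }
        n = 50_000
        genic = 0
        chroms = list(truth.reference)
        lengths = np.array([len(truth.reference[c]) for c in chroms])
        picks = rng.integers(0, lengths.sum(), n)
        for pick in picks:
            ci = 0 if pick < lengths[0] else 1
            a = int(pick - (0 if ci == 0 else lengths[0]))
            a = min(a, lengths[ci] - 3)
            chrom = chroms[ci]
            seq = truth.reference[chrom]
            v = InDelVariant(chrom, a + 1, seq[a : a + 2], seq[a])
            if classify(v, index, truth.reference).primary in genic_cats:
                genic += 1
        assert abs(genic / n - expected) <= 0.01
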
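# Methods

## The reference-bridge rule

Two accessions A and B are each described by (i) their InDel calls against a
shared reference genome and (ii) *identity intervals*: genomic spans where
the accession is confirmed identical to the reference (in the emulated study
these come from gap-free read alignment; here they are an explicit BED
input). An InDel `v` of A with reference footprint `[s, e)` (0-based
half-open; VCF-anchored records store the 1-based anchor base shared by REF
and ALT) is emitted as a real A-vs-B difference, carrier A, iff

* B has no variant whose footprint intersects `[s − w, e + w)`, and
* `[s − w, e + w)` lies entirely inside B's identity intervals,

and symmetrically for B. The window `w` (default 10 bp) operationalizes
"identical sequence around the locus"; the underlying alignment evidence has
read-scale resolution, and a small symmetric flank is the weakest assumption
that still guarantees both alleles can be distinguished locally. Loci where
both accessions carry the *identical* variant are excluded as shared (they
are not polymorphic between A and B); loci where they carry *different*
overlapping variants are emitted once with carrier `both-different`; windows
failing identity confirmation are counted `excluded_unconfirmed`. With
complete identity coverage the emitted set provably equals the simulated
pairwise truth restricted to non-colliding loci, and the suite checks this
exactly over 20 seeded 10-Mb simulations.

All variants are normalized on input: shared trailing bases are truncated
with leftward extension through repeats (the standard left-alignment), then
leading bases trimmed to a single anchor. Normalization is idempotent, and
every shifted representation of an InDel inside a repeat run maps to one
canonical record — a precondition for comparing call sets by coordinates.

## Effect classification

Each InDel receives exactly one primary category — the most severe of its
per-transcript calls — from the fixed severity order StartLost > StopGained
> StopLost > FrameShift > CodonChangePlusCodonInsertion/Deletion >
CodonInsertion/Deletion > SpliceSiteAcceptor/Donor > Intron > Upstream5kb >
Downstream5kb > IntragenicNoTranscript > Intergenic (with `Other` as a sink
for the unclassifiable). Coding calls are made at sequence level: the
spliced CDS is rebuilt with and without the variant on the coding strand,
and the category read off the two sequences — frameshift when the net length
change is not a multiple of 3, start lost when the mutant no longer begins
with ATG, stop gained/lost from stop-codon positions, and the pure-vs-
"change plus" distinction from whether the wild protein survives intact as
prefix+suffix of the mutant. This sequence-level definition, rather than
raw coordinate geometry, is deliberate: an in-frame insertion inside a
homopolymer codon run straddles a codon boundary geometrically yet spells a
pure codon insertion at protein level, and the classifier is required (and
tested, exhaustively over all 1–6-bp placements on short toy ORFs, both
strands) to agree with an independent translate-and-diff oracle.

Conventions at boundaries: an insertion belongs to the CDS iff its anchor
base lies in the CDS (so an insertion at an exon's 3' boundary attaches to
the exonic side); splice sites are the 2 terminal bases of an intron
(canonical GT/AG), strand-aware; distances for the 5-kb up/downstream
classes are measured from the changed region (deleted span or insertion
gap), not the anchor base, which keeps categories invariant under strand
reflection; a variant within 5 kb of two genes takes the nearer gene, ties
resolving to the upstream relation. The *genic fraction* counts categories
inside gene bodies (coding, splice, intron, transcript-less gene); the
up/downstream classes are flanking, not genic.

## Marker design

Selection: per-chromosome quotas proportional to length
(largest-remainder rounding), each chromosome cut into quota equal-width
bins, and in each bin the size-eligible InDel (3–49 bp by default) nearest
the bin midpoint picked, leftmost on ties — deterministic and close to
uniform genome spacing. Flanks of 150 bp are taken from the reference, the
left flank ending at the anchor base, the right starting after the REF
allele, truncated (flagged) at chromosome ends.

Primer search is exhaustive over all substrings of the two flanks with
length 19–22 nt, GC 40–60% and Tm 52–60 °C, using the GC-count formula
`Tm = 64.9 + 41·(nGC − 16.4)/N` — adequate at these lengths and monotone in
GC content; the formula is a pluggable callable so a nearest-neighbor model
can substitute. Feasible pairs need a reference product of 80–250 bp and a
Tm difference ≤ 3 °C; among them the pair minimizing (|ΔTm|, |product−150|,
forward position, reverse position) is returned, making designs
deterministic. Product prediction per accession adds the net signed size of
the accession's InDels strictly between the primer 3' ends; any InDel
interrupting a binding site (an insertion strictly inside it, or a deletion
overlapping it) abolishes amplification. Outcomes between two accessions:
codominant when both amplify and |Δproduct| ≥ 3 bp (the 10% PAGE
resolution limit, which is also why the 3-bp lower size bound exists),
monomorphic below that, dominant when exactly one amplifies, failed when
neither does or no primer pair exists. Marker ids follow
`InDel-<chromosome 2-digit>-<size>b-<serial>` with serials per chromosome
and size class; how the panel is stratified across size classes is left to
the caller (`n_target` plus the size bounds) rather than hard-coded.

## Diversity statistics and the tree

Accessions are homozygous inbred lines: one band per locus (a matrix with
two bands at a locus raises a specific error; missing loci are excluded
locus-wise). Per locus: allele count, major allele frequency, gene diversity
`D = 1 − Σp²` and Botstein's `PIC = 1 − Σp² − Σ_{i<j} 2p_i²p_j²`. Classical
`Fst` uses unweighted mean allele frequencies across species groups for
`H_T`, the group mean of `1 − Σp²` for `H_S`, per-locus `(H_T − H_S)/H_T`
with monomorphic loci undefined and excluded, and the mean taken as
`Σ(H_T − H_S)/ΣH_T`. "Nei's distance" defaults to Nei's **minimum** genetic
distance `mean_loci[(J_X + J_Y)/2 − J_XY]`; the 1972 standard distance and
the D_A distance are provided behind the same interface because the cited
genotyping software offers all three and the choice is a judgment call.

Neighbor joining is implemented in-package (Saitou–Nei agglomeration with
the Studier–Keppler Q criterion) rather than delegated, because the contract
requires determinism — ties in Q resolve to the lexicographically smallest
pair of cluster representatives — and a specific treatment of negative
branch lengths (clamped to zero with the excess moved to the sibling edge,
toggleable). On additive matrices the output reproduces the generating
tree's tip-to-tip distances to 1e-9; the suite cross-checks topology against
scikit-bio's independent NJ. Species cluster purity of the final unrooted
tree is the fraction of species whose leaves span a subtree containing no
foreign leaf (computed by pruning the tree graph to the Steiner subtree of
each species' leaves).

## The synthetic study system

The generator reproduces the *shape* of the emulated two-accession
comparison, not its genome:

* **Reference**: random i.i.d. sequence at GC 0.35 (solanaceous-like),
  chromosomes `Chr01…`; composition verified to ±0.02 at ≥100 kb.
* **InDels**: counts per chromosome Poisson(density × Mb) at 600/Mb per
  accession by default (the observed pairwise density of ~600/Mb then
  emerges from bridging two such accessions); sizes from a pmf matching the
  observed histogram exactly for 1–10 bp (68.4% single-base) with the ≥11 bp
  mass spread geometrically (ratio 0.85) to the observed 49-bp maximum;
  insertions and deletions equiprobable; placement non-overlapping with a
  1-bp spacer and a 60-bp chromosome-end margin, records stored
  left-aligned. Identity intervals are the unmutated complement minus a 5%
  masked fraction in 500-bp windows, emulating unconfirmed coverage.
* **Genes**: ~18 multi-exon genes per 500-kb chromosome (~4% of sequence),
  placed non-overlapping and rewritten into valid ORFs (ATG start, stop-free
  body, TAA stop, GT/AG splice sites) so coding-effect calls are meaningful.
  SNP background is not simulated; nothing in the InDel pipeline would read
  it.
* **Panel**: five species with 9/13/22/14/5 accessions (63 total) typed at
  3 loci with 5+6+5 band alleles (16 alleles, 1008 cells). Per locus each
  species carries a private ancestral band with probability equal to its
  between-species divergence (default 0.9), else a panel-wide shared band;
  each accession deviates from its species band with probability equal to
  the within-species divergence (default 0.02, far below the between-species
  value, as expected for strongly species-diagnostic markers), drawing a
  replacement that never coincides with another species' ancestral band —
  cross-species band homoplasy is deliberately not modelled, which is what
  licenses the expectation of 100% species cluster purity at default
  settings.

What the generator does **not** emulate — read-level errors, alignment
artefacts, repeat-driven call errors, linkage between loci, heterozygosity,
real genome composition — bounds what green tests mean: they verify the
*logic* of bridging, annotation, design and tree building against exact
ground truth, not robustness to real sequencing noise.

## Numerical conventions and problem sizes

Densities and percentages are rounded half-even to one decimal, matching
the presentation of the emulated tables. Coordinates are 0-based half-open
internally, 1-based in VCF, 0-based half-open in BED; every writer
documents its convention. Pipeline runs are byte-deterministic given
config + seed (no timestamps in outputs).

Default test/acceptance problem sizes — 300–400-kb two-chromosome genomes
for end-to-end runs, 10-Mb genomes for statistical checks (20 seeds for
bridge-truth equivalence, ~4,500 exhaustive classifier cases per strand,
50 random additive matrices, 10 panel seeds, 1,000 primer-design loci) —
were chosen so each statistical assertion has comfortable resolving power
(e.g. 3σ Poisson bounds at n ≈ 6,000) while a full run stays in the
minutes range on one core.

## Known limitations

* The bridge rule is evidence-limited: it cannot recover differences at
  loci the identity input does not confirm, and reports them only as
  `excluded_unconfirmed` counts.
* Primer design checks no thermodynamic dimer/hairpin structure and no
  genome-wide specificity (an exact-substring helper exists for toy
  genomes); product sizes are pure arithmetic, not PCR kinetics.
* The effect classifier assigns `Intron` to exonic-but-non-coding (UTR)
  positions, as the category scheme has no UTR class; transcripts with a
  CDS length not divisible by 3 are skipped with a warning.
* Fst is the classical H_T/H_S form without sample-size correction —
  appropriate for band data on inbred lines, not an unbiased estimator for
  small outbred samples.
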
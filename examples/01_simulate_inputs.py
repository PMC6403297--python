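"""Generate a small synthetic study: a two-chromosome reference, gene models,
two resequenced accessions with known InDel truth, and a 63-accession
five-species band panel.

Run: python examples/01_simulate_inputs.py
"""

from collections import Counter

from bridgemark import SimulationConfig, simulate_truth, write_truth

config = SimulationConfig(
    seed=1, n_chromosomes=2, chromosome_lengths=(300_000, 300_000)
)
truth = simulate_truth(config)
paths = write_truth(truth, "scratch/example_sim")

print(f"reference: {len(truth.reference)} chromosomes, "
      f"{sum(map(len, truth.reference.values())):,} bp, {len(truth.genes)} genes")
for acc, variants in truth.variants.items():
    sizes = Counter("1 bp" if v.size == 1 else ("2-5 bp" if v.size <= 5 else ">5 bp")
                    for v in variants)
    print(f"{acc}: {len(variants)} InDels vs reference "
          f"({sizes['1 bp']} single-base, {sizes['2-5 bp']} of 2-5 bp, "
          f"{sizes['>5 bp']} larger)")
print(f"panel: {len(truth.panel.accessions)} accessions x "
      f"{truth.panel.data.shape[1]} band alleles")
print(f"wrote {len(paths)} files to scratch/example_sim/")
# The size mix mirrors a real resequencing comparison: roughly two thirds of
# InDels are single-base, and identity intervals record where each accession
# is confirmed reference-identical (the precondition for the bridge rule).
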
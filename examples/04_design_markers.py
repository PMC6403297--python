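"""Design size-separable PCR markers from bridged InDels of 3-49 bp:
uniform genome-wide selection, 150-bp flanks, primer constraint search,
in-silico product sizes per accession and outcome classes.

Run: python examples/04_design_markers.py
"""

from bridgemark import SimulationConfig, bridge_compare, design_markers, simulate_truth
from bridgemark.markers import outcome_counts
from bridgemark.pipeline import polymorphism_rate

truth = simulate_truth(
    SimulationConfig(seed=1, n_chromosomes=2, chromosome_lengths=(300_000, 300_000))
)
result = bridge_compare(truth.call_set("PBC688"), truth.call_set("G29"))
call_sets = {a: truth.call_set(a) for a in ("PBC688", "G29")}
markers, failures = design_markers(
    truth.reference, result.variants, 60, call_sets=call_sets
)

m = markers[0]
print(f"example marker {m.marker_id} ({m.variant.size}-bp {m.variant.kind} "
      f"at {m.variant.chromosome}:{m.variant.position})")
print(f"  forward {m.primers.forward} (Tm {m.primers.tm_forward:.1f} C)")
print(f"  reverse {m.primers.reverse} (Tm {m.primers.tm_reverse:.1f} C)")
print(f"  products: reference {m.primers.product_size} bp, "
      + ", ".join(f"{a} {p} bp" if p else f"{a} none" for a, p in m.products.items())
      + f" -> {m.outcome}")

counts = outcome_counts(markers)
counts["failed"] += len(failures)
rates = polymorphism_rate(counts, designed=len(markers) + len(failures))
print(f"\n{len(markers) + len(failures)} markers attempted: "
      + ", ".join(f"{k} {v} ({rates[k]}%)" for k, v in counts.items()))
# A codominant marker amplifies in both accessions with product sizes
# differing by at least 3 bp (resolvable on 10% polyacrylamide gels);
# dominant markers amplify in only one genotype.
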
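"""End-to-end orchestration: simulate (or load) inputs, bridge the two
accessions, annotate effects, design markers, and run the diversity/tree
stage, writing deterministic text outputs plus a JSON run report."""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Sequence

import yaml

from . import __version__
from .bridge import bridge_compare, summarize
from .diversity import (
    allele_stats,
    distance_matrix,
    fst,
    nj_tree,
    species_cluster_purity,
    write_phylip,
)
from .effects import classify_all, summarize_effects
from .markers import design_markers, outcome_counts
from .simulate import SimulationConfig, simulate_truth, write_truth
from .variants import write_vcf

log = logging.getLogger("bridgemark")

STAGES = ("simulate", "bridge", "annotate", "design", "diversity")


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclasses.dataclass
class RunConfig:
    outdir: str
    simulation: SimulationConfig = dataclasses.field(default_factory=SimulationConfig)
    accessions: Sequence[str] = ("PBC688", "G29")
    stages: Sequence[str] = STAGES
    window_w: int = 10
    flank: int = 150
    n_markers: int = 100
    marker_size_min: int = 3
    marker_size_max: int = 49
    min_resolvable: int = 3
    distance_method: str = "nei_minimum"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        sim = SimulationConfig(**raw.pop("simulation", {}))
        return cls(simulation=sim, **raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d.pop("outdir")  # output location is not part of the run identity
        d["simulation"]["indel_size_pmf"] = {
            int(k): float(v) for k, v in d["simulation"]["indel_size_pmf"].items()
        }
        return d


def polymorphism_rate(counts: dict[str, int], designed: int | None = None) -> dict[str, float]:
    """Per-class percentages of designed markers, 1 decimal.

    ``polymorphic`` groups codominant + dominant (both show a genotype
    difference on the gel); ``codominant`` alone is also reported since the
    two roll-ups answer different questions.
    """
    total = designed if designed is not None else sum(counts.values())
    if total == 0:
        raise ValueError("no markers designed")
    pct = lambda n: round(100 * n / total, 1)
    out = {k: pct(v) for k, v in counts.items()}
    out["polymorphic"] = pct(counts.get("codominant", 0) + counts.get("dominant", 0))
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Run the enabled stages and return the run report (also written to
    ``report.json``). Outputs are byte-identical across reruns with the same
    config and seed."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "version": __version__,
        "seed": config.simulation.seed,
        "config": config.to_dict(),
        "stages": {},
    }
    enabled = set(config.stages)
    unknown = enabled - set(STAGES)
    if unknown:
        raise StageError("config", f"unknown stages {sorted(unknown)}")
    if "simulate" not in enabled:
        raise StageError("simulate", "this runner requires the simulate stage")
    if len(config.accessions) != 2:
        raise StageError("config", "exactly two accessions are compared")

    log.info("simulate: %d chromosomes", config.simulation.n_chromosomes)
    truth = simulate_truth(config.simulation, accessions=tuple(config.accessions))
    write_truth(truth, outdir)
    contigs = {c: len(s) for c, s in truth.reference.items()}
    report["stages"]["simulate"] = {
        "chromosomes": len(truth.reference),
        "genome_bp": sum(contigs.values()),
        "genes": len(truth.genes),
        "variants": {a: len(v) for a, v in truth.variants.items()},
    }

    bridged = None
    if "bridge" in enabled:
        a, b = config.accessions
        result = bridge_compare(truth.call_set(a), truth.call_set(b), config.window_w)
        lengths_mb = {c: length / 1e6 for c, length in contigs.items()}
        summ = summarize(result.variants, lengths_mb)
        write_vcf(
            outdir / "bridge.vcf",
            result.variants,
            contigs,
            f"{a}_vs_{b}",
            info_tags={v.key(): carrier for v, carrier in result.indels},
        )
        summ.per_chromosome.to_csv(outdir / "bridge.per_chromosome.tsv", sep="\t")
        summ.table_bins().to_csv(outdir / "bridge.size_histogram.tsv", sep="\t")
        report["stages"]["bridge"] = {
            "pair": [a, b],
            "emitted": len(result.indels),
            "excluded_shared": result.excluded_shared,
            "excluded_unconfirmed": result.excluded_unconfirmed,
            "overall_density_per_mb": summ.overall_density,
        }
        bridged = result

    if "annotate" in enabled:
        if bridged is None:
            raise StageError("annotate", "needs the bridge stage output")
        annotations = classify_all(bridged.variants, truth.genes, truth.reference)
        eff = summarize_effects(annotations)
        eff.to_csv(outdir / "effects.tsv", sep="\t")
        report["stages"]["annotate"] = {
            "annotated": len(annotations),
            "genic_count": eff.attrs["genic_count"],
            "genic_fraction_pct": eff.attrs["genic_fraction_pct"],
            "by_category": {
                k: int(v) for k, v in eff["count"].items() if v
            },
        }

    if "design" in enabled:
        if bridged is None:
            raise StageError("design", "needs the bridge stage output")
        call_sets = {acc: truth.call_set(acc) for acc in config.accessions}
        markers, failures = design_markers(
            truth.reference,
            bridged.variants,
            config.n_markers,
            call_sets=call_sets,
            flank=config.flank,
            size_min=config.marker_size_min,
            size_max=config.marker_size_max,
            min_resolvable=config.min_resolvable,
        )
        _write_marker_tables(outdir, markers, config.accessions)
        counts = outcome_counts(markers)
        counts["failed"] += len(failures)  # design failures join the failed class
        designed = len(markers) + len(failures)
        report["stages"]["design"] = {
            "selected": designed,
            "designed": len(markers),
            "design_failures": len(failures),
            "outcomes": counts,
            "rates_pct": polymorphism_rate(counts, designed) if designed else {},
        }

    if "diversity" in enabled:
        if truth.panel is None:
            raise StageError("diversity", "no panel simulated")
        panel = truth.panel
        stats = allele_stats(panel)
        stats.to_csv(outdir / "allele_stats.tsv", sep="\t")
        per_locus_fst, mean_fst = fst(panel)
        per_locus_fst.to_frame().to_csv(outdir / "fst.tsv", sep="\t")
        dist = distance_matrix(panel, level="accession", method=config.distance_method)
        write_phylip(outdir / "distances.phy", dist)
        tree = nj_tree(dist)
        (outdir / "tree.nwk").write_text(tree.newick + "\n")
        purity = species_cluster_purity(tree, panel.species.to_dict())
        report["stages"]["diversity"] = {
            "accessions": len(panel.accessions),
            "loci": len(panel.loci),
            "band_alleles": panel.data.shape[1],
            "data_points": panel.n_data_points,
            "mean_fst": round(mean_fst, 4),
            "mean_pic": round(float(stats["pic"].mean()), 4),
            "species_cluster_purity": purity,
        }

    (outdir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    return report


def _write_marker_tables(outdir: Path, markers, accessions) -> None:
    a, b = accessions
    rows = [
        "marker_id\tchromosome\tposition\tsize\tkind\tforward\treverse\ttm_f\ttm_r"
        f"\tproduct_ref\tproduct_{a}\tproduct_{b}\toutcome"
    ]
    fasta_lines = []
    bed_lines = []
    for m in markers:
        v = m.variant
        pa, pb = m.products.get(a), m.products.get(b)
        rows.append(
            f"{m.marker_id}\t{v.chromosome}\t{v.position}\t{v.size}\t{v.kind}"
            f"\t{m.primers.forward}\t{m.primers.reverse}"
            f"\t{m.primers.tm_forward:.1f}\t{m.primers.tm_reverse:.1f}"
            f"\t{m.primers.product_size}\t{pa if pa is not None else 'NA'}"
            f"\t{pb if pb is not None else 'NA'}\t{m.outcome}"
        )
        fasta_lines += [f">{m.marker_id}_F", m.primers.forward,
                        f">{m.marker_id}_R", m.primers.reverse]
        bed_lines.append(f"{v.chromosome}\t{v.start0}\t{v.end0}\t{m.marker_id}")
    (outdir / "markers.tsv").write_text("\n".join(rows) + "\n")
    (outdir / "primers.fa").write_text("\n".join(fasta_lines) + "\n")
    (outdir / "markers.bed").write_text("\n".join(bed_lines) + "\n")
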
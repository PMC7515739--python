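"""End-to-end orchestration with reproducible, self-describing run bundles.

Every run writes its resolved configuration, the tool version and the seed
next to its outputs; nothing in a bundle depends on wall-clock time, so a
rerun with the same config is byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .escapers import AlignmentScores, analyze_escapers
from .extraction import extract_from_reads
from .mapping import dedupe_to_clusters, map_spacers, positional_profile, write_bedgraph
from .seqmodel import write_array_spec, write_fasta, write_fastq, write_gff3
from .simulate import (
    SimulationConfig,
    default_array_spec,
    escaper_amplicon,
    generate_host_genomes,
    generate_phage_genome,
    mapping_reference,
    simulate_adaptation_reads,
    simulate_escaper_reads,
    simulate_expression_counts,
)
from .stats import (
    annotate_clusters,
    double_spacer_analysis,
    flank_matrix,
    jaccard_overlap,
    strand_bias_report,
)
from .temporal import classify_genes, heatmap_rows, normalize_abundance

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Flat run configuration; unknown keys in a config file are rejected."""

    seed: int = 0
    outdir: str = "spaceracq_run"
    # stage parameters
    max_mismatch: int = 3
    min_len: int = 20
    min_identity: float = 0.95
    flank: int = 10
    flank_window: int = 35
    pseudocount: float = 1.0
    normalization: str = "tpm"
    match: float = 1.0
    mismatch: float = -2.0
    gap_open: float = -6.0
    gap_extend: float = -0.5
    escaper_gene: str = "early_01"
    escaper_essential: bool = True
    log_level: str = "INFO"
    # simulation overrides (passed through to SimulationConfig)
    sim: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def sim_config(self) -> SimulationConfig:
        known = {f.name for f in dataclasses.fields(SimulationConfig)}
        unknown = set(self.sim) - known
        if unknown:
            raise ValueError(f"unknown simulation keys: {sorted(unknown)}")
        sim = dict(self.sim)
        sim.setdefault("seed", self.seed)
        return SimulationConfig(**sim)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _write_manifest(outdir: Path, config: RunConfig, counts: dict) -> None:
    manifest = {
        "tool": "spaceracq",
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "counts": counts,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")


def run_adaptation(config: RunConfig) -> dict:
    """Simulate (or load) amplicon reads, then extract -> map -> stats.

    Writes the simulated inputs, candidate/cluster/profile tables, the
    strand-bias and double-spacer reports and the flank matrix into
    ``config.outdir``, plus a manifest with per-stage counts. Returns the
    in-memory report dictionary.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim = config.sim_config()

    phage = generate_phage_genome(sim)
    hosts = generate_host_genomes(sim)
    array = default_array_spec(sim)
    reads, truth = simulate_adaptation_reads(phage, hosts, array, sim)

    write_fasta([phage], outdir / "phage.fasta")
    write_fasta(hosts, outdir / "host.fasta")
    write_gff3(phage.features, phage.id, outdir / "phage.gff3")
    write_array_spec(array, outdir / "array.txt")
    write_fastq(reads, outdir / "reads.fastq")
    truth.to_csv(outdir / "truth_spacers.tsv", sep="\t", index=False)

    candidates, qc = extract_from_reads(
        reads, array, config.max_mismatch, config.min_len, config.min_identity
    )
    if not candidates:
        logger.warning("no candidate spacers extracted; writing empty reports")
        report = {
            "qc": qc, "n_candidates": 0, "n_hits": 0, "n_unique_hits": 0,
            "n_clusters": 0,
            "phage_fraction_weighted": None, "phage_fraction_unweighted": None,
            "double_spacer": None, "convention": None,
        }
        (outdir / "adaptation_report.json").write_text(
            json.dumps(report, indent=2, sort_keys=True) + "\n"
        )
        _write_manifest(outdir, config, {"reads": len(reads), **qc, "clusters": 0})
        return report
    refs = [mapping_reference(phage), *hosts]
    hits = map_spacers(candidates, refs, config.min_identity)
    unique_hits = hits[hits["unique"]].reset_index(drop=True)
    clusters = dedupe_to_clusters(unique_hits)
    profile = positional_profile(clusters)

    ref_map = {r.id: r for r in refs}
    annotated = annotate_clusters(clusters, ref_map)
    bias = strand_bias_report(annotated)

    # per-read spacer table with regions, for the double-spacer analysis
    locus = annotated.set_index(["reference_id", "start", "length", "strand"])["region"]
    spacer_table = unique_hits.copy()
    spacer_table["region"] = [
        locus.get((r.reference_id, r.start, r.length, r.strand), "NA")
        for r in unique_hits.itertuples()
    ]
    try:
        double = double_spacer_analysis(spacer_table)
    except ValueError as exc:  # degenerate single-spacer distribution
        logger.warning("double-spacer analysis skipped: %s", exc)
        double = None
    flanks = flank_matrix(annotated, ref_map, config.flank, config.flank_window)

    pd.DataFrame(
        [(c.read_id, c.ordinal, c.sequence, c.length) for c in candidates],
        columns=["read_id", "ordinal", "sequence", "length"],
    ).to_csv(outdir / "candidates.tsv", sep="\t", index=False)
    hits.to_csv(outdir / "hits.tsv", sep="\t", index=False)
    clusters.to_csv(outdir / "clusters.tsv", sep="\t", index=False)
    write_bedgraph(profile, outdir / "profile_plus.bedgraph", outdir / "profile_minus.bedgraph")
    bias["table"].to_csv(outdir / "strand_bias.tsv", sep="\t", index=False)
    flanks.frequencies.to_csv(outdir / "flank_matrix.tsv", sep="\t")

    report = {
        "qc": qc,
        "n_candidates": len(candidates),
        "n_hits": int(len(hits)),
        "n_unique_hits": int(len(unique_hits)),
        "n_clusters": int(len(clusters)),
        "phage_fraction_weighted": bias["phage_fraction_weighted"],
        "phage_fraction_unweighted": bias["phage_fraction_unweighted"],
        "double_spacer": None
        if double is None
        else {
            "fraction_double": double.fraction_double,
            "chi_square": double.chi_square,
            "p_value": double.p_value,
            "cold_fraction_leader_proximal": double.cold_fraction_leader_proximal,
        },
        "convention": bias["convention"],
    }
    (outdir / "adaptation_report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True) + "\n"
    )
    _write_manifest(outdir, config, {"reads": len(reads), **qc, "clusters": len(clusters)})
    return report


def run_temporal(config: RunConfig) -> pd.DataFrame:
    """Simulate expression counts and classify gene temporal classes."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim = config.sim_config()
    phage = generate_phage_genome(sim)
    counts, lengths, truth = simulate_expression_counts(phage, config=sim)
    for rep, mat in counts.items():
        mat.to_csv(outdir / f"counts_{rep}.tsv", sep="\t")
    profiles = classify_genes(counts, lengths, config.normalization, config.pseudocount)
    profiles.to_csv(outdir / "temporal_profiles.tsv", sep="\t")
    abundance = normalize_abundance(counts["rep1"], lengths, config.normalization)
    rows, flagged = heatmap_rows(abundance)
    rows.to_csv(outdir / "heatmap.tsv", sep="\t")
    # classes written back into the annotation
    assigned = profiles.loc[[g for g in truth.index], "temporal_class"]
    feats = [
        dataclasses.replace(f, temporal_class=assigned.get(f.gene_id, f.temporal_class))
        for f in phage.features
    ]
    write_gff3(feats, phage.id, outdir / "phage_classified.gff3")
    recovery = float((assigned == truth).mean())
    (outdir / "temporal_report.json").write_text(
        json.dumps({"class_recovery": recovery, "flagged_zero_rows": flagged}, indent=2) + "\n"
    )
    _write_manifest(outdir, config, {"genes": len(profiles)})
    return profiles


def run_escapers(config: RunConfig) -> dict:
    """Simulate escaper amplicon reads and compute the deletion spectrum."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim = config.sim_config()
    phage = generate_phage_genome(sim)
    amplicon, protospacer, fwd, rev = escaper_amplicon(phage, config.escaper_gene, sim)
    reads, truth = simulate_escaper_reads(amplicon, protospacer, config.escaper_essential, sim)
    write_fastq(reads, outdir / "escaper_reads.fastq")
    truth.to_csv(outdir / "truth_deletions.tsv", sep="\t", index=False)

    scores = AlignmentScores(config.match, config.mismatch, config.gap_open, config.gap_extend)
    variants, summary = analyze_escapers(reads, amplicon, fwd, rev, protospacer, scores)
    pd.DataFrame(
        [
            {
                "sequence": v.sequence,
                "count": v.count,
                "deletions": ";".join(f"{s}:{l}" for s, l in v.deletions),
                "mismatches": v.mismatches,
                "frame_preserving": v.frame_preserving,
                "overlaps_protospacer": v.overlaps_protospacer,
                "is_wildtype": v.is_wildtype,
            }
            for v in variants
        ]
    ).to_csv(outdir / "escaper_variants.tsv", sep="\t", index=False)
    (outdir / "escaper_spectrum.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    _write_manifest(outdir, config, {"reads": len(reads), "variants": len(variants)})
    return summary


def run_all(config: RunConfig) -> dict:
    """Run adaptation, temporal and escaper analyses into one bundle."""
    base = Path(config.outdir)
    reports = {}
    for name, fn in (("adaptation", run_adaptation), ("temporal", run_temporal), ("escapers", run_escapers)):
        sub = dataclasses.replace(config, outdir=str(base / name))
        result = fn(sub)
        reports[name] = "ok" if result is not None else "failed"
    _write_manifest(base, config, {"stages": list(reports)})
    return reports
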
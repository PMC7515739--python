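"""Call the deletion spectrum of CRISPR-escaper phages.

Simulates amplicon reads of a targeted protospacer region for an essential
gene (deletions constrained to multiples of 3) and a non-essential gene
(unconstrained lengths), then primer-filters, dereplicates, aligns and
summarizes the deletions.
"""

from spaceracq import SimulationConfig, analyze_escapers, simulate_escaper_reads
from spaceracq.simulate import escaper_amplicon, generate_phage_genome

cfg = SimulationConfig(seed=4, escaper_n_reads=2_000, escaper_n_variants=40)
phage = generate_phage_genome(cfg)

for gene, essential in (("early_01", True), ("early_02", False)):
    amp, protospacer, fwd, rev = escaper_amplicon(phage, gene, cfg)
    reads, truth = simulate_escaper_reads(amp, protospacer, essential, cfg)
    variants, summary = analyze_escapers(reads, amp, fwd, rev, protospacer)
    sizes = summary["deletion_size_summary"]
    print(f"{gene} (essential={essential}):")
    print(f"  wild-type read fraction: {summary['wildtype_read_fraction']:.3f}")
    print(f"  deletion variants: {summary['n_deletion_variants']}")
    print(f"  frame-preserving fraction (unique variants): "
          f"{summary['frame_preserving_fraction_unweighted']:.3f}")
    print(f"  deletion sizes (bp): min {sizes['min']:.0f}, median {sizes['median']:.0f}, "
          f"max {sizes['max']:.0f}")
# an essential gene tolerates only frame-preserving deletions (fraction 1.0);
# a non-essential gene accepts any length, so ~1/3 preserve the frame
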
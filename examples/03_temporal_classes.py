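"""Classify phage genes into early/middle/late temporal classes.

Simulates two replicates of gene x timepoint RNA-seq counts over
0/10/30/50/70 min post-infection, TPM-normalizes them, averages the
replicates and applies the log-fold-change sign rules.
"""

from spaceracq import (
    SimulationConfig,
    classify_genes,
    generate_phage_genome,
    simulate_expression_counts,
)

cfg = SimulationConfig(seed=3)
phage = generate_phage_genome(cfg)
counts, lengths, truth = simulate_expression_counts(phage, config=cfg)

profiles = classify_genes(counts, lengths, mode="tpm")
phage_prof = profiles.loc[truth.index]

print(phage_prof[["logfc_30vs50", "logfc_50vs70", "temporal_class"]].head(6).round(3))
recovery = (phage_prof["temporal_class"] == truth).mean()
print(f"\nclass recovery vs implanted truth: {recovery:.2%} of {len(truth)} genes")
print(phage_prof["temporal_class"].value_counts().to_dict())
# logfc_30vs50 < 0 -> early (peak before 30 min); > 0 with a post-50 decline
# -> middle; logfc_50vs70 > 0 -> late (still rising at 70 min)
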
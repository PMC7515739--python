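# spaceracq

Analysis of **Type III CRISPR–Cas spacer acquisition during phage
infection**, built for amplicon-sequencing experiments in which expanded
CRISPR arrays are PCR-amplified (leader primer × leader-proximal-spacer
primer) and deep-sequenced. The package is a library first — its public
face is the importable API plus the narrative scripts in `examples/` —
with a thin `spaceracq` CLI for end-to-end runs.

It is aimed at researchers studying CRISPR adaptation who need to turn raw
expanded-array reads into quantitative acquisition statistics, and at
anyone who wants a fully synthetic, truth-tabled testbed for such
pipelines.

## What it computes

1. **Spacer extraction** — CRISPR repeats are located in each read by
   ungapped matching (Hamming distance ≤ `max_mismatch`, both
   orientations); the sequences between consecutive repeats are the newly
   acquired spacers, ordinal 1 = leader-proximal. Candidates shorter than
   20 bp or matching pre-existing array spacers are removed.
2. **Protospacer mapping** — each spacer is mapped to the phage and host
   replicons at a 95% identity threshold (identity = matches / spacer
   length, ungapped); only spacers with exactly one passing locus
   genome-wide are kept, then clustered by (reference, start, length,
   strand) and summed into strand-split positional profiles.
3. **Bias statistics** — a protospacer is *transcript-targeting* when the
   spacer matches the gene's template strand (crRNA complementary to the
   mRNA, the protective configuration for transcription-dependent Type III
   interference). The package reports targeting fractions per replicon /
   temporal class / region, both read-weighted and over unique spacers;
   replicate overlap as Jaccard similarity J = |A∩B| / |A∪B|; the region
   composition of two-spacer reads against the single-spacer law
   (chi-square goodness of fit, Σ(O−E)²/E); and flank/protospacer base
   frequencies (a PAM check for a system that should not have one).
4. **Temporal classes** — gene×timepoint counts are TPM- (or CPM-)
   normalized, replicates averaged, and each gene classified from
   LogFC_XvsY = log₁₀A(Y) − log₁₀A(X): early if LogFC_30vs50 < 0, middle
   if LogFC_30vs50 > 0 and LogFC_50vs70 < 0, late if LogFC_50vs70 > 0.
5. **Escaper deletion spectra** — protospacer-region amplicons from
   CRISPR-escaping phages are primer-filtered, dereplicated, globally
   aligned (affine gaps: match +1, mismatch −2, gap open −6, extend −0.5),
   deletions left-normalized, and the reading-frame consequences
   summarized (frame-preserving ⇔ Σ deletion lengths ≡ 0 mod 3).
6. **Synthetic data** — `spaceracq.simulate` generates every input with a
   known truth table: an LTR-bearing phage genome (default 6639 bp
   terminal repeat carrying the early "hot" gene block), amplicon reads
   with 0–5 inserted repeat–spacer units under a tunable selection model,
   RNA-seq-like count matrices, and escaper amplicons with implanted
   deletions.

## Worked example

```bash
python examples/01_simulate_and_extract.py
```

```
phage genome: 38000 bp, terminal repeat 6639 bp
reads: 2000, candidate spacers: 2088
spacer lengths: 35-42 bp
recall vs truth: 1.000  precision: 1.000
```

Every implanted repeat–spacer unit was recovered at its leader-proximal
ordinal, with no false calls, and the acquired spacers span the 35–42 bp
range characteristic of Type III arrays. The selection example contrasts
the acquisition null with strong selection (`examples/02_strand_bias.py`):

```
selection_factor = 1
  targeting fraction, unique phage spacers: 0.516
  cold-region spacers in double reads at leader-proximal position: 0.520
selection_factor = 100
  targeting fraction, hot region, read-weighted: 0.962
  cold-region spacers in double reads at leader-proximal position: 0.977
```

Without selection acquisition is strand-symmetric (~0.5); selection drives
the read-weighted hot-region targeting fraction toward 1 and makes
cold-region spacers in two-spacer reads almost exclusively leader-proximal
— they were acquired *after* the protective hot-region spacer. The other
examples print temporal-class recovery and the essential/non-essential
escaper deletion spectra.

An end-to-end run with all reports written to disk:

```bash
spaceracq all --seed 1 --outdir run1
```

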
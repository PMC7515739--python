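# Methods

This note documents the models, conventions and numerical choices behind
`spaceracq`, and what the synthetic testbed does and does not establish
about real data.

## Coordinates, alphabet, conventions

All internal coordinates are 0-based half-open on the top strand of the
stored reference; GFF3's 1-based closed intervals are converted at I/O and
nowhere else. Sequences are uppercase DNA over {A,C,G,T}; reads may carry
N; other ambiguity codes are rejected at input because spacers and repeats
in this assay are unambiguous.

**Targeting convention.** A protospacer is *transcript-targeting* when the
spacer sequence equals the gene's template strand there, i.e. the crRNA
base-pairs with the mRNA — the configuration that licenses
transcription-dependent Type III interference. With hit strand defined by
"spacer matches the stored top strand", a gene on "+" is targeted by hits
on "−" and vice versa. Strand vocabulary around this assay is notoriously
inconsistent ("targeting the transcribed/non-transcribed strand" is used
both ways in the literature), so every report states this convention
explicitly rather than relying on parallel/antiparallel phrasing.

## Spacer extraction

Repeats are found by ungapped (Hamming) matching of the array repeat and
its reverse complement at every read offset, keeping hits with at most
`max_mismatch` substitutions (default 3, ≈8% of a 36 bp repeat — the
tolerance is a knob because sequencing error rates vary). Overlapping
candidate hits are resolved greedily left to right, ties at equal offset
by fewer mismatches; this is deterministic and, after canonicalization,
orientation-invariant. Reads whose repeat hits disagree in orientation are
flagged and skipped. Terminal partial repeats do not delimit spacers —
only full-length hits count — which avoids chimeric spacer calls at read
ends at the cost of losing spacers in truncated reads.

A read with hits on "−" is reverse-complemented before ordinals are
assigned, so ordinal 1 is always the leader-proximal (most recently
acquired) unit. At most five spacers are taken per read; extras are
discarded with a warning. Candidates shorter than 20 bp, or matching a
pre-existing array spacer at the mapping identity threshold in either
orientation, are removed — the latter are old array content carried into
the amplicon, not acquisitions.

## Mapping

Identity is computed ungapped over the full spacer length
(matches / spacer length). Spacers are 35–42 bp, so the 95% threshold
admits at most two substitutions and a gapped alignment has nothing to
add; the identity denominator choice is recorded in output metadata.
"Uniquely mapped" means exactly one threshold-passing locus across **all**
references jointly (phage + chromosome + megaplasmid), which prevents a
spacer from being counted as both phage- and host-derived; equal-identity
ties are never broken — they make the spacer non-unique and it is dropped.

The scan itself is exact: candidate loci are generated by pigeonhole
seeding (any locus within m substitutions of the pattern contains one of
m+1 disjoint pattern chunks exactly; every chunk occurrence is verified by
full Hamming comparison). This is equivalent to scanning every offset of
both strands and is tested against an exhaustive windowed scan and an
independent indicator-convolution oracle. When the identity threshold is
loose enough that chunks drop below 8 bp the code falls back to the
exhaustive scan.

An LTR caveat: a virion genome carries its terminal repeat twice, so every
LTR protospacer would be multi-locus and die in the uniqueness filter.
Mapping therefore uses a single-copy view of simulated LTR genomes (left
LTR + interior, right LTR trimmed) — the same representation that
published assemblies of terminally redundant phages use.

## Bias statistics

Targeting fractions are reported per replicon, per temporal class and per
region, each computed twice: read-count-weighted ("all spacers") and
unweighted over clusters ("unique spacers"). The two weightings separate
acquisition bias from post-acquisition selection — selection moves the
weighted fractions, not the unweighted ones. Genes straddled by a
protospacer are resolved by majority overlap, exact ties to the gene with
the smaller start (deterministic). Categories with no genic spacers
report NaN.

The double-spacer analysis compares the region composition of spacers
from two-spacer reads against expected counts derived from the
single-spacer distribution, with a chi-square goodness-of-fit statistic
(Σ(O−E)²/E, no continuity correction, df = regions − 1). Because the
ordering question — were cold-region spacers in double reads acquired
first or last? — is best left to the data, the report gives the ordinal
composition of cold-region double-read spacers both ways (fraction at
ordinal 1 and at ordinal > 1).

Replicate overlap is Jaccard similarity over distinct spacer sequences.
Flank analysis builds a position frequency matrix over `flank` bases
upstream, the first `window` (default 35) protospacer bases and `flank`
bases downstream, oriented 5'→3' along the protospacer strand;
protospacers too close to a reference end are skipped and counted.

## Temporal classification

TPM here is rate = count/length(kb), scaled so each column sums to one
million; CPM skips the length normalization. Both are provided because
"normalized to the total number of counted reads" admits either reading;
TPM is the default and the mode is recorded in every output. Replicates
are combined by averaging normalized abundances before the LogFC
computation (the combination rule is a config option and per-replicate
classes are also reported). LogFC uses a pseudocount (default 1, on the
TPM scale where abundances are ~10³–10⁵) to guard zeros.

The class rules overlap (a gene with LogFC_30vs50 < 0 and LogFC_50vs70 > 0
satisfies both the early and late clauses), so they are applied in order
early → middle → late; this anchors "early" to the pre-30-min maximum.
Strict inequalities are kept: a gene with both LogFC exactly zero is
reported unclassified rather than forced into a class.

## Escaper analysis

Reads are primer-filtered (both primers at the ends, ≤ `max_mismatch`
each, orientation canonicalized), then dereplicated by exact identity —
no similarity clustering, matching how such amplicon data are usually
collapsed after quality trimming. Variants are globally aligned to the
wild-type amplicon with affine gap scores match +1 / mismatch −2 / gap
open −6 / gap extend −0.5; extension is far cheaper than mismatch so one
contiguous deletion of tens-to-hundreds of bases beats scattering the
difference, which is the regime escaper deletions live in. Deletions are
reported in reference coordinates and left-normalized (shifted to the
lowest coordinate while the flanking base equals the last deleted base —
the convention shared with standard variant normalization), so placements
inside homopolymers and tandem repeats are deterministic. Point mutations
are counted but not interpreted. A variant longer than the reference by
more than the insertion allowance is flagged rather than called.

Frame preservation is Σ deletion lengths ≡ 0 (mod 3), reported both over
unique variants and read-weighted, since "a third of deletions preserved
the frame" admits both denominators.

## The synthetic study

The generator's defaults are the study conditions:

| parameter | default | rationale |
| --- | --- | --- |
| genome_length / ltr_length | 38,000 / 6,639 bp | desk-scale phage with the measured terminal-repeat length |
| genes | 10 early (in LTR) + 10 middle + 10 late | early block inside the LTR ("hot"), interior "cold" |
| spacer_length_range | 35–42 bp | observed Type III spacer length spread |
| n_reads | 10,000 | enough for binomial CIs at ~1% precision |
| error_rate | 0.005/bp | post-merge Illumina amplicon scale |
| host_fraction | 0.05 | >95% of acquisitions are phage-derived |
| p_double (+ triple/quad/quint) | 0.032 (0.003/0.0005/0.0001) | observed two-spacer clone rate; up to 5 units per read |
| selection_factor | 1 (null); ~100 for selection runs | the per-spacer advantage is not experimentally quantified; s is free |
| expression depth / NB dispersion | 300,000 / 15 | moderate overdispersion; `None` gives the noiseless limit |
| escaper: 50% wild type, deletions ≤ 300 bp, 700 bp amplicon | | ~half of escaper reads retain the wild-type protospacer |

**Selection model.** Selection is modeled as post-acquisition clonal
amplification, not biased acquisition: every clone draws spacers
uniformly; a clone carrying at least one protective spacer
(transcript-targeting and, under the `ltr` model, in the hot region; under
the `any_gene` model, in any gene) has its abundance multiplied by
`selection_factor` once — protection is a threshold property, a second
protective spacer adds nothing. With s = 1 this collapses to the uniform
null, which is what makes the null calibration tests meaningful.

**Ordering of multiple acquisitions.** In clones with more than one new
unit, units at ordinal ≥ 2 are drawn from the selection-weighted
population (the clone pre-existed and survived selection) while the
leader-proximal unit is a fresh, not-yet-selected draw. Under strong
selection this reproduces, emergently, the signature that cold-region
spacers in double-spacer reads sit almost exclusively at the
leader-proximal position; with s = 1 the two laws coincide.

**Expression shapes.** Early genes peak at 10 min and decline; middle
genes rise to a 50-min maximum then decline (a peak at 30 min would be
classified early under the rule precedence — the rules define "middle" as
still rising between 30 and 50 min); late genes keep rising after 50 min.
Phage counts are zero in the pre-infection control column; flat-expression
host background genes keep that column non-degenerate under
normalization. Counts are negative-binomial around the expected
abundances.

**Escaper reads** emulate quality-trimmed merged amplicons, so their
residual error rate (`escaper_error_rate`) defaults to 0 and is separate
from the raw adaptation-read rate; every emitted read retains both primer
ends, and essential-gene deletions are multiples of 3 by construction.

**What the testbed does not emulate:** quality-score structure and
position-dependent error profiles, chimeric PCR artifacts, real genome
composition (references are iid-uniform DNA, so mapping uniqueness is
easier than in repeat-rich genomes), phage population dynamics over
multiple infection cycles, and packaging/termini read signatures. Passing
tests therefore establish the correctness of the algorithms and the
internal consistency of the statistics under the stated models, not
robustness to every artifact of a real sequencing run.

## Problem sizes and determinism

The test suite and acceptance script run the pipeline at 10,000 reads,
1,000 mapping oracles on a 50 kb reference, 1,000 chi-square null tables,
30 temporal genes × 2 replicates and 1,000 escaper variants — sizes chosen
so every binomial/multinomial check has the precision its tolerance needs.
Every generator draws from `numpy.random.default_rng([seed, stream])` with
a fixed stream id per generator, so outputs are byte-identical under a
fixed seed and independent of call order; run bundles embed the resolved
config, version and seed and contain no timestamps, making reruns
byte-for-byte reproducible.

## Known limitations

* Extraction requires full-length repeat hits, so a spacer adjacent to a
  truncated terminal repeat is not recovered.
* Mapping is exact ungapped scanning; for multi-megabase references a
  seeded index amortizes well, but no heuristic accelerations
  (minimizers, FM-indexes) are provided, and indel-containing protospacers
  are not found (a gapped fallback would be needed).
* `merge_pairs` uses a single best-overlap consensus; it does not model
  quality-aware posterior merging.
* The chi-square test is asymptotic; with fewer than ~5 expected counts
  per region it should not be trusted, and the code raises only on the
  degenerate zero-expected case.
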
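"""Synthetic inputs for every pipeline stage, with ground-truth tables.

The generator emulates a *Thermus*-phage infection experiment in which Type
III CRISPR arrays expand by acquiring new spacers:

* an LTR-bearing lytic phage genome — identical long terminal repeats at
  both ends (default 6639 bp), early genes inside the LTR ("hot" region),
  middle and late gene blocks in the interior ("cold" region);
* amplicon reads of expanded arrays: leader tail, then k inserted
  repeat+spacer units (k = 0..5, leader-proximal = newest), a closing
  repeat, and the old leader-proximal spacer that carries the reverse
  primer site;
* RNA-seq-like count matrices with implanted early/middle/late dynamics;
* escaper amplicons carrying deletions over a targeted protospacer,
  frame-preserving in an essential gene and unconstrained otherwise.

Selection is modeled as post-acquisition clonal amplification: a clone's
abundance is multiplied by ``selection_factor`` for every protective spacer
it carries (transcript-targeting and, under the LTR model, mapping to the
hot region). Acquisition itself is unbiased, so ``selection_factor = 1``
gives the uniform null. In clones with more than one new unit, the older
units (ordinal >= 2) are drawn from the selection-weighted population —
the clone pre-existed and survived — while the leader-proximal unit is a
fresh, unselected acquisition. This is what makes cold-region spacers in
double-spacer reads predominantly leader-proximal under strong selection.

Every generator is deterministic under a fixed ``seed``; each one derives
an independent stream from it, so outputs do not depend on call order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .seqmodel import (
    CRISPRArraySpec,
    GeneFeature,
    Read,
    ReadSet,
    ReferenceGenome,
    revcomp,
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i


@dataclass
class SimulationConfig:
    """All tunables of the synthetic study, with the study's defaults.

    ``ltr_length`` (6639 bp) and ``spacer_length_range`` (35–42 bp) follow
    the measured phage architecture and spacer-length spread this assay
    produces; ``p_double`` defaults to the observed 3.2% two-spacer clone
    rate. ``selection_factor`` is a free parameter (the per-spacer
    protection advantage is not quantified experimentally): 1 = no
    selection, large values (~100) give near-complete dominance of
    protective spacers among read-weighted counts.
    """

    seed: int = 0

    # phage genome architecture
    genome_length: int = 38_000
    ltr_length: int = 6_639
    n_early: int = 10
    n_middle: int = 10
    n_late: int = 10
    gene_strand_plus_prob: float = 0.8

    # host replicons (scaled-down stand-ins for chromosome + megaplasmid)
    host_chromosome_length: int = 50_000
    host_megaplasmid_length: int = 20_000

    # adaptation amplicon reads
    n_reads: int = 10_000
    selection_factor: float = 1.0
    error_rate: float = 0.005
    spacer_length_range: tuple[int, int] = (35, 42)
    host_fraction: float = 0.05
    p_zero: float = 0.0
    p_double: float = 0.032
    p_triple: float = 0.003
    p_quad: float = 0.0005
    p_quint: float = 0.0001
    protective_model: str = "ltr"  # "ltr" (phiFa-like) or "any_gene" (phiKo-like)

    # expression counts
    expression_depth: int = 300_000
    nb_dispersion: Optional[float] = 15.0  # None -> noiseless (rounded means)
    n_replicates: int = 2
    n_host_background: int = 20

    # escaper amplicons
    escaper_n_reads: int = 4_000
    escaper_n_variants: int = 50
    escaper_wildtype_fraction: float = 0.5
    escaper_max_deletion: int = 300
    escaper_amplicon_length: int = 700
    escaper_primer_length: int = 20
    # escaper reads emulate quality-trimmed, merged amplicons, so their
    # residual error rate is separate from the raw adaptation-read rate
    escaper_error_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.selection_factor < 1:
            raise ValueError("selection_factor must be >= 1")
        if not (0 <= self.error_rate <= 0.05):
            raise ValueError("error_rate must lie in [0, 0.05]")
        lo, hi = self.spacer_length_range
        if lo < 20 or hi < lo:
            raise ValueError("spacer_length_range must satisfy 20 <= min <= max")
        if self.ltr_length < 0 or self.ltr_length >= self.genome_length / 2:
            raise ValueError("ltr_length must satisfy 0 <= L < genome_length/2")
        if not (0 <= self.host_fraction <= 1):
            raise ValueError("host_fraction must lie in [0, 1]")

    def rng(self, stream: int) -> np.random.Generator:
        """Independent deterministic stream per generator."""
        return np.random.default_rng([self.seed, stream])


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return rng.choice(_BASES, size=n).tobytes().decode()


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Apply iid substitution errors at the given per-base rate."""
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(arr.size) < rate)[0]
    if hits.size:
        codes = _CODE[arr[hits]]
        # N or other codes left untouched
        ok = codes < 4
        hits, codes = hits[ok], codes[ok]
        arr[hits] = _BASES[(codes + rng.integers(1, 4, size=codes.size)) % 4]
    return arr.tobytes().decode()


# ---------------------------------------------------------------------------
# Phage + host genomes
# ---------------------------------------------------------------------------

def generate_phage_genome(config: SimulationConfig) -> ReferenceGenome:
    """An LTR-bearing phage genome with early/middle/late gene blocks.

    The virion sequence is ``core + core[:L]`` so its first and last L bp
    are identical terminal repeats. Early genes sit inside the left LTR
    (the "hot" region, injected first); middle and late blocks occupy the
    interior ("cold"). The right LTR is an exact copy and carries no
    separate feature records. ``metadata["packaging_start"]`` records the
    coordinate at which genome packaging begins (the left end).
    """
    rng = config.rng(0)
    G, L = config.genome_length, config.ltr_length
    core = _random_dna(rng, G - L)
    sequence = core + core[:L]

    features: list[GeneFeature] = []

    def _pack(prefix, n, lo, hi, tclass, essential_pattern):
        if n == 0:
            return
        span = (hi - lo) / n
        glen = int(span * 0.8)
        if glen < 60:
            raise ValueError(
                f"cannot pack {n} {tclass} genes into [{lo},{hi}): genes would be {glen} bp"
            )
        for i in range(n):
            s = lo + int(i * span)
            strand = "+" if rng.random() < config.gene_strand_plus_prob else "-"
            features.append(
                GeneFeature(
                    gene_id=f"{prefix}{i + 1:02d}",
                    start=s,
                    end=s + glen,
                    strand=strand,
                    temporal_class=tclass,
                    essential=essential_pattern(i),
                )
            )

    interior_lo, interior_hi = L, G - L
    mid_split = interior_lo + (interior_hi - interior_lo) // 2
    # alternate essential flags in the LTR: the hot region holds both an
    # essential (RNAP-like) and a dispensable gene for the escaper model
    _pack("early_", config.n_early, 0, L, "early", lambda i: i % 2 == 0)
    _pack("middle_", config.n_middle, interior_lo, mid_split, "middle", lambda i: False)
    _pack("late_", config.n_late, mid_split, interior_hi, "late", lambda i: False)

    regions = {
        "hot": (0, L),
        "cold": (L, G - L),
        "LTR_left": (0, L),
        "LTR_right": (G - L, G),
    }
    return ReferenceGenome(
        id="phage_sim",
        sequence=sequence,
        topology="linear",
        features=features,
        regions=regions,
        metadata={"packaging_start": 0, "ltr_length": L},
    )


def mapping_reference(genome: ReferenceGenome) -> ReferenceGenome:
    """Single-copy mapping view of an LTR genome (right LTR trimmed).

    Both terminal repeats carry the same sequence, so mapping against the
    full virion would make every LTR protospacer multi-locus and drop it
    under the uniqueness filter. Published phage assemblies represent the
    repeated region once; this view does the same.
    """
    L = genome.metadata.get("ltr_length", 0)
    if L == 0:
        return genome
    return ReferenceGenome(
        id=genome.id,
        sequence=genome.sequence[: len(genome.sequence) - L],
        topology=genome.topology,
        features=list(genome.features),
        regions={k: v for k, v in genome.regions.items() if k != "LTR_right"},
        metadata=dict(genome.metadata),
    )


def generate_host_genomes(config: SimulationConfig) -> list[ReferenceGenome]:
    """Scaled-down host chromosome and megaplasmid with gene annotations."""
    rng = config.rng(1)
    out = []
    for name, length in (
        ("chromosome_sim", config.host_chromosome_length),
        ("megaplasmid_sim", config.host_megaplasmid_length),
    ):
        seq = _random_dna(rng, length)
        feats = []
        pos, i = 200, 1
        while pos + 900 < length - 200:
            glen = int(rng.integers(500, 1500))
            glen = min(glen, length - 200 - pos)
            strand = "+" if rng.random() < 0.5 else "-"
            feats.append(GeneFeature(f"{name}_g{i:03d}", pos, pos + glen, strand))
            pos += glen + int(rng.integers(50, 300))
            i += 1
        out.append(ReferenceGenome(id=name, sequence=seq, features=feats))
    return out


def default_array_spec(config: SimulationConfig) -> CRISPRArraySpec:
    """A Type III-like array: 36 bp repeat, three pre-existing 38 bp spacers.

    The forward primer is the start of the emitted leader tail; the reverse
    primer anneals to the 3' end of the leader-proximal pre-existing spacer,
    so every amplicon ends inside that spacer.
    """
    rng = config.rng(2)
    leader = _random_dna(rng, 60)
    repeat = _random_dna(rng, 36)
    spacers = [_random_dna(rng, 38) for _ in range(3)]
    fwd = leader[-40:][:20]
    rev = revcomp(spacers[0][-20:])
    return CRISPRArraySpec(
        array_id="CRISPR-sim",
        repeat=repeat,
        spacers=spacers,
        leader=leader,
        amplicon_primers=(fwd, rev),
    )


# ---------------------------------------------------------------------------
# Adaptation amplicon reads
# ---------------------------------------------------------------------------

def _feature_index(genome: ReferenceGenome):
    feats = sorted(genome.features, key=lambda f: f.start)
    starts = np.array([f.start for f in feats], dtype=np.int64)
    ends = np.array([f.end for f in feats], dtype=np.int64)
    strands = np.array([1 if f.strand == "+" else -1 for f in feats], dtype=np.int8)
    return starts, ends, strands


def _draw_spacer_batch(n, refs, ref_probs, rng, config):
    """Draw n protospacer loci uniformly over the given references.

    Returns a DataFrame with source ref, start, length, strand, and the
    targeting/region/protective annotations used by the selection model.
    """
    lo, hi = config.spacer_length_range
    ref_idx = rng.choice(len(refs), size=n, p=ref_probs)
    lengths = rng.integers(lo, hi + 1, size=n)
    strands = rng.choice(np.array(["+", "-"]), size=n)
    ref_lens = np.array([len(r.sequence) for r in refs])
    starts = (rng.random(n) * (ref_lens[ref_idx] - lengths)).astype(np.int64)

    targeting = np.zeros(n, dtype=bool)
    in_hot = np.zeros(n, dtype=bool)
    in_gene = np.zeros(n, dtype=bool)
    for i, ref in enumerate(refs):
        mask = ref_idx == i
        if not mask.any():
            continue
        mid = starts[mask] + lengths[mask] // 2
        g_starts, g_ends, g_strands = _feature_index(ref)
        if g_starts.size:
            j = np.searchsorted(g_starts, mid, side="right") - 1
            inside = (j >= 0) & (mid < g_ends[np.clip(j, 0, None)])
            gene_strand = np.where(inside, g_strands[np.clip(j, 0, None)], 0)
        else:
            inside = np.zeros(mid.size, dtype=bool)
            gene_strand = np.zeros(mid.size, dtype=np.int8)
        spacer_strand = np.where(strands[mask] == "+", 1, -1)
        # targeting = crRNA complementary to mRNA = spacer on the strand
        # opposite the gene (spacer sequence equals the template strand)
        targeting[mask] = inside & (gene_strand != 0) & (gene_strand != spacer_strand)
        in_gene[mask] = inside
        if "hot" in ref.regions:
            h0, h1 = ref.regions["hot"]
            in_hot[mask] = (mid >= h0) & (mid < h1)

    if config.protective_model == "ltr":
        protective = targeting & in_hot
    elif config.protective_model == "any_gene":
        protective = targeting & in_gene
    else:
        raise ValueError(f"unknown protective_model {config.protective_model!r}")

    return pd.DataFrame(
        {
            "ref_idx": ref_idx,
            "start": starts,
            "length": lengths,
            "strand": strands,
            "targeting": targeting,
            "in_hot": in_hot,
            "protective": protective,
        }
    )


def simulate_adaptation_reads(
    genome: ReferenceGenome,
    hosts: Sequence[ReferenceGenome],
    array: CRISPRArraySpec,
    config: SimulationConfig,
) -> tuple[ReadSet, pd.DataFrame]:
    """Expanded-array amplicon reads plus a per-spacer truth table.

    Each read is ``leader_tail + (repeat + spacer)*k + repeat + old_spacer1``
    with k in {0..5} new units, ordinal 1 leader-proximal. Protospacers are
    drawn uniformly (phage majority, hosts at ``host_fraction``); clone
    abundance is multiplied by ``selection_factor`` per protective spacer
    and reads are sampled from clones by abundance. Substitution errors are
    applied at ``error_rate``.

    The truth table has one row per implanted spacer per emitted read:
    read_id, clone_id, ordinal, ref_id, source, start, length, strand,
    region, targeting, protective, sequence (error-free).
    """
    rng = config.rng(3)
    phage_map = mapping_reference(genome)
    refs = [phage_map, *hosts]
    host_lens = np.array([len(h.sequence) for h in hosts], dtype=float)
    if hosts and config.host_fraction > 0:
        probs = np.concatenate(
            [[1 - config.host_fraction], config.host_fraction * host_lens / host_lens.sum()]
        )
    else:
        probs = np.array([1.0] + [0.0] * len(hosts))

    truth_columns = [
        "read_id", "clone_id", "ordinal", "ref_id", "source", "start",
        "length", "strand", "region", "targeting", "protective", "sequence",
    ]
    if config.n_reads == 0:
        return ReadSet(reads=[], pairing="merged"), pd.DataFrame(columns=truth_columns)

    n_clones = config.n_reads
    p_multi = [config.p_zero, 0.0, config.p_double, config.p_triple, config.p_quad, config.p_quint]
    p_multi[1] = 1.0 - sum(p_multi)
    if p_multi[1] < 0:
        raise ValueError("multi-spacer probabilities exceed 1")
    k_per_clone = rng.choice(6, size=n_clones, p=p_multi)
    max_units = 5
    if (k_per_clone > max_units).any():  # pragma: no cover - guarded by p vector
        raise ValueError(f"clone with more than {max_units} new units")

    # leader-proximal (newest) unit: fresh, unselected acquisition
    fresh = _draw_spacer_batch(n_clones, refs, probs, rng, config)

    # older units: drawn from the selection-weighted population
    n_old = int(np.maximum(k_per_clone - 1, 0).sum())
    if n_old:
        pool = _draw_spacer_batch(max(20_000, n_clones), refs, probs, rng, config)
        w = np.where(pool["protective"], config.selection_factor, 1.0)
        older_idx = rng.choice(len(pool), size=n_old, p=w / w.sum())
        older = pool.iloc[older_idx].reset_index(drop=True)
    else:
        older = fresh.iloc[0:0]

    # assemble clones; protection saturates — one protective spacer already
    # confers resistance, so a protected clone's abundance is multiplied by
    # s once, regardless of how many protective spacers it carries
    spacer_rows = []  # (clone_id, ordinal, batch_row)
    old_cursor = 0
    protected = np.zeros(n_clones, dtype=bool)
    for c in range(n_clones):
        k = k_per_clone[c]
        if k == 0:
            continue
        spacer_rows.append((c, 1, fresh.iloc[c]))
        protected[c] |= bool(fresh["protective"].iloc[c])
        for o in range(2, k + 1):
            row = older.iloc[old_cursor]
            old_cursor += 1
            spacer_rows.append((c, o, row))
            protected[c] |= bool(row["protective"])

    weights = np.where(protected, config.selection_factor, 1.0)
    read_clones = rng.choice(n_clones, size=config.n_reads, p=weights / weights.sum())

    # materialize spacer sequences and per-clone layouts
    clone_spacers: dict[int, list[tuple[int, pd.Series, str]]] = {}
    for c, o, row in spacer_rows:
        ref = refs[int(row["ref_idx"])]
        s, l = int(row["start"]), int(row["length"])
        seq = ref.sequence[s : s + l]
        if row["strand"] == "-":
            seq = revcomp(seq)
        clone_spacers.setdefault(c, []).append((o, row, seq))

    leader_tail = array.leader[-40:]
    repeat = array.repeat
    old1 = array.spacers[0] if array.spacers else ""
    hot = phage_map.regions.get("hot", (0, 0))

    reads = []
    truth_rows = []
    for i, c in enumerate(read_clones):
        rid = f"read_{i:06d}"
        units = sorted(clone_spacers.get(int(c), []), key=lambda t: t[0])
        body = "".join(repeat + seq for _, _, seq in units)
        seq_full = leader_tail + body + repeat + old1
        reads.append(Read(rid, _mutate(seq_full, config.error_rate, rng), None))
        for o, row, seq in units:
            ref = refs[int(row["ref_idx"])]
            mid = int(row["start"]) + int(row["length"]) // 2
            if ref.id == phage_map.id:
                source = "phage"
                region = "hot" if hot[0] <= mid < hot[1] else "cold"
            else:
                source = "chromosome" if "chromosome" in ref.id else "megaplasmid"
                region = "NA"
            truth_rows.append(
                (
                    rid,
                    int(c),
                    o,
                    ref.id,
                    source,
                    int(row["start"]),
                    int(row["length"]),
                    row["strand"],
                    region,
                    bool(row["targeting"]),
                    bool(row["protective"]),
                    seq,
                )
            )

    truth = pd.DataFrame(truth_rows, columns=truth_columns)
    return ReadSet(reads=reads, pairing="merged"), truth


# ---------------------------------------------------------------------------
# Expression counts
# ---------------------------------------------------------------------------

# relative transcript abundance per class at 0/10/30/50/70 min post-infection
_CLASS_SHAPES = {
    "early": [0.0, 1.0, 0.45, 0.18, 0.08],
    "middle": [0.0, 0.10, 0.45, 1.0, 0.35],
    "late": [0.0, 0.03, 0.08, 0.30, 1.0],
}
_SHAPE_TIMES = [0, 10, 30, 50, 70]


def simulate_expression_counts(
    genome: ReferenceGenome,
    timepoints: Sequence[int] = (0, 10, 30, 50, 70),
    config: SimulationConfig = SimulationConfig(),
) -> tuple[dict[str, pd.DataFrame], pd.Series, pd.Series]:
    """Gene x timepoint count matrices with implanted temporal dynamics.

    Early genes peak before 30 min, middle genes rise to a 50-min maximum,
    late genes keep rising after 50 min; phage counts are zero in the
    pre-infection (t=0) control column while flat-expression host
    background genes keep the column non-degenerate. Counts are
    negative-binomial around the expected abundances (``nb_dispersion``;
    ``None`` gives the noiseless rounded means).

    Returns ``(counts_by_replicate, gene_lengths, true_classes)`` where
    ``true_classes`` covers the phage genes only.
    """
    rng = config.rng(4)
    tp = list(timepoints)
    genes = [f for f in genome.features if f.temporal_class in _CLASS_SHAPES]
    if not genes:
        raise ValueError("genome has no genes with temporal classes")

    ids = [f.gene_id for f in genes]
    lengths = [f.length for f in genes]
    shapes = np.array(
        [np.interp(tp, _SHAPE_TIMES, _CLASS_SHAPES[f.temporal_class]) for f in genes]
    )
    bases = rng.lognormal(mean=0.0, sigma=0.6, size=len(genes))

    host_ids = [f"host_bg_{i + 1:02d}" for i in range(config.n_host_background)]
    host_lengths = rng.integers(500, 2000, size=config.n_host_background)
    host_bases = rng.lognormal(mean=0.0, sigma=0.6, size=config.n_host_background)
    host_shapes = np.ones((config.n_host_background, len(tp)))

    all_ids = ids + host_ids
    all_lengths = np.concatenate([lengths, host_lengths]).astype(int)
    expected = np.vstack(
        [
            shapes * bases[:, None] * (np.array(lengths)[:, None] / 1000.0),
            host_shapes * host_bases[:, None] * (host_lengths[:, None] / 1000.0),
        ]
    )
    col_tot = expected.sum(axis=0)
    mean_counts = expected / col_tot * config.expression_depth

    counts_by_rep = {}
    for r in range(config.n_replicates):
        if config.nb_dispersion is None:
            counts = np.rint(mean_counts).astype(int)
        else:
            size = config.nb_dispersion
            p = size / (size + np.maximum(mean_counts, 1e-9))
            counts = rng.negative_binomial(size, p)
            counts[mean_counts == 0] = 0
        counts_by_rep[f"rep{r + 1}"] = pd.DataFrame(counts, index=all_ids, columns=tp)

    gene_lengths = pd.Series(all_lengths, index=all_ids, name="length")
    true_classes = pd.Series(
        {f.gene_id: f.temporal_class for f in genes}, name="temporal_class"
    )
    return counts_by_rep, gene_lengths, true_classes


# ---------------------------------------------------------------------------
# Escaper amplicons
# ---------------------------------------------------------------------------

def escaper_amplicon(
    genome: ReferenceGenome,
    gene_id: str,
    config: SimulationConfig,
    protospacer_length: int = 38,
) -> tuple[str, tuple[int, int], str, str]:
    """Cut an amplicon around a protospacer at the center of a gene.

    Returns (amplicon_sequence, protospacer interval in amplicon
    coordinates, forward primer, reverse primer). Primers are the terminal
    ``escaper_primer_length`` bases of the amplicon.
    """
    gene = next(f for f in genome.features if f.gene_id == gene_id)
    ps_mid = (gene.start + gene.end) // 2
    half = config.escaper_amplicon_length // 2
    a0 = max(0, ps_mid - half)
    a1 = min(len(genome.sequence), a0 + config.escaper_amplicon_length)
    amplicon = genome.sequence[a0:a1]
    p0 = ps_mid - protospacer_length // 2 - a0
    interval = (p0, p0 + protospacer_length)
    n = config.escaper_primer_length
    return amplicon, interval, amplicon[:n], revcomp(amplicon[-n:])


def simulate_escaper_reads(
    amplicon: str,
    protospacer: tuple[int, int],
    essential: bool,
    config: SimulationConfig,
) -> tuple[ReadSet, pd.DataFrame]:
    """Escaper amplicon reads: ~half wild type, the rest deletion variants.

    Every emitted read retains both primer ends. Each variant carries one
    deletion overlapping the protospacer; in the essential model the
    deletion length is a multiple of 3 (reading frame preserved), otherwise
    lengths are uniform on [1, escaper_max_deletion]. Returns the reads and
    a truth table of (variant_id, start, length, frame_preserving).
    """
    rng = config.rng(5)
    p0, p1 = protospacer
    plen = config.escaper_primer_length
    amp_n = len(amplicon)
    if not (plen <= p0 < p1 <= amp_n - plen):
        raise ValueError("protospacer must lie inside the amplicon, clear of the primers")
    max_del = config.escaper_max_deletion
    if max_del > amp_n - 2 * plen:
        raise ValueError("deletion length exceeds amplicon minus primers")

    variants = []
    truth_rows = []
    for v in range(config.escaper_n_variants):
        if essential:
            length = 3 * int(rng.integers(1, max_del // 3 + 1))
        else:
            length = int(rng.integers(1, max_del + 1))
        lo = max(plen, p0 - length + 1)
        hi = min(p1 - 1, amp_n - plen - length)
        if hi < lo:
            # deletion too long to overlap the protospacer and clear primers
            length = min(length, p1 - plen - 1, amp_n - plen - p0 - 1)
            lo = max(plen, p0 - length + 1)
            hi = min(p1 - 1, amp_n - plen - length)
        start = int(rng.integers(lo, hi + 1))
        variants.append(amplicon[:start] + amplicon[start + length :])
        truth_rows.append((f"var_{v + 1:03d}", start, length, length % 3 == 0))

    reads = []
    for i in range(config.escaper_n_reads):
        rid = f"esc_{i:06d}"
        if rng.random() < config.escaper_wildtype_fraction or not variants:
            seq = amplicon
        else:
            seq = variants[int(rng.integers(0, len(variants)))]
        reads.append(Read(rid, _mutate(seq, config.escaper_error_rate, rng), None))

    truth = pd.DataFrame(
        truth_rows, columns=["variant_id", "start", "length", "frame_preserving"]
    )
    return ReadSet(reads=reads, pairing="merged"), truth
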
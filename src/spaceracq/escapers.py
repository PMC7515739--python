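"""Escaper-phage amplicon analysis: deletion calling, reading-frame
classification and deletion-spectrum summaries.

Reads of the protospacer region from CRISPR-escaping phages are primer
filtered, dereplicated to exact-identity variants, globally aligned to the
wild-type amplicon with affine gap scores chosen so a single long deletion
beats scattered mismatches, and the resulting deletions are left-normalized
(shifted to the lowest coordinate within repetitive context — the same
convention as standard variant normalization). A variant preserves the
reading frame when the sum of its deletion lengths is a multiple of 3.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field as dc_field

import numpy as np
from Bio import Align

from .seqmodel import Read, ReadSet, revcomp


class InsertionAnomalyError(ValueError):
    """Variant longer than the reference beyond the insertion allowance."""


@dataclass
class AlignmentScores:
    """Affine-gap scoring for deletion calling.

    Gap extension is much cheaper than a mismatch so the aligner prefers
    one contiguous deletion of tens-to-hundreds of bases over spreading
    the difference across mismatches.
    """

    match: float = 1.0
    mismatch: float = -2.0
    gap_open: float = -6.0
    gap_extend: float = -0.5


@dataclass
class EscaperVariant:
    sequence: str
    count: int
    deletions: list[tuple[int, int]] = dc_field(default_factory=list)  # (start, length)
    mismatches: int = 0  # point differences, recorded but not interpreted
    frame_preserving: bool = True
    overlaps_protospacer: bool = False
    is_wildtype: bool = False


# ---------------------------------------------------------------------------
# Read preparation
# ---------------------------------------------------------------------------

def merge_pairs(
    readset: ReadSet, min_overlap: int = 20, max_mismatch_frac: float = 0.1
) -> tuple[ReadSet, int]:
    """Overlap-consensus merge of read pairs (mate ids ``X/1`` and ``X/2``).

    The largest suffix(R1)/prefix(revcomp R2) overlap with mismatch fraction
    <= ``max_mismatch_frac`` wins; at conflicting bases the higher-quality
    base is kept. Pairs without an acceptable overlap are dropped and
    counted.
    """
    by_pair: dict[str, dict[str, Read]] = {}
    for r in readset:
        base, _, mate = r.read_id.rpartition("/")
        if mate not in ("1", "2") or not base:
            raise ValueError(f"read id {r.read_id!r} is not mate-labelled (expected .../1, .../2)")
        by_pair.setdefault(base, {})[mate] = r

    merged, dropped = [], 0
    for base in by_pair:
        pair = by_pair[base]
        if set(pair) != {"1", "2"}:
            dropped += 1
            continue
        r1, r2 = pair["1"], pair["2"]
        s2 = revcomp(r2.sequence)
        q2 = r2.quality[::-1] if r2.quality else None
        best = None
        for olen in range(min(len(r1.sequence), len(s2)), min_overlap - 1, -1):
            a, b = r1.sequence[-olen:], s2[:olen]
            mm = sum(x != y for x, y in zip(a, b))
            if mm <= max_mismatch_frac * olen:
                best = olen
                break
        if best is None:
            dropped += 1
            continue
        olen = best
        head = r1.sequence[:-olen]
        tail = s2[olen:]
        overlap = []
        for i in range(olen):
            x, y = r1.sequence[len(r1.sequence) - olen + i], s2[i]
            if x == y:
                overlap.append(x)
            else:
                qx = r1.quality[len(r1.sequence) - olen + i] if r1.quality else "I"
                qy = q2[i] if q2 else "I"
                overlap.append(x if qx >= qy else y)
        merged.append(Read(base, head + "".join(overlap) + tail, None))
    return ReadSet(reads=merged, pairing="merged"), dropped


def _ends_match(seq: str, fwd: str, rev_rc: str, max_mismatch: int) -> bool:
    if len(seq) < len(fwd) + len(rev_rc):
        return False
    head = seq[: len(fwd)]
    tail = seq[-len(rev_rc) :]
    return (
        sum(a != b for a, b in zip(head, fwd)) <= max_mismatch
        and sum(a != b for a, b in zip(tail, rev_rc)) <= max_mismatch
    )


def filter_primer_anchored(
    readset: ReadSet, fwd: str, rev: str, max_mismatch: int = 2
) -> tuple[ReadSet, int]:
    """Keep reads carrying the forward primer at the 5' end and the reverse
    primer (given 5'->3' on its own strand) at the 3' end.

    Reads arriving in the opposite orientation are reverse-complemented
    before the check; primer bases are retained. Returns the kept reads
    and the number removed.
    """
    rev_rc = revcomp(rev)
    kept, removed = [], 0
    for r in readset:
        if _ends_match(r.sequence, fwd, rev_rc, max_mismatch):
            kept.append(r)
        else:
            rc = revcomp(r.sequence)
            if _ends_match(rc, fwd, rev_rc, max_mismatch):
                kept.append(Read(r.read_id, rc, r.quality[::-1] if r.quality else None))
            else:
                removed += 1
    return ReadSet(reads=kept, pairing=readset.pairing), removed


def dereplicate(readset: ReadSet) -> list[EscaperVariant]:
    """Exact-sequence dereplication; counts summed, sorted by count then
    lexicographically — deterministic under input permutation."""
    counter = Counter(r.sequence for r in readset)
    return [
        EscaperVariant(sequence=seq, count=n)
        for seq, n in sorted(counter.items(), key=lambda kv: (-kv[1], kv[0]))
    ]


# ---------------------------------------------------------------------------
# Deletion calling
# ---------------------------------------------------------------------------

def _make_aligner(scores: AlignmentScores) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = scores.match
    aligner.mismatch_score = scores.mismatch
    aligner.open_gap_score = scores.gap_open
    aligner.extend_gap_score = scores.gap_extend
    return aligner


def left_normalize(deletion: tuple[int, int], reference: str) -> tuple[int, int]:
    """Shift a deletion to its lowest-coordinate equivalent placement.

    Within a homopolymer or tandem repeat, deleting ``reference[s:s+L]``
    yields the same sequence for a range of s; the leftmost is reported.
    """
    start, length = deletion
    while start > 0 and reference[start - 1] == reference[start + length - 1]:
        start -= 1
    return start, length


def call_deletions(
    variant_sequence: str,
    reference: str,
    scores: AlignmentScores | None = None,
    insertion_allowance: int = 0,
) -> tuple[list[tuple[int, int]], int]:
    """Deletions of a variant relative to the reference amplicon.

    Global affine-gap alignment; gaps in the variant relative to the
    reference are reported as (reference start, length), left-normalized.
    Returns ``(deletions, n_mismatches)``; an identical sequence gives
    ``([], 0)``. Variants longer than the reference by more than
    ``insertion_allowance`` raise :class:`InsertionAnomalyError`.
    """
    if len(variant_sequence) > len(reference) + insertion_allowance:
        raise InsertionAnomalyError(
            f"variant exceeds reference by {len(variant_sequence) - len(reference)} bp"
        )
    if variant_sequence == reference:
        return [], 0
    aligner = _make_aligner(scores or AlignmentScores())
    aln = aligner.align(reference, variant_sequence)[0]
    t_blocks, q_blocks = aln.aligned
    deletions = []
    mismatches = 0
    prev_t_end = prev_q_end = 0
    for (ts, te), (qs, qe) in zip(t_blocks, q_blocks):
        ts, te, qs, qe = int(ts), int(te), int(qs), int(qe)
        if ts > prev_t_end and qs == prev_q_end:
            deletions.append((prev_t_end, ts - prev_t_end))
        ref_block = reference[ts:te]
        var_block = variant_sequence[qs:qe]
        mismatches += sum(a != b for a, b in zip(ref_block, var_block))
        prev_t_end, prev_q_end = te, qe
    if prev_t_end < len(reference) and prev_q_end == len(variant_sequence):
        deletions.append((prev_t_end, len(reference) - prev_t_end))
    deletions = [left_normalize(d, reference) for d in deletions]
    return deletions, mismatches


# ---------------------------------------------------------------------------
# Spectrum
# ---------------------------------------------------------------------------

def deletion_spectrum(
    variants: list[EscaperVariant],
    protospacer: tuple[int, int],
    top_n: int = 10,
) -> dict:
    """Summary of a called deletion spectrum.

    Frame preservation (sum of deletion lengths ≡ 0 mod 3) is reported both
    unweighted over unique deletion-bearing variants and read-weighted —
    the two possible denominators for "a third of deletions preserved the
    frame". Size distribution is the five-number summary over unique
    deletion-bearing variants.
    """
    p0, p1 = protospacer
    del_variants = []
    wt_reads = 0
    total_reads = 0
    for v in variants:
        total_reads += v.count
        if v.is_wildtype:
            wt_reads += v.count
        elif v.deletions:
            del_variants.append(v)

    sizes = [sum(l for _, l in v.deletions) for v in del_variants]
    if sizes:
        q = np.percentile(sizes, [0, 25, 50, 75, 100])
        size_summary = dict(zip(("min", "q1", "median", "q3", "max"), (float(x) for x in q)))
    else:
        size_summary = {k: float("nan") for k in ("min", "q1", "median", "q3", "max")}

    n_frame = sum(v.frame_preserving for v in del_variants)
    w_frame = sum(v.count for v in del_variants if v.frame_preserving)
    w_total = sum(v.count for v in del_variants)

    return {
        "n_variants": len(variants),
        "n_deletion_variants": len(del_variants),
        "wildtype_read_fraction": wt_reads / total_reads if total_reads else float("nan"),
        "frame_preserving_fraction_unweighted": n_frame / len(del_variants) if del_variants else float("nan"),
        "frame_preserving_fraction_weighted": w_frame / w_total if w_total else float("nan"),
        "deletion_size_summary": size_summary,
        "top_variants": [
            {
                "count": v.count,
                "deletions": v.deletions,
                "frame_preserving": v.frame_preserving,
                "overlaps_protospacer": v.overlaps_protospacer,
            }
            for v in del_variants[:top_n]
        ],
    }


def analyze_escapers(
    readset: ReadSet,
    reference: str,
    fwd_primer: str,
    rev_primer: str,
    protospacer: tuple[int, int],
    scores: AlignmentScores | None = None,
    max_primer_mismatch: int = 2,
    min_count: int = 1,
) -> tuple[list[EscaperVariant], dict]:
    """Primer-filter, dereplicate, call deletions and summarize one sample.

    ``min_count`` drops singleton-level variants (sequencing-error noise)
    before deletion calling. Read counts are conserved: kept + dropped =
    input, and the summary records every drop reason.
    """
    p0, p1 = protospacer
    filtered, n_primer_removed = filter_primer_anchored(
        readset, fwd_primer, rev_primer, max_primer_mismatch
    )
    variants = [v for v in dereplicate(filtered) if v.count >= min_count]
    n_low = len(dereplicate(filtered)) - len(variants)
    flagged = 0
    for v in variants:
        if v.sequence == reference:
            v.is_wildtype = True
            continue
        try:
            dels, mm = call_deletions(v.sequence, reference, scores)
        except InsertionAnomalyError:
            flagged += 1
            continue
        v.deletions = dels
        v.mismatches = mm
        v.frame_preserving = sum(l for _, l in dels) % 3 == 0
        v.overlaps_protospacer = any(s < p1 and s + l > p0 for s, l in dels)
    summary = deletion_spectrum(variants, protospacer)
    summary["reads_input"] = len(readset)
    summary["reads_primer_removed"] = n_primer_removed
    summary["variants_below_min_count"] = n_low
    summary["variants_flagged_insertion"] = flagged
    return variants, summary
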
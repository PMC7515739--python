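"""Repeat-anchored spacer extraction from expanded-array amplicon reads.

Repeats are located in each read by ungapped (Hamming) matching against the
array repeat in both orientations; the sequences between consecutive
repeats are the newly inserted spacers. Reads are canonicalized to
leader-first orientation before ordinals are assigned, so ordinal 1 is
always the leader-proximal (most recently acquired) spacer.

Terminal partial repeats do not delimit spacers: only full-length repeat
hits count, which avoids calling chimeric spacers at read ends.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .seqmodel import CRISPRArraySpec, ReadSet, revcomp

logger = logging.getLogger(__name__)

MAX_SPACERS_PER_READ = 5


class MixedStrandError(ValueError):
    """Repeat hits on both strands of one read — the read is uninterpretable."""


@dataclass(frozen=True)
class RepeatHit:
    read_id: str
    offset: int  # 0-based start of the hit in the read as given
    strand: str  # '+': repeat as written; '-': reverse complement matched
    mismatches: int


@dataclass(frozen=True)
class CandidateSpacer:
    sequence: str
    read_id: str
    ordinal: int  # 1 = leader-proximal

    @property
    def length(self) -> int:
        return len(self.sequence)


def _hamming_offsets(read: np.ndarray, pattern: np.ndarray, max_mismatch: int):
    """Offsets where pattern matches read with <= max_mismatch substitutions."""
    if pattern.size > read.size:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(read, pattern.size)
    mm = (windows != pattern).sum(axis=1)
    offs = np.nonzero(mm <= max_mismatch)[0]
    return offs, mm[offs]


def find_repeats(read: str, repeat: str, max_mismatch: int = 3, read_id: str = "") -> list[RepeatHit]:
    """All non-overlapping repeat occurrences in a read, either orientation.

    Candidate hits (Hamming distance <= max_mismatch to the repeat or its
    reverse complement) are resolved greedily left to right: the leftmost
    hit wins and overlapping hits to its right are discarded.
    """
    r = np.frombuffer(read.encode(), dtype=np.uint8)
    candidates = []
    for strand, pat in (("+", repeat), ("-", revcomp(repeat))):
        p = np.frombuffer(pat.encode(), dtype=np.uint8)
        offs, mms = _hamming_offsets(r, p, max_mismatch)
        candidates += [(int(o), strand, int(m)) for o, m in zip(offs, mms)]
    candidates.sort(key=lambda t: (t[0], t[2]))
    hits: list[RepeatHit] = []
    cursor = -1
    for off, strand, mm in candidates:
        if off < cursor:
            continue
        hits.append(RepeatHit(read_id=read_id, offset=off, strand=strand, mismatches=mm))
        cursor = off + len(repeat)
    return hits


def extract_spacers(
    read: str, hits: list[RepeatHit], array: CRISPRArraySpec
) -> list[CandidateSpacer]:
    """Candidate spacers = gaps between consecutive repeat hits of one read.

    All hits must share a strand (mixed-strand reads raise
    :class:`MixedStrandError` and are skipped by the batch driver). When the
    repeats matched on '-', the read is reverse-complemented first so the
    leader end comes first and extracted spacers are reported in array
    orientation. At most five spacers are emitted per read; extras are
    discarded with a warning.
    """
    if len(hits) < 2:
        return []
    strands = {h.strand for h in hits}
    if len(strands) > 1:
        raise MixedStrandError(f"read {hits[0].read_id!r} has repeat hits on both strands")
    rlen = len(array.repeat)
    if strands == {"-"}:
        read = revcomp(read)
        offsets = sorted(len(read) - (h.offset + rlen) for h in hits)
    else:
        offsets = sorted(h.offset for h in hits)

    read_id = hits[0].read_id
    out = []
    for i in range(len(offsets) - 1):
        gap_start = offsets[i] + rlen
        gap_end = offsets[i + 1]
        if gap_end <= gap_start:
            continue  # adjacent repeats with no spacer between
        ordinal = len(out) + 1
        if ordinal > MAX_SPACERS_PER_READ:
            logger.warning(
                "read %s: more than %d spacers, extras discarded", read_id, MAX_SPACERS_PER_READ
            )
            break
        out.append(CandidateSpacer(read[gap_start:gap_end], read_id, ordinal))
    return out


def _best_identity(a: str, b: str) -> float:
    """Best ungapped identity of the shorter sequence slid along the longer."""
    if len(a) > len(b):
        a, b = b, a
    pa = np.frombuffer(a.encode(), dtype=np.uint8)
    pb = np.frombuffer(b.encode(), dtype=np.uint8)
    windows = np.lib.stride_tricks.sliding_window_view(pb, pa.size)
    matches = (windows == pa).sum(axis=1)
    return float(matches.max()) / pa.size


def filter_new_spacers(
    candidates: list[CandidateSpacer],
    array: CRISPRArraySpec,
    min_len: int = 20,
    min_identity: float = 0.95,
) -> list[CandidateSpacer]:
    """Keep only plausible newly acquired spacers.

    Drops candidates shorter than ``min_len`` (20 bp, the mapping length
    floor) and candidates matching any pre-existing array spacer at the
    mapping identity threshold in either orientation — those are old array
    content, not new acquisitions.
    """
    kept = []
    for c in candidates:
        if c.length < min_len:
            continue
        seq_rc = revcomp(c.sequence)
        if any(
            _best_identity(c.sequence, s) >= min_identity
            or _best_identity(seq_rc, s) >= min_identity
            for s in array.spacers
        ):
            continue
        kept.append(c)
    return kept


def extract_from_reads(
    readset: ReadSet,
    array: CRISPRArraySpec,
    max_mismatch: int = 3,
    min_len: int = 20,
    min_identity: float = 0.95,
) -> tuple[list[CandidateSpacer], dict]:
    """Run find -> extract -> filter over a whole read set.

    Returns the filtered candidates and a QC dictionary with per-read
    counts (reads seen, reads with no new spacer, mixed-strand reads
    skipped, candidates before/after filtering).
    """
    qc = {
        "reads_total": len(readset),
        "reads_mixed_strand": 0,
        "reads_without_new_spacers": 0,
        "candidates_raw": 0,
        "candidates_filtered": 0,
    }
    kept: list[CandidateSpacer] = []
    for read in readset:
        hits = find_repeats(read.sequence, array.repeat, max_mismatch, read_id=read.read_id)
        try:
            cands = extract_spacers(read.sequence, hits, array)
        except MixedStrandError:
            qc["reads_mixed_strand"] += 1
            continue
        if not cands:
            qc["reads_without_new_spacers"] += 1
            continue
        qc["candidates_raw"] += len(cands)
        kept.extend(filter_new_spacers(cands, array, min_len, min_identity))
    qc["candidates_filtered"] = len(kept)
    return kept, qc
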
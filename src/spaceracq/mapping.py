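"""Protospacer mapping, clustering and positional profiles.

Mapping is an exhaustive ungapped scan of every offset on both strands of
every reference: spacers are short (35–42 bp) and the 95% identity
threshold (at most ~2 substitutions) makes gapped alignment unnecessary.
Identity is matches / spacer length. A spacer is *uniquely mapped* iff
exactly one locus passes the threshold across ALL references jointly, so a
spacer can never be counted as both phage- and host-derived; equal-identity
ties are not broken — they make the spacer non-unique.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .extraction import CandidateSpacer
from .seqmodel import ReferenceGenome, revcomp


@dataclass(frozen=True)
class SpacerHit:
    sequence: str
    reference_id: str
    start: int
    length: int
    strand: str  # '+': spacer equals the stored top strand at the locus
    identity: float
    unique: bool


class ReferenceIndex:
    """Byte-encoded references with cached sliding windows per spacer length."""

    def __init__(self, references: Sequence[ReferenceGenome]):
        self.references = list(references)
        self._arrays = {
            r.id: np.frombuffer(r.sequence.encode(), dtype=np.uint8) for r in references
        }
        self._windows: dict[tuple[str, int], np.ndarray] = {}

    def windows(self, ref_id: str, k: int) -> np.ndarray:
        key = (ref_id, k)
        if key not in self._windows:
            arr = self._arrays[ref_id]
            if k > arr.size:
                self._windows[key] = np.empty((0, k), dtype=np.uint8)
            else:
                self._windows[key] = np.lib.stride_tricks.sliding_window_view(arr, k)
        return self._windows[key]


def _scan_offsets_exhaustive(index: ReferenceIndex, ref_id: str, pat: np.ndarray, max_mm: int):
    """Mismatch count at every offset; returns (offsets, mismatches) passing."""
    win = index.windows(ref_id, pat.size)
    if win.shape[0] == 0:
        return []
    mm = (win != pat).sum(axis=1)
    offs = np.nonzero(mm <= max_mm)[0]
    return [(int(o), int(mm[o])) for o in offs]


def _scan_offsets_seeded(sequence: str, arr: np.ndarray, pattern: str, pat: np.ndarray, max_mm: int):
    """Exact Hamming search by pigeonhole seeding.

    Any locus with <= max_mm substitutions must contain at least one of
    max_mm+1 disjoint pattern chunks exactly; candidate offsets found by
    exact chunk search are then verified by full Hamming comparison. This
    is equivalent to the exhaustive scan, not a heuristic.
    """
    L = pat.size
    n_chunks = max_mm + 1
    bounds = np.linspace(0, L, n_chunks + 1).astype(int)
    candidates = set()
    last_valid = len(sequence) - L
    for c in range(n_chunks):
        lo, hi = int(bounds[c]), int(bounds[c + 1])
        chunk = pattern[lo:hi]
        pos = sequence.find(chunk)
        while pos != -1:
            off = pos - lo
            if 0 <= off <= last_valid:
                candidates.add(off)
            pos = sequence.find(chunk, pos + 1)
    out = []
    for off in sorted(candidates):
        mm = int((arr[off : off + L] != pat).sum())
        if mm <= max_mm:
            out.append((off, mm))
    return out


def map_spacer(
    spacer: str,
    references: Sequence[ReferenceGenome] | ReferenceIndex,
    min_identity: float = 0.95,
) -> list[SpacerHit]:
    """All loci on either strand of any reference with identity >= threshold.

    Returns an empty list for an unmapped spacer. ``unique`` is true on
    every returned hit iff exactly one locus passed genome-wide.
    """
    index = references if isinstance(references, ReferenceIndex) else ReferenceIndex(references)
    L = len(spacer)
    if L < 20:
        raise ValueError(f"spacer shorter than 20 bp ({L})")
    rc = revcomp(spacer)
    max_mm = int(np.floor(L * (1.0 - min_identity)))
    # seeded search needs informative chunks; fall back to the full scan
    # when the tolerance is so loose the chunks get short
    seeded = L // (max_mm + 1) >= 8

    raw = []
    for ref in index.references:
        for strand, pattern in (("+", spacer), ("-", rc)):
            pat = np.frombuffer(pattern.encode(), dtype=np.uint8)
            if seeded:
                found = _scan_offsets_seeded(ref.sequence, index._arrays[ref.id], pattern, pat, max_mm)
            else:
                found = _scan_offsets_exhaustive(index, ref.id, pat, max_mm)
            for off, mm in found:
                ident = (L - mm) / L
                if ident >= min_identity:
                    raw.append((ref.id, off, strand, ident))

    unique = len(raw) == 1
    return [
        SpacerHit(spacer, rid, off, L, strand, ident, unique)
        for rid, off, strand, ident in raw
    ]


def map_spacers(
    candidates: Iterable[CandidateSpacer],
    references: Sequence[ReferenceGenome],
    min_identity: float = 0.95,
) -> pd.DataFrame:
    """Map candidate spacers; one row per (candidate, passing locus).

    Columns: read_id, ordinal, sequence, reference_id, start, length,
    strand, identity, unique. Unmapped candidates contribute no rows.
    """
    index = ReferenceIndex(references)
    rows = []
    cache: dict[str, list[SpacerHit]] = {}  # identical sequences share one scan
    for c in candidates:
        if c.sequence not in cache:
            cache[c.sequence] = map_spacer(c.sequence, index, min_identity)
        for h in cache[c.sequence]:
            rows.append(
                (c.read_id, c.ordinal, h.sequence, h.reference_id, h.start, h.length, h.strand, h.identity, h.unique)
            )
    return pd.DataFrame(
        rows,
        columns=[
            "read_id", "ordinal", "sequence", "reference_id", "start",
            "length", "strand", "identity", "unique",
        ],
    )


def dedupe_to_clusters(hits: pd.DataFrame) -> pd.DataFrame:
    """Group uniquely mapped hits by (reference_id, start, length, strand).

    ``read_count`` accumulates one per hit row (= one per read-spacer);
    ``unique_sequences`` counts distinct spacer sequences in the cluster.
    Input must contain only unique, threshold-passing hits.
    """
    if len(hits) and not hits["unique"].all():
        raise ValueError("dedupe_to_clusters requires uniquely mapped hits only")
    if not len(hits):
        return pd.DataFrame(
            columns=["reference_id", "start", "length", "strand", "read_count", "unique_sequences"]
        )
    grouped = (
        hits.groupby(["reference_id", "start", "length", "strand"], as_index=False)
        .agg(read_count=("sequence", "size"), unique_sequences=("sequence", "nunique"))
        .sort_values(["reference_id", "start", "length", "strand"], kind="mergesort")
        .reset_index(drop=True)
    )
    return grouped


def positional_profile(clusters: pd.DataFrame) -> pd.DataFrame:
    """Sum cluster read counts over spacer lengths per (reference, start, strand)."""
    if not len(clusters):
        return pd.DataFrame(columns=["reference_id", "start", "strand", "read_count"])
    return (
        clusters.groupby(["reference_id", "start", "strand"], as_index=False)["read_count"]
        .sum()
        .sort_values(["reference_id", "start", "strand"], kind="mergesort")
        .reset_index(drop=True)
    )


def write_bedgraph(profile: pd.DataFrame, path_plus: str | Path, path_minus: str | Path) -> None:
    """Export a positional profile as one bedGraph track per strand."""
    for strand, path in (("+", path_plus), ("-", path_minus)):
        sub = profile[profile["strand"] == strand]
        with open(path, "w") as fh:
            for _, row in sub.iterrows():
                fh.write(f"{row.reference_id}\t{row.start}\t{row.start + 1}\t{row.read_count}\n")
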
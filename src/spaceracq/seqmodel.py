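"""Core domain types and readers/writers for the formats every stage touches.

Coordinate convention: everything internal is 0-based, half-open, on the
top ("+") strand of the stored reference. GFF3's 1-based closed intervals
are converted at the I/O boundary and nowhere else.

Alphabet: sequences are uppercase DNA over {A,C,G,T}; reads may additionally
contain N. Other IUPAC ambiguity codes are rejected at input — spacers and
repeats in this assay are unambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Optional

import gffutils.iterators
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_DNA = set("ACGT")
_DNA_N = set("ACGTN")

Strand = Literal["+", "-"]


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N allowed).

    ``revcomp(revcomp(s)) == s`` for any valid input.
    """
    bad = set(seq) - _DNA_N
    if bad:
        raise ValueError(f"non-DNA characters in sequence: {sorted(bad)}")
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GeneFeature:
    """A gene on a reference, 0-based half-open, with optional temporal class.

    ``essential`` is only meaningful for simulated genomes, where it controls
    the escaper deletion model.
    """

    gene_id: str
    start: int
    end: int
    strand: Strand
    temporal_class: str = "unassigned"
    essential: bool = False

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"{self.gene_id}: start {self.start} !< end {self.end}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class ReferenceGenome:
    """A reference sequence with strand-annotated gene features and named regions.

    ``regions`` maps names like ``"hot"``, ``"cold"``, ``"LTR_left"`` to
    half-open intervals; ``metadata`` holds free-form scalars (e.g. the
    packaging start coordinate of a simulated phage genome).
    """

    id: str
    sequence: str
    topology: Literal["linear", "circular"] = "linear"
    features: list[GeneFeature] = field(default_factory=list)
    regions: dict[str, tuple[int, int]] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.id}: empty sequence")
        bad = set(self.sequence) - _DNA_N
        if bad:
            raise ValueError(f"{self.id}: non-DNA characters {sorted(bad)}")
        self.validate()

    def validate(self) -> None:
        n = len(self.sequence)
        ids = [f.gene_id for f in self.features]
        if len(ids) != len(set(ids)):
            raise ValueError(f"{self.id}: duplicate feature ids")
        for f in self.features:
            if f.end > n:
                raise ValueError(f"{self.id}: feature {f.gene_id} [{f.start},{f.end}) exceeds length {n}")
        for name, (s, e) in self.regions.items():
            if not (0 <= s <= e <= n):
                raise ValueError(f"{self.id}: region {name} [{s},{e}) outside [0,{n})")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class CRISPRArraySpec:
    """A CRISPR array: repeat, ordered pre-existing spacers, leader, primers.

    Spacer index 1 is leader-proximal (most recently acquired). The amplicon
    primers are the leader-annealing forward primer and the primer annealing
    to the leader-proximal pre-existing spacer, each written 5'->3' on its
    own strand.
    """

    array_id: str
    repeat: str
    spacers: list[str]
    leader: str
    amplicon_primers: tuple[str, str]

    def __post_init__(self) -> None:
        if len(self.repeat) < 20:
            raise ValueError(f"{self.array_id}: repeat shorter than 20 bp")
        fwd, rev = self.amplicon_primers
        if not fwd or not rev:
            raise ValueError(f"{self.array_id}: empty amplicon primer")
        for s in (self.repeat, self.leader, fwd, rev, *self.spacers):
            bad = set(s) - _DNA
            if bad:
                raise ValueError(f"{self.array_id}: non-ACGT characters {sorted(bad)}")


@dataclass(frozen=True)
class Read:
    read_id: str
    sequence: str
    quality: Optional[str] = None  # phred+33 string, same length as sequence


@dataclass
class ReadSet:
    """A set of (possibly quality-bearing) reads. Pairing is recorded only;
    paired mates share a read_id prefix and are stored as two entries."""

    reads: list[Read]
    pairing: Literal["single", "paired", "merged"] = "single"

    def __post_init__(self) -> None:
        ids = [r.read_id for r in self.reads]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate read ids in ReadSet")

    def __len__(self) -> int:
        return len(self.reads)

    def __iter__(self):
        return iter(self.reads)


# ---------------------------------------------------------------------------
# FASTA / FASTQ
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[ReferenceGenome]:
    """Read a FASTA file into sequence-only :class:`ReferenceGenome` records.

    Sequences are uppercased and U is mapped to T. Features/regions are left
    empty; annotations come from :func:`read_annotations`.
    """
    path = Path(path)
    genomes = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper().replace("U", "T")
        if not seq:
            raise FormatError(f"{path}: record {rec.id!r} has an empty sequence")
        try:
            genomes.append(ReferenceGenome(id=rec.id, sequence=seq))
        except ValueError as exc:
            raise FormatError(f"{path}: {exc}") from exc
    if not genomes:
        raise FormatError(f"{path}: no FASTA records found")
    return genomes


def write_fasta(genomes: Iterable[ReferenceGenome], path: str | Path, width: int = 70) -> None:
    records = [SeqRecord(Seq(g.sequence), id=g.id, description="") for g in genomes]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def read_fastq(path: str | Path) -> ReadSet:
    reads = [
        Read(
            read_id=rec.id,
            sequence=str(rec.seq).upper(),
            quality="".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"]),
        )
        for rec in SeqIO.parse(str(path), "fastq")
    ]
    return ReadSet(reads=reads, pairing="single")


def write_fastq(readset: ReadSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in readset:
            qual = r.quality if r.quality is not None else "I" * len(r.sequence)
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{qual}\n")


# ---------------------------------------------------------------------------
# Annotations (GFF3 / BED6)
# ---------------------------------------------------------------------------

def read_annotations(path: str | Path, format: str = "gff3") -> list[GeneFeature]:
    """Read gene features from GFF3 or BED6.

    GFF3 1-based closed coordinates are converted to 0-based half-open;
    BED is taken as-is. The ``temporal_class`` attribute (GFF3) or a
    ``temporal_class=`` tag in the BED name column is preserved.
    """
    path = Path(path)
    if format == "gff3":
        return _read_gff3(path)
    if format == "bed":
        return _read_bed(path)
    raise ValueError(f"unknown annotation format {format!r}")


def _read_gff3(path: Path) -> list[GeneFeature]:
    feats = []
    for f in gffutils.iterators.DataIterator(str(path)):
        start = int(f.start) - 1  # 1-based closed -> 0-based half-open
        end = int(f.end)
        if end <= start:
            raise FormatError(f"{path}: feature with end <= start after conversion: {f}")
        gene_id = f.attributes.get("ID", [f.id or f"{f.seqid}:{start}-{end}"])[0]
        tclass = f.attributes.get("temporal_class", ["unassigned"])[0]
        essential = f.attributes.get("essential", ["false"])[0].lower() == "true"
        strand = f.strand if f.strand in ("+", "-") else "+"
        feats.append(GeneFeature(gene_id, start, end, strand, tclass, essential))
    return feats


def _read_bed(path: Path) -> list[GeneFeature]:
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "name", "score", "strand"],
        usecols=range(6), dtype={"start": int, "end": int},
    )
    feats = []
    for i, row in df.iterrows():
        if row.end <= row.start:
            raise FormatError(f"{path}: line {i + 1}: end <= start")
        name = str(row["name"])
        tclass = "unassigned"
        if "temporal_class=" in name:
            name, _, tclass = name.partition("temporal_class=")
            name = name.rstrip(";")
        strand = row.strand if row.strand in ("+", "-") else "+"
        feats.append(GeneFeature(name, int(row.start), int(row.end), strand, tclass))
    return feats


def write_gff3(features: Iterable[GeneFeature], reference_id: str, path: str | Path) -> None:
    """Write features as GFF3 gene lines (0-based half-open -> 1-based closed)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            attrs = f"ID={f.gene_id};temporal_class={f.temporal_class};essential={str(f.essential).lower()}"
            fh.write(
                f"{reference_id}\tspaceracq\tgene\t{f.start + 1}\t{f.end}\t.\t{f.strand}\t.\t{attrs}\n"
            )


# ---------------------------------------------------------------------------
# Array spec (plain-text key:value)
# ---------------------------------------------------------------------------

def read_array_spec(path: str | Path) -> CRISPRArraySpec:
    """Read an array spec in the documented key:value format.

    Keys: array_id, repeat, leader, primer_forward, primer_reverse and one
    ``spacer:`` line per pre-existing spacer in leader-proximal-first order.
    """
    fields: dict[str, str] = {}
    spacers: list[str] = []
    for ln, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if ":" not in line:
            raise FormatError(f"{path}: line {ln}: expected 'key: value'")
        key, _, val = line.partition(":")
        key, val = key.strip(), val.strip()
        if key != "array_id":
            val = val.upper()
        if key == "spacer":
            spacers.append(val)
        else:
            fields[key] = val
    try:
        return CRISPRArraySpec(
            array_id=fields["array_id"],
            repeat=fields["repeat"],
            spacers=spacers,
            leader=fields["leader"],
            amplicon_primers=(fields["primer_forward"], fields["primer_reverse"]),
        )
    except KeyError as exc:
        raise FormatError(f"{path}: missing required key {exc}") from exc


def write_array_spec(array: CRISPRArraySpec, path: str | Path) -> None:
    lines = [
        f"array_id: {array.array_id}",
        f"repeat: {array.repeat}",
        f"leader: {array.leader}",
        f"primer_forward: {array.amplicon_primers[0]}",
        f"primer_reverse: {array.amplicon_primers[1]}",
    ]
    lines += [f"spacer: {s}" for s in array.spacers]
    Path(path).write_text("\n".join(lines) + "\n")
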
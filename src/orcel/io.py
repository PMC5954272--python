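"""Readers/writers for the formats the pipeline touches, and the shared
coordinate conventions.

Conventions
-----------
* All **internal** coordinates are 0-based half-open ``[start, end)`` on the
  forward genomic strand, regardless of feature strand.
* On-disk GTF uses 1-based inclusive coordinates; the conversion happens here
  and nowhere else.  BED-like junction tables are already 0-based half-open
  and pass through unchanged.
* All sequence matching downstream happens in the DNA alphabet; FASTA input
  is uppercased and ``U`` is mapped to ``T`` on read.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO

__all__ = [
    "GeneModel",
    "TranscriptModel",
    "BackSplicedJunction",
    "GtfParseError",
    "JunctionValidationError",
    "read_gtf",
    "write_gtf",
    "read_junctions",
    "write_junctions",
    "read_fasta",
    "write_fasta",
    "reverse_complement",
    "transcript_sequence",
]

_RC = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    """Reverse complement in the DNA alphabet (N self-complements)."""
    return seq.translate(_RC)[::-1]


@dataclass(frozen=True)
class TranscriptModel:
    """A spliced transcript: ordered, non-overlapping exon blocks on a genome."""

    transcript_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if not self.exons:
            raise ValueError(f"transcript {self.transcript_id} has no exons")
        prev_end = None
        for start, end in self.exons:
            if end <= start:
                raise ValueError(
                    f"transcript {self.transcript_id}: exon ({start},{end}) has end <= start"
                )
            if prev_end is not None and start < prev_end:
                raise ValueError(
                    f"transcript {self.transcript_id}: exons overlap or are unsorted"
                )
            prev_end = end

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]


@dataclass
class GeneModel:
    gene_id: str
    transcripts: list[TranscriptModel] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise ValueError("gene_id must be non-empty")


@dataclass(frozen=True)
class BackSplicedJunction:
    """A back-spliced junction: acceptor (5' of the circle) at ``start``,
    donor (3') at ``end``, 0-based half-open, with the evidence counts the
    junction was imported with (publications reporting it, RNA-seq samples
    detecting it)."""

    chrom: str
    start: int
    end: int
    strand: str
    report_count: int = 0
    sample_count: int = 0
    name: str = ""

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise JunctionValidationError(
                f"junction {self.chrom}:{self.start}-{self.end}: end <= start"
            )
        if self.report_count < 0 or self.sample_count < 0:
            raise JunctionValidationError(
                f"junction {self.label}: negative evidence count"
            )
        if self.strand not in ("+", "-"):
            raise JunctionValidationError(f"junction strand must be + or -")

    @property
    def label(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}:{self.strand}"

    @property
    def junction_id(self) -> str:
        return self.name or self.label


class GtfParseError(ValueError):
    pass


class JunctionValidationError(ValueError):
    pass


def _parse_gtf_attributes(attr_field: str, lineno: int) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for chunk in attr_field.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        if " " not in chunk:
            raise GtfParseError(f"line {lineno}: malformed attribute {chunk!r}")
        key, _, value = chunk.partition(" ")
        attrs[key] = value.strip().strip('"')
    return attrs


def read_gtf(path: str | Path) -> list[GeneModel]:
    """Read a GTF2.2 file into gene models.

    Only ``exon`` features are used; they are grouped under their
    ``transcript_id`` and ``gene_id``.  GTF's 1-based inclusive coordinates
    are converted to internal 0-based half-open.  Exon records lacking a
    ``transcript_id`` are reported (warning) and skipped; structurally
    malformed lines raise :class:`GtfParseError` naming the line number.
    """
    per_tx: dict[str, dict] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GtfParseError(
                    f"line {lineno}: expected 9 tab-separated fields, got {len(fields)}"
                )
            chrom, _source, feature, start_s, end_s, _score, strand, _frame, attr_field = fields
            if feature != "exon":
                continue
            try:
                start_1 = int(start_s)
                end_1 = int(end_s)
            except ValueError as exc:
                raise GtfParseError(f"line {lineno}: non-integer coordinate") from exc
            if start_1 < 1 or end_1 < start_1:
                raise GtfParseError(f"line {lineno}: invalid coordinates {start_1}-{end_1}")
            attrs = _parse_gtf_attributes(attr_field, lineno)
            if "transcript_id" not in attrs or not attrs["transcript_id"]:
                warnings.warn(
                    f"{path}: line {lineno}: exon without transcript_id rejected",
                    stacklevel=2,
                )
                continue
            gene_id = attrs.get("gene_id", attrs["transcript_id"])
            tx_id = attrs["transcript_id"]
            rec = per_tx.setdefault(
                tx_id, {"gene_id": gene_id, "chrom": chrom, "strand": strand, "exons": []}
            )
            # GTF 1-based inclusive -> 0-based half-open
            rec["exons"].append((start_1 - 1, end_1))

    genes: dict[str, GeneModel] = {}
    for tx_id in sorted(per_tx):
        rec = per_tx[tx_id]
        tx = TranscriptModel(
            transcript_id=tx_id,
            chrom=rec["chrom"],
            strand=rec["strand"],
            exons=tuple(sorted(rec["exons"])),
        )
        genes.setdefault(rec["gene_id"], GeneModel(gene_id=rec["gene_id"])).transcripts.append(tx)
    return [genes[g] for g in sorted(genes)]


def write_gtf(genes: Iterable[GeneModel], path: str | Path, isoforms: Iterable = ()) -> None:
    """Write gene models (and optionally circRNA isoforms) as GTF2.2 exon lines.

    Round-trip contract: ``read_gtf(write_gtf(x))`` reproduces x's
    coordinates exactly.  CircRNA isoforms are written with their
    ``isoform_id`` as transcript_id, their host gene as gene_id and a
    ``junction`` attribute carrying the junction label.
    """
    with open(path, "w") as fh:
        fh.write("##format: gtf\n")
        for gene in genes:
            for tx in gene.transcripts:
                for start, end in tx.exons:
                    fh.write(
                        f"{tx.chrom}\torcel\texon\t{start + 1}\t{end}\t.\t{tx.strand}\t.\t"
                        f'gene_id "{gene.gene_id}"; transcript_id "{tx.transcript_id}";\n'
                    )
        for iso in isoforms:
            j = iso.junction
            for start, end in iso.blocks:
                fh.write(
                    f"{j.chrom}\torcel\texon\t{start + 1}\t{end}\t.\t{j.strand}\t.\t"
                    f'gene_id "{iso.host_gene}"; transcript_id "{iso.isoform_id}"; '
                    f'junction "{j.junction_id}";\n'
                )


def read_junctions(path: str | Path) -> list[BackSplicedJunction]:
    """Read back-spliced junctions from a BED6+2 TSV.

    Columns: chrom, start, end, name, score, strand, report_count,
    sample_count.  BED's 0-based half-open coordinates are kept unchanged.
    Rows violating the junction invariants raise
    :class:`JunctionValidationError` naming the row.
    """
    out: list[BackSplicedJunction] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 8:
                raise JunctionValidationError(
                    f"{path}: line {lineno}: expected 8 columns (BED6+2), got {len(fields)}"
                )
            try:
                j = BackSplicedJunction(
                    chrom=fields[0],
                    start=int(fields[1]),
                    end=int(fields[2]),
                    strand=fields[5],
                    report_count=int(fields[6]),
                    sample_count=int(fields[7]),
                    name=fields[3],
                )
            except JunctionValidationError as exc:
                raise JunctionValidationError(f"{path}: line {lineno}: {exc}") from exc
            out.append(j)
    return out


def write_junctions(junctions: Iterable[BackSplicedJunction], path: str | Path) -> None:
    with open(path, "w") as fh:
        for j in junctions:
            fh.write(
                f"{j.chrom}\t{j.start}\t{j.end}\t{j.junction_id}\t0\t{j.strand}\t"
                f"{j.report_count}\t{j.sample_count}\n"
            )


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA into an id -> sequence mapping.

    Sequences are uppercased and RNA ``U`` is mapped to ``T`` so that all
    downstream matching happens in one (DNA) alphabet.  Duplicate ids are an
    error.
    """
    out: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in out:
            raise ValueError(f"{path}: duplicate FASTA identifier {record.id!r}")
        out[record.id] = str(record.seq).upper().replace("U", "T")
    return out


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def transcript_sequence(tx: TranscriptModel, genome: Mapping[str, str]) -> str:
    """Spliced transcript sequence in 5'->3' transcript orientation."""
    if tx.chrom not in genome:
        raise KeyError(f"no genome sequence for chromosome {tx.chrom!r}")
    chrom_seq = genome[tx.chrom]
    if tx.end > len(chrom_seq):
        raise ValueError(
            f"transcript {tx.transcript_id} extends past end of {tx.chrom}"
        )
    seq = "".join(chrom_seq[s:e] for s, e in tx.exons)
    return reverse_complement(seq) if tx.strand == "-" else seq
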
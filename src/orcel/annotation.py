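"""Annotate back-spliced junctions into circRNA isoform sequences.

A back-spliced junction only pins down the closure point of the circle; the
internal structure is inferred from the gene annotation by four rules,
applied in order of specificity:

1. *exact_exon* — the junction endpoints coincide exactly with an exon start
   and an exon end of one transcript: the circle is all exons of that
   transcript lying within the junction interval.
2. *multi_isoform* — several transcripts satisfy rule 1: one candidate
   isoform is emitted per transcript (no attempt is made to pick the
   expressed one).
3. *misaligned* — the endpoints fall within ``slack`` nucleotides of exon
   boundaries: the flanked exons are taken and the first/last block is
   extended to the junction endpoint, so a small head/tail portion of
   intron is included.
4. *intergenic* — no same-strand gene overlaps the junction (gene deserts
   and antisense-only overlaps): the entire flanked genomic sequence is the
   circle, as a single block.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .io import (
    BackSplicedJunction,
    GeneModel,
    TranscriptModel,
    reverse_complement,
)

__all__ = [
    "RULE_EXACT",
    "RULE_MULTI",
    "RULE_MISALIGNED",
    "RULE_INTERGENIC",
    "CircIsoform",
    "annotate_junction",
    "annotate_all",
    "circularize",
]

RULE_EXACT = "exact_exon"
RULE_MULTI = "multi_isoform"
RULE_MISALIGNED = "misaligned"
RULE_INTERGENIC = "intergenic"

INTERGENIC_HOST = "intergenic"


@dataclass(frozen=True)
class CircIsoform:
    """An annotated circular RNA isoform.

    ``blocks`` are the genomic intervals (0-based half-open, genomic order)
    composing the circle; ``sequence`` is their concatenation in 5'->3'
    transcript orientation (reverse-complemented for '-' junctions);
    ``length`` is the circle length used by the sponge statistic.
    """

    isoform_id: str
    junction: BackSplicedJunction
    host_gene: str
    source_transcript: str | None
    blocks: tuple[tuple[int, int], ...]
    sequence: str
    rule_applied: str

    def __post_init__(self) -> None:
        span = sum(e - s for s, e in self.blocks)
        if span != len(self.sequence):
            raise ValueError(
                f"{self.isoform_id}: block span {span} != sequence length {len(self.sequence)}"
            )
        j = self.junction
        if self.blocks[0][0] != j.start or self.blocks[-1][1] != j.end:
            raise ValueError(f"{self.isoform_id}: blocks do not reach the junction endpoints")
        for s, e in self.blocks:
            if s < j.start or e > j.end:
                raise ValueError(f"{self.isoform_id}: block ({s},{e}) outside junction")

    @property
    def length(self) -> int:
        return len(self.sequence)


def circularize(sequence: str, max_seed_len: int) -> str:
    """Linearize a covalently closed circle for substring search.

    Appends the first ``max_seed_len - 1`` nucleotides so that every
    circular window of length <= ``max_seed_len`` occurs exactly once as a
    linear substring (junction-spanning windows included).
    """
    if len(sequence) < 1:
        raise ValueError("sequence must be non-empty")
    if max_seed_len < 1:
        raise ValueError("max_seed_len must be >= 1")
    return sequence + sequence[: max_seed_len - 1]


def _extract(genome: Mapping[str, str], j: BackSplicedJunction,
             blocks: Sequence[tuple[int, int]]) -> str:
    chrom_seq = genome[j.chrom]
    seq = "".join(chrom_seq[s:e] for s, e in blocks)
    return reverse_complement(seq) if j.strand == "-" else seq


def _rule1_blocks(tx: TranscriptModel, j: BackSplicedJunction) -> tuple | None:
    starts = {s for s, _ in tx.exons}
    ends = {e for _, e in tx.exons}
    if j.start not in starts or j.end not in ends:
        return None
    blocks = tuple((s, e) for s, e in tx.exons if s >= j.start and e <= j.end)
    if not blocks or blocks[0][0] != j.start or blocks[-1][1] != j.end:
        return None
    return blocks


def _rule3_blocks(tx: TranscriptModel, j: BackSplicedJunction, slack: int) -> tuple | None:
    # nearest exon start to the acceptor and nearest exon end to the donor,
    # each within the slack window
    best_a = min(
        (i for i in range(len(tx.exons)) if abs(tx.exons[i][0] - j.start) <= slack),
        key=lambda i: (abs(tx.exons[i][0] - j.start), i),
        default=None,
    )
    best_b = min(
        (i for i in range(len(tx.exons)) if abs(tx.exons[i][1] - j.end) <= slack),
        key=lambda i: (abs(tx.exons[i][1] - j.end), i),
        default=None,
    )
    if best_a is None or best_b is None or best_b < best_a:
        return None
    blocks = [list(b) for b in tx.exons[best_a : best_b + 1]]
    blocks[0][0] = j.start
    blocks[-1][1] = j.end
    if any(e <= s for s, e in blocks):
        return None
    # extension may not break block ordering (slack << intron length in
    # practice; guard anyway)
    for (s0, e0), (s1, e1) in zip(blocks, blocks[1:]):
        if s1 < e0:
            return None
    return tuple(tuple(b) for b in blocks)


def annotate_junction(
    j: BackSplicedJunction,
    genes: Iterable[GeneModel],
    genome: Mapping[str, str],
    slack: int = 5,
) -> list[CircIsoform]:
    """Apply the four annotation rules to one junction.

    Returns one isoform per matching transcript (rules 1-3) or a single
    intergenic isoform (rule 4).  Deterministic: candidate isoforms are
    ordered by source transcript id and numbered ``#1, #2, ...`` within the
    junction.
    """
    if slack < 0:
        raise ValueError("slack must be >= 0")
    if j.chrom not in genome:
        raise KeyError(f"no genome sequence for chromosome {j.chrom!r}")
    if j.end > len(genome[j.chrom]) or j.start < 0:
        raise ValueError(f"junction {j.label} beyond chromosome bounds")

    overlapping = [
        (g, tx)
        for g in genes
        for tx in g.transcripts
        if tx.chrom == j.chrom and tx.strand == j.strand
        and tx.start < j.end and tx.end > j.start
    ]

    matches: list[tuple[GeneModel, TranscriptModel, tuple, str]] = []
    exact = [
        (g, tx, blocks)
        for g, tx in overlapping
        if (blocks := _rule1_blocks(tx, j)) is not None
    ]
    if exact:
        rule = RULE_EXACT if len(exact) == 1 else RULE_MULTI
        matches = [(g, tx, blocks, rule) for g, tx, blocks in exact]
    else:
        near = [
            (g, tx, blocks)
            for g, tx in overlapping
            if (blocks := _rule3_blocks(tx, j, slack)) is not None
        ]
        matches = [(g, tx, blocks, RULE_MISALIGNED) for g, tx, blocks in near]

    if not matches:
        # rule 4: intergenic or antisense-only overlap
        blocks = ((j.start, j.end),)
        return [
            CircIsoform(
                isoform_id=f"{j.label}#1",
                junction=j,
                host_gene=INTERGENIC_HOST,
                source_transcript=None,
                blocks=blocks,
                sequence=_extract(genome, j, blocks),
                rule_applied=RULE_INTERGENIC,
            )
        ]

    matches.sort(key=lambda m: m[1].transcript_id)
    out = []
    for k, (g, tx, blocks, rule) in enumerate(matches, start=1):
        out.append(
            CircIsoform(
                isoform_id=f"{j.label}#{k}",
                junction=j,
                host_gene=g.gene_id,
                source_transcript=tx.transcript_id,
                blocks=blocks,
                sequence=_extract(genome, j, blocks),
                rule_applied=rule,
            )
        )
    return out


def annotate_all(
    junctions: Iterable[BackSplicedJunction],
    genes: Iterable[GeneModel],
    genome: Mapping[str, str],
    slack: int = 5,
) -> list[CircIsoform]:
    """Annotate a collection of junctions; isoform order follows input order."""
    gene_list = list(genes)
    out: list[CircIsoform] = []
    for j in junctions:
        out.extend(annotate_junction(j, gene_list, genome, slack=slack))
    return out
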
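"""Synthetic data generator for the whole pipeline.

Builds, from a single seed, a bundle emulating every input the pipeline
consumes: an i.i.d. genome with configurable GC, gene models (GTF),
back-spliced junctions with a configurable mix of the four annotation
rules (BED6+2 with evidence counts), mature miRNAs (FASTA), a verified
miRNA->gene target table (TSV), per-sample junction read counts and sample
statistics (TSV), and an isoform FPKM table (TSV) — together with the
ground truth of planted signals.

Planted signals:

* *sponges* — for selected exact-rule circles, exact 8mer target sites of a
  designated miRNA are written into the circle's exonic sequence at
  non-overlapping positions, at a density ``multiplier`` times the i.i.d.
  6mer null expectation (L/4096 sites; the 6mer class is the most
  permissive, and a literal 8mer null of L/4^8 would round to zero sites at
  realistic circle lengths, with at least 2 sites so the signal survives
  length normalization).
* *loops* — a subset of planted sponges additionally gets a verified
  (miRNA -> host gene) row in the target table, closing the loop.

Decoy target edges are drawn only from genes that host no junction, so a
decoy edge can never close a loop with any sponge call; decoy junctions
straddle both the evidence and the SRPBM thresholds.

The background sequence is i.i.d. (no dinucleotide or repeat structure),
which makes the site-count null analytically Poisson and hence testable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np

from .annotation import CircIsoform, annotate_all
from .expression import SampleStats
from .io import (
    BackSplicedJunction,
    GeneModel,
    TranscriptModel,
    reverse_complement,
    write_fasta,
    write_gtf,
    write_junctions,
)
from .network import TargetEdge, write_targets
from .sponge import MiRNA, SpongeResult
from .network import OrcelTriple

__all__ = [
    "SimConfig",
    "GroundTruth",
    "SimBundle",
    "StageRecovery",
    "simulate",
    "evaluate_recovery",
]

_ALPHABET = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for a synthetic run.

    Defaults describe a desk-scale transcriptome: 200 protein-coding genes
    of 4-8 exons (exons 120-320 nt, introns 200-800 nt), 50 miRNAs, 60
    back-spliced junctions in a 50/20/20/10 exact/multi-isoform/misaligned/
    intergenic mix, 20 planted sponge circles at 8x seed density of which
    10 close verified loops, profiled in 5 samples of 100-nt reads.
    """

    seed: int = 42
    n_genes: int = 200
    exons_per_gene: tuple[int, int] = (4, 8)
    exon_length: tuple[int, int] = (120, 320)
    intron_length: tuple[int, int] = (200, 800)
    intergenic_gap: tuple[int, int] = (500, 1500)
    n_mirnas: int = 50
    mirna_length: int = 22
    n_junctions: int = 60
    rule_mix: tuple[float, float, float, float] = (0.5, 0.2, 0.2, 0.1)
    misalign_offset: tuple[int, int] = (1, 5)
    intergenic_circle_length: tuple[int, int] = (300, 2000)
    n_planted_sponges: int = 20
    planted_multiplier: float = 8.0
    n_planted_loops: int = 10
    n_decoy_targets: int = 100
    n_samples: int = 5
    read_length: int = 100
    mapped_reads: tuple[int, int] = (20_000_000, 80_000_000)
    srpbm_pass_range: tuple[float, float] = (2.0, 20.0)
    srpbm_fail_frac: float = 0.5
    evidence_fail_frac: float = 0.3
    background_gc: float = 0.5

    def validate(self) -> None:
        if self.seed < 0:
            raise ValueError("seed must be >= 0")
        for name in (
            "n_genes", "n_mirnas", "n_junctions", "n_planted_sponges",
            "n_planted_loops", "n_decoy_targets", "n_samples",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.planted_multiplier < 1:
            raise ValueError("planted_multiplier must be >= 1")
        if abs(sum(self.rule_mix) - 1.0) > 1e-9:
            raise ValueError("rule_mix proportions must sum to 1")
        if not 0 < self.background_gc < 1:
            raise ValueError("background_gc must lie in (0, 1)")
        if self.n_planted_loops > self.n_planted_sponges:
            raise ValueError("cannot plant more loops than sponges")
        if self.mirna_length < 8:
            raise ValueError("mature miRNAs must be >= 8 nt")


@dataclass
class GroundTruth:
    """What was planted: sponge pairs, loop triples, per-junction evidence."""

    sponge_pairs: list[tuple[str, str]] = field(default_factory=list)
    loop_triples: list[tuple[str, str, str]] = field(default_factory=list)
    junction_evidence: dict[str, tuple[int, int]] = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "sponge_pairs": [list(p) for p in self.sponge_pairs],
                    "loop_triples": [list(t) for t in self.loop_triples],
                    "junction_evidence": {
                        k: list(v) for k, v in self.junction_evidence.items()
                    },
                },
                fh,
                indent=1,
            )

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            sponge_pairs=[tuple(p) for p in d["sponge_pairs"]],
            loop_triples=[tuple(t) for t in d["loop_triples"]],
            junction_evidence={k: tuple(v) for k, v in d["junction_evidence"].items()},
        )


@dataclass
class SimBundle:
    """All pipeline inputs (in memory) plus the planted ground truth."""

    config: SimConfig
    genome: dict[str, str]
    genes: list[GeneModel]
    junctions: list[BackSplicedJunction]
    mirnas: list[MiRNA]
    targets: list[TargetEdge]
    sample_stats: dict[str, SampleStats]
    junction_counts: dict[tuple[str, str], int]
    fpkm: dict[tuple[str, str], float]
    truth: GroundTruth | None = None
    isoforms: list[CircIsoform] = field(default_factory=list)

    def write(self, outdir) -> None:
        """Write every input as the plain-text format the readers consume."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        write_fasta(self.genome, out / "genome.fa")
        write_gtf(self.genes, out / "genes.gtf")
        write_junctions(self.junctions, out / "junctions.bed")
        write_fasta({m.mirna_id: m.mature_seq for m in self.mirnas}, out / "mirnas.fa")
        write_targets(self.targets, out / "targets.tsv")
        with open(out / "sample_stats.tsv", "w") as fh:
            fh.write("sample_id\tread_length\tmapped_reads\n")
            for s in self.sample_stats.values():
                fh.write(f"{s.sample_id}\t{s.read_length}\t{s.mapped_reads}\n")
        with open(out / "junction_counts.tsv", "w") as fh:
            fh.write("junction_id\tsample_id\tjunction_reads\n")
            for (jid, sid), reads in self.junction_counts.items():
                fh.write(f"{jid}\t{sid}\t{reads}\n")
        with open(out / "fpkm.tsv", "w") as fh:
            fh.write("isoform_id\tsample_id\tfpkm\n")
            for (iid, sid), v in self.fpkm.items():
                fh.write(f"{iid}\t{sid}\t{v:.6f}\n")
        if self.truth is not None:
            self.truth.to_json(out / "ground_truth.json")
        with open(out / "sim_config.json", "w") as fh:
            json.dump(asdict(self.config), fh, indent=1)


def _largest_remainder(total: int, proportions) -> list[int]:
    raw = [p * total for p in proportions]
    counts = [int(x) for x in raw]
    rem = total - sum(counts)
    order = sorted(range(len(raw)), key=lambda i: raw[i] - counts[i], reverse=True)
    for i in order[:rem]:
        counts[i] += 1
    return counts


def _random_seq(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(_ALPHABET[rng.choice(4, size=n, p=p)])


def simulate(config: SimConfig | None = None) -> SimBundle:
    """Generate a full input bundle from ``config`` (reproducible from its seed)."""
    config = config or SimConfig()
    config.validate()
    chrom = "chrS"
    streams = np.random.SeedSequence(config.seed).spawn(8)
    rng_layout, rng_genome, rng_mirna, rng_junc, rng_plant, rng_counts, rng_targets, rng_fpkm = (
        np.random.default_rng(s) for s in streams
    )

    # --- gene layout ---------------------------------------------------
    genes: list[GeneModel] = []
    cursor = 0
    exon_lists: list[list[tuple[int, int]]] = []
    strands: list[str] = []
    for i in range(config.n_genes):
        cursor += int(rng_layout.integers(*config.intergenic_gap, endpoint=True))
        n_ex = int(rng_layout.integers(*config.exons_per_gene, endpoint=True))
        exons = []
        pos = cursor
        for k in range(n_ex):
            elen = int(rng_layout.integers(*config.exon_length, endpoint=True))
            exons.append((pos, pos + elen))
            pos += elen
            if k < n_ex - 1:
                pos += int(rng_layout.integers(*config.intron_length, endpoint=True))
        cursor = pos
        strand = "+" if rng_layout.random() < 0.5 else "-"
        gid = f"G{i:04d}"
        genes.append(
            GeneModel(
                gene_id=gid,
                transcripts=[
                    TranscriptModel(f"{gid}.t1", chrom, strand, tuple(exons))
                ],
            )
        )
        exon_lists.append(exons)
        strands.append(strand)
    desert_start = cursor + 2000
    desert_len = 40_000
    genome_len = desert_start + desert_len

    genome_arr = np.frombuffer(
        _random_seq(rng_genome, genome_len, config.background_gc).encode(), dtype="S1"
    ).copy()

    # --- miRNAs ---------------------------------------------------------
    mirnas = [
        MiRNA.from_mature(f"miR-{i:03d}", _random_seq(rng_mirna, config.mirna_length, 0.5))
        for i in range(config.n_mirnas)
    ]

    # --- junctions ------------------------------------------------------
    n_exact, n_multi, n_mis, n_inter = _largest_remainder(config.n_junctions, config.rule_mix)
    if n_exact < config.n_planted_sponges:
        raise ValueError(
            f"rule mix yields only {n_exact} exact-rule junctions; "
            f"{config.n_planted_sponges} planted sponges requested"
        )
    genic_needed = n_exact + n_multi + n_mis
    if genic_needed > config.n_genes:
        raise ValueError("more genic junctions requested than genes available")
    gene_order = rng_junc.permutation(config.n_genes)
    junctions: list[BackSplicedJunction] = []
    junction_gene: dict[str, int] = {}
    jix = 0

    def _next_name() -> str:
        nonlocal jix
        jix += 1
        return f"j{jix:04d}"

    def _span(exons, need_internal: bool):
        n_ex = len(exons)
        if need_internal:
            a = int(rng_junc.integers(0, n_ex - 2))
            b = int(rng_junc.integers(a + 2, n_ex))
        else:
            a = int(rng_junc.integers(0, n_ex - 1))
            b = int(rng_junc.integers(a + 1, n_ex))
        return a, b

    used_genes = iter(gene_order)
    exact_span: dict[str, tuple[int, int, int]] = {}  # name -> (gene_idx, a, b)
    for _ in range(n_exact):
        gi = int(next(used_genes))
        exons = exon_lists[gi]
        a, b = _span(exons, need_internal=False)
        name = _next_name()
        j = BackSplicedJunction(
            chrom, exons[a][0], exons[b][1], strands[gi], name=name
        )
        junctions.append(j)
        junction_gene[name] = gi
        exact_span[name] = (gi, a, b)
    for _ in range(n_multi):
        gi = int(next(used_genes))
        exons = exon_lists[gi]
        a, b = _span(exons, need_internal=True)
        skip = int(rng_junc.integers(a + 1, b))
        g = genes[gi]
        t2 = TranscriptModel(
            f"{g.gene_id}.t2",
            chrom,
            strands[gi],
            tuple(e for k, e in enumerate(g.transcripts[0].exons) if k != skip),
        )
        g.transcripts.append(t2)
        name = _next_name()
        junctions.append(
            BackSplicedJunction(chrom, exons[a][0], exons[b][1], strands[gi], name=name)
        )
        junction_gene[name] = gi
    for _ in range(n_mis):
        gi = int(next(used_genes))
        exons = exon_lists[gi]
        a, b = _span(exons, need_internal=False)
        off1 = int(rng_junc.integers(*config.misalign_offset, endpoint=True))
        off2 = int(rng_junc.integers(*config.misalign_offset, endpoint=True))
        name = _next_name()
        junctions.append(
            BackSplicedJunction(
                chrom, exons[a][0] - off1, exons[b][1] + off2, strands[gi], name=name
            )
        )
        junction_gene[name] = gi
    inter_cursor = desert_start
    for _ in range(n_inter):
        ln = int(rng_junc.integers(*config.intergenic_circle_length, endpoint=True))
        if inter_cursor + ln > genome_len:
            raise ValueError("gene desert too small for requested intergenic junctions")
        name = _next_name()
        junctions.append(
            BackSplicedJunction(
                chrom, inter_cursor, inter_cursor + ln,
                "+" if rng_junc.random() < 0.5 else "-", name=name
            )
        )
        inter_cursor += ln + 200

    # --- plant sponge sites --------------------------------------------
    truth = GroundTruth()
    planted_names = [junctions[k].name for k in range(config.n_planted_sponges)]
    planted_mirna: dict[str, str] = {}
    for name in planted_names:
        gi, a, b = exact_span[name]
        blocks = exon_lists[gi][a : b + 1]
        L = sum(e - s for s, e in blocks)
        m = mirnas[int(rng_plant.integers(0, config.n_mirnas))]
        site = m.seeds["8mer"]
        genomic_site = site if strands[gi] == "+" else reverse_complement(site)
        n_sites = max(2, int(round(config.planted_multiplier * L / 4096)))
        slots: list[tuple[int, int]] = []
        positions: list[int] = []
        # candidate starts keep the whole site inside one exon block
        candidates = [
            (bi, p)
            for bi, (s, e) in enumerate(blocks)
            for p in range(s, e - len(site) + 1)
        ]
        if n_sites * len(site) * 2 > L:
            raise ValueError(
                f"cannot fit {n_sites} planted sites into a {L}-nt circle"
            )
        attempts = 0
        while len(positions) < n_sites:
            attempts += 1
            if attempts > 10_000:
                raise ValueError("failed to place non-overlapping planted sites")
            _, p = candidates[int(rng_plant.integers(0, len(candidates)))]
            if all(abs(p - q) >= len(site) for q in positions):
                positions.append(p)
        for p in positions:
            genome_arr[p : p + len(site)] = np.frombuffer(
                genomic_site.encode(), dtype="S1"
            )
            slots.append((p, p + len(site)))
        planted_mirna[name] = m.mirna_id

    genome = {chrom: genome_arr.tobytes().decode()}

    # --- annotate (post-planting genome) to fix isoform ids -------------
    isoforms = annotate_all(junctions, genes, genome, slack=config.misalign_offset[1])
    iso_by_junction: dict[str, list[CircIsoform]] = {}
    for iso in isoforms:
        iso_by_junction.setdefault(iso.junction.junction_id, []).append(iso)
    for name in planted_names:
        for iso in iso_by_junction[name]:
            truth.sponge_pairs.append((iso.isoform_id, planted_mirna[name]))

    # --- target table ----------------------------------------------------
    targets: list[TargetEdge] = []
    loop_names = planted_names[: config.n_planted_loops]
    for name in loop_names:
        gi = junction_gene[name]
        for iso in iso_by_junction[name]:
            truth.loop_triples.append(
                (genes[gi].gene_id, iso.isoform_id, planted_mirna[name])
            )
        targets.append(
            TargetEdge(planted_mirna[name], genes[gi].gene_id, evidence="planted")
        )
    junction_gene_ids = set(junction_gene.values())
    free_genes = [i for i in range(config.n_genes) if i not in junction_gene_ids]
    seen_decoys = set()
    while len(seen_decoys) < min(
        config.n_decoy_targets, len(free_genes) * config.n_mirnas
    ):
        gi = free_genes[int(rng_targets.integers(0, len(free_genes)))]
        mi = int(rng_targets.integers(0, config.n_mirnas))
        key = (mirnas[mi].mirna_id, genes[gi].gene_id)
        if key in seen_decoys:
            continue
        seen_decoys.add(key)
        targets.append(TargetEdge(key[0], key[1], evidence="decoy"))

    # --- evidence counts --------------------------------------------------
    rebuilt: list[BackSplicedJunction] = []
    for j in junctions:
        planted = j.name in planted_names
        fail = (not planted) and rng_counts.random() < config.evidence_fail_frac
        if fail:
            rep = int(rng_counts.integers(0, 4))
            samp = int(rng_counts.integers(0, max(1, 9 - rep)))
        else:
            rep = int(rng_counts.integers(3, 16))
            samp = int(rng_counts.integers(7, 60))
        rebuilt.append(
            BackSplicedJunction(
                j.chrom, j.start, j.end, j.strand,
                report_count=rep, sample_count=samp, name=j.name,
            )
        )
        truth.junction_evidence[j.name] = (rep, samp)
    junctions = rebuilt
    # re-link isoforms to the evidence-carrying junction records
    jmap = {j.name: j for j in junctions}
    isoforms = [
        CircIsoform(
            isoform_id=iso.isoform_id,
            junction=jmap[iso.junction.junction_id],
            host_gene=iso.host_gene,
            source_transcript=iso.source_transcript,
            blocks=iso.blocks,
            sequence=iso.sequence,
            rule_applied=iso.rule_applied,
        )
        for iso in isoforms
    ]

    # --- samples, junction read counts, FPKM ------------------------------
    sample_stats = {
        f"S{k:02d}": SampleStats(
            f"S{k:02d}",
            config.read_length,
            int(rng_counts.integers(*config.mapped_reads, endpoint=True)),
        )
        for k in range(1, config.n_samples + 1)
    }
    junction_counts: dict[tuple[str, str], int] = {}
    for j in junctions:
        planted = j.name in planted_names
        srpbm_fail = (not planted) and rng_counts.random() < config.srpbm_fail_frac
        for sid, s in sample_stats.items():
            denom = s.read_length * s.mapped_reads
            if srpbm_fail:
                max_reads = int(denom / 1e9)  # srpbm <= 1.0
                reads = int(rng_counts.integers(0, max(1, max_reads) + 1))
                reads = min(reads, max_reads)
            else:
                target = rng_counts.uniform(*config.srpbm_pass_range)
                reads = max(1, int(round(target * denom / 1e9)))
            junction_counts[(j.name, sid)] = reads

    fpkm: dict[tuple[str, str], float] = {}
    for iso in isoforms:
        planted = iso.junction.junction_id in planted_names
        for sid in sample_stats:
            if planted:
                v = rng_fpkm.uniform(2.0, 10.0)
            else:
                v = rng_fpkm.uniform(0.2, 3.0)
            fpkm[(iso.isoform_id, sid)] = float(v)

    return SimBundle(
        config=config,
        genome=genome,
        genes=genes,
        junctions=junctions,
        mirnas=mirnas,
        targets=targets,
        sample_stats=sample_stats,
        junction_counts=junction_counts,
        fpkm=fpkm,
        truth=truth,
        isoforms=isoforms,
    )


@dataclass(frozen=True)
class StageRecovery:
    sensitivity: float
    precision: float
    n_true: int
    n_detected: int


def _recovery(true_set: set, detected_set: set) -> StageRecovery:
    hit = len(true_set & detected_set)
    sens = hit / len(true_set) if true_set else 1.0
    prec = hit / len(detected_set) if detected_set else 1.0
    return StageRecovery(sens, prec, len(true_set), len(detected_set))


def evaluate_recovery(
    truth: GroundTruth,
    sponge_results: list[SpongeResult] | None = None,
    triples: list[OrcelTriple] | None = None,
) -> dict[str, StageRecovery]:
    """Sensitivity/precision of sponge calls and loop triples against the
    planted ground truth."""
    out: dict[str, StageRecovery] = {}
    if sponge_results is not None:
        detected = {(r.isoform_id, r.mirna_id) for r in sponge_results if r.is_sponge}
        out["sponge"] = _recovery(set(map(tuple, truth.sponge_pairs)), detected)
    if triples is not None:
        detected_t = {(t.gene_id, t.isoform_id, t.mirna_id) for t in triples}
        out["loop"] = _recovery(set(map(tuple, truth.loop_triples)), detected_t)
    return out
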
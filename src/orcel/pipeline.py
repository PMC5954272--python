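"""End-to-end driver: junction evidence filter -> isoform annotation ->
expression filter -> sponge scoring -> ORCEL loop join.

Stages run in the order the analysis applies its filters (evidence
co-occurrence first, then expression, then the sponge statistic, then the
target-table join), and the count surviving each stage is logged in
``stage_counts``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from .annotation import CircIsoform, annotate_all
from .expression import (
    build_expression_records,
    filter_cooccurrence,
    filter_expressed,
    read_fpkm_table,
    read_junction_counts,
    read_sample_stats,
    ExpressionRecord,
)
from .io import read_fasta, read_gtf, read_junctions, transcript_sequence
from .network import OrcelTriple, TripleSummary, detect_orcel, read_targets, summarize
from .simulate import SimBundle, SimConfig, GroundTruth
from .sponge import (
    BackgroundModel,
    MiRNA,
    SpongeResult,
    build_background,
    score_all,
)

__all__ = ["PipelineResult", "run_pipeline", "load_bundle"]


@dataclass
class PipelineResult:
    isoforms: list[CircIsoform]
    expression_records: list[ExpressionRecord]
    surviving_ids: list[str]
    background: BackgroundModel
    sponge_results: list[SpongeResult]
    triples: list[OrcelTriple]
    summary: TripleSummary
    stage_counts: dict[str, int] = field(default_factory=dict)

    @property
    def sponge_call_fraction(self) -> float:
        """Fraction of scored (isoform, miRNA) pairs called sponges."""
        if not self.sponge_results:
            return 0.0
        return sum(r.is_sponge for r in self.sponge_results) / len(self.sponge_results)


def load_bundle(indir) -> SimBundle:
    """Load a written input bundle back from disk (ground truth optional)."""
    d = Path(indir)
    mirna_seqs = read_fasta(d / "mirnas.fa")
    truth_path = d / "ground_truth.json"
    return SimBundle(
        config=SimConfig(),
        genome=read_fasta(d / "genome.fa"),
        genes=read_gtf(d / "genes.gtf"),
        junctions=read_junctions(d / "junctions.bed"),
        mirnas=[MiRNA.from_mature(k, v) for k, v in mirna_seqs.items()],
        targets=read_targets(d / "targets.tsv"),
        sample_stats=read_sample_stats(d / "sample_stats.tsv"),
        junction_counts=read_junction_counts(d / "junction_counts.tsv"),
        fpkm=read_fpkm_table(d / "fpkm.tsv"),
        truth=GroundTruth.from_json(truth_path) if truth_path.exists() else None,
    )


def run_pipeline(
    bundle: SimBundle,
    alpha: float = 0.005,
    slack: int = 5,
    srpbm_min: float = 1.0,
    fpkm_min: float = 1.0,
    min_combined: int = 10,
    circular: bool = True,
    combine: str = "min",
    background_mode: str = "per_mirna",
    score_all_isoforms: bool = False,
) -> PipelineResult:
    """Run the whole analysis over an input bundle.

    ``score_all_isoforms=True`` scores every annotated isoform instead of
    only the expression survivors (used for null-calibration measurements);
    the loop join always respects the expression filter.
    """
    stage_counts: dict[str, int] = {"junctions_input": len(bundle.junctions)}

    kept_junctions = [j for j in bundle.junctions if filter_cooccurrence(j, min_combined)]
    stage_counts["junctions_cooccurrence"] = len(kept_junctions)

    isoforms = annotate_all(kept_junctions, bundle.genes, bundle.genome, slack=slack)
    stage_counts["isoforms_annotated"] = len(isoforms)

    records = build_expression_records(
        isoforms, bundle.junction_counts, bundle.sample_stats, fpkm_table=bundle.fpkm
    )
    surviving = filter_expressed(records, srpbm_min=srpbm_min, fpkm_min=fpkm_min)
    stage_counts["isoforms_expressed"] = len(surviving)

    transcripts = {
        tx.transcript_id: transcript_sequence(tx, bundle.genome)
        for g in bundle.genes
        for tx in g.transcripts
    }
    background = build_background(transcripts, bundle.mirnas, mode=background_mode)

    surviving_set = set(surviving)
    to_score = (
        isoforms
        if score_all_isoforms
        else [iso for iso in isoforms if iso.isoform_id in surviving_set]
    )
    sponge_results = score_all(
        to_score, bundle.mirnas, background, alpha=alpha, circular=circular, combine=combine
    )
    stage_counts["pairs_scored"] = len(sponge_results)
    stage_counts["sponge_calls"] = sum(r.is_sponge for r in sponge_results)

    joinable = [
        r for r in sponge_results if r.isoform_id in surviving_set
    ]
    triples = detect_orcel(joinable, isoforms, bundle.targets)
    stage_counts["orcel_triples"] = len(triples)

    return PipelineResult(
        isoforms=isoforms,
        expression_records=records,
        surviving_ids=surviving,
        background=background,
        sponge_results=sponge_results,
        triples=triples,
        summary=summarize(triples),
        stage_counts=stage_counts,
    )
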
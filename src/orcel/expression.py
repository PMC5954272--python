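"""Expression-level evidence for circRNAs.

Two per-sample abundance measures are used as filters:

* SRPBM (spliced reads per billion mapping) for the back-spliced junction:
  ``junction_reads * 1e9 / (read_length * mapped_reads)``.
* FPKM for the annotated isoform sequence.  Full transcript deconvolution
  is not performed here; FPKM is either a naive length-normalized count or
  a precomputed table passed through unchanged.

An isoform is kept when, in at least one sample, its junction SRPBM and its
FPKM both exceed their thresholds (strict >, default 1.0 each).  A separate
co-occurrence filter requires a junction's combined external evidence
(publication reports + detecting samples) to reach 10.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .io import BackSplicedJunction

__all__ = [
    "SampleStats",
    "ExpressionRecord",
    "srpbm",
    "naive_fpkm",
    "build_expression_records",
    "filter_expressed",
    "filter_cooccurrence",
    "read_sample_stats",
    "read_junction_counts",
    "read_fpkm_table",
]


@dataclass(frozen=True)
class SampleStats:
    sample_id: str
    read_length: int
    mapped_reads: int

    def __post_init__(self) -> None:
        if self.read_length < 1:
            raise ValueError(f"sample {self.sample_id}: read_length must be >= 1")
        if self.mapped_reads < 1:
            raise ValueError(f"sample {self.sample_id}: mapped_reads must be >= 1")


@dataclass(frozen=True)
class ExpressionRecord:
    isoform_id: str
    junction_id: str
    sample_id: str
    junction_reads: int
    srpbm: float
    assigned_reads: int
    fpkm: float


def srpbm(junction_reads: int, sample: SampleStats) -> float:
    """Spliced reads per billion mapping for one junction in one sample."""
    if junction_reads < 0:
        raise ValueError("junction_reads must be >= 0")
    return junction_reads * 1e9 / (sample.read_length * sample.mapped_reads)


def naive_fpkm(assigned_reads: int, isoform_length: int, mapped_reads: int) -> float:
    """Naive FPKM: reads on the isoform per kb of isoform per million mapped."""
    if isoform_length < 1:
        raise ValueError("isoform_length must be >= 1")
    if mapped_reads < 1:
        raise ValueError("mapped_reads must be >= 1")
    return assigned_reads * 1e9 / (isoform_length * mapped_reads)


def read_sample_stats(path) -> dict[str, SampleStats]:
    df = pd.read_csv(path, sep="\t")
    return {
        str(r.sample_id): SampleStats(str(r.sample_id), int(r.read_length), int(r.mapped_reads))
        for r in df.itertuples()
    }


def read_junction_counts(path) -> dict[tuple[str, str], int]:
    """TSV (junction_id, sample_id, junction_reads) -> mapping."""
    df = pd.read_csv(path, sep="\t")
    return {
        (str(r.junction_id), str(r.sample_id)): int(r.junction_reads) for r in df.itertuples()
    }


def read_fpkm_table(path) -> dict[tuple[str, str], float]:
    """TSV (isoform_id, sample_id, fpkm) -> mapping, passed through bit-exactly."""
    df = pd.read_csv(path, sep="\t")
    return {(str(r.isoform_id), str(r.sample_id)): float(r.fpkm) for r in df.itertuples()}


def build_expression_records(
    isoforms: Iterable,
    junction_counts: Mapping[tuple[str, str], int],
    samples: Mapping[str, SampleStats],
    fpkm_table: Mapping[tuple[str, str], float] | None = None,
    assigned_reads: Mapping[tuple[str, str], int] | None = None,
) -> list[ExpressionRecord]:
    """One record per (isoform, sample).

    Junction reads are looked up by the isoform's junction id (absent
    entries count 0).  FPKM comes from ``fpkm_table`` when provided
    (pass-through), else from ``assigned_reads`` via :func:`naive_fpkm`,
    else 0.
    """
    out: list[ExpressionRecord] = []
    for iso in isoforms:
        jid = iso.junction.junction_id
        for sid, s in samples.items():
            reads = int(junction_counts.get((jid, sid), 0))
            ar = int(assigned_reads.get((iso.isoform_id, sid), 0)) if assigned_reads else 0
            if fpkm_table is not None:
                fpkm = float(fpkm_table.get((iso.isoform_id, sid), 0.0))
            elif assigned_reads is not None:
                fpkm = naive_fpkm(ar, iso.length, s.mapped_reads) if ar else 0.0
            else:
                fpkm = 0.0
            out.append(
                ExpressionRecord(
                    isoform_id=iso.isoform_id,
                    junction_id=jid,
                    sample_id=sid,
                    junction_reads=reads,
                    srpbm=srpbm(reads, s),
                    assigned_reads=ar,
                    fpkm=fpkm,
                )
            )
    return out


def filter_expressed(
    records: Iterable[ExpressionRecord],
    srpbm_min: float = 1.0,
    fpkm_min: float = 1.0,
    min_samples: int = 1,
    joint: bool = True,
) -> list[str]:
    """Isoform ids passing the expression thresholds (strict inequalities).

    ``joint=True`` (default) requires SRPBM and FPKM to clear their
    thresholds in the *same* sample, in at least ``min_samples`` samples;
    ``joint=False`` evaluates the two conditions over samples independently.
    """
    records = list(records)
    if not records:
        raise ValueError("no expression records")
    per_iso: dict[str, list[ExpressionRecord]] = {}
    for r in records:
        per_iso.setdefault(r.isoform_id, []).append(r)
    survivors = []
    for iso_id, recs in per_iso.items():
        if joint:
            hits = sum(1 for r in recs if r.srpbm > srpbm_min and r.fpkm > fpkm_min)
            ok = hits >= min_samples
        else:
            ok = (
                sum(1 for r in recs if r.srpbm > srpbm_min) >= min_samples
                and sum(1 for r in recs if r.fpkm > fpkm_min) >= min_samples
            )
        if ok:
            survivors.append(iso_id)
    return sorted(survivors)


def filter_cooccurrence(j: BackSplicedJunction, min_combined: int = 10) -> bool:
    """Evidence filter: publication reports + detecting samples >= threshold.

    Inclusive bound — accepted junctions' combined evidence starts exactly
    at the threshold.
    """
    return j.report_count + j.sample_count >= min_combined
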
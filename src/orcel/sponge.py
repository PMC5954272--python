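"""miRNA-sponge scoring of circRNA sequences.

For each (circRNA, miRNA) pair the four canonical seed-site classes are
counted by exact complementary match on the circle, converted to a
length-normalized frequency

    frequency = count * 1000 / (N * L)

(N = seed length in nt, L = circle length), and compared against the
background distribution of the same miRNA's seed frequencies over the
linear transcriptome via a z-score.  The one-tailed P-value is the upper
tail of the standard normal (survival function); a pair is called a
potential sponge when its combined P falls below ``alpha`` (default 0.005).

Seed-site definitions (target 5'->3', DNA alphabet):

* 6mer     — reverse complement of miRNA positions 2-7
* 7mer-m8  — reverse complement of miRNA positions 2-8
* 7mer-A1  — 6mer site followed by an A opposite miRNA position 1
* 8mer     — 7mer-m8 site followed by that A

Each class is counted independently on the raw sequence, so a site that
qualifies as an 8mer also increments the nested 6mer/7mer counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .annotation import CircIsoform, circularize
from .io import reverse_complement

__all__ = [
    "SEED_TYPES",
    "SEED_LENGTHS",
    "MiRNA",
    "SeedCount",
    "SpongeResult",
    "BackgroundModel",
    "extract_seeds",
    "count_sites",
    "seed_frequency",
    "build_background",
    "z_to_p",
    "score_pair",
    "score_all",
    "results_to_frame",
]

SEED_TYPES = ("6mer", "7mer-A1", "7mer-m8", "8mer")
SEED_LENGTHS = {"6mer": 6, "7mer-A1": 7, "7mer-m8": 7, "8mer": 8}


def extract_seeds(mature_seq: str) -> dict[str, str]:
    """Target-site strings for the four seed classes of a mature miRNA.

    ``mature_seq`` is the mature miRNA 5'->3'; RNA input (U) is accepted and
    mapped to the DNA alphabet.
    """
    seq = mature_seq.upper().replace("U", "T")
    if len(seq) < 8:
        raise ValueError(f"mature miRNA must be >= 8 nt, got {len(seq)}")
    six = reverse_complement(seq[1:7])   # positions 2-7
    seven_m8 = reverse_complement(seq[1:8])  # positions 2-8
    return {
        "6mer": six,
        "7mer-A1": six + "A",
        "7mer-m8": seven_m8,
        "8mer": seven_m8 + "A",
    }


@dataclass(frozen=True)
class MiRNA:
    mirna_id: str
    mature_seq: str
    seeds: Mapping[str, str] = field(default_factory=dict)

    @classmethod
    def from_mature(cls, mirna_id: str, mature_seq: str) -> "MiRNA":
        seq = mature_seq.upper().replace("U", "T")
        return cls(mirna_id=mirna_id, mature_seq=seq, seeds=extract_seeds(seq))


def count_sites(sequence: str, site: str, circular: bool = True) -> int:
    """Number of (possibly overlapping) exact occurrences of ``site``.

    With ``circular=True`` the search runs over the circularized sequence so
    sites spanning the back-spliced junction are included; each circular
    start position is counted at most once.
    """
    if not site:
        raise ValueError("site must be non-empty")
    hay = circularize(sequence, len(site)) if circular else sequence
    n = 0
    i = hay.find(site)
    while i != -1:
        n += 1
        i = hay.find(site, i + 1)
    return n


def seed_frequency(count: int, n: int, length: int) -> float:
    """Length-normalized seed frequency: ``count * 1000 / (n * length)``."""
    if length < 1:
        raise ValueError("circRNA length must be >= 1")
    if n < 1:
        raise ValueError("seed length must be >= 1")
    return count * 1000.0 / (n * length)


@dataclass(frozen=True)
class SeedCount:
    seed_type: str
    n: int
    count: int
    frequency: float


@dataclass(frozen=True)
class _BgStat:
    mean: float
    sd: float
    n_obs: int

    @property
    def degenerate(self) -> bool:
        return self.sd == 0.0


@dataclass
class BackgroundModel:
    """Per (miRNA, seed class) mean/sd of seed frequency over a reference
    population of linear transcripts.

    ``mode='per_mirna'`` keeps one distribution per miRNA (controls for seed
    composition); ``mode='pooled'`` pools frequencies across miRNAs within
    each seed class.
    """

    mode: str
    stats: dict[tuple[str, str], _BgStat]

    def get(self, mirna_id: str, seed_type: str) -> _BgStat:
        key = ("*", seed_type) if self.mode == "pooled" else (mirna_id, seed_type)
        if key not in self.stats:
            raise KeyError(f"no background for miRNA {mirna_id!r}, seed {seed_type!r}")
        return self.stats[key]


def build_background(
    transcripts: Mapping[str, str] | Sequence[str],
    mirnas: Iterable[MiRNA],
    mode: str = "per_mirna",
) -> BackgroundModel:
    """Seed-frequency background over the linear transcriptome.

    Frequencies use linear (non-circular) counting.  Population (n-divisor)
    standard deviation; with fewer than 2 transcripts the spread is
    meaningless and an error is raised.  A population whose sd is exactly 0
    is flagged degenerate and later forces P = 1 for that seed class.
    """
    seqs = list(transcripts.values()) if isinstance(transcripts, Mapping) else list(transcripts)
    if len(seqs) < 2:
        raise ValueError("background requires at least 2 linear transcripts")
    if mode not in ("per_mirna", "pooled"):
        raise ValueError(f"unknown background mode {mode!r}")
    lengths = [len(s) for s in seqs]
    out: dict[tuple[str, str], _BgStat] = {}
    pooled: dict[str, list[float]] = {t: [] for t in SEED_TYPES}
    for m in mirnas:
        for seed_type in SEED_TYPES:
            site = m.seeds[seed_type]
            n = SEED_LENGTHS[seed_type]
            freqs = [
                seed_frequency(count_sites(s, site, circular=False), n, L)
                for s, L in zip(seqs, lengths)
            ]
            if mode == "pooled":
                pooled[seed_type].extend(freqs)
            else:
                arr = np.asarray(freqs)
                out[(m.mirna_id, seed_type)] = _BgStat(
                    mean=float(arr.mean()), sd=float(arr.std(ddof=0)), n_obs=len(freqs)
                )
    if mode == "pooled":
        for seed_type, freqs in pooled.items():
            arr = np.asarray(freqs)
            out[("*", seed_type)] = _BgStat(
                mean=float(arr.mean()), sd=float(arr.std(ddof=0)), n_obs=len(freqs)
            )
    return BackgroundModel(mode=mode, stats=out)


def z_to_p(z: float) -> float:
    """One-tailed P from a z-score: the standard normal survival function 1 - Phi(z)."""
    if not math.isfinite(z):
        raise ValueError(f"z must be finite, got {z}")
    return float(stats.norm.sf(z))


@dataclass(frozen=True)
class SpongeResult:
    isoform_id: str
    mirna_id: str
    seed_counts: Mapping[str, SeedCount]
    z: Mapping[str, float]
    p: Mapping[str, float]
    combined_p: float
    is_sponge: bool
    degenerate_seeds: tuple[str, ...] = ()


def _combine(pvals: Sequence[float], method: str) -> float:
    if method == "min":
        return min(pvals)
    if method in ("fisher", "stouffer"):
        return float(stats.combine_pvalues(pvals, method=method)[1])
    raise ValueError(f"unknown combination method {method!r}")


def score_pair(
    iso: CircIsoform,
    mirna: MiRNA,
    background: BackgroundModel,
    alpha: float = 0.005,
    circular: bool = True,
    combine: str = "min",
) -> SpongeResult:
    """Score one (circRNA isoform, miRNA) pair against the background.

    Per seed class: circular site count, length-normalized frequency,
    z = (frequency - bg mean) / bg sd, one-tailed P.  A degenerate
    background (sd = 0) forces P = 1 for that class rather than fabricating
    significance.  ``combined_p`` is by default the minimum of the four
    per-class P-values (most inclusive reading; Fisher/Stouffer available).
    """
    counts: dict[str, SeedCount] = {}
    zs: dict[str, float] = {}
    ps: dict[str, float] = {}
    degenerate: list[str] = []
    L = iso.length
    for seed_type in SEED_TYPES:
        site = mirna.seeds[seed_type]
        n = SEED_LENGTHS[seed_type]
        c = count_sites(iso.sequence, site, circular=circular)
        f = seed_frequency(c, n, L)
        counts[seed_type] = SeedCount(seed_type=seed_type, n=n, count=c, frequency=f)
        bg = background.get(mirna.mirna_id, seed_type)
        if bg.degenerate:
            degenerate.append(seed_type)
            zs[seed_type] = math.nan
            ps[seed_type] = 1.0
        else:
            z = (f - bg.mean) / bg.sd
            zs[seed_type] = z
            ps[seed_type] = z_to_p(z)
    combined = _combine(list(ps.values()), combine)
    return SpongeResult(
        isoform_id=iso.isoform_id,
        mirna_id=mirna.mirna_id,
        seed_counts=counts,
        z=zs,
        p=ps,
        combined_p=combined,
        is_sponge=combined < alpha,
        degenerate_seeds=tuple(degenerate),
    )


def score_all(
    isoforms: Iterable[CircIsoform],
    mirnas: Iterable[MiRNA],
    background: BackgroundModel,
    alpha: float = 0.005,
    circular: bool = True,
    combine: str = "min",
) -> list[SpongeResult]:
    mirna_list = list(mirnas)
    return [
        score_pair(iso, m, background, alpha=alpha, circular=circular, combine=combine)
        for iso in isoforms
        for m in mirna_list
    ]


def results_to_frame(results: Iterable[SpongeResult]):
    """Flatten sponge results into a DataFrame (one row per pair)."""
    import pandas as pd

    rows = []
    for r in results:
        row: dict = {"isoform_id": r.isoform_id, "mirna_id": r.mirna_id}
        for t in SEED_TYPES:
            sc = r.seed_counts[t]
            row[f"count_{t}"] = sc.count
            row[f"freq_{t}"] = sc.frequency
            row[f"z_{t}"] = r.z[t]
            row[f"p_{t}"] = r.p[t]
        row["combined_p"] = r.combined_p
        row["is_sponge"] = r.is_sponge
        rows.append(row)
    return pd.DataFrame(rows)
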
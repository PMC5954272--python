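#!/usr/bin/env python
"""Measure the null behaviour of the sponge statistic.

Simulates studies with nothing planted (decoy target edges only, pointing at
circle-free genes) across several seeds, scores every annotated isoform
against every miRNA, and records the fraction of pairs called at
alpha = 0.005 together with the number of loop triples (always expected 0).

The measured per-pair call rate is ~0.10, far above the nominal 0.005: a
single occurrence of a rare 7mer/8mer site in a short circle produces a huge
z-score against the near-degenerate background of linear transcripts, and
taking the minimum over four correlated seed classes amplifies this.  The
table results/null_calibration.tsv quantifies that inflation.
"""

import dataclasses
from pathlib import Path

import pandas as pd

import orcel

ROOT = Path(__file__).resolve().parents[1]

rows = []
for seed in (1, 2, 3, 42):
    cfg = dataclasses.replace(
        orcel.SimConfig(seed=seed), n_planted_sponges=0, n_planted_loops=0
    )
    res = orcel.run_pipeline(orcel.simulate(cfg), score_all_isoforms=True)
    rows.append(
        {
            "seed": seed,
            "pairs_scored": res.stage_counts["pairs_scored"],
            "sponge_calls": res.stage_counts["sponge_calls"],
            "call_fraction": res.sponge_call_fraction,
            "orcel_triples": len(res.triples),
        }
    )

df = pd.DataFrame(rows)
(ROOT / "results").mkdir(exist_ok=True)
df.to_csv(ROOT / "results" / "null_calibration.tsv", sep="\t", index=False)
print(df.to_string(index=False))
print(f"\nmean null call fraction at alpha=0.005: {df.call_fraction.mean():.4f} "
      "(nominal would be 0.005; min-combination over sparse counts inflates it)")
print("loop triples under the null:", df.orcel_triples.sum())
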
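# Methods

## Model and procedure

The pipeline turns back-spliced junction calls into an ORCEL network in
four stages, each behind its own module:

1. **Evidence filter** (`orcel.expression.filter_cooccurrence`). A junction
   enters the analysis only if the number of publications reporting it plus
   the number of RNA-seq samples detecting it is at least `min_combined`
   (default 10, inclusive — accepted junctions' combined evidence starts
   exactly at the threshold). These counts travel with the junction record;
   the package does not re-run junction discovery on raw reads.
2. **Isoform annotation** (`orcel.annotation`). Four rules, in order of
   specificity: exact exon-boundary match (all flanked exons of the
   matching transcript), multiple matching transcripts (one candidate per
   transcript — no attempt to pick the expressed one), near-match within
   `slack` nucleotides (flanked exons plus the head/tail intron piece up to
   the junction), and intergenic/antisense-only (the entire flanked genomic
   sequence as a single block). When both an exact and a slack match exist,
   the exact match wins. A same-strand gene that overlaps without any
   boundary match also falls through to the whole-span rule. Sequences are
   extracted from the genome and reverse-complemented on `-` junctions;
   isoform ids are `chrom:start-end:strand#k` with `k` ordering candidates
   by transcript id, so annotation is deterministic.
3. **Sponge statistic** (`orcel.sponge`). Site counts per seed class are
   exact overlapping substring matches; by default counting runs over the
   circularized sequence (the molecule is covalently closed, so sites
   spanning the junction are real); a flag restores linear counting.
   Frequencies `count·1000/(N·L)` are z-scored against the per-miRNA
   background over the linear transcriptome and converted to one-tail
   P-values via the normal survival function; a pair is called at
   `combined_p < alpha`.
4. **Loop join** (`orcel.network.detect_orcel`). Sponge calls are joined
   with the verified target table on (miRNA, host gene), case-insensitively
   on the raw identifier strings — symbol-alias or cross-species mapping is
   the caller's responsibility. Intergenic circles never join. Every
   emitted triple is re-checked against both membership conditions by
   assertion.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `alpha` | 0.005 | sponge call threshold on the combined P (raw; no multiple-testing correction across pairs) |
| `slack` | 5 nt | maximum junction-to-exon-boundary offset for the misaligned rule; "a small portion of intron" implies a tight bound |
| `srpbm_min`, `fpkm_min` | 1.0, 1.0 | expression thresholds, strict `>`; both must hold in the same sample (configurable: k samples, or independent samples) |
| `min_combined` | 10 | inclusive combined-evidence threshold |
| `combine` | `min` | per-pair combination of the four per-seed-class P-values; `min` is the most inclusive reading (one strong class suffices); Fisher and Stouffer are available behind the same flag |
| `background_mode` | `per_mirna` | background population per miRNA over linear transcripts (controls for seed composition); `pooled` pools frequencies across miRNAs within a seed class |

Open design points resolved here: the seed taxonomy (6mer = positions 2–7,
7mer-m8 = 2–8, 7mer-A1 = 6mer + target-side A, 8mer = 7mer-m8 + A) follows
the canonical target-site classification; each class is counted
independently on the raw sequence, so nested sites increment every class
they satisfy. Degenerate backgrounds (zero standard deviation, e.g. a seed
never seen in any transcript) force P = 1 for that class with a flag,
rather than fabricating significance. FPKM is either a pass-through table
(returned bit-exactly) or a naive length-normalized count — transcript
deconvolution in the Cufflinks sense is out of scope, and the hypergeometric
gene-set enrichment is a plain Fisher-type test, not DAVID's EASE-modified
score.

## What the generator emulates — and what it does not

`orcel.simulate` builds a single-chromosome genome of i.i.d. nucleotides at
configurable GC, lays out genes (default 200, 4–8 exons of 120–320 nt,
introns 200–800 nt), draws 22-nt miRNAs, and places 60 junctions in a
50/20/20/10 mix of the four annotation rules (multi-isoform junctions get a
second, exon-skipping transcript). Planted sponge circles receive exact
8mer sites of a designated miRNA at non-overlapping positions inside their
exons. Because the literal i.i.d. 8mer expectation L/4⁸ rounds to zero
sites for kb-scale circles, planting density is anchored on the most
permissive class: `n_sites = max(2, round(multiplier · L/4⁶))` with
multiplier 8 by default. A subset of planted sponges additionally gets a
verified (miRNA → host gene) target row, closing the loop; decoy target
edges are drawn only from genes hosting no junction, so no decoy edge can
ever close a loop. Junction read counts are drawn so planted junctions'
SRPBM lands in a clearly passing range while half the decoys fail;
evidence counts similarly straddle the threshold. All randomness flows
from one root seed through named substreams, and a bundle written twice
from the same seed is byte-identical.

Deliberate simplifications: no dinucleotide, repeat or conservation
structure (the i.i.d. null makes seed counts analytically Poisson, which
the tests exploit); no read-level simulation (counts are drawn directly,
alignment is out of scope); one chromosome; mature miRNAs are uniform
random. Passing tests therefore demonstrate the pipeline's correctness and
the statistic's behaviour under its own assumptions — not performance on
real transcriptomes, where sequence composition, repeat-driven seed
clustering and length distributions differ.

## Null calibration — a known limitation

The z-score treats seed frequencies as approximately normal, but at
realistic lengths the counts are sparse: for a specific 7mer the expected
count in a 700-nt circle is ≈0.04. The background distribution over linear
transcripts is then nearly a point mass at zero with a tiny standard
deviation, so a *single* chance occurrence in a short circle yields z ≈
5–20 and an essentially zero P-value; taking the minimum over four
correlated seed classes amplifies this further. Measured on unplanted
synthetic studies (`analysis/03_null_calibration.py`), the per-pair call
fraction at alpha = 0.005 is ≈ 0.10–0.12 across seeds — twenty-fold above
nominal. This inflation is inherent to the normal approximation on sparse
discrete counts and is not curable by any parameter of the study
(per-miRNA vs pooled backgrounds and circular vs linear counting barely
move it); a calibrated variant would need an exact Poisson/binomial tail
or an empirical permutation null, which would be a different statistic.
Downstream, the target-table join is what restores specificity: in null
studies with no matching target edges, zero loop triples are emitted, and
in planted studies every planted loop and nothing else survives the join.

## Numerical notes

- Population (n-divisor) standard deviation for backgrounds; at least two
  background transcripts are required.
- Strict inequalities for the expression thresholds; inclusive for the
  evidence threshold.
- `z_to_p` is `scipy.stats.norm.sf`; it is strictly decreasing over the
  |z| ≤ 6 range where double precision resolves neighbouring values, which
  is the range the tests probe (beyond ≈ ±8 the tail saturates in double
  precision).
- GTF coordinates are converted between on-disk 1-based inclusive and
  internal 0-based half-open at the I/O boundary only; conversion is its
  own inverse and round-trips exactly.
- Circularized search appends `|site| − 1` leading nucleotides, so every
  circular window occurs exactly once; each start position is counted at
  most once.
- Default study sizes (200 genes, 50 miRNAs, 60 junctions, 5 samples) keep
  a full end-to-end run under ~2 s while leaving ≥ 2000 scored pairs for
  the calibration measurements.
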
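# Methods

This note documents the models and procedures `isotriage` implements, the
parameters that matter, the synthetic-data generator's scope, and the
numerical choices made where the design was genuinely open.

## Unit of analysis and coordinates

The unit of analysis is one full-length isoform sequence (a polished
long-read consensus). All coordinates in reports, gene models and hit
tables are 1-based inclusive, matching tabular search output; any
half-open arithmetic (e.g. BED input) is converted at the boundary.
Sequences are uppercased on read and U is mapped to T.

## Length filter

Reads shorter than `min_length` (default 300 bp) are removed; a read of
exactly 300 bp is kept, because the rule is "shorter than", not "at
most". The minimum is configurable since some datasets apply the cut at a
different point in their processing.

## Annotation scoring

A similarity search reports multiple HSPs per (query, subject). Annotation
quality is judged on the pooled subject, not single HSPs:

- **Identity length** of an HSP is its count of identical columns. The
  standard 12-column format carries only percent identity, so identity
  length is reconstructed as `round_half_up(pident × length / 100)`; a
  dialect with an explicit `nident` column overrides the reconstruction
  (exact by definition).
- **Cumulative identity** `ID = Σ identity_length / Σ aligned_length` over
  the subject's HSPs. Algebraically this is the alignment-length-weighted
  mean of per-HSP identity; the property suite tests that identity
  directly.
- **Query coverage** is recomputed from the union of HSP query intervals
  (`100 × |union| / qlen`) rather than trusted from the tool column, whose
  semantics vary across tool versions; `trust_qcovs: true` restores
  pass-through.

The best subject per query maximises cumulative bit score, with ties
broken by lower best E-value, then lexicographic subject id (total order,
hence deterministic reports).

**Tier thresholds.** High: `Qcovs ≥ 80`, `ID ≥ 0.80`; medium: `Qcovs ≥
50`, `ID ≥ 0.50`; otherwise low; no passing hit means unannotated. These
cutoffs are defaults of this package, fully exposed in configuration,
since published analyses rarely print their exact tiering cutoffs. An
optional minimum-query-length gate per tier exists (off by default) for
workflows that also gate tiers on sequence length. Threshold comparisons
are inclusive (`≥`).

Rows above the parser's E-value ceiling (default 1e-10) are dropped at
parse time with a counted warning. The number of subjects retained per
query can be capped (`limit_hits`, default 50) to mirror search-tool
settings.

## Contaminant screen

Stages run in a fixed order — chloroplast, mitochondrion, ribosomal,
virus/viroid/prokaryote, fungal — so a sequence matching two categories is
attributed to the earlier stage. Gates: bit score `A ≥ 300`, identity
`≥ 80 %`, E-value `≤ 1e-10`, all inclusive and configurable. Validation
compares `A` to the best general-database bit score `B`:

| case       | decision |
|------------|----------|
| `A > B`    | discard  |
| `A == B`   | keep     |
| `A < B`    | keep     |
| no `B`     | discard  |

`A` and `B` are single best-HSP bit scores, because the rule is stated on
raw search scores; "no B" discards because the keep condition requires a
better general-database hit, which is absent. Validation is applied to
every significant hit, not only borderline ones. Each input receives
exactly one decision; survivors are recorded as `passed_all`.

## Annotation cascade

Stage order and default cutoffs: protein database 1e-10 → nucleotide
database 1e-10 → species CDS+UTR / EST 1e-20 → ncRNA family table (taken
as-is, since family assignments arrive pre-scored). The CDS+UTR and EST
searches are combined as OR within one stage — a hit in either table
rescues the query — which is the permissive reading of "searched against
both"; callers preferring sequential semantics can run two cascades.
Stage membership is "has ≥ 1 row passing that stage's cutoff"; duplicate
rows are harmless (set semantics), and the tier classifier refines stage-1
members without changing membership. The ledger validates
`input = hits + no-hits` per stage, `input(k) = no-hits(k−1)`, and that
the five terminal sets partition the universe.

Percentages in reports are `round_half_up(100 n / total, 2)`; mean lengths
round half-up to integers; GC to one decimal. Half-up rounding matches how
such tables are conventionally printed (Python's builtin `round` would
round ties to even).

## Summary statistics

GC is pooled over all records (one GC per dataset), with ambiguity codes
excluded from numerator and denominator — this makes GC invariant to how
bases are split across records. N50 is the length at which the descending
cumulative sum first reaches half the total (computed as
`2·cumsum ≥ total` to avoid fractional halves). Length histograms use
half-open bins `[lo, hi)` — a length equal to an inner edge belongs to the
bin it opens — with out-of-range lengths counted in an overflow bin under
a warning, so counts always conserve.

## UTR toolkit

- **Main ORF**: longest ATG-initiated ORF with an in-frame stop, stop
  codon included in the coordinates; ties go to the 5′-most start. The
  per-frame scan pairs each stop with the earliest open ATG, which is
  equivalent to exhaustive enumeration (tested against a brute-force
  oracle).
- **uORFs**: every ATG strictly 5′ of the main start with an in-frame
  stop within the transcript and total length ≥ 9 nt (start + ≥ 1 codon +
  stop) counts. uORFs overlapping the main ORF are counted by default and
  flagged; both the minimum length and the overlap policy are
  configurable because published scanners differ on both.
- **Poly(A) signals**: all (possibly overlapping) AATAAA starts in the 3′
  UTR, ascending; alternative hexamers can be supplied as a motif list.
- **Extensions**: from a local affine alignment (match +2, mismatch −3,
  gap open 5, gap extend 2), `ext5 = max(0, t_start − r_start)` and
  `ext3 = max(0, (|t| − t_end) − (|r| − r_end))` over the aligned block —
  i.e. transcript bases outside the alignment not explained by unaligned
  reference bases. A precomputed coordinate map may be supplied instead of
  the aligner. A reference with no positive-scoring alignment is an
  error.

## Variant tools

- **Sub-genome assignment** uses global (not local) alignment identity
  `identities / alignment columns`, because homeolog discrimination rests
  on full-length divergence; local alignment would ignore exactly the
  diverged regions that carry the signal. The call margin defaults to 0.5
  percentage points: at the default study conditions (progenitor
  divergences 0.01 vs 0.10, 1 % read error) the identity gap is ~9 points,
  so the margin only guards genuinely borderline pairs. Swapping the two
  references inverts A/B calls and preserves ambiguity (tested).
- **Intron retention** is fraction-based (default 0.95 of intron bases
  covered), not contiguity-based, since single-molecule reads cover a
  retained intron in one piece anyway; the threshold is configurable.
  Coverage blocks must be sorted and non-overlapping.

## Synthetic-data generator

Defaults are the study conditions the pipeline targets: lengths
log-uniform in 301–23,335 bp, GC 41.4 %, sequencing-error rate 0.01
(99 %-accuracy consensus reads), progenitor divergences d_A = 0.01 and
d_B = 0.10 substitutions/site, planted uORF counts 0–12, a 136-bp 5′
extension case, two AATAAA signals in the two-signal case, and planted
contaminant counts per category. Hit tables are constructed so aggregates
land on the intended side of every threshold: bit scores are monotone in
`length × identity` with small additive noise (planted winners differ by
far more than the noise), contaminant hits carry `A ≥ 320` with
`B = A − U(20, 80)`, and tier hits use HSP blocks whose interval union and
identity place them in the planted tier.

Case-study leaders and UTR filler are drawn from a C/T alphabet. This is a
deliberate idealisation: with no A or G in the filler, planted ATG and
AATAAA occurrences are the *only* occurrences, so uORF and signal counts
are exact by construction and recovery tests are sharp. Divergence is
substitution-only by default so identity arithmetic stays exact for
oracles. Consequently, passing recovery tests demonstrates correctness of
the decision rules and scanners, not robustness to homopolymer indel
error profiles, chimeric reads, or biased codon composition — real
long-read data contain all three. Abundance structure is not simulated.

Determinism: all randomness flows from one integer seed through a single
`numpy` generator; regenerating with an identical configuration is
byte-identical on disk (tested). Infeasible configurations (e.g. a
requested 5′ extension too short to hold the requested uORFs, role counts
exceeding the transcript count) fail before generation.

## Problem sizes

Tests and the acceptance script run at desk scale by design: generator
datasets of 16–60 transcripts, 200 simulated transcripts for sub-genome
recovery at ancestral length 600, 100 seeded datasets for conservation
properties, and 500–1,000 random instances per oracle-equivalence check.
Bookkeeping identities (stage percentages, the cascade count chain, the
contaminant total) are recomputed from the reference dataset's printed
per-stage counts used as inputs, since the underlying 95,995-isoform
dataset and dated database snapshots are not reproducible offline.

## Known limitations

- Identity-length reconstruction from `pident` can differ from the true
  `nident` by ±0.5 per HSP; supply an `nident` column where available.
- The aligner is O(n·m) in memory; extension measurement is intended for
  case-study transcripts (kilobases), not chromosome-scale references.
- The cascade consumes precomputed hit tables; it does not run searches.
- Gene models must have ≥ 1 intronic base between exons; zero-gap
  "introns" are rejected rather than silently merged.
- The uORF scanner counts ORFs; it does not assess Kozak context or
  peptide conservation.
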
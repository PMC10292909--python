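# Methods note

This note records the scientific model, parameter choices, and numerical
conventions behind `masv`. It states what the package computes and why; all
empirical numbers quoted here are ones computed by the test suite or
`scripts/acceptance.py`.

## 1. Coordinate and record conventions

All SVs are represented as `SVRecord(contig, start, svtype, length, ...)`
with **1-based, inclusive** coordinates:

- For span types (DEL, DUP, INV), `start` is the first affected base and
  `end = start + length − 1` is the last.
- For insertions, `start` is the base immediately left of the insertion
  point and `end == start`; `length` is the number of inserted bases.
- Tandem duplications duplicate `[start, end]` immediately to its right;
  inversions reverse-complement `[start, end]` in place.

VCF I/O (via pysam) uses symbolic ALT alleles (`<DEL>`, `<DUP>`, `<INV>`,
and `<INS>` when no inserted sequence is available). `SVLEN` is written only
for insertions: htslib recomputes `END` from `SVLEN` on symbolic span
alleles, so span records carry `END` alone and the reader derives
`length = END − POS + 1`. Two custom INFO keys, `SOURCE` and `LINE_ID`,
preserve provenance through round trips; `IMPRECISE` flags caller
uncertainty. Unsupported record types (e.g. breakends) are skipped with a
warning rather than silently dropped.

## 2. SV simulator (`masv.svsim`)

The simulator plants a configured number of SVs of each type into a
reference contig and returns both the mutated sequence and truth records in
**original-reference coordinates**, so that caller output mapped against the
original reference can be benchmarked directly.

Parameters and defaults:

- **Length mixture**: three buckets, (50–1000 bp, weight 0.70),
  (1001–5000 bp, 0.20), (5001–10000 bp, 0.10), uniform within a bucket.
  This reflects the strongly short-skewed empirical SV length distribution
  in bacterial MA data while still exercising multi-kilobase events.
- **Placement**: breakpoints uniform over the contig; events must be
  separated by `min_gap = 2 × flank_bp` (default 200 bp) so breakpoint-flank
  noise windows never interact. The length of each SV is drawn **once** and
  only the position is retried on collision (up to 1000 attempts); redrawing
  the length on rejection would bias the mixture toward short events.
  Infeasible configurations raise `PlacementError` instead of looping.
- **Flank noise**: within ± `flank_bp` = 100 bp of each breakpoint (in
  mutated coordinates, clipped against all SV footprints), each position is
  substituted with probability `p_flank_bps = 0.001` and at most one indel
  of ≤ 20 bp occurs per flank with probability `p_flank_indel = 0.0005`.
  This models the local assembly/alignment degradation that real callers
  face near breakpoints, without moving the true breakpoints themselves.
- **Determinism**: one `--seed` spawns three child seeds (planning,
  insertion content, noise) via `numpy.random.SeedSequence`; all derived
  seeds are reduced mod 2³¹.

Integrity is verified structurally: independently re-applying the emitted
truth records to the original reference must reproduce the mutated genome
byte-for-byte (100 randomized configurations in the acceptance tests), and
a zero-variant configuration must leave the genome byte-identical.

## 3. Benchmarking (`masv.benchmark`)

A call matches a truth record when all of the following hold (inclusive
bounds): same contig, same SV type, `|Δstart| ≤ 30 bp`, and
`|len_call − len_truth| ≤ 0.30 × len_truth`. These are standard truth-set
tolerances for SV benchmarking. Matching is one-to-one and greedy, sorted by
(|Δstart|, relative length difference, call start); the acceptance tests
verify against an exhaustive maximum-cardinality matcher that greedy never
exceeds the optimum and equals it whenever the eligibility graph is
conflict-free. Metrics are sensitivity = TP/(TP+FN),
precision = TP/(TP+FP), and F1, with zero-denominator cases reported as 0.

Sanger-style validation of individual calls (`masv.ma_filter.validate_call`)
uses the stricter criteria `|Δstart| < 100 bp` and length deviation
`< 30 %` of the validated length, both strict inequalities.

## 4. MA filtering cascade (`masv.ma_filter`)

Real MA callsets contain three artifact classes, each with its own filter:

1. **Ancestor-inherited variants** — calls matching the ancestor callset
   (same platform required) are subtracted using the benchmark tolerances.
2. **Imprecise calls** — optionally dropped.
3. **Recurrent artifacts** — calls clustering (single-linkage union-find at
   the benchmark tolerances) across ≥ 3 distinct lines are removed from all
   lines. Under a Poisson mutation model the probability of ≥ 3 independent
   identical events is negligible, so recurrence almost surely indicates a
   reference or caller artifact.

Platform merging keeps the long-read representative of matched short/long
pairs (long-read breakpoints are more accurate) with `"long|short"`
provenance, and keeps platform-private calls.

## 5. Rate estimation (`masv.rates`)

μ̂ = m / (Σ Nᵢ · T) with N ≡ 1 for per-genome rates. T = transfers ×
log₂(CFU) divisions per transfer (e.g. 160 × 28 = 4480). Confidence
intervals are exact Garwood Poisson intervals from chi-square quantiles —
conservative by construction (simulated coverage ≥ 95 % in the tests). A
documented quirk: the m = 0 upper count bound is −ln(α/2) ≈ 3.689, which the
synthetic-experiment tests use as a closed-form check.

Headline values are rounded to 3 significant figures with banker's rounding
on exact decimal representations (`round_sig`), avoiding binary-float
artifacts at the reporting boundary.

Spectrum summaries report per-type counts, per-line means, the INS/DEL
count ratio and DEL/INS total-length ratio (undefined denominators reported
as `None`, never infinity), and a length histogram. Positional uniformity is
tested by chi-square on fixed-width bins, pooling adjacent bins by halving
whenever the expected count per bin falls below 1.

## 6. IS-element classification (`masv.is_elements`)

An insertion is IS-mediated when its inserted sequence matches an IS family
consensus at ≥ 0.90 ungapped identity over ≥ 0.80 of the consensus length,
on either strand (best over all sliding offsets, computed on numpy byte
arrays). Span SVs are IS-mediated when they overlap ≥ 0.80 of an annotated
IS copy. Insertions lacking sequence fall back to a proximity rule
(breakpoint within 10 bp of an annotated copy), flagged low-confidence.
Ungapped identity is a deliberate simplification: IS transposition copies
the element nearly verbatim, so indel-tolerant alignment adds cost without
changing classifications at the 0.90 threshold.

Family activity summaries include zero-event families. Copy-number versus
activity correlation reports Pearson and Spearman coefficients; for ≤ 8
families the Spearman p-value is computed by exact permutation enumeration,
since asymptotic p-values are unreliable at such small n. Degenerate
(zero-variance) inputs return r = 0, p = 1 with a flag.

## 7. Synthetic MA generator (`masv.synthetic_ma`)

Per line, the true SV count is Poisson(rate × T); events are placed
uniformly with type probabilities INS 0.70 / DEL 0.25 / DUP 0.02 / INV 0.03,
mirroring the strong insertion bias of IS-driven bacterial SV spectra.

The caller-error model (defaults chosen a priori, before any test was run):

| parameter | default | rationale |
|---|---|---|
| `fn_rate` | 0.03 | long-read SV callers miss a few % of ≥ 50 bp events |
| `fp_per_line` | 0.1 | Poisson-mean private false calls per line |
| `jitter_sd_bp` | 5.0 | breakpoint sd, truncated at ± 3σ, rounded |
| `len_noise_frac` | 0.05 | relative length error |
| `p_imprecise` | 0.02 | fraction flagged IMPRECISE |

Ancestor variants are injected identically into every line; shared false
positives are injected into a configurable subset of lines. The recovery
harness (`run_recovery`) runs the full cascade, matches survivors against
per-line truth, and estimates the rate from the true-positive count.
Acceptance criterion: over 200 synthetic experiments (50 lines, T = 4000,
true rate 3 × 10⁻⁴, default noise) the 95 % CI covers the true rate in
≥ 90 % of replicates and the mean estimate is within 10 % of truth. With the
defaults the expected recovery fraction is ≈ 0.97 (1 − fn_rate, minus the
small jitter-induced mismatch probability), so the design meets the bias
bound analytically, not by tuning.

## 8. Limitations

- Single-contig, linear genomes; circularity is metadata only, and SVs never
  wrap the origin.
- No translocations or breakends; complex/nested SVs are out of scope.
- The recurrence filter removes genuinely recurrent mutations (e.g. true IS
  hotspots hit in ≥ 3 lines) along with artifacts; this biases rates
  downward in hotspot-rich genomes and is inherent to the method.
- Private caller false positives are indistinguishable from real private
  mutations by construction; the estimator's residual bias is therefore
  fn-vs-fp balance, quantified only through the synthetic experiments.
- The caller-error model is parametric and stationary (no
  coverage-dependent or GC-dependent error structure).
- IS identity is ungapped; heavily degraded or rearranged IS copies below
  0.90 identity are classified non-IS.
- Exact Poisson CIs are conservative; small-m intervals are wide.
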
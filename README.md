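# masv — structural-variant rate analysis for mutation-accumulation experiments

`masv` is a small scientific Python package for studying **de novo structural
variations (SVs)** — insertions, deletions, duplications, and inversions of
≥ 50 bp — in bacterial **mutation-accumulation (MA)** experiments of the kind
run with *Escherichia coli*. In an MA experiment, many replicate lines are
propagated through repeated single-colony bottlenecks so that selection is
minimized and mutations accumulate nearly neutrally; sequencing the evolved
lines against the ancestor then yields direct estimates of spontaneous
mutation rates and spectra.

Detecting SVs is much harder than detecting point mutations: short-read
callers have high false-positive rates, breakpoints are reported with
coordinate jitter, and repetitive elements (especially **insertion sequences**,
IS elements, the dominant source of spontaneous SVs in *E. coli*) confuse
alignment. `masv` packages the full analysis chain needed to do this
rigorously:

1. **I/O** for references (FASTA), SV callsets (VCF with symbolic alleles, or
   TSV tables), and IS-element annotations (`masv.core_io`).
2. **SV simulation** into a reference genome with exact truth coordinates and
   optional breakpoint-flank noise, for caller benchmarking (`masv.svsim`).
3. **Truth-set benchmarking** with tolerance-based matching (same type,
   ± 30 bp breakpoint, ≤ 30 % length deviation) and sensitivity / precision /
   F1 metrics (`masv.benchmark`).
4. **MA filtering cascade**: ancestor subtraction, imprecise-call removal,
   cross-line recurrence filtering (recurrent calls are almost always shared
   artifacts, not independent mutations), and short/long-read platform
   merging (`masv.ma_filter`).
5. **Rate estimation**: μ = m / (Σ Nᵢ · T) with exact (Garwood) Poisson
   confidence intervals, spectrum summaries (INS/DEL biases, length
   histograms), and positional uniformity tests (`masv.rates`).
6. **IS-element classification** of SVs by consensus-sequence identity and
   copy-overlap, per-family activity summaries, and copy-number/activity
   correlation (`masv.is_elements`).
7. **Synthetic MA experiments** with a parametric caller-error model, to
   validate that the whole cascade recovers a known true rate
   (`masv.synthetic_ma`).
8. A `masv` **command-line interface** wiring these together (`masv.cli`).

## The statistical model

Each MA line i runs T cell divisions (T = transfers × log₂ CFU divisions per
transfer). SV events arise as a Poisson process, so the rate estimator for m
events pooled over n lines is

```
μ̂ = m / (n · T)        [per genome per cell division]
```

with the exact Poisson (Garwood) 95 % CI obtained from chi-square quantiles:

```
low  = ½ · χ²(α/2, 2m) / (n·T)          (0 when m = 0)
high = ½ · χ²(1 − α/2, 2m + 2) / (n·T)
```

Per-site rates use Σ Nᵢ · T in the denominator. All headline quantities are
reported at 3 significant figures (`masv.round_sig`).

## Running the tests

```bash
python -m pytest -q tests/
```

## Worked example

Estimate a per-genome SV rate with its exact CI, and simulate SVs into a
random genome:

```python
from masv import rate_per_genome, simulate, SimConfig
from masv.core_io import ReferenceGenome
import numpy as np

# 66 IS insertions across 67 lines at 4480 divisions each
est = rate_per_genome(66, 67, 4480)
print(f"rate = {est.rate_3sf:.3g} per genome per division")
print(f"95% CI = {est.ci_3sf[0]:.3g} - {est.ci_3sf[1]:.3g}")

rng = np.random.default_rng(42)
seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=100_000)])
genome = ReferenceGenome(contig_id="chr", sequence=seq)
cfg = SimConfig(n_per_type={"INS": 3, "DEL": 3},
                length_buckets=[(50, 500, 0.8), (501, 2000, 0.2)], seed=7)
result = simulate(genome, cfg)
for sv in result.truth:
    print(sv.svtype, sv.start, sv.length)
```

Output:

```
rate = 0.00022 per genome per division
95% CI = 0.00017 - 0.00028
DEL 3062 380
INS 4211 168
DEL 6619 75
INS 47425 138
INS 59824 136
DEL 77375 109
```

Or run the end-to-end demo from the command line — it simulates a synthetic
MA experiment (30 lines, T = 4000, true rate 3 × 10⁻⁴), pushes the noisy
calls through the full filtering cascade, and re-estimates the rate:

```bash
$ masv demo --seed 1 --out demo_out
lines: 30  T: 4000  true rate: 3.00e-04
true SV count: 33
surviving true positives: 29  residual FP: 4  missed: 4
estimated rate: 2.417e-04 per genome per division
95% CI: 1.618e-04 - 3.471e-04
CI covers true rate: True
```

The residual false positives are the caller's *private* (per-line) errors:
the cascade removes shared artifacts (ancestor-inherited and recurrent
calls) but cannot, by design, distinguish a private false call from a real
private mutation.

## CLI overview

```
masv simulate-genome   # plant SVs into a FASTA reference, emit truth VCF/TSV
masv simulate-ma       # generate a synthetic multi-line MA experiment
masv evaluate          # benchmark a callset against a truth set
masv filter-lines      # ancestor subtraction + recurrence filtering cascade
masv estimate-rates    # per-genome rates with exact Poisson CIs, per SV type
masv classify-is       # classify SVs as IS-mediated against an IS annotation
masv report            # merge per-stage TSV reports
masv demo              # deterministic end-to-end demonstration
```

Each subcommand has `--help`; every stochastic step takes an explicit
`--seed` and writes a JSON log of its configuration.

## Reproduction

`scripts/acceptance.py` recomputes the package's headline quantities —
published-style rate estimates and CIs from fixed event counts, spectrum
ratios, validation precisions, simulator reconstruction integrity, length
mixture occupancy, and end-to-end rate-recovery coverage over 100 synthetic
experiments — and writes them to JSON:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

All randomness derives from `--seed`; the deterministic quantities are
identical for every seed, and the stochastic ones (reconstruction fraction,
CI coverage, mean relative error) are reported with their sample sizes.

See `docs/methods.md` for the full methods note: model assumptions,
parameter choices, generator realism, numerical conventions, and known
limitations.
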
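"""Mutation-rate estimation and spectrum summaries for MA experiments.

The rate estimator is the standard MA formula

    mu = m / (sum_i N_i * T)

with m the mutation count over all lines, N_i the analyzed sites of line i
(N = 1 for per-genome rates), and T the cell divisions per line.  T is the
product of the number of single-colony transfers and log2(CFU) divisions per
transfer.  Confidence intervals on m are exact (Garwood) Poisson intervals
from chi-square quantiles, which is the method whose 3-significant-figure
output matches the intervals this kind of study reports.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_EVEN

import numpy as np
from scipy import stats

from .core_io import SVRecord, SV_TYPES


def round_sig(x: float, digits: int = 3) -> float:
    """Round to ``digits`` significant figures, half-even."""
    x = float(x)
    if x == 0 or not math.isfinite(x):
        return x
    d = Decimal(repr(x))
    shift = digits - 1 - math.floor(math.log10(abs(x)))
    q = Decimal(1).scaleb(-shift)
    return float(d.quantize(q, rounding=ROUND_HALF_EVEN))


@dataclass
class MAExperimentMeta:
    """Divisions bookkeeping for one MA line set.

    Defaults mirror a 160-transfer experiment; WT lines run ~28 divisions
    per transfer (T = 4480) and MMR-deficient lines ~27 (T = 4320).
    """

    n_lines: int
    transfers_mean: float = 160.0
    divisions_per_transfer: float = 28.0
    sites_per_line: list[float] | None = None

    def __post_init__(self) -> None:
        if self.n_lines <= 0 or self.transfers_mean <= 0 \
                or self.divisions_per_transfer <= 0:
            raise ValueError("all experiment quantities must be positive")

    @property
    def T(self) -> float:
        return self.transfers_mean * self.divisions_per_transfer


@dataclass
class RateEstimate:
    m: int
    denominator: float
    rate: float
    ci_low: float
    ci_high: float
    alpha: float = 0.05

    @property
    def rate_3sf(self) -> float:
        return round_sig(self.rate, 3)

    @property
    def ci_3sf(self) -> tuple[float, float]:
        return (round_sig(self.ci_low, 3), round_sig(self.ci_high, 3))


def divisions_per_transfer(cfu: float) -> float:
    """Cell divisions per single-colony growth cycle: log2(CFU)."""
    if cfu <= 1:
        raise ValueError("CFU must exceed 1 to yield positive divisions")
    return math.log2(cfu)


def total_divisions(transfers: float, per_transfer: float) -> float:
    """Total divisions per line over the whole experiment."""
    if transfers <= 0 or per_transfer <= 0:
        raise ValueError("transfers and per-transfer divisions must be positive")
    return transfers * per_transfer


def poisson_ci_exact(m: int, denominator: float,
                     alpha: float = 0.05) -> tuple[float, float]:
    """Exact (Garwood) Poisson CI for a rate m / denominator.

    Count bounds are chi-square quantiles: low = Q(alpha/2, 2m)/2 (0 when
    m = 0), high = Q(1 - alpha/2, 2m + 2)/2; both divided by the denominator.
    """
    if m < 0:
        raise ValueError("count must be non-negative")
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    low_count = 0.0 if m == 0 else 0.5 * stats.chi2.ppf(alpha / 2, 2 * m)
    high_count = 0.5 * stats.chi2.ppf(1 - alpha / 2, 2 * m + 2)
    return low_count / denominator, high_count / denominator


def rate_per_genome(m: int, n_lines: int, T: float,
                    alpha: float = 0.05) -> RateEstimate:
    """Events per genome per cell division with exact Poisson CI."""
    denom = n_lines * T
    low, high = poisson_ci_exact(m, denom, alpha)
    return RateEstimate(m=m, denominator=denom, rate=m / denom,
                        ci_low=low, ci_high=high, alpha=alpha)


def rate_per_site(m: int, sites_per_line: list[float], T: float,
                  alpha: float = 0.05) -> RateEstimate:
    """Events per site per cell division (mu = m / (sum N_i * T))."""
    if not sites_per_line:
        raise ValueError("sites_per_line must be non-empty")
    if any(n <= 0 for n in sites_per_line):
        raise ValueError("all per-line site counts must be positive")
    denom = sum(sites_per_line) * T
    low, high = poisson_ci_exact(m, denom, alpha)
    return RateEstimate(m=m, denominator=denom, rate=m / denom,
                        ci_low=low, ci_high=high, alpha=alpha)


@dataclass
class SpectrumSummary:
    counts: dict[str, int]
    mean_per_line: dict[str, float]
    ins_del_count_ratio: float | None
    total_ins_bp: int
    total_del_bp: int
    del_ins_length_ratio: float | None
    length_histogram: dict[tuple[int, int], int] = field(default_factory=dict)


DEFAULT_LENGTH_BINS = [(50, 500), (501, 1000), (1001, 1500), (1501, 5000),
                       (5001, 10**9)]


def spectrum_summary(calls: list[SVRecord], n_lines: int,
                     length_bins: list[tuple[int, int]] | None = None,
                     ) -> SpectrumSummary:
    """Counts, per-line means, INS/DEL biases, and a length histogram.

    Ratios with a zero denominator are reported as None (undefined), never
    infinity.
    """
    if n_lines <= 0:
        raise ValueError("n_lines must be positive")
    bins = length_bins or DEFAULT_LENGTH_BINS
    counts = {t: 0 for t in SV_TYPES}
    total_ins = total_del = 0
    hist = {b: 0 for b in bins}
    for c in calls:
        counts[c.svtype] += 1
        if c.svtype == "INS":
            total_ins += c.length
        elif c.svtype == "DEL":
            total_del += c.length
        for lo, hi in bins:
            if lo <= c.length <= hi:
                hist[(lo, hi)] += 1
                break
    ins_del = counts["INS"] / counts["DEL"] if counts["DEL"] else None
    del_ins_len = total_del / total_ins if total_ins else None
    return SpectrumSummary(
        counts=counts,
        mean_per_line={t: counts[t] / n_lines for t in SV_TYPES},
        ins_del_count_ratio=ins_del,
        total_ins_bp=total_ins,
        total_del_bp=total_del,
        del_ins_length_ratio=del_ins_len,
        length_histogram=hist,
    )


@dataclass
class PositionalDistribution:
    bin_edges: np.ndarray
    bin_counts: np.ndarray
    chi2: float | None
    pvalue: float | None
    n_pooled_bins: int


def positional_distribution(calls: list[SVRecord], genome_length: int,
                            bin_size: int) -> PositionalDistribution:
    """Bin SV start positions and test uniformity with chi-square.

    Fixed-width bins from position 1; the uniform expectation per bin is
    n / k.  If the expectation falls below 1, adjacent bins are pooled until
    it does not.  With no calls the statistic is undefined (None).
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    n_bins = max(1, math.ceil(genome_length / bin_size))
    edges = np.arange(0, (n_bins + 1) * bin_size, bin_size, dtype=float)
    edges[-1] = max(edges[-1], genome_length)
    positions = np.array([c.start for c in calls], dtype=float)
    counts, _ = np.histogram(positions, bins=edges)
    if len(calls) == 0:
        return PositionalDistribution(edges, counts, None, None, n_bins)

    k = n_bins
    pooled = counts.astype(float)
    while k > 1 and len(calls) / k < 1.0:
        # halve the number of bins by pairwise pooling
        if len(pooled) % 2:
            pooled = np.concatenate([pooled[:-2], [pooled[-2] + pooled[-1]]])
        pooled = pooled[::2] + pooled[1::2]
        k = len(pooled)
    expected = np.full(k, len(calls) / k)
    chi2, p = stats.chisquare(pooled, expected)
    return PositionalDistribution(edges, counts, float(chi2), float(p), k)
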
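"""Generate complete mock mutation-accumulation experiments.

Each synthetic experiment has the statistical structure the downstream
analysis assumes: per-line true SV counts are Poisson(true_rate * T) with
uniform positions and a multinomial type mixture; the "caller" then misses a
fraction of them (false negatives), jitters breakpoints and lengths, flags
some imprecise, adds per-line false positives, and re-reports ancestor
variants and shared artifacts in every (or several) lines — the exact
nuisances the filtering cascade exists to remove.  This makes the cascade
and the rate estimator testable end-to-end with no sequencing data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .benchmark import MatchCriteria, BENCHMARK_CRITERIA, match_callsets
from .core_io import SVRecord
from .ma_filter import (LineCallset, drop_imprecise, recurrence_filter,
                        subtract_ancestor)
from .rates import RateEstimate, rate_per_genome
from .svsim import DEFAULT_LENGTH_BUCKETS, _draw_length

#: de novo SV type mixture; reflects the strong insertion bias of wild-type
#: E. coli MA lines (IS transposition dominating), smoothed so all four
#: types occur
DEFAULT_TYPE_PROBS = {"INS": 0.70, "DEL": 0.25, "DUP": 0.02, "INV": 0.03}


@dataclass
class CallerModel:
    """Caller error model applied to each line's true SVs.

    Defaults mirror long-read caller behaviour on bacterial data: ~97%
    sensitivity for well-supported events, about one false positive per ten
    lines, single-digit-bp breakpoint jitter, small relative length error,
    and a small imprecise fraction.
    """

    fn_rate: float = 0.03
    fp_per_line: float = 0.1
    jitter_sd_bp: float = 5.0
    len_noise_frac: float = 0.05
    p_imprecise: float = 0.02


@dataclass
class SharedFPConfig:
    """Systematic artifacts injected identically into several lines."""

    count: int = 0
    n_lines_affected: int = 0


@dataclass
class MASimConfig:
    n_lines: int = 50
    T: float = 4000.0
    true_rate: float = 3e-4   # SVs per genome per cell division
    type_probs: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TYPE_PROBS))
    ancestor_sv_count: int = 0
    caller: CallerModel = field(default_factory=CallerModel)
    shared_fp: SharedFPConfig = field(default_factory=SharedFPConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.true_rate < 0:
            raise ValueError("true_rate must be >= 0")
        if abs(sum(self.type_probs.values()) - 1.0) > 1e-9:
            raise ValueError("type_probs must sum to 1")


@dataclass
class SyntheticExperiment:
    truth: dict[str, list[SVRecord]]      # line_id -> true de novo SVs
    ancestor_calls: LineCallset
    observed: list[LineCallset]
    config: MASimConfig
    genome_length: int
    contig: str = "chr"


def _random_sv(rng: np.random.Generator, contig: str, genome_length: int,
               type_probs: dict[str, float], source: str,
               line_id: str = "") -> SVRecord:
    types = sorted(type_probs)
    probs = np.array([type_probs[t] for t in types])
    svtype = types[int(rng.choice(len(types), p=probs / probs.sum()))]
    length = _draw_length(rng, DEFAULT_LENGTH_BUCKETS)
    span = 1 if svtype == "INS" else length
    start = int(rng.integers(2, genome_length - span + 1))
    return SVRecord(contig=contig, start=start, svtype=svtype, length=length,
                    source=source, line_id=line_id)


def _truncated_jitter(rng: np.random.Generator, sd: float) -> int:
    """Rounded Normal(0, sd) truncated at +-3 sd."""
    if sd == 0:
        return 0
    j = rng.normal(0.0, sd)
    j = max(-3 * sd, min(3 * sd, j))
    return int(round(j))


def generate_experiment(config: MASimConfig,
                        genome_length: int = 4_641_652,
                        contig: str = "chr") -> SyntheticExperiment:
    """Draw truth, ancestor variants, and noisy observed call sets."""
    rng = np.random.default_rng(config.seed)
    cm = config.caller

    ancestor_svs = [
        _random_sv(rng, contig, genome_length, config.type_probs, "ancestor")
        for _ in range(config.ancestor_sv_count)]
    shared_fps = [
        _random_sv(rng, contig, genome_length, config.type_probs, "shared_fp")
        for _ in range(config.shared_fp.count)]
    if config.shared_fp.count and \
            config.shared_fp.n_lines_affected > config.n_lines:
        raise ValueError("shared FP lines exceed n_lines")

    truth: dict[str, list[SVRecord]] = {}
    observed: list[LineCallset] = []
    for i in range(config.n_lines):
        line_id = f"line{i + 1:03d}"
        k = int(rng.poisson(config.true_rate * config.T))
        line_truth = [
            _random_sv(rng, contig, genome_length, config.type_probs,
                       "truth", line_id)
            for _ in range(k)]
        truth[line_id] = line_truth

        calls: list[SVRecord] = []
        for sv in line_truth:
            if rng.random() < cm.fn_rate:
                continue
            start = max(2, sv.start + _truncated_jitter(rng, cm.jitter_sd_bp))
            noise = 1.0 + rng.uniform(-cm.len_noise_frac, cm.len_noise_frac)
            length = max(1, int(round(sv.length * noise)))
            calls.append(SVRecord(
                contig=contig, start=start, svtype=sv.svtype, length=length,
                imprecise=bool(rng.random() < cm.p_imprecise),
                source="caller", line_id=line_id))
        n_fp = int(rng.poisson(cm.fp_per_line))
        calls.extend(
            _random_sv(rng, contig, genome_length, config.type_probs,
                       "caller_fp", line_id)
            for _ in range(n_fp))
        calls.extend(a.copy(line_id=line_id) for a in ancestor_svs)
        if i < config.shared_fp.n_lines_affected:
            calls.extend(s.copy(line_id=line_id) for s in shared_fps)
        calls.sort(key=lambda r: r.start)
        observed.append(LineCallset(line_id=line_id, strain="WT",
                                    platform="long_read", calls=calls))

    ancestor = LineCallset(line_id="ancestor", strain="WT",
                           platform="long_read",
                           calls=sorted(ancestor_svs, key=lambda r: r.start))
    return SyntheticExperiment(truth=truth, ancestor_calls=ancestor,
                               observed=observed, config=config,
                               genome_length=genome_length, contig=contig)


@dataclass
class RecoveryReport:
    estimate: RateEstimate
    true_rate: float
    true_count: int
    tp: int
    fp: int
    fn: int
    covered: bool  # does the CI contain the true rate?


def run_recovery(experiment: SyntheticExperiment,
                 criteria: MatchCriteria = BENCHMARK_CRITERIA,
                 recurrence_threshold: int = 3,
                 drop_imprecise_calls: bool = True) -> RecoveryReport:
    """Full cascade + benchmarking + rate estimation on one experiment.

    Ancestor subtraction, optional imprecise removal, and the cross-line
    recurrence filter are applied; surviving calls are matched per line
    against that line's truth and the rate is estimated from the matched
    (true positive) count.
    """
    cfg = experiment.config
    lines = [subtract_ancestor(ln, experiment.ancestor_calls, criteria)
             for ln in experiment.observed]
    if drop_imprecise_calls:
        lines = [drop_imprecise(ln) for ln in lines]
    lines, _clusters = recurrence_filter(lines, recurrence_threshold, criteria)

    tp = fp = fn = 0
    for ln in lines:
        result = match_callsets(experiment.truth[ln.line_id], ln.calls,
                                criteria)
        tp += len(result.pairs)
        fp += len(result.unmatched_calls)
        fn += len(result.unmatched_truth)

    estimate = rate_per_genome(tp, cfg.n_lines, cfg.T)
    true_count = sum(len(v) for v in experiment.truth.values())
    covered = estimate.ci_low <= cfg.true_rate <= estimate.ci_high
    return RecoveryReport(estimate=estimate, true_rate=cfg.true_rate,
                          true_count=true_count, tp=tp, fp=fp, fn=fn,
                          covered=covered)
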
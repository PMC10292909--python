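"""Match SV call sets against a truth set and score them.

A call validates a truth record when (1) the SV types are identical,
(2) the start positions differ by at most ``start_tol_bp`` (±30 bp by
default), and (3) the lengths differ by at most ``len_tol_frac`` of the
TRUTH length (30% by default).  Assignment is one-to-one: every call can
validate at most one truth record, and every unmatched call counts as one
false positive.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

from .core_io import SVRecord


@dataclass(frozen=True)
class MatchCriteria:
    """Tolerance triple for truth/call comparison (inclusive bounds)."""

    require_same_type: bool = True
    start_tol_bp: int = 30
    len_tol_frac: float = 0.30

    def __post_init__(self) -> None:
        if self.start_tol_bp < 0:
            raise ValueError("start_tol_bp must be >= 0")
        if not 0.0 <= self.len_tol_frac < 1.0:
            raise ValueError("len_tol_frac must be in [0, 1)")


#: benchmarking tolerances: same type, ±30 bp, length within 30% of truth
BENCHMARK_CRITERIA = MatchCriteria()


@dataclass
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0


@dataclass
class Metrics:
    sensitivity: float
    precision: float
    f1: float


@dataclass
class MatchResult:
    """One-to-one assignment between truth and call indices."""

    pairs: list[tuple[int, int]] = field(default_factory=list)
    unmatched_truth: list[int] = field(default_factory=list)
    unmatched_calls: list[int] = field(default_factory=list)


def match_pair(truth_rec: SVRecord, call: SVRecord,
               criteria: MatchCriteria = BENCHMARK_CRITERIA,
               ) -> tuple[bool, str]:
    """Evaluate the three matching conditions for one truth/call pair.

    Returns ``(matched, reason)`` where reason is ``"ok"`` or names the
    first failed condition (``"contig"``, ``"type"``, ``"start"``,
    ``"length"``).
    """
    if truth_rec.contig != call.contig:
        return False, "contig"
    if criteria.require_same_type and truth_rec.svtype != call.svtype:
        return False, "type"
    if abs(call.start - truth_rec.start) > criteria.start_tol_bp:
        return False, "start"
    if abs(call.length - truth_rec.length) > criteria.len_tol_frac * truth_rec.length:
        return False, "length"
    return True, "ok"


def match_callsets(truth: list[SVRecord], calls: list[SVRecord],
                   criteria: MatchCriteria = BENCHMARK_CRITERIA,
                   ) -> MatchResult:
    """Greedy one-to-one assignment of calls to truth records.

    Eligible pairs are assigned in order of smallest |Δstart|, ties broken
    by smallest relative length difference, then by earlier call position,
    then by input index; deterministic.  Multi-contig inputs are handled per
    contig independently.
    """
    candidates = []
    truth_by_contig: dict[str, list[int]] = defaultdict(list)
    for ti, t in enumerate(truth):
        truth_by_contig[t.contig].append(ti)
    for ci, c in enumerate(calls):
        for ti in truth_by_contig.get(c.contig, ()):
            t = truth[ti]
            ok, _ = match_pair(t, c, criteria)
            if ok:
                dstart = abs(c.start - t.start)
                rel_len = abs(c.length - t.length) / t.length
                candidates.append((dstart, rel_len, c.start, ci, ti))
    candidates.sort()

    used_truth: set[int] = set()
    used_calls: set[int] = set()
    pairs: list[tuple[int, int]] = []
    for _dstart, _rel, _cs, ci, ti in candidates:
        if ti in used_truth or ci in used_calls:
            continue
        used_truth.add(ti)
        used_calls.add(ci)
        pairs.append((ti, ci))
    pairs.sort()
    return MatchResult(
        pairs=pairs,
        unmatched_truth=[i for i in range(len(truth)) if i not in used_truth],
        unmatched_calls=[i for i in range(len(calls)) if i not in used_calls],
    )


def confusion(assignment: MatchResult) -> ConfusionCounts:
    """TP = matched pairs, FN = unmatched truth, FP = unmatched calls."""
    return ConfusionCounts(tp=len(assignment.pairs),
                           fn=len(assignment.unmatched_truth),
                           fp=len(assignment.unmatched_calls))


def metrics(counts: ConfusionCounts) -> Metrics:
    """sensitivity = TP/(TP+FN); precision = TP/(TP+FP); F1 harmonic mean."""
    sens = counts.tp / (counts.tp + counts.fn) if counts.tp + counts.fn else 0.0
    prec = counts.tp / (counts.tp + counts.fp) if counts.tp + counts.fp else 0.0
    f1 = (2 * sens * prec / (sens + prec)) if (sens + prec) > 0 else 0.0
    return Metrics(sensitivity=sens, precision=prec, f1=f1)


def evaluate(truth: list[SVRecord], calls: list[SVRecord],
             criteria: MatchCriteria = BENCHMARK_CRITERIA,
             ) -> tuple[ConfusionCounts, Metrics]:
    """Convenience wrapper: match, count, score."""
    counts = confusion(match_callsets(truth, calls, criteria))
    return counts, metrics(counts)
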
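"""The candidate-filtering cascade for mutation-accumulation call sets.

Real MA call sets contain variants inherited from the ancestor, systematic
reference artifacts shared across lines, and caller-flagged imprecise calls.
The cascade removes them in order: ancestor subtraction → imprecise removal
→ cross-line recurrence removal (a variant seen in ≥3 lines of one platform
is a reference artifact, not a de novo mutation) → platform merge.  A final
validation step compares each surviving candidate against a Sanger-derived
record with strict thresholds (<100 bp start difference, <30% length
difference).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .benchmark import MatchCriteria, BENCHMARK_CRITERIA, match_callsets, match_pair
from .core_io import SVRecord

#: Sanger-validation tolerances; strict inequalities (see validate_call)
VALIDATION_CRITERIA = MatchCriteria(start_tol_bp=100, len_tol_frac=0.30)

PLATFORMS = ("short_read", "long_read")
STRAINS = ("WT", "mutS_deficient")


@dataclass
class LineCallset:
    """All SV calls of one MA line on one sequencing platform."""

    line_id: str
    strain: str
    platform: str
    calls: list[SVRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.line_id:
            raise ValueError("line_id must be non-empty")
        if self.platform not in PLATFORMS:
            raise ValueError(f"unknown platform {self.platform!r}")
        if self.strain not in STRAINS:
            raise ValueError(f"unknown strain {self.strain!r}")


@dataclass
class ValidationVerdict:
    call: SVRecord
    status: str  # "true_positive" | "false_positive"
    reason: str


@dataclass
class RecurrentCluster:
    """A cross-line cluster removed by the recurrence filter."""

    representative: SVRecord
    line_ids: list[str]
    n_calls: int


def subtract_ancestor(line: LineCallset, ancestor: LineCallset,
                      criteria: MatchCriteria = BENCHMARK_CRITERIA,
                      ) -> LineCallset:
    """Remove calls already present in the ancestor (same platform)."""
    if line.platform != ancestor.platform:
        raise ValueError("line and ancestor must be from the same platform")
    kept = [c for c in line.calls
            if not any(match_pair(a, c, criteria)[0] for a in ancestor.calls)]
    return replace(line, calls=kept)


def drop_imprecise(line: LineCallset) -> LineCallset:
    """Remove calls whose breakpoints the caller flagged as imprecise."""
    return replace(line, calls=[c for c in line.calls if not c.imprecise])


def recurrence_filter(lines: list[LineCallset], threshold: int = 3,
                      criteria: MatchCriteria = BENCHMARK_CRITERIA,
                      ) -> tuple[list[LineCallset], list[RecurrentCluster]]:
    """Remove call clusters recurring in ``threshold`` or more lines.

    Calls from all lines (one platform) are clustered by single-linkage
    under the matching criteria; every call in a cluster touching at least
    ``threshold`` distinct lines is removed from its line.
    """
    platforms = {ln.platform for ln in lines}
    if len(platforms) > 1:
        raise ValueError("recurrence_filter expects a single platform")

    flat: list[tuple[int, int, SVRecord]] = []  # (line idx, call idx, record)
    for li, ln in enumerate(lines):
        for ci, c in enumerate(ln.calls):
            flat.append((li, ci, c))

    n = len(flat)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    for i in range(n):
        for j in range(i + 1, n):
            a, b = flat[i][2], flat[j][2]
            if match_pair(a, b, criteria)[0] or match_pair(b, a, criteria)[0]:
                union(i, j)

    clusters: dict[int, list[int]] = {}
    for i in range(n):
        clusters.setdefault(find(i), []).append(i)

    removed_flat: set[int] = set()
    removed_clusters: list[RecurrentCluster] = []
    for members in clusters.values():
        line_ids = sorted({lines[flat[i][0]].line_id for i in members})
        if len(line_ids) >= threshold:
            removed_flat.update(members)
            rep = flat[min(members)][2]
            removed_clusters.append(RecurrentCluster(
                representative=rep, line_ids=line_ids, n_calls=len(members)))

    removed_by_line: dict[int, set[int]] = {}
    for i in removed_flat:
        removed_by_line.setdefault(flat[i][0], set()).add(flat[i][1])
    filtered = [
        replace(ln, calls=[c for ci, c in enumerate(ln.calls)
                           if ci not in removed_by_line.get(li, ())])
        for li, ln in enumerate(lines)
    ]
    removed_clusters.sort(key=lambda cl: cl.representative.start)
    return filtered, removed_clusters


def merge_platforms(short_calls: LineCallset, long_calls: LineCallset,
                    criteria: MatchCriteria = BENCHMARK_CRITERIA,
                    ) -> LineCallset:
    """Union of both platforms' calls with tolerant deduplication.

    When a short-read call matches a long-read call, the long-read record is
    kept as the representative (its breakpoints are the more reliable) and
    the merged record carries both provenances, joined by ``|``.
    """
    if short_calls.line_id != long_calls.line_id:
        raise ValueError(
            f"line_id mismatch: {short_calls.line_id!r} vs "
            f"{long_calls.line_id!r}")
    assignment = match_callsets(long_calls.calls, short_calls.calls, criteria)
    merged: list[SVRecord] = []
    matched_short = {ci for _, ci in assignment.pairs}
    short_for_long = {ti: ci for ti, ci in assignment.pairs}
    for li, rec in enumerate(long_calls.calls):
        if li in short_for_long:
            other = short_calls.calls[short_for_long[li]]
            prov = "|".join(p for p in (rec.source, other.source) if p)
            merged.append(rec.copy(source=prov or rec.source))
        else:
            merged.append(rec)
    merged.extend(c for ci, c in enumerate(short_calls.calls)
                  if ci not in matched_short)
    merged.sort(key=lambda r: (r.contig, r.start))
    return LineCallset(line_id=long_calls.line_id, strain=long_calls.strain,
                       platform="long_read", calls=merged)


def validate_call(call: SVRecord, sanger: SVRecord) -> ValidationVerdict:
    """Classify a candidate against its Sanger-derived record.

    True positive iff the types agree, |Δstart| < 100 bp, and
    |Δlength| < 30% of the Sanger length — all strict inequalities.
    """
    if call.svtype != sanger.svtype:
        return ValidationVerdict(call, "false_positive", "type")
    if abs(call.start - sanger.start) >= VALIDATION_CRITERIA.start_tol_bp:
        return ValidationVerdict(call, "false_positive", "start")
    if abs(call.length - sanger.length) >= (
            VALIDATION_CRITERIA.len_tol_frac * sanger.length):
        return ValidationVerdict(call, "false_positive", "length")
    return ValidationVerdict(call, "true_positive", "ok")
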
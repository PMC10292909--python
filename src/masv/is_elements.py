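"""Attribute SVs to insertion-sequence (IS) elements and summarize activity.

An insertion is IS-mediated when its inserted sequence matches a family
consensus at >= 90% identity over >= 80% of the consensus length (ungapped
sliding comparison, both strands).  A span SV (DEL/DUP/INV) is IS-mediated
when its interval covers >= 80% of an annotated reference copy.  Near-exact
IS copies dominate real transposition events, so ungapped comparison
suffices at these thresholds; ``identity_fn`` is a hook for plugging an
external aligner.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core_io import ISLibrary, SVRecord, revcomp


@dataclass
class ISClassification:
    sv: SVRecord
    mediated: bool
    family: str | None
    evidence: str | None  # "sequence_match" | "copy_overlap" | "proximity"
    identity: float | None
    low_confidence: bool = False


@dataclass
class ISFamilyActivity:
    family: str
    reference_copy_number: int
    mediated_sv_count: int
    proportion: float


@dataclass
class ISActivitySummary:
    per_family: list[ISFamilyActivity]
    total_mediated: int


@dataclass
class CorrelationReport:
    pearson_r: float
    pearson_p: float
    spearman_rho: float
    spearman_p: float
    n_families: int
    degenerate: bool = False


def _seq_to_array(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def best_ungapped_identity(query: str, consensus: str,
                           min_cov: float) -> tuple[float, int]:
    """Best sliding-window identity of consensus against query (one strand).

    All offsets with an overlap of at least ``min_cov * len(consensus)`` are
    scored; identity is matches / overlap.  Returns (identity, overlap).
    """
    q = _seq_to_array(query)
    c = _seq_to_array(consensus)
    min_overlap = max(1, math.ceil(min_cov * len(c)))
    if len(q) < min_overlap:
        return 0.0, 0
    best_ident, best_ov = 0.0, 0
    for offset in range(-(len(c) - min_overlap), len(q) - min_overlap + 1):
        q_lo = max(0, offset)
        c_lo = q_lo - offset
        ov = min(len(q) - q_lo, len(c) - c_lo)
        if ov < min_overlap:
            continue
        matches = int(np.count_nonzero(q[q_lo:q_lo + ov] == c[c_lo:c_lo + ov]))
        ident = matches / ov
        if ident > best_ident:
            best_ident, best_ov = ident, ov
            if best_ident == 1.0 and ov == len(c):
                break
    return best_ident, best_ov


def _interval_overlap(a: tuple[int, int], b: tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]) + 1)


def classify_sv(sv: SVRecord, lib: ISLibrary, min_identity: float = 0.90,
                min_cov: float = 0.80,
                proximity_bp: int = 10) -> ISClassification:
    """Decide whether one SV is IS-mediated and by which family.

    Ties between families go to the higher identity, then the
    lexicographically smaller family name.  An INS without its inserted
    sequence falls back to breakpoint proximity (within ``proximity_bp`` of
    an annotated copy edge) and is flagged low-confidence.
    """
    if sv.svtype == "INS":
        if sv.inserted_seq:
            best: tuple[float, str] | None = None
            for fam in sorted(lib.families, key=lambda f: f.name):
                if not fam.consensus:
                    continue
                ident_f, _ = best_ungapped_identity(
                    sv.inserted_seq, fam.consensus, min_cov)
                ident_r, _ = best_ungapped_identity(
                    revcomp(sv.inserted_seq), fam.consensus, min_cov)
                ident = max(ident_f, ident_r)
                if ident >= min_identity and (best is None or ident > best[0]):
                    best = (ident, fam.name)
            if best is not None:
                return ISClassification(sv, True, best[1], "sequence_match",
                                        best[0])
            return ISClassification(sv, False, None, None, None)
        # no sequence: proximity rule, low confidence
        for fam in sorted(lib.families, key=lambda f: f.name):
            for s, e in fam.copies:
                if min(abs(sv.start - s), abs(sv.start - e)) <= proximity_bp:
                    return ISClassification(sv, True, fam.name, "proximity",
                                            None, low_confidence=True)
        return ISClassification(sv, False, None, None, None,
                                low_confidence=True)

    # span SVs: interval must cover >= min_cov of an annotated copy
    best_frac, best_fam = 0.0, None
    for fam in sorted(lib.families, key=lambda f: f.name):
        for s, e in fam.copies:
            frac = _interval_overlap((sv.start, sv.end), (s, e)) / (e - s + 1)
            if frac > best_frac:
                best_frac, best_fam = frac, fam.name
    if best_frac >= min_cov:
        return ISClassification(sv, True, best_fam, "copy_overlap", None)
    return ISClassification(sv, False, None, None, None)


def activity_summary(classified: list[ISClassification],
                     lib: ISLibrary) -> ISActivitySummary:
    """Per-family mediated-SV counts and their share of all mediated SVs."""
    counts = {f.name: 0 for f in lib.families}
    for cl in classified:
        if cl.mediated and cl.family is not None:
            counts.setdefault(cl.family, 0)
            counts[cl.family] += 1
    total = sum(counts.values())
    copy_numbers = lib.copy_numbers()
    per_family = [
        ISFamilyActivity(
            family=name,
            reference_copy_number=copy_numbers.get(name, 0),
            mediated_sv_count=cnt,
            proportion=(cnt / total) if total else 0.0,
        )
        for name, cnt in sorted(counts.items())
    ]
    return ISActivitySummary(per_family=per_family, total_mediated=total)


def _exact_spearman_p(x: np.ndarray, y: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact permutation p-value for Spearman's rho."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    n = len(rx)
    count = 0
    total = 0
    denom_x = np.sqrt(np.sum((rx - rx.mean()) ** 2))
    ry_c = ry - ry.mean()
    denom_y = np.sqrt(np.sum(ry_c ** 2))
    for perm in itertools.permutations(range(n)):
        rxp = rx[list(perm)]
        rho = float(np.sum((rxp - rxp.mean()) * ry_c) / (denom_x * denom_y))
        total += 1
        if abs(rho) >= abs(rho_obs) - 1e-12:
            count += 1
    return count / total


def copy_number_correlation(summary: ISActivitySummary,
                            exact_max_n: int = 8) -> CorrelationReport:
    """Correlate reference copy number with mediated-SV proportion.

    Pearson's r (p by the t transform) and Spearman's rho (exact permutation
    p for <= ``exact_max_n`` families, asymptotic above) over the
    (copy_number, proportion) pairs.  Zero-variance inputs are degenerate:
    coefficients are reported as 0 with the degenerate flag set.
    """
    fams = summary.per_family
    if len(fams) < 3:
        raise ValueError("copy-number correlation needs at least 3 families")
    x = np.array([f.reference_copy_number for f in fams], dtype=float)
    y = np.array([f.proportion for f in fams], dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationReport(0.0, 1.0, 0.0, 1.0, len(fams),
                                 degenerate=True)
    pear = stats.pearsonr(x, y)
    spear = stats.spearmanr(x, y)
    rho = float(spear.statistic)
    if len(fams) <= exact_max_n:
        sp_p = _exact_spearman_p(x, y, rho)
    else:
        sp_p = float(spear.pvalue)
    return CorrelationReport(float(pear.statistic), float(pear.pvalue),
                             rho, sp_p, len(fams))
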
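"""Implant known structural variants into a reference genome.

The simulator plants a requested number of INS/DEL/DUP/INV events with a
three-bucket length mixture (by default 70% 50–1,000 bp, 20% 1,001–5,000 bp,
10% 5,001–10,000 bp), uniform breakpoint positions, and optional small
substitution/indel noise in the ±100 bp flanks of each breakpoint.  It emits
the mutated FASTA together with a truth set whose coordinates are on the
ORIGINAL reference — i.e. what a caller benchmarked against the reference
should report.
"""

from __future__ import annotations

import bisect
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core_io import (ReferenceGenome, SVRecord, SV_TYPES, revcomp,
                      write_fasta, write_sv_table, write_sv_vcf)

DEFAULT_LENGTH_BUCKETS = [(50, 1000, 0.70), (1001, 5000, 0.20),
                          (5001, 10000, 0.10)]

_BASES = np.frombuffer(b"ACGT", dtype="S1").astype("U1")


class PlacementError(RuntimeError):
    """Raised when the requested SVs cannot be packed into the genome."""


@dataclass
class SimConfig:
    """Parameters of one genome simulation.

    ``p_flank_bps`` / ``p_flank_indel`` are per-flank occurrence
    probabilities: each ±``flank_bp`` window around a breakpoint receives at
    most one substitution and at most one indel.
    """

    n_per_type: dict[str, int] = field(
        default_factory=lambda: {t: 0 for t in SV_TYPES})
    length_buckets: list[tuple[int, int, float]] = field(
        default_factory=lambda: list(DEFAULT_LENGTH_BUCKETS))
    flank_bp: int = 100
    p_flank_bps: float = 0.001
    p_flank_indel: float = 0.0005
    max_flank_indel_bp: int = 20
    min_gap_bp: int | None = None  # defaults to 2 * flank_bp
    seed: int = 0

    def __post_init__(self) -> None:
        if self.min_gap_bp is None:
            self.min_gap_bp = 2 * self.flank_bp
        weights = [w for _, _, w in self.length_buckets]
        if abs(sum(weights) - 1.0) > 1e-9:
            raise ValueError("length bucket weights must sum to 1")
        for lo, hi, _ in self.length_buckets:
            if lo > hi:
                raise ValueError(f"bucket lo {lo} > hi {hi}")
        for p in (self.p_flank_bps, self.p_flank_indel):
            if not 0.0 <= p <= 1.0:
                raise ValueError("flank probabilities must be in [0, 1]")
        for t in self.n_per_type:
            if t not in SV_TYPES:
                raise ValueError(f"unknown SV type {t!r}")


@dataclass
class SimResult:
    mutated_genome: ReferenceGenome
    truth: list[SVRecord]          # coordinates on the ORIGINAL reference
    small_variants: list[tuple[int, str, str]]  # mutated-genome coordinates
    seed: int


def _draw_length(rng: np.random.Generator, buckets) -> int:
    weights = np.array([w for _, _, w in buckets])
    idx = rng.choice(len(buckets), p=weights / weights.sum())
    lo, hi, _ = buckets[idx]
    return int(rng.integers(lo, hi + 1))


def plan_svs(config: SimConfig, genome_length: int,
             seed: int | None = None,
             max_attempts: int = 1000) -> list[SVRecord]:
    """Choose SV types, lengths and positions on a genome of given length.

    Lengths are drawn by bucket weight then uniformly within the bucket;
    start positions are uniform; implanted spans are pairwise separated by
    at least ``min_gap_bp``.  Deterministic given the seed.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    occupied: list[tuple[int, int]] = []  # sorted (start, end) incl. gap

    def fits(s: int, e: int) -> bool:
        gap = config.min_gap_bp
        for os_, oe in occupied:
            if s <= oe + gap and e >= os_ - gap:
                return False
        return True

    planned: list[SVRecord] = []
    for svtype in SV_TYPES:  # fixed order for determinism
        n = config.n_per_type.get(svtype, 0)
        for _ in range(n):
            # draw the length once so rejected placements cannot bias the
            # bucket mixture toward short SVs
            length = _draw_length(rng, config.length_buckets)
            span = 1 if svtype == "INS" else length
            max_start = genome_length - span + 1
            placed = False
            for _attempt in range(max_attempts if max_start >= 2 else 0):
                start = int(rng.integers(2, max_start + 1))
                end = start + span - 1
                if fits(start, end):
                    occupied.append((start, end))
                    planned.append(SVRecord(contig="", start=start,
                                            svtype=svtype, length=length))
                    placed = True
                    break
            if not placed:
                raise PlacementError(
                    f"could not place all requested SVs: achieved "
                    f"{len(planned)} before failing on a {svtype} "
                    f"(genome_length={genome_length})")
    planned.sort(key=lambda r: r.start)
    return planned


def _check_truth(truth: list[SVRecord], genome_length: int) -> None:
    prev_end = 0
    for sv in truth:
        if sv.start <= prev_end:
            raise ValueError(
                f"truth records overlap or are unsorted at position {sv.start}")
        if sv.end > genome_length:
            raise ValueError(f"SV at {sv.start} exceeds genome length")
        prev_end = sv.end


def apply_svs(genome: ReferenceGenome, truth: list[SVRecord],
              seed: int = 0) -> ReferenceGenome:
    """Apply a sorted, non-overlapping truth set to the genome.

    DEL removes the span; INS inserts ``inserted_seq`` right of ``start``
    (uniform random A/C/G/T content is generated, and recorded back into the
    truth record, when absent); DUP appends one extra tandem copy after the
    span; INV reverse-complements the span.
    """
    truth = sorted(truth, key=lambda r: r.start)
    _check_truth(truth, len(genome))
    rng = np.random.default_rng(seed)
    seq = genome.sequence
    pieces: list[str] = []
    pos = 1  # 1-based cursor into the original sequence
    for sv in truth:
        if sv.svtype == "INS":
            if sv.inserted_seq is None:
                sv.inserted_seq = "".join(
                    rng.choice(_BASES, size=sv.length))
            pieces.append(seq[pos - 1:sv.start])   # up to and incl. anchor
            pieces.append(sv.inserted_seq)
            pos = sv.start + 1
        elif sv.svtype == "DEL":
            pieces.append(seq[pos - 1:sv.start - 1])
            pos = sv.end + 1
        elif sv.svtype == "DUP":
            pieces.append(seq[pos - 1:sv.end])
            pieces.append(seq[sv.start - 1:sv.end])
            pos = sv.end + 1
        elif sv.svtype == "INV":
            pieces.append(seq[pos - 1:sv.start - 1])
            pieces.append(revcomp(seq[sv.start - 1:sv.end]))
            pos = sv.end + 1
    pieces.append(seq[pos - 1:])
    return ReferenceGenome(contig_id=genome.contig_id,
                           sequence="".join(pieces),
                           circular=genome.circular)


def _edited_region_mutated(sv: SVRecord, delta: int) -> tuple[int, int]:
    """The SV's footprint in mutated-genome coordinates (may be empty)."""
    s = sv.start + delta
    if sv.svtype == "INS":
        return (s + 1, s + sv.length)
    if sv.svtype == "DEL":
        return (s, s - 1)  # empty: deletion leaves no footprint
    if sv.svtype == "DUP":
        return (s, sv.end + delta + sv.length)
    return (s, sv.end + delta)  # INV


def _length_delta(sv: SVRecord) -> int:
    if sv.svtype == "INS" or sv.svtype == "DUP":
        return sv.length
    if sv.svtype == "DEL":
        return -sv.length
    return 0


def inject_flanking_noise(genome_after_svs: ReferenceGenome,
                          truth: list[SVRecord], config: SimConfig,
                          seed: int = 0,
                          ) -> tuple[ReferenceGenome, list[tuple[int, str, str]]]:
    """Add substitution/indel noise in the flanks of each SV breakpoint.

    Each ±``flank_bp`` window (left and right of every SV's footprint, in
    mutated-genome coordinates) independently receives one substitution with
    probability ``p_flank_bps`` and one indel (length uniform in
    1..``max_flank_indel_bp``) with probability ``p_flank_indel``.  Windows
    are clipped so variants never touch another SV's span.  Returned variant
    positions refer to the noise-free mutated genome.
    """
    rng = np.random.default_rng(seed)
    truth = sorted(truth, key=lambda r: r.start)
    glen = len(genome_after_svs)

    footprints: list[tuple[int, int]] = []
    windows: list[tuple[int, int]] = []
    delta = 0
    for sv in truth:
        lo, hi = _edited_region_mutated(sv, delta)
        if lo <= hi:
            footprints.append((lo, hi))
        windows.append((lo - config.flank_bp, lo - 1))
        windows.append((hi + 1, hi + config.flank_bp))
        delta += _length_delta(sv)

    fp_starts = [fs for fs, _ in footprints]  # sorted, non-overlapping

    def clip(w: tuple[int, int]) -> tuple[int, int]:
        lo, hi = max(w[0], 1), min(w[1], glen)
        i = bisect.bisect_right(fp_starts, hi) - 1
        while i >= 0 and lo <= hi:
            fs, fe = footprints[i]
            if fe < lo:
                break
            # shrink towards whichever side survives
            if fs > lo:
                hi = min(hi, fs - 1)
            elif fe < hi:
                lo = max(lo, fe + 1)
            else:
                return (1, 0)
            i -= 1
        return (lo, hi)

    edits: list[tuple[int, str, str]] = []  # (pos, ref, alt); ref/alt strings
    used: list[tuple[int, int]] = []
    seq = genome_after_svs.sequence

    def reserve(lo: int, hi: int) -> bool:
        for ulo, uhi in used:
            if lo <= uhi and hi >= ulo:
                return False
        used.append((lo, hi))
        return True

    for w in windows:
        lo, hi = clip(w)
        if lo > hi:
            continue
        if rng.random() < config.p_flank_bps:
            pos = int(rng.integers(lo, hi + 1))
            ref = seq[pos - 1]
            choices = [b for b in "ACGT" if b != ref]
            alt = choices[int(rng.integers(0, 3))]
            if reserve(pos, pos):
                edits.append((pos, ref, alt))
        if rng.random() < config.p_flank_indel:
            ilen = int(rng.integers(1, config.max_flank_indel_bp + 1))
            if rng.random() < 0.5:  # insertion after pos
                pos = int(rng.integers(lo, hi + 1))
                ins = "".join(rng.choice(_BASES, size=ilen))
                ref = seq[pos - 1]
                if reserve(pos, pos):
                    edits.append((pos, ref, ref + ins))
            else:  # deletion within the window
                ilen = min(ilen, hi - lo + 1)
                pos = int(rng.integers(lo, hi - ilen + 2))
                ref = seq[pos - 1:pos - 1 + ilen]
                if reserve(pos, pos + ilen - 1):
                    edits.append((pos, ref, ""))

    # apply right-to-left so earlier coordinates stay valid
    out = seq
    for pos, ref, alt in sorted(edits, key=lambda e: -e[0]):
        if alt == "":  # deletion
            out = out[:pos - 1] + out[pos - 1 + len(ref):]
        elif len(alt) > 1:  # insertion (anchor retained)
            out = out[:pos] + alt[1:] + out[pos:]
        else:  # substitution
            out = out[:pos - 1] + alt + out[pos:]
    mutated = ReferenceGenome(contig_id=genome_after_svs.contig_id,
                              sequence=out,
                              circular=genome_after_svs.circular)
    return mutated, sorted(edits)


def simulate(reference: ReferenceGenome, config: SimConfig,
             out_prefix: str | Path | None = None) -> SimResult:
    """Plan, apply, and add flank noise; optionally write all artifacts.

    With ``out_prefix`` set, writes ``<prefix>.fa``, ``<prefix>.truth.vcf``,
    ``<prefix>.truth.tsv`` and ``<prefix>.log``.
    """
    ss = np.random.SeedSequence(config.seed)
    plan_seed, ins_seed, noise_seed = (int(s.generate_state(1)[0] % 2**31)
                                       for s in ss.spawn(3))
    truth = plan_svs(config, len(reference), seed=plan_seed)
    for sv in truth:
        sv.contig = reference.contig_id
        sv.source = "truth"
    after = apply_svs(reference, truth, seed=ins_seed)
    mutated, small = inject_flanking_noise(after, truth, config,
                                           seed=noise_seed)
    result = SimResult(mutated_genome=mutated, truth=truth,
                       small_variants=small, seed=config.seed)
    if out_prefix is not None:
        prefix = Path(out_prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        write_fasta(mutated, f"{prefix}.fa")
        write_sv_vcf(truth, reference, f"{prefix}.truth.vcf")
        write_sv_table(truth, f"{prefix}.truth.tsv")
        log = {
            "seed": config.seed,
            "n_per_type": config.n_per_type,
            "length_buckets": config.length_buckets,
            "flank_bp": config.flank_bp,
            "p_flank_bps": config.p_flank_bps,
            "p_flank_indel": config.p_flank_indel,
            "n_truth": len(truth),
            "n_small_variants": len(small),
            "reference_length": len(reference),
            "mutated_length": len(mutated),
        }
        with open(f"{prefix}.log", "w") as fh:
            json.dump(log, fh, indent=2)
            fh.write("\n")
    return result
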
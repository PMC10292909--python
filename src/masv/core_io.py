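"""Readers and writers for the formats the SV pipeline touches.

Coordinate conventions
----------------------
Internal coordinates are 1-based inclusive, matching VCF.  An insertion is
anchored at the base immediately LEFT of the insertion point, so for an
``INS`` record ``end == start``.  For span types (DEL/DUP/INV)
``end == start + length - 1``.  BED export converts to 0-based half-open.

The chromosome is treated as linear even though the *E. coli* chromosome is
circular; no SV may span the origin.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGTN")
SV_TYPES = ("INS", "DEL", "DUP", "INV")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of an A/C/G/T/N string."""
    return seq.translate(_COMPLEMENT)[::-1]


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass
class ReferenceGenome:
    """A single contig held in memory, uppercase {A,C,G,T,N}."""

    contig_id: str
    sequence: str
    circular: bool = False  # metadata only; all analysis is linear

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if len(self.sequence) == 0:
            raise FormatError(f"contig {self.contig_id!r}: empty sequence")
        bad = set(self.sequence) - VALID_BASES
        if bad:
            raise FormatError(
                f"contig {self.contig_id!r}: invalid character(s) "
                f"{sorted(bad)!r}; only A,C,G,T,N allowed"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class SVRecord:
    """One structural variant, either truth or call.

    ``start`` is the 1-based position of the first affected base; for an
    insertion it is the base immediately left of the insertion point.
    ``length`` is the inserted length for INS and the affected span
    otherwise.
    """

    contig: str
    start: int
    svtype: str
    length: int
    end: int | None = None
    inserted_seq: str | None = None
    imprecise: bool = False
    source: str = ""
    line_id: str = ""

    def __post_init__(self) -> None:
        if self.svtype not in SV_TYPES:
            raise ValueError(f"unknown svtype {self.svtype!r}")
        if self.length < 1:
            raise ValueError(f"length must be >= 1, got {self.length}")
        if self.start < 1:
            raise ValueError(f"start must be >= 1, got {self.start}")
        expected_end = self.start if self.svtype == "INS" else self.start + self.length - 1
        if self.end is None:
            self.end = expected_end
        elif self.end != expected_end:
            raise ValueError(
                f"inconsistent end for {self.svtype}: got {self.end}, "
                f"expected {expected_end}"
            )
        if self.inserted_seq is not None:
            if self.svtype != "INS":
                raise ValueError("inserted_seq only valid for INS records")
            self.inserted_seq = self.inserted_seq.upper()

    def copy(self, **changes) -> "SVRecord":
        return replace(self, **changes)


@dataclass
class ISFamily:
    """One insertion-sequence family: consensus plus its reference copies."""

    name: str
    consensus: str | None
    copies: list[tuple[int, int]] = field(default_factory=list)

    @property
    def copy_number(self) -> int:
        return len(self.copies)


@dataclass
class ISLibrary:
    """IS-element annotation: families, consensi, reference copy intervals."""

    families: list[ISFamily] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [f.name for f in self.families]
        if len(names) != len(set(names)):
            raise FormatError("duplicate IS family names in annotation")

    def copy_numbers(self) -> dict[str, int]:
        return {f.name: f.copy_number for f in self.families}

    def get(self, name: str) -> ISFamily:
        for f in self.families:
            if f.name == name:
                return f
        raise KeyError(name)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[ReferenceGenome]:
    """Read a (multi-)FASTA into :class:`ReferenceGenome` records.

    Sequences are uppercased; any character outside {A,C,G,T,N} is a
    :class:`FormatError` naming the offending character.
    """
    path = Path(path)
    genomes = []
    for rec in SeqIO.parse(str(path), "fasta"):
        genomes.append(ReferenceGenome(contig_id=rec.id, sequence=str(rec.seq)))
    if not genomes:
        raise FormatError(f"{path}: no FASTA records found (empty file?)")
    return genomes


def write_fasta(genome: ReferenceGenome | list[ReferenceGenome],
                path: str | Path, line_width: int = 80) -> None:
    """Write genome(s) to FASTA with fixed line width (round-trip safe)."""
    if line_width < 1:
        raise ValueError("line_width must be positive")
    genomes = [genome] if isinstance(genome, ReferenceGenome) else list(genome)
    with open(path, "w") as fh:
        for g in genomes:
            fh.write(f">{g.contig_id}\n")
            seq = g.sequence
            for i in range(0, len(seq), line_width):
                fh.write(seq[i:i + line_width] + "\n")


# ---------------------------------------------------------------------------
# SV VCF
# ---------------------------------------------------------------------------

_SVTYPE_ALIASES = {"DUP:TANDEM": "DUP", "DUP": "DUP", "INS": "INS",
                   "DEL": "DEL", "INV": "INV"}


def _info_scalar(value):
    if isinstance(value, (tuple, list)):
        return value[0]
    return value


def _info_get(rec, key):
    """INFO lookup tolerant of keys missing from the header."""
    try:
        return rec.info.get(key)
    except (KeyError, ValueError):
        return None


def read_sv_vcf(path: str | Path) -> list[SVRecord]:
    """Parse SV records from a VCF 4.x file.

    SVTYPE is taken from INFO (DUP:TANDEM collapses to DUP); length is
    ``|SVLEN|`` when present, else ``END - POS + 1``, else derived from
    sequence-resolved alleles.  ``IMPRECISE`` maps to the imprecise flag.
    Records of other SV types (BND, CNV, ...) and records lacking any
    length information are tallied and skipped with a warning.
    """
    path = Path(path)
    records: list[SVRecord] = []
    skipped_type = 0
    skipped_length = 0
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            svtype = _info_get(rec, "SVTYPE")
            if svtype is None:
                # sequence-resolved small record: infer from allele lengths
                if rec.alts and all(c in "ACGTN" for c in rec.alts[0].upper()):
                    svtype = "INS" if len(rec.alts[0]) > len(rec.ref) else "DEL"
                else:
                    skipped_type += 1
                    continue
            svtype = _SVTYPE_ALIASES.get(str(svtype))
            if svtype is None:
                skipped_type += 1
                continue

            svlen = _info_get(rec, "SVLEN")
            inserted_seq = None
            if rec.alts and rec.alts[0][0] != "<" and svtype == "INS":
                alt = rec.alts[0].upper()
                if len(alt) > len(rec.ref):
                    inserted_seq = alt[len(rec.ref):]
            if svlen is not None:
                length = abs(int(_info_scalar(svlen)))
            elif svtype != "INS" and rec.stop is not None and rec.stop >= rec.pos:
                # pysam rec.stop equals the 1-based inclusive END
                length = rec.stop - rec.pos + 1
            elif inserted_seq:
                length = len(inserted_seq)
            elif rec.alts and rec.alts[0][0] != "<":
                length = abs(len(rec.alts[0]) - len(rec.ref))
            else:
                skipped_length += 1
                continue
            if length < 1:
                skipped_length += 1
                continue

            records.append(SVRecord(
                contig=rec.chrom,
                start=rec.pos,
                svtype=svtype,
                length=length,
                inserted_seq=inserted_seq,
                imprecise="IMPRECISE" in rec.info,
                source=str(_info_get(rec, "SOURCE") or ""),
                line_id=str(_info_get(rec, "LINE_ID") or ""),
            ))
    if skipped_type:
        warnings.warn(f"{path}: skipped {skipped_type} record(s) with "
                      "unsupported/missing SVTYPE")
    if skipped_length:
        warnings.warn(f"{path}: skipped {skipped_length} record(s) lacking "
                      "SVLEN/END/resolved alleles")
    return records


def _sv_vcf_header(genome: ReferenceGenome) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    header.add_line("##fileformat=VCFv4.2")
    header.contigs.add(genome.contig_id, length=len(genome))
    header.info.add("SVTYPE", 1, "String", "Type of structural variant")
    header.info.add("SVLEN", 1, "Integer", "Length of structural variant")
    header.info.add("END", 1, "Integer", "End position (1-based inclusive)")
    header.info.add("IMPRECISE", 0, "Flag", "Imprecise breakpoints")
    header.info.add("SOURCE", 1, "String", "Record provenance")
    header.info.add("LINE_ID", 1, "String", "MA line identifier")
    return header


def write_sv_vcf(calls: list[SVRecord], genome: ReferenceGenome,
                 path: str | Path) -> None:
    """Write SV records as VCF 4.2 with symbolic ALTs.

    Sequence-resolved INS records (known ``inserted_seq``) are written with
    an explicit ALT allele; everything else uses ``<DEL>``/``<DUP>``/... .
    """
    header = _sv_vcf_header(genome)
    glen = len(genome)
    ordered = sorted(calls, key=lambda r: (r.contig, r.start, r.svtype))
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for sv in ordered:
            if sv.end > glen or sv.start > glen:
                raise ValueError(
                    f"SV at {sv.contig}:{sv.start} extends beyond contig "
                    f"length {glen}")
            ref_base = genome.sequence[sv.start - 1]
            if sv.svtype == "INS" and sv.inserted_seq:
                alleles = (ref_base, ref_base + sv.inserted_seq)
            else:
                alleles = (ref_base, f"<{sv.svtype}>")
            rec = vf.new_record(
                contig=sv.contig, start=sv.start - 1, alleles=alleles,
                stop=sv.end)
            rec.info["SVTYPE"] = sv.svtype
            if sv.svtype == "INS":
                # SVLEN on symbolic span alleles makes htslib recompute END
                # under the POS-anchored convention; END alone round-trips
                rec.info["SVLEN"] = sv.length
            if sv.imprecise:
                rec.info["IMPRECISE"] = True
            if sv.source:
                rec.info["SOURCE"] = sv.source
            if sv.line_id:
                rec.info["LINE_ID"] = sv.line_id
            vf.write(rec)


# ---------------------------------------------------------------------------
# BED conversion (0-based half-open) and truth tables
# ---------------------------------------------------------------------------

def to_bed_interval(sv: SVRecord) -> tuple[str, int, int]:
    """Convert an SV's affected span to a BED (0-based half-open) triple."""
    return (sv.contig, sv.start - 1, sv.end)


def from_bed_interval(contig: str, bed_start: int, bed_end: int) -> tuple[str, int, int]:
    """BED triple back to 1-based inclusive (contig, start, end)."""
    return (contig, bed_start + 1, bed_end)


_TRUTH_COLUMNS = ["contig", "start", "end", "svtype", "length",
                  "imprecise", "source", "line_id", "inserted_seq"]


def write_sv_table(calls: list[SVRecord], path: str | Path) -> None:
    """Write SV records to a TSV with documented headers."""
    rows = [{
        "contig": r.contig, "start": r.start, "end": r.end,
        "svtype": r.svtype, "length": r.length,
        "imprecise": r.imprecise, "source": r.source, "line_id": r.line_id,
        "inserted_seq": r.inserted_seq or "",
    } for r in calls]
    pd.DataFrame(rows, columns=_TRUTH_COLUMNS).to_csv(path, sep="\t", index=False)


def read_sv_table(path: str | Path) -> list[SVRecord]:
    """Read SV records back from a TSV written by :func:`write_sv_table`."""
    df = pd.read_csv(path, sep="\t", dtype={"source": str, "line_id": str,
                                            "inserted_seq": str},
                     keep_default_na=False)
    records = []
    for row in df.itertuples(index=False):
        records.append(SVRecord(
            contig=str(row.contig), start=int(row.start),
            svtype=str(row.svtype), length=int(row.length),
            inserted_seq=(row.inserted_seq or None),
            imprecise=(str(row.imprecise).lower() in ("true", "1")),
            source=row.source, line_id=row.line_id))
    return records


# ---------------------------------------------------------------------------
# IS-element annotation
# ---------------------------------------------------------------------------

def read_is_annotation(path: str | Path,
                       consensus_fasta: str | Path | None = None) -> ISLibrary:
    """Read a tab-separated IS annotation (family, start, end[, consensus]).

    A per-family consensus may come from a ``consensus`` column or from a
    separate FASTA whose record ids are family names.  Families without a
    consensus are kept but sequence classification is disabled for them.
    Overlapping copies are permitted (with a warning); ``end < start`` is an
    error naming the row.
    """
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    required = {"family", "start", "end"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing column(s) {sorted(missing)}")

    consensi: dict[str, str] = {}
    if consensus_fasta is not None:
        for g in read_fasta(consensus_fasta):
            consensi[g.contig_id] = g.sequence

    families: dict[str, ISFamily] = {}
    for i, row in enumerate(df.itertuples(index=False)):
        start, end = int(row.start), int(row.end)
        if end < start:
            raise FormatError(f"{path}: row {i + 1}: end {end} < start {start}")
        name = str(row.family)
        if name not in families:
            cons = consensi.get(name)
            if cons is None and "consensus" in df.columns and row.consensus:
                cons = str(row.consensus).upper()
            families[name] = ISFamily(name=name, consensus=cons, copies=[])
        families[name].copies.append((start, end))

    lib = ISLibrary(families=list(families.values()))
    for fam in lib.families:
        ivals = sorted(fam.copies)
        for (s1, e1), (s2, _e2) in zip(ivals, ivals[1:]):
            if s2 <= e1:
                warnings.warn(f"IS family {fam.name}: overlapping copies "
                              f"({s1}-{e1} and {s2}-...)")
                break
        if fam.consensus is None:
            logger.info("IS family %s has no consensus; sequence "
                        "classification disabled for it", fam.name)
    return lib
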
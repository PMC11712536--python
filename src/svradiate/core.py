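"""Core domain types, SV-VCF ingestion, call-level filters and size tables.

Structural variant (SV) calls enter the pipeline as Sniffles-style VCF
records.  The five SV classes reported throughout are DEL, INS, DUP, INV
and INVDUP; breakend (BND) / translocation records are outside the class
vocabulary and are skipped on ingestion.

Coordinate conventions
----------------------
:class:`SVRecord` stores VCF conventions verbatim (1-based ``start`` =
POS, ``end`` = INFO/END) so that parse → write → parse round-trips are
exact.  Whenever reference sequence is accessed the record is converted
to 0-based half-open at the module boundary: the affected segment of a
non-insertion SV is ``reference[start:end]`` (POS anchors the base before
the event, as in the VCF padding convention, so ``end - start`` equals
the SV length).  Insertions anchor at a single point (``end == start``)
and occupy the 1-bp anchor ``reference[start:start+1]`` for overlap
purposes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pysam

logger = logging.getLogger(__name__)

SV_TYPES = ("DEL", "INS", "DUP", "INV", "INVDUP")

#: Sniffles-dialect SVTYPE spellings mapped onto the five-class vocabulary.
SVTYPE_NORMALIZATION = {
    "DEL": "DEL",
    "INS": "INS",
    "DUP": "DUP",
    "INV": "INV",
    "INVDUP": "INVDUP",
    "INV/INVDUP": "INVDUP",
    "DUP/INS": "DUP",
    "DUP:TANDEM": "DUP",
}

#: SVTYPEs recognised but deliberately excluded (not in the five-class set).
EXCLUDED_SVTYPES = {"BND", "TRA"}


@dataclass(frozen=True)
class SVRecord:
    """One structural-variant call in VCF coordinates (1-based)."""

    id: str
    chrom: str
    start: int
    end: int
    sv_type: str
    length: int
    inserted_seq: str | None = None
    read_support: int = 0
    min_supporting_read_length: int = 0
    mapping_quality: float = 0.0

    def __post_init__(self) -> None:
        if self.sv_type not in SV_TYPES:
            raise ValueError(f"unknown sv_type {self.sv_type!r}")
        if self.start < 1:
            raise ValueError(f"start must be >= 1, got {self.start}")
        if self.sv_type != "INS" and self.end < self.start:
            raise ValueError(f"end < start for non-INS record {self.id}")
        if self.length < 1:
            raise ValueError(f"length must be >= 1, got {self.length}")
        if (
            self.inserted_seq is not None
            and self.sv_type == "INS"
            and len(self.inserted_seq) != self.length
        ):
            raise ValueError(
                f"inserted_seq length {len(self.inserted_seq)} != SV length "
                f"{self.length} for {self.id}"
            )

    @property
    def interval0(self) -> tuple[int, int]:
        """0-based half-open interval affected on the reference.

        Insertions occupy their 1-bp anchor; for all other types the
        segment is ``[start, end)`` in 0-based coordinates (length bases).
        """
        if self.sv_type == "INS":
            return (self.start, self.start + 1)
        return (self.start, self.end)

    def sort_key(self) -> tuple:
        return (self.chrom, self.start, self.end, self.sv_type, self.id)


@dataclass(frozen=True)
class FilterParams:
    """Call-level filter thresholds; all comparisons are inclusive."""

    min_sv_length: int = 1
    max_sv_length: int = 1_000_000
    min_read_length: int = 1000
    min_mapping_quality: float = 20.0

    def __post_init__(self) -> None:
        if self.min_sv_length < 1:
            raise ValueError("min_sv_length must be >= 1")
        if self.max_sv_length < self.min_sv_length:
            raise ValueError("max_sv_length must be >= min_sv_length")


@dataclass
class SVCallSet:
    """A sample's SV call collection plus sample metadata.

    Records are kept in a stable (chrom, start, end, sv_type, id) order and
    ids must be unique within the set.
    """

    sample_id: str
    genotype: str = "WT"
    treatment: str = "none"
    replicate: int = 1
    records: list[SVRecord] = field(default_factory=list)

    GENOTYPES = ("WT", "atm", "atr", "atm_atr", "other")
    TREATMENTS = ("none", "UV_B", "UV_C", "protons")

    def __post_init__(self) -> None:
        if self.genotype not in self.GENOTYPES:
            raise ValueError(f"unknown genotype {self.genotype!r}")
        if self.treatment not in self.TREATMENTS:
            raise ValueError(f"unknown treatment {self.treatment!r}")
        if self.replicate < 1:
            raise ValueError("replicate must be >= 1")
        ids = [r.id for r in self.records]
        if len(ids) != len(set(ids)):
            raise ValueError(f"duplicate record ids in {self.sample_id}")
        self.records = sorted(self.records, key=SVRecord.sort_key)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def ids(self) -> set[str]:
        return {r.id for r in self.records}

    def by_id(self, record_id: str) -> SVRecord:
        for r in self.records:
            if r.id == record_id:
                return r
        raise KeyError(record_id)

    def with_records(self, records: Iterable[SVRecord]) -> "SVCallSet":
        return SVCallSet(
            sample_id=self.sample_id,
            genotype=self.genotype,
            treatment=self.treatment,
            replicate=self.replicate,
            records=list(records),
        )


def _info_scalar(value):
    if isinstance(value, (tuple, list)):
        return value[0] if value else None
    return value


def parse_sv_vcf(
    vcf_path: str | Path,
    sample_id: str,
    genotype: str = "WT",
    treatment: str = "none",
    replicate: int = 1,
    honor_filter: bool = True,
) -> SVCallSet:
    """Read a Sniffles-style SV VCF into an :class:`SVCallSet`.

    One :class:`SVRecord` per SV line whose FILTER is PASS or '.' (set
    ``honor_filter=False`` to ingest everything).  BND/translocation lines
    and lines that are not SVs are skipped with a logged count; absent
    quality annotations map to sentinels (read_support=0,
    min_supporting_read_length=0, mapping_quality=0).

    Recognised INFO keys: SVTYPE, END, SVLEN, SEQ (insertion sequence; an
    explicit ALT allele is used when SEQ is absent), RE or SUPPORT (read
    support), MAPQ, MINRLEN (minimum supporting-read length).
    """
    records: list[SVRecord] = []
    n_skipped_bnd = 0
    n_skipped_other = 0
    n_filtered = 0
    with pysam.VariantFile(str(vcf_path)) as vcf:
        for line_no, rec in enumerate(vcf, start=1):
            info = rec.info
            svtype_raw = _info_scalar(info.get("SVTYPE"))
            if svtype_raw is None:
                n_skipped_other += 1
                continue
            if honor_filter:
                filters = set(rec.filter.keys())
                if filters and filters != {"PASS"}:
                    n_filtered += 1
                    continue
            if svtype_raw in EXCLUDED_SVTYPES:
                n_skipped_bnd += 1
                continue
            sv_type = SVTYPE_NORMALIZATION.get(svtype_raw)
            if sv_type is None:
                logger.warning(
                    "unknown SVTYPE %r at %s:%s — record skipped",
                    svtype_raw, rec.chrom, rec.pos,
                )
                n_skipped_other += 1
                continue

            start = rec.pos
            end = int(_info_scalar(info.get("END")) or rec.stop)
            svlen = _info_scalar(info.get("SVLEN"))

            inserted_seq = None
            if sv_type == "INS":
                end = start
                seq = _info_scalar(info.get("SEQ"))
                if seq:
                    inserted_seq = str(seq).upper()
                elif rec.alts and not rec.alts[0].startswith("<"):
                    alt = rec.alts[0]
                    inserted_seq = alt[len(rec.ref):].upper() or None
                if svlen is None and inserted_seq:
                    svlen = len(inserted_seq)

            if svlen is not None:
                length = abs(int(svlen))
            else:
                length = max(end - start, 1)
            if length < 1:
                length = 1
            if inserted_seq is not None and len(inserted_seq) != length:
                # caller disagreement between SVLEN and the reported sequence:
                # trust the sequence
                length = len(inserted_seq)

            support = _info_scalar(info.get("RE"))
            if support is None:
                support = _info_scalar(info.get("SUPPORT"))
            mapq = _info_scalar(info.get("MAPQ"))
            minrlen = _info_scalar(info.get("MINRLEN"))

            records.append(
                SVRecord(
                    id=rec.id or f"{sample_id}_{line_no}",
                    chrom=rec.chrom,
                    start=start,
                    end=end,
                    sv_type=sv_type,
                    length=length,
                    inserted_seq=inserted_seq,
                    read_support=int(support) if support is not None else 0,
                    min_supporting_read_length=int(minrlen) if minrlen is not None else 0,
                    mapping_quality=float(mapq) if mapq is not None else 0.0,
                )
            )
    if n_skipped_bnd or n_skipped_other or n_filtered:
        logger.info(
            "%s: skipped %d BND/TRA, %d non-SV/unknown, %d FILTER-failed lines",
            sample_id, n_skipped_bnd, n_skipped_other, n_filtered,
        )
    callset = SVCallSet(
        sample_id=sample_id,
        genotype=genotype,
        treatment=treatment,
        replicate=replicate,
        records=records,
    )
    callset.parse_skip_counts = {  # type: ignore[attr-defined]
        "bnd": n_skipped_bnd,
        "other": n_skipped_other,
        "filter": n_filtered,
    }
    return callset


REJECTION_REASONS = ("too_short", "too_long", "read_length", "mapping_quality")


def filter_calls(calls: SVCallSet, params: FilterParams | None = None) -> SVCallSet:
    """Apply the four call-level thresholds (all inclusive).

    A record is retained iff

    * ``min_sv_length <= length <= max_sv_length``
    * ``min_supporting_read_length >= params.min_read_length``
    * ``mapping_quality >= params.min_mapping_quality``

    The returned set carries a ``rejection_tally`` attribute mapping each
    criterion to the number of records it rejected (a record failing
    several criteria is tallied once, under the first failing criterion in
    the order above), so that ``len(output) + sum(tally) == len(input)``.
    """
    params = params or FilterParams()
    kept: list[SVRecord] = []
    tally = {reason: 0 for reason in REJECTION_REASONS}
    audit: list[tuple[str, str]] = []
    for rec in calls:
        if rec.length < params.min_sv_length:
            reason = "too_short"
        elif rec.length > params.max_sv_length:
            reason = "too_long"
        elif rec.min_supporting_read_length < params.min_read_length:
            reason = "read_length"
        elif rec.mapping_quality < params.min_mapping_quality:
            reason = "mapping_quality"
        else:
            kept.append(rec)
            continue
        tally[reason] += 1
        audit.append((rec.id, reason))
    out = calls.with_records(kept)
    out.rejection_tally = tally  # type: ignore[attr-defined]
    out.rejection_audit = audit  # type: ignore[attr-defined]
    return out


def size_table(calls: SVCallSet):
    """Per-type size distributions with median and quartiles.

    Quartiles use linear interpolation (numpy's default), matching the
    usual box-plot convention.  An ``INDEL`` aggregate row pools DEL and
    INS lengths.  Returns a dict keyed by sv_type (plus ``"INDEL"``) with
    ``lengths``, ``n``, ``median``, ``q1``, ``q3``.
    """
    groups: dict[str, list[int]] = {}
    for rec in calls:
        groups.setdefault(rec.sv_type, []).append(rec.length)
    indel = groups.get("DEL", []) + groups.get("INS", [])
    if indel:
        groups["INDEL"] = indel
    table = {}
    for sv_type, lengths in sorted(groups.items()):
        arr = np.asarray(sorted(lengths), dtype=float)
        q1, med, q3 = np.percentile(arr, [25, 50, 75], method="linear")
        table[sv_type] = {
            "lengths": [int(v) for v in arr],
            "n": int(arr.size),
            "median": float(med),
            "q1": float(q1),
            "q3": float(q3),
        }
    return table


# ---------------------------------------------------------------------------
# VCF writing

VCF_HEADER_LINES = [
    '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="Type of structural variant">',
    '##INFO=<ID=END,Number=1,Type=Integer,Description="End position of the variant">',
    '##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="Length of the variant">',
    '##INFO=<ID=SEQ,Number=1,Type=String,Description="Inserted sequence">',
    '##INFO=<ID=RE,Number=1,Type=Integer,Description="Number of supporting reads">',
    '##INFO=<ID=MAPQ,Number=1,Type=Float,Description="Mean mapping quality of supporting reads">',
    '##INFO=<ID=MINRLEN,Number=1,Type=Integer,Description="Minimum supporting read length">',
    '##FILTER=<ID=too_short,Description="SV length below minimum">',
    '##FILTER=<ID=too_long,Description="SV length above maximum">',
    '##FILTER=<ID=read_length,Description="Supporting read length below minimum">',
    '##FILTER=<ID=mapping_quality,Description="Mapping quality below minimum">',
]


def write_sv_vcf(
    calls: SVCallSet,
    path: str | Path,
    chrom_lengths: dict[str, int] | None = None,
    filter_reasons: dict[str, str] | None = None,
) -> None:
    """Write a call set as a plain-text SV VCF.

    ``filter_reasons`` maps record id to a FILTER reason tag; records not
    listed are written with FILTER=PASS.  The emitted dialect round-trips
    through :func:`parse_sv_vcf` field-for-field.
    """
    filter_reasons = filter_reasons or {}
    chroms = sorted({r.chrom for r in calls})
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source=svradiate\n")
        for chrom in chroms:
            if chrom_lengths and chrom in chrom_lengths:
                fh.write(f"##contig=<ID={chrom},length={chrom_lengths[chrom]}>\n")
            else:
                fh.write(f"##contig=<ID={chrom}>\n")
        for line in VCF_HEADER_LINES:
            fh.write(line + "\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for rec in calls:
            svlen = -rec.length if rec.sv_type == "DEL" else rec.length
            info = [
                f"SVTYPE={rec.sv_type}",
                f"END={rec.end}",
                f"SVLEN={svlen}",
                f"RE={rec.read_support}",
                f"MAPQ={rec.mapping_quality:g}",
                f"MINRLEN={rec.min_supporting_read_length}",
            ]
            if rec.inserted_seq:
                info.insert(3, f"SEQ={rec.inserted_seq}")
            flt = filter_reasons.get(rec.id, "PASS")
            fh.write(
                f"{rec.chrom}\t{rec.start}\t{rec.id}\tN\t<{rec.sv_type}>\t.\t"
                f"{flt}\t{';'.join(info)}\n"
            )
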
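"""Genome annotation layers and SV-to-element assignment.

The genome is partitioned three ways — protein-coding genes (PCG),
transposable elements (TE, with superfamily labels) and the intergenic
complement (IR) — and carries three further layers: chromatin states
(CS1–CS9, where CS8/CS9 form constitutive heterochromatin),
centromere/pericentromere windows, and HOT regions (hotspots of
rearrangement).  Each SV is assigned to exactly one element class by
maximal bp overlap of its affected interval (insertions use their 1-bp
anchor), with tie precedence TE > PCG > IR.

All coordinates are 0-based half-open internally; BED inputs are taken
as-is, GFF3 (1-based inclusive) is converted on load.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from intervaltree import Interval, IntervalTree

from .core import SVCallSet, SVRecord

ELEMENT_CLASSES = ("PCG", "TE", "IR")
#: tie precedence for element assignment (repeat-centric: TE wins ties)
ELEMENT_PRECEDENCE = {"TE": 0, "PCG": 1, "IR": 2}
CS_LABELS = tuple(f"CS{i}" for i in range(1, 10))
HETEROCHROMATIN_CS = ("CS8", "CS9")


@dataclass
class GenomeAnnotation:
    """Interval layers over a genome, indexed for overlap queries.

    ``pcg``, ``te``, ``ir``, ``cs``, ``centromeric`` and ``hot`` map
    chromosome name to an :class:`IntervalTree`; TE intervals carry their
    superfamily label and CS intervals their state label as ``data``.
    """

    chrom_lengths: dict[str, int]
    pcg: dict[str, IntervalTree]
    te: dict[str, IntervalTree]
    ir: dict[str, IntervalTree]
    cs: dict[str, IntervalTree]
    centromeric: dict[str, IntervalTree]
    hot: dict[str, IntervalTree]

    def layer_bp(self, layer_name: str) -> int:
        layer: dict[str, IntervalTree] = getattr(self, layer_name)
        return sum(iv.length() for tree in layer.values() for iv in tree)

    def element_bp_fractions(self) -> dict[str, float]:
        """Genome-wide bp share of each element class (background)."""
        total = sum(self.chrom_lengths.values())
        return {
            "PCG": self.layer_bp("pcg") / total,
            "TE": self.layer_bp("te") / total,
            "IR": self.layer_bp("ir") / total,
        }

    def element_count_fractions(self) -> dict[str, float]:
        """Background by interval count rather than bp share."""
        counts = {
            "PCG": sum(len(t) for t in self.pcg.values()),
            "TE": sum(len(t) for t in self.te.values()),
            "IR": sum(len(t) for t in self.ir.values()),
        }
        total = sum(counts.values())
        return {k: v / total for k, v in counts.items()} if total else counts


@dataclass(frozen=True)
class ElementAssignment:
    record_id: str
    element_class: str
    te_superfamily: str | None
    overlap_bp: int
    centromeric: bool
    hot: bool
    chromatin_state: str | None

    def __post_init__(self) -> None:
        if (self.te_superfamily is not None) != (self.element_class == "TE"):
            raise ValueError("te_superfamily present iff element_class == TE")


# ---------------------------------------------------------------------------
# loading

def _read_bed(path: str | Path) -> dict[str, list[tuple[int, int, str | None]]]:
    """BED3/BED4 → per-chromosome [(start0, end0, name)]."""
    out: dict[str, list] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            name = parts[3] if len(parts) > 3 else None
            out.setdefault(chrom, []).append((start, end, name))
    return out


def _read_chrom_sizes(path: str | Path) -> dict[str, int]:
    out = {}
    with open(path) as fh:
        for line in fh:
            if line.strip():
                chrom, length = line.split()[:2]
                out[chrom] = int(length)
    return out


def _merge_intervals(ivs: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[list[int]] = []
    for s, e in sorted(ivs):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def derive_ir(
    chrom_lengths: dict[str, int],
    pcg: dict[str, IntervalTree],
    te: dict[str, IntervalTree],
) -> dict[str, IntervalTree]:
    """Intergenic complement of (PCG ∪ TE) per chromosome."""
    ir: dict[str, IntervalTree] = {}
    for chrom, length in chrom_lengths.items():
        covered = _merge_intervals(
            [(iv.begin, iv.end) for iv in pcg.get(chrom, IntervalTree())]
            + [(iv.begin, iv.end) for iv in te.get(chrom, IntervalTree())]
        )
        tree = IntervalTree()
        prev = 0
        for s, e in covered:
            if s > prev:
                tree.addi(prev, s, None)
            prev = max(prev, e)
        if prev < length:
            tree.addi(prev, length, None)
        ir[chrom] = tree
    return ir


def load_annotation(
    gff_path: str | Path,
    cs_bed: str | Path,
    centromere_bed: str | Path,
    hot_bed: str | Path,
    chrom_sizes: str | Path,
) -> GenomeAnnotation:
    """Load GFF3 genes/TEs plus BED tracks into a :class:`GenomeAnnotation`.

    GFF3 feature types ``gene`` (or ``protein_coding_gene``) populate the
    PCG layer; ``transposable_element`` features populate the TE layer
    with the superfamily taken from the ``superfamily=`` (or ``Alias=``)
    attribute, defaulting to ``"unknown"``.  IR is derived as the
    per-chromosome complement of PCG ∪ TE.  Intervals extending beyond the
    chromosome length raise an error naming the feature.
    """
    chrom_lengths = _read_chrom_sizes(chrom_sizes)
    pcg: dict[str, IntervalTree] = {c: IntervalTree() for c in chrom_lengths}
    te: dict[str, IntervalTree] = {c: IntervalTree() for c in chrom_lengths}
    with open(gff_path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9:
                continue
            chrom, _, ftype, start, end = parts[0], parts[1], parts[2], parts[3], parts[4]
            attrs = dict(
                kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv
            )
            s0, e0 = int(start) - 1, int(end)  # GFF3 1-based inclusive → half-open
            if chrom not in chrom_lengths:
                continue
            if e0 > chrom_lengths[chrom] or s0 < 0:
                raise ValueError(
                    f"feature {attrs.get('ID', ftype)} at {chrom}:{start}-{end} "
                    f"exceeds chromosome length {chrom_lengths[chrom]}"
                )
            if ftype in ("gene", "protein_coding_gene"):
                pcg[chrom].addi(s0, e0, attrs.get("ID"))
            elif ftype == "transposable_element":
                superfam = attrs.get("superfamily") or attrs.get("Alias") or "unknown"
                te[chrom].addi(s0, e0, superfam)

    def bed_layer(path):
        layer = {c: IntervalTree() for c in chrom_lengths}
        for chrom, ivs in _read_bed(path).items():
            if chrom not in chrom_lengths:
                continue
            for s, e, name in ivs:
                if e > chrom_lengths[chrom]:
                    raise ValueError(
                        f"BED interval {chrom}:{s}-{e} exceeds chromosome length"
                    )
                layer[chrom].addi(s, e, name)
        return layer

    return GenomeAnnotation(
        chrom_lengths=chrom_lengths,
        pcg=pcg,
        te=te,
        ir=derive_ir(chrom_lengths, pcg, te),
        cs=bed_layer(cs_bed),
        centromeric=bed_layer(centromere_bed),
        hot=bed_layer(hot_bed),
    )


# ---------------------------------------------------------------------------
# assignment

def _overlap_bp(tree: IntervalTree | None, s: int, e: int) -> int:
    if tree is None:
        return 0
    return sum(min(iv.end, e) - max(iv.begin, s) for iv in tree.overlap(s, e))


def assign_element(record: SVRecord, ann: GenomeAnnotation) -> ElementAssignment:
    """Assign one SV to its element class, CS, centromeric and HOT context.

    Element class is the layer with maximal bp overlap with the SV's
    affected interval (ties: TE > PCG > IR); the TE superfamily is that of
    the maximally-overlapping TE.  Centromeric context is decided by the
    interval midpoint; HOT by any ≥1 bp overlap; chromatin state by
    maximal bp overlap, absent where no state covers the interval.
    """
    if record.chrom not in ann.chrom_lengths:
        raise KeyError(f"chromosome {record.chrom!r} absent from annotation")
    s, e = record.interval0
    overlaps = {
        "PCG": _overlap_bp(ann.pcg.get(record.chrom), s, e),
        "TE": _overlap_bp(ann.te.get(record.chrom), s, e),
        "IR": _overlap_bp(ann.ir.get(record.chrom), s, e),
    }
    element = min(
        ELEMENT_CLASSES,
        key=lambda c: (-overlaps[c], ELEMENT_PRECEDENCE[c]),
    )
    superfam = None
    if element == "TE":
        te_tree = ann.te.get(record.chrom, IntervalTree())
        best = None
        for iv in te_tree.overlap(s, e):
            ov = min(iv.end, e) - max(iv.begin, s)
            key = (-ov, iv.begin, iv.end)
            if best is None or key < best[0]:
                best = (key, iv.data or "unknown")
        superfam = best[1] if best else "unknown"

    mid = (s + e) // 2
    cen_tree = ann.centromeric.get(record.chrom)
    centromeric = bool(cen_tree and cen_tree.overlap(mid, mid + 1))
    hot_tree = ann.hot.get(record.chrom)
    hot = bool(hot_tree and hot_tree.overlap(s, e))

    cs_tree = ann.cs.get(record.chrom)
    chromatin_state = None
    if cs_tree:
        best_cs = None
        for iv in cs_tree.overlap(s, e):
            ov = min(iv.end, e) - max(iv.begin, s)
            key = (-ov, iv.data or "", iv.begin)
            if best_cs is None or key < best_cs[0]:
                best_cs = (key, iv.data)
        if best_cs is not None:
            chromatin_state = best_cs[1]

    return ElementAssignment(
        record_id=record.id,
        element_class=element,
        te_superfamily=superfam,
        overlap_bp=overlaps[element],
        centromeric=centromeric,
        hot=hot,
        chromatin_state=chromatin_state,
    )


def element_distribution(calls: SVCallSet, ann: GenomeAnnotation) -> dict:
    """All element/CS/centromere/HOT summary tables for a call set.

    Returns a dict with per-element counts, per sv_type × element counts,
    TE superfamily counts, chromatin-state counts (with a CH aggregate of
    CS8+CS9), centromeric fraction, HOT overlap count, the per-record
    assignments, and the genome background as both bp and count fractions.
    """
    assignments = [assign_element(r, ann) for r in calls]
    by_element = {c: 0 for c in ELEMENT_CLASSES}
    by_type_element: dict[str, dict[str, int]] = {}
    by_superfamily: dict[str, int] = {}
    by_cs: dict[str, int] = {}
    n_cen = 0
    n_hot = 0
    for rec, a in zip(calls, assignments):
        by_element[a.element_class] += 1
        by_type_element.setdefault(rec.sv_type, {c: 0 for c in ELEMENT_CLASSES})[
            a.element_class
        ] += 1
        if a.te_superfamily is not None:
            by_superfamily[a.te_superfamily] = by_superfamily.get(a.te_superfamily, 0) + 1
        if a.chromatin_state is not None:
            by_cs[a.chromatin_state] = by_cs.get(a.chromatin_state, 0) + 1
        n_cen += a.centromeric
        n_hot += a.hot
    n = len(calls)
    cs_with_ch = dict(sorted(by_cs.items()))
    cs_with_ch["CH"] = sum(by_cs.get(cs, 0) for cs in HETEROCHROMATIN_CS)
    return {
        "n_records": n,
        "element_counts": by_element,
        "type_element_counts": {k: by_type_element[k] for k in sorted(by_type_element)},
        "te_superfamily_counts": dict(sorted(by_superfamily.items())),
        "chromatin_state_counts": cs_with_ch,
        "centromeric_count": n_cen,
        "centromeric_fraction": (n_cen / n) if n else 0.0,
        "hot_count": n_hot,
        "hot_fraction": (n_hot / n) if n else 0.0,
        "background_bp_fractions": ann.element_bp_fractions(),
        "background_count_fractions": ann.element_count_fractions(),
        "assignments": assignments,
    }


def write_assignments_tsv(distribution: dict, path: str | Path) -> None:
    """Per-record annotation table (one row per SV)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(
            ["record_id", "element_class", "te_superfamily", "overlap_bp",
             "centromeric", "hot", "chromatin_state"]
        )
        for a in distribution["assignments"]:
            w.writerow(
                [a.record_id, a.element_class, a.te_superfamily or ".",
                 a.overlap_bp, int(a.centromeric), int(a.hot),
                 a.chromatin_state or "."]
            )


def write_circos_bed(calls: SVCallSet, path: str | Path) -> None:
    """Circos-ready BED of SV positions, named/colourable by sv_type."""
    colors = {"DEL": "220,50,50", "INS": "50,120,220", "DUP": "50,180,80",
              "INV": "240,160,30", "INVDUP": "150,60,200"}
    with open(path, "w") as fh:
        for rec in calls:
            s, e = rec.interval0
            fh.write(
                f"{rec.chrom}\t{s}\t{e}\t{rec.sv_type}\t0\t+\t{s}\t{e}\t"
                f"{colors[rec.sv_type]}\n"
            )
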
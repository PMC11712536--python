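"""Deletion-junction microhomology and repair-pathway classification.

A deletion produced by end-joining repair leaves a junction whose exact
breakpoint is ambiguous wherever the sequence entering the deletion
matches the sequence following it.  The length of that ambiguity tract —
the junction microhomology — is the repair-pathway signature:

* NHEJ (non-homologous end joining): 0–1 bp of microhomology;
* MMEJ (microhomology-mediated end joining): short homologous tracts,
  2–19 bp by default;
* SSA candidates (single-strand annealing): ≥20 bp.

For a deletion with 0-based half-open bounds ``[s, e)`` on reference
``R`` the right-hand microhomology is the largest ``k`` with
``R[s:s+k] == R[e:e+k]`` and the left-hand microhomology the largest
``j`` with ``R[s-j:s] == R[e-j:e]``; the total ``j + k`` is
representation-invariant: shifting the reported breakpoints anywhere
along the homology tract leaves it unchanged.  Comparison is
case-insensitive (soft-masking ignored) and any N terminates extension.

Flanks are fetched ±50 bp around the deleted segment; a flank truncated
at a chromosome end or containing N marks the deletion UNDETERMINED
(this reference-based reimplementation has no per-read quality, so "low
sequence quality" is operationalised as N content or truncation).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

from .core import SVCallSet, SVRecord

REPAIR_LABELS = ("NHEJ", "MMEJ", "SSA_CANDIDATE", "UNDETERMINED")


@dataclass(frozen=True)
class RepairParams:
    flank_window: int = 50
    mh_min_mmej: int = 2
    mh_max_mmej: int = 19
    mh_ssa_threshold: int = 20
    max_n_fraction: float = 0.0

    def __post_init__(self) -> None:
        if not (1 <= self.mh_min_mmej <= self.mh_max_mmej
                < self.mh_ssa_threshold <= self.flank_window):
            raise ValueError(
                "require 1 <= mh_min_mmej <= mh_max_mmej < mh_ssa_threshold "
                "<= flank_window"
            )


@dataclass(frozen=True)
class RepairClassification:
    record_id: str
    left_flank: str
    right_flank: str
    mh_left: int
    mh_right: int
    mh_total: int
    mh_sequence: str
    label: str
    truncated: bool = False

    def __post_init__(self) -> None:
        if self.mh_total != self.mh_left + self.mh_right:
            raise ValueError("mh_total must equal mh_left + mh_right")
        if len(self.mh_sequence) != self.mh_total:
            raise ValueError("mh_sequence length must equal mh_total")


class ReferenceGenome:
    """Uniform access to reference sequence from a FASTA or a dict.

    Accepts a ``pyfaidx.Fasta``, a mapping ``{chrom: sequence}`` or a path
    to a FASTA file.  ``fetch(chrom, start0, end0)`` returns upper-case
    sequence, clipped to the chromosome.
    """

    def __init__(self, source):
        if isinstance(source, (str, Path)):
            import pyfaidx

            self._fa = pyfaidx.Fasta(str(source))
            self._dict = None
        elif isinstance(source, Mapping):
            self._fa = None
            self._dict = {k: str(v).upper() for k, v in source.items()}
        else:  # pyfaidx.Fasta or similar
            self._fa = source
            self._dict = None

    def chroms(self) -> list[str]:
        if self._dict is not None:
            return list(self._dict)
        return list(self._fa.keys())

    def length(self, chrom: str) -> int:
        if self._dict is not None:
            return len(self._dict[chrom])
        return len(self._fa[chrom])

    def fetch(self, chrom: str, start0: int, end0: int) -> str:
        if self._dict is not None:
            if chrom not in self._dict:
                raise KeyError(f"chromosome {chrom!r} absent from reference")
            seq = self._dict[chrom]
        else:
            if chrom not in self._fa.keys():
                raise KeyError(f"chromosome {chrom!r} absent from reference")
            seq = None
        s = max(0, start0)
        e = min(self.length(chrom), end0)
        if e <= s:
            return ""
        if seq is not None:
            return seq[s:e]
        return str(self._fa[chrom][s:e]).upper()


def _as_genome(genome) -> ReferenceGenome:
    return genome if isinstance(genome, ReferenceGenome) else ReferenceGenome(genome)


def _deletion_bounds(deletion: SVRecord) -> tuple[int, int]:
    if deletion.sv_type != "DEL":
        raise ValueError(f"record {deletion.id} is {deletion.sv_type}, not DEL")
    s, e = deletion.interval0
    if e - s < 1:
        raise ValueError(f"deletion {deletion.id} shorter than 1 bp")
    return s, e


def fetch_flanks(
    deletion: SVRecord, genome, window: int = 50
) -> tuple[str, str, bool]:
    """Reference flanks ±``window`` bp around the deleted segment.

    Returns ``(left_flank, right_flank, truncated)`` where the left flank
    is ``R[s-window:s]`` and the right ``R[e:e+window]`` (0-based
    half-open); flanks shorter than ``window`` because they run off a
    chromosome end set the truncation flag.
    """
    g = _as_genome(genome)
    s, e = _deletion_bounds(deletion)
    left = g.fetch(deletion.chrom, s - window, s)
    right = g.fetch(deletion.chrom, e, e + window)
    truncated = len(left) < window or len(right) < window
    return left, right, truncated


def microhomology(
    deletion: SVRecord, genome, window: int = 50
) -> tuple[int, int, int, str]:
    """Junction microhomology lengths and sequence for one deletion.

    Returns ``(mh_left, mh_right, mh_total, mh_sequence)``; exact-identity
    extension only, case-insensitive, stopped by any N, capped at
    ``window`` per side.
    """
    g = _as_genome(genome)
    s, e = _deletion_bounds(deletion)
    chrom = deletion.chrom

    # right extension: R[s:s+k] == R[e:e+k]
    a = g.fetch(chrom, s, s + window).upper()
    b = g.fetch(chrom, e, e + window).upper()
    k = 0
    for x, y in zip(a, b):
        if x != y or x == "N":
            break
        k += 1
    # left extension: R[s-j:s] == R[e-j:e], compared inward from the junction
    a = g.fetch(chrom, s - window, s).upper()
    b = g.fetch(chrom, e - window, e).upper()
    j = 0
    for x, y in zip(reversed(a), reversed(b)):
        if x != y or x == "N":
            break
        j += 1
    mh_seq = g.fetch(chrom, s - j, s) + g.fetch(chrom, s, s + k)
    return j, k, j + k, mh_seq.upper()


def classify_repair(
    deletion: SVRecord, genome, params: RepairParams | None = None
) -> RepairClassification:
    """Label one deletion NHEJ / MMEJ / SSA_CANDIDATE / UNDETERMINED."""
    params = params or RepairParams()
    left, right, truncated = fetch_flanks(deletion, genome, params.flank_window)

    def n_frac(seq: str) -> float:
        return (seq.upper().count("N") / len(seq)) if seq else 1.0

    undetermined = truncated or (
        max(n_frac(left), n_frac(right)) > params.max_n_fraction
    )
    if undetermined:
        return RepairClassification(
            record_id=deletion.id, left_flank=left, right_flank=right,
            mh_left=0, mh_right=0, mh_total=0, mh_sequence="",
            label="UNDETERMINED", truncated=truncated,
        )
    j, k, total, mh_seq = microhomology(deletion, genome, params.flank_window)
    if total >= params.mh_ssa_threshold:
        label = "SSA_CANDIDATE"
    elif total >= params.mh_min_mmej:
        label = "MMEJ"
    else:
        label = "NHEJ"
    return RepairClassification(
        record_id=deletion.id, left_flank=left, right_flank=right,
        mh_left=j, mh_right=k, mh_total=total, mh_sequence=mh_seq,
        label=label, truncated=False,
    )


def repair_summary(
    calls: SVCallSet, genome, params: RepairParams | None = None
) -> dict:
    """Per-sample repair-pathway table and MMEJ microhomology histogram.

    Only deletions are processed; fractions are over all classified
    deletions and the histogram (bubble-chart data) is keyed by mh_total
    restricted to MMEJ events.
    """
    params = params or RepairParams()
    classifications = [
        classify_repair(r, genome, params) for r in calls if r.sv_type == "DEL"
    ]
    counts = {label: 0 for label in REPAIR_LABELS}
    histogram: dict[int, int] = {}
    for c in classifications:
        counts[c.label] += 1
        if c.label == "MMEJ":
            histogram[c.mh_total] = histogram.get(c.mh_total, 0) + 1
    n = len(classifications)
    return {
        "sample_id": calls.sample_id,
        "n_deletions": n,
        "counts": counts,
        "fractions": {k: (v / n if n else 0.0) for k, v in counts.items()},
        "mmej_mh_histogram": {k: histogram[k] for k in sorted(histogram)},
        "classifications": classifications,
    }


def write_repair_tsv(summary: dict, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["record_id", "left_flank", "right_flank", "mh_left",
                    "mh_right", "mh_total", "mh_sequence", "label"])
        for c in summary["classifications"]:
            w.writerow([c.record_id, c.left_flank, c.right_flank, c.mh_left,
                        c.mh_right, c.mh_total, c.mh_sequence or ".", c.label])
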
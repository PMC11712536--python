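"""Tolerance-based SV identity and call-set algebra.

Two SV calls are *identical* when they have the same type and the same
genomic coordinates (chromosome, start-end) within a ±50 bp tolerance on
both breakpoints.  This identity relation is symmetric but not
transitive, so set-level operations resolve it explicitly:

* :func:`match_sets` — deterministic greedy one-to-one pairing, closest
  pairs first;
* :func:`venn_partition` — connected components of the match graph over
  three replicate call sets;
* :func:`subtract` — removes every target call that matches any pooled
  control call (the "step 2" pedigree subtraction);
* :func:`induced_sv_workflow` — composes the subtractions that define
  radiation-induced calls for wild-type and DDR-mutant samples.

Pooling is concatenation, not union: replicate call sets keep their full
sizes when combined into a subtraction baseline (three untreated
replicates of sizes 248, 339 and 291 pool to 878 calls even though some
calls are shared between replicates).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
from intervaltree import IntervalTree

from .core import SVCallSet, SVRecord

VENN_REGIONS = ("A", "B", "C", "AB", "AC", "BC", "ABC")


@dataclass(frozen=True)
class MatchParams:
    """Breakpoint tolerance for call identity (±50 bp on start and end)."""

    tolerance: int = 50
    require_same_type: bool = True

    def __post_init__(self) -> None:
        if self.tolerance < 0:
            raise ValueError("tolerance must be >= 0")


@dataclass
class MatchPairing:
    """One-to-one resolution of the identity relation between two sets."""

    pairs: list[tuple[str, str, int, int]] = field(default_factory=list)
    unmatched_A: list[str] = field(default_factory=list)
    unmatched_B: list[str] = field(default_factory=list)


@dataclass
class VennPartition:
    """Counts for the 7 regions of a 3-set Venn, in match-graph components."""

    region_counts: dict[str, int]
    n_components: int
    n_inconsistent: int

    def __post_init__(self) -> None:
        assert sum(self.region_counts.values()) == self.n_components


def records_match(a: SVRecord, b: SVRecord, params: MatchParams | None = None) -> bool:
    """True iff *a* and *b* are identical under the ±tolerance rule.

    Same chromosome, same type (unless disabled), and both the start and
    the end coordinate within ``tolerance`` bp.  Inserted sequence content
    and SV length are not compared.
    """
    params = params or MatchParams()
    if a.chrom != b.chrom:
        return False
    if params.require_same_type and a.sv_type != b.sv_type:
        return False
    return (
        abs(a.start - b.start) <= params.tolerance
        and abs(a.end - b.end) <= params.tolerance
    )


def _candidate_pairs(
    A: Sequence[SVRecord], B: Sequence[SVRecord], params: MatchParams
) -> list[tuple[SVRecord, SVRecord]]:
    """All (a, b) with records_match true, via an interval index on B starts."""
    by_key: dict[tuple, IntervalTree] = {}
    for b in B:
        key = (b.chrom, b.sv_type if params.require_same_type else None)
        tree = by_key.setdefault(key, IntervalTree())
        # index by start; half-open interval of width 1
        tree.addi(b.start, b.start + 1, b)
    out = []
    tol = params.tolerance
    for a in A:
        key = (a.chrom, a.sv_type if params.require_same_type else None)
        tree = by_key.get(key)
        if tree is None:
            continue
        for iv in tree.overlap(a.start - tol, a.start + tol + 1):
            b = iv.data
            if abs(a.end - b.end) <= tol:
                out.append((a, b))
    return out


def match_sets(
    A: SVCallSet, B: SVCallSet, params: MatchParams | None = None
) -> MatchPairing:
    """Greedy nearest one-to-one pairing of matching records.

    Candidate pairs are sorted by ascending (start-distance +
    end-distance), ties broken by (chrom, start, id of a, id of b); each
    record participates in at most one pair.  The result is identical to
    enumerating all pairs brute-force and applying the same greedy rule.
    """
    params = params or MatchParams()
    candidates = _candidate_pairs(list(A), list(B), params)
    candidates.sort(
        key=lambda ab: (
            abs(ab[0].start - ab[1].start) + abs(ab[0].end - ab[1].end),
            ab[0].chrom,
            ab[0].start,
            ab[0].id,
            ab[1].id,
        )
    )
    used_a: set[str] = set()
    used_b: set[str] = set()
    pairing = MatchPairing()
    for a, b in candidates:
        if a.id in used_a or b.id in used_b:
            continue
        used_a.add(a.id)
        used_b.add(b.id)
        pairing.pairs.append(
            (a.id, b.id, abs(a.start - b.start), abs(a.end - b.end))
        )
    pairing.unmatched_A = sorted(r.id for r in A if r.id not in used_a)
    pairing.unmatched_B = sorted(r.id for r in B if r.id not in used_b)
    return pairing


def pool(sets: Iterable[SVCallSet], sample_id: str = "pool") -> SVCallSet:
    """Concatenate call sets into one baseline, with provenance-tagged ids.

    No deduplication is performed: the pooled size equals the sum of the
    input sizes.  Record ids are prefixed with their sample of origin to
    stay unique.
    """
    sets = list(sets)
    seen: set[str] = set()
    for s in sets:
        if s.sample_id in seen:
            raise ValueError(f"duplicate sample_id {s.sample_id!r} in pool")
        seen.add(s.sample_id)
    records = []
    for s in sets:
        for rec in s:
            records.append(
                SVRecord(
                    id=f"{s.sample_id}::{rec.id}",
                    chrom=rec.chrom,
                    start=rec.start,
                    end=rec.end,
                    sv_type=rec.sv_type,
                    length=rec.length,
                    inserted_seq=rec.inserted_seq,
                    read_support=rec.read_support,
                    min_supporting_read_length=rec.min_supporting_read_length,
                    mapping_quality=rec.mapping_quality,
                )
            )
    return SVCallSet(sample_id=sample_id, records=records)


def subtract(
    target: SVCallSet,
    controls: Iterable[SVCallSet],
    params: MatchParams | None = None,
) -> SVCallSet:
    """Remove every target call matching any call in the pooled controls.

    Returns the surviving records; the result carries a
    ``subtraction_audit`` attribute mapping each removed target id to the
    control record id that removed it (the nearest match).
    """
    params = params or MatchParams()
    controls = list(controls)
    control_records: list[SVRecord] = [r for s in controls for r in s]
    candidates = _candidate_pairs(list(target), control_records, params)
    # nearest control per target record, deterministic tie-break
    best: dict[str, tuple[int, str]] = {}
    for a, b in candidates:
        d = abs(a.start - b.start) + abs(a.end - b.end)
        cur = best.get(a.id)
        if cur is None or (d, b.id) < cur:
            best[a.id] = (d, b.id)
    kept = [r for r in target if r.id not in best]
    out = target.with_records(kept)
    out.subtraction_audit = {rid: bid for rid, (_, bid) in sorted(best.items())}  # type: ignore[attr-defined]
    return out


def venn_partition(
    A: SVCallSet, B: SVCallSet, C: SVCallSet, params: MatchParams | None = None
) -> VennPartition:
    """Three-replicate concordance by match-graph connected components.

    Builds an undirected graph over all records of the three sets with an
    edge wherever two records from *different* sets match; each connected
    component contributes one count to the Venn region named by the set
    labels present in it.  Components containing more than one record from
    the same sample are additionally tallied as *inconsistent* (they still
    contribute to their region).
    """
    params = params or MatchParams()
    sets = {"A": A, "B": B, "C": C}
    g = nx.Graph()
    nodes: dict[tuple[str, str], SVRecord] = {}
    for label, s in sets.items():
        for rec in s:
            g.add_node((label, rec.id))
            nodes[(label, rec.id)] = rec
    labels = list(sets)
    for i, la in enumerate(labels):
        for lb in labels[i + 1:]:
            for a, b in _candidate_pairs(list(sets[la]), list(sets[lb]), params):
                g.add_edge((la, a.id), (lb, b.id))
    region_counts = {r: 0 for r in VENN_REGIONS}
    n_inconsistent = 0
    n_components = 0
    for comp in nx.connected_components(g):
        n_components += 1
        present = sorted({label for label, _ in comp})
        region_counts["".join(present)] += 1
        per_set: dict[str, int] = {}
        for label, _ in comp:
            per_set[label] = per_set.get(label, 0) + 1
        if any(v > 1 for v in per_set.values()):
            n_inconsistent += 1
    return VennPartition(
        region_counts=region_counts,
        n_components=n_components,
        n_inconsistent=n_inconsistent,
    )


def induced_sv_workflow(
    treated: SVCallSet,
    untreated_same_genotype: SVCallSet | Sequence[SVCallSet] | None = None,
    wt_treated: SVCallSet | None = None,
    params: MatchParams | None = None,
) -> SVCallSet:
    """Subtraction workflow defining the radiation-induced call set.

    Wild-type treated samples: controls are the pooled untreated
    (pedigree) replicates.  DDR-mutant treated samples: controls are the
    untreated same-genotype calls *and* the treated wild-type calls, so
    that only mutant-specific induced events remain.  The result carries a
    ``workflow_provenance`` attribute listing each subtraction step.
    """
    params = params or MatchParams()
    if untreated_same_genotype is None:
        raise ValueError(
            f"no untreated control provided for treated sample {treated.sample_id!r}"
        )
    if isinstance(untreated_same_genotype, SVCallSet):
        untreated_controls = [untreated_same_genotype]
    else:
        untreated_controls = list(untreated_same_genotype)
    if not untreated_controls:
        raise ValueError(
            f"empty untreated control list for treated sample {treated.sample_id!r}"
        )
    is_mutant = treated.genotype != "WT"
    if is_mutant and wt_treated is None:
        raise ValueError(
            f"mutant treated sample {treated.sample_id!r} requires the matching "
            "WT treated call set as a control"
        )
    controls = list(untreated_controls)
    provenance = [
        {
            "step": "subtract_untreated",
            "controls": [c.sample_id for c in untreated_controls],
        }
    ]
    if is_mutant and wt_treated is not None:
        controls.append(wt_treated)
        provenance.append(
            {"step": "subtract_wt_treated", "controls": [wt_treated.sample_id]}
        )
    out = subtract(treated, controls, params)
    out.workflow_provenance = provenance  # type: ignore[attr-defined]
    return out
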
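"""Tracing inserted sequences back to their genomic donor locus.

Each insertion call carrying its inserted sequence is searched against
the reference genome with a seed-and-extend local aligner (exact k-mer
seeds on both strands, greedy diagonal chaining, affine-gap extension),
and the best hit — if it passes identity and query-coverage floors and
strictly outscores the runner-up locus — becomes the insertion's donor.
Donors are then classified by genetic element (PCG/TE/IR, maximal
overlap), flagged intrachromosomal when donor and insertion share a
chromosome, and flagged as truncated TEs when the donor overlaps a TE
annotation without covering (by default) ≥95% of its span — the
signature distinguishing copy fragments from transposition-like events.

Hits within ``self_exclusion_radius`` of the insertion site are
discarded so an insertion cannot trivially "originate" from its own
flanking context in a reference-based search.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable

from Bio.Align import PairwiseAligner
from Bio.Seq import reverse_complement

from .annotation import (
    ELEMENT_CLASSES,
    ELEMENT_PRECEDENCE,
    GenomeAnnotation,
    _overlap_bp,
    assign_element,
)
from .core import SVCallSet, SVRecord
from .repair import ReferenceGenome, _as_genome

ORIGIN_STATUSES = ("resolved", "ambiguous", "no_hit")


@dataclass(frozen=True)
class OriginParams:
    seed_k: int = 15
    min_identity: float = 0.8
    min_query_coverage: float = 0.8
    max_hits_reported: int = 5
    self_exclusion_radius: int = 100
    # affine-gap local-alignment scores, near blastn defaults
    match_score: int = 1
    mismatch_score: int = -2
    gap_open: int = -4
    gap_extend: int = -1
    te_full_span_fraction: float = 0.95

    def __post_init__(self) -> None:
        if not (0 < self.min_identity <= 1):
            raise ValueError("min_identity must be in (0, 1]")
        if not (0 < self.min_query_coverage <= 1):
            raise ValueError("min_query_coverage must be in (0, 1]")
        if self.seed_k < 8:
            raise ValueError("seed_k must be >= 8")


@dataclass(frozen=True)
class InsertionOrigin:
    record_id: str
    status: str
    donor_chrom: str | None = None
    donor_start: int | None = None  # 0-based half-open
    donor_end: int | None = None
    donor_strand: str | None = None
    identity: float | None = None
    query_coverage: float | None = None
    score: float | None = None
    donor_element_class: str | None = None
    donor_te_superfamily: str | None = None
    intrachromosomal: bool | None = None
    truncated_te: bool | None = None
    reason: str | None = None


class GenomeKmerIndex:
    """Exact k-mer index of a reference genome for seeding.

    Built once per genome; maps each k-mer to its (chrom, position)
    occurrences.  K-mers containing N are not indexed.
    """

    def __init__(self, genome, k: int = 15):
        self.genome = _as_genome(genome)
        self.k = k
        self.index: dict[str, list[tuple[str, int]]] = {}
        for chrom in self.genome.chroms():
            seq = self.genome.fetch(chrom, 0, self.genome.length(chrom)).upper()
            for i in range(len(seq) - k + 1):
                kmer = seq[i:i + k]
                if "N" in kmer:
                    continue
                self.index.setdefault(kmer, []).append((chrom, i))

    def hits(self, kmer: str) -> list[tuple[str, int]]:
        return self.index.get(kmer.upper(), [])


def _seed_clusters(
    query: str, index: GenomeKmerIndex, stride: int
) -> dict[tuple[str, str, int], list[tuple[int, int]]]:
    """Seed hits grouped by (chrom, strand, diagonal band).

    Returns {(chrom, strand, band): [(genome_pos, query_pos), ...]} where
    the band width equals the query length, grouping seeds that belong to
    one candidate locus.
    """
    k = index.k
    band = max(len(query), 50)
    clusters: dict[tuple[str, str, int], list[tuple[int, int]]] = {}
    for strand, q in (("+", query), ("-", reverse_complement(query))):
        for qpos in range(0, len(q) - k + 1, stride):
            for chrom, gpos in index.hits(q[qpos:qpos + k]):
                diag = gpos - qpos
                key = (chrom, strand, diag // band)
                clusters.setdefault(key, []).append((gpos, qpos))
    return clusters


def _align_window(
    query: str, window_seq: str, params: OriginParams
) -> tuple[float, int, int, float, float]:
    """Local affine-gap alignment of query vs a genome window.

    Returns (score, window_start_offset, window_end_offset, identity,
    query_coverage); identity is matches / aligned columns and coverage is
    aligned query bases / query length.
    """
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = params.match_score
    aligner.mismatch_score = params.mismatch_score
    # Biopython charges open_gap_score for the first gap base: a gap of
    # length L costs open + L*extend under the blast convention.
    aligner.open_gap_score = params.gap_open + params.gap_extend
    aligner.extend_gap_score = params.gap_extend
    try:
        aln = aligner.align(window_seq, query)[0]
    except (IndexError, OverflowError):
        return (float("-inf"), 0, 0, 0.0, 0.0)
    t_blocks, q_blocks = aln.aligned
    matches = 0
    columns = 0
    q_covered = 0
    for (ts, te), (qs, qe) in zip(t_blocks, q_blocks):
        for t_i, q_i in zip(range(ts, te), range(qs, qe)):
            columns += 1
            if window_seq[t_i] == query[q_i]:
                matches += 1
        q_covered += qe - qs
    # count gap columns inside the aligned span
    if len(t_blocks):
        t_span = t_blocks[-1][1] - t_blocks[0][0]
        q_span = q_blocks[-1][1] - q_blocks[0][0]
        columns += (t_span - sum(te - ts for ts, te in t_blocks))
        columns += (q_span - sum(qe - qs for qs, qe in q_blocks))
        t_start, t_end = t_blocks[0][0], t_blocks[-1][1]
    else:
        return (float("-inf"), 0, 0, 0.0, 0.0)
    identity = matches / columns if columns else 0.0
    coverage = q_covered / len(query) if query else 0.0
    return (float(aln.score), t_start, t_end, identity, coverage)


def find_origin(
    insert_seq: str,
    genome,
    insertion_chrom: str,
    insertion_pos: int,
    params: OriginParams | None = None,
    index: GenomeKmerIndex | None = None,
    record_id: str = "",
) -> InsertionOrigin:
    """Locate the genomic donor of one inserted sequence.

    ``insertion_pos`` is the 0-based insertion anchor used for
    self-exclusion.  Returns a resolved origin only when the best-scoring
    locus passes the identity and coverage floors and strictly outscores
    every other candidate locus; equal-best loci yield ``ambiguous`` and
    anything else ``no_hit``.
    """
    params = params or OriginParams()
    insert_seq = insert_seq.upper()
    if len(insert_seq) < params.seed_k:
        return InsertionOrigin(
            record_id=record_id, status="no_hit",
            reason=f"insert shorter than seed_k={params.seed_k}",
        )
    g = _as_genome(genome)
    if index is None:
        index = GenomeKmerIndex(g, params.seed_k)
    elif index.k != params.seed_k:
        raise ValueError("index k does not match params.seed_k")

    stride = max(1, params.seed_k // 3)
    clusters = _seed_clusters(insert_seq, index, stride)
    qlen = len(insert_seq)
    margin = max(20, qlen // 5)

    hits: list[tuple[float, str, int, int, str, float, float]] = []
    for (chrom, strand, _band), seeds in sorted(clusters.items()):
        gmin = min(g for g, _ in seeds)
        gmax = max(g for g, _ in seeds) + index.k
        w_start = max(0, gmin - margin - qlen)
        w_end = min(g.length(chrom), gmax + margin + qlen)
        window_seq = index.genome.fetch(chrom, w_start, w_end).upper()
        target = insert_seq if strand == "+" else reverse_complement(insert_seq)
        score, t_s, t_e, ident, cov = _align_window(target, window_seq, params)
        if score == float("-inf"):
            continue
        hits.append((float(score), chrom, int(w_start + t_s), int(w_start + t_e),
                     strand, float(ident), float(cov)))

    # self-exclusion: drop hits near the insertion's own locus
    r = params.self_exclusion_radius
    hits = [
        h for h in hits
        if not (h[1] == insertion_chrom
                and h[2] - r <= insertion_pos <= h[3] + r)
    ]
    if not hits:
        return InsertionOrigin(record_id=record_id, status="no_hit",
                               reason="no seed hit outside self-exclusion")
    # deduplicate overlapping windows describing the same locus: keep the
    # best-scoring hit per overlapping (chrom, strand) group
    hits.sort(key=lambda h: (-h[0], h[1], h[2], h[4]))
    distinct: list[tuple[float, str, int, int, str, float, float]] = []
    for h in hits:
        dup = False
        for d in distinct:
            if h[1] == d[1] and not (h[3] <= d[2] or h[2] >= d[3]):
                dup = True
                break
        if not dup:
            distinct.append(h)
        if len(distinct) >= max(params.max_hits_reported, 2):
            break
    best = distinct[0]
    score, chrom, d_s, d_e, strand, ident, cov = best
    if ident < params.min_identity or cov < params.min_query_coverage:
        return InsertionOrigin(record_id=record_id, status="no_hit",
                               reason="best hit below identity/coverage floor")
    if len(distinct) > 1 and distinct[1][0] >= score:
        return InsertionOrigin(record_id=record_id, status="ambiguous",
                               reason="equal-best loci")
    return InsertionOrigin(
        record_id=record_id, status="resolved",
        donor_chrom=chrom, donor_start=d_s, donor_end=d_e,
        donor_strand=strand, identity=ident, query_coverage=cov, score=score,
        intrachromosomal=(chrom == insertion_chrom),
    )


def classify_origin(
    origin: InsertionOrigin,
    ann: GenomeAnnotation,
    insertion_record: SVRecord,
    params: OriginParams | None = None,
) -> InsertionOrigin:
    """Enrich a resolved origin with donor element class and TE truncation."""
    params = params or OriginParams()
    if origin.status != "resolved":
        raise ValueError(f"cannot classify unresolved origin ({origin.status})")
    d_s, d_e = origin.donor_start, origin.donor_end
    overlaps = {
        "PCG": _overlap_bp(ann.pcg.get(origin.donor_chrom), d_s, d_e),
        "TE": _overlap_bp(ann.te.get(origin.donor_chrom), d_s, d_e),
        "IR": _overlap_bp(ann.ir.get(origin.donor_chrom), d_s, d_e),
    }
    donor_class = min(
        ELEMENT_CLASSES, key=lambda c: (-overlaps[c], ELEMENT_PRECEDENCE[c])
    )
    donor_superfam = None
    if donor_class == "TE":
        te_tree0 = ann.te.get(origin.donor_chrom)
        best = None
        for iv in (te_tree0.overlap(d_s, d_e) if te_tree0 else ()):
            ov = min(iv.end, d_e) - max(iv.begin, d_s)
            key = (-ov, iv.begin, iv.end)
            if best is None or key < best[0]:
                best = (key, iv.data or "unknown")
        donor_superfam = best[1] if best else "unknown"
    truncated = None
    te_tree = ann.te.get(origin.donor_chrom)
    if te_tree:
        overlapping = sorted(
            te_tree.overlap(origin.donor_start, origin.donor_end),
            key=lambda iv: -(min(iv.end, origin.donor_end)
                             - max(iv.begin, origin.donor_start)),
        )
        if overlapping:
            te_iv = overlapping[0]
            covered = (min(te_iv.end, origin.donor_end)
                       - max(te_iv.begin, origin.donor_start))
            truncated = bool(covered < params.te_full_span_fraction * te_iv.length())
    return replace(
        origin,
        donor_element_class=donor_class,
        donor_te_superfamily=donor_superfam,
        truncated_te=truncated,
        intrachromosomal=(origin.donor_chrom == insertion_record.chrom),
    )


def origin_summary(
    calls: SVCallSet,
    genome,
    ann: GenomeAnnotation,
    params: OriginParams | None = None,
    index: GenomeKmerIndex | None = None,
) -> dict:
    """Donor-class × recipient-class matrix plus status tallies.

    The recipient class is the element assignment of the insertion
    anchor; insertions without a resolvable donor are tallied under their
    status.  resolved + ambiguous + no_hit equals the INS count.
    """
    params = params or OriginParams()
    g = _as_genome(genome)
    if index is None:
        index = GenomeKmerIndex(g, params.seed_k)
    matrix = {d: {r: 0 for r in ("PCG", "TE", "IR")} for d in ("PCG", "TE", "IR")}
    statuses = {s: 0 for s in ORIGIN_STATUSES}
    origins: list[InsertionOrigin] = []
    n_intra = 0
    n_resolved = 0
    for rec in calls:
        if rec.sv_type != "INS":
            continue
        if not rec.inserted_seq:
            statuses["no_hit"] += 1
            origins.append(InsertionOrigin(record_id=rec.id, status="no_hit",
                                           reason="no inserted sequence"))
            continue
        origin = find_origin(
            rec.inserted_seq, g, rec.chrom, rec.start, params,
            index=index, record_id=rec.id,
        )
        if origin.status == "resolved":
            origin = classify_origin(origin, ann, rec, params)
            recipient = assign_element(rec, ann).element_class
            matrix[origin.donor_element_class][recipient] += 1
            n_resolved += 1
            n_intra += bool(origin.intrachromosomal)
        statuses[origin.status] += 1
        origins.append(origin)
    return {
        "sample_id": calls.sample_id,
        "n_insertions": sum(statuses.values()),
        "status_counts": statuses,
        "donor_recipient_matrix": matrix,
        "intrachromosomal_fraction": (n_intra / n_resolved) if n_resolved else 0.0,
        "origins": origins,
    }


def write_origins_tsv(summary: dict, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["record_id", "status", "donor_chrom", "donor_start",
                    "donor_end", "strand", "identity", "query_coverage",
                    "donor_element_class", "donor_te_superfamily",
                    "intrachromosomal", "truncated_te"])
        for o in summary["origins"]:
            w.writerow([
                o.record_id, o.status, o.donor_chrom or ".",
                o.donor_start if o.donor_start is not None else ".",
                o.donor_end if o.donor_end is not None else ".",
                o.donor_strand or ".",
                f"{o.identity:.4f}" if o.identity is not None else ".",
                f"{o.query_coverage:.4f}" if o.query_coverage is not None else ".",
                o.donor_element_class or ".", o.donor_te_superfamily or ".",
                "." if o.intrachromosomal is None else int(o.intrachromosomal),
                "." if o.truncated_te is None else int(o.truncated_te),
            ])
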
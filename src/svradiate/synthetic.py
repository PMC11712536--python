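"""Hermetic synthetic genome + SV scenario generator with truth manifests.

The generator emulates the statistical structure of a long-read SV study
of irradiated Arabidopsis: a small multi-chromosome genome whose central
centromeric/pericentromeric zone is built from a mutated 180-bp tandem
repeat and densely annotated with transposable elements, chromosome arms
carrying protein-coding genes, chromatin states (CS8/CS9 over the
centromeric zone, CS1–CS7 over arms) and HOT regions; three untreated
replicate call sets sharing a configurable core of pedigree SVs plus
replicate-private calls; and treated call sets composed of the pedigree
calls plus implanted radiation-induced calls.

Implanted deletions are *mismatch-guarded*: the reference sequence is
rewritten at each junction so that the junction microhomology equals the
planned value exactly (the copied tract extends across the junction and
the flanking bases are forced to differ), making parameter-recovery
checks sharp.  Insertions copy a donor segment — optionally a truncated
TE, optionally reverse-complemented, with an intrachromosomal bias —
from the chromosome arms.  Categorical plans (SV-type mix, element mix,
microhomology spectrum) are allocated exactly by largest remainder and
shuffled, so recovered distributions equal the plan, not a multinomial
draw of it.

All randomness flows from the single scenario seed; identical specs
produce byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable

import numpy as np
from Bio.Seq import reverse_complement
from intervaltree import IntervalTree

from .annotation import GenomeAnnotation, derive_ir
from .core import SVCallSet, SVRecord, write_sv_vcf
from .repair import ReferenceGenome

BASES = "ACGT"
TE_SUPERFAMILIES = ("LTR/Gypsy", "LTR/Copia", "MuDR", "DNA/En-Spm",
                    "LINE/L1", "RC/Helitron")
TE_SUPERFAMILY_WEIGHTS = (0.35, 0.20, 0.15, 0.10, 0.10, 0.10)

#: padding around every implant so that no two implants can ever satisfy
#: the ±50 bp identity rule, even after emission jitter
IMPLANT_PAD = 200


@dataclass
class ScenarioSpec:
    """Study-condition parameters for one synthetic scenario.

    Defaults emulate the study's structure at desk scale: 3 chromosomes
    of 150 kb with a 30% centromeric zone, TE-dense centromeres
    (55% bp) versus arms (15% bp), gene-rich arms (35% bp), 60 pedigree
    SVs with half shared by all three untreated replicates, and 40
    induced SVs per treated sample.  The SV-type mix is INDEL-dominated,
    the deletion microhomology spectrum is NHEJ-dominant with a short
    MMEJ tail and no SSA tract, and insertion donors are drawn
    intrachromosomally 80% of the time with half the TE donors truncated.
    """

    seed: int
    n_chromosomes: int = 3
    chrom_length: int = 150_000
    centromere_fraction: float = 0.30
    te_density_arm: float = 0.15
    te_density_cen: float = 0.55
    pcg_density_arm: float = 0.35
    pcg_density_cen: float = 0.05
    n_pedigree_sv: int = 60
    n_induced_sv: int = 40
    sv_type_mix: dict = field(default_factory=lambda: {
        "DEL": 0.40, "INS": 0.40, "DUP": 0.10, "INV": 0.05, "INVDUP": 0.05,
    })
    deletion_mh_spectrum: dict = field(default_factory=lambda: {
        0: 0.45, 1: 0.15, 2: 0.08, 3: 0.08, 4: 0.08,
        5: 0.06, 6: 0.05, 8: 0.03, 10: 0.02,
    })
    element_mix: dict = field(default_factory=lambda: {
        "TE": 0.50, "IR": 0.35, "PCG": 0.15,
    })
    donor_element_mix: dict = field(default_factory=lambda: {
        "TE": 0.50, "IR": 0.40, "PCG": 0.10,
    })
    intrachromosomal_bias: float = 0.80
    truncation_fraction: float = 0.50
    revcomp_fraction: float = 0.25
    replicate_core_fraction: float = 0.50
    jitter_sd: int = 10
    false_negative_rate: float = 0.0
    n_false_positives: int = 0
    treated_samples: list = field(default_factory=lambda: [("WT", "UV_B")])
    match_tolerance: int = 50

    def __post_init__(self) -> None:
        for name in ("centromere_fraction", "te_density_arm", "te_density_cen",
                     "pcg_density_arm", "pcg_density_cen", "intrachromosomal_bias",
                     "truncation_fraction", "revcomp_fraction",
                     "replicate_core_fraction", "false_negative_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("sv_type_mix", "deletion_mh_spectrum", "element_mix",
                     "donor_element_mix"):
            total = sum(getattr(self, name).values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{name} proportions must sum to 1, got {total}")
        if self.te_density_arm + self.pcg_density_arm > 0.85:
            raise ValueError("arm TE+PCG densities exceed placement capacity")
        if self.te_density_cen + self.pcg_density_cen > 0.85:
            raise ValueError("centromeric TE+PCG densities exceed capacity")


def allocate_counts(n: int, proportions: dict) -> dict:
    """Exact largest-remainder allocation of n items to categories."""
    keys = list(proportions)
    raw = {k: n * proportions[k] for k in keys}
    counts = {k: int(raw[k]) for k in keys}
    remainder = n - sum(counts.values())
    by_frac = sorted(keys, key=lambda k: (-(raw[k] - counts[k]), str(k)))
    for k in by_frac[:remainder]:
        counts[k] += 1
    return counts


# ---------------------------------------------------------------------------
# genome

@dataclass
class SyntheticGenome:
    """In-memory toy genome plus its annotation interval layers."""

    chrom_lengths: dict
    seqs: dict  # chrom -> bytearray
    pcg: list   # (chrom, start0, end0)
    te: list    # (chrom, start0, end0, superfamily)
    cs: list    # (chrom, start0, end0, label)
    centromeric: list  # (chrom, start0, end0)
    hot: list   # (chrom, start0, end0)

    def sequence(self, chrom: str) -> str:
        return self.seqs[chrom].decode()

    def reference(self) -> ReferenceGenome:
        return ReferenceGenome({c: self.sequence(c) for c in self.seqs})

    def annotation(self) -> GenomeAnnotation:
        def layer(items, with_label=False):
            trees = {c: IntervalTree() for c in self.chrom_lengths}
            for item in items:
                chrom, s, e = item[0], item[1], item[2]
                data = item[3] if with_label and len(item) > 3 else None
                trees[chrom].addi(s, e, data)
            return trees

        pcg = layer(self.pcg)
        te = layer(self.te, with_label=True)
        return GenomeAnnotation(
            chrom_lengths=dict(self.chrom_lengths),
            pcg=pcg,
            te=te,
            ir=derive_ir(self.chrom_lengths, pcg, te),
            cs=layer(self.cs, with_label=True),
            centromeric=layer(self.centromeric),
            hot=layer(self.hot),
        )

    def layer_bp(self, layer: str) -> int:
        return sum(item[2] - item[1] for item in getattr(self, layer))

    def write(self, out_dir: str | Path) -> dict:
        """Write FASTA / GFF3 / BEDs / chrom.sizes; returns the path map."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta": out_dir / "genome.fa",
            "gff": out_dir / "annotation.gff3",
            "cs_bed": out_dir / "chromatin_states.bed",
            "centromere_bed": out_dir / "centromeres.bed",
            "hot_bed": out_dir / "hot_regions.bed",
            "chrom_sizes": out_dir / "chrom.sizes",
        }
        with open(paths["fasta"], "w") as fh:
            for chrom in sorted(self.seqs):
                fh.write(f">{chrom}\n")
                seq = self.sequence(chrom)
                for i in range(0, len(seq), 80):
                    fh.write(seq[i:i + 80] + "\n")
        with open(paths["chrom_sizes"], "w") as fh:
            for chrom in sorted(self.chrom_lengths):
                fh.write(f"{chrom}\t{self.chrom_lengths[chrom]}\n")
        with open(paths["gff"], "w") as fh:
            fh.write("##gff-version 3\n")
            features = (
                [(c, s, e, "gene", f"ID=gene{idx:05d}")
                 for idx, (c, s, e) in enumerate(self.pcg)]
                + [(c, s, e, "transposable_element",
                    f"ID=te{idx:05d};superfamily={fam}")
                   for idx, (c, s, e, fam) in enumerate(self.te)]
            )
            for c, s, e, ftype, attrs in sorted(features):
                fh.write(f"{c}\tsynthetic\t{ftype}\t{s + 1}\t{e}\t.\t+\t.\t{attrs}\n")
        for key, items in (("cs_bed", self.cs),
                           ("centromere_bed", self.centromeric),
                           ("hot_bed", self.hot)):
            with open(paths[key], "w") as fh:
                for item in sorted(items):
                    chrom, s, e = item[0], item[1], item[2]
                    label = item[3] if len(item) > 3 else key.split("_")[0]
                    fh.write(f"{chrom}\t{s}\t{e}\t{label}\n")
        return {k: str(v) for k, v in paths.items()}


def _random_seq(rng: np.random.Generator, n: int) -> bytearray:
    lut = np.frombuffer(BASES.encode(), dtype=np.uint8)
    return bytearray(lut[rng.integers(0, 4, n)].tobytes())


def _place_intervals(
    rng: np.random.Generator,
    zones: list,
    target_bp: int,
    len_range: tuple,
    occupied: IntervalTree,
    min_len: int = 60,
) -> list:
    """Place non-overlapping intervals totalling ``target_bp`` within zones.

    The final interval is clipped so the placed total lands on the target
    (within ``min_len``); placement is rejection sampling against the
    shared occupancy tree.
    """
    placed = []
    total = 0
    attempts = 0
    max_attempts = 200 + 40 * max(1, target_bp // max(len_range[0], 1))
    zone_spans = [(s, e) for s, e in zones if e - s > len_range[0] + 20]
    if not zone_spans:
        return placed
    zone_weights = np.array([e - s for s, e in zone_spans], dtype=float)
    zone_weights /= zone_weights.sum()
    while total < target_bp - min_len and attempts < max_attempts:
        attempts += 1
        zi = rng.choice(len(zone_spans), p=zone_weights)
        zs, ze = zone_spans[zi]
        length = int(rng.integers(len_range[0], len_range[1] + 1))
        remaining = target_bp - total
        if remaining < length:
            length = max(min_len, remaining)
        if ze - zs <= length + 2:
            continue
        start = int(rng.integers(zs, ze - length))
        if occupied.overlap(start - 1, start + length + 1):
            continue
        occupied.addi(start, start + length)
        placed.append((start, start + length))
        total += length
    return placed


def generate_genome(spec: ScenarioSpec) -> SyntheticGenome:
    """Build the toy genome and all annotation layers, deterministically."""
    rng = np.random.default_rng(spec.seed)
    L = spec.chrom_length
    chrom_lengths = {}
    seqs = {}
    pcg, te, cs, cen_layer, hot = [], [], [], [], []
    for ci in range(1, spec.n_chromosomes + 1):
        chrom = f"Chr{ci}"
        chrom_lengths[chrom] = L
        seq = _random_seq(rng, L)

        cen_len = int(round(spec.centromere_fraction * L))
        cen_s = (L - cen_len) // 2
        cen_e = cen_s + cen_len
        cen_layer.append((chrom, cen_s, cen_e))
        # 180-bp tandem repeat across the centromeric zone, each copy
        # carrying ~2% point mutations
        unit = bytes(_random_seq(rng, 180))
        pos = cen_s
        while pos < cen_e:
            copy = bytearray(unit)
            n_mut = max(1, int(round(0.02 * len(copy))))
            for mi in rng.integers(0, len(copy), n_mut):
                copy[mi] = ord(BASES[int(rng.integers(0, 4))])
            chunk = copy[: min(len(copy), cen_e - pos)]
            seq[pos:pos + len(chunk)] = chunk
            pos += len(chunk)
        seqs[chrom] = seq

        arms = [(0, cen_s), (cen_e, L)]
        cen_zone = [(cen_s, cen_e)]
        arm_bp = L - cen_len
        occupied = IntervalTree()
        for zones, zone_bp, te_d, pcg_d in (
            (arms, arm_bp, spec.te_density_arm, spec.pcg_density_arm),
            (cen_zone, cen_len, spec.te_density_cen, spec.pcg_density_cen),
        ):
            for s, e in _place_intervals(
                rng, zones, int(te_d * zone_bp), (250, 1500), occupied
            ):
                fam = TE_SUPERFAMILIES[
                    int(rng.choice(len(TE_SUPERFAMILIES), p=TE_SUPERFAMILY_WEIGHTS))
                ]
                te.append((chrom, s, e, fam))
            for s, e in _place_intervals(
                rng, zones, int(pcg_d * zone_bp), (800, 3000), occupied
            ):
                pcg.append((chrom, s, e))

        # chromatin states: CS8/CS9 alternating over the centromeric zone,
        # CS1-CS7 tiling the arms
        pos = cen_s
        toggle = 0
        while pos < cen_e:
            end = min(pos + 4000, cen_e)
            cs.append((chrom, pos, end, "CS8" if toggle == 0 else "CS9"))
            toggle ^= 1
            pos = end
        for zs, ze in arms:
            pos = zs
            while pos < ze:
                end = min(pos + int(rng.integers(2000, 5001)), ze)
                cs.append((chrom, pos, end, f"CS{int(rng.integers(1, 8))}"))
                pos = end

        for _ in range(4):
            hlen = int(rng.integers(2000, 4001))
            zs, ze = arms[int(rng.integers(0, 2))]
            if ze - zs > hlen + 2:
                hs = int(rng.integers(zs, ze - hlen))
                hot.append((chrom, hs, hs + hlen))

    return SyntheticGenome(
        chrom_lengths=chrom_lengths, seqs=seqs, pcg=sorted(pcg),
        te=sorted(te), cs=sorted(cs), centromeric=sorted(cen_layer),
        hot=sorted(hot),
    )


# ---------------------------------------------------------------------------
# implanting

@dataclass
class TruthRecord:
    truth_id: str
    sv_type: str
    chrom: str
    start: int          # VCF 1-based POS (anchor for INS)
    end: int            # VCF END (== start for INS)
    length: int
    element_class: str
    cohort: str         # "pedigree" or "induced:<sample_id>"
    replicates: list = field(default_factory=list)
    mh_total: int | None = None
    inserted_seq: str | None = None
    donor_chrom: str | None = None
    donor_start: int | None = None   # 0-based half-open
    donor_end: int | None = None
    donor_strand: str | None = None
    donor_element_class: str | None = None
    donor_truncated_te: bool | None = None


@dataclass
class SyntheticTruth:
    records: list

    def by_cohort(self, cohort: str) -> list:
        return [r for r in self.records if r.cohort == cohort]

    def by_id(self, truth_id: str) -> TruthRecord:
        for r in self.records:
            if r.truth_id == truth_id:
                return r
        raise KeyError(truth_id)

    def ids(self, cohort: str | None = None) -> set:
        return {
            r.truth_id for r in self.records
            if cohort is None or r.cohort == cohort
        }

    def write(self, out_dir: str | Path) -> dict:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        json_path = out_dir / "truth.json"
        tsv_path = out_dir / "truth.tsv"
        rows = [asdict(r) for r in self.records]
        with open(json_path, "w") as fh:
            json.dump(rows, fh, sort_keys=True, indent=2)
            fh.write("\n")
        cols = list(rows[0]) if rows else []
        with open(tsv_path, "w") as fh:
            fh.write("\t".join(cols) + "\n")
            for row in rows:
                fh.write("\t".join(
                    ",".join(map(str, v)) if isinstance(v, list) else str(v)
                    for v in (row[c] for c in cols)
                ) + "\n")
        return {"truth_json": str(json_path), "truth_tsv": str(tsv_path)}


def _other_base(rng: np.random.Generator, *avoid: int) -> int:
    choices = [ord(b) for b in BASES if ord(b) not in avoid]
    return choices[int(rng.integers(0, len(choices)))]


class _Placer:
    """Shared placement bookkeeping across all implants."""

    def __init__(self, genome: SyntheticGenome, rng: np.random.Generator):
        self.genome = genome
        self.rng = rng
        self.occupied = {c: IntervalTree() for c in genome.chrom_lengths}
        ann = genome.annotation()
        self.by_class: dict[str, list] = {"PCG": [], "TE": [], "IR": []}
        self.cen = {c: None for c in genome.chrom_lengths}
        for chrom, s, e in genome.centromeric:
            self.cen[chrom] = (s, e)
        for chrom in genome.chrom_lengths:
            for iv in ann.pcg[chrom]:
                self.by_class["PCG"].append((chrom, iv.begin, iv.end))
            for iv in ann.te[chrom]:
                self.by_class["TE"].append((chrom, iv.begin, iv.end))
            for iv in ann.ir[chrom]:
                self.by_class["IR"].append((chrom, iv.begin, iv.end))
        for k in self.by_class:
            self.by_class[k].sort()
        # arm-only intervals (outside the centromeric zone) for donors
        self.arm_by_class = {
            k: [
                (c, s, e) for c, s, e in v
                if self.cen[c] is None or e <= self.cen[c][0] or s >= self.cen[c][1]
            ]
            for k, v in self.by_class.items()
        }

    def is_free(self, chrom: str, s: int, e: int) -> bool:
        return not self.occupied[chrom].overlap(s - IMPLANT_PAD, e + IMPLANT_PAD)

    def reserve(self, chrom: str, s: int, e: int) -> None:
        self.occupied[chrom].addi(s - IMPLANT_PAD, e + IMPLANT_PAD)

    def max_span(self, element: str, margin: int = 60) -> int:
        spans = [e - s for _, s, e in self.by_class[element]]
        return (max(spans) - 2 * margin - 10) if spans else 0

    def place_span(self, element: str, length: int, margin: int = 60,
                   retries: int = 400) -> tuple:
        """A free [s, e) of ``length`` bp fully inside an ``element`` interval."""
        candidates = [
            iv for iv in self.by_class[element]
            if iv[2] - iv[1] >= length + 2 * margin
        ]
        if not candidates:
            raise RuntimeError(
                f"no {element} interval can hold a {length} bp implant — "
                "lower the SV count or sizes"
            )
        for _ in range(retries):
            chrom, is_, ie = candidates[int(self.rng.integers(0, len(candidates)))]
            s = int(self.rng.integers(is_ + margin, ie - margin - length + 1))
            if self.is_free(chrom, s, s + length):
                self.reserve(chrom, s, s + length)
                return chrom, s, s + length
        raise RuntimeError(
            f"could not place a {length} bp implant in {element} after "
            f"{retries} retries — lower the SV count"
        )

    def place_anchor(self, element: str, retries: int = 400) -> tuple:
        chrom, s, e = self.place_span(element, 1, margin=20, retries=retries)
        return chrom, s


def _place_with_backoff(placer: "_Placer", element: str, length: int,
                        lo: int) -> tuple:
    """place_span with geometric length backoff when space runs short."""
    while True:
        try:
            return placer.place_span(element, length) + (length,)
        except RuntimeError:
            if length <= lo:
                raise
            length = max(lo, length // 2)


def implant_svs(genome: SyntheticGenome, spec: ScenarioSpec) -> SyntheticTruth:
    """Implant all planned SVs into the genome; returns the truth manifest.

    Deletion junctions are rewritten in the reference so the measured
    microhomology equals the plan exactly; insertion sequences are
    extracted from the final (rewritten) genome.
    """
    rng = np.random.default_rng(spec.seed + 1)
    placer = _Placer(genome, rng)

    cohorts = (["pedigree"] * spec.n_pedigree_sv
               + [f"induced:{g}_{t}" for g, t in spec.treated_samples
                  for _ in range(spec.n_induced_sv)])
    n_total = len(cohorts)

    type_counts = allocate_counts(n_total, spec.sv_type_mix)
    types = [t for t, c in sorted(type_counts.items()) for _ in range(c)]
    rng.shuffle(types)
    elem_counts = allocate_counts(n_total, spec.element_mix)
    elements = [k for k, c in sorted(elem_counts.items()) for _ in range(c)]
    rng.shuffle(elements)
    n_del = sum(1 for t in types if t == "DEL")
    mh_counts = allocate_counts(n_del, spec.deletion_mh_spectrum)
    mh_values = [m for m, c in sorted(mh_counts.items()) for _ in range(c)]
    rng.shuffle(mh_values)

    records: list[TruthRecord] = []
    pending_ins: list[tuple] = []
    mh_iter = iter(mh_values)
    for i, (cohort, sv_type, element) in enumerate(zip(cohorts, types, elements)):
        truth_id = f"sv{i:04d}_{sv_type.lower()}"
        if sv_type == "DEL":
            m = next(mh_iter)
            lo = max(60, m + 30)
            hi = max(lo + 1, min(2000, placer.max_span(element)))
            length = int(rng.integers(lo, hi))
            chrom, s, e, length = _place_with_backoff(placer, element, length, lo)
            seq = genome.seqs[chrom]
            # rewrite: R[e:e+m] := R[s:s+m]; guard both boundaries
            if m > 0:
                seq[e:e + m] = seq[s:s + m]
            if seq[e + m] == seq[s + m]:
                seq[e + m] = _other_base(rng, seq[s + m])
            if seq[e - 1] == seq[s - 1]:
                seq[e - 1] = _other_base(rng, seq[s - 1])
            records.append(TruthRecord(
                truth_id=truth_id, sv_type="DEL", chrom=chrom,
                start=s, end=e, length=length,
                element_class=element, cohort=cohort, mh_total=m,
            ))
        elif sv_type == "INS":
            chrom, p = placer.place_anchor(element)
            records.append(TruthRecord(
                truth_id=truth_id, sv_type="INS", chrom=chrom,
                start=p, end=p, length=0,  # filled after donor extraction
                element_class=element, cohort=cohort,
            ))
            pending_ins.append((len(records) - 1, chrom, p))
        else:  # DUP / INV / INVDUP
            hi = max(101, min(1500, placer.max_span(element)))
            length = int(rng.integers(100, hi))
            chrom, s, e, length = _place_with_backoff(placer, element, length, 100)
            records.append(TruthRecord(
                truth_id=truth_id, sv_type=sv_type, chrom=chrom,
                start=s, end=e, length=length,
                element_class=element, cohort=cohort,
            ))

    # donors are extracted after every deletion-junction rewrite so the
    # inserted sequence matches the final reference
    for rec_idx, ins_chrom, ins_pos in pending_ins:
        donor_class_opts = list(spec.donor_element_mix)
        donor_class = donor_class_opts[int(rng.choice(
            len(donor_class_opts),
            p=[spec.donor_element_mix[k] for k in donor_class_opts],
        ))]
        intra = rng.random() < spec.intrachromosomal_bias
        placed = None
        for _ in range(400):
            candidates = [
                iv for iv in placer.arm_by_class[donor_class]
                if (iv[0] == ins_chrom) == intra
            ] or placer.arm_by_class[donor_class]
            if not candidates:
                break
            chrom, is_, ie = candidates[int(rng.integers(0, len(candidates)))]
            span = ie - is_
            truncated = None
            if donor_class == "TE":
                if span <= 600 and rng.random() > spec.truncation_fraction:
                    d_s, d_e = is_, ie        # full TE span
                    truncated = False
                else:
                    frac = 0.4 + 0.4 * rng.random()
                    dlen = max(40, int(frac * span))
                    dlen = min(dlen, int(0.90 * span), 600)
                    d_s = is_ + int(rng.integers(0, span - dlen + 1))
                    d_e = d_s + dlen
                    truncated = True
            else:
                dlen = int(rng.integers(40, min(250, max(41, span - 2)) + 1))
                if span <= dlen + 2:
                    continue
                d_s = is_ + int(rng.integers(1, span - dlen))
                d_e = d_s + dlen
            if chrom == ins_chrom and abs(d_s - ins_pos) < 500 + (d_e - d_s):
                continue
            placed = (chrom, d_s, d_e, truncated)
            break
        if placed is None:
            raise RuntimeError("could not place an insertion donor — lower counts")
        chrom, d_s, d_e, truncated = placed
        strand = "-" if rng.random() < spec.revcomp_fraction else "+"
        donor_seq = genome.sequence(chrom)[d_s:d_e]
        ins_seq = reverse_complement(donor_seq) if strand == "-" else donor_seq
        rec = records[rec_idx]
        rec.length = len(ins_seq)
        rec.inserted_seq = ins_seq
        rec.donor_chrom = chrom
        rec.donor_start = d_s
        rec.donor_end = d_e
        rec.donor_strand = strand
        rec.donor_element_class = donor_class
        rec.donor_truncated_te = truncated if donor_class == "TE" else None

    return SyntheticTruth(records=records)


# ---------------------------------------------------------------------------
# call-set emission

def _truth_to_record(t: TruthRecord, rng: np.random.Generator,
                     jitter: int, chrom_len: int) -> SVRecord:
    d = int(rng.integers(-jitter, jitter + 1)) if jitter > 0 else 0
    start = max(1, min(t.start + d, chrom_len - t.length - 1))
    end = start if t.sv_type == "INS" else start + (t.end - t.start)
    return SVRecord(
        id=t.truth_id, chrom=t.chrom, start=start, end=end,
        sv_type=t.sv_type, length=max(t.length, 1),
        inserted_seq=t.inserted_seq if t.sv_type == "INS" else None,
        read_support=int(rng.integers(10, 31)),
        min_supporting_read_length=int(rng.integers(5000, 20001)),
        mapping_quality=60.0,
    )


def emit_callsets(
    genome: SyntheticGenome,
    truth: SyntheticTruth,
    spec: ScenarioSpec,
    out_dir: str | Path,
    force: bool = False,
) -> dict:
    """Write per-sample VCFs (3 untreated replicates + treated samples).

    Replicate membership is assigned here (core fraction in all three
    replicates, the rest private to one) and recorded back into the truth
    manifest.  Per-record jitter is drawn independently per sample; since
    identity between two emitted copies of the same truth SV must survive
    the ±tolerance rule, 2×jitter_sd must not exceed the tolerance
    (override with ``force=True`` for stress scenarios).
    """
    if 2 * spec.jitter_sd > spec.match_tolerance and not force:
        raise ValueError(
            f"2×jitter_sd ({2 * spec.jitter_sd}) exceeds the matching tolerance "
            f"({spec.match_tolerance}); induced-call recovery would not be "
            "guaranteed.  Pass force=True for a stress scenario."
        )
    rng = np.random.default_rng(spec.seed + 2)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    pedigree = truth.by_cohort("pedigree")
    order = list(range(len(pedigree)))
    rng.shuffle(order)
    n_core = int(round(spec.replicate_core_fraction * len(pedigree)))
    for rank, idx in enumerate(order):
        if rank < n_core:
            pedigree[idx].replicates = [1, 2, 3]
        else:
            pedigree[idx].replicates = [int(rng.integers(1, 4))]

    samples = []
    for rep in (1, 2, 3):
        samples.append({
            "sample_id": f"WT_none_rep{rep}", "genotype": "WT",
            "treatment": "none", "replicate": rep,
            "truths": [t for t in pedigree if rep in t.replicates],
        })
    mutant_genotypes = sorted({g for g, _ in spec.treated_samples if g != "WT"})
    for g in mutant_genotypes:
        samples.append({
            "sample_id": f"{g}_none_rep1", "genotype": g,
            "treatment": "none", "replicate": 1,
            "truths": list(pedigree),
        })
    for g, t in spec.treated_samples:
        sid = f"{g}_{t}"
        samples.append({
            "sample_id": sid, "genotype": g, "treatment": t, "replicate": 1,
            "truths": list(pedigree) + truth.by_cohort(f"induced:{sid}"),
        })

    manifest = {"samples": [], "spec_seed": spec.seed}
    for sample in samples:
        recs = []
        for t in sample["truths"]:
            if spec.false_negative_rate > 0 and rng.random() < spec.false_negative_rate:
                continue
            recs.append(_truth_to_record(
                t, rng, spec.jitter_sd, genome.chrom_lengths[t.chrom]
            ))
        for fp in range(spec.n_false_positives):
            chrom = f"Chr{int(rng.integers(1, spec.n_chromosomes + 1))}"
            L = genome.chrom_lengths[chrom]
            s = int(rng.integers(1000, L - 3000))
            length = int(rng.integers(60, 1500))
            recs.append(SVRecord(
                id=f"fp_{sample['sample_id']}_{fp:03d}", chrom=chrom,
                start=s, end=s + length, sv_type="DEL", length=length,
                read_support=int(rng.integers(10, 31)),
                min_supporting_read_length=int(rng.integers(5000, 20001)),
                mapping_quality=60.0,
            ))
        callset = SVCallSet(
            sample_id=sample["sample_id"], genotype=sample["genotype"],
            treatment=sample["treatment"], replicate=sample["replicate"],
            records=recs,
        )
        vcf_path = out_dir / f"{sample['sample_id']}.vcf"
        write_sv_vcf(callset, vcf_path, chrom_lengths=genome.chrom_lengths)
        manifest["samples"].append({
            "sample_id": sample["sample_id"],
            "vcf": str(vcf_path),
            "genotype": sample["genotype"],
            "treatment": sample["treatment"],
            "replicate": sample["replicate"],
            "n_records": len(recs),
        })
    manifest.update(truth.write(out_dir))
    with open(out_dir / "samples.json", "w") as fh:
        json.dump(manifest, fh, sort_keys=True, indent=2)
        fh.write("\n")
    return manifest


def generate_scenario(spec: ScenarioSpec, out_dir: str | Path) -> dict:
    """Genome + implants + call sets in one call; returns the path manifest."""
    out_dir = Path(out_dir)
    genome = generate_genome(spec)
    truth = implant_svs(genome, spec)
    genome_paths = genome.write(out_dir)
    manifest = emit_callsets(genome, truth, spec, out_dir)
    manifest.update(genome_paths)
    manifest["truth"] = truth
    manifest["genome"] = genome
    return manifest
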
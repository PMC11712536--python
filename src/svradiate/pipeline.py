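"""Run configuration, validation and end-to-end orchestration.

A run is described by a YAML/dict manifest: reference and annotation
paths, the per-sample VCFs with their genotype/treatment/replicate
metadata, and the parameter blocks for each stage.  Control
relationships are data, not code: a treated wild-type sample is
subtracted against the pooled untreated wild-type replicates (the
pedigree pool), and a treated mutant sample against the untreated
same-genotype calls plus the treated wild-type calls.

``run_all`` executes filter → subtraction workflows → annotation →
repair classification → origin tracing → statistics, writing every
intermediate table, a canonical ``report.json`` and a checksum manifest.
Stage outputs are pure functions of (inputs, config), so reruns are
byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import algebra, annotation, origins, repair, stats
from .core import FilterParams, SVCallSet, filter_calls, parse_sv_vcf, size_table, write_sv_vcf

logger = logging.getLogger(__name__)


class ConfigurationError(ValueError):
    pass


@dataclass
class SampleSpec:
    sample_id: str
    vcf: str
    genotype: str = "WT"
    treatment: str = "none"
    replicate: int = 1


@dataclass
class RunConfig:
    reference: str
    gff: str
    cs_bed: str
    centromere_bed: str
    hot_bed: str
    chrom_sizes: str
    output_dir: str
    samples: list
    filter_params: FilterParams = field(default_factory=FilterParams)
    match_params: algebra.MatchParams = field(default_factory=algebra.MatchParams)
    repair_params: repair.RepairParams = field(default_factory=repair.RepairParams)
    origin_params: origins.OriginParams = field(default_factory=origins.OriginParams)
    seed: int = 0
    log_level: str = "INFO"


def _params_from(block: dict | None, cls):
    return cls(**(block or {}))


def validate_config(config: dict | str | Path) -> RunConfig:
    """Schema-check a run manifest and its control structure.

    Raises :class:`ConfigurationError` naming the problem: duplicate
    sample ids, unknown genotype/treatment, unreadable paths, a treated
    wild-type sample without untreated wild-type controls, or a treated
    mutant sample missing either its untreated same-genotype control or
    the treated wild-type sample for the same treatment.
    """
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    ann_block = config.get("annotation", {})
    try:
        samples = [SampleSpec(**s) for s in config["samples"]]
        run = RunConfig(
            reference=config["reference"],
            gff=ann_block["gff"],
            cs_bed=ann_block["chromatin_states"],
            centromere_bed=ann_block["centromeres"],
            hot_bed=ann_block["hot"],
            chrom_sizes=ann_block["chrom_sizes"],
            output_dir=config.get("output_dir", "svradiate_out"),
            samples=samples,
            filter_params=_params_from(config.get("filter"), FilterParams),
            match_params=_params_from(config.get("match"), algebra.MatchParams),
            repair_params=_params_from(config.get("repair"), repair.RepairParams),
            origin_params=_params_from(config.get("origin"), origins.OriginParams),
            seed=int(config.get("seed", 0)),
            log_level=str(config.get("log_level", "INFO")),
        )
    except (KeyError, TypeError) as exc:
        raise ConfigurationError(f"invalid run configuration: {exc}") from exc

    ids = [s.sample_id for s in run.samples]
    if len(ids) != len(set(ids)):
        raise ConfigurationError("duplicate sample_id in manifest")
    for s in run.samples:
        if s.genotype not in SVCallSet.GENOTYPES:
            raise ConfigurationError(f"unknown genotype {s.genotype!r} ({s.sample_id})")
        if s.treatment not in SVCallSet.TREATMENTS:
            raise ConfigurationError(f"unknown treatment {s.treatment!r} ({s.sample_id})")
    for path_name in ("reference", "gff", "cs_bed", "centromere_bed",
                      "hot_bed", "chrom_sizes"):
        p = getattr(run, path_name)
        if not Path(p).exists():
            raise ConfigurationError(f"{path_name} path not readable: {p}")
    for s in run.samples:
        if not Path(s.vcf).exists():
            raise ConfigurationError(f"sample VCF not readable: {s.vcf} ({s.sample_id})")

    wt_untreated = [s for s in run.samples
                    if s.genotype == "WT" and s.treatment == "none"]
    for s in run.samples:
        if s.treatment == "none":
            continue
        if s.genotype == "WT":
            if not wt_untreated:
                raise ConfigurationError(
                    f"treated WT sample {s.sample_id!r} has no untreated WT "
                    "(pedigree) controls in the manifest"
                )
        else:
            same_genotype = [c for c in run.samples
                            if c.genotype == s.genotype and c.treatment == "none"]
            if not same_genotype:
                raise ConfigurationError(
                    f"treated {s.genotype} sample {s.sample_id!r} is missing its "
                    f"untreated {s.genotype} control"
                )
            wt_same_treatment = [c for c in run.samples
                                 if c.genotype == "WT" and c.treatment == s.treatment]
            if not wt_same_treatment:
                raise ConfigurationError(
                    f"treated {s.genotype} sample {s.sample_id!r} is missing the "
                    f"WT {s.treatment} control"
                )
    return run


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_all(config: RunConfig | dict | str | Path) -> dict:
    """Execute the full pipeline; returns the report dict.

    Writes, under ``output_dir``: per-sample filtered VCFs and rejection
    tallies, induced-call VCFs with subtraction provenance, annotation
    and repair and origin TSVs, the Venn region table (when exactly three
    untreated wild-type replicates are present), ``report.json`` and
    ``manifest.json`` with checksums of every artifact.
    """
    if not isinstance(config, RunConfig):
        config = validate_config(config)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level, logging.INFO))

    genome = repair.ReferenceGenome(config.reference)
    ann = annotation.load_annotation(
        config.gff, config.cs_bed, config.centromere_bed,
        config.hot_bed, config.chrom_sizes,
    )

    # stage 1: parse + filter
    filtered: dict[str, SVCallSet] = {}
    for s in config.samples:
        try:
            raw = parse_sv_vcf(s.vcf, s.sample_id, s.genotype, s.treatment,
                               s.replicate)
        except Exception as exc:
            raise RuntimeError(f"stage=filter sample={s.sample_id}: {exc}") from exc
        flt = filter_calls(raw, config.filter_params)
        filtered[s.sample_id] = flt
        write_sv_vcf(flt, out / f"{s.sample_id}.filtered.vcf",
                     chrom_lengths=ann.chrom_lengths)
        with open(out / f"{s.sample_id}.filter_tally.tsv", "w") as fh:
            fh.write("criterion\trejected\n")
            for k, v in flt.rejection_tally.items():
                fh.write(f"{k}\t{v}\n")
        logger.info("filter: %s %d -> %d records", s.sample_id, len(raw), len(flt))

    wt_untreated = sorted(
        (s.sample_id for s in config.samples
         if s.genotype == "WT" and s.treatment == "none"),
    )
    pedigree_sets = [filtered[sid] for sid in wt_untreated]

    # stage 2: Venn of untreated replicates
    venn_dict = None
    if len(pedigree_sets) == 3:
        venn = algebra.venn_partition(*pedigree_sets, config.match_params)
        venn_dict = {
            "samples": wt_untreated,
            "region_counts": venn.region_counts,
            "n_components": venn.n_components,
            "n_inconsistent": venn.n_inconsistent,
        }
        with open(out / "venn.tsv", "w") as fh:
            fh.write("region\tcount\n")
            for region, count in venn.region_counts.items():
                fh.write(f"{region}\t{count}\n")

    # stage 3: subtraction workflows — which call set is analysed per sample
    analysed: dict[str, SVCallSet] = {}
    for s in config.samples:
        calls = filtered[s.sample_id]
        if s.treatment == "none":
            analysed[s.sample_id] = calls
            continue
        if s.genotype == "WT":
            controls = pedigree_sets
            induced = algebra.induced_sv_workflow(
                calls, controls, None, config.match_params)
        else:
            same_genotype = [filtered[c.sample_id] for c in config.samples
                             if c.genotype == s.genotype and c.treatment == "none"]
            wt_same = [filtered[c.sample_id] for c in config.samples
                       if c.genotype == "WT" and c.treatment == s.treatment]
            induced = algebra.induced_sv_workflow(
                calls, same_genotype, wt_same[0], config.match_params)
        analysed[s.sample_id] = induced
        write_sv_vcf(induced, out / f"{s.sample_id}.induced.vcf",
                     chrom_lengths=ann.chrom_lengths)
        with open(out / f"{s.sample_id}.subtraction.json", "w") as fh:
            json.dump({
                "provenance": induced.workflow_provenance,
                "removed": induced.subtraction_audit,
            }, fh, sort_keys=True, indent=2)
            fh.write("\n")
        logger.info("subtract: %s %d -> %d induced", s.sample_id,
                    len(calls), len(induced))

    # stages 4-6: annotation, repair, origins per analysed set
    kmer_index = origins.GenomeKmerIndex(genome, config.origin_params.seed_k)
    sample_tables: dict[str, dict] = {}
    for sid in sorted(analysed):
        calls = analysed[sid]
        dist = annotation.element_distribution(calls, ann)
        annotation.write_assignments_tsv(dist, out / f"{sid}.elements.tsv")
        annotation.write_circos_bed(calls, out / f"{sid}.circos.bed")
        rep = repair.repair_summary(calls, genome, config.repair_params)
        repair.write_repair_tsv(rep, out / f"{sid}.repair.tsv")
        orig = origins.origin_summary(calls, genome, ann, config.origin_params,
                                      index=kmer_index)
        origins.write_origins_tsv(orig, out / f"{sid}.origins.tsv")
        type_counts: dict[str, int] = {}
        for rec in calls:
            type_counts[rec.sv_type] = type_counts.get(rec.sv_type, 0) + 1
        sample_tables[sid] = {
            "sv_type_counts": type_counts,
            "size_table": size_table(calls),
            "element_distribution": dist,
            "repair_summary": rep,
            "origin_summary": orig,
        }

    report = stats.build_report(sample_tables, venn=venn_dict, out_dir=out)

    manifest = {
        "artifacts": {
            p.name: _sha256(p)
            for p in sorted(out.iterdir())
            if p.is_file() and p.name != "manifest.json"
        }
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, sort_keys=True, indent=2)
        fh.write("\n")
    return report
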
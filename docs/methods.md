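# Methods

## Scope and model of the data

The package operates downstream of SV calling: its inputs are per-sample
Sniffles-style VCFs (one call set per genotype × treatment × replicate),
a reference FASTA, a GFF3 with gene and transposable-element features,
and BED tracks for chromatin states, centromere/pericentromere windows
and HOT regions. Only the five SV classes DEL / INS / DUP / INV / INVDUP
are modelled; breakends and translocations are skipped on ingestion with
a logged count. `SVRecord` stores VCF conventions verbatim (POS, END,
signed SVLEN) so write→parse round-trips are field-exact; all sequence
access converts to 0-based half-open coordinates at the module boundary,
with the affected segment of a non-insertion SV being `R[start:end]` and
insertions occupying their 1-bp anchor.

## Call filtering

Four thresholds, all inclusive: SV length in [1 bp, 1,000,000 bp],
minimum supporting-read length ≥ 1,000 bp, mapping quality ≥ 20.
Inclusivity is a deliberate choice — "minimum mapping quality 20" is read
as "20 passes". Quality annotations absent from a VCF map to sentinel 0,
which fails the read-length and MAPQ floors; users ingesting VCFs without
those INFO keys must lower the corresponding thresholds explicitly.
Records failing several criteria are tallied once, under the first
failing criterion in the order length-min, length-max, read-length, MAPQ,
so tallies and survivors always sum to the input size. By default only
PASS/'.' FILTER lines are ingested (disable with `honor_filter=False`).

## Call identity, pairing, pooling, subtraction, Venn

Identity: same chromosome, same type, and |Δstart| ≤ 50 and |Δend| ≤ 50
(both breakpoints independently; length and inserted-sequence content are
not compared). The relation is symmetric but not transitive, so:

* **match_sets** resolves it to a one-to-one pairing greedily, closest
  pairs first (ascending |Δstart|+|Δend|, ties by (chrom, start, id));
  the interval-indexed implementation is required by its tests to equal a
  brute-force all-pairs oracle.
* **venn_partition** builds the undirected match graph over three
  replicate call sets and counts connected components per region; a
  component holding two records of one sample is flagged *inconsistent*
  but still counted once. With tolerance 0 and unique coordinates this
  degenerates to exact set algebra, which the tests verify.
* **pool** concatenates call sets without deduplication — a pooled
  baseline of replicates sized 248, 339 and 291 has 878 records even when
  calls are shared between replicates. This mirrors how a pedigree
  baseline is used in subtraction: any of the pooled copies can absorb a
  treated call, so deduplication would change nothing downstream while
  concatenation keeps the arithmetic transparent.
* **subtract** removes every target call matching any pooled control call
  and records which control removed it. The pedigree subtraction uses the
  same ±50 bp rule as replicate comparison (a flag switches to exact
  coordinates).
* **induced_sv_workflow** composes subtraction per the control design:
  wild-type treated ⊖ pooled untreated replicates; mutant treated ⊖
  (untreated same-genotype ∪ wild-type treated). The control structure is
  validated from the sample manifest, not hard-coded.

## Element and chromatin annotation

The genome is partitioned into PCG ∪ TE ∪ IR, with IR derived per
chromosome as the complement of the union of the other two (so the three
layers tile every chromosome exactly — an invariant the tests check).
Each SV gets exactly one element class by maximal bp overlap of its
affected interval; ties use precedence TE > PCG > IR, chosen because
repeats are the analytic focus, and exposed as configuration. Centromeric
context follows the interval midpoint (an SV spanning the boundary
belongs where its centre lies); HOT context is any-overlap; chromatin
state is maximal overlap, absent where no state covers the interval.
The genome background for enrichment tests is the bp fraction of each
layer; a count-based alternative is also emitted.

## Junction microhomology and repair labels

For a deletion `[s, e)` on reference `R`, the right extension is the
largest `k ≤ 50` with `R[s..s+k) = R[e..e+k)` and the left extension the
largest `j ≤ 50` with `R[s−j..s) = R[e−j..e)`; `mh_total = j + k`. This
is the standard breakpoint-ambiguity definition: shifting the reported
breakpoints anywhere along the homology tract leaves `mh_total` unchanged
(a property test exercises 500 random junctions), which makes the
measurement robust to caller-dependent breakpoint placement. Summing both
sides is a documented choice; comparison is case-insensitive (soft
masking ignored), only exact identity extends the tract, and any N stops
it.

Labels: NHEJ for mh ≤ 1, MMEJ for 2–19 bp, SSA candidate for ≥ 20 bp.
The MMEJ band reconciles the conventional 2–20 bp microhomology range
with the 20–25 bp tract lengths attributed to canonical single-strand
annealing; all three boundaries are `RepairParams` fields since the
literature draws them differently. "Undetermined" is operationalised as
a flank truncated at a chromosome end or containing any N (max N
fraction configurable) — a reference-based stand-in for per-read quality,
which this pipeline does not see.

## Insertion-origin tracing

The donor search is a self-contained seed-and-extend local aligner:
exact 15-mer seeds on both strands (stride k/3), seeds grouped by
(chromosome, strand, diagonal band), each candidate window aligned with
an affine-gap local alignment (match +1, mismatch −2, gap open −4, gap
extend −1 — near blastn defaults; the extension itself uses
`Bio.Align.PairwiseAligner`). Hits overlapping the insertion's own
±100 bp neighbourhood are discarded (self-exclusion). The best hit is
*resolved* only if it passes identity ≥ 0.8 and query coverage ≥ 0.8 and
strictly outscores the best hit at any other locus; equal-best loci give
*ambiguous*. Strict-outscore disambiguation replaces E-value ranking,
which is uninformative on kilobase-scale test genomes. A resolved donor
overlapping a TE without covering ≥ 95% of its span is flagged a
truncated TE — the signature separating sequence capture from
transposition-like events; the 95% cutoff is configurable.

## Statistical tests

Pearson chi-squared is computed from first principles, goodness-of-fit
(`E = N·p`, df = k−1) and homogeneity (`E_ij = r_i c_j / N`,
df = (r−1)(c−1)), with p from the upper chi-squared tail and a warning
when any expected cell is below 5. Mann-Whitney U uses midranks, the
tie-corrected variance and a 0.5 continuity correction on the normal
approximation; U is reported for the first sample (U = 0 when it is
wholly smaller). Both are validated against an independent reference
implementation to 1e−9 on the statistic and 1e−6 on p. P values are
reported per panel without multiple-testing correction, matching
common practice for figure-level exact P values; Benjamini-Hochberg
adjustment is available as an explicit helper.

## Synthetic scenarios and what they do (not) show

The generator's defaults define the study conditions at desk scale:
3 chromosomes × 150 kb; a 30% central centromeric zone built from a
per-chromosome 180-bp tandem repeat with ~2% per-copy mutations (the
Arabidopsis centromeric repeat scale, exercising repeat-aware edge cases
in origin search); TE densities 15% (arms) / 55% (centromeric zone) and
PCG densities 35% / 5% by bp; CS8/CS9 tiling the centromeric zone and
CS1–CS7 the arms; 4 HOT regions per chromosome. 60 pedigree SVs with a
50% three-replicate core, 40 induced SVs per treated sample; SV-type mix
40/40/10/5/5% (DEL/INS/DUP/INV/INVDUP), INDEL-dominated as in long-read
plant data; deletion microhomology spectrum 60% NHEJ-range (0–1 bp) with
a decaying MMEJ tail to 10 bp and no SSA tract; insertion donors 80%
intrachromosomal, half of TE donors truncated, 25% reverse-complemented.
These sizes keep the default test suite and the acceptance script in the
tens of seconds while leaving every distribution multi-category.

Categorical plans are allocated by largest remainder and shuffled, so
recovered distributions equal the plan exactly rather than a multinomial
draw. Deletion junctions are *mismatch-guarded*: the reference is
rewritten so the copied tract crosses the junction for exactly the
planned length and the flanking bases on both sides are forced to
mismatch — truth microhomology is exact by construction, which is what
lets recovery tests assert equality instead of approximation. All
implants are separated by ≥ 200 bp of padding so no two distinct
implants can ever satisfy the ±50 bp identity rule, even after jitter.

Emission draws per-record coordinate jitter independently per sample, so
two emitted copies of one truth SV can differ by up to 2×`jitter_sd`;
the generator therefore refuses (without `force=True`) any scenario with
2×`jitter_sd` above the matching tolerance, and the default jitter of
10 bp keeps the subtraction-recovery contract intact. Larger jitter is an
explicit stress mode in which exact recovery is no longer guaranteed.

What passing tests on these fixtures show: the algebra, measurement and
classification machinery is exact under its own assumptions. What they do
not show: behaviour under real Nanopore artefacts — imprecise breakpoints
beyond the tolerance, segmental duplications confounding donor search,
caller-specific SVLEN conventions, somatic mosaicism, or coverage-driven
false negatives. The false-negative/false-positive knobs exist for stress
testing but default to zero.

## Numerical and degenerate-input choices

Quartiles use linear interpolation (the common box-plot convention).
Deterministic ordering everywhere: records sort by (chrom, start, end,
type, id) and all tie-breaks are lexicographic, so every stage is a pure
function of (inputs, config, seed) and `report.json` is byte-identical
across reruns (sorted keys, repr-stable floats). Empty inputs are legal
throughout (empty filter output, zero deletions, zero insertions); a
single-category chi-squared or an all-tied rank test returns p = 1 with
a warning rather than an error. All generator randomness flows from the
single scenario seed through separate derived streams for genome,
implantation and emission.

## Known limitations

No BND/translocation support; no probabilistic multi-caller merging; no
filler-DNA detection at NHEJ junctions or SD-MMEJ synthesis-tract
inference; origin search targets the provided reference only (no
external databases, no eccDNA logic); chromatin states and HOT regions
are inputs, never inferred. The one-to-one greedy pairing and the
connected-component Venn are documented resolutions of a non-transitive
identity rule — other resolutions (e.g. ILP matching) could partition
borderline cases differently.
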
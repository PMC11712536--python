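"""Tolerance-based identity, pairing, pooling, subtraction, Venn."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from svradiate import algebra
from svradiate.algebra import (
    MatchParams,
    match_sets,
    pool,
    records_match,
    subtract,
    venn_partition,
)
from svradiate.core import SVRecord

from conftest import make_callset, make_record


def brute_force_pairing(A, B, params):
    """O(n·m) oracle: enumerate every pair, apply the same greedy rule."""
    cands = []
    for a in A:
        for b in B:
            if records_match(a, b, params):
                cands.append((a, b))
    cands.sort(key=lambda ab: (
        abs(ab[0].start - ab[1].start) + abs(ab[0].end - ab[1].end),
        ab[0].chrom, ab[0].start, ab[0].id, ab[1].id,
    ))
    used_a, used_b, pairs = set(), set(), []
    for a, b in cands:
        if a.id in used_a or b.id in used_b:
            continue
        used_a.add(a.id)
        used_b.add(b.id)
        pairs.append((a.id, b.id))
    return pairs


def random_callset(rng, n, sample_id, chroms=("Chr1", "Chr2"), span=6000):
    recs = []
    for i in range(n):
        sv_type = ["DEL", "INS", "DUP"][int(rng.integers(0, 3))]
        start = int(rng.integers(100, span))
        length = int(rng.integers(20, 400))
        end = start if sv_type == "INS" else start + length
        recs.append(make_record(
            id=f"{sample_id}_{i}", chrom=chroms[int(rng.integers(0, len(chroms)))],
            start=start, end=end, sv_type=sv_type, length=length,
        ))
    return make_callset(recs, sample_id=sample_id)


class TestRecordsMatch:
    def test_both_offsets_within_tolerance(self):
        a = make_record(id="a", start=100, end=500)
        b = make_record(id="b", start=140, end=460)
        assert records_match(a, b, MatchParams(tolerance=50))
        assert not records_match(a, b, MatchParams(tolerance=39))

    def test_type_mismatch_never_matches(self):
        a = make_record(id="a", start=100, end=500, sv_type="DEL")
        b = make_record(id="b", start=100, sv_type="INS")
        assert not records_match(a, b, MatchParams(tolerance=50))

    @given(
        start=st.integers(1, 10_000), end_off=st.integers(0, 5000),
        tol=st.integers(0, 100), d1=st.integers(-120, 120),
        d2=st.integers(-120, 120),
    )
    @settings(max_examples=200, derandomize=True)
    def test_reflexive_and_symmetric(self, start, end_off, tol, d1, d2):
        params = MatchParams(tolerance=tol)
        a = make_record(id="a", start=start, end=start + end_off,
                        length=max(end_off, 1))
        b_start = max(1, start + d1)
        b = make_record(id="b", start=b_start, end=b_start + max(0, end_off + d2),
                        length=max(end_off + d2, 1))
        assert records_match(a, a, params)
        assert records_match(a, b, params) == records_match(b, a, params)


class TestMatchSets:
    def test_greedy_prefers_nearest(self):
        A = make_callset([make_record(id="a", start=1000, end=1500)], "A")
        B = make_callset([
            make_record(id="b10", start=1010, end=1510),
            make_record(id="b40", start=1040, end=1540),
        ], "B")
        pairing = match_sets(A, B)
        assert pairing.pairs == [("a", "b10", 10, 10)]
        assert pairing.unmatched_B == ["b40"]

    def test_disjoint_chromosomes_unmatched(self):
        A = make_callset([make_record(id="a", chrom="Chr1")], "A")
        B = make_callset([make_record(id="b", chrom="Chr2")], "B")
        pairing = match_sets(A, B)
        assert pairing.pairs == []
        assert pairing.unmatched_A == ["a"] and pairing.unmatched_B == ["b"]

    @pytest.mark.parametrize("seed", range(8))
    def test_equals_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        A = random_callset(rng, int(rng.integers(20, 200)), "A")
        B = random_callset(rng, int(rng.integers(20, 200)), "B")
        params = MatchParams(tolerance=50)
        got = [(a, b) for a, b, _, _ in match_sets(A, B, params).pairs]
        assert got == brute_force_pairing(list(A), list(B), params)


class TestPool:
    def test_worked_example_sizes_sum(self):
        sizes = (248, 339, 291)
        sets = []
        for si, n in enumerate(sizes):
            rng = np.random.default_rng(100 + si)
            sets.append(random_callset(rng, n, f"rep{si + 1}", span=100_000))
        pooled = pool(sets)
        assert len(pooled) == 878

    def test_pool_of_one_is_identity_and_duplicates_rejected(self):
        s = make_callset([make_record(id="a")], "s")
        assert len(pool([s])) == 1
        with pytest.raises(ValueError, match="duplicate sample_id"):
            pool([s, s])


class TestSubtract:
    def test_self_subtraction_empty_and_empty_controls_identity(self):
        A = make_callset([make_record(id=f"a{i}", start=1000 * (i + 1),
                                      end=1000 * (i + 1) + 100)
                          for i in range(5)], "A")
        assert len(subtract(A, [A.with_records(A.records)])) == 0
        assert list(subtract(A, [])) == list(A)

    def test_anti_monotone_in_controls(self):
        rng = np.random.default_rng(3)
        A = random_callset(rng, 60, "A")
        C1 = random_callset(rng, 40, "C1")
        C2 = random_callset(rng, 40, "C2")
        few = subtract(A, [C1])
        more = subtract(A, [C1, C2])
        assert more.ids() <= few.ids() <= A.ids()

    def test_audit_names_removing_control(self):
        A = make_callset([make_record(id="a", start=1000, end=1500)], "A")
        C = make_callset([make_record(id="c", start=1010, end=1510)], "C")
        out = subtract(A, [C])
        assert len(out) == 0
        assert out.subtraction_audit == {"a": "c"}


class TestVenn:
    def test_identical_singletons_all_shared(self):
        sets = [make_callset([make_record(id=f"x{i}")], f"s{i}") for i in range(3)]
        part = venn_partition(*sets)
        assert part.region_counts["ABC"] == 1
        assert part.n_components == 1
        assert sum(part.region_counts.values()) == part.n_components

    def test_tolerance_zero_equals_exact_set_algebra(self):
        rng = np.random.default_rng(9)
        # integer-distinct coordinates: draw unique starts per record
        starts = rng.choice(np.arange(100, 100_000, 7), 90, replace=False)
        keys = [("Chr1", int(s), int(s) + 100, "DEL") for s in starts]
        groups = [keys[:40], keys[25:65], keys[50:90]]
        sets = []
        for gi, group in enumerate(groups):
            recs = [make_record(id=f"g{gi}_{i}", chrom=c, start=s, end=e,
                                sv_type=t)
                    for i, (c, s, e, t) in enumerate(group)]
            sets.append(make_callset(recs, f"g{gi}"))
        part = venn_partition(*sets, MatchParams(tolerance=0))
        ka, kb, kc = (set(g) for g in groups)
        expected = {
            "A": len(ka - kb - kc), "B": len(kb - ka - kc), "C": len(kc - ka - kb),
            "AB": len((ka & kb) - kc), "AC": len((ka & kc) - kb),
            "BC": len((kb & kc) - ka), "ABC": len(ka & kb & kc),
        }
        assert part.region_counts == expected
        assert part.n_inconsistent == 0

    def test_replicate_core_recovered(self, default_scenario):
        from svradiate.core import parse_sv_vcf

        truth = default_scenario["truth"]
        out = default_scenario["out_dir"]
        reps = [parse_sv_vcf(out / f"WT_none_rep{r}.vcf", f"rep{r}",
                             replicate=r) for r in (1, 2, 3)]
        part = venn_partition(*reps)
        n_core = sum(1 for t in truth.by_cohort("pedigree")
                     if t.replicates == [1, 2, 3])
        assert part.region_counts["ABC"] == n_core
        assert sum(part.region_counts.values()) == part.n_components


class TestInducedWorkflow:
    def test_wt_recovery_equals_truth(self, default_scenario):
        from svradiate.core import parse_sv_vcf

        truth = default_scenario["truth"]
        out = default_scenario["out_dir"]
        reps = [parse_sv_vcf(out / f"WT_none_rep{r}.vcf", f"rep{r}",
                             replicate=r) for r in (1, 2, 3)]
        treated = parse_sv_vcf(out / "WT_UV_B.vcf", "WT_UV_B",
                               treatment="UV_B")
        induced = algebra.induced_sv_workflow(treated, reps)
        assert induced.ids() == truth.ids("induced:WT_UV_B")

    def test_treated_equals_control_yields_empty(self):
        rng = np.random.default_rng(5)
        A = random_callset(rng, 30, "A")
        assert len(algebra.induced_sv_workflow(A, A.with_records(A.records))) == 0

    def test_mutant_requires_wt_treated_control(self):
        treated = make_callset([make_record(id="a")], "atm_p",
                               genotype="atm", treatment="protons")
        ctrl = make_callset([make_record(id="c", start=90_000, end=90_100)],
                            "atm_u", genotype="atm")
        with pytest.raises(ValueError, match="WT treated"):
            algebra.induced_sv_workflow(treated, ctrl, None)
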
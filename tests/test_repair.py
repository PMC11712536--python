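"""Deletion flanks, junction microhomology, repair-pathway labels."""

import numpy as np
import pytest

from svradiate.core import SVRecord
from svradiate.repair import (
    ReferenceGenome,
    RepairParams,
    classify_repair,
    fetch_flanks,
    microhomology,
    repair_summary,
)

from conftest import make_callset, make_record


def mh_oracle(R, s, e, window):
    """Brute-force enumeration of the largest valid (j, k) extensions."""
    def valid_right(k):
        return all(
            s + i >= 0 and e + i < len(R)
            and R[s + i] == R[e + i] and R[s + i].upper() != "N"
            for i in range(k)
        )

    def valid_left(j):
        return all(
            s - i - 1 >= 0 and e - i - 1 >= 0
            and R[s - i - 1] == R[e - i - 1] and R[s - i - 1].upper() != "N"
            for i in range(j)
        )

    k = max(k for k in range(window + 1) if valid_right(k))
    j = max(j for j in range(window + 1) if valid_left(j))
    return j, k, j + k


def del_record(s, e, chrom="Chr1", id="d"):
    # SVRecord stores the 0-based deletion start directly as its POS anchor
    return SVRecord(id=id, chrom=chrom, start=s, end=e, sv_type="DEL",
                    length=e - s)


class TestFetchFlanks:
    def test_window_indexing(self):
        R = "".join("ACGT"[(i * 7) % 4] for i in range(300))
        g = ReferenceGenome({"Chr1": R})
        left, right, trunc = fetch_flanks(del_record(100, 200), g, window=5)
        assert left == R[95:100]
        assert right == R[200:205]
        assert not trunc

    def test_truncation_at_chromosome_start(self):
        g = ReferenceGenome({"Chr1": "ACGTACGTACGTACGTACGTACGTACGT"})
        left, right, trunc = fetch_flanks(del_record(3, 10), g, window=50)
        assert len(left) == 3
        assert trunc

    def test_flanks_plus_deleted_segment_reconstruct_reference(self):
        rng = np.random.default_rng(2)
        R = "".join(np.random.default_rng(2).choice(list("ACGT"), 500))
        g = ReferenceGenome({"Chr1": R})
        s, e, w = 150, 320, 50
        left, right, _ = fetch_flanks(del_record(s, e), g, window=w)
        assert left + R[s:e] + right == R[s - w:e + w]

    def test_non_deletion_rejected(self):
        g = ReferenceGenome({"Chr1": "A" * 100})
        with pytest.raises(ValueError, match="not DEL"):
            fetch_flanks(make_record(id="i", start=50, sv_type="INS"), g)


class TestMicrohomology:
    def test_hand_example_zero_homology(self):
        g = ReferenceGenome({"Chr1": "AAAACGTTTT"})
        j, k, total, seq = microhomology(del_record(4, 7), g, window=5)
        assert (j, k, total, seq) == (0, 0, 0, "")

    def test_constructed_two_sided_homology(self):
        #        s=6         e=12
        # R: GGCATA CATGGG ATAATC...  left "ATA" repeats before s and e,
        # right "AT" after both s and e
        R = "GGCATACATGGGATAATCGCGC"
        # right: R[6:]="CATGGGATAATCGCGC", R[12:]="ATAATCGCGC" -> no common prefix
        g = ReferenceGenome({"Chr1": R})
        j, k, total, seq = microhomology(del_record(6, 12), g, window=6)
        assert (j, k) == (mh_oracle(R, 6, 12, 6)[0], mh_oracle(R, 6, 12, 6)[1])
        assert total == j + k and len(seq) == total

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_oracle_on_random_sequences(self, seed):
        rng = np.random.default_rng(seed)
        R = "".join(rng.choice(list("ACGTN"), 400, p=[0.24, 0.24, 0.24, 0.24, 0.04]))
        g = ReferenceGenome({"Chr1": R})
        for _ in range(30):
            s = int(rng.integers(60, 200))
            e = int(rng.integers(s + 1, 340))
            j, k, total, seq = microhomology(del_record(s, e), g, window=50)
            oj, ok, ototal = mh_oracle(R, s, e, 50)
            assert (j, k, total) == (oj, ok, ototal)
            assert len(seq) == total

    def test_implanted_truth_recovered_exactly(self, default_scenario):
        truth = default_scenario["truth"]
        ref = default_scenario["genome"].reference()
        deletions = [t for t in truth.records if t.sv_type == "DEL"]
        assert deletions
        for t in deletions:
            _, _, total, _ = microhomology(
                del_record(t.start, t.end, chrom=t.chrom, id=t.truth_id), ref)
            assert total == t.mh_total

    def test_breakpoint_representation_invariance(self):
        rng = np.random.default_rng(77)
        n_cases = 0
        while n_cases < 500:
            R = list(rng.choice(list("ACGT"), 300))
            s = int(rng.integers(60, 120))
            e = int(rng.integers(s + 30, 230))
            m = int(rng.integers(1, 12))
            # implant homology tract of length m across the junction
            R[e:e + m] = R[s:s + m]
            R = "".join(R)
            g = ReferenceGenome({"Chr1": R})
            _, _, total0, _ = microhomology(del_record(s, e), g)
            tract = total0
            if tract < 1:
                continue
            for d in range(1, min(tract, m) + 1):
                _, _, total_d, _ = microhomology(del_record(s + d, e + d), g)
                assert total_d == total0
                n_cases += 1


class TestClassify:
    @pytest.mark.parametrize("mh,label", [
        (0, "NHEJ"), (1, "NHEJ"), (2, "MMEJ"), (4, "MMEJ"), (19, "MMEJ"),
        (20, "SSA_CANDIDATE"), (25, "SSA_CANDIDATE"),
    ])
    def test_threshold_labels(self, mh, label):
        rng = np.random.default_rng(mh + 123)
        R = list(rng.choice(list("ACGT"), 400))
        s, e = 150, 250
        R[e:e + mh] = R[s:s + mh]
        # guard both ends so the measured homology is exactly mh
        R[e + mh] = {"A": "C", "C": "G", "G": "T", "T": "A"}[R[s + mh]]
        R[e - 1] = {"A": "C", "C": "G", "G": "T", "T": "A"}[R[s - 1]]
        g = ReferenceGenome({"Chr1": "".join(R)})
        c = classify_repair(del_record(s, e), g)
        assert c.mh_total == mh
        assert c.label == label

    def test_n_in_flank_is_undetermined(self):
        R = "A" * 100 + "N" + "A" * 299
        g = ReferenceGenome({"Chr1": R})
        c = classify_repair(del_record(120, 200), g)
        assert c.label == "UNDETERMINED"

    def test_truncated_flank_is_undetermined(self):
        g = ReferenceGenome({"Chr1": "ACGT" * 50})
        c = classify_repair(del_record(10, 100), g)
        assert c.label == "UNDETERMINED"
        assert c.truncated


class TestSummary:
    def test_empty_and_conservation(self):
        g = ReferenceGenome({"Chr1": "ACGT" * 1000})
        no_dels = make_callset([make_record(id="i", start=500, sv_type="INS")])
        summary = repair_summary(no_dels, g)
        assert summary["n_deletions"] == 0
        assert sum(summary["counts"].values()) == 0

    def test_fractions_and_histogram_on_scenario(self, default_scenario):
        from svradiate.core import parse_sv_vcf
        from svradiate.synthetic import allocate_counts

        truth = default_scenario["truth"]
        ref = default_scenario["genome"].reference()
        spec = default_scenario["spec"]
        dels = [t for t in truth.records if t.sv_type == "DEL"]
        calls = make_callset([
            make_record(id=t.truth_id, chrom=t.chrom, start=t.start,
                        end=t.end, sv_type="DEL", length=t.length)
            for t in dels
        ])
        summary = repair_summary(calls, ref)
        assert sum(summary["counts"].values()) == len(dels)
        planned = allocate_counts(len(dels), spec.deletion_mh_spectrum)
        n_nhej = sum(c for m, c in planned.items() if m <= 1)
        n_mmej = sum(c for m, c in planned.items() if 2 <= m <= 19)
        assert summary["counts"]["NHEJ"] == n_nhej
        assert summary["counts"]["MMEJ"] == n_mmej
        assert sum(summary["mmej_mh_histogram"].values()) == n_mmej
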
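"""VCF ingestion, call filtering and size tables."""

import numpy as np
import pytest

from svradiate.core import (
    FilterParams,
    SVRecord,
    filter_calls,
    parse_sv_vcf,
    size_table,
    write_sv_vcf,
)

from conftest import make_callset, make_record


PARSE_FIXTURE = """\
##fileformat=VCFv4.2
##contig=<ID=Chr1,length=100000>
##contig=<ID=Chr2,length=100000>
##INFO=<ID=SVTYPE,Number=1,Type=String,Description="t">
##INFO=<ID=END,Number=1,Type=Integer,Description="e">
##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="l">
##INFO=<ID=SEQ,Number=1,Type=String,Description="s">
##INFO=<ID=RE,Number=1,Type=Integer,Description="r">
##INFO=<ID=MAPQ,Number=1,Type=Float,Description="m">
##INFO=<ID=MINRLEN,Number=1,Type=Integer,Description="n">
##INFO=<ID=CHR2,Number=1,Type=String,Description="c">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
Chr1\t1000\tdel1\tN\t<DEL>\t.\tPASS\tSVTYPE=DEL;END=1500;SVLEN=-500;RE=12;MAPQ=60;MINRLEN=5000
Chr1\t2000\tins1\tN\t<INS>\t.\tPASS\tSVTYPE=INS;END=2000;SVLEN=8;SEQ=ACGTACGT;RE=9;MAPQ=58;MINRLEN=4000
Chr1\t3000\tdup1\tN\t<DUP>\t.\tPASS\tSVTYPE=DUP;END=3400;SVLEN=400;RE=7;MAPQ=60;MINRLEN=3000
Chr1\t4000\tinv1\tN\t<INV>\t.\tPASS\tSVTYPE=INV;END=4800;SVLEN=800;RE=6;MAPQ=55;MINRLEN=2500
Chr1\t5000\tinvdup1\tN\t<INVDUP>\t.\tPASS\tSVTYPE=INVDUP;END=5300;SVLEN=300;RE=5;MAPQ=60;MINRLEN=2000
Chr1\t6000\tbnd1\tN\t<BND>\t.\tPASS\tSVTYPE=BND;END=6001;SVLEN=1;CHR2=Chr2;RE=4;MAPQ=60;MINRLEN=2000
Chr2\t1000\tdel2\tN\t<DEL>\t.\tPASS\tSVTYPE=DEL;END=1200;SVLEN=-200;RE=11;MAPQ=60;MINRLEN=6000
Chr2\t2000\tins2\tN\t<INS>\t.\tPASS\tSVTYPE=INS;END=2000;SVLEN=5;SEQ=TTTTT;RE=8;MAPQ=60;MINRLEN=5000
Chr2\t3000\tdel3\tN\t<DEL>\t.\tPASS\tSVTYPE=DEL;END=3100;SVLEN=-100;RE=10;MAPQ=60;MINRLEN=7000
Chr2\t4000\tinvdup2\tN\t<INV/INVDUP>\t.\tPASS\tSVTYPE=INVDUP;END=4200;SVLEN=200;RE=6;MAPQ=60;MINRLEN=3000
"""


@pytest.fixture()
def parse_fixture_vcf(tmp_path):
    path = tmp_path / "toy.vcf"
    path.write_text(PARSE_FIXTURE)
    return path


class TestParse:
    def test_deletion_field_mapping(self, parse_fixture_vcf):
        calls = parse_sv_vcf(parse_fixture_vcf, "s1")
        rec = calls.by_id("del1")
        assert (rec.sv_type, rec.start, rec.end, rec.length) == ("DEL", 1000, 1500, 500)
        assert rec.read_support == 12
        assert rec.mapping_quality == 60.0
        assert rec.min_supporting_read_length == 5000

    def test_insertion_anchors_at_point_with_sequence(self, parse_fixture_vcf):
        rec = parse_sv_vcf(parse_fixture_vcf, "s1").by_id("ins1")
        assert rec.sv_type == "INS"
        assert rec.start == rec.end == 2000
        assert rec.length == 8
        assert rec.inserted_seq == "ACGTACGT"

    def test_bnd_line_skipped_with_logged_count(self, parse_fixture_vcf):
        calls = parse_sv_vcf(parse_fixture_vcf, "s1")
        # 10 SV lines in the fixture, one of them BND
        assert len(calls) == 9
        assert calls.parse_skip_counts["bnd"] == 1
        assert "bnd1" not in calls.ids()

    def test_svtype_dialect_normalized(self, parse_fixture_vcf):
        rec = parse_sv_vcf(parse_fixture_vcf, "s1").by_id("invdup2")
        assert rec.sv_type == "INVDUP"

    def test_roundtrip_is_fixed_point(self, parse_fixture_vcf, tmp_path):
        calls = parse_sv_vcf(parse_fixture_vcf, "s1")
        out = tmp_path / "rt.vcf"
        write_sv_vcf(calls, out, chrom_lengths={"Chr1": 100000, "Chr2": 100000})
        reparsed = parse_sv_vcf(out, "s1")
        assert [r for r in reparsed] == [r for r in calls]


class TestFilter:
    def _grid(self):
        # 10 records: 2 too long, 1 low MAPQ, 1 short supporting reads
        recs = [make_record(id=f"ok{i}", start=1000 * (i + 1),
                            end=1000 * (i + 1) + 100) for i in range(6)]
        recs.append(make_record(id="long1", start=20000, end=20000 + 1_000_001,
                                length=1_000_001))
        recs.append(make_record(id="long2", start=2_000_000,
                                end=2_000_000 + 1_500_000, length=1_500_000))
        recs.append(make_record(id="lowmapq", start=30000, end=30100,
                                mapping_quality=19.0))
        recs.append(make_record(id="shortreads", start=40000, end=40100,
                                min_supporting_read_length=900))
        return make_callset(recs)

    def test_hand_counted_survivors_under_default_thresholds(self):
        out = filter_calls(self._grid(), FilterParams())
        assert len(out) == 6
        assert out.ids() == {f"ok{i}" for i in range(6)}
        assert out.rejection_tally == {
            "too_short": 0, "too_long": 2, "read_length": 1, "mapping_quality": 1,
        }

    def test_thresholds_are_inclusive(self):
        boundary = make_callset([
            make_record(id="mq20", mapping_quality=20.0),
            make_record(id="len1", start=100, end=101, length=1, chrom="Chr2"),
            make_record(id="rl1000", start=5000, end=5100,
                        min_supporting_read_length=1000),
            make_record(id="max", start=9000, end=9000 + 1_000_000,
                        length=1_000_000, chrom="Chr3"),
        ])
        out = filter_calls(boundary, FilterParams())
        assert out.ids() == {"mq20", "len1", "rl1000", "max"}

    def test_idempotent_and_conserving(self):
        params = FilterParams()
        calls = self._grid()
        once = filter_calls(calls, params)
        twice = filter_calls(once, params)
        assert list(twice) == list(once)
        assert len(once) + sum(once.rejection_tally.values()) == len(calls)


class TestSizeTable:
    def test_single_and_even_medians(self):
        calls = make_callset(
            [make_record(id="d", start=100, end=200)]
            + [make_record(id=f"i{v}", start=1000 + 100 * v, sv_type="INS",
                           length=v) for v in (1, 2, 3, 4)]
        )
        table = size_table(calls)
        assert table["DEL"]["median"] == table["DEL"]["q1"] == table["DEL"]["q3"] == 100
        assert table["INS"]["median"] == 2.5

    def test_quartiles_match_sort_and_interpolate_oracle(self):
        rng = np.random.default_rng(11)
        lengths = [int(v) for v in rng.integers(10, 5000, 20)]
        calls = make_callset(
            [make_record(id=f"d{i}", start=100 + 3000 * i,
                         end=100 + 3000 * i + L, length=L)
             for i, L in enumerate(lengths)]
        )
        table = size_table(calls)

        def interpolate(sorted_vals, q):
            pos = (len(sorted_vals) - 1) * q
            lo, hi = int(np.floor(pos)), int(np.ceil(pos))
            frac = pos - lo
            return sorted_vals[lo] * (1 - frac) + sorted_vals[hi] * frac

        s = sorted(lengths)
        assert table["DEL"]["q1"] == pytest.approx(interpolate(s, 0.25))
        assert table["DEL"]["median"] == pytest.approx(interpolate(s, 0.50))
        assert table["DEL"]["q3"] == pytest.approx(interpolate(s, 0.75))
        # INDEL aggregate pools DEL and INS
        assert table["INDEL"]["n"] == table["DEL"]["n"]
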
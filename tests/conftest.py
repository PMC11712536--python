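import pytest

from svradiate.core import SVCallSet, SVRecord
from svradiate.synthetic import ScenarioSpec, generate_scenario


def make_record(
    id="r1", chrom="Chr1", start=1000, end=1500, sv_type="DEL",
    length=None, **kw,
):
    if sv_type == "INS":
        end = start
        length = length or 100
    else:
        length = length or (end - start)
    defaults = dict(read_support=20, min_supporting_read_length=8000,
                    mapping_quality=60.0)
    defaults.update(kw)
    return SVRecord(id=id, chrom=chrom, start=start, end=end,
                    sv_type=sv_type, length=length, **defaults)


def make_callset(records, sample_id="s1", **kw):
    return SVCallSet(sample_id=sample_id, records=list(records), **kw)


@pytest.fixture(scope="session")
def default_scenario(tmp_path_factory):
    """Default synthetic scenario: 3 WT replicates + one treated WT sample."""
    out = tmp_path_factory.mktemp("scenario")
    spec = ScenarioSpec(seed=20260)
    manifest = generate_scenario(spec, out)
    manifest["out_dir"] = out
    manifest["spec"] = spec
    return manifest
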
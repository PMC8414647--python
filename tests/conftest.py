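import pytest
from hypothesis import settings

from repscope.io import AlignedRecord, JunctionFields

settings.register_profile("repscope", derandomize=True, deadline=None)
settings.load_profile("repscope")
from repscope.simulate import SimulationParams, default_germline, simulate_repertoire


@pytest.fixture(scope="session")
def germline():
    return default_germline()


@pytest.fixture(scope="session")
def germline_by_name(germline):
    return {s.name: s for s in germline}


@pytest.fixture(scope="session")
def sim_result():
    """One moderately sized simulated sample shared by read-only tests."""
    return simulate_repertoire(SimulationParams(seed=123, n_clones=2000), sample_id="fix")


@pytest.fixture(scope="session")
def sim_repertoire(sim_result):
    return sim_result.repertoire


def make_record(
    record_id="r1",
    v_call="IGHV1-2*01",
    j_call="IGHJ4*02",
    cdr3_nt="TGTGCTTGG",
    **kwargs,
):
    kwargs.setdefault("cdr3_aa", None)
    return AlignedRecord(record_id=record_id, v_call=v_call, j_call=j_call, cdr3_nt=cdr3_nt, **kwargs)


@pytest.fixture
def hand_records():
    """Three records: two share the clone key, one differs in CDR3."""
    return [
        make_record("a", duplicate_count=2, c_call="IGHG1"),
        make_record("b", duplicate_count=1, c_call="IGHG1"),
        make_record("c", cdr3_nt="TGTGGTTGG", duplicate_count=1, c_call="IGHG1"),
    ]


@pytest.fixture
def complete_junction():
    return JunctionFields(v_del3=2, d_del5=1, d_del3=0, j_del5=0, ins_vd=0, ins_dj=4)
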
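"""Group selection, feature comparison summaries, public-clone detection."""

import numpy as np
import pytest

from repscope.clonotype import Clone, Repertoire
from repscope.compare import (
    SampleGroup,
    compare_feature,
    detect_public_clones,
    clone_sharing_key,
    select_reference,
    SHARING_KEYS,
)
from repscope.io import RepscopeError, ValidationError
from repscope.simulate import SimulationParams, simulate_group, synthesize_cdr3


def rep_with(sample_id, cdr3aas, metadata=None):
    clones = [
        Clone(
            v_gene="IGHV1-2",
            j_gene="IGHJ4",
            cdr3_nt=synthesize_cdr3(aa),
            cdr3_aa=aa,
            read_count=1,
        )
        for aa in cdr3aas
    ]
    return Repertoire(sample_id=sample_id, clones=clones, metadata=metadata or {})


# ----------------------------------------------------------- select_reference

def catalog():
    return [
        rep_with("r1", ["CAW"], {"health_condition": "Healthy", "tissue": "PBMC"}),
        rep_with("r2", ["CAW"], {"health_condition": "Healthy", "tissue": "PBMC"}),
        rep_with("r3", ["CAW"], {"health_condition": "Healthy", "tissue": "Spleen"}),
        rep_with("r4", ["CAW"], {"health_condition": "COVID-19", "tissue": "PBMC"}),
        rep_with("r5", ["CAW"], {"health_condition": "COVID-19", "tissue": "PBMC"}),
    ]


def test_criteria_filter_exact_match():
    group = select_reference(catalog(), {"health_condition": "Healthy", "tissue": "PBMC"})
    assert [r.sample_id for r in group.repertoires] == ["r1", "r2"]


def test_empty_criteria_match_all():
    assert len(select_reference(catalog(), {}).repertoires) == 5


def test_no_match_is_an_error():
    with pytest.raises(RepscopeError, match="relax"):
        select_reference(catalog(), {"read_length": "2x300"})


def test_duplicate_sample_ids_rejected():
    with pytest.raises(ValidationError, match="duplicate"):
        SampleGroup(label="x", repertoires=[rep_with("a", ["CAW"]), rep_with("a", ["CVW"])])


# ------------------------------------------------------------ compare_feature

def usage_group(label, values_by_sample):
    reps = []
    for sid, gene_counts in values_by_sample.items():
        clones = []
        i = 0
        for gene, count in gene_counts.items():
            for _ in range(count):
                aa = "CA" + "GA"[i % 2] + "W"
                clones.append(
                    Clone(v_gene=gene, j_gene="IGHJ4", cdr3_nt=synthesize_cdr3(aa) + "GCT" * i, cdr3_aa=None, read_count=1)
                )
                i += 1
        reps.append(Repertoire(sample_id=sid, clones=clones))
    return SampleGroup(label=label, repertoires=reps)


def test_reference_quantiles_linear_interpolation():
    # reference V usage of gene IGHV1 across 3 samples: 0.1, 0.2, 0.3
    ref = usage_group(
        "reference",
        {
            "r1": {"IGHV1": 1, "IGHV2": 9},
            "r2": {"IGHV1": 2, "IGHV2": 8},
            "r3": {"IGHV1": 3, "IGHV2": 7},
        },
    )
    exp = usage_group("experimental", {"e1": {"IGHV1": 9, "IGHV2": 1}})
    comparison = compare_feature(exp, ref, "v_usage")
    mn, q1, med, q3, mx, n = comparison.reference_summary["IGHV1"]
    assert (q1, med, q3) == pytest.approx((0.15, 0.2, 0.25))
    assert (mn, mx) == pytest.approx((0.1, 0.3))
    assert n == 3
    # experimental point passes through unclipped
    assert comparison.experimental_points["IGHV1"]["e1"] == pytest.approx(0.9)


def test_quantiles_match_numpy_oracle(sim_repertoire):
    rng = np.random.default_rng(0)
    ref_values = {}
    ref = usage_group(
        "reference",
        {f"r{i}": {"IGHV1": int(rng.integers(1, 10)), "IGHV2": 5} for i in range(7)},
    )
    exp = usage_group("experimental", {"e1": {"IGHV1": 1, "IGHV2": 1}})
    comparison = compare_feature(exp, ref, "v_usage")
    for gene in comparison.categories:
        vals = []
        for r in ref.repertoires:
            counts = {}
            for c in r.clones:
                counts[c.v_gene] = counts.get(c.v_gene, 0) + 1
            vals.append(counts.get(gene, 0) / len(r.clones))
        _, q1, med, q3, _, _ = comparison.reference_summary[gene]
        assert q1 == pytest.approx(np.percentile(vals, 25), abs=1e-12)
        assert med == pytest.approx(np.percentile(vals, 50), abs=1e-12)
        assert q3 == pytest.approx(np.percentile(vals, 75), abs=1e-12)


def test_gene_absent_from_reference_summarized_as_zero():
    ref = usage_group("reference", {"r1": {"IGHV2": 5}, "r2": {"IGHV2": 5}})
    exp = usage_group("experimental", {"e1": {"IGHV9": 5}})
    comparison = compare_feature(exp, ref, "v_usage")
    assert comparison.reference_summary["IGHV9"][:5] == (0.0, 0.0, 0.0, 0.0, 0.0)
    assert comparison.reference_summary["IGHV9"][5] == 2


def test_unknown_feature_rejected():
    g = usage_group("experimental", {"e1": {"IGHV1": 1}})
    with pytest.raises(RepscopeError, match="unknown feature"):
        compare_feature(g, g, "nope")


# -------------------------------------------------------------- public clones

def test_worked_sharing_example():
    exp = SampleGroup(
        label="experimental",
        repertoires=[rep_with("S1", ["CAW", "CVW"]), rep_with("S2", ["CVW", "CCW"])],
    )
    ref = SampleGroup(label="reference", repertoires=[rep_with("R1", ["CCW", "CDW"])])
    records = {r.sharing_key: r for r in detect_public_clones(exp, ref, "cdr3aa", 2)}
    assert records["CVW"].clone_class == "intragroup"
    assert records["CVW"].exp_samples == ("S1", "S2")
    assert records["CCW"].clone_class == "intergroup"
    assert records["CCW"].exp_samples == ("S2",) and records["CCW"].ref_samples == ("R1",)
    assert "CAW" not in records and "CDW" not in records


def test_one_exp_one_ref_is_intergroup():
    exp = SampleGroup(label="experimental", repertoires=[rep_with("S1", ["CAW"])])
    ref = SampleGroup(label="reference", repertoires=[rep_with("R1", ["CAW"])])
    (rec,) = detect_public_clones(exp, ref, "cdr3aa", 2)
    assert rec.clone_class == "intergroup"


def test_min_share_lower_bound():
    exp = SampleGroup(label="experimental", repertoires=[rep_with("S1", ["CAW"])])
    with pytest.raises(ValidationError):
        detect_public_clones(exp, None, "cdr3aa", min_share=1)


def brute_force_public(exp, ref, mode, min_share):
    """Independent oracle: key -> sample-set map, then filter."""
    emap, rmap = {}, {}
    for group, table in ((exp, emap), (ref, rmap)):
        for rep in group.repertoires:
            for c in rep.clones:
                key = clone_sharing_key(c, mode)
                if key:
                    table.setdefault(key, set()).add(rep.sample_id)
    out = {}
    for key, es in emap.items():
        rs = rmap.get(key, set())
        if rs and len(es) + len(rs) >= min_share:
            out[key] = ("intergroup", frozenset(es), frozenset(rs))
        elif not rs and len(es) >= min_share:
            out[key] = ("intragroup", frozenset(es), frozenset())
    return out


@pytest.mark.parametrize("mode", SHARING_KEYS)
def test_detection_matches_brute_force_on_simulated_groups(mode):
    params = SimulationParams(seed=77, n_clones=1000)
    planted = [("CARGFDYW", range(5)), ("CARDLDYW", [0, 1])]
    exp, _ = simulate_group(params, 5, planted_keys=planted, label="experimental")
    ref_params = SimulationParams(seed=78, n_clones=1000)
    ref, _ = simulate_group(
        ref_params, 15, planted_keys=[("CARGFDYW", range(10))], label="reference", sample_prefix="R"
    )
    records = detect_public_clones(exp, ref, mode, 2)
    oracle = brute_force_public(exp, ref, mode, 2)
    got = {
        r.sharing_key: (r.clone_class, frozenset(r.exp_samples), frozenset(r.ref_samples))
        for r in records
    }
    assert got == oracle
    # planted recovery: the key planted in 5 exp + 10 ref samples
    key = {
        "cdr3aa": "CARGFDYW",
        "cdr3nt": synthesize_cdr3("CARGFDYW"),
        "vj_cdr3nt": f"IGHV1-2|IGHJ4|{synthesize_cdr3('CARGFDYW')}",
    }[mode]
    rec = next(r for r in records if r.sharing_key == key)
    assert rec.clone_class == "intergroup"
    assert len(rec.exp_samples) == 5 and len(rec.ref_samples) == 10


def test_sorted_by_total_share_then_key():
    exp = SampleGroup(
        label="experimental",
        repertoires=[
            rep_with("S1", ["CAW", "CVW", "CCW"]),
            rep_with("S2", ["CAW", "CVW"]),
            rep_with("S3", ["CAW", "CCW"]),
        ],
    )
    records = detect_public_clones(exp, None, "cdr3aa", 2)
    assert [r.sharing_key for r in records] == ["CAW", "CCW", "CVW"]
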
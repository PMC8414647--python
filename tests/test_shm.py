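"""SHM profiling: locus classification, motif annotation, clone-as-unit
position frequencies, and repertoire-level aggregation."""

import itertools

import pytest

from repscope.clonotype import Clone
from repscope.io import GermlineSegment, ValidationError, translate_nt
from repscope.shm import (
    BASES,
    classify_loci,
    classify_position,
    annotate_motifs,
    clone_position_frequencies,
    repertoire_shm_profile,
    COLDSPOT_SYC_GRS,
    HOTSPOT_WA_TW,
    HOTSPOT_WRCY_RGYW,
)
from repscope.simulate import SimulationParams, simulate_repertoire


def v_segment(seq, name="IGHV1-1*01"):
    n = len(seq) - len(seq) % 3
    return GermlineSegment(name, "V", seq, {"FR1": (0, n)} if n else {}, 0)


# ------------------------------------------------------- locus classification

@pytest.mark.parametrize(
    "codon,within,expected",
    [
        ("CTG", 2, "silent"),       # CTA/CTC/CTT all Leu
        ("AAA", 0, "replacement"),  # CAA Gln, GAA Glu, TAA stop
        ("ATT", 2, "composite"),    # ATA/ATC Ile, ATG Met
    ],
)
def test_classify_position_examples(codon, within, expected):
    assert classify_position(codon, within) == expected


def brute_force_class(codon, within):
    """Independent oracle: enumerate the genetic code directly."""
    ref = translate_nt(codon)
    syn = []
    for alt in "ACGT":
        if alt == codon[within]:
            continue
        aa = translate_nt(codon[:within] + alt + codon[within + 1 :])
        syn.append(aa == ref)  # '*' never equals a sense residue -> replacement
    return "silent" if all(syn) else ("replacement" if not any(syn) else "composite")


def test_all_192_codon_position_cases_match_enumeration():
    for codon in map("".join, itertools.product("ACGT", repeat=3)):
        for within in range(3):
            assert classify_position(codon, within) == brute_force_class(codon, within), (
                codon,
                within,
            )


def test_classify_loci_respects_regions_and_frame():
    seg = GermlineSegment("IGHV1-1*01", "V", "AAACTGATT", {"FR1": (0, 9)}, 0)
    loci = classify_loci(seg)
    assert loci[0] == "replacement"  # AAA first position
    assert loci[5] == "silent"       # CTG third position
    assert loci[8] == "composite"    # ATT third position


# ------------------------------------------------------------------- motifs

def test_wrcy_hotspot_tags_the_c():
    tags = annotate_motifs(v_segment("TACT"))
    assert HOTSPOT_WRCY_RGYW in tags[2]


def test_syc_coldspot_tags_the_c():
    tags = annotate_motifs(v_segment("GTC"))
    assert COLDSPOT_SYC_GRS in tags[2]


def test_no_motif_in_poly_g():
    seg = v_segment("GGGGGG")
    # GRS matches GG[C/G]: focal G positions exist; poly-G with S=G matches GRS
    tags = annotate_motifs(seg)
    assert all(t == {COLDSPOT_SYC_GRS} for t in map(set, tags.values()))


def test_wa_and_tw_tag_focal_bases():
    tags = annotate_motifs(v_segment("TA"))
    assert HOTSPOT_WA_TW in tags.get(1, frozenset())  # WA tags the A
    assert HOTSPOT_WA_TW in tags.get(0, frozenset())  # TW tags the T


def test_focal_base_matches_motif(germline):
    for seg in germline:
        if seg.segment_type != "V":
            continue
        for pos, tags in annotate_motifs(seg).items():
            base = seg.sequence[pos]
            if HOTSPOT_WRCY_RGYW in tags:
                assert base in "CG"
            if HOTSPOT_WA_TW in tags:
                assert base in "AT"
            if COLDSPOT_SYC_GRS in tags:
                assert base in "CG"


# ----------------------------------------------------- clone-level frequencies

def _clone(reads, v="IGHV1-2", cdr3="TGTGCTTGG"):
    return Clone(
        v_gene=v, j_gene="IGHJ4", cdr3_nt=cdr3, c_gene="IGHG1",
        read_count=len(reads), mutation_events_by_read=tuple(tuple(r) for r in reads),
    )


def test_position_frequency_is_read_fraction(germline_by_name):
    seg = germline_by_name["IGHV1-2*01"]
    base10 = seg.sequence[10]
    dst = "G" if base10 != "G" else "A"
    clone = _clone([[(10, base10, dst)], []])
    freq = clone_position_frequencies(clone, seg)
    assert freq[10] == pytest.approx(0.5)


def test_three_event_types_accumulate(germline_by_name):
    seg = germline_by_name["IGHV1-2*01"]
    src = seg.sequence[7]
    alts = [b for b in "ACGT" if b != src]
    clone = _clone([[(7, src, alts[0])], [(7, src, alts[0])], [(7, src, alts[1])], []])
    freq, events = clone_position_frequencies(clone, seg, with_events=True)
    assert freq[7] == pytest.approx(0.75)
    assert events[(7, src, alts[0])] == pytest.approx(0.5)
    assert events[(7, src, alts[1])] == pytest.approx(0.25)


def test_unmutated_clone_has_empty_map(germline_by_name):
    seg = germline_by_name["IGHV1-2*01"]
    assert clone_position_frequencies(_clone([[], []]), seg) == {}


def test_event_beyond_segment_rejected(germline_by_name):
    seg = germline_by_name["IGHV1-2*01"]
    with pytest.raises(ValidationError):
        clone_position_frequencies(_clone([[(999, "A", "G")]]), seg)


# --------------------------------------------------------- repertoire profile

def test_profile_means_clone_frequencies(germline):
    by_name = {s.name: s for s in germline}
    seg = by_name["IGHV1-2*01"]
    base10 = seg.sequence[10]
    dst = "G" if base10 != "G" else "A"
    c1 = _clone([[(10, base10, dst)], []])                      # freq 0.5
    c2 = _clone([[(10, base10, dst)]] + [[]] * 9, cdr3="TGTGGTTGG")  # freq 0.1
    from repscope.clonotype import Repertoire

    rep = Repertoire(sample_id="t", clones=[c1, c2])
    profile = repertoire_shm_profile(rep, germline, "IGHG")
    assert profile.position_freq[("IGHV1-2", 10)] == pytest.approx(0.3)


def test_unmutated_repertoire_all_zero(germline):
    result = simulate_repertoire(SimulationParams(seed=4, n_clones=100, base_mutation_rate=0.0))
    for isotype in ("IGHM", "IGHG"):
        profile = repertoire_shm_profile(result.repertoire, germline, isotype)
        assert all(v == 0.0 for v in profile.region_rate.values())
        assert all(v == 0.0 for row in profile.transition.values() for v in row.values())


def test_positions_restricted_to_fr1_fr3(germline, sim_repertoire):
    profile = repertoire_shm_profile(sim_repertoire, germline, "IGHG")
    by_gene = {s.gene: s for s in germline if s.segment_type == "V"}
    assert profile.n_clones > 0
    for (gene, pos) in profile.position_freq:
        assert pos < by_gene[gene].regions["FR3"][1]


def test_region_rate_equals_mean_of_position_freq_single_gene(germline):
    """With a single V gene in play, the regionRate must equal the arithmetic
    mean of that gene's positionFreq over the region's positions."""
    params = SimulationParams(
        seed=8,
        n_clones=200,
        v_usage={"IGHV1-2*01": 1.0},
    )
    result = simulate_repertoire(params)
    profile = repertoire_shm_profile(result.repertoire, germline, "IGHM")
    seg = {s.name: s for s in germline}["IGHV1-2*01"]
    for region, (start, end) in seg.regions.items():
        vals = [profile.position_freq[("IGHV1-2", p)] for p in range(start, end)]
        assert profile.region_rate[region] == pytest.approx(sum(vals) / len(vals), abs=1e-12)


def test_transition_rows_conserve_base_totals(germline):
    """Per germline base, the summed transition frequencies equal the mean
    per-position mutation frequency at positions with that base."""
    params = SimulationParams(seed=15, n_clones=300, v_usage={"IGHV1-2*01": 1.0})
    result = simulate_repertoire(params)
    profile = repertoire_shm_profile(result.repertoire, germline, "IGHG")
    seg = {s.name: s for s in germline}["IGHV1-2*01"]
    positions = [p for r in ("FR1", "CDR1", "FR2", "CDR2", "FR3") for p in range(*seg.regions[r])]
    for b in BASES:
        bpos = [p for p in positions if seg.sequence[p] == b]
        expected = sum(profile.position_freq[("IGHV1-2", p)] for p in bpos) / len(bpos)
        assert sum(profile.transition[b].values()) == pytest.approx(expected, abs=1e-9)


def test_hotspot_rates_exceed_untagged_under_biased_simulation(germline):
    """With a 5x hotspot multiplier, hotspot-tagged positions accumulate more
    mutations than untagged positions in every seeded replicate."""
    for seed in range(20):
        params = SimulationParams(
            seed=1000 + seed, n_clones=400, hotspot_multiplier=5.0, coldspot_multiplier=1.0
        )
        result = simulate_repertoire(params)
        profile = repertoire_shm_profile(result.repertoire, germline, "IGHM")
        hot = [v for (cls, tag), v in profile.motif_rate.items() if tag.startswith("hotspot")]
        none = [v for (cls, tag), v in profile.motif_rate.items() if tag == "none"]
        assert sum(hot) / len(hot) > sum(none) / len(none), seed
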
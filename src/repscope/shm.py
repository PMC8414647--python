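"""Somatic-hypermutation profiling over the germline V region (FR1-FR3).

The clone is the basic unit: per-position mutation frequencies are first
computed within each clone (fraction of its nonredundant supporting reads
carrying each mutation event) and then averaged over clones with equal
weight.  Positions are classified by what the three possible substitutions
can do to the encoded amino acid (silent / replacement / composite loci) and
tagged with the canonical SHM hotspot (WRCY/RGYW, WA/TW) and coldspot
(SYC/GRS) motifs; mutation rates are cross-tabulated over locus class and
motif tag, and 4x4 germline-to-observed transition frequencies are
accumulated the same clone-as-unit way.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .clonotype import Clone, Repertoire
from .io import GermlineSegment, ValidationError, translate_nt

logger = logging.getLogger(__name__)

BASES = ("A", "C", "G", "T")
SHM_REGIONS = ("FR1", "CDR1", "FR2", "CDR2", "FR3")

LOCUS_CLASSES = ("silent", "replacement", "composite")
HOTSPOT_WRCY_RGYW = "hotspot_WRCY_RGYW"
HOTSPOT_WA_TW = "hotspot_WA_TW"
COLDSPOT_SYC_GRS = "coldspot_SYC_GRS"
MOTIF_TAGS = (HOTSPOT_WRCY_RGYW, HOTSPOT_WA_TW, COLDSPOT_SYC_GRS)

_IUPAC = {"W": "AT", "R": "AG", "Y": "CT", "S": "CG", "A": "A", "C": "C", "G": "G", "T": "T"}

# (motif, focal offset, tag): the focal base is the mutable position.
MOTIFS = (
    ("WRCY", 2, HOTSPOT_WRCY_RGYW),
    ("RGYW", 1, HOTSPOT_WRCY_RGYW),
    ("WA", 1, HOTSPOT_WA_TW),
    ("TW", 0, HOTSPOT_WA_TW),
    ("SYC", 2, COLDSPOT_SYC_GRS),
    ("GRS", 0, COLDSPOT_SYC_GRS),
)


def _region_positions(segment: GermlineSegment) -> list[int]:
    pos: list[int] = []
    for region in SHM_REGIONS:
        if region in segment.regions:
            start, end = segment.regions[region]
            pos.extend(range(start, end))
    return pos


def classify_loci(segment: GermlineSegment) -> dict[int, str]:
    """Classify every coding FR1-FR3 position of a V segment as a silent,
    replacement or composite locus by enumerating the three substitutions
    (a stop codon counts as a replacement outcome)."""
    if segment.segment_type != "V":
        raise ValidationError(f"{segment.name}: locus classification applies to V segments")
    seq = segment.sequence
    offset = segment.reading_frame_offset
    out: dict[int, str] = {}
    excluded = 0
    for pos in _region_positions(segment):
        codon_start = pos - ((pos - offset) % 3)
        if codon_start < offset or codon_start + 3 > len(seq):
            excluded += 1
            continue
        codon = seq[codon_start : codon_start + 3]
        within = pos - codon_start
        out[pos] = classify_position(codon, within)
    if excluded:
        logger.info("%s: %d positions outside a complete codon excluded", segment.name, excluded)
    return out


def classify_position(codon: str, within: int) -> str:
    """Locus class of position ``within`` (0..2) of ``codon``."""
    ref_aa = translate_nt(codon)
    outcomes = []
    for alt in BASES:
        if alt == codon[within]:
            continue
        mutated = codon[:within] + alt + codon[within + 1 :]
        outcomes.append(translate_nt(mutated) == ref_aa)
    if all(outcomes):
        return "silent"
    if not any(outcomes):
        return "replacement"
    return "composite"


def annotate_motifs(segment: GermlineSegment) -> dict[int, frozenset[str]]:
    """Tag every position of a V segment that is the focal (mutable) base of
    a hotspot/coldspot motif; overlapping matches are all recorded."""
    seq = segment.sequence
    tags: dict[int, set[str]] = {}
    for motif, focal, tag in MOTIFS:
        k = len(motif)
        for start in range(len(seq) - k + 1):
            if all(seq[start + i] in _IUPAC[motif[i]] for i in range(k)):
                tags.setdefault(start + focal, set()).add(tag)
    return {pos: frozenset(t) for pos, t in tags.items()}


def clone_position_frequencies(
    clone: Clone, segment: GermlineSegment, with_events: bool = False
):
    """Per-position mutation frequency within one clone.

    The frequency at position p is the fraction of the clone's nonredundant
    supporting reads carrying a mutation there (equivalently the sum over the
    at-most-three event types of their read fractions).  Positions outside
    FR1-FR3 are dropped.  With ``with_events=True`` also returns the
    per-event-type frequencies ``{(pos, from, to): fraction}``.
    """
    reads = clone.mutation_events_by_read or ((),)
    n_reads = len(reads)
    scope = set(_region_positions(segment))
    freq: dict[int, float] = {}
    events: dict[tuple[int, str, str], float] = {}
    for read_events in reads:
        for pos, src, dst in read_events:
            if pos >= len(segment.sequence):
                raise ValidationError(
                    f"mutation position {pos} beyond germline {segment.name} length"
                )
            if pos not in scope:
                continue
            freq[pos] = freq.get(pos, 0.0) + 1.0 / n_reads
            events[(pos, src, dst)] = events.get((pos, src, dst), 0.0) + 1.0 / n_reads
    if with_events:
        return freq, events
    return freq


@dataclass
class SHMProfile:
    """Repertoire-level SHM summary for one isotype."""

    isotype: str
    position_freq: dict[tuple[str, int], float] = field(default_factory=dict)
    region_rate: dict[str, float] = field(default_factory=dict)
    transition: dict[str, dict[str, float]] = field(default_factory=dict)
    motif_rate: dict[tuple[str, str], float] = field(default_factory=dict)
    n_clones: int = 0


def repertoire_shm_profile(
    repertoire: Repertoire,
    germline: Iterable[GermlineSegment] | Mapping[str, GermlineSegment],
    isotype: str,
) -> SHMProfile:
    """Aggregate clone-level SHM statistics for clones of one isotype.

    Every clone weighs 1.  ``position_freq`` is keyed per (V gene, position)
    and averaged over the clones of that gene; region rates, transition
    frequencies (mean per-position rate per germline base) and locus-class x
    motif-tag rates are averaged over clone-level values.
    """
    if isinstance(germline, Mapping):
        segs = list(germline.values())
    else:
        segs = list(germline)
    by_gene: dict[str, GermlineSegment] = {}
    for seg in segs:
        if seg.segment_type == "V" and seg.regions:
            by_gene.setdefault(seg.gene, seg)

    clones = [c for c in repertoire.clones if c.isotype == isotype and c.v_gene in by_gene]
    if not clones:
        logger.warning("%s: no clones of isotype %s with a known V gene", repertoire.sample_id, isotype)
        return SHMProfile(isotype=isotype)

    loci_cache: dict[str, dict[int, str]] = {}
    motif_cache: dict[str, dict[int, frozenset[str]]] = {}

    pos_sum: dict[tuple[str, int], float] = {}
    pos_n: dict[tuple[str, int], int] = {}
    region_sums: dict[str, list[float]] = {r: [] for r in SHM_REGIONS}
    trans_sums: dict[str, dict[str, list[float]]] = {
        b: {x: [] for x in BASES if x != b} for b in BASES
    }
    motif_sums: dict[tuple[str, str], list[float]] = {}

    for clone in clones:
        seg = by_gene[clone.v_gene]
        if seg.gene not in loci_cache:
            loci_cache[seg.gene] = classify_loci(seg)
            motif_cache[seg.gene] = annotate_motifs(seg)
        loci = loci_cache[seg.gene]
        motifs = motif_cache[seg.gene]

        freq, events = clone_position_frequencies(clone, seg, with_events=True)
        positions = _region_positions(seg)

        for p in positions:
            key = (seg.gene, p)
            pos_sum[key] = pos_sum.get(key, 0.0) + freq.get(p, 0.0)
            pos_n[key] = pos_n.get(key, 0) + 1

        for region in SHM_REGIONS:
            if region not in seg.regions:
                continue
            start, end = seg.regions[region]
            vals = [freq.get(p, 0.0) for p in range(start, end)]
            if vals:
                region_sums[region].append(sum(vals) / len(vals))

        # clone-level transition rates: mean per-position event frequency,
        # per germline base, so row sums conserve the base's total rate
        base_positions = {b: [p for p in positions if seg.sequence[p] == b] for b in BASES}
        for b in BASES:
            n_b = len(base_positions[b])
            if n_b == 0:
                continue
            for x in BASES:
                if x == b:
                    continue
                s = sum(events.get((p, b, x), 0.0) for p in base_positions[b])
                trans_sums[b][x].append(s / n_b)

        # locus class x motif tag cells (plus the untagged "none" cell)
        cells: dict[tuple[str, str], list[float]] = {}
        for p in positions:
            cls = loci.get(p)
            if cls is None:
                continue
            tags = motifs.get(p) or frozenset({"none"})
            for tag in tags:
                cells.setdefault((cls, tag), []).append(freq.get(p, 0.0))
        for cell, vals in cells.items():
            motif_sums.setdefault(cell, []).append(sum(vals) / len(vals))

    profile = SHMProfile(isotype=isotype, n_clones=len(clones))
    profile.position_freq = {k: pos_sum[k] / pos_n[k] for k in sorted(pos_sum)}
    profile.region_rate = {
        r: (sum(v) / len(v) if v else 0.0) for r, v in region_sums.items()
    }
    profile.transition = {
        b: {x: (sum(v) / len(v) if v else 0.0) for x, v in row.items()}
        for b, row in trans_sums.items()
    }
    profile.motif_rate = {
        cell: sum(v) / len(v) for cell, v in sorted(motif_sums.items())
    }
    return profile


def write_shm_tables(profile: SHMProfile, repertoire_id: str, outdir: str | Path) -> dict[str, int]:
    """Write shm_positions / shm_regions / shm_transitions / shm_motifs TSVs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    suffix = f"{profile.isotype}"
    written: dict[str, int] = {}

    rows = [
        {"sample_id": repertoire_id, "isotype": profile.isotype, "v_gene": g, "position": p, "frequency": f}
        for (g, p), f in profile.position_freq.items()
    ]
    name = f"shm_positions_{suffix}.tsv"
    pd.DataFrame(rows, columns=["sample_id", "isotype", "v_gene", "position", "frequency"]).to_csv(
        outdir / name, sep="\t", index=False
    )
    written[name] = len(rows)

    rows = [
        {"sample_id": repertoire_id, "isotype": profile.isotype, "region": r, "rate": v}
        for r, v in profile.region_rate.items()
    ]
    name = f"shm_regions_{suffix}.tsv"
    pd.DataFrame(rows, columns=["sample_id", "isotype", "region", "rate"]).to_csv(
        outdir / name, sep="\t", index=False
    )
    written[name] = len(rows)

    rows = [
        {"sample_id": repertoire_id, "isotype": profile.isotype, "from": b, "to": x, "frequency": v}
        for b, row in profile.transition.items()
        for x, v in row.items()
    ]
    name = f"shm_transitions_{suffix}.tsv"
    pd.DataFrame(rows, columns=["sample_id", "isotype", "from", "to", "frequency"]).to_csv(
        outdir / name, sep="\t", index=False
    )
    written[name] = len(rows)

    rows = [
        {"sample_id": repertoire_id, "isotype": profile.isotype, "locus_class": c, "motif_tag": t, "rate": v}
        for (c, t), v in profile.motif_rate.items()
    ]
    name = f"shm_motifs_{suffix}.tsv"
    pd.DataFrame(rows, columns=["sample_id", "isotype", "locus_class", "motif_tag", "rate"]).to_csv(
        outdir / name, sep="\t", index=False
    )
    written[name] = len(rows)
    return written
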
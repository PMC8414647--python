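"""Repertoire feature extraction.

Gene usage and CDR3 length distributions are clone-count based (every clone
weighs 1); the diversity indices (Shannon, Simpson, D50, top-100 clone
fraction) are computed on read-weighted clone frequencies.  Junction
diversity summarizes deletion lengths at the four trim sites (V3, D5, D3,
J5) and non-templated insertion lengths at the two joints (VD, DJ), treating
insertions and deletions at the same joint as mutually exclusive events.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .clonotype import Clone, Repertoire, _sortable_key
from .io import JunctionFields, ValidationError

logger = logging.getLogger(__name__)

DELETION_SITES = ("V3", "D5", "D3", "J5")
INSERTION_SITES = ("VD", "DJ")

_FREQ_TOL = 1e-9


@dataclass
class UsageTable:
    segment_type: str
    freq: dict[str, float] = field(default_factory=dict)


@dataclass
class LengthDistribution:
    unit: str
    freq: dict[int, float] = field(default_factory=dict)


@dataclass
class JunctionProfile:
    deletion_freq: dict[str, dict[int, float]] = field(default_factory=dict)
    insertion_freq: dict[str, dict[int, float]] = field(default_factory=dict)
    n_clones_used: int = 0


@dataclass
class DiversityIndices:
    shannon: float
    simpson: float
    d50: float
    top100_fraction: float


def _validate_freqs(freqs: Sequence[float]) -> np.ndarray:
    p = np.asarray(freqs, dtype=float)
    if p.size == 0:
        raise ValidationError("empty frequency vector")
    if (p < 0).any():
        raise ValidationError("negative clone frequency")
    if abs(p.sum() - 1.0) > _FREQ_TOL:
        raise ValidationError(f"clone frequencies sum to {p.sum()!r}, not 1")
    return p


def gene_usage(repertoire: Repertoire, segment_type: str) -> UsageTable:
    """Fraction of clones assigned to each gene of ``segment_type`` (V/D/J),
    over the clones that have that segment assigned."""
    if segment_type not in {"V", "D", "J"}:
        raise ValidationError(f"segment type must be V, D or J, got {segment_type!r}")
    if not repertoire.clones:
        raise ValidationError(f"{repertoire.sample_id}: empty repertoire")
    attr = {"V": "v_gene", "J": "j_gene"}.get(segment_type)
    genes = []
    for clone in repertoire.clones:
        if segment_type == "D":
            g = _clone_d_gene(clone)
        else:
            g = getattr(clone, attr)
        if g:
            genes.append(g)
    if not genes:
        logger.warning("%s: no clone has a %s assignment", repertoire.sample_id, segment_type)
        return UsageTable(segment_type=segment_type, freq={})
    total = len(genes)
    freq: dict[str, float] = {}
    for g in sorted(set(genes)):
        freq[g] = genes.count(g) / total
    return UsageTable(segment_type=segment_type, freq=freq)


def _clone_d_gene(clone: Clone) -> str | None:
    return clone.d_gene


def cdr3_length_distribution(repertoire: Repertoire, unit: str = "nt") -> LengthDistribution:
    """Clone-count-based distribution of CDR3 lengths in nt or aa."""
    if unit not in {"nt", "aa"}:
        raise ValidationError(f"unit must be 'nt' or 'aa', got {unit!r}")
    if not repertoire.clones:
        raise ValidationError(f"{repertoire.sample_id}: empty repertoire")
    lengths = []
    for clone in repertoire.clones:
        n = len(clone.cdr3_nt)
        lengths.append(n if unit == "nt" else n // 3)
    total = len(lengths)
    freq = {L: lengths.count(L) / total for L in sorted(set(lengths))}
    return LengthDistribution(unit=unit, freq=freq)


def junction_contributions(
    fields: JunctionFields, exclusivity: str = "junction"
) -> dict[str, int]:
    """Per-site tally contributions of one clone under the
    insertion/deletion mutual-exclusivity rule.

    With ``exclusivity="junction"`` the rule is applied at each joint
    independently: an insertion at a joint zeroes that joint's deletion
    contributions and any deletion at the joint zeroes its insertion
    contribution.  With ``"clone"`` any insertion anywhere zeroes all four
    deletion contributions and vice versa.
    """
    if not fields.complete:
        raise ValidationError("junction contributions require complete junction fields")
    if exclusivity not in {"junction", "clone"}:
        raise ValidationError(f"unknown exclusivity scope {exclusivity!r}")
    v3, d5, d3, j5 = fields.v_del3, fields.d_del5, fields.d_del3, fields.j_del5
    vd, dj = fields.ins_vd, fields.ins_dj
    if exclusivity == "junction":
        out = {
            "V3": 0 if vd > 0 else v3,
            "D5": 0 if vd > 0 else d5,
            "VD": 0 if (v3 > 0 or d5 > 0) else vd,
            "D3": 0 if dj > 0 else d3,
            "J5": 0 if dj > 0 else j5,
            "DJ": 0 if (d3 > 0 or j5 > 0) else dj,
        }
    else:
        any_ins = vd > 0 or dj > 0
        any_del = v3 > 0 or d5 > 0 or d3 > 0 or j5 > 0
        out = {
            "V3": 0 if any_ins else v3,
            "D5": 0 if any_ins else d5,
            "D3": 0 if any_ins else d3,
            "J5": 0 if any_ins else j5,
            "VD": 0 if any_del else vd,
            "DJ": 0 if any_del else dj,
        }
    return out


def junction_profile(repertoire: Repertoire, exclusivity: str = "junction") -> JunctionProfile:
    """Deletion/insertion length distributions over clones with complete
    V/D/J junction information."""
    tallies: dict[str, list[int]] = {s: [] for s in (*DELETION_SITES, *INSERTION_SITES)}
    n_used = 0
    for clone in repertoire.clones:
        jf = clone.junction_fields
        if jf is None or not jf.complete:
            continue
        n_used += 1
        for site, value in junction_contributions(jf, exclusivity).items():
            tallies[site].append(value)
    if n_used == 0:
        logger.warning("%s: no clone has complete V/D/J junction data", repertoire.sample_id)
        return JunctionProfile(n_clones_used=0)

    def normalize(values: list[int]) -> dict[int, float]:
        total = len(values)
        return {L: values.count(L) / total for L in sorted(set(values))}

    return JunctionProfile(
        deletion_freq={s: normalize(tallies[s]) for s in DELETION_SITES},
        insertion_freq={s: normalize(tallies[s]) for s in INSERTION_SITES},
        n_clones_used=n_used,
    )


def shannon_index(freqs: Sequence[float]) -> float:
    """Shannon diversity, -sum(p_i ln p_i), in nats (0 ln 0 := 0)."""
    p = _validate_freqs(freqs)
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum())


def simpson_index(freqs: Sequence[float]) -> float:
    """Simpson index, sum(p_i^2)."""
    p = _validate_freqs(freqs)
    return float((p * p).sum())


def d50(freqs: Sequence[float]) -> float:
    """Percentage of distinct clones (ranked by abundance) whose cumulative
    frequency first reaches 50% of the total reads."""
    p = _validate_freqs(freqs)
    ranked = np.sort(p)[::-1]
    cumulative = np.cumsum(ranked)
    m = int(np.searchsorted(cumulative, 0.5 - _FREQ_TOL) + 1)
    return 100.0 * m / p.size


def top_clone_fraction(repertoire: Repertoire, top_n: int = 100) -> float:
    """Summed frequency of the ``top_n`` most abundant clones (1.0 when the
    repertoire has fewer clones); boundary ties break by clone key."""
    if top_n < 1:
        raise ValidationError("top_n must be >= 1")
    clones = sorted(repertoire.clones, key=lambda c: (-c.read_count, _sortable_key(c)))
    if not clones:
        raise ValidationError(f"{repertoire.sample_id}: empty repertoire")
    total = repertoire.total_reads
    top = clones[: min(top_n, len(clones))]
    return float(sum(c.read_count for c in top) / total)


def diversity_indices(repertoire: Repertoire, top_n: int = 100) -> DiversityIndices:
    freqs = repertoire.frequencies()
    return DiversityIndices(
        shannon=shannon_index(freqs),
        simpson=simpson_index(freqs),
        d50=d50(freqs),
        top100_fraction=top_clone_fraction(repertoire, top_n),
    )


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_feature_tables(repertoire: Repertoire, outdir: str | Path) -> dict[str, int]:
    """Write per-sample feature TSVs; returns {filename: row count}."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, int] = {}

    for seg in ("V", "D", "J"):
        table = gene_usage(repertoire, seg)
        df = pd.DataFrame(
            {"sample_id": repertoire.sample_id, "gene": list(table.freq), "fraction": list(table.freq.values())}
        )
        name = f"usage_{seg}.tsv"
        df.to_csv(outdir / name, sep="\t", index=False)
        written[name] = len(df)

    for unit in ("nt", "aa"):
        dist = cdr3_length_distribution(repertoire, unit)
        df = pd.DataFrame(
            {"sample_id": repertoire.sample_id, "length": list(dist.freq), "fraction": list(dist.freq.values())}
        )
        name = f"cdr3_length_{unit}.tsv"
        df.to_csv(outdir / name, sep="\t", index=False)
        written[name] = len(df)

    profile = junction_profile(repertoire)
    del_rows = [
        {"sample_id": repertoire.sample_id, "site": site, "length": L, "fraction": f}
        for site in DELETION_SITES
        for L, f in profile.deletion_freq.get(site, {}).items()
    ]
    ins_rows = [
        {"sample_id": repertoire.sample_id, "site": site, "length": L, "fraction": f}
        for site in INSERTION_SITES
        for L, f in profile.insertion_freq.get(site, {}).items()
    ]
    pd.DataFrame(del_rows, columns=["sample_id", "site", "length", "fraction"]).to_csv(
        outdir / "junction_deletions.tsv", sep="\t", index=False
    )
    pd.DataFrame(ins_rows, columns=["sample_id", "site", "length", "fraction"]).to_csv(
        outdir / "junction_insertions.tsv", sep="\t", index=False
    )
    written["junction_deletions.tsv"] = len(del_rows)
    written["junction_insertions.tsv"] = len(ins_rows)

    idx = diversity_indices(repertoire)
    df = pd.DataFrame(
        [
            {
                "sample_id": repertoire.sample_id,
                "shannon": idx.shannon,
                "simpson": idx.simpson,
                "d50": idx.d50,
                "top100_fraction": idx.top100_fraction,
                "n_clones": len(repertoire.clones),
                "total_reads": repertoire.total_reads,
            }
        ]
    )
    df.to_csv(outdir / "diversity.tsv", sep="\t", index=False)
    written["diversity.tsv"] = 1
    return written
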
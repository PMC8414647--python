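"""Synthetic heavy-chain repertoire simulator with recorded ground truth.

Each clone is built by the V(D)J recombination schema: sample a V, D and J
segment from the usage priors, trim each joint side with a truncated
geometric deletion, insert non-templated nucleotides at both joints
(truncated geometric lengths, uniform bases), and read the CDR3 off the
junction between the conserved Cys codon (end of the germline V) and the
conserved Trp codon (head of the germline J).  The D-J insertion is extended
by 0-2 nt to keep the junction in frame (the V-D insertion is never
adjusted, so its sampled distribution is exact).  Clone abundances follow a
rank power law; each clone carries one or more distinct reads whose
mutations are drawn independently per position over FR1-FR3 of the germline
V, with rates multiplied at hotspot / coldspot motif positions.

Everything is deterministic for a fixed seed, and the emitted native TSV
round-trips through the io module.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np

from . import shm
from .clonotype import Repertoire, cluster_clones
from .compare import SampleGroup
from .io import (
    AlignedRecord,
    AntibodyRecord,
    GermlineSegment,
    JunctionFields,
    ValidationError,
    AA_ALPHABET,
    read_germline_fasta,
    translate_nt,
    write_clone_table,
    write_germline_fasta,
)

logger = logging.getLogger(__name__)

BASES = np.array(list("ACGT"))

TRIM_SITES = ("V3", "D5", "D3", "J5")
INS_SITES = ("VD", "DJ")

ISOTYPE_C_CALL = {
    "IGHM": "IGHM",
    "IGHD": "IGHD",
    "IGHG": "IGHG1",
    "IGHA": "IGHA1",
    "IGHE": "IGHE",
}

# one fixed codon per amino acid, used to synthesize planted CDR3s
CODON_OF = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT", "G": "GGT",
    "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTG", "M": "ATG", "N": "AAT",
    "P": "CCT", "Q": "CAA", "R": "AGA", "S": "AGC", "T": "ACT", "V": "GTT",
    "W": "TGG", "Y": "TAT",
}


def default_germline() -> list[GermlineSegment]:
    """The bundled tiny germline fixture (3 V, 2 D, 2 J, 2 C segments)."""
    data = resources.files("repscope.data")
    with resources.as_file(data / "germline.fasta") as fasta, resources.as_file(
        data / "boundaries.yaml"
    ) as boundaries:
        return read_germline_fasta(fasta, boundaries)


@dataclass
class SimulationParams:
    """Generator settings.  The defaults define the simulated study
    conditions used throughout the test suite; probabilities are over the
    bundled germline's genes."""

    germline: list[GermlineSegment] = field(default_factory=default_germline)
    v_usage: dict[str, float] = field(
        default_factory=lambda: {"IGHV1-2*01": 0.5, "IGHV3-7*01": 0.3, "IGHV4-34*01": 0.2}
    )
    d_usage: dict[str, float] = field(
        default_factory=lambda: {"IGHD2-2*01": 0.6, "IGHD3-10*01": 0.4}
    )
    j_usage: dict[str, float] = field(
        default_factory=lambda: {"IGHJ4*02": 0.7, "IGHJ6*02": 0.3}
    )
    # truncated geometric (p, max) per deletion site / insertion joint
    trim_dist: dict[str, tuple[float, int]] = field(
        default_factory=lambda: {"V3": (0.35, 6), "D5": (0.3, 6), "D3": (0.3, 6), "J5": (0.3, 9)}
    )
    ins_dist: dict[str, tuple[float, int]] = field(
        default_factory=lambda: {"VD": (0.25, 12), "DJ": (0.25, 12)}
    )
    base_mutation_rate: float = 0.01
    hotspot_multiplier: float = 3.0
    coldspot_multiplier: float = 0.3
    n_clones: int = 1000
    abundance_exponent: float = 1.0
    mean_reads_per_clone: float = 10.0
    distinct_reads_lambda: float = 1.0
    isotype_probs: dict[str, float] = field(
        default_factory=lambda: {
            "IGHM": 0.35, "IGHD": 0.03, "IGHG": 0.37, "IGHA": 0.18, "IGHE": 0.02, "NA": 0.05
        }
    )
    seed: int = 0

    def validate(self) -> None:
        for name, probs in (("v_usage", self.v_usage), ("d_usage", self.d_usage),
                            ("j_usage", self.j_usage), ("isotype_probs", self.isotype_probs)):
            total = sum(probs.values())
            if abs(total - 1.0) > 1e-9:
                raise ValidationError(f"{name} probabilities sum to {total}, not 1")
            if any(p < 0 for p in probs.values()):
                raise ValidationError(f"{name} contains a negative probability")
        if not (0.0 <= self.base_mutation_rate <= 1.0):
            raise ValidationError("base_mutation_rate must lie in [0, 1]")
        if self.hotspot_multiplier <= 0 or self.coldspot_multiplier <= 0:
            raise ValidationError("motif multipliers must be positive")
        if self.n_clones < 1:
            raise ValidationError("n_clones must be >= 1")
        for name, dists in (("trim_dist", self.trim_dist), ("ins_dist", self.ins_dist)):
            for site, (p, mx) in dists.items():
                if not (0 < p < 1) or mx < 0:
                    raise ValidationError(f"{name}[{site}] = ({p}, {mx}) is invalid")
        by_name = {s.name: s for s in self.germline}
        for usage, st in ((self.v_usage, "V"), (self.d_usage, "D"), (self.j_usage, "J")):
            for allele in usage:
                if allele not in by_name:
                    raise ValidationError(f"usage prior names unknown allele {allele}")
                if by_name[allele].segment_type != st:
                    raise ValidationError(f"{allele} is not a {st} segment")


def truncated_geometric_weights(p: float, maximum: int) -> np.ndarray:
    k = np.arange(maximum + 1)
    w = (1.0 - p) ** k * p
    return w / w.sum()


def truncated_geometric_moments(p: float, maximum: int) -> tuple[float, float]:
    """(mean, variance) of the geometric(p) distribution truncated at ``maximum``."""
    w = truncated_geometric_weights(p, maximum)
    k = np.arange(maximum + 1)
    mean = float((w * k).sum())
    var = float((w * (k - mean) ** 2).sum())
    return mean, var


@dataclass
class GroundTruthClone:
    v_call: str
    d_call: str
    j_call: str
    c_call: str | None
    cdr3_nt: str
    junction: dict
    read_count: int
    mutations_by_read: list
    planted: bool = False


@dataclass
class GroundTruth:
    sample_id: str
    seed: int
    clones: list[GroundTruthClone] = field(default_factory=list)
    planted_keys: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "sample_id": self.sample_id,
            "seed": self.seed,
            "planted_keys": self.planted_keys,
            "clones": [dataclasses.asdict(c) for c in self.clones],
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        clones = [GroundTruthClone(**c) for c in payload["clones"]]
        return cls(
            sample_id=payload["sample_id"],
            seed=payload["seed"],
            clones=clones,
            planted_keys=payload["planted_keys"],
        )


@dataclass
class SimulationResult:
    records: list[AlignedRecord]
    repertoire: Repertoire
    truth: GroundTruth


def _mutation_rates(params: SimulationParams, segment: GermlineSegment) -> np.ndarray:
    """Per-position mutation probability over the V sequence (0 outside FR1-FR3)."""
    rates = np.zeros(len(segment.sequence))
    tags = shm.annotate_motifs(segment)
    for region in shm.SHM_REGIONS:
        if region not in segment.regions:
            continue
        start, end = segment.regions[region]
        for pos in range(start, end):
            r = params.base_mutation_rate
            t = tags.get(pos, frozenset())
            if shm.HOTSPOT_WRCY_RGYW in t or shm.HOTSPOT_WA_TW in t:
                r *= params.hotspot_multiplier
            if shm.COLDSPOT_SYC_GRS in t:
                r *= params.coldspot_multiplier
            rates[pos] = min(r, 1.0)
    return rates


def _abundances(n_clones: int, exponent: float, mean_reads: float) -> np.ndarray:
    ranks = np.arange(1, n_clones + 1, dtype=float)
    w = ranks ** (-exponent)
    total = n_clones * mean_reads
    counts = np.maximum(1, np.round(total * w / w.sum())).astype(int)
    return counts


def synthesize_cdr3(cdr3_aa: str) -> str:
    """Encode an amino-acid CDR3 with the fixed codon table."""
    bad = set(cdr3_aa) - AA_ALPHABET
    if bad:
        raise ValidationError(f"planted CDR3 {cdr3_aa!r} has non-standard letters {sorted(bad)}")
    return "".join(CODON_OF[a] for a in cdr3_aa)


def simulate_repertoire(
    params: SimulationParams,
    sample_id: str = "sim",
    metadata: dict | None = None,
    planted: Sequence[str] = (),
) -> SimulationResult:
    """Simulate one sample; ``planted`` is a list of CDR3 aa sequences each
    injected as one extra clone with a fixed V/J/C context."""
    params.validate()
    rng = np.random.default_rng(params.seed)

    by_name = {s.name: s for s in params.germline}
    v_names = sorted(params.v_usage)
    d_names = sorted(params.d_usage)
    j_names = sorted(params.j_usage)
    v_cum = np.cumsum([params.v_usage[n] for n in v_names])
    d_cum = np.cumsum([params.d_usage[n] for n in d_names])
    j_cum = np.cumsum([params.j_usage[n] for n in j_names])
    iso_names = sorted(params.isotype_probs)
    iso_cum = np.cumsum([params.isotype_probs[n] for n in iso_names])

    trim_cum = {
        site: np.cumsum(truncated_geometric_weights(*params.trim_dist[site])) for site in TRIM_SITES
    }
    ins_cum = {
        site: np.cumsum(truncated_geometric_weights(*params.ins_dist[site])) for site in INS_SITES
    }
    rate_cache = {name: _mutation_rates(params, by_name[name]) for name in v_names}

    counts = _abundances(params.n_clones, params.abundance_exponent, params.mean_reads_per_clone)

    default_meta = {
        "tissue": "PBMC",
        "health_condition": "Healthy",
        "amplification_strategy": "Multiplex",
        "read_length": "2x300",
        "primer_5": "FR1",
        "primer_3": "CH1",
    }
    default_meta.update(metadata or {})

    records: list[AlignedRecord] = []
    truth = GroundTruth(sample_id=sample_id, seed=params.seed)
    seen_keys: set[tuple] = set()

    def pick(cum: np.ndarray) -> int:
        return int(np.searchsorted(cum, rng.random(), side="right"))

    for ci in range(params.n_clones):
        v_name = v_names[pick(v_cum)]
        d_name = d_names[pick(d_cum)]
        j_name = j_names[pick(j_cum)]
        v, d, j = by_name[v_name], by_name[d_name], by_name[j_name]
        v_tail = v.sequence[v.cdr3_tail_start :]
        j_head = j.sequence[: j.cdr3_head_end]

        for _attempt in range(200):
            v_del3 = min(pick(trim_cum["V3"]), len(v_tail) - 3)
            d_del5 = pick(trim_cum["D5"])
            d_del3 = pick(trim_cum["D3"])
            if d_del5 + d_del3 > len(d.sequence):
                continue
            j_del5 = min(pick(trim_cum["J5"]), len(j_head) - 3)
            ins_vd = pick(ins_cum["VD"])
            ins_dj = pick(ins_cum["DJ"])
            v_part = v_tail[: len(v_tail) - v_del3]
            d_part = d.sequence[d_del5 : len(d.sequence) - d_del3]
            j_part = j_head[j_del5:]
            length = len(v_part) + ins_vd + len(d_part) + ins_dj + len(j_part)
            ins_dj += (3 - length % 3) % 3  # keep the junction in frame
            vd_bases = "".join(rng.choice(BASES, ins_vd)) if ins_vd else ""
            dj_bases = "".join(rng.choice(BASES, ins_dj)) if ins_dj else ""
            cdr3_nt = v_part + vd_bases + d_part + dj_bases + j_part

            isotype = iso_names[pick(iso_cum)]
            c_call = ISOTYPE_C_CALL.get(isotype)
            key = (v_name.split("*")[0], j_name.split("*")[0],
                   c_call.split("*")[0] if c_call else None, cdr3_nt)
            if key not in seen_keys:
                seen_keys.add(key)
                break
        else:
            raise ValidationError("could not draw a unique junction; germline too small")

        jf = JunctionFields(
            v_del3=v_del3, d_del5=d_del5, d_del3=d_del3, j_del5=j_del5,
            ins_vd=ins_vd, ins_dj=ins_dj,
        )
        read_count = int(counts[ci])
        n_distinct = int(min(read_count, 1 + rng.poisson(params.distinct_reads_lambda)))
        dup = np.ones(n_distinct, dtype=int)
        if read_count > n_distinct:
            dup += rng.multinomial(read_count - n_distinct, np.full(n_distinct, 1.0 / n_distinct))

        rates = rate_cache[v_name]
        mutations_by_read: list[list[tuple[int, str, str]]] = []
        for ri in range(n_distinct):
            hits = np.flatnonzero(rng.random(rates.size) < rates)
            events = []
            for pos in hits:
                src = v.sequence[pos]
                alternatives = [b for b in "ACGT" if b != src]
                dst = alternatives[int(rng.integers(3))]
                events.append((int(pos), src, dst))
            mutations_by_read.append(events)

        cdr3_aa = translate_nt(cdr3_nt)
        for ri in range(n_distinct):
            records.append(
                AlignedRecord(
                    record_id=f"{sample_id}:c{ci:06d}r{ri}",
                    v_call=v_name,
                    d_call=d_name,
                    j_call=j_name,
                    c_call=c_call,
                    cdr3_nt=cdr3_nt,
                    cdr3_aa=cdr3_aa,
                    duplicate_count=int(dup[ri]),
                    mutation_events=tuple(mutations_by_read[ri]),
                    junction_fields=jf,
                )
            )
        truth.clones.append(
            GroundTruthClone(
                v_call=v_name,
                d_call=d_name,
                j_call=j_name,
                c_call=c_call,
                cdr3_nt=cdr3_nt,
                junction={
                    "v_del3": v_del3, "d_del5": d_del5, "d_del3": d_del3,
                    "j_del5": j_del5, "ins_vd": ins_vd, "ins_dj": ins_dj,
                    "vd_bases": vd_bases, "dj_bases": dj_bases,
                },
                read_count=read_count,
                mutations_by_read=[[list(e) for e in ev] for ev in mutations_by_read],
            )
        )

    for pi, cdr3_aa in enumerate(planted):
        cdr3_nt = synthesize_cdr3(cdr3_aa)
        records.append(
            AlignedRecord(
                record_id=f"{sample_id}:planted{pi:03d}",
                v_call=v_names[0],
                d_call=None,
                j_call=j_names[0],
                c_call="IGHG1",
                cdr3_nt=cdr3_nt,
                cdr3_aa=cdr3_aa,
                duplicate_count=3,
            )
        )
        truth.planted_keys[cdr3_aa] = cdr3_nt

    repertoire = cluster_clones(records, use_c_gene=True, sample_id=sample_id, metadata=default_meta)
    return SimulationResult(records=records, repertoire=repertoire, truth=truth)


def sample_seeds(master_seed: int, n: int) -> list[int]:
    """Derive n deterministic per-sample seeds (< 2**31) from a master seed."""
    state = np.random.SeedSequence(master_seed).generate_state(n, dtype=np.uint32)
    return [int(s & 0x7FFFFFFF) for s in state]


def simulate_group(
    params: SimulationParams,
    n_samples: int,
    planted_keys: Sequence[tuple[str, Sequence[int]]] = (),
    label: str = "experimental",
    sample_prefix: str = "S",
    metadata: dict | None = None,
) -> tuple[SampleGroup, dict]:
    """Simulate a group of independent samples with per-sample seeds derived
    from the master seed; each planted (cdr3_aa, sample_indices) entry is
    injected as a clone into exactly the listed samples."""
    for cdr3_aa, indices in planted_keys:
        for idx in indices:
            if not (0 <= idx < n_samples):
                raise ValidationError(f"planted key {cdr3_aa!r} names sample index {idx} out of range")
        synthesize_cdr3(cdr3_aa)  # fail before any sampling if not constructible

    seeds = sample_seeds(params.seed, n_samples)
    repertoires: list[Repertoire] = []
    truths: dict[str, GroundTruth] = {}
    for i in range(n_samples):
        sid = f"{sample_prefix}{i:03d}"
        planted = [aa for aa, indices in planted_keys if i in indices]
        result = simulate_repertoire(
            replace(params, seed=seeds[i]), sample_id=sid, metadata=metadata, planted=planted
        )
        repertoires.append(result.repertoire)
        truths[sid] = result.truth
    group = SampleGroup(label=label, repertoires=repertoires)
    planted_map = {
        aa: [f"{sample_prefix}{i:03d}" for i in sorted(indices)] for aa, indices in planted_keys
    }
    return group, {"samples": truths, "planted": planted_map}


def emit_sample(result: SimulationResult, outdir: str | Path) -> dict[str, str]:
    """Write one simulated sample as native TSV + germline FASTA + boundary
    config + ground-truth JSON; returns the file map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sid = result.repertoire.sample_id
    files = {
        "clones": str(outdir / f"{sid}.clones.tsv"),
        "germline_fasta": str(outdir / "germline.fasta"),
        "boundaries": str(outdir / "boundaries.yaml"),
        "truth": str(outdir / f"{sid}.truth.json"),
    }
    write_clone_table(result.records, files["clones"])
    write_germline_fasta(default_germline(), files["germline_fasta"], files["boundaries"])
    result.truth.to_json(files["truth"])
    return files


def synthetic_antibody_db(
    seed: int,
    n_records: int = 100,
    diseases: Sequence[str] = ("HIV Infections", "COVID-19", "Influenza"),
    planted: Sequence[tuple[str, Sequence[str]]] = (),
    tag_probability: float = 0.8,
) -> list[AntibodyRecord]:
    """Generate a random antibody database for annotation/enrichment tests.

    ``planted`` entries are (cdr3_aa, disease list) records appended with
    deterministic ids.
    """
    rng = np.random.default_rng(seed)
    aa_pool = np.array(sorted(AA_ALPHABET))
    records: list[AntibodyRecord] = []
    for i in range(n_records):
        middle = "".join(rng.choice(aa_pool, int(rng.integers(6, 14))))
        tags: tuple[str, ...] = ()
        if rng.random() < tag_probability:
            n_tags = 1 + int(rng.random() < 0.15)
            tags = tuple(sorted(rng.choice(diseases, n_tags, replace=False)))
        records.append(
            AntibodyRecord(
                id=f"AB{i:05d}",
                source="known",
                cdr3_aa=f"C{middle}W",
                diseases=tags,
                description="synthetic database record",
            )
        )
    for i, (cdr3_aa, tag_list) in enumerate(planted):
        records.append(
            AntibodyRecord(
                id=f"PLANT{i:03d}",
                source="known",
                cdr3_aa=cdr3_aa,
                diseases=tuple(tag_list),
                description="synthetic planted record",
            )
        )
    return records
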
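"""Readers and writers for the formats the toolkit consumes and emits.

Supported inputs
----------------
* germline V/D/J/C segments as FASTA plus a region-boundary config (YAML),
* clone/read tables in three dialects:

  - ``airr``   — AIRR Rearrangement TSV (standard column names, 1-based
    closed coordinates converted at this boundary),
  - ``mixcr``  — a defined subset of MiXCR ``exportClones`` columns
    (cloneCount, allVHitsWithScore, ..., nSeqCDR3, refPoints),
  - ``native`` — this package's own flat TSV (column list in
    :data:`NATIVE_COLUMNS`); the only dialect with a writer, and the
    round-trip format used by the simulator,

* an antibody database as TSV (id, source, cdr3_aa, v_call, j_call, c_call,
  diseases, description).

All internal coordinates are 0-based half-open.

refPoints layout
----------------
The ``refPoints`` column is a colon-separated string of 21 slots of read
coordinates.  Only six slots are consumed here; the rest are carried opaquely:

====  =========================================================
slot  meaning
====  =========================================================
9     CDR3 begin (first base of the conserved Cys codon)
10    V 3' end (end of the V-aligned block, exclusive)
11    D 5' begin
12    D 3' end (exclusive)
13    J 5' begin
14    CDR3 end (exclusive; end of the conserved Trp codon)
15    D germline alignment begin (germline-D coordinate)
====  =========================================================

Slot 15 carries the germline coordinate at which the D alignment starts,
which is required to split the total D deletion into its 5' and 3' parts.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

NT_ALPHABET = frozenset("ACGT")
AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY")

V_REGIONS = ("FR1", "CDR1", "FR2", "CDR2", "FR3")

N_REFPOINT_SLOTS = 21
_RP_CDR3_BEGIN, _RP_V_END, _RP_D_BEGIN, _RP_D_END, _RP_J_BEGIN, _RP_CDR3_END, _RP_D_GERM_BEGIN = (
    9, 10, 11, 12, 13, 14, 15,
)


class RepscopeError(Exception):
    """Base class for all package errors."""


class FormatError(RepscopeError):
    """A file does not parse as the expected format."""


class SchemaError(RepscopeError):
    """A table is missing a mandatory column."""


class ValidationError(RepscopeError):
    """Content parses but violates a documented invariant."""


def translate_nt(nt: str) -> str:
    """Translate an in-frame nucleotide string with the standard code.

    Stop codons appear as ``*``. Raises :class:`ValidationError` when the
    length is not a multiple of three.
    """
    if len(nt) % 3 != 0:
        raise ValidationError(f"cannot translate sequence of length {len(nt)} (not a codon multiple)")
    return str(Seq(nt).translate())


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class JunctionFields:
    """Exonucleolytic deletion and non-templated insertion lengths at the
    two recombination joints.  ``None`` marks a value that is unavailable
    (typically because no D segment was assigned)."""

    v_del3: int | None = None
    d_del5: int | None = None
    d_del3: int | None = None
    j_del5: int | None = None
    ins_vd: int | None = None
    ins_dj: int | None = None

    def __post_init__(self) -> None:
        for name in ("v_del3", "d_del5", "d_del3", "j_del5", "ins_vd", "ins_dj"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValidationError(f"junction field {name} is negative: {v}")

    @property
    def complete(self) -> bool:
        return all(
            getattr(self, n) is not None
            for n in ("v_del3", "d_del5", "d_del3", "j_del5", "ins_vd", "ins_dj")
        )


@dataclass
class GermlineSegment:
    """One germline V/D/J/C allele with optional region boundaries.

    ``regions`` maps region names (FR1..FR3, CDR1/2 for V; FR4 for J, whose
    start marks the end of the J part of the CDR3) to 0-based half-open
    intervals on ``sequence``.  ``reading_frame_offset`` is the position of
    the first complete codon.
    """

    name: str
    segment_type: str
    sequence: str
    regions: dict[str, tuple[int, int]] = field(default_factory=dict)
    reading_frame_offset: int = 0

    def __post_init__(self) -> None:
        if self.segment_type not in {"V", "D", "J", "C"}:
            raise ValidationError(f"{self.name}: segment type {self.segment_type!r} not one of V/D/J/C")
        if not self.sequence:
            raise ValidationError(f"{self.name}: empty sequence")
        bad = set(self.sequence) - NT_ALPHABET
        if bad:
            raise ValidationError(
                f"{self.name}: sequence contains non-ACGT characters {sorted(bad)}"
            )
        if self.reading_frame_offset not in (0, 1, 2):
            raise ValidationError(f"{self.name}: reading frame offset must be 0, 1 or 2")
        ordered = dict(sorted(self.regions.items(), key=lambda kv: kv[1][0]))
        prev_end = None
        for region, (start, end) in ordered.items():
            if not (0 <= start < end <= len(self.sequence)):
                raise ValidationError(
                    f"{self.name}: region {region} interval ({start},{end}) outside sequence"
                )
            if prev_end is not None and start < prev_end:
                raise ValidationError(f"{self.name}: region {region} overlaps the previous region")
            prev_end = end
            if self.segment_type == "V" and (start - self.reading_frame_offset) % 3 != 0:
                raise ValidationError(
                    f"{self.name}: region {region} start {start} is not codon-aligned"
                )
        self.regions = ordered

    @property
    def gene(self) -> str:
        return gene_of(self.name)

    @property
    def cdr3_tail_start(self) -> int:
        """For V segments: germline position where the CDR3 part begins (FR3 end)."""
        if "FR3" not in self.regions:
            raise ValidationError(f"{self.name}: FR3 boundary required but absent")
        return self.regions["FR3"][1]

    @property
    def cdr3_head_end(self) -> int:
        """For J segments: germline position where the CDR3 part ends (FR4 start)."""
        if "FR4" not in self.regions:
            raise ValidationError(f"{self.name}: FR4 boundary required but absent")
        return self.regions["FR4"][0]


def gene_of(allele: str) -> str:
    """Collapse an allele name to its gene (truncate at '*')."""
    return allele.split("*", 1)[0]


@dataclass
class AlignedRecord:
    """One aligned read/clone row entering clonotyping."""

    record_id: str
    v_call: str
    j_call: str
    cdr3_nt: str
    duplicate_count: int = 1
    d_call: str | None = None
    c_call: str | None = None
    cdr3_aa: str | None = None
    mutation_events: tuple[tuple[int, str, str], ...] = ()
    junction_fields: JunctionFields | None = None

    def __post_init__(self) -> None:
        if not self.v_call or not self.j_call:
            raise ValidationError(f"{self.record_id}: records require both V and J calls")
        if not self.cdr3_nt:
            raise ValidationError(f"{self.record_id}: empty CDR3 nucleotide sequence")
        if self.duplicate_count < 1:
            raise ValidationError(f"{self.record_id}: duplicate_count must be positive")
        if self.cdr3_aa is not None and len(self.cdr3_nt) != 3 * len(self.cdr3_aa):
            raise ValidationError(
                f"{self.record_id}: cdr3_aa length inconsistent with cdr3_nt length"
            )
        for pos, src, dst in self.mutation_events:
            if src == dst:
                raise ValidationError(f"{self.record_id}: mutation event {pos}:{src}>{dst} is a no-op")


@dataclass
class AntibodyRecord:
    """One curated/therapeutic antibody (or exported repertoire clone)."""

    id: str
    source: str
    cdr3_aa: str
    v_call: str | None = None
    j_call: str | None = None
    c_call: str | None = None
    diseases: tuple[str, ...] = ()
    description: str = ""
    variable_nt: str | None = None
    variable_aa: str | None = None

    def __post_init__(self) -> None:
        if not self.cdr3_aa:
            raise ValidationError(f"antibody {self.id}: empty CDR3 aa")
        bad = set(self.cdr3_aa) - AA_ALPHABET
        if bad:
            raise ValidationError(
                f"antibody {self.id}: ambiguous CDR3 aa letters {sorted(bad)}"
            )


# ---------------------------------------------------------------------------
# germline FASTA + boundary config
# ---------------------------------------------------------------------------

def load_boundary_config(path: str | Path) -> dict:
    """Load a YAML region-boundary table: allele -> {regions: {name: [start, end]},
    reading_frame_offset: int}."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise FormatError(f"{path}: boundary config must be a mapping of allele -> entry")
    return cfg


def _infer_segment_type(name: str) -> str:
    m = re.match(r"IG[HKL]([VDJ])", name)
    if m:
        return m.group(1)
    if re.match(r"IGH[MDGAE]", name):
        return "C"
    raise ValidationError(f"cannot infer segment type from allele name {name!r}")


def read_germline_fasta(
    path: str | Path,
    boundary_config: Mapping[str, Mapping] | None = None,
) -> list[GermlineSegment]:
    """Read germline segments from FASTA, attaching region boundaries.

    ``boundary_config`` maps allele name to ``{"regions": {region: [start, end]},
    "reading_frame_offset": int}`` (or a YAML path loadable with
    :func:`load_boundary_config`).  V segments absent from the config are
    loaded with empty regions and a logged flag; config entries naming
    alleles absent from the FASTA are an error.
    """
    path = Path(path)
    if isinstance(boundary_config, (str, Path)):
        boundary_config = load_boundary_config(boundary_config)
    boundary_config = dict(boundary_config or {})

    with open(path) as fh:
        first = ""
        for lineno, line in enumerate(fh, start=1):
            if line.strip():
                first = line
                break
        if first and not first.startswith(">"):
            raise FormatError(f"{path}: line {lineno}: expected FASTA header starting with '>'")

    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        logger.warning("%s: empty germline FASTA, no segments loaded", path)
        return []

    names = {r.id for r in records}
    missing = sorted(set(boundary_config) - names)
    if missing:
        raise ValidationError(f"boundary config names alleles absent from {path}: {missing}")

    segments: list[GermlineSegment] = []
    for rec in records:
        entry = boundary_config.get(rec.id, {})
        regions = {
            str(k): (int(v[0]), int(v[1])) for k, v in (entry.get("regions") or {}).items()
        }
        seg = GermlineSegment(
            name=rec.id,
            segment_type=str(entry.get("type") or _infer_segment_type(rec.id)),
            sequence=str(rec.seq).upper(),
            regions=regions,
            reading_frame_offset=int(entry.get("reading_frame_offset", 0)),
        )
        if seg.segment_type == "V" and not seg.regions:
            logger.warning("%s: V segment %s has no boundary entry; regions empty", path, seg.name)
        segments.append(seg)
    return segments


def write_germline_fasta(
    segments: Sequence[GermlineSegment], fasta_path: str | Path, boundary_path: str | Path | None = None
) -> None:
    with open(fasta_path, "w") as fh:
        for seg in segments:
            fh.write(f">{seg.name}\n{seg.sequence}\n")
    if boundary_path is not None:
        cfg = {
            seg.name: {
                "type": seg.segment_type,
                "reading_frame_offset": seg.reading_frame_offset,
                "regions": {k: [int(a), int(b)] for k, (a, b) in seg.regions.items()},
            }
            for seg in segments
            if seg.regions or seg.reading_frame_offset
        }
        with open(boundary_path, "w") as fh:
            yaml.safe_dump(cfg, fh, sort_keys=True)


# ---------------------------------------------------------------------------
# refPoints
# ---------------------------------------------------------------------------

def _segment_lookup(germline: Iterable[GermlineSegment] | Mapping[str, GermlineSegment] | None):
    if germline is None:
        return {}
    if isinstance(germline, Mapping):
        segs = list(germline.values())
    else:
        segs = list(germline)
    table: dict[str, GermlineSegment] = {}
    for seg in segs:
        table[seg.name] = seg
        table.setdefault(seg.gene, seg)
    return table


def parse_refpoints(
    refpoints: str,
    v: GermlineSegment | None = None,
    d: GermlineSegment | None = None,
    j: GermlineSegment | None = None,
) -> JunctionFields:
    """Derive junction insertion/deletion lengths from a refPoints string.

    Insertions need only the read coordinates.  Deletions additionally need
    the germline segments (V FR3 end, J FR4 start, D length and the D
    germline alignment begin in slot 15); when a segment is not supplied the
    corresponding deletion fields are left unavailable (``None``).
    """
    slots = refpoints.split(":")
    if len(slots) < N_REFPOINT_SLOTS:
        raise FormatError(
            f"refPoints has {len(slots)} slots, {N_REFPOINT_SLOTS} required: {refpoints!r}"
        )

    def geti(idx: int) -> int | None:
        s = slots[idx].strip()
        return int(s) if s else None

    cdr3_begin = geti(_RP_CDR3_BEGIN)
    v_end = geti(_RP_V_END)
    d_begin = geti(_RP_D_BEGIN)
    d_end = geti(_RP_D_END)
    j_begin = geti(_RP_J_BEGIN)
    cdr3_end = geti(_RP_CDR3_END)
    d_germ_begin = geti(_RP_D_GERM_BEGIN)

    if v_end is None or j_begin is None:
        raise FormatError(f"refPoints lacks V-end or J-begin coordinates: {refpoints!r}")
    has_d = d_begin is not None and d_end is not None

    ins_vd = max(d_begin - v_end, 0) if has_d else None
    ins_dj = max(j_begin - d_end, 0) if has_d else None

    v_del3 = None
    if v is not None and cdr3_begin is not None:
        tail = len(v.sequence) - v.cdr3_tail_start
        v_del3 = tail - (v_end - cdr3_begin)
        if v_del3 < 0:
            raise ValidationError(
                f"inconsistent refPoints: V extent exceeds germline tail ({refpoints!r})"
            )
    j_del5 = None
    if j is not None and cdr3_end is not None:
        head = j.cdr3_head_end
        j_del5 = head - (cdr3_end - j_begin)
        if j_del5 < 0:
            raise ValidationError(
                f"inconsistent refPoints: J extent exceeds germline head ({refpoints!r})"
            )
    d_del5 = d_del3 = None
    if has_d and d is not None and d_germ_begin is not None:
        d_del5 = d_germ_begin
        d_del3 = len(d.sequence) - (d_germ_begin + (d_end - d_begin))
        if d_del3 < 0:
            raise ValidationError(
                f"inconsistent refPoints: D extent exceeds germline length ({refpoints!r})"
            )
    return JunctionFields(
        v_del3=v_del3, d_del5=d_del5, d_del3=d_del3, j_del5=j_del5, ins_vd=ins_vd, ins_dj=ins_dj
    )


def compose_refpoints(
    fields: JunctionFields,
    v: GermlineSegment,
    d: GermlineSegment,
    j: GermlineSegment,
) -> str:
    """Inverse of :func:`parse_refpoints` for complete junction fields, with
    the CDR3 placed at read coordinate 0."""
    if not fields.complete:
        raise ValidationError("compose_refpoints requires complete junction fields")
    slots = [""] * N_REFPOINT_SLOTS
    cdr3_begin = 0
    v_end = cdr3_begin + (len(v.sequence) - v.cdr3_tail_start) - fields.v_del3
    d_begin = v_end + fields.ins_vd
    d_aligned = len(d.sequence) - fields.d_del5 - fields.d_del3
    if d_aligned < 0:
        raise ValidationError("D deletions exceed germline D length")
    d_end = d_begin + d_aligned
    j_begin = d_end + fields.ins_dj
    cdr3_end = j_begin + j.cdr3_head_end - fields.j_del5
    slots[_RP_CDR3_BEGIN] = str(cdr3_begin)
    slots[_RP_V_END] = str(v_end)
    slots[_RP_D_BEGIN] = str(d_begin)
    slots[_RP_D_END] = str(d_end)
    slots[_RP_J_BEGIN] = str(j_begin)
    slots[_RP_CDR3_END] = str(cdr3_end)
    slots[_RP_D_GERM_BEGIN] = str(fields.d_del5)
    return ":".join(slots)


# ---------------------------------------------------------------------------
# clone tables
# ---------------------------------------------------------------------------

NATIVE_COLUMNS = (
    "record_id", "v_call", "d_call", "j_call", "c_call", "cdr3_nt", "cdr3_aa",
    "duplicate_count", "v_del3", "d_del5", "d_del3", "j_del5", "ins_vd", "ins_dj",
    "mutations",
)

_AIRR_MANDATORY = ("sequence_id", "v_call", "j_call", "junction", "duplicate_count")
_MIXCR_MANDATORY = ("cloneCount", "allVHitsWithScore", "allJHitsWithScore", "nSeqCDR3", "refPoints")
_NATIVE_MANDATORY = ("record_id", "v_call", "j_call", "cdr3_nt", "duplicate_count")

_HIT_RE = re.compile(r"([^,()]+)\((-?\d+(?:\.\d+)?)\)")


def best_hit(hits: str) -> str | None:
    """Pick the best-scoring allele from a MiXCR-style hit list such as
    ``"IGHV1-2*01(900),IGHV1-3*01(500)"``; ties break lexicographically."""
    if not hits or not hits.strip():
        return None
    parsed = _HIT_RE.findall(hits)
    if not parsed:
        # bare allele list without scores
        names = [h.strip() for h in hits.split(",") if h.strip()]
        return sorted(names)[0] if names else None
    return min(parsed, key=lambda nv: (-float(nv[1]), nv[0].strip()))[0].strip()


def _maybe_translate(cdr3_nt: str, fallback: str | None = None) -> str | None:
    if len(cdr3_nt) % 3 == 0 and set(cdr3_nt) <= NT_ALPHABET:
        return translate_nt(cdr3_nt)
    return fallback or None


def parse_mutation_string(text: str) -> tuple[tuple[int, str, str], ...]:
    """Parse the native ``"pos:from>to"`` comma list."""
    events = []
    for token in text.split(","):
        token = token.strip()
        if not token:
            continue
        m = re.fullmatch(r"(\d+):([ACGT])>([ACGT])", token)
        if not m:
            raise FormatError(f"malformed mutation token {token!r}")
        events.append((int(m.group(1)), m.group(2), m.group(3)))
    return tuple(events)


def format_mutation_string(events: Iterable[tuple[int, str, str]]) -> str:
    return ",".join(f"{p}:{a}>{b}" for p, a, b in events)


def _require_columns(df: pd.DataFrame, cols: Sequence[str], dialect: str, path) -> None:
    for col in cols:
        if col not in df.columns:
            raise SchemaError(f"{path}: {dialect} table is missing mandatory column {col!r}")


def read_clone_table(
    path: str | Path,
    dialect: str,
    germline: Iterable[GermlineSegment] | None = None,
    return_stats: bool = False,
):
    """Read a clone/read table in one of the three dialects.

    Rows lacking a V call, a J call, or a CDR3 are counted and skipped.
    With ``return_stats=True`` returns ``(records, {"skipped": n})``.
    """
    if dialect not in {"airr", "mixcr", "native"}:
        raise RepscopeError(f"unknown clone-table dialect {dialect!r}")
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    lookup = _segment_lookup(germline)

    records: list[AlignedRecord] = []
    skipped = 0

    if dialect == "airr":
        _require_columns(df, _AIRR_MANDATORY, dialect, path)
        for _, row in df.iterrows():
            v, j, junction = row["v_call"].strip(), row["j_call"].strip(), row["junction"].strip()
            if not v or not j or not junction:
                skipped += 1
                continue
            records.append(
                AlignedRecord(
                    record_id=row["sequence_id"],
                    v_call=v,
                    j_call=j,
                    d_call=row.get("d_call", "").strip() or None,
                    c_call=row.get("c_call", "").strip() or None,
                    cdr3_nt=junction.upper(),
                    cdr3_aa=_maybe_translate(junction.upper(), row.get("junction_aa", "").strip() or None),
                    duplicate_count=int(float(row["duplicate_count"] or 1)),
                )
            )
    elif dialect == "mixcr":
        _require_columns(df, _MIXCR_MANDATORY, dialect, path)
        for i, row in df.iterrows():
            v = best_hit(row["allVHitsWithScore"])
            jj = best_hit(row["allJHitsWithScore"])
            dd = best_hit(row.get("allDHitsWithScore", ""))
            cc = best_hit(row.get("allCHitsWithScore", ""))
            cdr3 = row["nSeqCDR3"].strip().upper()
            if not v or not jj or not cdr3:
                skipped += 1
                continue
            jf = None
            rp = row["refPoints"].strip()
            if rp:
                jf = parse_refpoints(
                    rp,
                    v=lookup.get(v) or lookup.get(gene_of(v)),
                    d=(lookup.get(dd) or lookup.get(gene_of(dd))) if dd else None,
                    j=lookup.get(jj) or lookup.get(gene_of(jj)),
                )
            records.append(
                AlignedRecord(
                    record_id=row.get("cloneId", str(i)),
                    v_call=v,
                    j_call=jj,
                    d_call=dd,
                    c_call=cc,
                    cdr3_nt=cdr3,
                    cdr3_aa=_maybe_translate(cdr3, row.get("aaSeqCDR3", "").strip() or None),
                    duplicate_count=int(float(row["cloneCount"])),
                    junction_fields=jf,
                )
            )
    else:  # native
        _require_columns(df, _NATIVE_MANDATORY, dialect, path)
        for _, row in df.iterrows():
            v, j, cdr3 = row["v_call"].strip(), row["j_call"].strip(), row["cdr3_nt"].strip()
            if not v or not j or not cdr3:
                skipped += 1
                continue

            def jfield(col: str, row=row) -> int | None:
                s = row.get(col, "").strip()
                return int(s) if s != "" else None

            vals = {c: jfield(c) for c in ("v_del3", "d_del5", "d_del3", "j_del5", "ins_vd", "ins_dj")}
            jf = JunctionFields(**vals) if any(x is not None for x in vals.values()) else None
            records.append(
                AlignedRecord(
                    record_id=row["record_id"],
                    v_call=v,
                    j_call=j,
                    d_call=row.get("d_call", "").strip() or None,
                    c_call=row.get("c_call", "").strip() or None,
                    cdr3_nt=cdr3.upper(),
                    cdr3_aa=row.get("cdr3_aa", "").strip() or _maybe_translate(cdr3.upper()),
                    duplicate_count=int(float(row["duplicate_count"])),
                    mutation_events=parse_mutation_string(row.get("mutations", "")),
                    junction_fields=jf,
                )
            )

    if skipped:
        logger.warning("%s: skipped %d rows lacking V call, J call or CDR3", path, skipped)
    if return_stats:
        return records, {"skipped": skipped}
    return records


def write_clone_table(records: Sequence[AlignedRecord], path: str | Path) -> None:
    """Write records in the native TSV dialect (lossless round-trip)."""
    rows = []
    for r in records:
        jf = r.junction_fields or JunctionFields()

        def fmt(v) -> str:
            return "" if v is None else str(v)

        rows.append(
            {
                "record_id": r.record_id,
                "v_call": r.v_call,
                "d_call": r.d_call or "",
                "j_call": r.j_call,
                "c_call": r.c_call or "",
                "cdr3_nt": r.cdr3_nt,
                "cdr3_aa": r.cdr3_aa or "",
                "duplicate_count": r.duplicate_count,
                "v_del3": fmt(jf.v_del3),
                "d_del5": fmt(jf.d_del5),
                "d_del3": fmt(jf.d_del3),
                "j_del5": fmt(jf.j_del5),
                "ins_vd": fmt(jf.ins_vd),
                "ins_dj": fmt(jf.ins_dj),
                "mutations": format_mutation_string(r.mutation_events),
            }
        )
    pd.DataFrame(rows, columns=NATIVE_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# antibody database
# ---------------------------------------------------------------------------

_AB_MANDATORY = ("id", "source", "cdr3_aa")


def read_antibody_db(path: str | Path, return_stats: bool = False):
    """Read the antibody-database TSV.

    Rows with empty or ambiguous (non-standard-letter) CDR3 aa are rejected
    with logged reasons; duplicate ids raise; zero valid records raise.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    _require_columns(df, _AB_MANDATORY, "antibody-db", path)
    records: list[AntibodyRecord] = []
    rejected: list[tuple[str, str]] = []
    for _, row in df.iterrows():
        cdr3 = row["cdr3_aa"].strip()
        rid = row["id"].strip()
        if not cdr3:
            rejected.append((rid, "empty cdr3_aa"))
            continue
        if set(cdr3) - AA_ALPHABET:
            rejected.append((rid, f"ambiguous cdr3_aa {cdr3!r}"))
            continue
        diseases = tuple(
            t.strip() for t in row.get("diseases", "").split(";") if t.strip()
        )
        records.append(
            AntibodyRecord(
                id=rid,
                source=row["source"].strip(),
                cdr3_aa=cdr3,
                v_call=row.get("v_call", "").strip() or None,
                j_call=row.get("j_call", "").strip() or None,
                c_call=row.get("c_call", "").strip() or None,
                diseases=diseases,
                description=row.get("description", ""),
                variable_nt=row.get("variable_nt", "").strip() or None,
                variable_aa=row.get("variable_aa", "").strip() or None,
            )
        )
    ids = [r.id for r in records]
    dupes = sorted({i for i in ids if ids.count(i) > 1})
    if dupes:
        raise ValidationError(f"{path}: duplicate antibody ids {dupes}")
    if not records:
        raise ValidationError(f"{path}: no valid antibody records")
    for rid, reason in rejected:
        logger.warning("%s: rejected antibody %s (%s)", path, rid, reason)
    if return_stats:
        return records, {"rejected": rejected}
    return records


def write_antibody_db(records: Sequence[AntibodyRecord], path: str | Path) -> None:
    rows = [
        {
            "id": r.id,
            "source": r.source,
            "cdr3_aa": r.cdr3_aa,
            "v_call": r.v_call or "",
            "j_call": r.j_call or "",
            "c_call": r.c_call or "",
            "diseases": "; ".join(r.diseases),
            "description": r.description,
            "variable_nt": r.variable_nt or "",
            "variable_aa": r.variable_aa or "",
        }
        for r in records
    ]
    pd.DataFrame(
        rows,
        columns=["id", "source", "cdr3_aa", "v_call", "j_call", "c_call", "diseases", "description", "variable_nt", "variable_aa"],
    ).to_csv(path, sep="\t", index=False)
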
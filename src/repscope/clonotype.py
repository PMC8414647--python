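"""Clonotype assignment: group aligned records into clones and call isotypes.

A clone is the set of records sharing the same V gene, J gene, optionally C
gene, and identical CDR3 nucleotide sequence.  Gene calls are collapsed to
gene level (allele truncated at ``*``) before grouping, since allele calls
are unstable across aligners.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .io import AlignedRecord, JunctionFields, ValidationError, gene_of

logger = logging.getLogger(__name__)

ISOTYPES = ("IGHM", "IGHD", "IGHG", "IGHA", "IGHE")
NA_ISOTYPE = "NA"

_ISOTYPE_RE = re.compile(r"^(IGH[MDGAE])")
_SCORED_HIT_RE = re.compile(r"([^,()]+)\((-?\d+(?:\.\d+)?)\)")


def assign_isotype(c_hits: Sequence) -> str:
    """Map C-gene hits to one of the six isotype categories.

    ``c_hits`` is a list of ``"IGHG1(500)"``-style strings or
    ``(name, score)`` pairs.  The best-scoring hit's IGH[MDGAE] prefix is the
    isotype; an empty list or an unrecognized name yields ``"NA"``.
    """
    parsed: list[tuple[str, float]] = []
    for hit in c_hits:
        if isinstance(hit, str):
            m = _SCORED_HIT_RE.fullmatch(hit.strip())
            if m:
                parsed.append((m.group(1).strip(), float(m.group(2))))
            elif hit.strip():
                parsed.append((hit.strip(), 0.0))
        else:
            name, score = hit
            parsed.append((str(name), float(score)))
    if not parsed:
        return NA_ISOTYPE
    best = min(parsed, key=lambda nv: (-nv[1], nv[0]))[0]
    m = _ISOTYPE_RE.match(best)
    if not m:
        logger.warning("C call %r does not match an IGH[MDGAE] prefix; isotype NA", best)
        return NA_ISOTYPE
    return m.group(1)


@dataclass
class Clone:
    """The analysis unit: a (V, J, [C], CDR3nt) group of supporting reads."""

    v_gene: str
    j_gene: str
    cdr3_nt: str
    c_gene: str | None = None
    d_gene: str | None = None  # informational; not part of the clone key
    cdr3_aa: str | None = None
    read_count: int = 1
    junction_fields: JunctionFields | None = None
    mutation_events_by_read: tuple[tuple[tuple[int, str, str], ...], ...] = ()

    @property
    def key(self) -> tuple:
        return (self.v_gene, self.j_gene, self.c_gene, self.cdr3_nt)

    @property
    def isotype(self) -> str:
        if self.c_gene is None:
            return NA_ISOTYPE
        return assign_isotype([(self.c_gene, 0.0)])


@dataclass
class Repertoire:
    """One sample's clone set plus metadata."""

    sample_id: str
    clones: list[Clone] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        keys = [c.key for c in self.clones]
        if len(keys) != len(set(keys)):
            raise ValidationError(f"{self.sample_id}: duplicate clone keys")

    @property
    def total_reads(self) -> int:
        return sum(c.read_count for c in self.clones)

    def frequencies(self) -> np.ndarray:
        """Read-weighted clone frequencies, aligned with ``self.clones``."""
        counts = np.array([c.read_count for c in self.clones], dtype=float)
        total = counts.sum()
        if total <= 0:
            return counts
        return counts / total


def cluster_clones(
    records: Iterable[AlignedRecord],
    use_c_gene: bool = True,
    sample_id: str = "sample",
    metadata: dict | None = None,
) -> Repertoire:
    """Cluster aligned records into clones.

    Records sharing (V gene, J gene, [C gene], CDR3 nt) form one clone whose
    read count is the sum of duplicate counts.  The clone's CDR3 aa and
    junction fields are taken from the highest-count supporting record
    (ties broken by record id).  Output order is descending read count, then
    lexicographic key.
    """
    records = list(records)
    if not records:
        logger.warning("%s: no records to cluster; empty repertoire", sample_id)
        return Repertoire(sample_id=sample_id, metadata=metadata or {})

    groups: dict[tuple, list[AlignedRecord]] = {}
    for rec in records:
        c_gene = gene_of(rec.c_call) if (use_c_gene and rec.c_call) else None
        key = (gene_of(rec.v_call), gene_of(rec.j_call), c_gene, rec.cdr3_nt)
        groups.setdefault(key, []).append(rec)

    clones: list[Clone] = []
    for (v_gene, j_gene, c_gene, cdr3_nt), recs in groups.items():
        exemplar = max(recs, key=lambda r: (r.duplicate_count, r.record_id))
        clones.append(
            Clone(
                v_gene=v_gene,
                j_gene=j_gene,
                c_gene=c_gene,
                d_gene=gene_of(exemplar.d_call) if exemplar.d_call else None,
                cdr3_nt=cdr3_nt,
                cdr3_aa=exemplar.cdr3_aa,
                read_count=sum(r.duplicate_count for r in recs),
                junction_fields=exemplar.junction_fields,
                mutation_events_by_read=tuple(
                    r.mutation_events for r in sorted(recs, key=lambda r: r.record_id)
                ),
            )
        )
    clones.sort(key=lambda c: (-c.read_count, _sortable_key(c)))
    return Repertoire(sample_id=sample_id, clones=clones, metadata=metadata or {})


def _sortable_key(clone: Clone) -> tuple:
    return (clone.v_gene, clone.j_gene, clone.c_gene or "", clone.cdr3_nt)


def flatten_repertoire(repertoire: Repertoire) -> list[AlignedRecord]:
    """Expand a repertoire back into one record per supporting read
    (inverse-ish of :func:`cluster_clones`; used for idempotence checks and
    re-export)."""
    out: list[AlignedRecord] = []
    for ci, clone in enumerate(repertoire.clones):
        per_read = clone.mutation_events_by_read or ((),)
        n = len(per_read)
        base, extra = divmod(clone.read_count, n)
        for ri, events in enumerate(per_read):
            count = base + (1 if ri < extra else 0)
            if count == 0:
                count = 1
            out.append(
                AlignedRecord(
                    record_id=f"{repertoire.sample_id}:{ci}:{ri}",
                    v_call=clone.v_gene,
                    j_call=clone.j_gene,
                    d_call=clone.d_gene,
                    c_call=clone.c_gene,
                    cdr3_nt=clone.cdr3_nt,
                    cdr3_aa=clone.cdr3_aa,
                    duplicate_count=count,
                    mutation_events=events,
                    junction_fields=clone.junction_fields,
                )
            )
    return out
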
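"""Antibody annotation, disease enrichment, and sequence query.

Clones are annotated by exact, case-sensitive CDR3 amino-acid identity to
database antibodies.  Disease over-representation among the annotated clones
is tested with the hypergeometric upper tail P(X >= k) and controlled with
Benjamini-Hochberg FDR across the diseases observed in the sample.  Sequence
query returns exact matches in amino-acid mode and >= 90%-identity matches in
nucleotide mode (semi-global alignment; identity = matches over alignment
columns including gaps, the whole query being aligned).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import edlib
import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .clonotype import Repertoire
from .io import AntibodyRecord, RepscopeError, ValidationError

logger = logging.getLogger(__name__)

NT_IDENTITY_THRESHOLD = 0.90


@dataclass
class CloneAnnotation:
    clone_key: tuple
    cdr3_aa: str
    matched_antibody_ids: tuple[str, ...]
    diseases: tuple[str, ...]


@dataclass
class EnrichmentRow:
    disease: str
    k: int  # annotated clones tagged with the disease
    n: int  # annotated clones with any disease tag
    K: int  # database records tagged with the disease
    N: int  # database records in the universe
    p_value: float
    p_adj: float
    significant: bool = False


@dataclass
class QueryHit:
    query_id: str
    subject_id: str
    scope: str  # "cdr3" | "vregion"
    mode: str  # "nt" | "aa"
    identity: float


def match_clones_to_db(
    repertoire: Repertoire, db: Sequence[AntibodyRecord]
) -> list[CloneAnnotation]:
    """Annotate clones whose CDR3 aa exactly equals a database record's."""
    if not db:
        raise ValidationError("empty antibody database")
    index: dict[str, list[AntibodyRecord]] = {}
    for rec in db:
        index.setdefault(rec.cdr3_aa, []).append(rec)
    annotations: list[CloneAnnotation] = []
    for clone in repertoire.clones:
        if not clone.cdr3_aa:
            continue
        hits = index.get(clone.cdr3_aa)
        if not hits:
            continue
        diseases = sorted({d for rec in hits for d in rec.diseases})
        annotations.append(
            CloneAnnotation(
                clone_key=clone.key,
                cdr3_aa=clone.cdr3_aa,
                matched_antibody_ids=tuple(r.id for r in hits),
                diseases=tuple(diseases),
            )
        )
    return annotations


def hypergeom_upper_tail(k: int, n: int, K: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N population, K successes, n draws)."""
    for name, v in (("k", k), ("n", n), ("K", K), ("N", N)):
        if not isinstance(v, (int, np.integer)) or v < 0:
            raise ValidationError(f"hypergeometric argument {name}={v!r} must be a non-negative integer")
    if n > N or K > N or k > min(n, K):
        raise ValidationError(f"inconsistent hypergeometric arguments k={k}, n={n}, K={K}, N={N}")
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjustment, returned in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if ((p < 0) | (p > 1)).any():
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adjusted = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(adjusted[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m, dtype=float)
    out[order] = adjusted
    return out.tolist()


def disease_enrichment(
    annotations: Sequence[CloneAnnotation],
    db: Sequence[AntibodyRecord],
    significance_cutoff: float = 0.05,
    universe: str = "tagged",
) -> list[EnrichmentRow]:
    """Hypergeometric disease enrichment over annotated clones.

    Universe N is the database records with at least one disease tag
    (``universe="tagged"``, default) or all records (``"all"``); K counts
    records tagged with the disease; n counts annotated clones carrying any
    tag; k counts annotated clones carrying the disease (a clone counts once
    per disease).  One row per disease with k >= 1, BH-adjusted across those
    rows; rows with adjusted p below the cutoff are flagged significant.
    The full table is returned sorted by p-value.
    """
    if universe not in {"tagged", "all"}:
        raise RepscopeError(f"unknown enrichment universe {universe!r}")
    if not (0 < significance_cutoff < 1):
        raise ValidationError("significance cutoff must lie in (0, 1)")
    universe_records = [r for r in db if r.diseases] if universe == "tagged" else list(db)
    N = len(universe_records)
    K_by_disease: dict[str, int] = {}
    for rec in universe_records:
        for d in set(rec.diseases):
            K_by_disease[d] = K_by_disease.get(d, 0) + 1

    tagged_annotations = [a for a in annotations if a.diseases]
    n = len(tagged_annotations)
    if n == 0:
        logger.warning("no annotated clone carries a disease tag; empty enrichment")
        return []
    k_by_disease: dict[str, int] = {}
    for a in tagged_annotations:
        for d in set(a.diseases):
            k_by_disease[d] = k_by_disease.get(d, 0) + 1

    rows: list[EnrichmentRow] = []
    for disease in sorted(k_by_disease):
        k = k_by_disease[disease]
        K = K_by_disease.get(disease, 0)
        if K == 0:
            # disease tag came from a record outside the chosen universe
            continue
        p = hypergeom_upper_tail(min(k, K), n, K, N)
        rows.append(EnrichmentRow(disease=disease, k=k, n=n, K=K, N=N, p_value=p, p_adj=1.0))
    adj = bh_adjust([r.p_value for r in rows])
    for row, a in zip(rows, adj):
        row.p_adj = a
        row.significant = a < significance_cutoff
    rows.sort(key=lambda r: (r.p_value, r.disease))
    return rows


# ---------------------------------------------------------------------------
# sequence query
# ---------------------------------------------------------------------------

def _cigar_identity(cigar: str) -> tuple[int, int]:
    """(matches, alignment columns) from an edlib extended CIGAR."""
    matches = columns = 0
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            count = int(num)
            num = ""
            columns += count
            if ch == "=":
                matches += count
    return matches, columns


def _safe_seed_length(query_len: int, threshold: float) -> int:
    # pigeonhole: <= floor(L * (1 - threshold)) mismatches/indels split the
    # query into runs, the longest of which has length >= L // (maxdiff + 1)
    max_diff = int(query_len * (1.0 - threshold))
    return max(4, query_len // (max_diff + 1))


def sequence_query(
    query: str,
    subjects: Mapping[str, str],
    mode: str = "aa",
    scope: str = "cdr3",
    query_id: str = "query",
) -> list[QueryHit]:
    """Search subject sequences for a query.

    ``subjects`` maps subject id to the scoped sequence (CDR3 or variable
    region, nt or aa to match ``mode``).  Amino-acid mode reports exact
    full-string matches; nucleotide mode reports subjects whose best
    semi-global alignment of the query reaches >= 90% identity.  Hits are
    sorted by identity descending, then subject id.
    """
    if not query:
        raise RepscopeError("empty query sequence")
    if mode not in {"nt", "aa"}:
        raise RepscopeError(f"unknown query mode {mode!r}")
    query = query.upper()
    hits: list[QueryHit] = []
    if mode == "aa":
        for sid, seq in subjects.items():
            if seq.upper() == query:
                hits.append(QueryHit(query_id, sid, scope, mode, 1.0))
    else:
        k = _safe_seed_length(len(query), NT_IDENTITY_THRESHOLD)
        seeds = {query[i : i + k] for i in range(0, len(query) - k + 1)}
        for sid, seq in subjects.items():
            seq = seq.upper()
            if len(seq) >= k and not any(s in seq for s in seeds):
                continue
            result = edlib.align(query, seq, mode="HW", task="path")
            if result["editDistance"] < 0 or not result.get("cigar"):
                continue
            matches, columns = _cigar_identity(result["cigar"])
            identity = matches / columns if columns else 0.0
            if identity >= NT_IDENTITY_THRESHOLD:
                hits.append(QueryHit(query_id, sid, scope, mode, identity))
    hits.sort(key=lambda h: (-h.identity, h.subject_id))
    return hits


def build_subject_index(
    db: Sequence[AntibodyRecord], scope: str = "cdr3", mode: str = "aa"
) -> dict[str, str]:
    """Extract the scoped sequences from antibody records for querying."""
    out: dict[str, str] = {}
    for rec in db:
        if scope == "cdr3" and mode == "aa":
            seq = rec.cdr3_aa
        elif scope == "vregion" and mode == "nt":
            seq = rec.variable_nt
        elif scope == "vregion" and mode == "aa":
            seq = rec.variable_aa
        else:
            raise RepscopeError(
                "cdr3 nucleotide queries index repertoire clones, not antibody records"
            )
        if seq:
            out[rec.id] = seq
    return out


def clone_subject_index(repertoire: Repertoire, mode: str = "nt") -> dict[str, str]:
    """Index a repertoire's clone CDR3s for querying (nt or aa)."""
    out: dict[str, str] = {}
    for i, clone in enumerate(repertoire.clones):
        seq = clone.cdr3_nt if mode == "nt" else (clone.cdr3_aa or "")
        if seq:
            out[f"{repertoire.sample_id}:clone{i}"] = seq
    return out


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_annotations(annotations: Sequence[CloneAnnotation], outdir: str | Path) -> tuple[str, int]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = [
        {
            "v_gene": a.clone_key[0],
            "j_gene": a.clone_key[1],
            "c_gene": a.clone_key[2] or "",
            "cdr3_nt": a.clone_key[3],
            "cdr3_aa": a.cdr3_aa,
            "matched_ids": ";".join(a.matched_antibody_ids),
            "diseases": ";".join(a.diseases),
        }
        for a in annotations
    ]
    pd.DataFrame(
        rows, columns=["v_gene", "j_gene", "c_gene", "cdr3_nt", "cdr3_aa", "matched_ids", "diseases"]
    ).to_csv(outdir / "annotations.tsv", sep="\t", index=False)
    return "annotations.tsv", len(rows)


def write_enrichment(rows: Sequence[EnrichmentRow], outdir: str | Path) -> tuple[str, int]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table = [
        {
            "disease": r.disease,
            "k": r.k,
            "n": r.n,
            "K": r.K,
            "N": r.N,
            "p_value": r.p_value,
            "p_adj": r.p_adj,
            "significant": r.significant,
        }
        for r in rows
    ]
    pd.DataFrame(
        table, columns=["disease", "k", "n", "K", "N", "p_value", "p_adj", "significant"]
    ).to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
    return "enrichment.tsv", len(table)


def write_query_hits(hits: Sequence[QueryHit], outdir: str | Path) -> tuple[str, int]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = [
        {
            "query_id": h.query_id,
            "subject_id": h.subject_id,
            "scope": h.scope,
            "mode": h.mode,
            "identity": h.identity,
        }
        for h in hits
    ]
    pd.DataFrame(rows, columns=["query_id", "subject_id", "scope", "mode", "identity"]).to_csv(
        outdir / "query_hits.tsv", sep="\t", index=False
    )
    return "query_hits.tsv", len(rows)
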
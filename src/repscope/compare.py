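"""Group comparison of repertoire features and public-clone detection.

An experimental group of uploaded samples is compared against a reference
group selected from a catalog by exact metadata match (tissue, health
condition, amplification strategy, primer locations, read length, isotype,
age, sex).  Each feature is summarized per category by the reference group's
five-number summary, with the experimental samples overlaid as points.
Public clones are CDR3 (or clone-key) matches shared across samples:
intragroup when all carriers are experimental samples, intergroup when
carriers span both groups.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .clonotype import Clone, Repertoire
from .io import RepscopeError, ValidationError
from . import features as feat

logger = logging.getLogger(__name__)

SHARING_KEYS = ("cdr3aa", "cdr3nt", "vj_cdr3nt")


@dataclass
class SampleGroup:
    label: str
    repertoires: list[Repertoire] = field(default_factory=list)
    selection_criteria: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [r.sample_id for r in self.repertoires]
        if len(ids) != len(set(ids)):
            raise ValidationError(f"group {self.label}: duplicate sample ids")


@dataclass
class FeatureComparison:
    feature_name: str
    categories: list
    reference_summary: dict  # category -> (min, q1, median, q3, max, n)
    experimental_points: dict  # category -> {sample_id: value}


@dataclass
class PublicCloneRecord:
    sharing_key: str
    exp_samples: tuple[str, ...]
    ref_samples: tuple[str, ...]
    clone_class: str  # "intragroup" | "intergroup"


def select_reference(catalog: Sequence[Repertoire], criteria: dict) -> SampleGroup:
    """Filter a repertoire catalog by exact match on each provided metadata
    criterion; unspecified criteria match everything."""
    matches = [
        r
        for r in catalog
        if all(r.metadata.get(k) == v for k, v in criteria.items())
    ]
    if not matches:
        raise RepscopeError(
            f"no catalog sample matches criteria {criteria}; relax the selection"
        )
    matches.sort(key=lambda r: r.sample_id)
    return SampleGroup(label="reference", repertoires=matches, selection_criteria=dict(criteria))


# --- feature registry: feature name -> (Repertoire -> {category: value}) ----

def _usage_feature(seg: str) -> Callable[[Repertoire], dict]:
    def fn(rep: Repertoire) -> dict:
        return dict(feat.gene_usage(rep, seg).freq)
    return fn


def _length_feature(unit: str) -> Callable[[Repertoire], dict]:
    def fn(rep: Repertoire) -> dict:
        return dict(feat.cdr3_length_distribution(rep, unit).freq)
    return fn


def _junction_feature(rep: Repertoire) -> dict:
    profile = feat.junction_profile(rep)
    out: dict[str, float] = {}
    for site, dist in profile.deletion_freq.items():
        for L, f in dist.items():
            out[f"del_{site}_{L}"] = f
    for site, dist in profile.insertion_freq.items():
        for L, f in dist.items():
            out[f"ins_{site}_{L}"] = f
    return out


def _diversity_feature(rep: Repertoire) -> dict:
    idx = feat.diversity_indices(rep)
    return {
        "shannon": idx.shannon,
        "simpson": idx.simpson,
        "d50": idx.d50,
        "top100_fraction": idx.top100_fraction,
    }


FEATURES: dict[str, Callable[[Repertoire], dict]] = {
    "v_usage": _usage_feature("V"),
    "d_usage": _usage_feature("D"),
    "j_usage": _usage_feature("J"),
    "cdr3_length_nt": _length_feature("nt"),
    "cdr3_length_aa": _length_feature("aa"),
    "junction": _junction_feature,
    "diversity": _diversity_feature,
}


def compare_feature(exp: SampleGroup, ref: SampleGroup, feature_name: str) -> FeatureComparison:
    """Reference five-number summary (linear-interpolation quantiles) per
    category, with every experimental sample's value; categories are the
    union over both groups and absent distribution values count as 0."""
    if feature_name not in FEATURES:
        raise RepscopeError(f"unknown feature {feature_name!r}; known: {sorted(FEATURES)}")
    fn = FEATURES[feature_name]
    try:
        exp_tables = {r.sample_id: fn(r) for r in exp.repertoires}
        ref_tables = {r.sample_id: fn(r) for r in ref.repertoires}
    except ValidationError as e:
        raise RepscopeError(f"feature {feature_name} unavailable: {e}") from e

    categories = sorted(
        {c for t in (*exp_tables.values(), *ref_tables.values()) for c in t},
        key=lambda c: (isinstance(c, str), c),
    )
    summary = {}
    points = {}
    n_ref = len(ref.repertoires)
    for cat in categories:
        vals = np.array([ref_tables[s].get(cat, 0.0) for s in ref_tables], dtype=float)
        summary[cat] = (
            float(vals.min()),
            float(np.percentile(vals, 25)),
            float(np.percentile(vals, 50)),
            float(np.percentile(vals, 75)),
            float(vals.max()),
            n_ref,
        )
        points[cat] = {s: float(exp_tables[s].get(cat, 0.0)) for s in exp_tables}
    return FeatureComparison(
        feature_name=feature_name,
        categories=categories,
        reference_summary=summary,
        experimental_points=points,
    )


def clone_sharing_key(clone: Clone, mode: str) -> str:
    if mode == "cdr3aa":
        return clone.cdr3_aa or ""
    if mode == "cdr3nt":
        return clone.cdr3_nt
    if mode == "vj_cdr3nt":
        return f"{clone.v_gene}|{clone.j_gene}|{clone.cdr3_nt}"
    raise RepscopeError(f"unknown sharing key {mode!r}; known: {SHARING_KEYS}")


def detect_public_clones(
    exp: SampleGroup,
    ref: SampleGroup | None = None,
    sharing_key: str = "cdr3aa",
    min_share: int = 2,
) -> list[PublicCloneRecord]:
    """Detect keys shared by at least ``min_share`` samples.

    A key counts once per sample regardless of clone multiplicity.
    Intragroup records carry only experimental samples; intergroup records
    span both groups (total carrier count >= ``min_share``).  Keys carried
    only by reference samples are not reported.
    """
    if min_share < 2:
        raise ValidationError("min_share must be >= 2")
    exp_map: dict[str, set[str]] = {}
    ref_map: dict[str, set[str]] = {}
    for rep in exp.repertoires:
        for clone in rep.clones:
            key = clone_sharing_key(clone, sharing_key)
            if key:
                exp_map.setdefault(key, set()).add(rep.sample_id)
    for rep in (ref.repertoires if ref else []):
        for clone in rep.clones:
            key = clone_sharing_key(clone, sharing_key)
            if key:
                ref_map.setdefault(key, set()).add(rep.sample_id)

    records: list[PublicCloneRecord] = []
    for key, exp_samples in exp_map.items():
        ref_samples = ref_map.get(key, set())
        if ref_samples:
            if len(exp_samples) + len(ref_samples) >= min_share:
                records.append(
                    PublicCloneRecord(
                        sharing_key=key,
                        exp_samples=tuple(sorted(exp_samples)),
                        ref_samples=tuple(sorted(ref_samples)),
                        clone_class="intergroup",
                    )
                )
        elif len(exp_samples) >= min_share:
            records.append(
                PublicCloneRecord(
                    sharing_key=key,
                    exp_samples=tuple(sorted(exp_samples)),
                    ref_samples=(),
                    clone_class="intragroup",
                )
            )
    records.sort(key=lambda r: (-(len(r.exp_samples) + len(r.ref_samples)), r.sharing_key))
    return records


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_comparison(comparison: FeatureComparison, outdir: str | Path) -> tuple[str, int]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for cat in comparison.categories:
        mn, q1, med, q3, mx, n = comparison.reference_summary[cat]
        row = {
            "category": cat,
            "ref_min": mn,
            "ref_q1": q1,
            "ref_median": med,
            "ref_q3": q3,
            "ref_max": mx,
            "ref_n": n,
        }
        for sample, value in comparison.experimental_points[cat].items():
            row[f"exp_{sample}"] = value
        rows.append(row)
    name = f"comparison_{comparison.feature_name}.tsv"
    pd.DataFrame(rows).to_csv(outdir / name, sep="\t", index=False)
    return name, len(rows)


def write_public_clones(records: Sequence[PublicCloneRecord], outdir: str | Path) -> tuple[str, int]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = [
        {
            "sharing_key": r.sharing_key,
            "class": r.clone_class,
            "n_exp_samples": len(r.exp_samples),
            "n_ref_samples": len(r.ref_samples),
            "exp_samples": ";".join(r.exp_samples),
            "ref_samples": ";".join(r.ref_samples),
        }
        for r in records
    ]
    pd.DataFrame(
        rows,
        columns=["sharing_key", "class", "n_exp_samples", "n_ref_samples", "exp_samples", "ref_samples"],
    ).to_csv(outdir / "public_clones.tsv", sep="\t", index=False)
    return "public_clones.tsv", len(rows)
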
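"""Candidate-gene mapping: genes overlapping significant zones plus the
nearest flanking gene on each side, and upset-style sharing across
variables."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import gffutils
import pandas as pd

from .localscore import SignificantZone

__all__ = [
    "GeneAnnotation",
    "read_gff_genes",
    "zone_to_genes",
    "candidate_table",
    "shared_gene_sets",
    "unique_fractions",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneAnnotation:
    """One gene: 1-based inclusive coordinates as in GFF3."""

    gene_id: str
    scaffold: str
    start: int
    end: int
    strand: str = "."
    product: str | None = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"gene {self.gene_id}: start > end")


def read_gff_genes(path: str | Path) -> list[GeneAnnotation]:
    """Parse gene records from a GFF3 file (in-memory gffutils database)."""
    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True, merge_strategy="merge"
    )
    genes = []
    for feat in db.features_of_type("gene"):
        genes.append(
            GeneAnnotation(
                gene_id=feat.id,
                scaffold=feat.seqid,
                start=feat.start,
                end=feat.end,
                strand=feat.strand or ".",
                product=(feat.attributes.get("product") or [None])[0],
            )
        )
    genes.sort(key=lambda g: (g.scaffold, g.start, g.end))
    return genes


def zone_to_genes(
    zones: list[SignificantZone],
    genes: list[GeneAnnotation],
) -> dict[tuple[str, int, int], list[tuple[GeneAnnotation, str]]]:
    """Candidates per zone: overlapping genes (>= 1 bp) plus the single
    nearest non-overlapping gene on each side, strand-agnostic.

    Returns a mapping from (scaffold, start, end) to a deduplicated list of
    (gene, relation) with relation in {overlap, upstream, downstream}.
    """
    by_scaf: dict[str, list[GeneAnnotation]] = {}
    for g in sorted(genes, key=lambda g: (g.scaffold, g.start, g.end)):
        by_scaf.setdefault(g.scaffold, []).append(g)

    out: dict[tuple[str, int, int], list[tuple[GeneAnnotation, str]]] = {}
    for z in zones:
        key = (z.scaffold, z.start, z.end)
        scaf_genes = by_scaf.get(z.scaffold)
        if not scaf_genes:
            log.warning("zone %s:%d-%d on unannotated scaffold", *key)
            out[key] = []
            continue
        cands: list[tuple[GeneAnnotation, str]] = []
        upstream = downstream = None
        for g in scaf_genes:
            if g.end >= z.start and g.start <= z.end:
                cands.append((g, "overlap"))
            elif g.end < z.start:
                # nearest on the left; ties broken toward the later start,
                # then lexically, for record-order independence
                if upstream is None or (g.end, g.start, g.gene_id) > (
                    upstream.end, upstream.start, upstream.gene_id
                ):
                    upstream = g
            elif g.start > z.end:
                if downstream is None or (-g.start, -g.end, g.gene_id) > (
                    -downstream.start, -downstream.end, downstream.gene_id
                ):
                    downstream = g
        if upstream is not None:
            cands.append((upstream, "upstream"))
        if downstream is not None:
            cands.append((downstream, "downstream"))
        seen: set[str] = set()
        dedup = []
        for g, rel in cands:
            if g.gene_id not in seen:
                seen.add(g.gene_id)
                dedup.append((g, rel))
        out[key] = dedup
    return out


def candidate_table(
    per_variable_zones: dict[str, list[SignificantZone]],
    genes: list[GeneAnnotation],
) -> pd.DataFrame:
    """Long-format candidate gene table across variables."""
    rows = []
    for variable, zones in per_variable_zones.items():
        mapping = zone_to_genes(zones, genes)
        for (scaf, start, end), cands in mapping.items():
            for g, rel in cands:
                rows.append(
                    {
                        "variable": variable,
                        "zone": f"{scaf}:{start}-{end}",
                        "gene_id": g.gene_id,
                        "relation": rel,
                    }
                )
    return pd.DataFrame(rows, columns=["variable", "zone", "gene_id", "relation"])


def shared_gene_sets(per_variable_candidates: dict[str, set[str]]) -> pd.DataFrame:
    """Upset-style exclusive intersection sizes.

    One row per non-empty variable combination that exclusively contains at
    least one element; exclusive sizes sum to the union cardinality.
    """
    if not per_variable_candidates:
        raise ValueError("need at least one variable")
    variables = list(per_variable_candidates)
    membership: dict[str, frozenset[str]] = {}
    for v, items in per_variable_candidates.items():
        for it in items:
            membership[it] = membership.get(it, frozenset()) | {v}
    combo_counts: dict[frozenset[str], int] = {}
    for combo in membership.values():
        combo_counts[combo] = combo_counts.get(combo, 0) + 1
    rows = []
    for r in range(len(variables), 0, -1):
        for combo in combinations(variables, r):
            fs = frozenset(combo)
            if fs in combo_counts:
                rows.append(
                    {
                        "combination": "&".join(v for v in variables if v in fs),
                        "degree": r,
                        "exclusive_size": combo_counts[fs],
                    }
                )
    df = pd.DataFrame(rows, columns=["combination", "degree", "exclusive_size"])
    df.attrs["union_size"] = len(membership)
    return df


def unique_fractions(per_variable_candidates: dict[str, set[str]]) -> pd.DataFrame:
    """Per variable: total members, members shared with no other variable,
    and the percentage unique — the upset summary reported for top-SNP
    sharing across ecological variables."""
    rows = []
    for v, items in per_variable_candidates.items():
        others = set().union(
            *(s for w, s in per_variable_candidates.items() if w != v)
        ) if len(per_variable_candidates) > 1 else set()
        unique = len(items - others)
        rows.append(
            {
                "variable": v,
                "n_total": len(items),
                "n_unique": unique,
                "pct_unique": 100.0 * unique / len(items) if items else float("nan"),
            }
        )
    return pd.DataFrame(rows, columns=["variable", "n_total", "n_unique", "pct_unique"])
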
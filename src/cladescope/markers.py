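"""Evolutionary profiling of single-cell cluster marker genes.

Cluster markers (a Seurat-style table) are filtered, each surviving marker
is annotated with the lineage-specificity of its orthogroup against a
configurable clade ladder, and per-cluster / per-cell-type profiles are
summarized: proportion of markers per category and the fraction of markers
that are lineage-specific (confined within the focal phylum or narrower).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .specificity import SpecificityAssignment, sharing_spectrum

logger = logging.getLogger(__name__)

NOT_ASSIGNED = "not_assigned"
OTHER_MULTISPECIES = "other_multispecies"


@dataclass(frozen=True)
class FilterCriteria:
    """Marker filter thresholds (Seurat-style defaults)."""

    max_p_adj: float = 0.05
    min_log2fc: float = 0.25
    min_pct_in: float = 0.25
    max_pct_out: float = 1.0
    positive_only: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.max_p_adj <= 1.0:
            raise ValueError("max_p_adj must be in [0, 1]")

    def mask(self, markers: pd.DataFrame) -> pd.Series:
        keep = (
            (markers["p_val_adj"] <= self.max_p_adj)
            & (markers["avg_log2FC"] >= self.min_log2fc)
            & (markers["pct_in"] >= self.min_pct_in)
            & (markers["pct_out"] <= self.max_pct_out)
        )
        if self.positive_only:
            keep &= markers["avg_log2FC"] > 0
        return keep


def filter_markers(markers: pd.DataFrame,
                   criteria: FilterCriteria = FilterCriteria()) -> pd.DataFrame:
    """Keep rows passing every criterion; log per-cluster kept/dropped."""
    keep = criteria.mask(markers)
    for cluster, grp in markers.groupby("cluster"):
        kept = int(keep[grp.index].sum())
        logger.info("filter_markers: cluster %s kept %d / %d",
                    cluster, kept, len(grp))
    out = markers[keep].reset_index(drop=True)
    if out.empty:
        logger.warning("filter_markers: no markers survived filtering")
    return out


def category_ladder(ladder_clades: Sequence[str], focal_species: str) -> list[str]:
    """Full ordered category list: unassigned, focal-specific, one bucket
    per ladder clade (least inclusive first), then the residual bucket."""
    return [NOT_ASSIGNED, f"{focal_species}_specific",
            *[f"{c}_confined" for c in ladder_clades], OTHER_MULTISPECIES]


def assign_marker_categories(
    markers: pd.DataFrame,
    assignment: SpecificityAssignment,
    ladder: Sequence[str],
    gene_to_og: Mapping[str, str],
    focal_species: str,
) -> pd.DataFrame:
    """Annotate each marker with its lineage-specificity category.

    ``ladder`` lists clade names ordered least -> most inclusive (e.g.
    genus, Hydrozoa, Medusozoa, Cnidaria, Metazoa).  A marker's category is:
    the focal-species-specific bucket when its orthogroup has a single
    possessor species; otherwise the *smallest* ladder clade its orthogroup
    is confined to; the residual multispecies bucket when confined to none;
    or not-assigned when the gene maps to no orthogroup.
    """
    for clade in ladder:
        if clade not in assignment.clades:
            raise KeyError(f"ladder clade {clade!r} not in clade map")
    categories: list[str] = []
    n_poss: list[int] = []
    ogs: list[Optional[str]] = []
    for gene in markers["gene"]:
        og = gene_to_og.get(gene)
        if og is None:
            categories.append(NOT_ASSIGNED)
            n_poss.append(0)
            ogs.append(None)
            continue
        if og not in assignment:
            raise KeyError(f"marker gene {gene!r} maps to unknown orthogroup {og!r}")
        rec = assignment[og]
        ogs.append(og)
        n_poss.append(rec.n_species)
        if rec.species_specific:
            categories.append(f"{focal_species}_specific")
            continue
        confined = set(rec.confined_clades)
        for clade in ladder:  # least inclusive first
            if clade in confined:
                categories.append(f"{clade}_confined")
                break
        else:
            categories.append(OTHER_MULTISPECIES)
    out = markers.copy()
    out["og_id"] = ogs
    out["category"] = categories
    out["n_possessor_species"] = n_poss
    return out


def group_profiles(
    annotated: pd.DataFrame,
    grouping: Mapping[str, str],
    lineage_def: Iterable[str],
    categories: Optional[Sequence[str]] = None,
    denominator: str = "all",
) -> pd.DataFrame:
    """Per-group marker-category profile and lineage-specific fraction.

    ``grouping`` maps cluster ids to group names (identity mapping profiles
    each cluster on its own).  A gene marking several clusters of the same
    group is counted once for that group.  ``lineage_def`` names the
    categories counted as lineage-specific; the fraction's denominator is
    all markers of the group including not-assigned ones (``denominator=
    "assigned-only"`` excludes them).
    """
    unmapped = sorted(set(annotated["cluster"]) - set(grouping))
    if unmapped:
        raise KeyError(f"clusters missing from grouping: {unmapped}")
    if denominator not in ("all", "assigned-only"):
        raise ValueError("denominator must be 'all' or 'assigned-only'")
    lineage_def = set(lineage_def)
    if categories is None:
        categories = sorted(annotated["category"].unique())
    work = annotated.copy()
    work["group"] = work["cluster"].map(grouping)
    # one count per (group, gene): a gene marking two clusters of one group
    # contributes once to that group's profile
    work = work.drop_duplicates(subset=["group", "gene"])
    rows = []
    for group, grp in work.groupby("group", sort=True):
        n = len(grp)
        counts = grp["category"].value_counts()
        n_assigned = n - int(counts.get(NOT_ASSIGNED, 0))
        denom = n if denominator == "all" else n_assigned
        lineage = int(grp["category"].isin(lineage_def).sum())
        for cat in categories:
            c = int(counts.get(cat, 0))
            rows.append({
                "group": group, "category": cat, "count": c,
                "proportion": c / n if n else 0.0,
            })
        rows.append({
            "group": group, "category": "lineage_specific_fraction",
            "count": lineage,
            "proportion": lineage / denom if denom else 0.0,
        })
    return pd.DataFrame(rows)


def lineage_specific_fraction(profiles: pd.DataFrame, group: str) -> float:
    row = profiles[(profiles["group"] == group)
                   & (profiles["category"] == "lineage_specific_fraction")]
    if row.empty:
        raise KeyError(f"no group {group!r} in profile table")
    return float(row["proportion"].iloc[0])


def icell_sharing_histogram(
    annotated: pd.DataFrame,
    clusters: Iterable[str],
    assignment: SpecificityAssignment,
    wide_threshold: int = 40,
) -> tuple[dict[int, int], int, float]:
    """Sharing histogram for the orthogroup-assigned markers of chosen clusters.

    Returns ``(histogram, n_assigned, fraction_widely_shared)`` where the
    histogram keys are possessor-species counts, ``n_assigned`` counts
    markers that map to an orthogroup (deduplicated by gene across the
    cluster union), and the fraction counts markers shared by at least
    ``wide_threshold`` species.
    """
    clusters = set(clusters)
    unknown = clusters - set(annotated["cluster"])
    if unknown:
        raise KeyError(f"unknown cluster(s): {sorted(unknown)}")
    sub = annotated[annotated["cluster"].isin(clusters)]
    sub = sub.drop_duplicates(subset=["gene"])
    assigned = sub[sub["og_id"].notna()]
    hist = sharing_spectrum(assignment, list(assigned["og_id"]))
    n_assigned = len(assigned)
    wide = int((assigned["n_possessor_species"] >= wide_threshold).sum())
    frac = wide / n_assigned if n_assigned else 0.0
    return hist, n_assigned, frac
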
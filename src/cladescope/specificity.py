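"""Taxon-specificity classification of orthogroups.

An orthogroup is *confined to* a clade when every species possessing it
(>= 1 gene) lies inside that clade's leaf set.  Confinement is inclusive:
an orthogroup confined to Hydrozoa is automatically also confined to
Medusozoa and Cnidaria, so confinement counts are monotone along the
ladder.  The MRCA-stratified (exclusive) view — each orthogroup counted
once, at the smallest containing clade — is derivable from the same
assignment and emitted alongside.

Gene-level categories follow the five-way proteome split used in
phylostratigraphic genome reports: species-specific, phylum-specific
(which deliberately merges genus/family/subphylum confinement levels),
metazoan-specific, other multispecies, and unassigned (genes in no
orthogroup at all).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .data_io import OrthogroupTable
from .trees import CladeMap, SpeciesTree

GENE_CATEGORIES = [
    "species_specific",
    "phylum_specific",
    "metazoan_specific",
    "other_multispecies",
    "unassigned",
]


@dataclass(frozen=True)
class OrthogroupSpecificity:
    og_id: str
    possessors: frozenset[str]
    n_species: int
    n_genes: int
    mrca_node: str
    #: configured clades containing the possessor set, most inclusive first
    confined_clades: tuple[str, ...]

    @property
    def species_specific(self) -> bool:
        return self.n_species == 1

    @property
    def smallest_confining_clade(self) -> Optional[str]:
        return self.confined_clades[-1] if self.confined_clades else None


@dataclass
class SpecificityAssignment:
    """Per-orthogroup specificity records plus the clade ladder they use."""

    records: dict[str, OrthogroupSpecificity]
    clades: CladeMap

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, og_id: str) -> OrthogroupSpecificity:
        return self.records[og_id]

    def __contains__(self, og_id: str) -> bool:
        return og_id in self.records

    def confined_count(self, clade_name: str, min_species: int = 1) -> int:
        """Number of orthogroups confined to the clade (inclusive)."""
        return sum(
            1
            for r in self.records.values()
            if clade_name in r.confined_clades and r.n_species >= min_species
        )

    def confinement_fractions(self, min_species: int = 1) -> dict[str, float]:
        n = len(self.records)
        return {
            name: (self.confined_count(name, min_species) / n if n else 0.0)
            for name in self.clades.names
        }

    def species_specific_count(self, species: str) -> int:
        return sum(
            1
            for r in self.records.values()
            if r.species_specific and species in r.possessors
        )

    def mrca_stratified_counts(self) -> dict[Optional[str], int]:
        """Exclusive view: each orthogroup at its smallest confining clade."""
        out: Counter = Counter(
            r.smallest_confining_clade for r in self.records.values()
        )
        return dict(out)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for og in self.records:
            r = self.records[og]
            row = {
                "og_id": og,
                "n_species": r.n_species,
                "n_genes": r.n_genes,
                "mrca": r.mrca_node,
                "species_specific": r.species_specific,
            }
            for name in self.clades.names:
                row[f"confined_{name}"] = name in r.confined_clades
            rows.append(row)
        return pd.DataFrame(rows)


def classify_orthogroups(
    table: OrthogroupTable, tree: SpeciesTree, clades: CladeMap
) -> SpecificityAssignment:
    """Assign every non-empty orthogroup its MRCA node and confinement ladder.

    Orthogroups with no possessor species are skipped; a possessor that is
    not a tree leaf is a hard error.
    """
    leaves = frozenset(tree.leaf_names)
    clade_list = list(clades)
    records: dict[str, OrthogroupSpecificity] = {}
    for og in table.og_ids:
        possessors = table.possessors(og)
        if not possessors:
            continue
        missing = possessors - leaves
        if missing:
            raise KeyError(
                f"orthogroup {og}: possessor species not in tree: "
                f"{sorted(missing)}"
            )
        mrca = tree.mrca(possessors)
        confined = tuple(
            name for name, leafset in clade_list if possessors <= leafset
        )
        records[og] = OrthogroupSpecificity(
            og_id=og,
            possessors=possessors,
            n_species=len(possessors),
            n_genes=table.n_genes(og),
            mrca_node=mrca.name,
            confined_clades=confined,
        )
    return SpecificityAssignment(records=records, clades=clades)


def gene_categories(
    table: OrthogroupTable,
    assignment: SpecificityAssignment,
    focal_species: str,
    all_genes: Sequence[str],
    clades: CladeMap,
) -> pd.DataFrame:
    """Categorize every gene of a focal species into the five-way split.

    Returns a frame with one row per gene in ``all_genes`` and a
    ``category`` column; proportions over the full gene list come from
    :func:`category_proportions`.  Requires the clade map to flag a focal
    phylum and a Metazoa clade.
    """
    if clades.focal_phylum is None or clades.metazoa is None:
        raise ValueError(
            "gene_categories needs focal_phylum and metazoa flags in the clade map"
        )
    gene_set = set(all_genes)
    table_genes = set(table.species_genes(focal_species))
    stray = table_genes - gene_set
    if stray:
        raise ValueError(
            f"{len(stray)} orthogroup gene(s) of {focal_species} missing from "
            f"all_genes, e.g. {sorted(stray)[:3]}"
        )
    gene_to_og = {}
    for og in table.og_ids:
        for g in table.membership[og].get(focal_species, ()):
            gene_to_og[g] = og
    rows = []
    for gene in all_genes:
        og = gene_to_og.get(gene)
        if og is None or og not in assignment:
            cat = "unassigned"
        else:
            rec = assignment[og]
            if rec.species_specific:
                cat = "species_specific"
            elif clades.focal_phylum in rec.confined_clades:
                cat = "phylum_specific"
            elif clades.metazoa in rec.confined_clades:
                cat = "metazoan_specific"
            else:
                cat = "other_multispecies"
        rows.append({"gene": gene, "og_id": og, "category": cat})
    return pd.DataFrame(rows)


def category_proportions(categorized: pd.DataFrame) -> pd.Series:
    """Proportion of genes in each of the five categories (sums to 1)."""
    counts = categorized["category"].value_counts()
    total = len(categorized)
    return pd.Series(
        {cat: counts.get(cat, 0) / total if total else 0.0
         for cat in GENE_CATEGORIES},
        name="proportion",
    )


def clade_overlaps(
    table: OrthogroupTable, groups: Mapping[str, Iterable[str]]
) -> dict[frozenset[str], int]:
    """Exclusive overlap counts of orthogroups between disjoint species groups.

    For every nonempty combination of group names, counts orthogroups
    possessed by >= 1 species of *each* group in the combination and by
    no species of any group outside it.  Species in no group are ignored;
    orthogroups possessed only by such species do not enter the universe.
    """
    named = {name: frozenset(sp) for name, sp in groups.items()}
    for a in named:
        for b in named:
            if a < b and named[a] & named[b]:
                raise ValueError(
                    f"groups {a!r} and {b!r} overlap: {sorted(named[a] & named[b])}"
                )
    out: Counter = Counter()
    for og in table.og_ids:
        possessors = table.possessors(og)
        combo = frozenset(
            name for name, members in named.items() if possessors & members
        )
        if combo:
            out[combo] += 1
    return dict(out)


def sharing_spectrum(
    assignment: SpecificityAssignment, subset: Iterable[str]
) -> dict[int, int]:
    """Histogram of possessor-species counts over a set of orthogroups."""
    hist: Counter = Counter()
    for og in subset:
        if og not in assignment:
            raise KeyError(f"unknown orthogroup id in subset: {og!r}")
        hist[assignment[og].n_species] += 1
    return dict(hist)
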
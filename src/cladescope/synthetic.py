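"""Synthetic data with the statistical structure the analyses assume.

Three generators share one seeded random source (independent named
substreams per stage, so adding a stage never perturbs another):

* ``simulate_gene_content`` — gene families originating on uniformly drawn
  tree branches, evolving below the origin by an integer copy-number drift
  (0 absorbing) with Dollo-style irreversible subtree losses;
* ``simulate_genomes`` — two extant genomes whose scaffolds descend from
  shared ancestral linkage groups, perturbed by translocations and local
  inversions;
* ``simulate_markers`` — per-cluster marker tables whose genes are drawn
  from planted lineage-specificity strata, with effect sizes and adjusted
  p-values realizing planted pass/fail filter labels.

Every generator returns machine-readable ground truth so recovery can be
scored exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .data_io import MARKER_COLUMNS, OrthogroupTable
from .markers import NOT_ASSIGNED, OTHER_MULTISPECIES, FilterCriteria
from .specificity import SpecificityAssignment
from .trees import SpeciesTree, TreeNode, parse_newick

_STAGE_KEYS = {"tree": 0, "content": 1, "genomes": 2, "markers": 3}


def _rng(seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(_STAGE_KEYS[stage],))
    )


@dataclass
class SimulationConfig:
    """Knobs for all three generators; defaults give a mid-size study.

    The default tree size and family number sit at the scale of a
    multi-species orthology study's within-phylum subset (a few thousand
    families over ~16 species) so that every downstream stage is exercised
    with realistic sparsity in minutes on one CPU.
    """

    seed: int = 0
    newick: Optional[str] = None  # supplied tree beats the random one
    n_leaves: int = 16
    n_families: int = 5000
    loss_prob: float = 0.05  # Dollo loss probability per branch
    drift_prob: float = 0.2  # copy-number +-1 step probability per branch
    # genome pair
    focal_pair: Optional[tuple[str, str]] = None  # default: first two leaves
    n_linkage_groups: int = 5
    scaffolds_per_group: int = 2
    translocation_rate: float = 0.01
    inversion_rate: float = 0.05
    # marker tables
    n_clusters: int = 12
    markers_per_cluster: int = 100
    marker_mixture: Optional[Mapping[str, Mapping[str, float]]] = None
    fail_fraction: float = 0.1  # planted filter-failure fraction

    def __post_init__(self) -> None:
        for p in (self.loss_prob, self.drift_prob, self.translocation_rate,
                  self.inversion_rate, self.fail_fraction):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")


@dataclass
class GeneContentTruth:
    origin: dict[str, str]  # family -> origin node
    losses: dict[str, list[str]]  # family -> branches where Dollo loss fired
    counts: dict[str, dict[str, int]]  # family -> node -> true count

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)


def random_species_tree(seed: int, n_leaves: int) -> SpeciesTree:
    """Random rooted binary tree by successive uniform joins."""
    rng = _rng(seed, "tree")
    nodes = [TreeNode(name=f"sp{i + 1:02d}", length=1.0)
             for i in range(n_leaves)]
    counter = 1
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        right = nodes.pop(j)
        left = nodes.pop(i)
        parent = TreeNode(name=f"N{counter}", length=1.0,
                          children=[left, right])
        left.parent = right.parent = parent
        counter += 1
        nodes.append(parent)
    root = nodes[0]
    root.length = None
    return SpeciesTree(root)


def _config_tree(cfg: SimulationConfig) -> SpeciesTree:
    if cfg.newick is not None:
        return parse_newick(cfg.newick)
    return random_species_tree(cfg.seed, cfg.n_leaves)


def simulate_gene_content(
    cfg: SimulationConfig,
) -> tuple[OrthogroupTable, pd.DataFrame, SpeciesTree, GeneContentTruth]:
    """Evolve gene families over the tree; emit orthogroups + leaf counts.

    Each family originates on a uniformly drawn branch (root included)
    with one copy.  Below the origin, along each branch, the family is
    lost with ``loss_prob`` (Dollo: the whole subtree stays 0) or drifts
    by +-1 copy with ``drift_prob``; a count of 0 is absorbing.  Families
    extinct at every leaf are kept in the truth but excluded from the
    emitted tables (an orthogroup inference would never see them).
    """
    if cfg.n_families < 1:
        raise ValueError("need at least one family")
    tree = _config_tree(cfg)
    leaves = tree.leaf_names
    if not leaves:
        raise ValueError("tree has no leaves")
    rng = _rng(cfg.seed, "content")
    node_names = tree.node_names()
    nodes_pre = list(tree.preorder())

    origin: dict[str, str] = {}
    losses: dict[str, list[str]] = {}
    all_counts: dict[str, dict[str, int]] = {}
    fam_ids = [f"OG{i:07d}" for i in range(cfg.n_families)]
    for fam in fam_ids:
        org = node_names[int(rng.integers(len(node_names)))]
        counts: dict[str, int] = {}
        loss_list: list[str] = []
        in_subtree = False
        for node in nodes_pre:
            if node.name == org:
                counts[node.name] = 1
                continue
            parent = node.parent
            if parent is None or parent.name not in counts:
                continue
            pc = counts.get(parent.name, 0)
            if pc == 0:
                counts[node.name] = 0
                continue
            if rng.random() < cfg.loss_prob:
                counts[node.name] = 0
                loss_list.append(node.name)
                continue
            c = pc
            if rng.random() < cfg.drift_prob:
                c = c + (1 if rng.random() < 0.5 else -1)
            counts[node.name] = max(c, 0)
        full = {n: counts.get(n, 0) for n in node_names}
        origin[fam] = org
        losses[fam] = loss_list
        all_counts[fam] = full

    surviving = [f for f in fam_ids
                 if any(all_counts[f][l] > 0 for l in leaves)]
    gene_counter = {sp: 0 for sp in leaves}
    membership: dict[str, dict[str, list[str]]] = {}
    for fam in surviving:
        row: dict[str, list[str]] = {}
        for sp in leaves:
            k = all_counts[fam][sp]
            genes = []
            for _ in range(k):
                gene_counter[sp] += 1
                genes.append(f"{sp}_g{gene_counter[sp]:06d}")
            row[sp] = genes
        membership[fam] = row
    table = OrthogroupTable(og_ids=surviving, membership=membership,
                            species_order=list(leaves))
    leaf_counts = pd.DataFrame(
        {sp: [all_counts[f][sp] for f in surviving] for sp in leaves},
        index=pd.Index(surviving, name="family"),
    )
    truth = GeneContentTruth(origin=origin, losses=losses, counts=all_counts)
    return table, leaf_counts, tree, truth


@dataclass
class GenomeTruth:
    #: (species, scaffold) -> ancestral linkage group
    scaffold_groups: dict[tuple[str, str], int]
    #: family -> ancestral linkage group
    family_groups: dict[str, int]
    #: genes moved to a foreign group's scaffold
    translocated: list[str] = field(default_factory=list)


def simulate_genomes(
    cfg: SimulationConfig, content: OrthogroupTable,
) -> tuple[pd.DataFrame, pd.DataFrame, GenomeTruth]:
    """Lay out the two focal species' shared genes on scaffolds.

    Families present in both species are assigned to ancestral linkage
    groups; each species splits every group into ``scaffolds_per_group``
    scaffolds.  Each gene lands on a scaffold of its family's group,
    except translocations (rate per gene) which move it to a scaffold of
    another group.  Per scaffold, ``inversion_rate`` × n segment reversals
    shuffle local order.  Coordinates are synthesized non-overlapping.
    """
    pair = cfg.focal_pair or tuple(content.species_order[:2])
    sp_a, sp_b = pair
    for sp in pair:
        if sp not in content.species_order:
            raise KeyError(f"focal species {sp!r} not in orthogroup table")
    shared = [og for og in content.og_ids
              if content.genes_of(og, sp_a) and content.genes_of(og, sp_b)]
    if cfg.n_linkage_groups > len(shared):
        raise ValueError(
            f"{cfg.n_linkage_groups} linkage groups but only "
            f"{len(shared)} shared families"
        )
    rng = _rng(cfg.seed, "genomes")
    fam_group = {og: int(rng.integers(cfg.n_linkage_groups)) for og in shared}

    scaffold_groups: dict[tuple[str, str], int] = {}
    translocated: list[str] = []

    def layout(species: str) -> pd.DataFrame:
        scaff_of = {}
        for g in range(cfg.n_linkage_groups):
            for s in range(cfg.scaffolds_per_group):
                name = f"{species}_sc{g * cfg.scaffolds_per_group + s + 1:03d}"
                scaff_of.setdefault(g, []).append(name)
                scaffold_groups[(species, name)] = g
        contents: dict[str, list[str]] = {
            s: [] for group in scaff_of.values() for s in group
        }
        for og in shared:
            for gene in content.genes_of(og, species):
                group = fam_group[og]
                if rng.random() < cfg.translocation_rate:
                    # reassign uniformly over all groups; at rate 1 the
                    # scaffold/group association vanishes entirely
                    new_group = int(rng.integers(cfg.n_linkage_groups))
                    if new_group != group:
                        translocated.append(gene)
                    group = new_group
                scaffs = scaff_of[group]
                contents[scaffs[int(rng.integers(len(scaffs)))]].append(gene)
        rows = []
        for scaffold in sorted(contents):
            genes = contents[scaffold]
            n_inv = int(round(cfg.inversion_rate * len(genes)))
            for _ in range(n_inv):
                if len(genes) < 2:
                    break
                i, j = sorted(rng.choice(len(genes), size=2, replace=False))
                genes[i:j + 1] = genes[i:j + 1][::-1]
            for idx, gene in enumerate(genes):
                start = idx * 1000 + 100
                strand = "+" if rng.random() < 0.5 else "-"
                rows.append((species, gene, scaffold, start, start + 500,
                             strand))
        return pd.DataFrame(
            rows,
            columns=["species", "gene", "scaffold", "start", "end", "strand"],
        )

    pos_a = layout(sp_a)
    pos_b = layout(sp_b)
    truth = GenomeTruth(scaffold_groups=scaffold_groups,
                        family_groups=fam_group, translocated=translocated)
    return pos_a, pos_b, truth


def marker_category_pools(
    content: OrthogroupTable,
    assignment: SpecificityAssignment,
    ladder: Sequence[str],
    focal_species: str,
    n_unassigned: int = 500,
) -> dict[str, list[str]]:
    """Genes of the focal species available per marker category.

    Synthesizes ``n_unassigned`` extra gene identifiers for the
    not-assigned stratum (genes an orthology inference left out).
    """
    pools: dict[str, list[str]] = {
        NOT_ASSIGNED: [f"{focal_species}_u{i:05d}" for i in range(n_unassigned)],
        f"{focal_species}_specific": [],
        OTHER_MULTISPECIES: [],
    }
    for clade in ladder:
        pools[f"{clade}_confined"] = []
    for og in content.og_ids:
        genes = content.genes_of(og, focal_species)
        if not genes or og not in assignment:
            continue
        rec = assignment[og]
        if rec.species_specific:
            cat = f"{focal_species}_specific"
        else:
            for clade in ladder:
                if clade in rec.confined_clades:
                    cat = f"{clade}_confined"
                    break
            else:
                cat = OTHER_MULTISPECIES
        pools[cat].extend(genes)
    return pools


def simulate_markers(
    cfg: SimulationConfig,
    pools: Mapping[str, Sequence[str]],
    criteria: FilterCriteria = FilterCriteria(),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw per-cluster markers from planted category strata.

    ``pools`` maps category names to available focal-species genes (see
    :func:`marker_category_pools`).  Each cluster's planted mixture comes
    from ``cfg.marker_mixture`` (one mixture per cluster name, or the
    ``"*"`` key applied to all; default: uniform over the pool
    categories).  Effect sizes and adjusted p-values are drawn so that
    planted pass/fail labels hold under ``criteria``.  Returns the marker
    table and a truth frame (gene, cluster, true_category, passes_filter).
    """
    rng = _rng(cfg.seed, "markers")
    clusters = [f"C{i}" for i in range(cfg.n_clusters)]
    mixtures = cfg.marker_mixture or {}
    default_mix = mixtures.get("*")
    categories_all = [c for c in pools if len(pools[c]) > 0]

    rows, truth_rows = [], []
    for cluster in clusters:
        mix = mixtures.get(cluster, default_mix)
        if mix is None:
            cats = categories_all
            probs = np.full(len(cats), 1.0 / len(cats))
        else:
            cats = list(mix)
            probs = np.asarray([mix[c] for c in cats], dtype=float)
            if abs(probs.sum() - 1.0) > 1e-9:
                raise ValueError(f"mixture for {cluster} does not sum to 1")
            for c in cats:
                if not pools.get(c):
                    raise ValueError(f"planted stratum {c!r} has no genes")
        used: set[str] = set()
        for _ in range(cfg.markers_per_cluster):
            cat = cats[int(rng.choice(len(cats), p=probs))]
            pool = pools[cat]
            gene = pool[int(rng.integers(len(pool)))]
            tries = 0
            while gene in used and tries < 100:
                gene = pool[int(rng.integers(len(pool)))]
                tries += 1
            if gene in used:
                continue  # tiny pool exhausted for this cluster
            used.add(gene)
            passes = bool(rng.random() >= cfg.fail_fraction)
            if passes:
                p_adj = rng.uniform(0.0, criteria.max_p_adj * 0.9)
                lfc = rng.uniform(max(criteria.min_log2fc, 0.0) + 0.1, 3.0)
                pct_in = rng.uniform(min(criteria.min_pct_in + 0.05, 1.0), 1.0)
                pct_out = rng.uniform(0.0, min(criteria.max_pct_out, 0.3))
            else:
                # violate exactly one criterion: the adjusted p-value
                p_adj = rng.uniform(min(criteria.max_p_adj * 2, 0.5), 1.0)
                lfc = rng.uniform(max(criteria.min_log2fc, 0.0) + 0.1, 3.0)
                pct_in = rng.uniform(min(criteria.min_pct_in + 0.05, 1.0), 1.0)
                pct_out = rng.uniform(0.0, min(criteria.max_pct_out, 0.3))
            rows.append((gene, cluster, round(float(lfc), 6),
                         round(float(p_adj), 8), round(float(pct_in), 4),
                         round(float(pct_out), 4)))
            truth_rows.append((gene, cluster, cat, passes))
    markers = pd.DataFrame(rows, columns=MARKER_COLUMNS)
    truth = pd.DataFrame(
        truth_rows, columns=["gene", "cluster", "true_category",
                             "passes_filter"]
    )
    return markers, truth
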
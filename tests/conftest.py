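"""Shared fixtures: toy trees, orthogroup builders, brute-force oracles."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from cladescope.data_io import OrthogroupTable
from cladescope.trees import CladeMap, SpeciesTree, parse_newick


def make_orthogroups(spec: dict[str, dict[str, list[str]]],
                     species_order: list[str]) -> OrthogroupTable:
    """Build an OrthogroupTable from {og: {species: [genes]}}."""
    membership = {
        og: {sp: list(spec[og].get(sp, [])) for sp in species_order}
        for og in spec
    }
    return OrthogroupTable(og_ids=list(spec), membership=membership,
                           species_order=species_order)


def random_orthogroups(rng: np.random.Generator, species: list[str],
                       n_ogs: int, max_genes: int = 3) -> OrthogroupTable:
    spec = {}
    counter = 0
    for i in range(n_ogs):
        row = {}
        for sp in species:
            k = int(rng.integers(0, max_genes + 1))
            row[sp] = [f"{sp}_g{counter + j}" for j in range(k)]
            counter += k
        spec[f"OG{i:04d}"] = row
    return make_orthogroups(spec, species)


def random_binary_tree(rng: np.random.Generator, n_leaves: int) -> SpeciesTree:
    """Random rooted binary tree over leaves L1..Ln by successive joins."""
    from cladescope.trees import TreeNode

    nodes = [TreeNode(name=f"L{i + 1}") for i in range(n_leaves)]
    counter = 1
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        right = nodes.pop(j)
        left = nodes.pop(i)
        parent = TreeNode(name=f"I{counter}", children=[left, right])
        left.parent = right.parent = parent
        counter += 1
        nodes.append(parent)
    return SpeciesTree(nodes[0])


def brute_force_mrca(tree: SpeciesTree, possessors: frozenset[str]) -> str:
    """MRCA by scanning every node for the smallest covering leaf set."""
    best_name, best_size = None, None
    for name in tree.node_names():
        leafset = tree.leafset(name)
        if possessors <= leafset:
            if best_size is None or len(leafset) < best_size:
                best_name, best_size = name, len(leafset)
    return best_name


def brute_force_confinement(clades: CladeMap,
                            possessors: frozenset[str]) -> tuple[str, ...]:
    """Confined clades by testing possessor-subset against every clade."""
    return tuple(name for name, leafset in clades if possessors <= leafset)


@pytest.fixture
def toy_tree() -> SpeciesTree:
    return parse_newick("((A,B)X,(C,D)Y)R;")


@pytest.fixture
def toy_clades() -> CladeMap:
    return CladeMap(
        [("R", {"A", "B", "C", "D"}), ("X", {"A", "B"}), ("Y", {"C", "D"})],
        focal_phylum="X", metazoa="R",
    )
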
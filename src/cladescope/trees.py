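"""Rooted species trees and named-clade ladders.

A :class:`SpeciesTree` is a lightweight rooted tree whose leaves are species
names.  Internal nodes carry stable identifiers: Newick labels are kept when
present, otherwise nodes are auto-named ``N1, N2, ...`` in postorder.  A
:class:`CladeMap` is an ordered ladder of named clades (leaf-name sets),
ordered from most to least inclusive, used to express taxon specificity
("confined to clade X" = every possessor species lies inside X).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Optional, Sequence

import dendropy
import yaml

__all__ = [
    "TreeNode",
    "SpeciesTree",
    "CladeMap",
    "read_tree",
    "read_clades",
    "read_tree_and_clades",
]


class CladeConfigError(ValueError):
    """Raised when a clade definition is inconsistent with the tree."""


@dataclass(eq=False)
class TreeNode:
    name: str
    children: list["TreeNode"] = field(default_factory=list)
    parent: Optional["TreeNode"] = None
    length: Optional[float] = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover
        return f"TreeNode({self.name!r}, {len(self.children)} children)"


class SpeciesTree:
    """Rooted tree over uniquely named species leaves.

    Parameters
    ----------
    root:
        Root :class:`TreeNode`.  Every node must carry a unique ``name``.
    """

    def __init__(self, root: TreeNode):
        self.root = root
        self._by_name: dict[str, TreeNode] = {}
        for node in self.postorder():
            if node.name in self._by_name:
                raise ValueError(f"duplicate node name in tree: {node.name!r}")
            self._by_name[node.name] = node
        self._leafset_cache: dict[str, frozenset[str]] = {}
        for node in self.postorder():
            if node.is_leaf:
                self._leafset_cache[node.name] = frozenset([node.name])
            else:
                self._leafset_cache[node.name] = frozenset().union(
                    *(self._leafset_cache[c.name] for c in node.children)
                )

    # -- traversal -----------------------------------------------------
    def postorder(self) -> Iterator[TreeNode]:
        stack: list[tuple[TreeNode, bool]] = [(self.root, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded:
                yield node
            else:
                stack.append((node, True))
                for child in reversed(node.children):
                    stack.append((child, False))

    def preorder(self) -> Iterator[TreeNode]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def leaves(self) -> list[TreeNode]:
        return [n for n in self.postorder() if n.is_leaf]

    @property
    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves()]

    def node(self, name: str) -> TreeNode:
        try:
            return self._by_name[name]
        except KeyError:
            raise KeyError(f"no tree node named {name!r}") from None

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def node_names(self) -> list[str]:
        return [n.name for n in self.postorder()]

    def leafset(self, name: str) -> frozenset[str]:
        """Leaf names spanned by the node called ``name``."""
        return self._leafset_cache[name]

    # -- queries -------------------------------------------------------
    def mrca(self, leaf_names: Iterable[str]) -> TreeNode:
        """Smallest node whose leaf set contains every name given."""
        wanted = frozenset(leaf_names)
        if not wanted:
            raise ValueError("mrca of an empty leaf set is undefined")
        missing = wanted - self._leafset_cache[self.root.name]
        if missing:
            raise KeyError(f"species not in tree: {sorted(missing)}")
        # walk down from the root while a single child still covers the set
        node = self.root
        while True:
            for child in node.children:
                if wanted <= self._leafset_cache[child.name]:
                    node = child
                    break
            else:
                return node

    def to_newick(self) -> str:
        def fmt(node: TreeNode) -> str:
            label = node.name
            brlen = f":{node.length:g}" if node.length is not None else ""
            if node.is_leaf:
                return f"{label}{brlen}"
            inner = ",".join(fmt(c) for c in node.children)
            return f"({inner}){label}{brlen}"

        return fmt(self.root) + ";"


def _from_dendropy(tree: dendropy.Tree) -> SpeciesTree:
    counter = itertools.count(1)
    seen: set[str] = set()

    def convert(dnode) -> TreeNode:
        if dnode.is_leaf():
            name = dnode.taxon.label if dnode.taxon else dnode.label
            if not name:
                raise ValueError("unlabeled leaf in Newick tree")
        else:
            name = dnode.label
            if not name:
                name = f"N{next(counter)}"
                while name in seen:
                    name = f"N{next(counter)}"
        seen.add(name)
        node = TreeNode(name=name, length=dnode.edge.length)
        for dchild in dnode.child_nodes():
            child = convert(dchild)
            child.parent = node
            node.children.append(child)
        return node

    return SpeciesTree(convert(tree.seed_node))


def parse_newick(newick: str) -> SpeciesTree:
    dtree = dendropy.Tree.get(
        data=newick, schema="newick", suppress_internal_node_taxa=True
    )
    return _from_dendropy(dtree)


def read_tree(path) -> SpeciesTree:
    """Read a rooted Newick tree; unlabeled internal nodes get stable ids."""
    with open(path) as fh:
        return parse_newick(fh.read())


class CladeMap:
    """Ordered ladder of named clades, most inclusive first.

    ``flags`` marks up to one clade as the focal phylum, one as Metazoa,
    and any number as outgroups; all three are optional and only needed by
    the gene-category logic.
    """

    def __init__(
        self,
        clades: Sequence[tuple[str, Iterable[str]]],
        focal_phylum: Optional[str] = None,
        metazoa: Optional[str] = None,
        outgroups: Iterable[str] = (),
    ):
        entries = [(name, frozenset(leaves)) for name, leaves in clades]
        for name, leaves in entries:
            if not leaves:
                raise CladeConfigError(f"clade {name!r} is empty")
        names = [name for name, _ in entries]
        if len(set(names)) != len(names):
            raise CladeConfigError("duplicate clade names")
        # nesting consistency: any two clade sets are disjoint or nested
        for (na, sa), (nb, sb) in itertools.combinations(entries, 2):
            if sa & sb and not (sa <= sb or sb <= sa):
                raise CladeConfigError(
                    f"clades {na!r} and {nb!r} partially overlap: "
                    f"{sorted(sa & sb)} shared"
                )
        entries.sort(key=lambda item: (-len(item[1]), item[0]))
        self._entries: list[tuple[str, frozenset[str]]] = entries
        self._by_name = dict(entries)
        self.focal_phylum = focal_phylum
        self.metazoa = metazoa
        self.outgroup_clades = tuple(outgroups)
        for flag_name in filter(None, [focal_phylum, metazoa, *self.outgroup_clades]):
            if flag_name not in self._by_name:
                raise CladeConfigError(f"flagged clade {flag_name!r} not defined")

    def __iter__(self) -> Iterator[tuple[str, frozenset[str]]]:
        return iter(self._entries)

    def __len__(self) -> int:
        return len(self._entries)

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    @property
    def names(self) -> list[str]:
        return [name for name, _ in self._entries]

    def leafset(self, name: str) -> frozenset[str]:
        try:
            return self._by_name[name]
        except KeyError:
            raise KeyError(f"no clade named {name!r}") from None

    def all_species(self) -> frozenset[str]:
        return frozenset().union(*(s for _, s in self._entries))

    def validate_against(self, tree: SpeciesTree) -> None:
        leaves = set(tree.leaf_names)
        bad = sorted(self.all_species() - leaves)
        if bad:
            raise CladeConfigError(
                f"clade species not found as tree leaves: {bad}"
            )


def read_clades(path) -> CladeMap:
    """Read a YAML clade config.

    Schema::

        clades:
          Cnidaria: [spA, spB, ...]
          Metazoa:  [...]
        flags:                      # optional
          focal_phylum: Cnidaria
          metazoa: Metazoa
          outgroups: [Opisthokonta_out]
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, Mapping) or "clades" not in cfg:
        raise CladeConfigError(f"{path}: expected a mapping with a 'clades' key")
    clades = [(str(k), list(v)) for k, v in cfg["clades"].items()]
    flags = cfg.get("flags") or {}
    return CladeMap(
        clades,
        focal_phylum=flags.get("focal_phylum"),
        metazoa=flags.get("metazoa"),
        outgroups=flags.get("outgroups", ()),
    )


def read_tree_and_clades(newick_path, clade_path) -> tuple[SpeciesTree, CladeMap]:
    """Load a Newick tree and its clade ladder, cross-validating the two."""
    tree = read_tree(newick_path)
    clades = read_clades(clade_path)
    clades.validate_against(tree)
    return tree, clades
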
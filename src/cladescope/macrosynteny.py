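"""Macrosynteny from shared orthogroup content between two genomes.

For a genome pair, each scaffold is summarized by the set of orthogroups
with at least one gene on it; scaffold pairs are then tested for excess
sharing with a one-sided hypergeometric test, corrected across pairs with
Benjamini–Hochberg, and significant pairs are linked into putative
linkage groups (connected components of the scaffold–scaffold graph).
Dot-plot coordinates over the induced scaffold order are emitted for
plotting.

Orthogroup presence is collapsed per scaffold (multi-copy families count
once) and orthogroups spread over many scaffolds in either species are
excluded as promiscuous — both guards against repeat-family orthogroups
dominating the counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


@dataclass
class SharedOGMatrix:
    species_a: str
    species_b: str
    matrix: pd.DataFrame  # scaffolds of A (rows) x scaffolds of B (cols)
    margin_a: pd.Series  # distinct orthogroups per A scaffold
    margin_b: pd.Series
    universe: int  # orthogroups placed in both species
    og_scaffolds_a: dict[str, frozenset[str]]  # og -> A scaffolds (shared universe)
    og_scaffolds_b: dict[str, frozenset[str]]

    def transpose(self) -> "SharedOGMatrix":
        return SharedOGMatrix(
            species_a=self.species_b, species_b=self.species_a,
            matrix=self.matrix.T, margin_a=self.margin_b,
            margin_b=self.margin_a, universe=self.universe,
            og_scaffolds_a=self.og_scaffolds_b,
            og_scaffolds_b=self.og_scaffolds_a,
        )


def shared_og_matrix(
    pos_a: pd.DataFrame,
    pos_b: pd.DataFrame,
    gene_to_og: Mapping[str, str],
    max_scaffolds_per_og: int = 5,
) -> SharedOGMatrix:
    """Count distinct shared orthogroups for every scaffold pair.

    Genes without an orthogroup are dropped (logged); orthogroups present
    on more than ``max_scaffolds_per_og`` scaffolds in either species are
    excluded as promiscuous (logged).  The universe N is the number of
    orthogroups retained with placement in both species.
    """
    def og_map(pos: pd.DataFrame) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        dropped = 0
        for row in pos.itertuples(index=False):
            og = gene_to_og.get(row.gene)
            if og is None:
                dropped += 1
                continue
            out.setdefault(og, set()).add(row.scaffold)
        if dropped:
            logger.info("shared_og_matrix: %d gene(s) without orthogroup dropped",
                        dropped)
        return out

    sp_a = pos_a["species"].iloc[0] if len(pos_a) else "A"
    sp_b = pos_b["species"].iloc[0] if len(pos_b) else "B"
    map_a, map_b = og_map(pos_a), og_map(pos_b)
    shared_ogs = set(map_a) & set(map_b)
    promiscuous = {
        og for og in shared_ogs
        if len(map_a[og]) > max_scaffolds_per_og
        or len(map_b[og]) > max_scaffolds_per_og
    }
    if promiscuous:
        logger.info("shared_og_matrix: excluded %d promiscuous orthogroup(s)",
                    len(promiscuous))
    shared_ogs -= promiscuous
    if not shared_ogs:
        raise ValueError("no orthogroups placed in both species (N = 0)")

    scaffolds_a = sorted({s for og in shared_ogs for s in map_a[og]})
    scaffolds_b = sorted({s for og in shared_ogs for s in map_b[og]})
    mat = pd.DataFrame(0, index=scaffolds_a, columns=scaffolds_b, dtype=int)
    for og in shared_ogs:
        for sa in map_a[og]:
            for sb in map_b[og]:
                mat.loc[sa, sb] += 1
    margin_a = pd.Series(
        {s: sum(1 for og in shared_ogs if s in map_a[og]) for s in scaffolds_a}
    )
    margin_b = pd.Series(
        {s: sum(1 for og in shared_ogs if s in map_b[og]) for s in scaffolds_b}
    )
    return SharedOGMatrix(
        species_a=sp_a, species_b=sp_b, matrix=mat,
        margin_a=margin_a, margin_b=margin_b, universe=len(shared_ogs),
        og_scaffolds_a={og: frozenset(map_a[og]) for og in shared_ogs},
        og_scaffolds_b={og: frozenset(map_b[og]) for og in shared_ogs},
    )


def test_scaffold_pairs(m: SharedOGMatrix, fdr: float = 0.05) -> pd.DataFrame:
    """Hypergeometric upper-tail enrichment for every sharing scaffold pair.

    For pair (a, b): ``p = P(X >= k)`` with ``X ~ Hypergeom(N, K, n)``
    where ``k`` is the shared-orthogroup count, ``K`` and ``n`` the
    scaffold margins and ``N`` the shared universe.  Benjamini–Hochberg is
    applied across all pairs with ``k >= 1``; pairs with ``k = 0`` are
    untested.
    """
    if not 0.0 < fdr < 1.0:
        raise ValueError("fdr must be in (0, 1)")
    rows = []
    for sa in m.matrix.index:
        K = int(m.margin_a[sa])
        for sb in m.matrix.columns:
            k = int(m.matrix.loc[sa, sb])
            if k == 0:
                continue
            n = int(m.margin_b[sb])
            p = float(stats.hypergeom.sf(k - 1, m.universe, K, n))
            rows.append({"scaffold_a": sa, "scaffold_b": sb,
                         "k": k, "K": K, "n": n, "N": m.universe, "p": p})
    tests = pd.DataFrame(rows)
    if tests.empty:
        tests["q"] = []
        tests["significant"] = []
        return tests
    reject, q, _, _ = multipletests(tests["p"], alpha=fdr, method="fdr_bh")
    tests["q"] = q
    tests["significant"] = reject
    return tests


def linkage_groups(
    m: SharedOGMatrix,
    tests: pd.DataFrame,
    pos_a: Optional[pd.DataFrame] = None,
    pos_b: Optional[pd.DataFrame] = None,
    gene_to_og: Optional[Mapping[str, str]] = None,
) -> tuple[pd.DataFrame, Optional[pd.DataFrame]]:
    """Cluster scaffolds into linkage groups and derive dot-plot ranks.

    Scaffolds of both species are nodes; significant pairs are edges;
    connected components are linkage groups, numbered by descending total
    shared-orthogroup content (then lexically).  Without any significant
    pair every scaffold is its own singleton group (warned).  When the
    position tables and orthology mapping are supplied, a dot-plot table
    is also returned: one row per shared orthogroup placement with gene
    ranks along the ordered scaffolds of each axis.
    """
    sig = tests[tests["significant"]] if len(tests) else tests
    G = nx.Graph()
    G.add_nodes_from(("A", s) for s in m.matrix.index)
    G.add_nodes_from(("B", s) for s in m.matrix.columns)
    for row in sig.itertuples(index=False):
        G.add_edge(("A", row.scaffold_a), ("B", row.scaffold_b))
    if sig.empty:
        logger.warning("linkage_groups: no significant pairs; "
                       "every scaffold is a singleton group")

    def component_weight(comp) -> int:
        total = 0
        for side, s in comp:
            total += int((m.margin_a if side == "A" else m.margin_b)[s])
        return total

    comps = sorted(
        nx.connected_components(G),
        key=lambda c: (-component_weight(c), min(c)),
    )
    rows = []
    for gid, comp in enumerate(comps, start=1):
        for side, scaffold in sorted(comp):
            rows.append({
                "linkage_group": gid,
                "species": m.species_a if side == "A" else m.species_b,
                "scaffold": scaffold,
            })
    clusters = pd.DataFrame(rows)

    dotplot = None
    if pos_a is not None and pos_b is not None and gene_to_og is not None:
        dotplot = _dotplot_table(m, clusters, pos_a, pos_b, gene_to_og)
    return clusters, dotplot


def _scaffold_order(m: SharedOGMatrix, clusters: pd.DataFrame, species: str,
                    margin: pd.Series) -> dict[str, int]:
    sub = clusters[clusters["species"] == species]
    lg = dict(zip(sub["scaffold"], sub["linkage_group"]))
    ordered = sorted(
        margin.index,
        key=lambda s: (lg.get(s, np.inf), -int(margin[s]), s),
    )
    return {s: i for i, s in enumerate(ordered)}


def _dotplot_table(m, clusters, pos_a, pos_b, gene_to_og) -> pd.DataFrame:
    order_a = _scaffold_order(m, clusters, m.species_a, m.margin_a)
    order_b = _scaffold_order(m, clusters, m.species_b, m.margin_b)
    shared = set(m.og_scaffolds_a)

    def ranked(pos, order):
        sub = pos[pos["scaffold"].isin(order)].copy()
        sub["og"] = sub["gene"].map(gene_to_og)
        sub = sub[sub["og"].isin(shared)]
        sub["scaffold_rank"] = sub["scaffold"].map(order)
        sub = sub.sort_values(["scaffold_rank", "start", "gene"],
                              kind="mergesort")
        sub["rank"] = np.arange(len(sub))
        return sub

    ra = ranked(pos_a, order_a)
    rb = ranked(pos_b, order_b)
    merged = ra.merge(rb, on="og", suffixes=("_a", "_b"))
    return merged[[
        "og", "rank_a", "rank_b", "scaffold_a", "scaffold_b"
    ]].rename(columns={"scaffold_a": "scaffold_a", "scaffold_b": "scaffold_b"}
              ).reset_index(drop=True)
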
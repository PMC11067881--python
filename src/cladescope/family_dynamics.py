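"""Gene-family size-change summaries over a species tree.

Ancestral family sizes either come in precomputed (e.g. from a CAFE run,
``provenance="external"``) or are filled in by linear-cost (Wagner)
parsimony via a Sankoff dynamic program, which minimizes the total
absolute copy-number change summed over branches.  Per-branch deltas are
then tallied into expansion/contraction tables, compared between terminal
and internal branches with a Welch two-sample t-test, and summarized for a
focal species pair (gain/loss ratios, lost-family overlap).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .trees import SpeciesTree


@dataclass
class AncestralCounts:
    """Family x node count matrix covering every tree node.

    ``provenance`` records whether internal counts were supplied
    externally or inferred by parsimony.
    """

    counts: pd.DataFrame  # families x node names, int
    provenance: str  # "external" | "parsimony"

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative ancestral count")


def infer_ancestral_counts(
    leaf_counts: pd.DataFrame, tree: SpeciesTree, max_count: Optional[int] = None
) -> AncestralCounts:
    """Wagner-parsimony ancestral counts by Sankoff dynamic programming.

    Per family, internal-node counts minimize the sum of ``|parent -
    child|`` over all branches, with states ``0..max_count``.  Ties are
    broken deterministically toward the *smallest* count, resolved from
    the root toward the tips.  Columns of ``leaf_counts`` already naming
    internal tree nodes are used verbatim (external provenance) and the
    parsimony step is skipped.
    """
    leaves = tree.leaf_names
    if len(leaves) < 2:
        raise ValueError("tree must have at least 2 leaves")
    missing = [l for l in leaves if l not in leaf_counts.columns]
    if missing:
        raise ValueError(f"no counts for leaves: {missing}")
    internal = [n for n in tree.node_names() if n not in set(leaves)]
    if all(n in leaf_counts.columns for n in internal):
        return AncestralCounts(
            counts=leaf_counts[tree.node_names()].astype(int),
            provenance="external",
        )

    obs = leaf_counts[leaves].to_numpy(dtype=np.int64)
    cap = int(obs.max()) if max_count is None else int(max_count)
    if cap < obs.max():
        raise ValueError("max_count below the largest leaf count")
    n_states = cap + 1
    n_fam = obs.shape[0]
    big = np.float64(1e18)
    states = np.arange(n_states)
    # linear transition cost |s - t|, shape (parent state, child state)
    trans = np.abs(states[:, None] - states[None, :]).astype(np.float64)

    post = list(tree.postorder())
    cost: dict[str, np.ndarray] = {}
    # bottom-up: cost[node][f, s] = min cost of subtree given node state s
    for node in post:
        if node.is_leaf:
            c = np.full((n_fam, n_states), big)
            col = obs[:, leaves.index(node.name)]
            c[np.arange(n_fam), col] = 0.0
        else:
            c = np.zeros((n_fam, n_states))
            for child in node.children:
                # min over child state t of |s - t| + cost_child[t]
                c += np.min(cost[child.name][:, None, :] + trans[None, :, :],
                            axis=2)
        cost[node.name] = c

    # top-down assignment, smallest state among minimizers
    assign: dict[str, np.ndarray] = {}
    root = tree.root
    assign[root.name] = np.argmin(cost[root.name], axis=1)
    for node in tree.preorder():
        for child in node.children:
            if child.is_leaf:
                assign[child.name] = obs[:, leaves.index(child.name)]
            else:
                parent_state = assign[node.name]
                total = trans[parent_state, :] + cost[child.name]
                assign[child.name] = np.argmin(total, axis=1)

    ordered = tree.node_names()
    out = pd.DataFrame(
        {name: assign[name].astype(int) for name in ordered},
        index=leaf_counts.index,
    )
    return AncestralCounts(counts=out, provenance="parsimony")


def parsimony_cost(counts: AncestralCounts, tree: SpeciesTree) -> np.ndarray:
    """Total |parent - child| change per family under the given counts."""
    total = np.zeros(len(counts.counts), dtype=np.int64)
    for node in tree.postorder():
        if node.parent is not None:
            total += np.abs(
                counts.counts[node.name].to_numpy()
                - counts.counts[node.parent.name].to_numpy()
            )
    return total


def branch_changes(counts: AncestralCounts, tree: SpeciesTree) -> pd.DataFrame:
    """Per-branch expansion/contraction tallies.

    One row per non-root node (the branch leading to it): number of
    families expanded / contracted / unchanged, total gene copies gained
    and lost, and the branch class (terminal vs internal).
    """
    missing = [n for n in tree.node_names() if n not in counts.counts.columns]
    if missing:
        raise KeyError(f"missing node count column(s): {missing}")
    rows = []
    for node in tree.postorder():
        if node.parent is None:
            continue
        delta = (counts.counts[node.name].to_numpy(dtype=np.int64)
                 - counts.counts[node.parent.name].to_numpy(dtype=np.int64))
        rows.append({
            "branch": node.name,
            "parent": node.parent.name,
            "branch_class": "terminal" if node.is_leaf else "internal",
            "n_families_expanded": int((delta > 0).sum()),
            "n_families_contracted": int((delta < 0).sum()),
            "n_families_unchanged": int((delta == 0).sum()),
            "genes_gained": int(delta[delta > 0].sum()),
            "genes_lost": int(-delta[delta < 0].sum()),
        })
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class WelchResult:
    mean_terminal: float
    mean_internal: float
    t: float
    df: float
    p: float


def welch_t_test(a: Sequence[float], b: Sequence[float]) -> WelchResult:
    """Two-sided Welch two-sample t-test (unequal variances)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs >= 2 observations")
    with warnings.catch_warnings():
        # near-identical samples trip scipy's precision-loss warning; the
        # degenerate case is handled explicitly below
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(a, b, equal_var=False)
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    if va + vb == 0:
        df = float(len(a) + len(b) - 2)
        t, p = 0.0, 1.0
    else:
        df = (va + vb) ** 2 / (
            va**2 / (len(a) - 1) + vb**2 / (len(b) - 1)
        )
        t, p = float(res.statistic), float(res.pvalue)
    return WelchResult(
        mean_terminal=float(a.mean()), mean_internal=float(b.mean()),
        t=t, df=float(df), p=p,
    )


def terminal_vs_internal_test(
    bct: pd.DataFrame, metric: str = "families_changed"
) -> WelchResult:
    """Welch test of per-branch change between terminal and internal branches.

    ``metric="families_changed"`` (default) uses the number of families
    expanded + contracted per branch; ``"genes_changed"`` uses gene copies
    gained + lost.
    """
    if metric == "families_changed":
        values = bct["n_families_expanded"] + bct["n_families_contracted"]
    elif metric == "genes_changed":
        values = bct["genes_gained"] + bct["genes_lost"]
    else:
        raise ValueError(f"unknown metric {metric!r}")
    terminal = values[bct["branch_class"] == "terminal"].to_numpy()
    internal = values[bct["branch_class"] == "internal"].to_numpy()
    if len(terminal) < 2 or len(internal) < 2:
        raise ValueError("need >= 2 branches in each class")
    return welch_t_test(terminal, internal)


@dataclass
class SpeciesPairSummary:
    species_a: str
    species_b: str
    reference_node: str
    frac_changed_a: float  # fraction of families changed vs the reference
    frac_changed_b: float
    gained_a: int
    lost_a: int
    gained_b: int
    lost_b: int
    gain_ratio_a_over_b: float
    loss_ratio_b_over_a: float
    lost_families_a: frozenset[str]
    lost_families_b: frozenset[str]
    lost_overlap: int

    def to_dict(self) -> dict:
        d = {
            k: v for k, v in self.__dict__.items()
            if not k.startswith("lost_families")
        }
        d["n_lost_families_a"] = len(self.lost_families_a)
        d["n_lost_families_b"] = len(self.lost_families_b)
        return d


def species_pair_summary(
    bct: pd.DataFrame,
    counts: AncestralCounts,
    species_pair: tuple[str, str],
    tree: SpeciesTree,
    reference_node: Optional[str] = None,
) -> SpeciesPairSummary:
    """Contrast gain/loss dynamics of two leaf species.

    Per species: the fraction of families whose extant size differs from
    the size at ``reference_node`` (default: the pair's MRCA), terminal-
    branch gene gains and losses, cross ratios, and the overlap of the
    family sets lost to zero on each terminal branch.
    """
    sp_a, sp_b = species_pair
    for sp in (sp_a, sp_b):
        if sp not in tree or not tree.node(sp).is_leaf:
            raise KeyError(f"{sp!r} is not a leaf of the tree")
    if reference_node is None:
        reference_node = tree.mrca([sp_a, sp_b]).name
    ref = counts.counts[reference_node]

    def stats_for(sp: str) -> tuple[float, int, int, frozenset[str]]:
        extant = counts.counts[sp]
        frac_changed = float((extant != ref).mean())
        row = bct[bct["branch"] == sp].iloc[0]
        parent = counts.counts[row["parent"]]
        lost_to_zero = frozenset(
            counts.counts.index[(parent > 0) & (extant == 0)].astype(str)
        )
        return frac_changed, int(row["genes_gained"]), int(row["genes_lost"]), \
            lost_to_zero

    frac_a, gained_a, lost_a, lostfam_a = stats_for(sp_a)
    frac_b, gained_b, lost_b, lostfam_b = stats_for(sp_b)
    return SpeciesPairSummary(
        species_a=sp_a, species_b=sp_b, reference_node=reference_node,
        frac_changed_a=frac_a, frac_changed_b=frac_b,
        gained_a=gained_a, lost_a=lost_a, gained_b=gained_b, lost_b=lost_b,
        gain_ratio_a_over_b=gained_a / gained_b if gained_b else float("inf"),
        loss_ratio_b_over_a=lost_b / lost_a if lost_a else float("inf"),
        lost_families_a=lostfam_a, lost_families_b=lostfam_b,
        lost_overlap=len(lostfam_a & lostfam_b),
    )
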
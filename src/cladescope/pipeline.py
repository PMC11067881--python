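"""End-to-end orchestration: config, staging, and the consolidated report.

A run is described by one flat config (YAML mapping or dict).  Inputs are
either files (``inputs:`` paths) or simulated on the fly (``simulate:``
generator settings).  Each enabled stage writes its tables into the output
directory — every file carries the config hash in its comment header — and
contributes its headline numbers to a JSON summary.  Reruns with the same
config and inputs are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Optional

import pandas as pd

from . import __version__, data_io
from .markers import (FilterCriteria, assign_marker_categories,
                      category_ladder, filter_markers, group_profiles,
                      icell_sharing_histogram)
from .family_dynamics import (branch_changes, infer_ancestral_counts,
                              species_pair_summary, terminal_vs_internal_test)
from .macrosynteny import linkage_groups, shared_og_matrix, test_scaffold_pairs
from .specificity import (category_proportions, clade_overlaps,
                          classify_orthogroups, gene_categories)
from .synthetic import (SimulationConfig, marker_category_pools,
                        simulate_gene_content, simulate_genomes,
                        simulate_markers)
from .trees import CladeMap, SpeciesTree, read_tree_and_clades

logger = logging.getLogger(__name__)

DEFAULT_STAGES = ("specificity", "markers", "family_dynamics", "macrosynteny")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def config_hash(cfg: Mapping[str, Any]) -> str:
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def ladder_from_tree(
    tree: SpeciesTree, focal_species: str, n_levels: int = 4
) -> tuple[CladeMap, list[str]]:
    """Build a nested clade ladder from the ancestors of a focal leaf.

    Returns a CladeMap whose clades are the ``n_levels`` smallest strict
    ancestors of the focal species (named after the internal nodes), with
    the root clade flagged as Metazoa-equivalent and the largest non-root
    ancestor as the focal phylum, plus the ladder ordered least inclusive
    first (for marker annotation).
    """
    node = tree.node(focal_species)
    ancestors = []
    while node.parent is not None:
        node = node.parent
        ancestors.append(node)
    chosen = ancestors[:n_levels]
    clades = [(n.name, tree.leafset(n.name)) for n in chosen]
    root_name = tree.root.name
    if root_name not in [c[0] for c in clades]:
        clades.append((root_name, tree.leafset(root_name)))
    non_root = [c[0] for c in clades if c[0] != root_name]
    focal_phylum = non_root[-1] if non_root else root_name
    cmap = CladeMap(clades, focal_phylum=focal_phylum, metazoa=root_name)
    ladder = [c for c in non_root]
    return cmap, ladder


@dataclass
class PipelineData:
    """In-memory bundle the stages consume."""

    orthogroups: Any = None
    tree: Optional[SpeciesTree] = None
    clades: Optional[CladeMap] = None
    ladder: Optional[list[str]] = None
    markers: Optional[pd.DataFrame] = None
    positions_a: Optional[pd.DataFrame] = None
    positions_b: Optional[pd.DataFrame] = None
    leaf_counts: Optional[pd.DataFrame] = None
    focal_species: Optional[str] = None
    focal_pair: Optional[tuple[str, str]] = None
    truth: dict = field(default_factory=dict)


def _load_inputs(cfg: Mapping[str, Any]) -> PipelineData:
    data = PipelineData()
    if "simulate" in cfg:
        sim_kwargs = dict(cfg["simulate"] or {})
        sim_kwargs.setdefault("seed", cfg.get("seed", 0))
        sim = SimulationConfig(**sim_kwargs)
        content, leaf_counts, tree, truth = simulate_gene_content(sim)
        data.orthogroups, data.leaf_counts, data.tree = (content, leaf_counts,
                                                         tree)
        data.truth["gene_content"] = truth
        data.focal_species = cfg.get("focal_species", tree.leaf_names[0])
        data.focal_pair = sim.focal_pair or tuple(tree.leaf_names[:2])
        data.clades, data.ladder = ladder_from_tree(
            tree, data.focal_species, n_levels=cfg.get("ladder_levels", 4)
        )
        pos_a, pos_b, genome_truth = simulate_genomes(sim, content)
        data.positions_a, data.positions_b = pos_a, pos_b
        data.truth["genomes"] = genome_truth
        assignment = classify_orthogroups(content, tree, data.clades)
        pools = marker_category_pools(content, assignment, data.ladder,
                                      data.focal_species)
        markers, marker_truth = simulate_markers(sim, pools)
        data.markers = markers
        data.truth["markers"] = marker_truth
        return data

    inputs = cfg.get("inputs", {})
    if "orthogroups" not in inputs:
        raise FileNotFoundError("config lists no orthogroup table")
    data.orthogroups = data_io.read_orthogroups(inputs["orthogroups"])
    data.tree, data.clades = read_tree_and_clades(inputs["tree"],
                                                  inputs["clades"])
    data.focal_species = cfg.get("focal_species")
    data.ladder = cfg.get("ladder")
    if "markers" in inputs:
        data.markers = data_io.read_markers(inputs["markers"])
    if "positions_a" in inputs:
        data.positions_a = data_io.read_gene_positions(
            inputs["positions_a"], format=cfg.get("position_format", "gff3"),
            species=cfg["species_a"])
        data.positions_b = data_io.read_gene_positions(
            inputs["positions_b"], format=cfg.get("position_format", "gff3"),
            species=cfg["species_b"])
        data.focal_pair = (cfg["species_a"], cfg["species_b"])
    if "family_counts" in inputs:
        data.leaf_counts = data_io.read_family_counts(inputs["family_counts"],
                                                      tree=data.tree)
    return data


def run_pipeline(cfg: Mapping[str, Any], output_dir=None) -> dict:
    """Execute the enabled stages; return (and optionally write) the report.

    Stage hard errors are re-raised as :class:`StageError` naming the
    failing stage.  With ``output_dir`` (or ``cfg["output_dir"]``) set,
    all stage tables, the JSON summary and a log file are written there.
    """
    cfg = dict(cfg)
    chash = config_hash(cfg)
    meta = {"config": chash, "seed": str(cfg.get("seed", 0))}
    outdir = Path(output_dir or cfg.get("output_dir")) if (
        output_dir or cfg.get("output_dir")) else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)

    stages = list(cfg.get("stages", DEFAULT_STAGES))
    report: dict[str, Any] = {"tool_version": __version__,
                              "config_hash": chash}

    try:
        data = _load_inputs(cfg)
    except Exception as exc:
        raise StageError("data_io", exc) from exc

    assignment = None
    annotated = None
    if "specificity" in stages:
        try:
            assignment = classify_orthogroups(data.orthogroups, data.tree,
                                              data.clades)
            report["specificity"] = {
                "n_orthogroups": len(assignment),
                "confinement_fractions": assignment.confinement_fractions(),
                "species_specific_counts": {
                    sp: assignment.species_specific_count(sp)
                    for sp in data.orthogroups.species_order
                },
            }
            if data.focal_species:
                cats = gene_categories(
                    data.orthogroups, assignment, data.focal_species,
                    data.orthogroups.species_genes(data.focal_species),
                    data.clades)
                props = category_proportions(cats)
                report["specificity"]["category_proportions"] = {
                    data.focal_species: props.to_dict()
                }
            if outdir:
                data_io.write_table(assignment.to_frame(),
                                    outdir / "specificity.tsv", meta=meta)
        except Exception as exc:
            raise StageError("specificity", exc) from exc

    if "markers" in stages and data.markers is not None:
        try:
            if assignment is None:
                assignment = classify_orthogroups(data.orthogroups, data.tree,
                                                  data.clades)
            criteria = FilterCriteria(**cfg.get("filter_criteria", {}))
            filtered = filter_markers(data.markers, criteria)
            gene_to_og = data.orthogroups.gene_to_og()
            annotated = assign_marker_categories(
                filtered, assignment, data.ladder, gene_to_og,
                data.focal_species)
            grouping = cfg.get("grouping") or {
                c: c for c in annotated["cluster"].unique()
            }
            lineage_def = cfg.get("lineage_def") or [
                f"{data.focal_species}_specific",
                *[f"{c}_confined" for c in data.ladder
                  if c != data.clades.metazoa],
            ]
            cats = category_ladder(data.ladder, data.focal_species)
            profiles = group_profiles(annotated, grouping, lineage_def,
                                      categories=cats)
            lsf = profiles[profiles["category"] == "lineage_specific_fraction"]
            report["markers"] = {
                "n_filtered": len(filtered),
                "lineage_specific_fraction": dict(
                    zip(lsf["group"], lsf["proportion"])),
            }
            if outdir:
                data_io.write_table(annotated, outdir / "annotated_markers.tsv",
                                    meta=meta)
                data_io.write_table(profiles, outdir / "group_profiles.tsv",
                                    meta=meta)
        except Exception as exc:
            raise StageError("markers", exc) from exc

    if "family_dynamics" in stages and data.leaf_counts is not None:
        try:
            anc = infer_ancestral_counts(data.leaf_counts, data.tree,
                                         max_count=cfg.get("max_count"))
            bct = branch_changes(anc, data.tree)
            welch = terminal_vs_internal_test(
                bct, metric=cfg.get("branch_metric", "families_changed"))
            report["family_dynamics"] = {
                "provenance": anc.provenance,
                "welch": welch.__dict__,
            }
            if data.focal_pair:
                pair = species_pair_summary(bct, anc, data.focal_pair,
                                            data.tree)
                report["family_dynamics"]["pair_summary"] = pair.to_dict()
            if outdir:
                data_io.write_table(bct, outdir / "branch_changes.tsv",
                                    meta=meta)
        except Exception as exc:
            raise StageError("family_dynamics", exc) from exc

    if "macrosynteny" in stages and data.positions_a is not None:
        try:
            gene_to_og = data.orthogroups.gene_to_og()
            m = shared_og_matrix(
                data.positions_a, data.positions_b, gene_to_og,
                max_scaffolds_per_og=cfg.get("max_scaffolds_per_og", 5))
            tests = test_scaffold_pairs(m, fdr=cfg.get("fdr", 0.05))
            clusters, dotplot = linkage_groups(m, tests, data.positions_a,
                                               data.positions_b, gene_to_og)
            report["macrosynteny"] = {
                "universe": m.universe,
                "n_significant_pairs": int(tests["significant"].sum())
                if len(tests) else 0,
                "n_linkage_groups": int(clusters["linkage_group"].nunique()),
            }
            if outdir:
                data_io.write_table(
                    m.matrix.reset_index().rename(columns={"index": "scaffold_a"}),
                    outdir / "shared_og_matrix.tsv", meta=meta)
                data_io.write_table(tests, outdir / "pair_tests.tsv", meta=meta)
                data_io.write_table(clusters, outdir / "linkage_groups.tsv",
                                    meta=meta)
                if dotplot is not None:
                    data_io.write_table(dotplot, outdir / "dotplot.tsv",
                                        meta=meta)
        except Exception as exc:
            raise StageError("macrosynteny", exc) from exc

    if outdir:
        (outdir / "summary.json").write_text(
            json.dumps(report, indent=2, sort_keys=True, default=str) + "\n")
    return report
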
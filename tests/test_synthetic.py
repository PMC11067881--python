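"""Generator determinism, planted truth self-consistency, distributions."""

import itertools

import numpy as np
import pandas as pd
import pytest

from cladescope import data_io
from cladescope.markers import (FilterCriteria, assign_marker_categories,
                                filter_markers, group_profiles,
                                lineage_specific_fraction)
from cladescope.specificity import classify_orthogroups
from cladescope.synthetic import (SimulationConfig, marker_category_pools,
                                  random_species_tree, simulate_gene_content,
                                  simulate_genomes, simulate_markers)
from cladescope.trees import CladeMap, parse_newick


class TestGeneContent:
    def test_zero_rates_place_families_exactly_below_origin(self):
        cfg = SimulationConfig(seed=1, n_leaves=8, n_families=200,
                               loss_prob=0.0, drift_prob=0.0)
        content, leaf_counts, tree, truth = simulate_gene_content(cfg)
        assert len(content) == 200  # nothing goes extinct without losses
        for og in content.og_ids:
            below = tree.leafset(truth.origin[og])
            assert content.possessors(og) == below
            for sp in tree.leaf_names:
                assert len(content.genes_of(og, sp)) == (1 if sp in below
                                                         else 0)

    def test_same_seed_byte_identical_outputs(self, tmp_path):
        files = []
        for run in ("x", "y"):
            cfg = SimulationConfig(seed=42, n_leaves=6, n_families=100)
            content, leaf_counts, tree, _ = simulate_gene_content(cfg)
            pos_a, pos_b, _ = simulate_genomes(cfg, content)
            d = tmp_path / run
            d.mkdir()
            data_io.write_orthogroups(content, d / "og.tsv")
            data_io.write_family_counts(leaf_counts, d / "fc.tsv")
            data_io.write_gene_positions_gff3(pos_a, d / "a.gff3")
            (d / "tree.nwk").write_text(tree.to_newick())
            files.append(d)
        for name in ("og.tsv", "fc.tsv", "a.gff3", "tree.nwk"):
            assert (files[0] / name).read_bytes() == \
                (files[1] / name).read_bytes()

    def test_truth_rederivable_from_emitted_tables(self):
        """Independent self-check: truth counts at leaves equal the emitted
        membership and count tables for every surviving family."""
        cfg = SimulationConfig(seed=9, n_leaves=8, n_families=300)
        content, leaf_counts, tree, truth = simulate_gene_content(cfg)
        for og in content.og_ids:
            for sp in tree.leaf_names:
                want = truth.counts[og][sp]
                assert len(content.genes_of(og, sp)) == want
                assert leaf_counts.loc[og, sp] == want
        # families absent from the tables are exactly the extinct ones
        extinct = set(truth.origin) - set(content.og_ids)
        for og in extinct:
            assert all(truth.counts[og][sp] == 0 for sp in tree.leaf_names)
        # Dollo: below a loss branch every count is zero
        for og, loss_branches in truth.losses.items():
            for branch in loss_branches:
                for leaf in tree.leafset(branch):
                    assert truth.counts[og][leaf] == 0

    @staticmethod
    def survivor_set_distribution(node, p_loss):
        """Exact distribution over surviving leaf sets, given the family is
        present at ``node``: each child edge loses independently with
        ``p_loss``, otherwise the child subtree's own distribution applies.
        Independent of the simulator's code path."""
        if node.is_leaf:
            return {frozenset([node.name]): 1.0}
        dist = {frozenset(): 1.0}
        for child in node.children:
            child_dist = {frozenset(): p_loss}
            sub = TestGeneContent.survivor_set_distribution(child, p_loss)
            for s, p in sub.items():
                child_dist[s] = child_dist.get(s, 0.0) + (1 - p_loss) * p
            merged = {}
            for s1, p1 in dist.items():
                for s2, p2 in child_dist.items():
                    key = s1 | s2
                    merged[key] = merged.get(key, 0.0) + p1 * p2
            dist = merged
        return dist

    def test_confinement_frequencies_match_exact_enumeration(self):
        """On a fixed 4-leaf tree with loss probability 0.5, observed
        per-clade confinement frequencies among surviving families sit
        within 3 sigma of the exactly enumerated probabilities."""
        newick = "((A,B)X,(C,D)Y)R;"
        tree = parse_newick(newick)
        loss = 0.5
        cfg = SimulationConfig(seed=77, newick=newick, n_families=10000,
                               loss_prob=loss, drift_prob=0.0)
        content, _, _, _ = simulate_gene_content(cfg)

        nodes = list(tree.postorder())
        set_prob: dict[frozenset, float] = {}
        for origin in nodes:  # origin branch is uniform over all nodes
            for s, p in self.survivor_set_distribution(origin, loss).items():
                set_prob[s] = set_prob.get(s, 0.0) + p / len(nodes)
        p_survive = sum(p for s, p in set_prob.items() if s)
        clades = {"X": frozenset("AB"), "Y": frozenset("CD"),
                  "R": frozenset("ABCD")}
        for name, leafset in clades.items():
            p_conf = sum(p for s, p in set_prob.items()
                         if s and s <= leafset) / p_survive
            observed = sum(
                1 for og in content.og_ids
                if content.possessors(og) <= leafset) / len(content)
            sigma = (p_conf * (1 - p_conf) / len(content)) ** 0.5
            assert abs(observed - p_conf) <= 3 * sigma + 1e-9, name

    def test_species_specific_rate_matches_enumeration(self):
        """Observed fraction of single-species families among survivors
        matches the exactly enumerated conditional probability."""
        newick = "((A,B)X,(C,D)Y)R;"
        cfg = SimulationConfig(seed=13, newick=newick, n_families=8000,
                               loss_prob=0.3, drift_prob=0.0)
        content, _, tree, _ = simulate_gene_content(cfg)
        observed = sum(1 for og in content.og_ids
                       if len(content.possessors(og)) == 1) / len(content)
        nodes = list(tree.postorder())
        p_single = p_alive = 0.0
        for origin in nodes:
            for s, p in self.survivor_set_distribution(origin, 0.3).items():
                w = p / len(nodes)
                if len(s) == 1:
                    p_single += w
                if s:
                    p_alive += w
        expected = p_single / p_alive
        sigma = (expected * (1 - expected) / len(content)) ** 0.5
        assert abs(observed - expected) <= 4 * sigma

    def test_zero_families_rejected(self):
        with pytest.raises(ValueError):
            simulate_gene_content(SimulationConfig(seed=1, n_families=0))


class TestGenomes:
    def test_zero_translocation_keeps_groups_pure(self):
        cfg = SimulationConfig(seed=3, n_leaves=6, n_families=800,
                               translocation_rate=0.0, inversion_rate=0.2,
                               n_linkage_groups=4)
        content, _, tree, _ = simulate_gene_content(cfg)
        pos_a, pos_b, truth = simulate_genomes(cfg, content)
        g2o = content.gene_to_og()
        for pos in (pos_a, pos_b):
            for row in pos.itertuples(index=False):
                scaffold_group = truth.scaffold_groups[(row.species,
                                                        row.scaffold)]
                assert truth.family_groups[g2o[row.gene]] == scaffold_group

    def test_full_translocation_breaks_association(self):
        """At rate 1 the scaffold/ancestral-group association vanishes
        (chi-squared independence test not rejected at p = 0.01)."""
        from scipy.stats import chi2_contingency

        cfg = SimulationConfig(seed=11, n_leaves=6, n_families=2000,
                               loss_prob=0.02, translocation_rate=1.0,
                               inversion_rate=0.0, n_linkage_groups=4)
        content, _, tree, _ = simulate_gene_content(cfg)
        pos_a, _, truth = simulate_genomes(cfg, content)
        g2o = content.gene_to_og()
        tab = pd.crosstab(
            pos_a["scaffold"],
            pos_a["gene"].map(lambda g: truth.family_groups[g2o[g]]))
        _, p, _, _ = chi2_contingency(tab)
        assert p > 0.01

    def test_more_groups_than_shared_families_rejected(self):
        cfg = SimulationConfig(seed=5, n_leaves=4, n_families=3,
                               n_linkage_groups=50)
        content, _, _, _ = simulate_gene_content(cfg)
        with pytest.raises(ValueError, match="linkage groups"):
            simulate_genomes(cfg, content)

    def test_same_seed_identical_gff(self, tmp_path):
        outs = []
        for run in range(2):
            cfg = SimulationConfig(seed=21, n_leaves=6, n_families=300)
            content, _, _, _ = simulate_gene_content(cfg)
            pos_a, _, _ = simulate_genomes(cfg, content)
            f = tmp_path / f"g{run}.gff3"
            data_io.write_gene_positions_gff3(pos_a, f)
            outs.append(f.read_bytes())
        assert outs[0] == outs[1]


class TestMarkers:
    def _setup(self, seed=7, **kwargs):
        cfg = SimulationConfig(seed=seed, n_leaves=10, n_families=2500,
                               **kwargs)
        content, _, tree, _ = simulate_gene_content(cfg)
        focal = tree.leaf_names[0]
        internal = [n for n in tree.node_names()
                    if n not in tree.leaf_names]
        node = tree.node(focal)
        ladder = []
        while node.parent is not None:
            node = node.parent
            ladder.append(node.name)
        clades = CladeMap([(n, tree.leafset(n)) for n in ladder],
                          focal_phylum=ladder[-2] if len(ladder) > 1
                          else ladder[-1],
                          metazoa=ladder[-1])
        assignment = classify_orthogroups(content, tree, clades)
        ladder_names = [n for n in ladder if n != tree.root.name]
        pools = marker_category_pools(content, assignment, ladder_names,
                                      focal)
        return cfg, content, assignment, pools, ladder_names, focal

    def test_emitted_truth_matches_emitted_table(self):
        cfg, content, assignment, pools, ladder, focal = self._setup()
        cats = [c for c in pools if pools[c]][:2]
        cfg2 = SimulationConfig(
            seed=cfg.seed, n_clusters=2, markers_per_cluster=10,
            marker_mixture={"*": {cats[0]: 0.5, cats[1]: 0.5}})
        markers, truth = simulate_markers(cfg2, pools)
        assert len(markers) == len(truth)
        assert (markers["gene"].to_numpy() == truth["gene"].to_numpy()).all()
        assert (markers["cluster"].to_numpy()
                == truth["cluster"].to_numpy()).all()

    def test_same_seed_identical_csv(self, tmp_path):
        _, _, _, pools, _, _ = self._setup()
        outs = []
        for run in range(2):
            cfg = SimulationConfig(seed=33, n_clusters=3,
                                   markers_per_cluster=20)
            markers, _ = simulate_markers(cfg, pools)
            f = tmp_path / f"m{run}.csv"
            data_io.write_markers(markers, f)
            outs.append(f.read_bytes())
        assert outs[0] == outs[1]

    def test_planted_stratum_without_genes_rejected(self):
        cfg = SimulationConfig(seed=1, n_clusters=1, markers_per_cluster=5,
                               marker_mixture={"*": {"ghost": 1.0}})
        with pytest.raises(ValueError, match="ghost"):
            simulate_markers(cfg, {"ghost": [], "real": ["g1"]})

    def test_planted_mixture_recovered_within_binomial_ci(self):
        """The analyzer's per-group category proportions sit inside the
        99% binomial CI of the planted mixture at n = 1000 markers."""
        # a ladder-shaped tree so the focal species has deep nested clades
        newick = ("(((((Hs,He)g1,s3)g2,s4)g3,(s5,s6)g4)g5,(o1,o2)out)root;")
        cfg = SimulationConfig(seed=47, newick=newick, n_families=12000,
                               loss_prob=0.05, drift_prob=0.1)
        content, _, tree, _ = simulate_gene_content(cfg)
        focal = "Hs"
        node = tree.node(focal)
        ancestors = []
        while node.parent is not None:
            node = node.parent
            ancestors.append(node.name)
        clades = CladeMap([(n, tree.leafset(n)) for n in ancestors],
                          focal_phylum=ancestors[-2], metazoa=ancestors[-1])
        assignment = classify_orthogroups(content, tree, clades)
        ladder = [n for n in ancestors if n != tree.root.name]
        pools = marker_category_pools(content, assignment, ladder, focal,
                                      n_unassigned=2000)
        cat_a = "not_assigned"
        cat_b = max((c for c in pools if c != cat_a),
                    key=lambda c: len(pools[c]))
        assert len(pools[cat_b]) >= 700, {c: len(p) for c, p in pools.items()}
        mixture = {cat_a: 0.3, cat_b: 0.7}
        n = 1000
        mcfg = SimulationConfig(seed=48, newick=newick, n_clusters=1,
                                markers_per_cluster=n, fail_fraction=0.0,
                                marker_mixture={"*": mixture})
        markers, truth = simulate_markers(mcfg, pools)
        filtered = filter_markers(markers)
        annotated = assign_marker_categories(
            filtered, assignment, ladder, content.gene_to_og(), focal)
        profiles = group_profiles(annotated, {"C0": "C0"},
                                  lineage_def={cat_b})
        for cat, planted_p in mixture.items():
            row = profiles[(profiles["group"] == "C0")
                           & (profiles["category"] == cat)]
            got = float(row["proportion"].iloc[0])
            half = 2.576 * (planted_p * (1 - planted_p) / n) ** 0.5
            assert abs(got - planted_p) <= half + 0.01, cat


class TestRandomTree:
    def test_deterministic_and_binary(self):
        t1 = random_species_tree(5, 12)
        t2 = random_species_tree(5, 12)
        assert t1.to_newick() == t2.to_newick()
        assert len(t1.leaf_names) == 12
        for node in t1.postorder():
            assert node.is_leaf or len(node.children) == 2
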
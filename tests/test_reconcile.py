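import numpy as np
import pytest

from _oracles import leafset_duplications, leafset_images, subdivision_losses
from polynj import simulate, treeio
from polynj.reconcile import (
    CostScheme,
    SpeciesIndex,
    annotate_events,
    branch_tally,
    count_losses,
    gene_content,
    lca_map,
    reconcile,
    tally_table,
)
from polynj.treeio import parse_newick


def images_by_name(rec):
    return {n.name: rec.mapping[n].name for n in rec.gene_tree.iter_leaves()}


class TestCostScheme:
    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            CostScheme(-1, 1)

    def test_both_zero_rejected(self):
        with pytest.raises(ValueError):
            CostScheme(0, 0)


class TestLcaMap:
    def test_cherry_same_species(self, species_abc):
        g = parse_newick("(b1,b2);")
        rec = lca_map(g, species_abc, {"b1": "b", "b2": "b"})
        assert rec.mapping[g].name == "b"

    def test_cherry_spanning_root(self, species_abc):
        g = parse_newick("(a1,c1);")
        rec = lca_map(g, species_abc, {"a1": "a", "c1": "c"})
        assert rec.mapping[g] is species_abc

    def test_unmapped_leaf_errors(self, species_abc):
        g = parse_newick("(a1,c1);")
        with pytest.raises(ValueError, match="a1"):
            lca_map(g, species_abc, {"c1": "c"})

    def test_matches_leafset_oracle(self):
        # quadratic clade-scan oracle over random simulated families
        count = 0
        for seed in range(600):
            S = simulate.simulate_species_tree(2 + seed % 6, seed=seed * 7 + 1)
            fam = simulate.simulate_gene_family(S, 0.3, 0.2, seed=seed)
            rec = lca_map(fam.tree, S, fam.leaf_species)
            oracle = leafset_images(fam.tree, S, fam.leaf_species)
            for node in fam.tree.iter_postorder():
                assert rec.mapping[node] is oracle[node]
            count += 1
            if count >= 500:
                break
        assert count == 500


class TestEvents:
    def test_same_species_cherry_is_duplication(self, species_abc):
        g = parse_newick("(b1,b2);")
        rec = annotate_events(lca_map(g, species_abc, {"b1": "b", "b2": "b"}))
        assert rec.events[g] == "duplication"

    def test_cross_species_cherry_is_speciation(self, species_abc):
        g = parse_newick("(a1,b1);")
        rec = annotate_events(lca_map(g, species_abc, {"a1": "a", "b1": "b"}))
        assert rec.events[g] == "speciation"

    def test_three_genes_two_duplications(self, species_abc):
        # three genes of b resolved as ((b1,b2),b3): both internal nodes dup
        g = parse_newick("((b1,b2),b3);")
        rec = annotate_events(lca_map(g, species_abc, dict.fromkeys(["b1", "b2", "b3"], "b")))
        events = [rec.events[n] for n in g.iter_postorder() if n.children]
        assert events == ["duplication", "duplication"]


class TestLosses:
    def test_congruent_tree_no_losses(self, species_abc):
        g = parse_newick("((a1,b1),c1);")
        rec = reconcile(g, species_abc, {"a1": "a", "b1": "b", "c1": "c"})
        assert rec.loss_count() == 0

    def test_k_lineages_bypassing_leaf(self, species_abc):
        # two lineages pass the root speciation without a b gene: 2 losses on b
        g = parse_newick("((a1,c1),(a2,c2));")
        rec = reconcile(g, species_abc, {"a1": "a", "a2": "a", "c1": "c", "c2": "c"})
        b = next(l for l in species_abc.iter_leaves() if l.name == "b")
        assert rec.losses == {b: 2}

    def test_matches_subdivision_oracle(self):
        for seed in range(300):
            S = simulate.simulate_species_tree(2 + seed % 6, seed=seed * 13 + 5)
            fam = simulate.simulate_gene_family(S, 0.3, 0.25, seed=seed + 10_000)
            rec = reconcile(fam.tree, S, fam.leaf_species)
            oracle = subdivision_losses(fam.tree, S, fam.leaf_species)
            assert rec.losses == {s: k for s, k in oracle.items() if k}

    def test_cost_invariant_under_child_order(self, species_abc):
        g = parse_newick("((a1,c1),(b1,b2));")
        leaf_map = {"a1": "a", "b1": "b", "b2": "b", "c1": "c"}
        rec = reconcile(g, species_abc, leaf_map)
        # shuffle children everywhere
        g2 = g.copy()
        for node in g2.iter_postorder():
            node.children.reverse()
        rec2 = reconcile(g2, species_abc, leaf_map)
        assert rec.cost() == rec2.cost()
        assert rec.dup_count() == rec2.dup_count()


class TestGeneContent:
    def test_congruent_content_one_everywhere(self, species_abc):
        g = parse_newick("((a1,b1),c1);")
        rec = reconcile(g, species_abc, {"a1": "a", "b1": "b", "c1": "c"})
        content = gene_content(rec)
        assert all(v == 1 for v in content.values())
        assert len(content) == 5

    def test_content_counts_entering_lineages(self, species_abc):
        # ((b1,b2),b3): one lineage enters b, duplications happen inside
        g = parse_newick("((b1,b2),b3);")
        rec = reconcile(g, species_abc, dict.fromkeys(["b1", "b2", "b3"], "b"))
        b = next(l for l in species_abc.iter_leaves() if l.name == "b")
        assert gene_content(rec) == {b: 1}

    def test_root_content_is_one_for_root_mapped_tree(self, species_abc):
        g = parse_newick("((a1,b1),c1);")
        rec = reconcile(g, species_abc, {"a1": "a", "b1": "b", "c1": "c"})
        assert gene_content(rec)[species_abc] == 1


class TestBranchTally:
    def test_single_duplication(self, species_abc):
        g = parse_newick("(b1,b2);")
        rec = reconcile(g, species_abc, {"b1": "b", "b2": "b"})
        tally = branch_tally([rec])
        b = next(l for l in species_abc.iter_leaves() if l.name == "b")
        assert tally[b] == (1, 0)
        assert all(t == (0, 0) for s, t in tally.items() if s is not b)

    def test_additivity(self, family_factory):
        S, fam1 = family_factory(1)
        _, fam2 = family_factory(2)
        idx = SpeciesIndex(S)
        r1 = reconcile(fam1.tree, idx, fam1.leaf_species)
        r2 = reconcile(fam2.tree, idx, fam2.leaf_species)
        t1 = branch_tally([r1], idx)
        t2 = branch_tally([r2], idx)
        t12 = branch_tally([r1, r2], idx)
        for s in idx.nodes:
            assert t12[s] == (t1[s][0] + t2[s][0], t1[s][1] + t2[s][1])

    def test_recovers_simulator_ground_truth(self, family_factory):
        S, _ = family_factory(0)
        idx = SpeciesIndex(S)
        recs, fams = [], []
        for seed in range(25):
            _, fam = family_factory(seed + 100)
            fams.append(fam)
            recs.append(reconcile(fam.tree, idx, fam.leaf_species))
        tally = branch_tally(recs, idx)
        for s in idx.nodes:
            want_d = sum(f.truth_dups.get(s, 0) for f in fams)
            want_l = sum(f.truth_losses.get(s, 0) for f in fams)
            assert tally[s] == (want_d, want_l)

    def test_mismatched_species_tree_rejected(self, species_abc, family_factory):
        S, fam = family_factory(3)
        rec = reconcile(fam.tree, S, fam.leaf_species)
        g = parse_newick("(b1,b2);")
        rec2 = reconcile(g, species_abc, {"b1": "b", "b2": "b"})
        with pytest.raises(ValueError):
            branch_tally([rec, rec2])

    def test_tally_table_format(self, species_abc):
        g = parse_newick("(b1,b2);")
        rec = reconcile(g, species_abc, {"b1": "b", "b2": "b"})
        idx = rec.index
        text = tally_table(branch_tally([rec]), idx)
        lines = text.strip().splitlines()
        assert lines[0] == "branch\tduplications\tlosses"
        assert len(lines) == 1 + len(idx.nodes)


class TestInternalConsistency:
    def test_cost_equals_weighted_tallies(self, family_factory):
        costs = CostScheme(2.0, 0.5)
        for seed in range(20):
            S, fam = family_factory(seed + 500)
            rec = reconcile(fam.tree, S, fam.leaf_species)
            tally = branch_tally([rec])
            dups = sum(d for d, _ in tally.values())
            losses = sum(l for _, l in tally.values())
            assert rec.cost(costs) == pytest.approx(costs.dup * dups + costs.loss * losses)

    def test_duplications_match_leafset_oracle(self, family_factory):
        for seed in range(20):
            S, fam = family_factory(seed + 900)
            rec = reconcile(fam.tree, S, fam.leaf_species)
            oracle = leafset_duplications(fam.tree, S, fam.leaf_species)
            got = {}
            for n in rec.duplications():
                got[rec.mapping[n]] = got.get(rec.mapping[n], 0) + 1
            assert got == dict(oracle)
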
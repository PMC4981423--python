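import itertools

import numpy as np
import pytest

from polynj import compare, simulate, treeio
from polynj.prepare import contract_low_support
from polynj.reconcile import SpeciesIndex, reconcile
from polynj.treeio import parse_newick, write_newick


class TestSpeciesTree:
    def test_two_leaves_cherry(self):
        S = simulate.simulate_species_tree(2, seed=0)
        assert len(S.children) == 2
        assert all(c.is_leaf() for c in S.children)

    def test_sixteen_leaves_fifteen_internal(self):
        S = simulate.simulate_species_tree(16, seed=1)
        internal = [n for n in S.iter_postorder() if n.children]
        assert len(internal) == 15
        assert S.is_binary()

    def test_deterministic(self):
        a = simulate.simulate_species_tree(9, seed=7)
        b = simulate.simulate_species_tree(9, seed=7)
        assert write_newick(a) == write_newick(b)

    def test_too_small(self):
        with pytest.raises(ValueError):
            simulate.simulate_species_tree(1, seed=0)


class TestGeneFamily:
    def test_zero_rates_congruent(self):
        S = simulate.simulate_species_tree(7, seed=3)
        fam = simulate.simulate_gene_family(S, 0.0, 0.0, seed=4)
        assert fam.size == 7
        assert fam.raw_dup_count == 0 and fam.raw_loss_count == 0
        assert not fam.truth_dups and not fam.truth_losses
        # topology congruent with S: identical bipartitions after renaming
        renamed = S.copy()
        for leaf in renamed.iter_leaves():
            leaf.name = f"g1_{leaf.name}"
        assert compare.rf_distance(renamed, fam.tree) == 0

    def test_no_loss_every_species_sampled(self):
        S = simulate.simulate_species_tree(6, seed=9)
        for seed in range(10):
            fam = simulate.simulate_gene_family(S, 0.2, 0.0, seed=seed)
            assert set(fam.census) == set(S.leaf_names())
            assert not fam.truth_losses

    def test_ground_truth_closure(self, family_factory):
        # reconciling the true tree reproduces recorded events exactly
        for seed in range(40):
            S, fam = family_factory(seed + 300)
            rec = reconcile(fam.tree, S, fam.leaf_species)
            got_dups = {}
            for n in rec.duplications():
                got_dups[rec.mapping[n]] = got_dups.get(rec.mapping[n], 0) + 1
            assert got_dups == fam.truth_dups
            assert rec.losses == fam.truth_losses

    def test_deterministic(self):
        S = simulate.simulate_species_tree(6, seed=2)
        a = simulate.simulate_gene_family(S, 0.3, 0.2, seed=5)
        b = simulate.simulate_gene_family(S, 0.3, 0.2, seed=5)
        assert write_newick(a.tree) == write_newick(b.tree)

    def test_doubling_dup_rate_doubles_expectation(self):
        # Monte-Carlo check at rate_loss=0, where every birth is observable
        S = simulate.simulate_species_tree(6, seed=8)
        base, doubled = 0.02, 0.04
        n_rep = 400
        c1 = sum(simulate.simulate_gene_family(S, base, 0.0, seed=i).raw_dup_count
                 for i in range(n_rep))
        c2 = sum(simulate.simulate_gene_family(S, doubled, 0.0, seed=10_000 + i).raw_dup_count
                 for i in range(n_rep))
        ratio = c2 / max(c1, 1)
        assert 1.5 < ratio < 2.6


class TestDistances:
    def test_zero_noise_additive_four_point(self):
        S = simulate.simulate_species_tree(8, seed=4)
        fam = simulate.simulate_gene_family(S, 0.2, 0.1, seed=6)
        dm = simulate.simulate_distances(fam.tree, noise_sd=0.0, seed=0)
        labels = dm.labels
        for quartet in itertools.islice(itertools.combinations(labels, 4), 30):
            a, b, c, d = quartet
            sums = sorted([
                dm.get(a, b) + dm.get(c, d),
                dm.get(a, c) + dm.get(b, d),
                dm.get(a, d) + dm.get(b, c),
            ])
            assert sums[1] == pytest.approx(sums[2], abs=1e-9)

    def test_nj_on_exact_matrix_recovers_topology(self):
        from skbio import DistanceMatrix as SkDM
        from skbio.tree import nj as sknj

        for seed in range(8):
            S = simulate.simulate_species_tree(7, seed=seed)
            fam = simulate.simulate_gene_family(S, 0.2, 0.1, seed=seed + 50)
            if fam.size < 4:
                continue
            dm = simulate.simulate_distances(fam.tree, noise_sd=0.0, seed=0)
            rebuilt = parse_newick(str(sknj(SkDM(dm.matrix, dm.labels))))
            assert compare.rf_distance(rebuilt, fam.tree) == 0

    def test_seed_reproducible(self):
        S = simulate.simulate_species_tree(6, seed=1)
        fam = simulate.simulate_gene_family(S, 0.2, 0.1, seed=2)
        a = simulate.simulate_distances(fam.tree, noise_sd=0.1, seed=3)
        b = simulate.simulate_distances(fam.tree, noise_sd=0.1, seed=3)
        assert np.array_equal(a.matrix, b.matrix)

    def test_noise_keeps_contract(self):
        S = simulate.simulate_species_tree(6, seed=1)
        fam = simulate.simulate_gene_family(S, 0.2, 0.1, seed=2)
        dm = simulate.simulate_distances(fam.tree, noise_sd=0.5, seed=3)
        assert (dm.matrix >= 0).all()
        assert np.array_equal(dm.matrix, dm.matrix.T)
        assert np.allclose(np.diag(dm.matrix), 0)


class TestDegradeAndPerturb:
    def test_no_weak_nothing_contracted(self):
        S = simulate.simulate_species_tree(7, seed=5)
        fam = simulate.simulate_gene_family(S, 0.2, 0.1, seed=5)
        degraded, weak = simulate.degrade_supports(fam.tree, 0, seed=0)
        assert weak == []
        out = contract_low_support(degraded, 0.95)
        assert compare.bipartitions(out) == compare.bipartitions(fam.tree)

    def test_all_weak_gives_star(self):
        S = simulate.simulate_species_tree(7, seed=6)
        fam = simulate.simulate_gene_family(S, 0.0, 0.0, seed=6)
        internal = [n for n in fam.tree.iter_postorder()
                    if n.children and n.parent is not None]
        degraded, _ = simulate.degrade_supports(fam.tree, len(internal), seed=1)
        star = contract_low_support(degraded, 0.95)
        assert len(star.children) == fam.size

    def test_planted_set_equals_contracted_set(self):
        S = simulate.simulate_species_tree(9, seed=7)
        fam = simulate.simulate_gene_family(S, 0.2, 0.05, seed=7)
        internal = [n for n in fam.tree.iter_postorder()
                    if n.children and n.parent is not None]
        degraded, weak = simulate.degrade_supports(fam.tree, len(internal) // 2, seed=2)
        contracted = contract_low_support(degraded, 0.95)
        lost = compare.bipartitions(degraded) - compare.bipartitions(contracted)
        all_leaves = degraded.leaf_set()
        ref = min(all_leaves)
        planted = set()
        for node in weak:
            side = node.leaf_set()
            if len(side) >= 2 and len(all_leaves - side) >= 2:
                planted.add(frozenset(all_leaves - side) if ref in side else frozenset(side))
        assert lost == planted

    def test_nni_changes_one_bipartition_per_move(self):
        S = simulate.simulate_species_tree(10, seed=8)
        fam = simulate.simulate_gene_family(S, 0.0, 0.0, seed=8)
        perturbed, moved = simulate.perturb_topology(fam.tree, 1, seed=3)
        assert compare.rf_distance(perturbed, fam.tree) in (0, 2)
        assert sorted(perturbed.leaf_names()) == sorted(fam.tree.leaf_names())


class TestFixtureBundle:
    def test_bundle_round_trips(self, tmp_path):
        S = simulate.simulate_species_tree(5, seed=10)
        fams = [simulate.simulate_gene_family(S, 0.2, 0.1, seed=i) for i in range(3)]
        dms = [simulate.simulate_distances(f.tree, seed=i) for i, f in enumerate(fams)]
        simulate.write_fixture_bundle(tmp_path / "bundle", S, fams, dms)
        root = tmp_path / "bundle"
        S2 = parse_newick((root / "species.nw").read_text(), kind="species")
        assert compare.bipartitions(S2) == compare.bipartitions(S)
        for i, fam in enumerate(fams, 1):
            t = parse_newick((root / f"gene{i}.nw").read_text())
            assert sorted(t.leaf_names()) == sorted(fam.tree.leaf_names())
            dm = treeio.read_distance_matrix((root / f"gene{i}.dist").read_text())
            assert set(dm.labels) == set(fam.leaf_species)
        manifest = (root / "manifest.tsv").read_text().splitlines()
        assert len(manifest) == 1 + len(fams)
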
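"""Coalescent simulator: MUL tree construction, MSC behavior, determinism."""

import math

import numpy as np
import pytest

import mulsignal as m
import mulsignal.treeio as tio

from conftest import oracle_induced_clades


class TestBuildMulSpeciesTree:
    def test_basic_attachment(self):
        sp = m.tree_from_newick("((P1:2,P2:2):1,Out:3);", rooted=True)
        mul = m.build_mul_species_tree(
            sp, m.AllopolyploidyEvent("H", "P1", "P2", 1.0)
        )
        assert m.tree_to_newick(mul) == \
            "(((A-H:1.0,P1:1.0):1.0,(B-H:1.0,P2:1.0):1.0):1.0,Out:3.0);"

    def test_zero_time_boundary(self):
        sp = m.tree_from_newick("((P1:2,P2:2):1,Out:3);", rooted=True)
        mul = m.build_mul_species_tree(
            sp, m.AllopolyploidyEvent("H", "P1", "P2", 0.0)
        )
        clades = tio.clade_sets(mul)
        assert frozenset({"A-H", "P1"}) in clades
        assert frozenset({"B-H", "P2"}) in clades

    def test_adds_exactly_two_tips(self):
        sp = m.tree_from_newick("((P1:2,P2:2):1,Out:3);", rooted=True)
        mul = m.build_mul_species_tree(
            sp, m.AllopolyploidyEvent("H", "P1", "P2", 1.5)
        )
        assert len(tio.leaf_labels(mul)) == len(tio.leaf_labels(sp)) + 2

    def test_too_old_event_errors(self):
        sp = m.tree_from_newick("((P1:2,P2:2):1,Out:3);", rooted=True)
        with pytest.raises(ValueError, match="older"):
            m.build_mul_species_tree(
                sp, m.AllopolyploidyEvent("H", "P1", "P2", 10.0)
            )

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            m.AllopolyploidyEvent("H", "P1", "P2", -1.0)


class TestSimulateGeneTree:
    def test_two_taxa_forced_topology(self):
        sp = m.tree_from_newick("(A:1,B:1);", rooted=True)
        gt, _ = m.simulate_gene_tree(sp, 5)
        species = {l.split("__")[0] for l in tio.leaf_labels(gt)}
        assert species == {"A", "B"}
        assert len(tio.leaf_labels(gt)) == 2

    def test_no_ils_limit_matches_species_tree(self):
        nwk = m.ultrametric_from_topology(
            "((a,b),((c,d),(e,out)));", unit=50.0, extra_leaf_depth=0.0
        )
        sp = m.tree_from_newick(nwk, rooted=True)
        expect = {
            frozenset(s.split("__")[0] for s in c)
            for c in tio.clade_sets(sp)
        }
        for seed in range(20):
            gt, _ = m.simulate_gene_tree(sp, seed)
            got = {
                frozenset(l.split("__")[0] for l in c)
                for c in tio.clade_sets(gt)
            }
            assert got == expect

    def test_same_seed_identical_tree(self):
        sp = m.tree_from_newick(
            m.ultrametric_from_topology("((a,b),(c,out));", unit=1.0),
            rooted=True,
        )
        t1, _ = m.simulate_gene_tree(sp, 99)
        t2, _ = m.simulate_gene_tree(sp, 99)
        assert m.tree_to_newick(t1) == m.tree_to_newick(t2)

    def test_hybrid_tips_emitted_as_hybrid_taxon_with_truth(self):
        sp = m.tree_from_newick("((P1:4,P2:4):2,Out:6);", rooted=True)
        mul = m.build_mul_species_tree(
            sp, m.AllopolyploidyEvent("H", "P1", "P2", 1.0)
        )
        gt, truth = m.simulate_gene_tree(mul, 1)
        h_tips = [l for l in tio.leaf_labels(gt) if l.startswith("H__")]
        assert len(h_tips) == 2
        assert sorted(truth[l.split("__")[1]] for l in h_tips) == ["A", "B"]

    def test_gene_trees_are_ultrametric(self):
        sp = m.tree_from_newick(
            m.ultrametric_from_topology("((a,(b,c)),(d,out));", unit=2.0),
            rooted=True,
        )
        for seed in range(5):
            gt, _ = m.simulate_gene_tree(sp, seed)
            depths = {}
            for leaf in gt.leaf_node_iter():
                d, node = 0.0, leaf
                while node.parent_node is not None:
                    d += node.edge.length
                    node = node.parent_node
                depths[leaf.taxon.label] = d
            vals = list(depths.values())
            assert max(vals) - min(vals) < 1e-9 * max(1.0, max(vals))

    def test_discordance_matches_closed_form(self):
        """4-taxon MSC: discordant fraction ~ (2/3)exp(-T) at T=1."""
        T = 1.0
        sp = m.tree_from_newick(
            f"(((A:1,B:1):{T},C:{1+T}):1,D:{2+T});", rooted=True
        )
        n, disc = 2000, 0
        for i in range(n):
            rng = np.random.default_rng(
                np.random.SeedSequence(entropy=51, spawn_key=(i,))
            )
            gt, _ = m.simulate_gene_tree(sp, rng)
            clades = {
                frozenset(l.split("__")[0] for l in c)
                for c in tio.clade_sets(gt)
            }
            if frozenset({"A", "B"}) not in clades:
                disc += 1
        expect = (2 / 3) * math.exp(-T)
        se = math.sqrt(expect * (1 - expect) / n)
        assert abs(disc / n - expect) < 3 * se


class TestInjectParalogs:
    def _gt(self, seed=0):
        sp = m.tree_from_newick(
            m.ultrametric_from_topology("((a,(b,c)),(d,out));", unit=2.0),
            rooted=True,
        )
        gt, _ = m.simulate_gene_tree(sp, seed)
        return gt

    def test_zero_rate_identity(self):
        gt = self._gt()
        out, parents = m.inject_paralogs(gt, 0.0, 1)
        assert parents == {}
        assert m.tree_to_newick(out) == m.tree_to_newick(gt)

    def test_deterministic_replay(self):
        gt = self._gt()
        o1, p1 = m.inject_paralogs(gt, 1.0, 42)
        o2, p2 = m.inject_paralogs(gt, 1.0, 42)
        assert m.tree_to_newick(o1) == m.tree_to_newick(o2)
        assert p1 == p2

    def test_restriction_recovers_original(self):
        """Restricting to the original tips undoes every grafted duplicate."""
        for seed in range(30):
            gt = self._gt(seed)
            out, parents = m.inject_paralogs(gt, 1.5, seed + 100)
            orig = set(tio.leaf_labels(gt))
            back = m.restrict(out, orig)
            got = {c for c in tio.clade_sets(back) if len(c) >= 2}
            assert got == {c for c in tio.clade_sets(gt) if len(c) >= 2}
            # every fresh tip is mapped to a parent gene
            fresh = set(tio.leaf_labels(out)) - orig
            assert {l.split("__")[1] for l in fresh} == set(parents)


class TestSimulateDataset:
    def _config(self, **kw):
        setting = m.nymphaeales_demo(unit=5.0)
        defaults = dict(
            species_tree=setting.species_tree, events=setting.events,
            n_genes=5, outgroup=setting.outgroup, dup_rate=0.5, seed=8,
        )
        defaults.update(kw)
        return m.SimConfig(**defaults)

    def test_zero_genes_empty(self):
        ds = m.simulate_dataset(self._config(n_genes=0))
        assert ds.trees == [] and ds.lengths == {}

    def test_byte_identical_replay(self):
        d1 = m.simulate_dataset(self._config())
        d2 = m.simulate_dataset(self._config())
        assert [m.tree_to_newick(t) for t in d1.trees] == \
            [m.tree_to_newick(t) for t in d2.trees]
        assert d1.lengths == d2.lengths
        assert d1.truth.to_json() == d2.truth.to_json()

    def test_per_gene_results_independent_of_n_genes(self):
        small = m.simulate_dataset(self._config(n_genes=3))
        large = m.simulate_dataset(self._config(n_genes=6))
        for a, b in zip(small.trees, large.trees):
            assert m.tree_to_newick(a) == m.tree_to_newick(b)

    def test_outgroup_never_dropped(self):
        ds = m.simulate_dataset(self._config(n_genes=30, missing_rate=0.3))
        for tree in ds.trees:
            assert any(l.startswith("amb__") for l in tio.leaf_labels(tree))

    def test_invalid_config_rejected_before_generation(self):
        with pytest.raises(ValueError):
            m.simulate_dataset(self._config(n_genes=-1))
        with pytest.raises(ValueError):
            m.simulate_dataset(self._config(dup_rate=-0.1))
        with pytest.raises(ValueError):
            m.simulate_dataset(self._config(missing_rate=1.5))

    def test_truth_covers_all_hybrid_tips(self):
        ds = m.simulate_dataset(self._config(n_genes=10))
        for i, tree in enumerate(ds.trees):
            truth = ds.truth.per_gene[i]["subgenome"]
            for lbl in tio.leaf_labels(tree):
                sp, gid = lbl.split("__")
                if sp in ("mid", "wbg"):
                    assert truth[gid] in ("A", "B")
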
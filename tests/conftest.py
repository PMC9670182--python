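"""Shared fixtures and independent oracle helpers.

The oracle helpers deliberately avoid the library's own tree machinery:
induced clades are computed by set intersection, quartet topologies by
explicit ancestor-path walks on dendropy nodes.
"""

from __future__ import annotations

import itertools

import dendropy
import pytest

import mulsignal as m


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def oracle_induced_clades(tree: dendropy.Tree, keep: set[str]) -> set[frozenset]:
    """Clades of the induced subtree on ``keep``, derived purely by
    intersecting every original clade with ``keep`` (no pruning code)."""
    out = set()
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            continue
        clade = frozenset(lf.taxon.label for lf in node.leaf_iter()) & keep
        if len(clade) >= 2:
            out.add(clade)
    return out


def oracle_quartet_topology(tree: dendropy.Tree, quad: tuple[str, str, str, str]):
    """Induced unrooted topology of four tips: the pair holding quad[0],
    or None when unresolved.  Uses explicit root-path edge counts."""
    leaves = {lf.taxon.label: lf for lf in tree.leaf_node_iter()}
    paths = {}
    for name in quad:
        path = []
        node = leaves[name]
        while node is not None:
            path.append(node)
            node = node.parent_node
        paths[name] = path

    def dist(a, b):
        pa, pb = paths[a], paths[b]
        sb = {id(n): i for i, n in enumerate(pb)}
        for i, n in enumerate(pa):
            if id(n) in sb:
                return i + sb[id(n)]
        raise AssertionError("disconnected tips")

    a, b, c, d = quad
    s = {
        frozenset({a, b}): dist(a, b) + dist(c, d),
        frozenset({a, c}): dist(a, c) + dist(b, d),
        frozenset({a, d}): dist(a, d) + dist(b, c),
    }
    lo = min(s.values())
    winners = [k for k, v in s.items() if v == lo]
    if len(winners) != 1:
        return None
    return winners[0]


def oracle_quartet_score(candidate: dendropy.Tree, gene_trees) -> int:
    """Brute-force quartet score by per-subset topology comparison."""
    cand_taxa = sorted(lf.taxon.label for lf in candidate.leaf_node_iter())
    score = 0
    for gt in gene_trees:
        gt_taxa = {lf.taxon.label for lf in gt.leaf_node_iter()}
        for quad in itertools.combinations(cand_taxa, 4):
            if not set(quad) <= gt_taxa:
                continue
            tc = oracle_quartet_topology(candidate, quad)
            tg = oracle_quartet_topology(gt, quad)
            if tc is not None and tc == tg:
                score += 1
    return score


def oracle_enumerate_unrooted(taxa: list[str]):
    """All unrooted binary topologies on ``taxa`` as dendropy trees.

    Unrooted trees on n taxa biject with rooted binary trees on n-1 taxa
    (re-attach the first taxon at the root), and rooted trees are enumerated
    canonically: the smallest element always goes in the left subtree, so
    each unordered split is produced exactly once.
    """
    rest = tuple(sorted(taxa[1:]))

    def rooted(subset: tuple[str, ...]):
        if len(subset) == 1:
            yield subset[0]
            return
        pivot, others = subset[0], subset[1:]
        for r in range(len(others)):
            for side in itertools.combinations(others, r):
                left = (pivot,) + side
                right = tuple(x for x in others if x not in side)
                for lt in rooted(left):
                    for rt in rooted(right):
                        yield f"({lt},{rt})"

    for sub in rooted(rest):
        yield m.tree_from_newick(f"({taxa[0]},{sub});", rooted=False)


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

FIG4_NEWICK = "(((mid__a1,(col__x1,col__x2)),((wbg__b1,cae__y1),mid__a2)),amb__z1);"
FIG4_EXPECTED = "(((A-mid,col),((B-wbg,cae),B-mid)),amb);"


@pytest.fixture
def fig4_tree():
    return m.tree_from_newick(FIG4_NEWICK)


@pytest.fixture
def fig4_hypotheses():
    return [
        m.HybridHypothesis("mid", frozenset({"col"}), frozenset({"cae"})),
        m.HybridHypothesis("wbg", frozenset({"col"}), frozenset({"cae"})),
    ]


@pytest.fixture(scope="session")
def demo_setting():
    return m.nymphaeales_demo(unit=5.0)


@pytest.fixture(scope="session")
def demo_dataset(demo_setting):
    """A modest low-ILS dataset shared across tests (60 genes, seed 11)."""
    config = m.SimConfig(
        species_tree=demo_setting.species_tree,
        events=demo_setting.events,
        n_genes=60,
        outgroup=demo_setting.outgroup,
        dup_rate=0.5,
        seed=11,
    )
    return m.simulate_dataset(config)


@pytest.fixture(scope="session")
def demo_mul_trees(demo_setting, demo_dataset):
    out = []
    for tree in demo_dataset.trees:
        mul, log = m.mul_convert(
            tree, demo_setting.hypotheses, demo_setting.outgroup,
            lengths=demo_dataset.lengths,
        )
        out.append((mul, log))
    return out
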
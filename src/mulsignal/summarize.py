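"""Quartet-based coalescent summary of MUL-labeled gene trees.

The summary species tree is the unrooted topology maximizing the quartet
score: the number of (gene tree, 4-taxon subset) pairs whose induced quartet
topology the candidate reproduces.  Quartet-score maximization is the
statistically consistent core of coalescent summary methods (the role ASTRAL
plays in practice); subgenome labels are treated as distinct taxa, so a MUL
reference with ``A-hybrid`` and ``B-hybrid`` tips is summarized directly.

Exact mode enumerates every unrooted topology (feasible to 8 taxa,
(2n-5)!! trees); heuristic mode starts from neighbor joining on
quartet-mismatch distances and hill-climbs with nearest-neighbor
interchanges.  Enumeration order, edge order, and tie-breaks are fixed so
results are reproducible.
"""

from __future__ import annotations

import io
import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import dendropy
import numpy as np

from .treeio import leaf_labels, tree_from_newick
from .mulprune import MulLabeledTree

EXACT_TAXON_LIMIT = 8

# An unrooted tree in the search machinery is an adjacency dict
# {node: tuple(neighbors)} whose leaves are taxon-name strings and whose
# internal nodes are ints, plus an ordered edge list for deterministic
# iteration.
Adjacency = dict


def _as_tree(tree) -> dendropy.Tree:
    return tree.tree if isinstance(tree, MulLabeledTree) else tree


# ---------------------------------------------------------------------------
# quartet tally
# ---------------------------------------------------------------------------

def _topo_distance_matrix(tree: dendropy.Tree, order: Sequence[str]) -> np.ndarray:
    """Pairwise topological (edge-count) leaf distances in the given order."""
    pos = {lbl: i for i, lbl in enumerate(order)}
    n = len(order)
    D = np.zeros((n, n), dtype=np.int32)
    depth_maps: dict = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            depth_maps[node] = {pos[node.taxon.label]: 0}
            continue
        merged: dict[int, int] = {}
        child_maps = [depth_maps.pop(c) for c in node.child_nodes()]
        for i, m1 in enumerate(child_maps):
            for m2 in child_maps[i + 1:]:
                for a, da in m1.items():
                    for b, db in m2.items():
                        d = da + db + 2
                        D[a, b] = d
                        D[b, a] = d
            for a, da in m1.items():
                merged[a] = da + 1
        depth_maps[node] = merged
    return D


def _quartet_votes(order_idx: np.ndarray, D: np.ndarray):
    """Voted quartets of one tree.

    Returns (quads, topo) where ``quads`` is an (m, 4) array of global taxon
    indices in increasing order and ``topo`` the topology index: 0, 1, 2 when
    the smallest taxon pairs with the 2nd, 3rd, 4th respectively.  Quartets
    unresolved by the tree (polytomies) cast no vote.
    """
    m = len(order_idx)
    if m < 4:
        return np.empty((0, 4), dtype=np.int64), np.empty(0, dtype=np.int64)
    combos = np.array(list(itertools.combinations(range(m), 4)), dtype=np.int64)
    a, b, c, d = combos[:, 0], combos[:, 1], combos[:, 2], combos[:, 3]
    S = np.stack([D[a, b] + D[c, d], D[a, c] + D[b, d], D[a, d] + D[b, c]])
    topo = np.argmin(S, axis=0)
    resolved = (S == S.min(axis=0)).sum(axis=0) == 1
    quads = order_idx[combos[resolved]]
    return quads, topo[resolved]


class QuartetTally:
    """Counts of the three unrooted topologies for every 4-taxon subset."""

    def __init__(self, taxa: Sequence[str]):
        self.taxa = tuple(sorted(set(taxa)))
        self.index = {t: i for i, t in enumerate(self.taxa)}
        n = len(self.taxa)
        self._rank = {q: r for r, q in
                      enumerate(itertools.combinations(range(n), 4))}
        self.counts = np.zeros((len(self._rank), 3), dtype=np.int64)
        self.n_trees = 0

    @classmethod
    def from_trees(cls, gene_trees: Sequence) -> "QuartetTally":
        trees = [_as_tree(t) for t in gene_trees]
        taxa = sorted({lbl for t in trees for lbl in leaf_labels(t)})
        tally = cls(taxa)
        for tree in trees:
            tally.add_tree(tree)
        return tally

    def add_tree(self, tree: dendropy.Tree) -> None:
        order = sorted(set(leaf_labels(tree)), key=lambda l: self.index[l])
        D = _topo_distance_matrix(tree, order)
        order_idx = np.array([self.index[l] for l in order], dtype=np.int64)
        quads, topo = _quartet_votes(order_idx, D)
        if len(quads):
            rows = np.fromiter(
                (self._rank[tuple(q)] for q in quads), dtype=np.int64,
                count=len(quads),
            )
            np.add.at(self.counts, (rows, topo), 1)
        self.n_trees += 1

    def count(self, quad: tuple[int, int, int, int], topo: int) -> int:
        return int(self.counts[self._rank[quad], topo])


# ---------------------------------------------------------------------------
# adjacency trees
# ---------------------------------------------------------------------------

def _adj_from_dendropy(tree: dendropy.Tree) -> tuple[Adjacency, list]:
    adj: Adjacency = {}
    ids: dict = {}
    next_id = [0]

    def node_key(node):
        if node.is_leaf():
            return node.taxon.label
        if node not in ids:
            ids[node] = next_id[0]
            next_id[0] += 1
        return ids[node]

    edges = []
    for node in tree.preorder_node_iter():
        for child in node.child_nodes():
            u, v = node_key(node), node_key(child)
            adj.setdefault(u, []).append(v)
            adj.setdefault(v, []).append(u)
            edges.append((u, v))
    # suppress a degree-2 root so the structure is properly unrooted
    changed = True
    while changed:
        changed = False
        for node, nbrs in list(adj.items()):
            if isinstance(node, int) and len(nbrs) == 2:
                a, b = nbrs
                adj[a] = [x if x != node else b for x in adj[a]]
                adj[b] = [x if x != node else a for x in adj[b]]
                del adj[node]
                edges = [e for e in edges if node not in e] + [(a, b)]
                changed = True
                break
    return adj, edges


def _adj_to_dendropy(adj: Adjacency) -> dendropy.Tree:
    """Canonical serialization: anchored at the smallest leaf's neighbor,
    subtrees ordered by their smallest leaf, so isomorphic adjacencies give
    byte-identical newick regardless of internal node numbering."""
    leaves = sorted(n for n in adj if isinstance(n, str))
    if len(adj) == 1:
        return tree_from_newick(f"({leaves[0]});", rooted=False)
    anchor = leaves[0]
    start = adj[anchor][0] if adj[anchor] else anchor

    def write(node, parent) -> tuple[str, str]:
        nbrs = [x for x in adj[node] if x != parent]
        if not nbrs:
            return str(node), str(node)
        parts = sorted((write(x, node) for x in nbrs), key=lambda p: p[1])
        text = "(" + ",".join(p[0] for p in parts) + ")"
        return text, min(p[1] for p in parts)

    text, _ = write(start, None)
    return tree_from_newick(text + ";", rooted=False)


def _adj_distances(adj: Adjacency, order: Sequence[str]) -> np.ndarray:
    pos = {lbl: i for i, lbl in enumerate(order)}
    n = len(order)
    D = np.zeros((n, n), dtype=np.int32)
    for src in order:
        dist = {src: 0}
        frontier = [src]
        while frontier:
            nxt = []
            for u in frontier:
                for v in adj[u]:
                    if v not in dist:
                        dist[v] = dist[u] + 1
                        nxt.append(v)
            frontier = nxt
        for lbl in order:
            D[pos[src], pos[lbl]] = dist[lbl]
    return D


def _score_adj(adj: Adjacency, tally: QuartetTally) -> int:
    order = sorted((n for n in adj if isinstance(n, str)),
                   key=lambda l: tally.index[l])
    D = _adj_distances(adj, order)
    order_idx = np.array([tally.index[l] for l in order], dtype=np.int64)
    quads, topo = _quartet_votes(order_idx, D)
    if not len(quads):
        return 0
    rows = np.fromiter((tally._rank[tuple(q)] for q in quads),
                       dtype=np.int64, count=len(quads))
    return int(tally.counts[rows, topo].sum())


def quartet_score(candidate, gene_trees_or_tally) -> int:
    """Number of (gene tree, 4-subset) pairs agreeing with the candidate."""
    tally = (gene_trees_or_tally
             if isinstance(gene_trees_or_tally, QuartetTally)
             else QuartetTally.from_trees(gene_trees_or_tally))
    cand = _as_tree(candidate)
    missing = set(leaf_labels(cand)) - set(tally.taxa)
    if missing:
        raise ValueError(f"candidate taxa absent from gene trees: {sorted(missing)}")
    adj, _ = _adj_from_dendropy(cand)
    return _score_adj(adj, tally)


# ---------------------------------------------------------------------------
# exact enumeration
# ---------------------------------------------------------------------------

def enumerate_topologies(taxa: Sequence[str]):
    """All unrooted topologies on the taxa by deterministic stepwise addition.

    Taxa are added in sorted order; each new leaf is tried on every existing
    edge in creation order, giving (2n-5)!! trees in a fixed sequence.
    """
    taxa = sorted(taxa)
    if len(taxa) < 3:
        raise ValueError("need >=3 taxa to enumerate topologies")
    base_adj = {0: list(taxa[:3])}
    for t in taxa[:3]:
        base_adj[t] = [0]
    base_edges = [(0, t) for t in taxa[:3]]
    stack = [(base_adj, base_edges, 3, 1)]
    while stack:
        adj, edges, k, next_internal = stack.pop()
        if k == len(taxa):
            yield adj
            continue
        leaf = taxa[k]
        for u, v in edges:
            new_adj = {n: list(nb) for n, nb in adj.items()}
            w = next_internal
            new_adj[u] = [x if x != v else w for x in new_adj[u]]
            new_adj[v] = [x if x != u else w for x in new_adj[v]]
            new_adj[w] = [u, v, leaf]
            new_adj[leaf] = [w]
            new_edges = [e for e in edges if e != (u, v)]
            new_edges += [(u, w), (w, v), (w, leaf)]
            stack.append((new_adj, new_edges, k + 1, next_internal + 1))


# ---------------------------------------------------------------------------
# heuristic search: NJ start + NNI hill climbing
# ---------------------------------------------------------------------------

def _quartet_mismatch_distances(tally: QuartetTally) -> np.ndarray:
    """d(i,j): fraction of quartet votes on subsets holding i,j that separate them."""
    n = len(tally.taxa)
    together = np.zeros((n, n))
    total = np.zeros((n, n))
    for quad, row in tally._rank.items():
        counts = tally.counts[row]
        s = counts.sum()
        if s == 0:
            continue
        i, j, k, l = quad
        pairs = [((i, j), (k, l), 0), ((i, k), (j, l), 1), ((i, l), (j, k), 2)]
        for (a, b), (c, d), topo in pairs:
            together[a, b] += counts[topo]
            together[c, d] += counts[topo]
        for a, b in itertools.combinations(quad, 2):
            total[a, b] += s
    D = np.zeros((n, n))
    for a in range(n):
        for b in range(a + 1, n):
            t = total[a, b]
            d = 1.0 - together[a, b] / t if t else 1.0
            D[a, b] = D[b, a] = d
    return D


def _nj_start(tally: QuartetTally) -> Adjacency:
    D = _quartet_mismatch_distances(tally)
    names = list(tally.taxa)
    buf = io.StringIO()
    buf.write("." + "".join(f",{n}" for n in names) + "\n")
    for i, n in enumerate(names):
        buf.write(n + "".join(f",{D[i, j]}" for j in range(len(names))) + "\n")
    buf.seek(0)
    pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(buf, delimiter=",")
    nj = pdm.nj_tree()
    adj, _ = _adj_from_dendropy(nj)
    return adj


def _internal_edges(adj: Adjacency):
    out = []
    for u in sorted((n for n in adj if isinstance(n, int))):
        for v in adj[u]:
            if isinstance(v, int) and u < v:
                out.append((u, v))
    return out


def _nni_neighbors(adj: Adjacency):
    """The two nearest-neighbor-interchange rearrangements per internal edge."""
    for u, v in _internal_edges(adj):
        a_side = [x for x in adj[u] if x != v]
        b_side = [x for x in adj[v] if x != u]
        if len(a_side) != 2 or len(b_side) != 2:
            continue  # polytomy: skip (inputs to the search are binary)
        a2 = a_side[1]
        for b in b_side:
            new_adj = {n: list(nb) for n, nb in adj.items()}
            new_adj[u] = [x if x != a2 else b for x in new_adj[u]]
            new_adj[v] = [x if x != b else a2 for x in new_adj[v]]
            new_adj[a2] = [x if x != u else v for x in new_adj[a2]]
            new_adj[b] = [x if x != v else u for x in new_adj[b]]
            yield new_adj


def _bipartitions_adj(adj: Adjacency) -> list[frozenset[str]]:
    """One side (the one not holding the first taxon) of each internal split."""
    leaves = sorted(n for n in adj if isinstance(n, str))
    first = leaves[0]
    sides = []
    for u, v in _internal_edges(adj):
        # leaves reachable from v without crossing u
        seen = {u, v}
        frontier = [v]
        side = set()
        while frontier:
            x = frontier.pop()
            for y in adj[x]:
                if y in seen:
                    continue
                seen.add(y)
                if isinstance(y, str):
                    side.add(y)
                else:
                    frontier.append(y)
        if first in side:
            side = set(leaves) - side
        if 2 <= len(side) <= len(leaves) - 2:
            sides.append(frozenset(side))
    return sides


def _branch_fractions(adj: Adjacency, tally: QuartetTally) -> dict[frozenset[str], Optional[float]]:
    leaves = sorted(n for n in adj if isinstance(n, str))
    all_set = set(leaves)
    out: dict[frozenset[str], Optional[float]] = {}
    for side in _bipartitions_adj(adj):
        other = sorted(all_set - side)
        agree = 0
        total = 0
        for a, b in itertools.combinations(sorted(side), 2):
            ia, ib = tally.index[a], tally.index[b]
            for c, d in itertools.combinations(other, 2):
                ic, id_ = tally.index[c], tally.index[d]
                quad = tuple(sorted((ia, ib, ic, id_)))
                counts = tally.counts[tally._rank[quad]]
                total += int(counts.sum())
                # topology pairing the two smallest-side members together
                i, j, k, l = quad
                if {i, j} <= {ia, ib} or {i, j} <= {ic, id_}:
                    topo = 0
                elif {i, k} <= {ia, ib} or {i, k} <= {ic, id_}:
                    topo = 1
                else:
                    topo = 2
                agree += int(counts[topo])
        out[side] = agree / total if total else None
    return out


@dataclass
class SummaryResult:
    """Inferred summary topology with its quartet score and branch support."""

    tree: dendropy.Tree
    score: int
    branch_fractions: dict[frozenset[str], Optional[float]]
    mode: str
    tie: bool = False
    note: Optional[str] = None

    def annotated_newick(self) -> str:
        annotated = self.tree.clone(depth=1)
        all_leaves = frozenset(leaf_labels(annotated))
        for node in annotated.preorder_node_iter():
            if node.is_leaf() or node.parent_node is None:
                continue
            side = frozenset(lf.taxon.label for lf in node.leaf_iter())
            frac = self.branch_fractions.get(side)
            if frac is None:
                frac = self.branch_fractions.get(all_leaves - side)
            if frac is not None:
                node.label = f"{frac:.3f}"
        from .treeio import tree_to_newick
        return tree_to_newick(annotated)


def infer_summary_tree(
    gene_trees: Sequence,
    mode: str = "heuristic",
    tally: Optional[QuartetTally] = None,
) -> SummaryResult:
    """Infer the quartet-score-maximizing summary topology.

    ``mode="exact"`` enumerates all unrooted topologies (requires <=8 taxa);
    ``mode="heuristic"`` runs NJ + NNI hill climbing.  Ties in exact mode are
    broken toward the first topology in enumeration order and reported.
    """
    if mode not in ("exact", "heuristic"):
        raise ValueError(f"unknown mode {mode!r}")
    if tally is None:
        if not gene_trees:
            raise ValueError("need at least one gene tree")
        tally = QuartetTally.from_trees(gene_trees)
    taxa = tally.taxa
    if len(taxa) < 4:
        star = tree_from_newick("(" + ",".join(taxa) + ");", rooted=False)
        return SummaryResult(tree=star, score=0, branch_fractions={},
                             mode=mode, note="fewer than 4 taxa: star tree")

    if mode == "exact":
        if len(taxa) > EXACT_TAXON_LIMIT:
            raise ValueError(
                f"exact mode supports <= {EXACT_TAXON_LIMIT} taxa "
                f"(got {len(taxa)}); use heuristic mode"
            )
        best_adj, best_score, tie = None, -1, False
        for adj in enumerate_topologies(taxa):
            s = _score_adj(adj, tally)
            if s > best_score:
                best_adj, best_score, tie = adj, s, False
            elif s == best_score:
                tie = True
        note = "tie: multiple topologies share the maximum score" if tie else None
        return SummaryResult(
            tree=_adj_to_dendropy(best_adj), score=best_score,
            branch_fractions=_branch_fractions(best_adj, tally),
            mode=mode, tie=tie, note=note,
        )

    adj = _nj_start(tally)
    score = _score_adj(adj, tally)
    improved = True
    while improved:
        improved = False
        best_n, best_s = None, score
        for cand in _nni_neighbors(adj):
            s = _score_adj(cand, tally)
            if s > best_s:
                best_n, best_s = cand, s
        if best_n is not None:
            adj, score = best_n, best_s
            improved = True
    return SummaryResult(
        tree=_adj_to_dendropy(adj), score=score,
        branch_fractions=_branch_fractions(adj, tally),
        mode="heuristic",
    )
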
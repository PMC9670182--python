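"""Coalescent simulation of multi-copy gene family trees with allopolyploidy.

The generator takes an ultrametric species tree with branch lengths in
coalescent units (time divided by 2N; population size is implicitly one per
branch) and one allopolyploidy event per hybrid taxon.  Each event attaches
the hybrid twice to the species tree — subgenome A on the A-donor's branch
and subgenome B on the B-donor's branch, both at the hybridization time —
yielding a MUL species tree.  Gene trees are then drawn under the
multispecies coalescent: one haploid lineage per MUL tip (so each hybrid
contributes one gene copy per subgenome), lineages coalescing within each
branch as a Kingman coalescent with pairwise rate 1 and uniform pair choice.
Paralogs are injected by grafting subtree copies, tips optionally drop out
(never the outgroup), and per-tip sequence lengths are drawn from a normal
distribution.  A machine-readable truth record ties every hybrid copy to its
subgenome and every injected paralog to its parent gene.

Randomness contract: numpy ``Generator`` (PCG64) seeded through
``SeedSequence(seed, spawn_key=(gene_index, stage))``, so each gene's output
is independent of ``n_genes`` and every dataset is reproducible bit-for-bit
from its config.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import dendropy
import numpy as np

from .treeio import tree_from_newick, tree_to_newick, leaf_labels
from .mulprune import HybridHypothesis

DEFAULT_MUL_PREFIXES = ("A-", "B-")


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class AllopolyploidyEvent:
    """One hybrid taxon plus its two donor lineages and hybridization time.

    ``t_hyb`` (coalescent units before present) must be non-negative and
    younger than each donor's parent node.
    """

    hybrid: str
    donor_A: str
    donor_B: str
    t_hyb: float

    def __post_init__(self):
        if self.t_hyb < 0:
            raise SimulationError(f"event {self.hybrid}: t_hyb < 0")
        if self.donor_A == self.donor_B:
            raise SimulationError(f"event {self.hybrid}: identical donors")


@dataclass
class SimTruthRecord:
    """Everything the simulator knows that the pipeline must rediscover."""

    mul_tree_newick: str
    events: list[AllopolyploidyEvent]
    # per gene index: {"subgenome": {gene_id: "A"|"B"}, "paralog_parent": {child: parent}}
    per_gene: dict[int, dict] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "mul_tree": self.mul_tree_newick,
                "events": [vars(e) for e in self.events],
                "per_gene": {
                    str(i): rec for i, rec in sorted(self.per_gene.items())
                },
            },
            indent=2,
        )


@dataclass
class SimConfig:
    """Generator settings; defaults match the low-ILS study conditions."""

    species_tree: str  # newick, branch lengths in coalescent units
    events: list[AllopolyploidyEvent]
    n_genes: int
    outgroup: frozenset[str] = frozenset()
    dup_rate: float = 0.5
    missing_rate: float = 0.0
    length_mean: float = 1000.0
    length_sd: float = 200.0
    bias_true_ortholog_longest: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 0:
            raise SimulationError("n_genes must be >= 0")
        if self.dup_rate < 0 or self.missing_rate < 0:
            raise SimulationError("rates must be >= 0")
        if not (0 <= self.missing_rate < 1):
            raise SimulationError("missing_rate must lie in [0, 1)")
        if self.length_mean <= 0 or self.length_sd < 0:
            raise SimulationError("length distribution must be positive")
        tree = tree_from_newick(self.species_tree, rooted=True)
        build_mul_species_tree(tree, self.events)  # raises on invalid events


# ---------------------------------------------------------------------------
# species-tree machinery
# ---------------------------------------------------------------------------

def node_ages(tree: dendropy.Tree, tol: float = 1e-6) -> dict[dendropy.Node, float]:
    """Ages (time before present) of every node of an ultrametric tree."""
    ages: dict[dendropy.Node, float] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            ages[node] = 0.0
            continue
        child_tops = [
            ages[c] + (c.edge.length if c.edge.length is not None else 0.0)
            for c in node.child_nodes()
        ]
        if max(child_tops) - min(child_tops) > tol * max(1.0, max(child_tops)):
            raise SimulationError(
                f"species tree is not ultrametric at node "
                f"{sorted(l.taxon.label for l in node.leaf_iter())[:3]}"
            )
        ages[node] = float(np.mean(child_tops))
    return ages


def build_mul_species_tree(
    tree: dendropy.Tree,
    events: AllopolyploidyEvent | Iterable[AllopolyploidyEvent],
    prefixes: tuple[str, str] = DEFAULT_MUL_PREFIXES,
) -> dendropy.Tree:
    """Attach each hybrid twice, producing the MUL species tree.

    Subgenome A attaches on the A-donor's terminal branch at ``t_hyb`` and
    subgenome B on the B-donor's; all other structure is unchanged.  Events
    are applied in the given order; each must fit below its donor's parent
    node in the original tree.
    """
    if isinstance(events, AllopolyploidyEvent):
        events = [events]
    t = tree.clone(depth=1)
    t.is_rooted = True
    for event in events:
        for donor, prefix in ((event.donor_A, prefixes[0]),
                              (event.donor_B, prefixes[1])):
            ages = node_ages(t)
            leaf = next((lf for lf in t.leaf_node_iter()
                         if lf.taxon.label == donor), None)
            if leaf is None:
                raise SimulationError(
                    f"event {event.hybrid}: donor {donor!r} not a leaf"
                )
            # find the edge on the donor's root path spanning t_hyb
            node = leaf
            while (node.parent_node is not None
                   and ages[node.parent_node] <= event.t_hyb):
                node = node.parent_node
            parent = node.parent_node
            if parent is None:
                raise SimulationError(
                    f"event {event.hybrid}: t_hyb={event.t_hyb} is older "
                    f"than donor {donor!r}'s root path"
                )
            # split the edge at t_hyb and hang the hybrid tip there
            attach = parent.new_child()
            attach.edge.length = ages[parent] - event.t_hyb
            hyb = attach.new_child()
            hyb.taxon = dendropy.Taxon(label=prefix + event.hybrid)
            t.taxon_namespace.add_taxon(hyb.taxon)
            hyb.edge.length = event.t_hyb
            parent.remove_child(node)
            attach.add_child(node)
            node.edge.length = event.t_hyb - ages[node]
    return t


# ---------------------------------------------------------------------------
# gene-tree simulation
# ---------------------------------------------------------------------------

def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass
class _Lineage:
    node: dendropy.Node
    height: float


def simulate_gene_tree(
    mul_tree: dendropy.Tree,
    seed,
    gene_prefix: str = "g0",
    prefixes: tuple[str, str] = DEFAULT_MUL_PREFIXES,
    delimiter: str = "__",
) -> tuple[dendropy.Tree, dict[str, str]]:
    """One gene tree under the multispecies coalescent on the MUL tree.

    Each MUL tip contributes one lineage; the two subgenome tips of a hybrid
    emit copies of the *hybrid* taxon with distinct gene ids, and the returned
    truth dict maps those gene ids to their subgenome (``"A"``/``"B"``).
    Branch lengths of the output are coalescent times (the tree is
    ultrametric).  The same seed always yields the identical tree.
    """
    rng = _rng(seed)
    ages = node_ages(mul_tree)
    truth: dict[str, str] = {}
    counter = [0]

    def new_leaf(species: str) -> dendropy.Node:
        gid = f"{gene_prefix}_{counter[0]}"
        counter[0] += 1
        node = dendropy.Node()
        node.taxon = dendropy.Taxon(label=f"{species}{delimiter}{gid}")
        return node, gid

    def coalesce_in(lineages: list[_Lineage], lower: float, upper: float
                    ) -> list[_Lineage]:
        t = lower
        lineages = list(lineages)
        while len(lineages) >= 2:
            k = len(lineages)
            t += rng.exponential(1.0 / (k * (k - 1) / 2.0))
            if t >= upper:
                break
            i, j = sorted(rng.choice(k, size=2, replace=False))
            a = lineages.pop(j)
            b = lineages.pop(i)
            parent = dendropy.Node()
            for lin in (b, a):
                parent.add_child(lin.node)
                lin.node.edge.length = t - lin.height
            lineages.append(_Lineage(parent, t))
        return lineages

    def lineages_at_top(sp_node: dendropy.Node) -> list[_Lineage]:
        if sp_node.is_leaf():
            label = sp_node.taxon.label
            species = label
            sub = None
            for prefix, code in zip(prefixes, ("A", "B")):
                if label.startswith(prefix):
                    species = label[len(prefix):]
                    sub = code
                    break
            node, gid = new_leaf(species)
            if sub is not None:
                truth[gid] = sub
            incoming = [_Lineage(node, 0.0)]
            lower = 0.0
        else:
            incoming = []
            for child in sp_node.child_nodes():
                incoming.extend(lineages_at_top(child))
            lower = ages[sp_node]
        if sp_node.parent_node is None:
            return coalesce_in(incoming, lower, math.inf)
        return coalesce_in(incoming, lower, ages[sp_node.parent_node])

    remaining = lineages_at_top(mul_tree.seed_node)
    assert len(remaining) == 1
    root = remaining[0].node
    gene_tree = dendropy.Tree(seed_node=root)
    gene_tree.is_rooted = True
    for leaf in gene_tree.leaf_node_iter():
        gene_tree.taxon_namespace.add_taxon(leaf.taxon)
    return gene_tree, truth


def inject_paralogs(
    gene_tree: dendropy.Tree,
    dup_rate: float,
    seed,
    gene_prefix: str = "d0",
    delimiter: str = "__",
) -> tuple[dendropy.Tree, dict[str, str]]:
    """Graft Poisson(dup_rate) duplicate subtrees as sisters of random edges.

    Each duplication picks a uniform random edge and grafts a copy of the
    subtree below it, with fresh gene ids, as its sister at the edge
    midpoint.  Returns the expanded tree and a map of each fresh gene id to
    the gene id it was copied from.  Restricting the output to the original
    tips recovers the input tree exactly.
    """
    if dup_rate < 0:
        raise SimulationError("dup_rate must be >= 0")
    rng = _rng(seed)
    n_dup = int(rng.poisson(dup_rate))
    t = gene_tree.clone(depth=1)
    t.is_rooted = True
    parent_map: dict[str, str] = {}
    counter = [0]

    def copy_subtree(node: dendropy.Node) -> dendropy.Node:
        new = dendropy.Node()
        new.edge.length = node.edge.length
        if node.is_leaf():
            species, gid = node.taxon.label.split(delimiter, 1)
            new_gid = f"{gene_prefix}_{counter[0]}"
            counter[0] += 1
            parent_map[new_gid] = gid
            new.taxon = dendropy.Taxon(label=f"{species}{delimiter}{new_gid}")
            t.taxon_namespace.add_taxon(new.taxon)
        for child in node.child_nodes():
            new.add_child(copy_subtree(child))
        return new

    for _ in range(n_dup):
        edges = [nd.edge for nd in t.preorder_node_iter()
                 if nd.parent_node is not None]
        edge = edges[int(rng.integers(len(edges)))]
        child = edge.head_node
        parent = edge.tail_node
        length = edge.length if edge.length is not None else 0.0
        dup = copy_subtree(child)
        joint = dendropy.Node()
        joint.edge.length = length / 2.0
        parent.remove_child(child)
        parent.add_child(joint)
        joint.add_child(child)
        child.edge.length = length / 2.0
        dup.edge.length = length / 2.0
        joint.add_child(dup)
    return t, parent_map


# ---------------------------------------------------------------------------
# dataset assembly
# ---------------------------------------------------------------------------

@dataclass
class SimDataset:
    trees: list[dendropy.Tree]
    lengths: dict[str, int]
    truth: SimTruthRecord


def simulate_dataset(config: SimConfig) -> SimDataset:
    """Generate the full synthetic dataset described by ``config``.

    Per gene: coalescent simulation on the MUL species tree, paralog
    injection, tip dropout (outgroup tips are never dropped), and length
    assignment.  Each gene uses its own RNG substreams spawned from
    ``(config.seed, gene_index, stage)``, so outputs are deterministic and
    per-gene independent of ``n_genes``.
    """
    config.validate()
    species_tree = tree_from_newick(config.species_tree, rooted=True)
    mul_tree = build_mul_species_tree(species_tree, config.events)
    truth = SimTruthRecord(
        mul_tree_newick=tree_to_newick(mul_tree), events=list(config.events)
    )
    trees: list[dendropy.Tree] = []
    lengths: dict[str, int] = {}
    for i in range(config.n_genes):
        streams = [
            np.random.default_rng(
                np.random.SeedSequence(entropy=config.seed, spawn_key=(i, s))
            )
            for s in range(4)
        ]
        coal_rng, dup_rng, drop_rng, len_rng = streams
        gt, subgenome = simulate_gene_tree(
            mul_tree, coal_rng, gene_prefix=f"g{i}"
        )
        gt, parent_map = inject_paralogs(
            gt, config.dup_rate, dup_rng, gene_prefix=f"d{i}"
        )
        # duplicated hybrid copies inherit their parent's subgenome
        for child, parent in parent_map.items():
            if parent in subgenome:
                subgenome[child] = subgenome[parent]

        if config.missing_rate > 0:
            labels = leaf_labels(gt)
            keep = []
            for lbl in labels:
                species = lbl.split("__", 1)[0]
                if species in config.outgroup:
                    keep.append(lbl)
                elif drop_rng.random() >= config.missing_rate:
                    keep.append(lbl)
            if len(keep) >= 3:
                from .treeio import restrict
                gt = restrict(gt, keep)

        originals = set()
        for lbl in leaf_labels(gt):
            gid = lbl.split("__", 1)[1]
            if gid not in parent_map:
                originals.add(gid)
            raw = len_rng.normal(config.length_mean, config.length_sd)
            if config.bias_true_ortholog_longest and gid in originals:
                raw += 4.0 * config.length_sd
            lengths[gid] = max(1, int(round(raw)))

        gt.label = f"gene{i}"
        trees.append(gt)
        truth.per_gene[i] = {
            "subgenome": subgenome, "paralog_parent": parent_map
        }
    return SimDataset(trees=trees, lengths=lengths, truth=truth)


def write_length_table(lengths: dict[str, int], path) -> None:
    with open(path, "w") as fh:
        for gid in sorted(lengths):
            fh.write(f"{gid}\t{lengths[gid]}\n")


# ---------------------------------------------------------------------------
# the water-lily-style demonstration setting
# ---------------------------------------------------------------------------

def ultrametric_from_topology(
    newick: str, unit: float = 5.0, extra_leaf_depth: float = 2.0
) -> str:
    """Assign ultrametric branch lengths so every internal branch >= unit.

    Each internal node's age is ``unit`` times its internal height (levels of
    internal nodes below it) plus ``extra_leaf_depth`` units, so internal
    branches are at least one unit long and terminal branches at least
    ``1 + extra_leaf_depth`` units.  The extra terminal depth leaves room to
    attach hybrid tips on donor branches without creating internal branches
    shorter than a unit (which would silently reintroduce ILS into a
    nominally low-ILS setting).
    """
    tree = tree_from_newick(newick, rooted=True)
    age: dict[dendropy.Node, float] = {}
    height: dict[dendropy.Node, int] = {}
    for node in tree.postorder_node_iter():
        height[node] = (0 if node.is_leaf()
                        else 1 + max(height[c] for c in node.child_nodes()))
    for node in tree.postorder_node_iter():
        age[node] = 0.0 if node.is_leaf() else unit * (height[node] + extra_leaf_depth)
    for node in tree.postorder_node_iter():
        if node.parent_node is not None:
            node.edge.length = age[node.parent_node] - age[node]
    return tree_to_newick(tree)


@dataclass
class DemoSetting:
    """A ready-to-run study setting: tree, events, groups, hypotheses."""

    species_tree: str
    events: list[AllopolyploidyEvent]
    outgroup: frozenset[str]
    hypotheses: list[HybridHypothesis]
    groups: dict[str, frozenset[str]]
    taxa: frozenset[str]


#: 16 sampled non-hybrid taxa in a water-lily-like arrangement: an outgroup
#: (amb), a two-taxon sister family (cab, bra), an early-diverging genus pair
#: (nup_*), then successively diverging subgenera with the hybrid parents
#: (col, cae) sister to the remaining crown clades.
_DEMO_TOPOLOGY = (
    "(amb,((cab,bra),((nup_lut,nup_adv),((nym_tet,nym_mex),"
    "((gig_alb,gig_hyb),((col,cae),((vic,eur),(rub,(pot,pro)))))))));"
)


def nymphaeales_demo(
    unit: float = 5.0,
    t_frac_mid: float = 1.0,
    t_frac_wbg: float = 2.0,
) -> DemoSetting:
    """The 18-taxon demonstration setting: 16 species plus two hybrid
    cultivars (``mid``, ``wbg``) sharing donors ``col`` (subgenome A) and
    ``cae`` (subgenome B).

    ``unit`` scales every internal branch (coalescent units): 5.0 gives the
    low-ILS regime, 0.5 a moderate-ILS regime.  Donor terminal branches are
    three units deep and the two hybrids attach one and two units before
    present, so every internal branch of the resulting MUL species tree —
    including the segments between the attachment points — is at least one
    full unit long.
    """
    species_tree = ultrametric_from_topology(_DEMO_TOPOLOGY, unit=unit)
    events = [
        AllopolyploidyEvent("mid", "col", "cae", t_frac_mid * unit),
        AllopolyploidyEvent("wbg", "col", "cae", t_frac_wbg * unit),
    ]
    hypotheses = [
        HybridHypothesis("mid", frozenset({"col"}), frozenset({"cae"})),
        HybridHypothesis("wbg", frozenset({"col"}), frozenset({"cae"})),
    ]
    groups = {
        "a": frozenset({"col", "mid"}),
        "b": frozenset({"cae", "wbg"}),
        "c": frozenset({"gig_alb", "gig_hyb"}),
        "d": frozenset({"nym_mex", "nym_tet"}),
        "e": frozenset({"pot", "pro", "rub"}),
        "f": frozenset({"vic", "eur"}),
        "g": frozenset({"nup_lut", "nup_adv"}),
        "h": frozenset({"cab", "bra"}),
        "i": frozenset({"amb"}),
    }
    taxa = frozenset().union(*groups.values())
    return DemoSetting(
        species_tree=species_tree,
        events=events,
        outgroup=frozenset({"amb"}),
        hypotheses=hypotheses,
        groups=groups,
        taxa=taxa,
    )
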